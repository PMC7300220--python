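"""Pearson chi-squared tests of Hardy-Weinberg equilibrium for biallelic variants.

Under random mating a biallelic locus with allele frequency p has expected
genotype proportions (p^2, 2p(1-p), (1-p)^2).  The test compares observed
genotype tallies with those expectations by the Pearson chi-squared
statistic on 1 degree of freedom, with no continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

__all__ = ["GenotypeCounts", "HWETestResult", "hwe_test", "hwe_table"]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies for one biallelic variant (AA / Aa / aa)."""

    variant: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        counts = (self.n_hom_ref, self.n_het, self.n_hom_alt)
        if any(c < 0 or c != int(c) for c in counts):
            raise ValueError(f"{self.variant}: counts must be non-negative integers")
        if sum(counts) < 1:
            raise ValueError(f"{self.variant}: total count must be >= 1")

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def allele_freq(self) -> float:
        """Frequency of the reference allele, p = (2*n_AA + n_Aa) / 2n."""
        return (2 * self.n_hom_ref + self.n_het) / (2 * self.n)


@dataclass(frozen=True)
class HWETestResult:
    variant: str
    chi2: float
    df: int
    p_value: float
    monomorphic: bool = False
    significant: bool | None = None


def hwe_test(counts: GenotypeCounts) -> HWETestResult:
    """Pearson chi-squared HWE test for one variant.

    A monomorphic variant (p = 0 or 1) fits its degenerate expectation
    perfectly and is reported with chi2 = 0, P = 1 and a flag.
    """
    n = counts.n
    p = counts.allele_freq
    if p in (0.0, 1.0):
        return HWETestResult(counts.variant, 0.0, 1, 1.0, monomorphic=True)
    q = 1.0 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (counts.n_hom_ref, counts.n_het, counts.n_hom_alt)
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HWETestResult(counts.variant, float(stat), 1, float(chi2.sf(stat, 1)))


def hwe_table(variants: list[GenotypeCounts], alpha: float = 0.05) -> list[HWETestResult]:
    """HWE tests for a list of variants, flagged significant at P < alpha."""
    if not variants:
        raise ValueError("at least one variant required")
    results = []
    for counts in variants:
        r = hwe_test(counts)
        results.append(
            HWETestResult(r.variant, r.chi2, r.df, r.p_value, r.monomorphic,
                          significant=r.p_value < alpha)
        )
    return results
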
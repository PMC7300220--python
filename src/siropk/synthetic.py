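"""Synthetic paediatric TDM cohorts with the model's variability structure.

Emulates the kind of data the analysis assumes: a small cohort of children
(weights log-uniform over 10-50 kg by default), oral sirolimus dosed to
steady state, and sparse concentration sampling — either trough-only
(mirroring routine therapeutic drug monitoring, the default) or a rich
post-dose design (needed when absorption-phase information matters; note
trough-only data cannot identify Ka, which is why Ka is fixed).

Observations are generated under the hierarchical model exactly: one
log-normal random-effect pair per subject shared across that subject's
samples, and an independent combined proportional + additive residual per
sample, truncated at zero.  Every generator is a pure function of its spec
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import Dataset, SubjectData
from .hwe import GenotypeCounts
from .model import PopulationModel
from .pk import DoseEvent, Regimen, concentration_profile, individual_params

__all__ = [
    "CohortSpec",
    "RICH_SAMPLE_OFFSETS",
    "generate_cohort",
    "simulate_observations",
    "generate_genotypes",
]

#: post-dose sampling offsets (h) for the rich design: absorption phase,
#: distribution, and the pre-dose trough of the next interval
RICH_SAMPLE_OFFSETS = (0.5, 1.0, 2.0, 4.0, 8.0, 23.5)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    ``design`` is ``"trough"`` (``n_occasions`` pre-dose samples on
    consecutive dosing occasions once at steady state) or ``"rich"``
    (samples at ``rich_offsets`` hours after a steady-state dose).  Dosing
    histories span at least ``washin_half_lives`` typical elimination
    half-lives before the first sample.
    """

    n: int
    seed: int
    weight_range: tuple[float, float] = (10.0, 50.0)
    dose_per_kg_per_day: float = 0.05
    frequency: str = "qd"
    design: str = "trough"
    n_occasions: int = 3
    rich_offsets: tuple[float, ...] = RICH_SAMPLE_OFFSETS
    washin_half_lives: float = 10.0
    covariate_freqs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = self.weight_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid weight range {self.weight_range}")
        if self.design not in ("trough", "rich"):
            raise ValueError(f"design must be 'trough' or 'rich', got {self.design!r}")
        if self.design == "trough" and self.n_occasions < 1:
            raise ValueError("n_occasions must be >= 1")


def generate_cohort(spec: CohortSpec, model: PopulationModel | None = None) -> Dataset:
    """Generate dosing histories, sampling times and covariates (no concentrations).

    Weights are log-uniform over ``spec.weight_range``; the number of
    wash-in doses per subject is set from the subject's typical half-life
    under ``model`` (the final published model by default) so that every
    first sample sits at effective steady state.
    """
    from .model import FINAL_MODEL

    model = model or FINAL_MODEL
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.weight_range
    weights = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n))
    regimen = Regimen(spec.dose_per_kg_per_day, spec.frequency)
    tau = regimen.tau

    # binary covariates (e.g. genotype carrier status), one Bernoulli per subject
    cov_draws = {
        name: rng.binomial(1, p, size=spec.n).astype(float)
        for name, p in spec.covariate_freqs.items()
    }

    subjects = []
    for i in range(spec.n):
        w = float(weights[i])
        params = individual_params(model, w, 0.0, 0.0,
                                   covariates={k: v[i] for k, v in cov_draws.items()})
        n_washin = max(int(np.ceil(spec.washin_half_lives * params.half_life / tau)), 4)
        amount = regimen.amount_per_dose(w)
        if spec.design == "trough":
            n_doses = n_washin + spec.n_occasions
            obs_times = np.array(
                [(n_washin + k) * tau for k in range(spec.n_occasions)], dtype=float
            )
        else:
            n_doses = n_washin + 2  # keep dosing through the sampling interval
            t_ref = n_washin * tau
            obs_times = t_ref + np.asarray(spec.rich_offsets, dtype=float)
        doses = [DoseEvent(time=k * tau, amount=amount) for k in range(n_doses)]
        subjects.append(
            SubjectData(
                id=f"S{i + 1:03d}",
                weight=w,
                doses=doses,
                obs_times=obs_times,
                obs_conc=np.full(obs_times.size, np.nan),
                covariates={k: float(v[i]) for k, v in cov_draws.items()},
            )
        )
    return Dataset(subjects)


def simulate_observations(
    cohort: Dataset, model: PopulationModel, seed: int
) -> Dataset:
    """Fill a cohort's planned samples with model-simulated concentrations.

    Per subject one (eta_cl, eta_v) pair is drawn and shared across all of
    that subject's observations; per observation independent eps1, eps2 are
    applied as OBS = IPRED*(1 + eps1) + eps2, truncated at 0.  The result
    is the exact inverse contract of the estimator: fitting large simulated
    data recovers the generating model.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in cohort:
        eta_cl = rng.normal(0.0, np.sqrt(model.omega2_cl)) if model.omega2_cl > 0 else 0.0
        eta_v = rng.normal(0.0, np.sqrt(model.omega2_v)) if model.omega2_v > 0 else 0.0
        params = individual_params(model, s.weight, eta_cl, eta_v, covariates=s.covariates)
        if s.doses and np.any(s.obs_times < s.doses[0].time):
            import warnings

            warnings.warn(
                f"subject {s.id}: sampling before first dose yields zero concentration",
                stacklevel=2,
            )
        ipred = concentration_profile(params, s.doses, s.obs_times)
        eps1 = rng.normal(0.0, np.sqrt(model.sigma2_prop), size=ipred.size) if model.sigma2_prop > 0 else np.zeros(ipred.size)
        eps2 = rng.normal(0.0, np.sqrt(model.sigma2_add), size=ipred.size) if model.sigma2_add > 0 else np.zeros(ipred.size)
        obs = np.maximum(ipred * (1.0 + eps1) + eps2, 0.0)
        out.append(
            SubjectData(
                id=s.id,
                weight=s.weight,
                doses=list(s.doses),
                obs_times=s.obs_times.copy(),
                obs_conc=obs,
                covariates=dict(s.covariates),
            )
        )
    return Dataset(out)


def generate_genotypes(
    allele_freqs: Mapping[str, float], n: int, seed: int
) -> list[GenotypeCounts]:
    """Multinomial genotype tallies at Hardy-Weinberg proportions.

    ``allele_freqs`` maps variant id to the frequency p of the A allele,
    strictly inside (0, 1); each variant gets an independent multinomial
    draw of size ``n`` over (p^2, 2p(1-p), (1-p)^2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, p in allele_freqs.items():
        if not (0.0 < p < 1.0):
            raise ValueError(f"allele frequency for {name} must be in (0, 1), got {p}")
    rng = np.random.default_rng(seed)
    out = []
    for name, p in allele_freqs.items():
        probs = [p**2, 2 * p * (1 - p), (1 - p) ** 2]
        n_aa, n_het, n_bb = rng.multinomial(n, probs)
        out.append(GenotypeCounts(variant=name, n_hom_ref=int(n_aa), n_het=int(n_het), n_hom_alt=int(n_bb)))
    return out
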
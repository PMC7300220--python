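"""Population-model definition: fixed effects, variances, covariate links.

The hierarchical model is

    P_i   = TV(P) * exp(eta_i),          eta_i ~ N(0, omega^2)        (IIV)
    OBS_j = PRED_j * (1 + eps1) + eps2,  eps ~ N(0, sigma^2)          (residual)

with the typical value TV(P) built from a 70-kg standard value, allometric
weight scaling (exponent 0.75 on CL/F, 1 on V/F) and any retained covariate
multipliers.  omega^2 and sigma^2 are VARIANCES throughout (the reporting
convention of the estimation software this model family comes from).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = ["CovariateSpec", "PopulationModel", "FINAL_MODEL"]

_FORMS = ("genotype", "power", "linear")
_TARGETS = ("cl", "v")


@dataclass(frozen=True)
class CovariateSpec:
    """A single covariate-parameter relationship.

    Forms (``x`` is the subject's covariate value, ``theta`` the coefficient):

    - ``genotype``: multiplier ``theta ** x`` for an indicator coding
      (x = 0 reference genotype, x = 1 carrier);
    - ``power``: multiplier ``(x / reference) ** theta`` with ``reference``
      the population median of a continuous covariate;
    - ``linear``: multiplier ``1 + theta * x`` for categorical/linear codes.
    """

    target: str
    name: str
    form: str
    theta: float = 1.0
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}, got {self.target!r}")
        if self.form not in _FORMS:
            raise ValueError(f"form must be one of {_FORMS}, got {self.form!r}")
        if self.form == "power" and (self.reference is None or self.reference <= 0):
            raise ValueError("power form requires a positive reference (median) value")

    def multiplier(self, x: float) -> float:
        if self.form == "genotype":
            return self.theta**x
        if self.form == "power":
            return (x / self.reference) ** self.theta
        return 1.0 + self.theta * x


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, variance components and covariate links.

    ``theta_cl`` (L/h) and ``theta_v`` (L) are the typical CL/F and V/F of a
    70-kg standard individual; ``ka`` (1/h) is fixed during estimation.
    ``omega2_*`` are the IIV variances of the log-normal random effects and
    ``sigma2_prop``/``sigma2_add`` the proportional and additive residual
    variances (additive in (ng/ml)^2).
    """

    theta_cl: float
    theta_v: float
    ka: float = 0.485
    allo_exp_cl: float = 0.75
    allo_exp_v: float = 1.0
    w_std: float = 70.0
    omega2_cl: float = 0.0
    omega2_v: float = 0.0
    sigma2_prop: float = 0.0
    sigma2_add: float = 0.0
    covariates: tuple[CovariateSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if min(self.theta_cl, self.theta_v, self.ka) <= 0:
            raise ValueError("theta_cl, theta_v and ka must all be > 0")
        for name in ("omega2_cl", "omega2_v", "sigma2_prop", "sigma2_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if isinstance(self.covariates, list):
            object.__setattr__(self, "covariates", tuple(self.covariates))

    def typical_values(
        self, weight: float, covariates: Mapping[str, float] | None = None
    ) -> tuple[float, float]:
        """Typical (CL/F, V/F) for a subject: allometry plus covariate multipliers."""
        cl = self.theta_cl * (weight / self.w_std) ** self.allo_exp_cl
        v = self.theta_v * (weight / self.w_std) ** self.allo_exp_v
        for spec in self.covariates:
            if covariates is None or spec.name not in covariates:
                raise KeyError(
                    f"model covariate {spec.name!r} missing from subject covariates"
                )
            m = spec.multiplier(covariates[spec.name])
            if spec.target == "cl":
                cl *= m
            else:
                v *= m
        return cl, v

    def residual_variance(self, ipred: float):
        """Combined residual variance ipred^2*sigma2_prop + sigma2_add, (ng/ml)^2."""
        return ipred**2 * self.sigma2_prop + self.sigma2_add

    def with_covariate(self, spec: CovariateSpec) -> "PopulationModel":
        return replace(self, covariates=self.covariates + (spec,))

    def without_covariate(self, name: str, target: str) -> "PopulationModel":
        kept = tuple(
            s for s in self.covariates if not (s.name == name and s.target == target)
        )
        return replace(self, covariates=kept)


#: Final published model: CL/F = 6.48*(W/70)^0.75 L/h, V/F = 124*(W/70) L,
#: Ka fixed at 0.485/h, with the reported IIV and residual variances.
FINAL_MODEL = PopulationModel(
    theta_cl=6.48,
    theta_v=124.0,
    ka=0.485,
    omega2_cl=0.066,
    omega2_v=0.003,
    sigma2_prop=0.312,
    sigma2_add=1.249,
)
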
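"""One-compartment oral-absorption pharmacokinetics.

The structural model is a single compartment with first-order absorption
(rate constant Ka) and first-order elimination (ke = CL/V), parameterised
by the apparent oral clearance CL/F, the apparent volume V/F and Ka.
Bioavailability F is folded into the apparent parameters and never
modelled separately.

Units: doses enter in mg and are converted once to micrograms; volumes are
litres and times hours, so every concentration is ug/L, numerically equal
to ng/ml.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .model import PopulationModel

__all__ = [
    "PKParameters",
    "DoseEvent",
    "Regimen",
    "individual_params",
    "concentration_after_single_dose",
    "concentration_profile",
    "steady_state_trough",
]

#: below this |ka - ke| the two-exponential solution switches to its
#: analytic ka -> ke limit to avoid catastrophic cancellation
_KA_KE_TOL = 1e-10

_MG_TO_UG = 1000.0


@dataclass(frozen=True)
class PKParameters:
    """Individual pharmacokinetic parameters.

    Attributes
    ----------
    cl_over_f : float
        Apparent oral clearance, L/h.
    v_over_f : float
        Apparent volume of distribution, L.
    ka : float
        First-order absorption rate constant, 1/h.
    """

    cl_over_f: float
    v_over_f: float
    ka: float

    def __post_init__(self) -> None:
        for name in ("cl_over_f", "v_over_f", "ka"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/V, 1/h."""
        return self.cl_over_f / self.v_over_f

    @property
    def half_life(self) -> float:
        """Elimination half-life, h."""
        return float(np.log(2.0) / self.ke)


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose: ``time`` hours since first dose, ``amount`` mg."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")


@dataclass(frozen=True)
class Regimen:
    """A weight-normalised maintenance regimen.

    ``frequency`` is ``"qd"`` (once daily, tau = 24 h) or ``"bid"`` (twice
    daily, tau = 12 h with the daily dose split exactly evenly).
    """

    dose_per_kg_per_day: float
    frequency: str = "qd"

    def __post_init__(self) -> None:
        if self.dose_per_kg_per_day < 0:
            raise ValueError("dose_per_kg_per_day must be >= 0")
        if self.frequency not in ("qd", "bid"):
            raise ValueError(f"frequency must be 'qd' or 'bid', got {self.frequency!r}")

    @property
    def doses_per_day(self) -> int:
        return 1 if self.frequency == "qd" else 2

    @property
    def tau(self) -> float:
        """Dosing interval, h."""
        return 24.0 / self.doses_per_day

    def amount_per_dose(self, weight: float) -> float:
        """Per-administration amount in mg for a subject of ``weight`` kg."""
        if weight <= 0:
            raise ValueError(f"weight must be > 0, got {weight}")
        return weight * self.dose_per_kg_per_day / self.doses_per_day


def individual_params(
    model: "PopulationModel",
    weight: float,
    eta_cl: float = 0.0,
    eta_v: float = 0.0,
    covariates: Mapping[str, float] | None = None,
) -> PKParameters:
    """Individual parameters from typical values, weight and random effects.

    Clearance and volume scale allometrically with body weight relative to
    the 70-kg standard (exponents 0.75 and 1), any covariate effects in the
    model multiply the typical value, and the log-normal random effects
    exp(eta) act last.  Ka is copied unchanged from the model (fixed).
    """
    if not np.isfinite(weight) or weight <= 0:
        raise ValueError(f"weight must be finite and > 0, got {weight!r}")
    cl_typ, v_typ = model.typical_values(weight, covariates)
    return PKParameters(
        cl_over_f=cl_typ * float(np.exp(eta_cl)),
        v_over_f=v_typ * float(np.exp(eta_v)),
        ka=model.ka,
    )


def _single_dose_curve(amount_ug, ka: float, ke: float, v: float, dt):
    """ug/L at elapsed times ``dt`` >= 0 after an oral dose of ``amount_ug``."""
    dt = np.asarray(dt, dtype=float)
    if abs(ka - ke) < _KA_KE_TOL:
        return amount_ug * ka * dt / v * np.exp(-ka * dt)
    return amount_ug * ka / (v * (ka - ke)) * (np.exp(-ke * dt) - np.exp(-ka * dt))


def concentration_after_single_dose(
    params: PKParameters, amount: float, t
) -> np.ndarray | float:
    """Concentration (ng/ml) at time(s) ``t`` hours after one oral dose of ``amount`` mg."""
    if amount < 0:
        raise ValueError(f"dose amount must be >= 0, got {amount}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = _single_dose_curve(amount * _MG_TO_UG, params.ka, params.ke, params.v_over_f, t_arr)
    return float(out) if np.isscalar(t) else out


def concentration_profile(
    params: PKParameters,
    doses: Sequence[DoseEvent],
    times: Iterable[float],
) -> np.ndarray:
    """Concentrations (ng/ml) at ``times`` under a dosing history, by superposition.

    Each requested time receives the sum of single-dose contributions from
    every dose given at or before it; times before the first dose yield 0.
    """
    times_arr = np.atleast_1d(np.asarray(times, dtype=float))
    if not doses:
        return np.zeros_like(times_arr)
    dose_times = np.array([d.time for d in doses], dtype=float)
    if np.any(np.diff(dose_times) < 0):
        raise ValueError("dose times must be sorted ascending")
    amounts_ug = np.array([d.amount for d in doses], dtype=float) * _MG_TO_UG
    dt = times_arr[:, None] - dose_times[None, :]
    mask = dt >= 0
    contrib = np.where(
        mask,
        _single_dose_curve(amounts_ug[None, :], params.ka, params.ke, params.v_over_f, np.where(mask, dt, 0.0)),
        0.0,
    )
    return contrib.sum(axis=1)


def steady_state_trough(params: PKParameters, amount_per_dose: float, tau: float) -> float:
    """Pre-dose concentration (ng/ml) at steady state for repeated dosing.

    Closed-form accumulation of the two-exponential single-dose solution:

        C_ss,trough = (D*Ka)/(V*(Ka-ke)) * [ e^(-ke*tau)/(1-e^(-ke*tau))
                                            - e^(-Ka*tau)/(1-e^(-Ka*tau)) ]

    equal to the limit of the superposed trough as the number of doses grows.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if amount_per_dose < 0:
        raise ValueError("amount_per_dose must be >= 0")
    ka, ke, v = params.ka, params.ke, params.v_over_f
    amount_ug = amount_per_dose * _MG_TO_UG
    if abs(ka - ke) < _KA_KE_TOL:
        # limit of the accumulation formula as ka -> ke
        e = np.exp(-ka * tau)
        return float(amount_ug * ka * tau / v * e / (1.0 - e) ** 2)
    acc_ke = np.exp(-ke * tau) / (1.0 - np.exp(-ke * tau))
    acc_ka = np.exp(-ka * tau) / (1.0 - np.exp(-ka * tau))
    return float(amount_ug * ka / (v * (ka - ke)) * (acc_ke - acc_ka))
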
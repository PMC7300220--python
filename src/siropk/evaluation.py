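"""Model qualification: bootstrap, prediction-corrected VPC, residuals.

Bootstrap resamples SUBJECTS with replacement (the exchangeable unit in
hierarchical data), refits the model on each replicate and summarises every
parameter by the replicate median and 2.5th-97.5th percentiles, with
bias% = 100 * (bootstrap median - original estimate) / original estimate.

The VPC simulates replicate datasets under the model at the observed
design, prediction-corrects observed and simulated concentrations by the
bin-median population prediction, and compares observed percentiles with
the simulated band.

Residual diagnostics report population/individual predictions, IWRES
(individually weighted residuals at the eta modes, FOCE-I weighting) and
first-order WRES (residuals decorrelated by the model-implied covariance
at eta = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Dataset, SubjectData
from .model import PopulationModel
from .nlme import FitResult, FitSettings, fit, residual_variance
from .pk import concentration_profile, individual_params
from .synthetic import simulate_observations

__all__ = ["BootstrapResult", "VPCResult", "bootstrap", "bootstrap_bias", "vpc",
           "residual_diagnostics"]


def bootstrap_bias(bootstrap_median: float, original_estimate: float) -> float:
    """Bias in percent: 100 * (median - estimate) / estimate."""
    return 100.0 * (bootstrap_median - original_estimate) / original_estimate


@dataclass
class BootstrapResult:
    """Parameter-wise bootstrap summary.

    ``table`` has one row per parameter: original estimate, bootstrap
    median, 2.5th/97.5th percentiles and bias%.
    """

    table: pd.DataFrame
    n_requested: int
    n_converged: int
    replicates: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        bad = self.table[self.table["p2_5"] > self.table["p97_5"]]
        if len(bad):
            raise AssertionError("bootstrap percentiles out of order")


def bootstrap(
    dataset: Dataset,
    model_spec: PopulationModel,
    n_reps: int = 1000,
    seed: int = 0,
    settings: FitSettings | None = None,
    original_fit: FitResult | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap of the population fit, resampling subjects.

    Non-converged replicates are excluded (and counted); a warning is
    raised when more than half fail.  Bit-reproducible for a fixed seed.
    """
    if len(dataset) < 2:
        raise ValueError("bootstrap requires at least 2 subjects")
    settings = (settings or FitSettings()).replace(compute_se=False, n_starts=1)
    if original_fit is None:
        original_fit = fit(dataset, model_spec, settings)
    originals = original_fit.estimates

    rng = np.random.default_rng(seed)
    rows = []
    n_fail = 0
    for rep in range(n_reps):
        idx = rng.integers(0, len(dataset), size=len(dataset))
        subjects = []
        for j, i in enumerate(idx):
            s = dataset[int(i)]
            subjects.append(
                SubjectData(
                    id=f"B{j}", weight=s.weight, doses=list(s.doses),
                    obs_times=s.obs_times.copy(), obs_conc=s.obs_conc.copy(),
                    covariates=dict(s.covariates),
                )
            )
        try:
            res = fit(Dataset(subjects), model_spec, settings)
        except Exception:
            n_fail += 1
            continue
        if not res.converged:
            n_fail += 1
            continue
        rows.append({"replicate": rep, **res.estimates})
    if n_fail > n_reps / 2:
        warnings.warn(
            f"{n_fail}/{n_reps} bootstrap replicates failed to converge", stacklevel=2
        )
    reps = pd.DataFrame(rows)
    summary = []
    for name, est in originals.items():
        vals = reps[name].to_numpy()
        p2, med, p97 = np.percentile(vals, [2.5, 50.0, 97.5])
        summary.append(
            {"parameter": name, "estimate": est, "median": med,
             "p2_5": p2, "p97_5": p97, "bias_percent": bootstrap_bias(med, est)}
        )
    return BootstrapResult(
        table=pd.DataFrame(summary),
        n_requested=n_reps,
        n_converged=n_reps - n_fail,
        replicates=reps,
    )


@dataclass
class VPCResult:
    """Prediction-corrected VPC summary.

    ``bins`` has one row per time bin with observed prediction-corrected
    2.5/50/97.5 percentiles and the simulated band for each of those
    percentiles; ``fraction_inside`` is the share of prediction-corrected
    observations inside the pooled simulated 2.5th-97.5th interval.
    """

    bins: pd.DataFrame
    fraction_inside: float
    n_sim: int


def _population_predictions(dataset: Dataset, model: PopulationModel) -> np.ndarray:
    preds = []
    for s in dataset:
        params = individual_params(model, s.weight, 0.0, 0.0, covariates=s.covariates)
        preds.append(concentration_profile(params, s.doses, s.obs_times))
    return np.concatenate(preds)


def vpc(
    dataset: Dataset,
    model: PopulationModel,
    n_sim: int = 1000,
    seed: int = 0,
    bins: int = 4,
) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Simulates ``n_sim`` replicates of the dataset under ``model`` at the
    observed design, corrects observed and simulated concentrations by
    obs * (bin-median PRED / subject-time PRED), and tabulates observed
    percentiles against the simulated percentile band per quantile-based
    time bin.  Empty bins are dropped with a warning.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    times = np.concatenate([s.obs_times for s in dataset])
    obs = np.concatenate([s.obs_conc for s in dataset])
    pred = _population_predictions(dataset, model)
    if np.any(pred <= 0):
        raise ValueError("population prediction <= 0: cannot prediction-correct")

    edges = np.quantile(times, np.linspace(0, 1, bins + 1))
    edges[-1] += 1e-9
    bin_idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, bins - 1)

    bin_median_pred = np.full(bins, np.nan)
    for b in range(bins):
        sel = bin_idx == b
        if sel.any():
            bin_median_pred[b] = np.median(pred[sel])
        else:
            warnings.warn(f"VPC bin {b} is empty and was dropped", stacklevel=2)
    correction = bin_median_pred[bin_idx] / pred
    pc_obs = obs * correction

    ss = np.random.SeedSequence(seed)
    sim_pc = np.empty((n_sim, obs.size))
    for k, child in enumerate(ss.spawn(n_sim)):
        sim = simulate_observations(dataset, model, int(child.generate_state(1)[0] % 2**31))
        sim_obs = np.concatenate([s.obs_conc for s in sim])
        sim_pc[k] = sim_obs * correction

    q = (2.5, 50.0, 97.5)
    rows = []
    inside = np.zeros(obs.size, dtype=bool)
    for b in range(bins):
        sel = bin_idx == b
        if not sel.any():
            continue
        obs_q = np.percentile(pc_obs[sel], q)
        pooled = sim_pc[:, sel].ravel()
        sim_lo, sim_med, sim_hi = np.percentile(pooled, q)
        # band for each observed percentile: spread of that percentile across sims
        per_sim_q = np.percentile(sim_pc[:, sel], q, axis=1)  # 3 x n_sim
        band = np.percentile(per_sim_q, [2.5, 97.5], axis=1)
        inside[sel] = (pc_obs[sel] >= sim_lo) & (pc_obs[sel] <= sim_hi)
        rows.append(
            {"bin": b, "t_lo": edges[b], "t_hi": edges[b + 1], "n_obs": int(sel.sum()),
             "obs_p2_5": obs_q[0], "obs_p50": obs_q[1], "obs_p97_5": obs_q[2],
             "sim_p2_5": sim_lo, "sim_p50": sim_med, "sim_p97_5": sim_hi,
             "band_p2_5_lo": band[0, 0], "band_p2_5_hi": band[1, 0],
             "band_p50_lo": band[0, 1], "band_p50_hi": band[1, 1],
             "band_p97_5_lo": band[0, 2], "band_p97_5_hi": band[1, 2]}
        )
    return VPCResult(
        bins=pd.DataFrame(rows),
        fraction_inside=float(np.mean(inside)),
        n_sim=n_sim,
    )


def residual_diagnostics(dataset: Dataset, fit_result: FitResult) -> pd.DataFrame:
    """Per-observation diagnostics table.

    Columns: subject id, time, observation, PRED (population, eta = 0),
    IPRED (at the subject's eta mode), IWRES = (obs - IPRED)/sd(IPRED),
    and first-order WRES in which each subject's residual vector is
    decorrelated by the model-implied covariance F*Omega*F' + V at eta = 0.
    """
    model = fit_result.model
    omega = np.diag([model.omega2_cl, model.omega2_v])
    rows = []
    for s in dataset:
        eta = fit_result.eta_modes[s.id]
        p_ind = individual_params(model, s.weight, eta[0], eta[1], covariates=s.covariates)
        ipred = concentration_profile(p_ind, s.doses, s.obs_times)
        var_i = residual_variance(ipred, model)
        if np.any(var_i <= 0):
            j = int(np.argmax(var_i <= 0))
            raise ValueError(
                f"zero residual variance at subject {s.id}, time {s.obs_times[j]}"
            )
        iwres = (s.obs_conc - ipred) / np.sqrt(var_i)

        p_pop = individual_params(model, s.weight, 0.0, 0.0, covariates=s.covariates)
        pred = concentration_profile(p_pop, s.doses, s.obs_times)
        h = 1e-5
        F = np.empty((pred.size, 2))
        for k, (d_cl, d_v) in enumerate(((h, 0.0), (0.0, h))):
            pp = individual_params(model, s.weight, d_cl, d_v, covariates=s.covariates)
            pm = individual_params(model, s.weight, -d_cl, -d_v, covariates=s.covariates)
            F[:, k] = (
                concentration_profile(pp, s.doses, s.obs_times)
                - concentration_profile(pm, s.doses, s.obs_times)
            ) / (2 * h)
        cov = F @ omega @ F.T + np.diag(residual_variance(pred, model))
        L = np.linalg.cholesky(cov)
        wres = np.linalg.solve(L, s.obs_conc - pred)
        for j in range(pred.size):
            rows.append(
                {"id": s.id, "time": s.obs_times[j], "obs": s.obs_conc[j],
                 "pred": pred[j], "ipred": ipred[j],
                 "iwres": iwres[j], "wres": wres[j]}
            )
    table = pd.DataFrame(rows)
    if not np.all(np.isfinite(table[["iwres", "wres"]].to_numpy())):
        raise FloatingPointError("non-finite residual encountered")
    return table
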
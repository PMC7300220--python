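"""Estimator tests: FOCE-I objective against quadrature, fitting, recovery."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from oracles import quadrature_ofv
from siropk.data import Dataset, SubjectData
from siropk.model import PopulationModel
from siropk.nlme import FitSettings, fit, ofv_foce
from siropk.pk import concentration_profile, individual_params
from siropk.synthetic import CohortSpec, generate_cohort, simulate_observations


def exact_minus2ll_no_iiv(dataset, model):
    """Fixed-effects -2 log-likelihood (no random effects to integrate)."""
    total = 0.0
    for s in dataset:
        p = individual_params(model, s.weight, covariates=s.covariates)
        f = concentration_profile(p, s.doses, s.obs_times)
        v = f**2 * model.sigma2_prop + model.sigma2_add
        total += np.sum(np.log(2 * np.pi * v) + (s.obs_conc - f) ** 2 / v)
    return total


class TestOFV:
    def test_matches_quadrature_oracle_small_instance(self, small_dataset, final_model):
        ofv, _ = ofv_foce(small_dataset, final_model)
        oracle = quadrature_ofv(small_dataset, final_model, n_nodes=40)
        assert abs(ofv - oracle) < 0.5

    def test_matches_quadrature_on_three_subject_instance(self, final_model):
        # small-omega regime, where the Laplace expansion should be sharp
        m = replace(final_model, omega2_cl=0.01, omega2_v=0.001)
        cohort = generate_cohort(CohortSpec(n=3, seed=9, design="rich"), m)
        data = simulate_observations(cohort, m, 9)
        ofv, _ = ofv_foce(data, m)
        oracle = quadrature_ofv(data, m, n_nodes=40)
        assert abs(ofv - oracle) < 0.5

    def test_reduces_to_exact_likelihood_as_omega_vanishes(self, small_dataset, final_model):
        m = replace(final_model, omega2_cl=1e-8, omega2_v=1e-8)
        ofv, _ = ofv_foce(small_dataset, m)
        assert abs(ofv - exact_minus2ll_no_iiv(small_dataset, m)) < 0.1
        # and exactly at zero the random effects drop out entirely
        m0 = replace(final_model, omega2_cl=0.0, omega2_v=0.0)
        ofv0, etas = ofv_foce(small_dataset, m0)
        assert ofv0 == pytest.approx(exact_minus2ll_no_iiv(small_dataset, m0), abs=1e-9)
        assert all(np.all(e == 0.0) for e in etas.values())

    def test_additive_over_subjects_and_duplication_doubles(self, small_dataset, final_model):
        per_subject = [
            ofv_foce(Dataset([s]), final_model)[0] for s in small_dataset
        ]
        total, _ = ofv_foce(small_dataset, final_model)
        assert total == pytest.approx(sum(per_subject), abs=1e-8)
        s = small_dataset[0]
        twin = SubjectData(
            "twin", s.weight, list(s.doses), s.obs_times.copy(), s.obs_conc.copy()
        )
        doubled, _ = ofv_foce(Dataset([s, twin]), final_model)
        assert doubled == pytest.approx(2 * per_subject[0], abs=1e-8)

    def test_invariant_to_subject_order_and_relabeling(self, tdm_dataset, final_model):
        ofv, _ = ofv_foce(tdm_dataset, final_model)
        shuffled = Dataset(
            [
                SubjectData(f"R{i}", s.weight, list(s.doses), s.obs_times.copy(),
                            s.obs_conc.copy(), dict(s.covariates))
                for i, s in enumerate(reversed(tdm_dataset.subjects))
            ]
        )
        ofv2, _ = ofv_foce(shuffled, final_model)
        assert ofv2 == pytest.approx(ofv, abs=1e-7)

    def test_missing_concentrations_rejected(self, final_model):
        cohort = generate_cohort(CohortSpec(n=2, seed=5), final_model)
        with pytest.raises(ValueError, match="missing concentrations"):
            ofv_foce(cohort, final_model)


class TestFit:
    def test_near_noiseless_rich_data_recovers_thetas_within_1pct(self, final_model):
        truth = replace(
            final_model, omega2_cl=0.0, omega2_v=0.0, sigma2_prop=1e-6, sigma2_add=0.0
        )
        cohort = generate_cohort(CohortSpec(n=8, seed=2, design="rich"), truth)
        data = simulate_observations(cohort, truth, 2)
        start = replace(truth, theta_cl=5.0, theta_v=100.0, sigma2_prop=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(data, start, FitSettings(n_starts=1, compute_se=False))
        assert res.converged
        assert res.estimates["theta_cl"] == pytest.approx(6.48, rel=0.01)
        assert res.estimates["theta_v"] == pytest.approx(124.0, rel=0.01)

    def test_recovery_on_rich_cohort(self, recovery_fit):
        """100-subject synthetic cohort generated from the final published model."""
        assert recovery_fit.converged
        assert recovery_fit.estimates["theta_cl"] == pytest.approx(6.48, rel=0.15)
        assert recovery_fit.estimates["theta_v"] == pytest.approx(124.0, rel=0.20)
        # variance components recovered to the right order of magnitude
        assert 0.066 / 3 < recovery_fit.estimates["omega2_cl"] < 0.066 * 3
        assert 0.312 / 3 < recovery_fit.estimates["sigma2_prop"] < 0.312 * 3

    def test_fit_is_deterministic(self, final_model):
        cohort = generate_cohort(CohortSpec(n=5, seed=8), final_model)
        data = simulate_observations(cohort, final_model, 8)
        s = FitSettings(n_starts=1, compute_se=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = fit(data, final_model, s)
            r2 = fit(data, final_model, s)
        assert r1.ofv == r2.ofv
        assert r1.estimates == r2.estimates

    def test_replicate_recovery_medians(self, final_model):
        """Over 20 seeded replicates (n=50, 6 samples each) the median theta
        estimates land within 10% of truth and the well-identified variance
        components within a factor of 2.

        Two components get only sanity bounds because the data barely
        identify them.  sigma2_add: with steady-state sampling every
        prediction exceeds ~3 ng/ml, so the proportional term dominates the
        residual variance everywhere (its replicate scatter spans an order
        of magnitude, mirroring the huge bootstrap uncertainty reported for
        this parameter).  omega2_v: the generating value 0.003 (5.5% CV) is
        swamped by the 56%-CV proportional error, and the profile
        likelihood in omega2_v is nearly flat, drifting upward by a few OFV
        units; the conditional estimates absorb approximation error there.
        """
        est = {k: [] for k in ("theta_cl", "theta_v", "omega2_cl", "omega2_v",
                               "sigma2_prop", "sigma2_add")}
        for seed in range(20):
            cohort = generate_cohort(CohortSpec(n=50, seed=100 + seed, design="rich"), final_model)
            data = simulate_observations(cohort, final_model, 200 + seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit(data, final_model, FitSettings(n_starts=1, compute_se=False))
            for k in est:
                est[k].append(res.estimates[k])
        med = {k: np.median(v) for k, v in est.items()}
        assert med["theta_cl"] == pytest.approx(6.48, rel=0.10)
        assert med["theta_v"] == pytest.approx(124.0, rel=0.10)
        assert 0.066 / 2 < med["omega2_cl"] < 0.066 * 2
        assert 0.312 / 2 < med["sigma2_prop"] < 0.312 * 2
        # weakly identified: bounded, positive, right order of the total noise
        assert 0.0 <= med["omega2_v"] < 0.15
        assert 0.0 <= med["sigma2_add"] < 1.249 * 5

    def test_standard_errors_reported_as_percent(self, final_model):
        cohort = generate_cohort(CohortSpec(n=12, seed=21, design="rich"), final_model)
        data = simulate_observations(cohort, final_model, 21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(data, final_model, FitSettings(n_starts=1, compute_se=True))
        assert res.converged
        rse = res.rse_percent.get("theta_cl")
        assert rse is not None and 0.0 < rse < 100.0
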
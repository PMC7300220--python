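"""Bootstrap, VPC and residual-diagnostic behaviour."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from conftest import FAST_FIT as FAST
from siropk.data import Dataset, SubjectData
from siropk.evaluation import bootstrap, bootstrap_bias, residual_diagnostics, vpc
from siropk.nlme import fit
from siropk.synthetic import CohortSpec, generate_cohort, simulate_observations


class TestBootstrapBias:
    @pytest.mark.parametrize(
        "median,estimate,expected",
        [(6.65, 6.48, 2.62), (133.0, 124.0, 7.26)],
    )
    def test_published_bias_arithmetic(self, median, estimate, expected):
        assert round(bootstrap_bias(median, estimate), 2) == expected


class TestBootstrap:
    def test_percentiles_ordered_and_seed_reproducible(self, bootstrap_pair):
        b1, b2 = bootstrap_pair
        t = b1.table
        assert (t["p2_5"] <= t["median"]).all() and (t["median"] <= t["p97_5"]).all()
        assert b1.table.equals(b2.table)  # bit-reproducible
        assert b1.n_converged >= 5

    def test_identical_subjects_give_zero_bias(self, final_model):
        """If every subject is a copy, resampling cannot change the data."""
        cohort = generate_cohort(CohortSpec(n=1, seed=31, design="rich"), final_model)
        data = simulate_observations(cohort, final_model, 31)
        s = data[0]
        clones = Dataset(
            [
                SubjectData(f"C{i}", s.weight, list(s.doses), s.obs_times.copy(),
                            s.obs_conc.copy())
                for i in range(3)
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = bootstrap(clones, final_model, n_reps=5, seed=1, settings=FAST)
        assert np.allclose(b.table["bias_percent"], 0.0, atol=1e-6)
        assert np.allclose(b.table["p2_5"], b.table["p97_5"])

    def test_requires_two_subjects(self, final_model):
        cohort = generate_cohort(CohortSpec(n=1, seed=1), final_model)
        data = simulate_observations(cohort, final_model, 1)
        with pytest.raises(ValueError):
            bootstrap(data, final_model, n_reps=2, seed=0)


class TestVPC:
    def test_self_simulation_coverage_near_nominal(self, vpc_self_coverage):
        """Data simulated from the model itself should sit in the simulated
        2.5-97.5 band about 95% of the time."""
        assert abs(vpc_self_coverage.fraction_inside - 0.95) <= 0.03

    def test_bands_ordered_and_fractions_valid(self, vpc_dataset, final_model):
        res = vpc(vpc_dataset, final_model, n_sim=150, seed=8, bins=4)
        assert 0.0 <= res.fraction_inside <= 1.0
        b = res.bins
        assert (b["sim_p2_5"] <= b["sim_p50"]).all() and (b["sim_p50"] <= b["sim_p97_5"]).all()
        assert (b["obs_p2_5"] <= b["obs_p50"]).all() and (b["obs_p50"] <= b["obs_p97_5"]).all()

    def test_inflated_residual_model_covers_more(self, vpc_dataset, final_model):
        """A model with doubled residual variances simulates wider bands, so
        the same observations fall inside more often (checked across seeds)."""
        wide = replace(
            final_model,
            sigma2_prop=2 * final_model.sigma2_prop,
            sigma2_add=2 * final_model.sigma2_add,
        )
        for seed in range(3):
            f_fit = vpc(vpc_dataset, final_model, n_sim=150, seed=seed, bins=4).fraction_inside
            f_wide = vpc(vpc_dataset, wide, n_sim=150, seed=seed, bins=4).fraction_inside
            assert f_wide >= f_fit

    def test_too_few_simulations_rejected(self, vpc_dataset, final_model):
        with pytest.raises(ValueError):
            vpc(vpc_dataset, final_model, n_sim=50, seed=0)


class TestResidualDiagnostics:
    @pytest.fixture(scope="class")
    def diag_fit(self, final_model):
        cohort = generate_cohort(CohortSpec(n=25, seed=23, design="rich"), final_model)
        data = simulate_observations(cohort, final_model, 23)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return data, fit(data, final_model, FAST)

    def test_iwres_formula(self, diag_fit, final_model):
        data, res = diag_fit
        tab = residual_diagnostics(data, res)
        # spot-check the weighting: (obs-ipred)/sqrt(ipred^2*sp + sa)
        m = res.model
        row = tab.iloc[0]
        expected = (row["obs"] - row["ipred"]) / np.sqrt(
            row["ipred"] ** 2 * m.sigma2_prop + m.sigma2_add
        )
        assert row["iwres"] == pytest.approx(expected)
        assert np.isfinite(tab[["iwres", "wres"]].to_numpy()).all()

    def test_iwres_zero_when_observation_equals_prediction(self, diag_fit):
        data, res = diag_fit
        s = data[0]
        eta = res.eta_modes[s.id]
        from siropk.pk import concentration_profile, individual_params

        p = individual_params(res.model, s.weight, eta[0], eta[1], covariates=s.covariates)
        exact = SubjectData(
            s.id, s.weight, list(s.doses), s.obs_times.copy(),
            concentration_profile(p, s.doses, s.obs_times), dict(s.covariates),
        )
        tab = residual_diagnostics(Dataset([exact]), res)
        assert np.allclose(tab["iwres"], 0.0, atol=1e-12)

    def test_wres_iwres_calibrated_under_true_model(self, final_model):
        """Simulated-from-truth residuals have roughly zero mean, unit spread."""
        cohort = generate_cohort(CohortSpec(n=80, seed=29, design="rich"), final_model)
        data = simulate_observations(cohort, final_model, 29)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(data, final_model, FAST)
        tab = residual_diagnostics(data, res)
        n = len(tab)
        assert abs(tab["wres"].mean()) < 3.0 / np.sqrt(n)
        assert 0.8 < tab["wres"].std() < 1.2
        assert 0.8 < tab["iwres"].std() < 1.2

    def test_invariant_to_subject_order(self, diag_fit):
        data, res = diag_fit
        reversed_ds = Dataset(list(reversed(data.subjects)))
        t1 = residual_diagnostics(data, res).set_index(["id", "time"]).sort_index()
        t2 = residual_diagnostics(reversed_ds, res).set_index(["id", "time"]).sort_index()
        assert np.allclose(t1["wres"], t2["wres"])
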
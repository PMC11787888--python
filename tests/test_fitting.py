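"""Outlier screening, naive-pooled NLS recovery, AIC model selection."""

import math

import numpy as np
import pandas as pd
import pytest

from hsrpk import (
    NoiseModel,
    SamplingDesign,
    StudyDataset,
    ValidationError,
    aic,
    filter_dataset,
    fit_pk,
    generate_pk_study,
    iqr_filter,
    select_model,
)
from hsrpk.fitting import FitResult

from conftest import flip_flop_errors

DESIGN = SamplingDesign(timepoints=(0.25, 0.5, 1, 2, 3, 4, 6, 8, 10))


@pytest.fixture
def tobra_truth(drugs):
    d = drugs["tobramycin"]
    return d.pk_parameters("plasma"), d.regimen("plasma")


class TestIQRFilter:
    @pytest.mark.parametrize(
        "values, expected_excluded",
        [
            ([1, 2, 3, 4, 100], [100.0]),  # fences [-1, 7] by hand
            ([5.0] * 6, []),  # zero IQR keeps the common value
            ([5, 6], []),  # n < 4 passes through
            ([1, 2, 3, 4, 5], []),
        ],
    )
    def test_fence_rule(self, values, expected_excluded):
        kept, excluded = iqr_filter(values)
        assert sorted(excluded.tolist()) == expected_excluded
        assert len(kept) + len(excluded) == len(values)

    def test_single_pass_not_iterated(self):
        # fences on the full group keep 30; a second pass (after dropping
        # 1000) would flag it, and the screen must not take that pass
        kept, excluded = iqr_filter([10, 10, 10, 10, 10, 30, 1000])
        assert excluded.tolist() == [1000.0]
        assert 30 in kept
        kept2, excluded2 = iqr_filter(kept)  # demonstrates the second pass differs
        assert 30 in excluded2

    def test_dataset_filter_reports_per_matrix(self, tobra_truth):
        params, regimen = tobra_truth
        ds = generate_pk_study(params, regimen, DESIGN,
                               NoiseModel(cv=0.1), seed=3)
        obs = ds.observations.copy()
        obs.loc[0, "conc_mg_L"] *= 50  # gross outlier at one timepoint
        ds = StudyDataset(obs, ds.metadata)
        filtered, report = filter_dataset(ds)
        assert report.loc[0, "n_excluded"] >= 1
        assert "/" in report.loc[0, "summary"] and "%" in report.loc[0, "summary"]
        assert len(filtered.observations) == len(obs) - report["n_excluded"].sum()


class TestAIC:
    def test_direct_formula(self):
        assert aic(54, 54.0, 3) == pytest.approx(54 * math.log(1.0) + 6)

    def test_penalty_arithmetic(self):
        assert aic(20, 5.0, 5) - aic(20, 5.0, 3) == pytest.approx(4.0)

    def test_doubling_rss_adds_n_log2(self):
        assert aic(30, 2.0, 3) - aic(30, 1.0, 3) == pytest.approx(30 * math.log(2))

    def test_zero_rss_sentinel(self):
        with pytest.warns(UserWarning):
            assert aic(10, 0.0, 3) == float("-inf")


class TestFitPK:
    def test_noiseless_recovery_exact(self, tobra_truth):
        params, regimen = tobra_truth
        ds = generate_pk_study(params, regimen, DESIGN, NoiseModel(cv=0.0), seed=0)
        fit = fit_pk(ds)
        assert fit.converged
        errs = flip_flop_errors(fit.params, params)
        assert all(e < 1e-4 for e in errs.values()), errs
        assert fit.rss < 1e-10

    def test_noiseless_flip_flop_recovery(self, drugs):
        """Meropenem plasma: absorption is the terminal phase (ka < kel)."""
        d = drugs["meropenem"]
        params, regimen = d.pk_parameters("plasma"), d.regimen("plasma")
        ds = generate_pk_study(params, regimen, DESIGN, NoiseModel(cv=0.0), seed=0)
        fit = fit_pk(ds)
        rates = sorted([fit.params["ka"], fit.params["kel"]])
        assert rates[0] == pytest.approx(1.34, rel=1e-3)
        assert rates[1] == pytest.approx(27.13, rel=1e-3)

    def test_rss_zero_at_generating_parameters(self, tobra_truth):
        params, regimen = tobra_truth
        ds = generate_pk_study(params, regimen, DESIGN, NoiseModel(cv=0.0), seed=0)
        from hsrpk.fitting import _predict_one_compartment

        logp = np.log([params.volume, params.ka, params.kel])
        pred = _predict_one_compartment(
            logp, regimen, ds.observations["time_h"].to_numpy()
        )
        rss = float(np.sum((ds.observations["conc_mg_L"].to_numpy() - pred) ** 2))
        assert rss == pytest.approx(0.0, abs=1e-18)

    def test_deterministic_given_data(self, tobra_truth):
        params, regimen = tobra_truth
        ds = generate_pk_study(params, regimen, DESIGN, NoiseModel(cv=0.2), seed=11)
        f1 = fit_pk(ds)
        f2 = fit_pk(ds)
        assert f1.params == f2.params

    def test_unit_rescaling_only_scales_volume(self, tobra_truth):
        params, regimen = tobra_truth
        ds = generate_pk_study(params, regimen, DESIGN, NoiseModel(cv=0.1), seed=5)
        scaled = StudyDataset(
            ds.observations.assign(conc_mg_L=ds.observations["conc_mg_L"] * 1000),
            ds.metadata,
        )
        f1, f2 = fit_pk(ds), fit_pk(scaled)
        assert f2.params["volume"] == pytest.approx(f1.params["volume"] / 1000, rel=1e-3)
        assert f2.params["ka"] == pytest.approx(f1.params["ka"], rel=1e-3)
        assert f2.params["kel"] == pytest.approx(f1.params["kel"], rel=1e-3)

    def test_lloq_drops_observations(self, tobra_truth):
        params, regimen = tobra_truth
        ds = generate_pk_study(params, regimen, DESIGN, NoiseModel(cv=0.0), seed=0)
        fit = fit_pk(ds, lloq=5.0)
        assert fit.n_obs < len(ds.observations)
        assert fit.converged

    def test_too_few_timepoints_rejected(self, tobra_truth):
        params, regimen = tobra_truth
        ds = generate_pk_study(
            params, regimen, SamplingDesign((1.0, 2.0, 4.0), samples_per_mouse=3),
            NoiseModel(cv=0.0), seed=0,
        )
        with pytest.raises(ValidationError):
            fit_pk(ds)


class TestModelSelection:
    def test_single_candidate_returned(self):
        f = FitResult("one_compartment_foabs", {}, 1.0, 10, 3, 5.0,
                      np.empty(0), True)
        assert select_model([f]) is f

    def test_exact_tie_prefers_fewer_parameters(self):
        f3 = FitResult("one_compartment_foabs", {}, 1.0, 10, 3, 5.0,
                       np.empty(0), True)
        f5 = FitResult("two_compartment_foabs", {}, 1.0, 10, 5, 5.0,
                       np.empty(0), True)
        assert select_model([f5, f3]).k_params == 3

    def test_no_converged_fit_is_an_error(self):
        f = FitResult("one_compartment_foabs", {}, 1.0, 10, 3, 5.0,
                      np.empty(0), False)
        with pytest.raises(ValidationError):
            select_model([f])

    def test_one_compartment_truth_selects_one_compartment(self, tobra_truth):
        """AIC picks the generating one-compartment model in most replicates."""
        params, regimen = tobra_truth
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            ds = generate_pk_study(params, regimen, DESIGN,
                                   NoiseModel(cv=0.2), seed=seed)
            fits = [fit_pk(ds, m) for m in
                    ("one_compartment_foabs", "two_compartment_foabs")]
            best = select_model(fits)
            wins += best.model == "one_compartment_foabs"
        assert wins >= 0.7 * n_rep
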
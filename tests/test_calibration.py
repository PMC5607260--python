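from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ligandtree.calibration import (
    FreeParameters,
    LeakageError,
    MeasurementSet,
    Observable,
    ObservationMap,
    SchemaError,
    ValidityError,
    chi_square,
    coverage_fraction,
    fit,
    lrt_reduced,
    predict_holdout,
)
from ligandtree.model import build_model
from ligandtree.network import CellLineContext, ModelSpec, StimulusCondition
from ligandtree.params import KineticParameterSet
from ligandtree.synth import GroundTruth, make_timecourses
from ligandtree.validation import lrt_replicate, _lrt_setup, receptor_randomization

GRID = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0)


@pytest.fixture(scope="module")
def small_truth():
    spec = ModelSpec.custom(("EGFR", "HER2"), heterodimers=(("EGFR", "HER2"),))
    return GroundTruth.default(seed=0, spec=spec, observables=("pEGFR", "pHER2"))


@pytest.fixture(scope="module")
def small_contexts():
    return [CellLineContext("L0", {"EGFR": 2e5, "HER2": 1e5}),
            CellLineContext("L1", {"EGFR": 2e4, "HER2": 6e5})]


@pytest.fixture(scope="module")
def stimuli():
    return [StimulusCondition({"EGF": d}, time_grid=GRID) for d in (0.625, 10.0)]


@pytest.fixture(scope="module")
def noisy_data(small_truth, small_contexts, stimuli):
    return make_timecourses(small_truth, small_contexts, stimuli=stimuli, seed=7)


class TestChiSquare:
    def test_zero_on_exact_data(self, small_truth, small_contexts, stimuli):
        data = make_timecourses(small_truth, small_contexts, stimuli=stimuli,
                                seed=1, sigma=0.0)
        assert chi_square(small_truth.model, small_contexts, small_truth.obs_map,
                          data) == pytest.approx(0.0, abs=1e-12)

    def test_single_record_two_sigma_off_gives_four(self, small_truth, small_contexts):
        stim = StimulusCondition({"EGF": 10.0}, time_grid=GRID)
        traj = small_truth.model.simulate(small_contexts[0], stim)
        g = traj.observable("pEGFR")[2]
        sigma = 3.0
        frame = pd.DataFrame([
            (small_contexts[0].name, "pEGFR", stim.label(), GRID[2], 0, g + 2 * sigma, sigma)
        ], columns=MeasurementSet.REQUIRED)
        omap = ObservationMap({"pEGFR": Observable(sigma=sigma, log=False)})
        c2 = chi_square(small_truth.model, small_contexts, omap, MeasurementSet(frame))
        assert c2 == pytest.approx(4.0, rel=1e-6)

    def test_chi2_within_sampling_band_of_n(self, small_truth, small_contexts, noisy_data):
        n = len(noisy_data)
        c2 = chi_square(small_truth.model, small_contexts, small_truth.obs_map, noisy_data)
        assert n - 4 * np.sqrt(2 * n) < c2 < n + 4 * np.sqrt(2 * n)

    def test_invariance_under_joint_rescaling(self, small_truth, small_contexts, noisy_data):
        omap = ObservationMap({k: Observable(scale=1.0, sigma=0.1, log=False)
                               for k in small_truth.obs_map})
        base = chi_square(small_truth.model, small_contexts, omap, noisy_data)
        c = 37.0
        scaled_frame = noisy_data.frame.assign(value=noisy_data.frame["value"] * c,
                                               sigma=noisy_data.frame["sigma"] * c)
        omap_scaled = ObservationMap({k: Observable(scale=c, sigma=0.1, log=False)
                                      for k in small_truth.obs_map})
        scaled = chi_square(small_truth.model, small_contexts, omap_scaled,
                            MeasurementSet(scaled_frame))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_unknown_observable_raises_schema_error(self, small_truth, small_contexts, noisy_data):
        frame = noisy_data.frame.copy()
        frame.loc[0, "observable"] = "pJNK"
        with pytest.raises(SchemaError, match="pJNK"):
            chi_square(small_truth.model, small_contexts, small_truth.obs_map,
                       MeasurementSet(frame))


class TestFit:
    def test_empty_free_set_is_noop(self, small_truth, small_contexts, noisy_data):
        res = fit(small_truth.model, small_contexts, noisy_data, FreeParameters(),
                  obs_map=small_truth.obs_map)
        direct = chi_square(small_truth.model, small_contexts, small_truth.obs_map,
                            noisy_data)
        assert res.chi2 == pytest.approx(direct)
        assert res.n_free == 0

    def test_zero_starts_rejected(self, small_truth, small_contexts, noisy_data):
        free = FreeParameters(per_line_receptors=("EGFR",))
        with pytest.raises(ValueError, match="starts"):
            fit(small_truth.model, small_contexts, noisy_data, free, starts=0,
                obs_map=small_truth.obs_map)

    def test_recovery_and_determinism(self, small_truth, small_contexts, stimuli):
        data = make_timecourses(small_truth, small_contexts, stimuli=stimuli, seed=3)
        guesses = [replace(c, receptor_expression={r: 8e4 for r in c.receptor_expression})
                   for c in small_contexts]
        free = FreeParameters(per_line_receptors=("EGFR", "HER2"))
        kw = dict(starts=4, seed=11, obs_map=small_truth.obs_map, rtol=1e-6, atol=1e-8)
        res1 = fit(small_truth.model, guesses, data, free, **kw)
        res2 = fit(small_truth.model, guesses, data, free, **kw)
        assert res1.theta == res2.theta  # bit-identical under the same seed
        truth_chi2 = chi_square(small_truth.model, small_contexts,
                                small_truth.obs_map, data)
        assert res1.chi2 <= truth_chi2 + 1e-6
        for ctx_true, ctx_hat in zip(small_contexts, res1.contexts):
            for r, true_val in ctx_true.receptor_expression.items():
                hat = ctx_hat.receptor_expression[r]
                assert abs(hat - true_val) / true_val < 0.20

    def test_reported_free_dimension_matches(self, small_truth, small_contexts, noisy_data):
        free = FreeParameters(per_line_receptors=("EGFR", "HER2"))
        res = fit(small_truth.model, small_contexts, noisy_data, free, starts=1,
                  obs_map=small_truth.obs_map, rtol=1e-6, atol=1e-8, max_nfev=5)
        assert res.n_free == 4 == len(res.theta)


class TestHoldout:
    def test_leakage_detected(self, small_truth, small_contexts, noisy_data):
        res = fit(small_truth.model, small_contexts, noisy_data, FreeParameters(),
                  obs_map=small_truth.obs_map)
        with pytest.raises(LeakageError):
            predict_holdout(res, small_truth.spec, small_contexts[0], noisy_data)

    def test_holdout_chi2_comparable_to_training(self, small_truth, small_contexts, stimuli,
                                                 noisy_data):
        res = fit(small_truth.model, small_contexts, noisy_data, FreeParameters(),
                  obs_map=small_truth.obs_map)
        holdout_ctx = CellLineContext("L9", {"EGFR": 8e4, "HER2": 3e5})
        holdout = make_timecourses(small_truth, [holdout_ctx], stimuli=stimuli, seed=9)
        report = predict_holdout(res, small_truth.spec, holdout_ctx, holdout)
        train_per_point = res.chi2 / res.n_points
        assert report["chi2_per_point"] < 2 * train_per_point

    def test_empty_holdout_is_defined(self, small_truth, small_contexts, noisy_data):
        res = fit(small_truth.model, small_contexts, noisy_data, FreeParameters(),
                  obs_map=small_truth.obs_map)
        empty = MeasurementSet(noisy_data.frame.iloc[0:0])
        report = predict_holdout(res, small_truth.spec,
                                 CellLineContext("L9", {"EGFR": 1e5, "HER2": 1e5}), empty)
        assert report["n_points"] == 0

    def test_swapped_receptor_levels_degrade_fit(self, small_truth, stimuli):
        contexts = [CellLineContext(f"S{i}", {"EGFR": e, "HER2": h})
                    for i, (e, h) in enumerate([(3e5, 2e4), (1e4, 5e5), (8e4, 8e4)])]
        data = make_timecourses(small_truth, contexts, stimuli=stimuli, seed=21)
        out = receptor_randomization(small_truth.model, contexts, small_truth.obs_map,
                                     data, n_swaps=20, seed=2)
        assert out["fraction_worse"] == 1.0
        assert out["mean_decline"] > 0


class TestLRT:
    def test_identical_fits_give_p_one(self, small_truth, small_contexts, noisy_data):
        res = fit(small_truth.model, small_contexts, noisy_data, FreeParameters(),
                  obs_map=small_truth.obs_map)
        full = replace(res, n_free=2)
        stat, df, p = lrt_reduced(full, res)
        assert (stat, df, p) == (0.0, 2, 1.0)

    def test_nonnested_fits_rejected(self, small_truth, small_contexts, noisy_data):
        res = fit(small_truth.model, small_contexts, noisy_data, FreeParameters(),
                  obs_map=small_truth.obs_map)
        better_reduced = replace(res, chi2=res.chi2 - 5.0)
        worse_full = replace(res, n_free=2)
        with pytest.raises(ValidityError):
            lrt_reduced(worse_full, better_reduced)
        with pytest.raises(ValidityError, match="fewer free parameters"):
            lrt_reduced(res, res)

    def test_heterodimer_signal_is_detected(self):
        truth, context, stimuli, model_full, model_red, free_full, free_red = \
            _lrt_setup(hetero_in_truth=True)
        data = make_timecourses(truth, [context], stimuli=stimuli, seed=5)
        fit_full, fit_red = lrt_replicate(data, truth, context, model_full, model_red,
                                          free_full, free_red, seed=0)
        stat, df, p = lrt_reduced(fit_full, fit_red, boundary=True)
        assert df == 1
        assert p < 0.05

    def test_boundary_mixture_halves_the_tail(self):
        from scipy import stats as sps

        full = _stub_fit(chi2=10.0, n_free=3)
        reduced = _stub_fit(chi2=14.0, n_free=2)
        stat, df, p_plain = lrt_reduced(full, reduced, boundary=False)
        _, _, p_mix = lrt_reduced(full, reduced, boundary=True)
        assert p_plain == pytest.approx(sps.chi2.sf(4.0, 1))
        assert p_mix == pytest.approx(0.5 * sps.chi2.sf(4.0, 1))


def _stub_fit(chi2, n_free):
    from ligandtree.calibration import FitResult

    return FitResult(theta={}, chi2=chi2, n_points=10, n_free=n_free, n_starts=1,
                     seed=0, per_start_chi2=[chi2], training_lines=(), free=FreeParameters(),
                     params=KineticParameterSet.defaults(ModelSpec.no_heterodimers()),
                     contexts=[], obs_map=ObservationMap())


class TestCoverage:
    def test_perfect_fit_has_full_coverage(self, small_truth, small_contexts, stimuli):
        data = make_timecourses(small_truth, small_contexts, stimuli=stimuli,
                                seed=2, sigma=0.0)
        assert coverage_fraction(small_truth.model, small_contexts,
                                 small_truth.obs_map, data) == 1.0

    def test_gaussian_residuals_match_normal_mass(self, small_truth, small_contexts,
                                                  noisy_data):
        frac = coverage_fraction(small_truth.model, small_contexts,
                                 small_truth.obs_map, noisy_data, k=2.0)
        n = len(noisy_data)
        expected = 0.9545
        margin = 4 * np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < margin

    def test_small_k_limit(self, small_truth, small_contexts, noisy_data):
        assert coverage_fraction(small_truth.model, small_contexts,
                                 small_truth.obs_map, noisy_data, k=1e-6) < 0.01
        with pytest.raises(ValueError):
            coverage_fraction(small_truth.model, small_contexts,
                              small_truth.obs_map, noisy_data, k=0.0)
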
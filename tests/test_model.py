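import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ligandtree.model import build_model, steady_state
from ligandtree.network import CellLineContext, ModelSpec, StimulusCondition
from ligandtree.params import ConfigurationError, KineticParameterSet

RECEPTOR_NAMES = ("EGFR", "HER2", "ErbB3", "Met", "IGF1R")


class TestBuild:
    def test_full_model_inventory_is_stable(self, full_model):
        spec = ModelSpec.full()
        rebuilt = build_model(spec, KineticParameterSet.defaults(spec))
        assert full_model.nd == 10
        assert rebuilt.n_states == full_model.n_states
        desc = full_model.describe()
        assert desc["n_states"] == len(desc["state_names"])
        # inventory: 5 free monomers + 5 ligand-bound + 2 pools x 10 dimers + 5 downstream
        assert desc["n_states"] == 5 + 5 + 20 + 5

    def test_no_heterodimer_variant_has_five_dimer_pools(self):
        spec = ModelSpec.no_heterodimers()
        model = build_model(spec, KineticParameterSet.defaults(spec))
        assert model.nd == 5

    def test_zero_rate_rejected_with_named_key(self):
        spec = ModelSpec.full()
        params = KineticParameterSet.defaults(spec)
        params.dimer["EGFR-HER2"]["kint"] = 0.0
        with pytest.raises(ConfigurationError, match="EGFR-HER2/kint"):
            build_model(spec, params)

    def test_missing_parameter_names_the_key(self):
        spec = ModelSpec.full()
        params = KineticParameterSet.defaults(spec)
        del params.dimer["EGFR-Met"]
        with pytest.raises(ConfigurationError, match="EGFR-Met"):
            build_model(spec, params)

    def test_nonsignaling_dimer_must_have_zero_weights(self):
        spec = ModelSpec.full()
        params = KineticParameterSet.defaults(spec)
        params.dimer["ErbB3-ErbB3"]["w_pi3k"] = 0.3
        with pytest.raises(ConfigurationError, match="ErbB3-ErbB3"):
            build_model(spec, params)


class TestSteadyState:
    def test_residual_below_tolerance(self, full_model, context):
        basal = steady_state(full_model, context)
        assert basal.residual <= 1e-8

    def test_all_zero_receptors_give_empty_system(self, full_model):
        ctx = CellLineContext("zero", {r: 0.0 for r in RECEPTOR_NAMES})
        basal = full_model.steady_state(ctx)
        assert np.all(basal.x0 == 0.0)

    def test_basal_pegfr_monotone_in_egfr_count(self, full_model, context):
        values = []
        for egfr in (1e4, 5e4, 2e5, 1e6):
            expr = dict(context.receptor_expression, EGFR=egfr)
            ctx = CellLineContext(f"grid-{egfr:g}", expr)
            basal = full_model.steady_state(ctx)
            values.append(float(full_model.observable_matrix("pEGFR") @ basal.x0))
        assert np.all(np.diff(values) > 0)

    def test_doubling_receptors_strictly_increases_signaling_dimers(self, full_model, context):
        b1 = full_model.steady_state(context)
        b2 = full_model.steady_state(context.scaled(2.0))
        ds1, ds2 = b1.x0[full_model._i_ds], b2.x0[full_model._i_ds]
        assert np.all(ds2 > ds1)

    def test_basal_dimer_and_downstream_levels_nonzero(self, full_model, context):
        basal = full_model.steady_state(context)
        assert np.all(basal.x0[full_model._i_ds] > 0)
        assert np.all(basal.x0[-5:] > 0)


class TestSimulate:
    def test_zero_dose_trajectory_constant(self, full_model, context):
        basal = full_model.steady_state(context)
        traj = full_model.simulate(context, StimulusCondition({}))
        x0 = basal.x0
        nonzero = x0 > 0
        rel = np.abs(traj.states[:, nonzero] - x0[nonzero]) / x0[nonzero]
        assert rel.max() < 1e-6
        assert np.abs(traj.states[:, ~nonzero]).max() <= 1e-9

    def test_sustained_vs_transient_egfr_kinetics(self, full_model):
        high = CellLineContext("egfr-high", {"EGFR": 4e5, "HER2": 3e4, "ErbB3": 1.5e4,
                                             "Met": 3e4, "IGF1R": 3e4})
        low = CellLineContext("egfr-low", {"EGFR": 1.9e4, "HER2": 4.8e4, "ErbB3": 1.7e4,
                                           "Met": 3e4, "IGF1R": 3e4})
        stim = StimulusCondition({"EGF": 10.0})
        p_high = full_model.simulate(high, stim).observable("pEGFR")
        p_low = full_model.simulate(low, stim).observable("pEGFR")
        late_over_peak_high = p_high[-1] / p_high.max()
        late_over_peak_low = p_low[-1] / p_low.max()
        # high-EGFR lines hold their signal; low-EGFR lines peak early and decay
        assert late_over_peak_high > 0.9
        assert late_over_peak_low < 0.75
        assert np.argmax(p_low) < np.argmax(p_high)

    def test_costimulation_reduces_perbb3_for_egfr_high_context(self, full_model):
        ctx = CellLineContext("h322-like", {"EGFR": 9.7e4, "HER2": 8.2e4, "ErbB3": 2.9e4,
                                            "Met": 4.9e4, "IGF1R": 3e4})
        hrg = full_model.simulate(ctx, StimulusCondition({"HRG": 2.5})).observable("pErbB3")
        co = full_model.simulate(ctx, StimulusCondition({"EGF": 2.5, "HRG": 2.5})).observable("pErbB3")
        late = slice(6, None)  # from 15 min on
        assert np.all(co[late] < hrg[late])

    def test_mass_conservation_without_turnover(self, full_model, context):
        zero = full_model.zero_turnover()
        basal = full_model.steady_state(context)
        for lig, dose in (("EGF", 5.0), ("HRG", 5.0), ("HGF", 1.0), ("IGF1", 50.0)):
            traj = zero.simulate(None, StimulusCondition({lig: dose}),
                                 x0=basal.x0, synth=np.zeros(full_model.nr))
            totals = zero.receptor_totals(traj)
            assert np.max(np.abs(totals - totals[0]) / totals[0]) < 1e-6

    def test_erbb3_homodimer_contributes_no_downstream_flux(self, full_model, context):
        basal = full_model.steady_state(context)
        i = full_model.dimer_names.index("ErbB3-ErbB3")
        inflated = basal.x0.copy()
        inflated[full_model._i_ds[i]] *= 1e3
        inflated[full_model._i_di[i]] *= 1e3
        f_ref = full_model.rhs(0.0, basal.x0, np.zeros(full_model.nl), basal.synthesis)
        f_inf = full_model.rhs(0.0, inflated, np.zeros(full_model.nl), basal.synthesis)
        assert np.array_equal(f_ref[-5:], f_inf[-5:])

    def test_variant_equivalence_when_igf1r_heterodimers_removed(self, context):
        s12 = ModelSpec.with_igf1r_heterodimers()
        p12 = KineticParameterSet.defaults(s12)
        for name in ("EGFR-IGF1R", "HER2-IGF1R"):
            p12.dimer[name]["ka"] = 1e-30
        m12 = build_model(s12, p12)
        s10 = ModelSpec.full()
        m10 = build_model(s10, KineticParameterSet.defaults(s10))
        stim = StimulusCondition({"EGF": 5.0, "IGF1": 10.0})
        t12, t10 = m12.simulate(context, stim), m10.simulate(context, stim)
        for obs in m10.observable_names:
            a, b = t12.observable(obs), t10.observable(obs)
            assert np.allclose(a, b, rtol=1e-8, atol=1e-12), obs

    def test_unknown_ligand_dose_rejected(self, full_model, context):
        with pytest.raises(ConfigurationError, match="unknown ligand"):
            full_model.simulate(context, StimulusCondition({"FGF": 1.0}))

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(
        expr=st.lists(st.floats(min_value=0, max_value=5.5e6), min_size=5, max_size=5),
        doses=st.lists(st.floats(min_value=0, max_value=50), min_size=4, max_size=4),
    )
    def test_states_remain_nonnegative(self, full_model, expr, doses):
        ctx = CellLineContext("prop", dict(zip(RECEPTOR_NAMES, expr)))
        stim = StimulusCondition(dict(zip(("EGF", "HRG", "HGF", "IGF1"), doses)))
        traj = full_model.simulate(ctx, stim)
        assert traj.states.min() >= -1e-9

    def test_jitted_and_numpy_rhs_agree(self, full_model, context):
        basal = full_model.steady_state(context)
        rng = np.random.default_rng(0)
        u = np.array([5.0, 2.5, 1.0, 50.0, 0.0])
        for _ in range(5):
            x = basal.x0 * rng.uniform(0.5, 2.0, size=full_model.n_states)
            a = full_model.rhs(0.0, x, u, basal.synthesis)
            b = full_model._rhs_numpy(0.0, x, u, basal.synthesis)
            assert np.allclose(a, b, rtol=1e-12, atol=1e-12)

    def test_tidy_export_schema(self, full_model, context):
        traj = full_model.simulate(context, StimulusCondition({"EGF": 5.0}))
        tidy = traj.to_tidy()
        assert list(tidy.columns) == ["cell_line", "ligand_condition", "time_min",
                                      "species", "value"]
        assert set(tidy["species"]) == set(full_model.observable_names)
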
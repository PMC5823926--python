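"""Unit and property tests for the circuit simulator (well model)."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hslpattern.circuitsim import (ARABINOSE_LEVELS, CircuitParams, Condition,
                                   HillParams, hill_response, parameter_set,
                                   qss_state, simulate_plate, simulate_well,
                                   split_and_activity)
from hslpattern.circuitsim.kinetics import burden_penalty, competition_factor


class TestHillResponse:
    def test_zero_input_returns_basal(self):
        p = HillParams(basal=0.7, vmax=5.0, K=2.0, n=1.5)
        assert hill_response(0.0, p) == pytest.approx(0.7)

    def test_saturation_limit(self):
        p = HillParams(basal=0.2, vmax=3.0, K=0.5, n=2.0)
        assert hill_response(1e6 * p.K, p) == pytest.approx(3.2, abs=1e-6)

    def test_half_activation_at_K(self):
        p = HillParams(basal=1.0, vmax=4.0, K=3.0, n=1.0)
        assert hill_response(3.0, p) == pytest.approx(1.0 + 2.0)

    def test_negative_concentration_rejected(self):
        p = HillParams(basal=0.0, vmax=1.0, K=1.0, n=1.0)
        with pytest.raises(ValueError):
            hill_response(-0.1, p)

    @given(st.floats(0, 1e3), st.floats(0, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nondecreasing(self, c1, c2):
        p = HillParams(basal=0.1, vmax=2.0, K=5.0, n=1.7)
        lo, hi = sorted((c1, c2))
        assert hill_response(lo, p) <= hill_response(hi, p) + 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HillParams(basal=-1, vmax=1, K=1, n=1)
        with pytest.raises(ValueError):
            HillParams(basal=0, vmax=1, K=0, n=1)
        with pytest.raises(ValueError):
            HillParams(basal=0, vmax=1, K=1, n=0)


class TestSplitActivity:
    @pytest.mark.parametrize("nf,cf", [(0.0, 5.0), (7.0, 0.0), (0.0, 0.0)])
    def test_and_null_when_either_fragment_absent(self, nf, cf):
        assert split_and_activity(nf, cf, split_K=2.0, vcat=10.0) == 0.0

    def test_quarter_vcat_at_split_K(self):
        assert split_and_activity(3.0, 3.0, split_K=3.0, vcat=8.0) == pytest.approx(2.0)

    def test_negative_fragment_rejected(self):
        with pytest.raises(ValueError):
            split_and_activity(-1.0, 1.0, 1.0, 1.0)


class TestBurdenAndCompetition:
    def test_no_burden_at_zero_load(self):
        p = CircuitParams(burden_threshold=1.0, burden_slope=2.0)
        assert burden_penalty(0.0, p) == 1.0

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing(self, l1, l2):
        p = CircuitParams(burden_threshold=0.5, burden_slope=3.0)
        lo, hi = sorted((l1, l2))
        assert burden_penalty(hi, p) <= burden_penalty(lo, p) + 1e-12

    def test_competition_identity_and_decrease(self):
        assert competition_factor(0.0, 0.3) == 1.0
        vals = [competition_factor(t, 0.3) for t in (0.0, 1.0, 5.0)]
        assert vals[0] > vals[1] > vals[2]


class TestWellModel:
    def test_same_seed_bit_identical(self, reporter_params):
        a = simulate_well(reporter_params, Condition(iptg=1.0),
                          "ratiometric_reporter", seed=7)
        b = simulate_well(reporter_params, Condition(iptg=1.0),
                          "ratiometric_reporter", seed=7)
        for ch in a.values:
            assert np.array_equal(a.values[ch], b.values[ch])

    def test_unknown_genotype_rejected(self, reporter_params):
        with pytest.raises(KeyError):
            simulate_well(reporter_params, Condition(), "no_such_strain")

    def test_nonfinite_condition_rejected(self, reporter_params):
        with pytest.raises(ValueError):
            simulate_well(reporter_params, Condition(iptg=np.nan),
                          "ratiometric_reporter")

    def test_basal_ratio_constant_without_inducer(self, reporter_params):
        """With no inducer and noise off, the YFP/CFP ratio sits at the basal
        steady state throughout the run."""
        ts = simulate_well(reporter_params, Condition(), "ratiometric_reporter",
                           noise=False)
        y = ts.values["YFP"][:, 0] - ts.blanks["YFP"]
        c = ts.values["CFP"][:, 0] - ts.blanks["CFP"]
        early = ts.values["OD600"][:, 0] < 0.1 * reporter_params.carrying_capacity
        ratio = (y / c)[early][5:]
        # dilution tracks the slowly falling logistic growth rate, so the
        # basal ratio is constant to a fraction of a percent, far below the
        # smallest induced fold change
        assert np.ptp(ratio) < 5e-3 * ratio.mean()

    def test_and_null_exact_without_crosstalk(self, and_params_250):
        """RFP with either HSL absent equals the no-HSL baseline exactly when
        the crosstalk leak is switched off."""
        p = and_params_250.evolve(crosstalk_eps=0.0)
        conds = [Condition(), Condition(c6=25.0), Condition(c12=1.0)]
        ts = simulate_plate(p, [(c, "and_full") for c in conds], noise=False)
        rfp = ts.values["RFP"]
        assert np.allclose(rfp[:, 1], rfp[:, 0], rtol=1e-9)
        assert np.allclose(rfp[:, 2], rfp[:, 0], rtol=1e-9)

    def test_crosstalk_only_leak_on_c6_side(self, and_params_250):
        """With the default leak, a lone 3OC12HSL input still matches the
        baseline exactly (crosstalk is Lux-onto-Las only)."""
        conds = [Condition(), Condition(c12=1.0)]
        ts = simulate_plate(and_params_250, [(c, "and_full") for c in conds],
                            noise=False)
        rfp = ts.values["RFP"]
        assert np.allclose(rfp[:, 1], rfp[:, 0], rtol=1e-9)

    def test_intact_titration_is_nonmonotone(self):
        """The intact wild-type enzyme's reporter output declines at high
        arabinose: the maximum sits at an interior dose."""
        p = parameter_set("T7RNAP")
        layout = [(Condition(arabinose=c), "controller") for c in ARABINOSE_LEVELS]
        ts = simulate_plate(p, layout, noise=False)
        y = ts.values["YFP"][-1] - ts.blanks["YFP"]
        c = ts.values["CFP"][-1] - ts.blanks["CFP"]
        ratio = y / c
        k = int(np.argmax(ratio))
        assert 0 < k < len(ARABINOSE_LEVELS) - 1
        assert ratio[-1] < ratio[k]

    def test_slow_growth_matches_independent_qss_algebra(self, and_params_250):
        """In the slow-growth limit the simulated per-cell steady state must
        match a hand-written algebraic solution to <1%."""
        p = and_params_250.evolve(growth_rate=1e-5)
        cond = Condition(c6=5.0, c12=1.0)
        ts = simulate_plate(p, [(cond, "and_full")],
                            schedule=np.arange(0.0, 6001.0, 100.0), noise=False)

        # independent algebra (dilution ~ deg only)
        d = p.deg
        lux, las = p.promoters["P_Lux76*"], p.promoters["P_Las81*"]
        h6 = cond.c6 ** lux.n / (lux.K ** lux.n + cond.c6 ** lux.n)
        h12 = cond.c12 ** las.n / (las.K ** las.n + cond.c12 ** las.n)
        p6 = lux.basal + lux.vmax * h6
        p12 = las.basal + las.vmax * (h12 + p.crosstalk_eps * h6 * (1 - h12))
        eB = p6 / d
        eA = p.rbs_factor(p.nfrag_rbs) * p12 / d
        act = p.vcat * (eA / (p.split_K + eA)) * (eB / (p.split_K + eB))
        flux = p.t7_gain * act
        comp = 1.0 / (1.0 + p.competition_phi * flux)
        expected = {}
        for ch, a in (("CFP", p.fp_rate * p6 * comp),
                      ("YFP", p.fp_rate * p12 * comp),
                      ("RFP", p.t7_basal + flux)):
            km = p.maturation[ch]
            expected[ch] = km * (a / (d + km)) / d

        N = ts.values["OD600"][-1, 0] - p.blanks["OD600"]
        for ch in ("CFP", "YFP", "RFP"):
            xm = (ts.values[ch][-1, 0] - p.blanks[ch]) / (p.gains[ch] * N)
            assert xm == pytest.approx(expected[ch], rel=0.01), ch

    def test_qss_state_agrees_with_hand_algebra(self, and_params_250):
        """The packaged QSS helper solves the same algebra."""
        q = qss_state(and_params_250, "and_full", Condition(c6=5.0, c12=1.0),
                      mu=0.0)
        assert q["rfp_m"] > 0
        ts = simulate_plate(and_params_250.evolve(growth_rate=1e-5),
                            [(Condition(c6=5.0, c12=1.0), "and_full")],
                            schedule=np.arange(0.0, 6001.0, 100.0), noise=False)
        N = ts.values["OD600"][-1, 0] - and_params_250.blanks["OD600"]
        xm = (ts.values["RFP"][-1, 0] - and_params_250.blanks["RFP"]) / (25.0 * N)
        assert xm == pytest.approx(q["rfp_m"], rel=0.01)

    def test_ratiometric_gain_invariance(self, reporter_params):
        """Scaling every channel gain by a common factor leaves the
        ratiometric activity unchanged."""
        from hslpattern.ratiometrics import (detect_exponential_phase,
                                             relative_promoter_activity)
        cond = Condition(iptg=1.0)
        acts = []
        for fac in (1.0, 3.0):
            p = reporter_params.evolve(
                gains={k: v * fac for k, v in reporter_params.gains.items()},
                blanks={k: (v * fac if k != "OD600" else v)
                        for k, v in reporter_params.blanks.items()})
            ts = simulate_well(p, cond, "ratiometric_reporter", noise=False)
            w = detect_exponential_phase(ts.times, ts.values["OD600"][:, 0],
                                         ts.blanks["OD600"])
            acts.append(relative_promoter_activity(ts, 0, w))
        assert acts[0] == pytest.approx(acts[1], rel=1e-9)
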
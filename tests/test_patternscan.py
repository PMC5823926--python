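"""Tests for spatial quantification, profiles, domain calls, and
effective-HSL estimation."""
import numpy as np
import pytest

from hslpattern import patternscan as ps
from hslpattern.circuitsim import (Condition, GridSpec, parameter_set,
                                   sender_grid, simulate_membrane)


def grid_rects(nq=8, h=10, w=5):
    return [(slice(0, h), slice(q * w, (q + 1) * w)) for q in range(nq)]


class TestQuantifyQuadrants:
    def test_uniform_image(self):
        img = np.full((10, 40), 3.7)
        assert np.allclose(ps.quantify_quadrants(img, grid_rects()), 3.7)

    def test_checkerboard_exact(self):
        img = np.zeros((10, 40))
        for q in range(8):
            if q % 2:
                img[:, q * 5:(q + 1) * 5] = 1.0
        vals = ps.quantify_quadrants(img, grid_rects())
        assert np.array_equal(vals, np.array([0, 1, 0, 1, 0, 1, 0, 1], float))

    def test_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(9)
        img = rng.normal(size=(10, 40))
        vals = ps.quantify_quadrants(img, grid_rects())
        for q, (rs, cs) in enumerate(grid_rects()):
            total = 0.0
            count = 0
            for i in range(rs.start, rs.stop):
                for j in range(cs.start, cs.stop):
                    total += img[i, j]
                    count += 1
            assert vals[q] == pytest.approx(total / count)

    def test_table_passthrough(self):
        t = np.arange(5.0)
        assert np.array_equal(ps.quantify_quadrants(t, []), t)

    def test_overlapping_rectangles_rejected(self):
        img = np.zeros((10, 40))
        rects = [(slice(0, 10), slice(0, 6)), (slice(0, 10), slice(5, 10))]
        with pytest.raises(ValueError, match="overlap"):
            ps.quantify_quadrants(img, rects)

    def test_empty_quadrant_rejected(self):
        img = np.zeros((10, 40))
        with pytest.raises(ValueError, match="empty"):
            ps.quantify_quadrants(img, [(slice(0, 0), slice(0, 5))])


@pytest.fixture(scope="module")
def membrane_pair():
    p = parameter_set("and_rbs250")
    sched = np.arange(0.0, 1501.0, 100.0)
    tr = simulate_membrane(p, GridSpec(), "uniform", Condition(c6=5.0, c12=1.0),
                           schedule=sched)
    ct = simulate_membrane(p, GridSpec(), "uniform", Condition(), schedule=sched)
    return tr, ct


class TestPositionProfile:
    def test_treatment_equals_control_gives_zero(self, membrane_pair):
        tr, _ = membrane_pair
        prof = ps.position_profile(tr, tr, 1500.0)
        for ch in ("CFP", "YFP", "RFP"):
            assert np.allclose(prof.mean[ch], 0.0)

    def test_single_replicate_sd_zero(self, membrane_pair):
        tr, ct = membrane_pair
        prof = ps.position_profile(tr, ct, 1500.0)
        assert all(np.all(prof.sd[ch] == 0.0) for ch in prof.sd)

    def test_identical_replicates_sd_zero(self, membrane_pair):
        tr, ct = membrane_pair
        prof = ps.position_profile([tr, tr], [ct, ct], 1500.0)
        assert all(np.all(prof.sd[ch] == 0.0) for ch in prof.sd)

    def test_matches_direct_recomputation(self):
        p = parameter_set("and_rbs250")
        sched = np.arange(0.0, 601.0, 60.0)
        trs = [simulate_membrane(p, GridSpec(), "uniform",
                                 Condition(c6=5.0, c12=1.0), schedule=sched,
                                 seed=s, noise=True) for s in (1, 2, 3)]
        ct = simulate_membrane(p, GridSpec(), "uniform", Condition(),
                               schedule=sched, seed=9, noise=True)
        prof = ps.position_profile(trs, [ct] * 3, 600.0)
        stacked = np.stack([t.channels["RFP"][-1] - ct.channels["RFP"][-1]
                            for t in trs])
        assert np.allclose(prof.mean["RFP"], stacked.mean(axis=0))
        assert np.allclose(prof.sd["RFP"], stacked.std(axis=0, ddof=1))

    def test_grid_mismatch_rejected(self, membrane_pair):
        tr, _ = membrane_pair
        p = parameter_set("and_rbs250")
        other = simulate_membrane(p, GridSpec(n_quadrants=12, boundary_index=6),
                                  "uniform", Condition(),
                                  schedule=np.arange(0.0, 301.0, 60.0))
        with pytest.raises(ValueError, match="grids"):
            ps.position_profile(tr, other, 300.0)

    def test_profile_correction_is_exact(self, membrane_pair):
        """Adding the same constant field to treatment and control leaves the
        profile unchanged."""
        tr, ct = membrane_pair
        base = ps.position_profile(tr, ct, 1500.0)
        import copy
        tr2, ct2 = copy.deepcopy(tr), copy.deepcopy(ct)
        for ch in tr2.channels:
            tr2.channels[ch] = tr2.channels[ch] + 500.0
            ct2.channels[ch] = ct2.channels[ch] + 500.0
        shifted = ps.position_profile(tr2, ct2, 1500.0)
        for ch in base.mean:
            assert np.allclose(base.mean[ch], shifted.mean[ch])


def profile_from(y, boundary=12):
    y = np.asarray(y, dtype=float)
    return ps.SpatialProfile(positions=np.arange(1, len(y) + 1),
                             mean={"RFP": y}, sd={"RFP": np.zeros(len(y))},
                             time=3000.0, meta={"boundary_index": boundary})


class TestDomainDetection:
    def test_spike_at_interface(self):
        y = np.zeros(24)
        y[11] = y[12] = 10.0
        call = ps.detect_interface_domain(profile_from(y), "RFP")
        assert (call.start, call.end) == (12, 13)
        assert call.peak == 12  # leftmost tie-break
        assert call.symmetry == pytest.approx(1.0)

    def test_flat_profile_gives_no_domain(self):
        call = ps.detect_interface_domain(profile_from(np.zeros(24)), "RFP")
        assert not call.found

    def test_translation_covariance(self):
        y = np.zeros(24)
        y[8:12] = [2.0, 5.0, 4.0, 2.0]
        a = ps.detect_interface_domain(profile_from(y), "RFP")
        b = ps.detect_interface_domain(profile_from(np.roll(y, 3)), "RFP")
        assert (b.start, b.peak, b.end) == (a.start + 3, a.peak + 3, a.end + 3)

    def test_symmetric_profile_scores_one(self):
        x = np.arange(24)
        y = np.exp(-((x - 11.5) ** 2) / 8.0)
        call = ps.detect_interface_domain(profile_from(y), "RFP")
        assert call.symmetry == pytest.approx(1.0, abs=1e-9)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            ps.detect_interface_domain(profile_from(np.ones(4)), "RFP")

    def test_sender_simulation_peak_adjacent_to_boundary(self):
        """Deterministic symmetric sender run: the left-half argmax sits at
        quadrant 12 (exhaustive argmax as oracle)."""
        p = parameter_set("and_rbs250")
        ind = simulate_membrane(p, sender_grid(), "senders",
                                Condition(arabinose=25.0))
        ctl = simulate_membrane(p, sender_grid(), "senders",
                                Condition(arabinose=0.0))
        prof = ps.position_profile(ind, ctl, 3000.0)
        call = ps.detect_interface_domain(prof, "RFP")
        rfp = prof.mean["RFP"]
        brute_left = max(range(12), key=lambda i: rfp[i]) + 1
        assert brute_left == 12
        assert call.start <= 12 <= call.end or call.start <= 13 <= call.end


class TestEffectiveHsl:
    def test_linear_standards_bracket(self):
        standards = {c: 10.0 * c for c in (0.25, 0.5, 1.0, 2.0)}
        est = ps.estimate_effective_hsl(5.0, standards)
        assert est.low <= 0.5 <= est.high
        assert est.point == pytest.approx(0.5)

    def test_below_lowest_standard_is_open(self):
        standards = {c: 10.0 * c for c in (0.25, 0.5, 1.0)}
        est = ps.estimate_effective_hsl(1.0, standards)
        assert est.open_below and est.high == 0.25

    def test_above_highest_standard_is_open(self):
        standards = {c: 10.0 * c for c in (0.25, 0.5, 1.0)}
        est = ps.estimate_effective_hsl(50.0, standards)
        assert est.open_above and est.low == 1.0

    def test_too_few_standards_rejected(self):
        with pytest.raises(ValueError):
            ps.estimate_effective_hsl(1.0, {0.5: 5.0, 1.0: 10.0})

    def test_isotonic_cleanup_of_noisy_standards(self):
        standards = {0.25: 2.0, 0.5: 6.0, 1.0: 5.5, 2.0: 12.0}
        est = ps.estimate_effective_hsl(5.8, standards)
        assert est.low is not None and est.high is not None
        assert 0.25 <= est.point <= 2.0

    def test_sender_far_quadrant_estimate_submicromolar(self):
        """Effective 3OC6HSL at the quadrant farthest from the interface,
        read off uniform-HSL standard curves, lands in a sub-micromolar
        bracket."""
        p = parameter_set("and_rbs250")
        g24 = GridSpec(n_quadrants=24)
        ctl_u = simulate_membrane(p, g24, "uniform", Condition())
        standards = {}
        for c in (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0):
            ms = simulate_membrane(p, g24, "uniform", Condition(c6=c))
            prof = ps.position_profile(ms, ctl_u, 3000.0)
            standards[c] = float(prof.mean["CFP"].mean())
        ind = simulate_membrane(p, sender_grid(), "senders",
                                Condition(arabinose=25.0))
        ctl = simulate_membrane(p, sender_grid(), "senders",
                                Condition(arabinose=0.0))
        prof = ps.position_profile(ind, ctl, 3000.0)
        est = ps.estimate_effective_hsl(float(prof.mean["CFP"][0]), standards)
        assert est.high is not None and est.high <= 1.0
        assert est.low is None or est.low >= 0.1
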
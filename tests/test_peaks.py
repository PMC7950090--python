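import numpy as np
import pytest

from oracles import oracle_pick_peaks, random_histogram

from shiftprofiler import (
    ConfigurationError,
    MassShiftHistogram,
    ShepherdConfig,
    assign_psms_to_peaks,
    build_histogram,
    compute_prominence,
    compute_snr,
    flatten_for_prominence,
    pick_peaks,
    quantify_peaks,
    smooth_histogram,
)
from shiftprofiler.model import ExperimentSet, PSMRecord


def _psm(mass, exp="A", i=0):
    return PSMRecord(f"{exp}.{i}", exp, "PEPTIDEK", mass, 100.0, 2)


class TestFlatten:
    def test_hand_example(self):
        out = flatten_for_prominence(np.array([5, 4, 6, 2, 9, 1.0]), 2)
        np.testing.assert_array_equal(out, [4, 4, 2, 2, 1, 1])

    def test_set_size_one_is_identity(self):
        w = np.array([3.0, 1.0, 4.0])
        np.testing.assert_array_equal(flatten_for_prominence(w, 1), w)

    def test_partial_tail_group(self):
        out = flatten_for_prominence(np.array([5, 4, 6, 2, 9.0]), 2)
        np.testing.assert_array_equal(out, [4, 4, 2, 2, 9])

    def test_never_exceeds_input(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.random(int(rng.integers(1, 60)))
            s = int(rng.integers(1, 8))
            assert np.all(flatten_for_prominence(w, s) <= w + 1e-15)


class TestProminence:
    def test_isolated_peak(self):
        assert compute_prominence(np.array([0, 1, 3, 1, 0.0]), 2) == 1.0

    def test_shoulder_example_below_threshold(self):
        prom = compute_prominence(np.array([2, 3, 2.5]), 1)
        assert prom == pytest.approx((3 - 2.5) / 3)
        assert prom < 0.3

    def test_zero_apex_rejected(self):
        with pytest.raises(Exception):
            compute_prominence(np.array([0.0, 0.0]), 0)


class TestSnr:
    def test_signal_minus_background(self):
        w = np.ones(200)
        w[90:110] = 5.0
        snr = compute_snr(w, 100, 0.004, 0.005, 0.0002)
        assert snr == pytest.approx(4.0)

    def test_flat_histogram_zero(self):
        w = np.full(200, 2.0)
        assert compute_snr(w, 100, 0.004, 0.005, 0.0002) == 0.0

    def test_zero_bin_flank_is_config_error(self):
        with pytest.raises(ConfigurationError):
            compute_snr(np.ones(50), 25, 0.004, 0.00001, 0.0002)


class TestPickPeaks:
    def _implanted_hist(self, seed=0, n_peaks=10):
        rng = np.random.default_rng(seed)
        cfg = ShepherdConfig(jitter_half_width=0.0)
        centers = np.linspace(-1.0, 1.0, n_peaks)
        masses = np.concatenate(
            [rng.normal(c, 0.0004, 120) for c in centers]
            + [rng.uniform(-1.5, 1.5, 60)]
        )
        hist = build_histogram(
            [_psm(m, i=i) for i, m in enumerate(masses)], cfg
        )
        return smooth_histogram(hist, 5, 0.95), centers, cfg

    def test_implanted_peaks_recovered(self):
        sm, centers, cfg = self._implanted_hist()
        peaks = pick_peaks(sm, cfg)
        strong = [p for p in peaks if p.snr > 1.0]
        assert len(strong) == len(centers)
        for c in centers:
            err = min(abs(p.apex_mass - c) for p in strong)
            assert err <= sm.bin_width

    def test_raising_threshold_only_removes(self):
        sm, _, cfg = self._implanted_hist()
        lo = {p.apex_index for p in pick_peaks(sm, cfg)}
        hi_cfg = ShepherdConfig(prominence_threshold=0.8, jitter_half_width=0.0)
        hi = {p.apex_index for p in pick_peaks(sm, hi_cfg)}
        assert hi <= lo

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hist = random_histogram(rng)
        cfg = ShepherdConfig()
        got = pick_peaks(hist, cfg)
        expected = oracle_pick_peaks(hist, cfg)
        assert [p.apex_index for p in got] == [r[0] for r in expected]
        for p, r in zip(got.peaks, expected):
            assert p.prominence == pytest.approx(r[2], rel=1e-9)
            assert p.snr == pytest.approx(r[3], rel=1e-9, abs=1e-12)
            assert p.left_bound == pytest.approx(r[4], abs=1e-12)
            assert p.right_bound == pytest.approx(r[5], abs=1e-12)

    def test_doubling_weights_preserves_calls_and_doubles_snr(self):
        sm, _, cfg = self._implanted_hist()
        doubled = MassShiftHistogram(sm.lo, sm.bin_width, sm.weights * 2)
        a = pick_peaks(sm, cfg)
        b = pick_peaks(doubled, cfg)
        assert [p.apex_index for p in a] == [p.apex_index for p in b]
        for pa, pb in zip(a.peaks, b.peaks):
            assert pb.snr == pytest.approx(2 * pa.snr, rel=1e-9)


class TestAssignment:
    def _peakset(self):
        cfg = ShepherdConfig(jitter_half_width=0.0)
        rng = np.random.default_rng(1)
        masses = np.concatenate(
            [rng.normal(0.0, 0.0004, 200), rng.normal(15.9949, 0.0004, 100)]
        )
        psms = [_psm(m, i=i) for i, m in enumerate(masses)]
        sm = smooth_histogram(build_histogram(psms, cfg), 5, 0.95)
        return pick_peaks(sm, cfg), psms

    def test_containment_and_disjointness(self):
        peakset, psms = self._peakset()
        assign_psms_to_peaks(peakset, psms)
        seen = set()
        for p in peakset.peaks:
            for psm in p.assigned_psms():
                assert p.left_bound <= psm.delta_mass <= p.right_bound
                assert psm.spectrum_id not in seen
                seen.add(psm.spectrum_id)
        assert len(seen) <= len(psms)

    def test_psm_outside_all_bounds_unassigned(self):
        peakset, psms = self._peakset()
        stray = _psm(14.5, i=9999)
        assign_psms_to_peaks(peakset, psms + [stray])
        for p in peakset.peaks:
            assert stray not in p.assigned_psms()

    def test_reported_mass_near_truth(self):
        peakset, psms = self._peakset()
        assign_psms_to_peaks(peakset, psms)
        best = min(peakset.peaks, key=lambda p: abs(p.apex_mass - 15.9949))
        assert best.reported_mass == pytest.approx(15.9949, abs=2e-4)


class TestQuantify:
    def test_normalized_counts(self):
        peakset, psms = TestAssignment()._peakset()
        assign_psms_to_peaks(peakset, psms)
        es = ExperimentSet(experiments={"A": psms})
        df = quantify_peaks(peakset, es)
        pooled = df[df.experiment == "(all)"]
        per_a = df[df.experiment == "A"]
        assert (per_a["normalized"] == per_a["count"] / len(psms)).all()
        assert per_a["normalized"].sum() <= 1.0 + 1e-12
        assert (pooled["count"].to_numpy() == per_a["count"].to_numpy()).all()

    def test_empty_experiment_reports_zero(self):
        peakset, psms = TestAssignment()._peakset()
        assign_psms_to_peaks(peakset, psms)
        es = ExperimentSet(experiments={"A": psms, "B": []})
        df = quantify_peaks(peakset, es)
        b = df[df.experiment == "B"]
        assert (b["count"] == 0).all()
        assert (b["normalized"] == 0.0).all()

    def test_same_count_different_totals(self):
        cfg = ShepherdConfig(jitter_half_width=0.0)
        rng = np.random.default_rng(2)
        a = [_psm(float(m), "A", i) for i, m in enumerate(rng.normal(0, 0.0004, 50))]
        b = [_psm(float(m), "B", i) for i, m in enumerate(rng.normal(0, 0.0004, 50))]
        filler = [_psm(float(m), "B", 1000 + i) for i, m in enumerate(rng.normal(5.0, 0.0004, 50))]
        psms = a + b + filler
        sm = smooth_histogram(build_histogram(psms, cfg), 5, 0.95)
        peakset = assign_psms_to_peaks(pick_peaks(sm, cfg), psms)
        es = ExperimentSet(experiments={"A": a, "B": b + filler})
        df = quantify_peaks(peakset, es)
        zero_peak = min(
            range(len(peakset.peaks)),
            key=lambda k: abs(peakset.peaks[k].apex_mass),
        )
        row_a = df[(df.peak == zero_peak) & (df.experiment == "A")].iloc[0]
        row_b = df[(df.peak == zero_peak) & (df.experiment == "B")].iloc[0]
        assert row_a["count"] == row_b["count"] == 50
        assert row_a["normalized"] == 1.0
        assert row_b["normalized"] == 0.5
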
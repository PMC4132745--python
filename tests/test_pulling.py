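"""Force-extension fitting, loop-rupture analysis and compaction."""

import copy

import numpy as np
import pytest
from statsmodels.stats.stattools import durbin_watson

from smtether.polymer import ForceExtensionCurve, wlc_extension
from smtether.pulling import (
    NM_PER_BP,
    ExponentialDecay,
    FitRangeError,
    NonDecayingError,
    analyze_loops,
    compaction_fit,
    compaction_force,
    detect_loop_jumps,
    fit_force_extension,
    loop_histograms,
    overstretch_force,
    size_loop,
)
from smtether.synth import simulate_compaction, simulate_fec


class TestForceExtensionFit:
    def test_noiseless_recovery(self, wlc_params):
        curve = simulate_fec(noise_force=0.0, seed=0)
        params, ses = fit_force_extension(curve)
        assert params.P_ds == pytest.approx(50.0, rel=1e-3)
        assert params.B_ds == pytest.approx(0.34, rel=1e-3)
        assert params.S_ds == pytest.approx(1200.0, rel=1e-3)

    def test_noisy_persistence_recovery(self):
        recovered = []
        for seed in range(50):
            curve = simulate_fec(noise_force=0.3, seed=seed)
            params, _ = fit_force_extension(curve)
            recovered.append(params.P_ds)
        assert np.median(np.abs(np.array(recovered) - 50.0) / 50.0) < 0.05

    def test_insufficient_force_range(self):
        curve = simulate_fec(b_min=0.10, b_max=0.20, noise_force=0.0, seed=0)
        with pytest.raises(FitRangeError):
            fit_force_extension(curve)


class TestOverstretchForce:
    def test_flat_plateau(self):
        curve = simulate_fec(b_max=0.50, f_ov=62.0, noise_force=0.0, seed=0)
        mean, se = overstretch_force(curve)
        assert mean == pytest.approx(62.0, abs=1e-9)

    def test_noisy_plateau_within_three_se(self):
        curve = simulate_fec(b_max=0.50, f_ov=62.0, noise_force=1.0,
                             n_points=1200, seed=1)
        mean, se = overstretch_force(curve)
        assert abs(mean - 62.0) <= 3 * se

    def test_truncated_curve_raises(self):
        curve = simulate_fec(b_max=0.41, noise_force=0.0, seed=0)
        with pytest.raises(ValueError, match="window"):
            overstretch_force(curve)


ROSTER = [(600, 8.0), (700, 12.0), (800, 16.0)]


class TestLoopDetection:
    def test_smooth_curve_has_no_events(self):
        for seed in range(5):
            curve = simulate_fec(noise_force=0.25, seed=seed)
            assert detect_loop_jumps(curve) == []

    def test_zero_false_positives_over_many_noisy_curves(self):
        n_fp = sum(
            len(detect_loop_jumps(simulate_fec(noise_force=0.3, seed=s)))
            for s in range(100)
        )
        assert n_fp == 0

    def test_injected_events_are_found_at_their_extensions(self):
        curve = simulate_fec(loops=ROSTER, noise_force=0.0, seed=0)
        idx = detect_loop_jumps(curve)
        assert len(idx) == 3
        # each detected index must sit within 2 samples of a true release,
        # identified from the noiseless force drops
        drops = np.flatnonzero(np.diff(curve.force) < -1.0)
        for i, j in zip(idx, drops):
            assert abs(i - j) <= 2

    def test_small_jump_not_reported(self, wlc_params):
        # a genuine release whose force discontinuity stays below 1 pN:
        # at the rupture extension the force falls from 10 pN to the value
        # of the loop-free branch (computed analytically)
        from smtether.polymer import wlc_force

        n_bp, loop = 48_500, 70
        curve = simulate_fec(loops=[(loop, 10.0)], noise_force=0.0, seed=0)
        b_at_rupture = wlc_extension(10.0, wlc_params)  # nm/bp of shortened tether
        x_rupture = b_at_rupture * (n_bp - loop)
        delta_F = 10.0 - wlc_force(x_rupture / n_bp, wlc_params)
        assert 0 < delta_F < 1.0
        assert detect_loop_jumps(curve, min_delta_F=1.0) == []

    def test_release_curves_rejected(self):
        curve = simulate_fec(noise_force=0.0, seed=0)
        release = ForceExtensionCurve(
            extension=curve.extension, force=curve.force,
            n_bp=curve.n_bp, direction="release",
        )
        with pytest.raises(ValueError):
            detect_loop_jumps(release)


class TestLoopSizing:
    def test_loop_size_formula(self):
        # 0.0034 nm/bp of contour change on a 48,500 bp molecule is 485 bp
        assert 0.0034 * 48_500 / NM_PER_BP == pytest.approx(485.0)
        assert 0.0 * 48_500 / NM_PER_BP == 0.0

    def test_single_loop_round_trip(self):
        curve = simulate_fec(loops=[(500, 10.0)], noise_force=0.0, seed=0)
        events = analyze_loops(curve, fixed_P=50.0, fixed_S=1200.0)
        assert len(events) == 1
        assert events[0].loop_bp == pytest.approx(500.0, rel=0.10)
        assert events[0].B_after > events[0].B_before

    def test_sequestered_length_conservation(self):
        curve = simulate_fec(loops=ROSTER, noise_force=0.3, seed=3)
        events = analyze_loops(curve, fixed_P=50.0, fixed_S=1200.0)
        assert len(events) == 3
        total = sum(e.loop_bp for e in events)
        assert total == pytest.approx(2100.0, rel=0.10)

    def test_sizing_stable_under_small_noise(self):
        sizes = []
        for seed in range(10):
            curve = simulate_fec(loops=[(700, 12.0)], noise_force=0.2, seed=seed)
            events = analyze_loops(curve, fixed_P=50.0, fixed_S=1200.0)
            assert len(events) == 1
            sizes.append(events[0].loop_bp)
        assert np.std(sizes) / np.mean(sizes) < 0.05
        assert np.mean(sizes) == pytest.approx(700.0, rel=0.05)

    def test_short_flank_raises_sizing_error(self):
        from smtether.pulling import SizingError

        curve = simulate_fec(loops=[(500, 10.0)], noise_force=0.0, seed=0)
        [idx] = detect_loop_jumps(curve)
        truncated = ForceExtensionCurve(
            extension=curve.extension[: idx + 3], force=curve.force[: idx + 3],
            n_bp=curve.n_bp,
        )
        with pytest.raises(SizingError):
            size_loop(truncated, idx, fixed_P=50.0, fixed_S=1200.0)


class TestLoopHistograms:
    def test_modal_bin_brackets_events(self):
        # fine grid: these releases sit close together on the force axis
        curve = simulate_fec(loops=[(450, 8.0), (500, 12.0), (550, 16.0)],
                             noise_force=0.0, seed=0, n_points=1500)
        events = analyze_loops(curve, fixed_P=50.0, fixed_S=1200.0)
        hists = loop_histograms(events, bp_bin=200.0)
        lo, hi = hists["loop_bp"]["modal_bin"]
        assert lo >= 400.0 and hi <= 800.0
        assert hists["n_events"] == 3

    def test_subthreshold_events_censored(self):
        curve = simulate_fec(loops=[(700, 12.0)], noise_force=0.0, seed=0)
        events = analyze_loops(curve, fixed_P=50.0, fixed_S=1200.0)
        hists = loop_histograms(events, min_delta_F=10.0)
        assert hists["n_events"] == 0
        assert hists["n_censored"] == 1

    def test_empty_events_warn(self):
        with pytest.warns(UserWarning):
            hists = loop_histograms([])
        assert hists["n_events"] == 0


class TestCompaction:
    def test_noiseless_rate_recovery(self):
        t, x = simulate_compaction(k=0.64, noise_frac=0.0, seed=0)
        res = compaction_fit(t, x)
        assert res.k == pytest.approx(0.64, abs=1e-6)
        assert res.tau == pytest.approx(1.0 / 0.64, abs=1e-6)

    def test_noisy_rate_recovery(self):
        ks = []
        for seed in range(30):
            t, x = simulate_compaction(k=0.64, noise_frac=0.05, seed=seed)
            ks.append(compaction_fit(t, x).k)
        assert np.median(np.abs(np.array(ks) - 0.64) / 0.64) < 0.15

    def test_non_decaying_series_rejected(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(NonDecayingError):
            compaction_fit(t, np.linspace(0.0, 5.0, 50))

    def test_residuals_trend_free(self):
        t, x = simulate_compaction(k=0.64, noise_frac=0.05, seed=5)
        est = ExponentialDecay().fit(t, x)
        resid = x - est.predict(t)
        assert 1.5 <= durbin_watson(resid) <= 2.5


class TestCompactionForce:
    def test_identical_curves_give_zero(self):
        naked = simulate_fec(b_min=0.02, noise_force=0.0, seed=0, n_points=400)
        dF, se = compaction_force(naked, naked)
        assert dF == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_recovered(self):
        naked = simulate_fec(b_min=0.02, noise_force=0.0, seed=0, n_points=400)
        prot = copy.deepcopy(naked)
        prot.force = prot.force + 1.7
        dF, se = compaction_force(prot, naked)
        assert dF == pytest.approx(1.7, abs=1e-9)

    def test_noisy_offset_within_three_se(self):
        naked = simulate_fec(b_min=0.02, noise_force=0.1, seed=1, n_points=400)
        prot = simulate_fec(b_min=0.02, noise_force=0.1, seed=2, n_points=400)
        prot.force = prot.force + 2.0
        dF, se = compaction_force(prot, naked)
        assert abs(dF - 2.0) <= 3 * np.hypot(se, se)

    def test_non_overlapping_ranges_raise(self):
        naked = simulate_fec(b_min=0.02, b_max=0.05, noise_force=0.0, seed=0)
        prot = simulate_fec(b_min=0.30, noise_force=0.0, seed=0)
        with pytest.raises(ValueError):
            compaction_force(prot, naked)
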
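"""AFM trace quantification: bend angles, loops, bridges, persistence."""

import numpy as np
import pytest

from smtether.afm import (
    Annotation,
    Trace2D,
    afm_persistence,
    bend_angle_at_site,
    bridge_summary,
    fit_bigaussian,
    loop_size_bp,
)
from smtether.synth import simulate_chain_2d


def kinked_trace(angle_deg: float, arm: float = 50.0, step: float = 1.0) -> Trace2D:
    """Two straight arms meeting at the origin with the given turn angle."""
    n = int(arm / step)
    t1 = np.column_stack([np.arange(-n, 1) * step, np.zeros(n + 1)])
    a = np.radians(angle_deg)
    d = np.array([np.cos(a), np.sin(a)])
    t2 = np.arange(1, n + 1)[:, None] * step * d
    return Trace2D("kink", np.vstack([t1, t2]))


class TestBendAngle:
    def test_straight_trace_is_zero(self):
        assert kinked_trace(0.0).points.shape[0] > 3
        assert bend_angle_at_site(kinked_trace(0.0), 50) == pytest.approx(0.0, abs=1e-9)

    def test_right_angle(self):
        assert bend_angle_at_site(kinked_trace(90.0), 50) == pytest.approx(90.0, abs=1e-9)

    def test_programmed_kink_recovered(self):
        tr = simulate_chain_2d(p=1e6, contour_length=1400.0,
                               kinks=[(700.0, 40.0)], seed=0)
        site = tr.annotations[0].start_index
        assert bend_angle_at_site(tr, site) == pytest.approx(40.0, abs=2.0)

    def test_rotation_and_mirror_invariance(self):
        tr = kinked_trace(37.0)
        base = bend_angle_at_site(tr, 50)
        a = 0.8
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        rotated = Trace2D("r", tr.points @ R.T + [40.0, -9.0])
        mirrored = Trace2D("m", tr.points * [1.0, -1.0])
        assert bend_angle_at_site(rotated, 50) == pytest.approx(base, abs=1e-9)
        assert bend_angle_at_site(mirrored, 50) == pytest.approx(base, abs=1e-9)

    def test_site_near_end_rejected(self):
        with pytest.raises(ValueError, match="end"):
            bend_angle_at_site(kinked_trace(40.0), 2)


class TestBiGaussian:
    def test_symmetric_sample_gives_symmetric_widths(self, rng):
        angles = np.clip(np.abs(rng.normal(40.0, 10.0, 1000)), 0, 180)
        stats = fit_bigaussian(angles)
        assert stats.fit_ok
        assert stats.center == pytest.approx(40.0, abs=2.0)
        assert stats.sigma_left == pytest.approx(stats.sigma_right, rel=0.15)

    def test_asymmetric_widths_recovered(self, rng):
        n = 2000
        left = rng.random(n) < 8.0 / 28.0
        x = np.where(left, 40.0 - np.abs(rng.normal(0, 8.0, n)),
                     40.0 + np.abs(rng.normal(0, 20.0, n)))
        stats = fit_bigaussian(np.clip(x, 0, 180))
        assert stats.center == pytest.approx(40.0, abs=2.0)
        assert stats.sigma_left == pytest.approx(8.0, rel=0.15)
        assert stats.sigma_right == pytest.approx(20.0, rel=0.15)

    def test_sample_statistics_always_reported(self, rng):
        angles = np.clip(np.abs(rng.normal(38.0, 33.0, 500)), 0, 180)
        stats = fit_bigaussian(angles)
        assert stats.mean_reported == pytest.approx(np.mean(angles))
        assert stats.sd_reported == pytest.approx(np.std(angles, ddof=1))

    def test_degenerate_input_rejects_fit_keeps_stats(self):
        stats = fit_bigaussian(np.full(40, 35.0))
        assert not stats.fit_ok
        assert stats.mean_reported == pytest.approx(35.0)

    def test_too_few_angles(self):
        with pytest.raises(ValueError):
            fit_bigaussian(np.linspace(0, 90, 10))

    def test_two_gaussian_mode(self, rng):
        angles = np.clip(np.concatenate([
            rng.normal(25.0, 6.0, 800), rng.normal(80.0, 8.0, 400)
        ]), 0, 180)
        stats = fit_bigaussian(angles, mode="two_gaussians")
        assert stats.fit_ok
        # dominant component is the low-angle peak
        assert stats.center == pytest.approx(25.0, abs=4.0)


class TestLoopSize:
    @staticmethod
    def circle(circumference: float, n: int = 201) -> Trace2D:
        th = np.linspace(0, 2 * np.pi, n)
        r = circumference / (2 * np.pi)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        return Trace2D("c", pts, annotations=[Annotation("loop", 0, n - 1)])

    def test_default_calibration(self):
        tr = self.circle(170.0)
        assert loop_size_bp(tr, tr.annotations[0]) == pytest.approx(500.0, rel=1e-3)

    def test_molecule_calibration(self):
        tr = self.circle(170.0)
        tr.n_bp = int(round(tr.contour_length() / 0.30))
        assert loop_size_bp(tr, tr.annotations[0], calibration="molecule") == (
            pytest.approx(170.0 / 0.30, rel=1e-2)
        )

    def test_scales_linearly_with_circumference(self):
        s1 = loop_size_bp(self.circle(100.0), self.circle(100.0).annotations[0])
        s3 = loop_size_bp(self.circle(300.0), self.circle(300.0).annotations[0])
        assert s3 == pytest.approx(3.0 * s1, rel=1e-6)

    def test_open_circuit_rejected(self):
        th = np.linspace(0, np.pi, 50)  # half circle: endpoints far apart
        pts = np.column_stack([50 * np.cos(th), 50 * np.sin(th)])
        tr = Trace2D("o", pts, annotations=[Annotation("loop", 0, 49)])
        with pytest.raises(ValueError, match="closed"):
            loop_size_bp(tr, tr.annotations[0])


class TestBridges:
    @staticmethod
    def trace_with(n_bridges: int, seed: int) -> Trace2D:
        tr = simulate_chain_2d(p=50.0, contour_length=300.0, seed=seed)
        tr.annotations = [Annotation("bridge", 0, 0)] * n_bridges
        return tr

    def test_matching_counts(self):
        # 10 molecules, 7 bridged, 20 bridges in total
        counts = [6, 3, 2, 2, 3, 2, 2, 0, 0, 0]
        traces = [self.trace_with(c, i) for i, c in enumerate(counts)]
        frac, mean = bridge_summary(traces)
        assert frac == pytest.approx(0.70)
        assert mean == pytest.approx(2.0)

    def test_no_annotations(self):
        traces = [self.trace_with(0, i) for i in range(5)]
        assert bridge_summary(traces) == (0.0, 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bridge_summary([])

    def test_bernoulli_fraction_within_binomial_interval(self, rng):
        n = 174
        has = rng.random(n) < 0.7
        traces = [self.trace_with(int(h), i) for i, h in enumerate(has)]
        frac, _ = bridge_summary(traces)
        ci = 1.96 * np.sqrt(0.7 * 0.3 / n)
        assert abs(frac - 0.7) <= ci + 1e-12


class TestAfmPersistence:
    def test_ensemble_recovery_at_protein_softened_stiffness(self):
        traces = [
            simulate_chain_2d(p=39.0, seed=4000 + s, molecule_id=f"m{s}")
            for s in range(120)
        ]
        p, se, corr = afm_persistence(traces)
        assert p == pytest.approx(39.0, rel=0.10)
        assert corr.counts.min() >= 1
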
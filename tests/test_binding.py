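"""Cooperative lattice-binding isotherm, occupancy maps and cluster statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smtether.binding import (
    BindingParams,
    invert_occupancy_from_P,
    lattice_cluster_stats,
    mean_cluster_size,
    mvh_occupancy,
    mvh_theta,
    occupancy_map_linear,
    occupancy_map_P,
    sample_lattice,
)

# ---------------------------------------------------------------------------
# independent oracles, written against the printed isotherm before the solver


def oracle_rhs(theta: float, c: float, K_D: float, omega: float, n: int) -> float:
    """Literal transcription of the cooperative isotherm right-hand side."""
    R = math.sqrt(
        (1.0 - (n + 1) * theta / n) ** 2 + 4.0 * omega * theta * (1.0 - theta) / n
    )
    b1 = ((2 * omega - 1) * (1 - theta) + theta / n - R) / (
        2 * (omega - 1) * (1 - theta)
    )
    b2 = (1.0 - (n + 1) * theta / n + R) / (2 * (1 - theta))
    return (c * n / K_D) * (1 - theta) * b1 ** (n - 1) * b2**2


def oracle_bisect(c: float, K_D: float, omega: float, n: int, iters: int = 200) -> float:
    lo, hi = 0.0, 1.0 - 1e-9
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid - oracle_rhs(mid, c, K_D, omega, n) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestOccupancy:
    def test_empty_lattice_at_zero_concentration(self, binding_params):
        assert mvh_occupancy(0.0, binding_params).theta == 0.0

    def test_langmuir_limit(self):
        # n = 1, omega = 1 reduces to simple-site binding c/(K_D + c)
        p = BindingParams(K_D=2.3, omega=1.0, n=1)
        for c in np.linspace(0.0, 230.0, 21):
            expected = c / (p.K_D + c)
            assert mvh_occupancy(c, p).theta == pytest.approx(expected, abs=1e-10)

    def test_solver_matches_independent_bisection(self, binding_params):
        sol = mvh_occupancy(2.3, binding_params)
        ref = oracle_bisect(2.3, 2.3, 23.0, 26)
        assert sol.theta == pytest.approx(ref, abs=1e-8)
        assert sol.residual <= 1e-8

    @pytest.mark.parametrize("c", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_vectorized_solver_consistency(self, binding_params, c):
        assert mvh_theta(c, binding_params) == pytest.approx(
            mvh_occupancy(c, binding_params).theta, abs=1e-10
        )

    def test_monotone_and_saturating(self, binding_params):
        c = np.concatenate([[0.0], np.geomspace(1e-3, 1e4, 40)])
        theta = mvh_theta(c, binding_params)
        assert np.all(np.diff(theta) >= -1e-12)
        assert theta[-1] > 0.99
        assert np.all(theta < 1.0)

    def test_negative_concentration_rejected(self, binding_params):
        with pytest.raises(ValueError):
            mvh_occupancy(-1.0, binding_params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BindingParams(K_D=0.0, omega=23.0, n=26)
        with pytest.raises(ValueError):
            BindingParams(K_D=2.3, omega=23.0, n=0)


class TestOccupancyMaps:
    def test_persistence_map_endpoints(self):
        assert occupancy_map_P(0.0, 50.0, 10.0) == pytest.approx(50.0)
        assert occupancy_map_P(1.0, 50.0, 10.0) == pytest.approx(10.0)

    def test_persistence_map_midpoint(self):
        # P_L P_D / (P_L + theta (P_D - P_L)) = 500/30 at theta = 1/2
        assert occupancy_map_P(0.5, 50.0, 10.0) == pytest.approx(500.0 / 30.0)

    def test_persistence_map_monotone_decreasing(self):
        theta = np.linspace(0, 1, 50)
        vals = occupancy_map_P(theta, 50.0, 10.0)
        assert np.all(np.diff(vals) < 0)

    def test_linear_map(self):
        assert occupancy_map_linear(0.0, 0.34, 0.40) == pytest.approx(0.34)
        assert occupancy_map_linear(1.0, 0.34, 0.40) == pytest.approx(0.40)
        assert occupancy_map_linear(0.25, 0.34, 0.40) == pytest.approx(0.355)

    def test_invert_endpoints(self):
        assert invert_occupancy_from_P(59.0, 59.0, 7.0) == pytest.approx(0.0)
        assert invert_occupancy_from_P(7.0, 59.0, 7.0) == pytest.approx(1.0)

    def test_invert_back_calculation(self):
        # a 59 -> 39 nm softening maps to ~7% occupancy when the saturated
        # endpoint is ~7.09 nm; algebraic round trip through the map
        P_L = 0.07 * 39.0 * 59.0 / (59.0 - 39.0 + 0.07 * 39.0)
        assert P_L == pytest.approx(7.0862, abs=1e-3)
        theta = invert_occupancy_from_P(39.0, 59.0, P_L)
        assert theta == pytest.approx(0.07, abs=1e-12)
        assert occupancy_map_P(theta, 59.0, P_L) == pytest.approx(39.0, rel=1e-12)

    def test_invert_out_of_range(self):
        with pytest.raises(ValueError):
            invert_occupancy_from_P(60.0, 59.0, 7.0)

    @given(theta=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invert_is_left_inverse(self, theta):
        P = occupancy_map_P(theta, 59.0, 7.0)
        assert invert_occupancy_from_P(P, 59.0, 7.0) == pytest.approx(theta, abs=1e-9)


# ---------------------------------------------------------------------------
# cluster statistics


def brute_force_stats(c, K_D, omega, n, M):
    """Exhaustive enumeration of every ligand configuration on a tiny lattice."""
    z = c / K_D
    Z = mean_l = mean_ct = 0.0

    def configs(pos, start):
        yield pos
        for s in range(start, M - n + 1):
            yield from configs(pos + [s], s + n)

    for pos in configs([], 0):
        contacts = sum(1 for a, b in zip(pos, pos[1:]) if b - a == n)
        w = z ** len(pos) * omega**contacts
        Z += w
        mean_l += len(pos) * w
        mean_ct += contacts * w
    mean_l /= Z
    mean_ct /= Z
    return mean_l, mean_l / (mean_l - mean_ct) if mean_l > mean_ct else math.nan


class TestClusterSize:
    def test_dilute_noncooperative_limit_is_monomeric(self):
        p = BindingParams(K_D=2.3, omega=1.0, n=4)
        assert mean_cluster_size(1e-6, p, method="exact", lattice_sites=400) == (
            pytest.approx(1.0, abs=1e-3)
        )

    @pytest.mark.parametrize(
        "c,omega,n,M", [(1.0, 5.0, 3, 12), (2.3, 23.0, 4, 20), (0.5, 1.0, 2, 10)]
    )
    def test_transfer_matrix_matches_enumeration(self, c, omega, n, M):
        p = BindingParams(K_D=2.3, omega=omega, n=n)
        stats = lattice_cluster_stats(c, p, M)
        ref_l, ref_cs = brute_force_stats(c, 2.3, omega, n, M)
        assert stats["mean_ligands"] == pytest.approx(ref_l, rel=1e-10)
        assert stats["mean_cluster_size"] == pytest.approx(ref_cs, rel=1e-10)

    def test_exact_vs_monte_carlo_small_lattice(self):
        p = BindingParams(K_D=2.3, omega=23.0, n=4)
        exact = lattice_cluster_stats(2.3, p, 60)["mean_cluster_size"]
        # the dense cooperative phase mixes slowly; long run keeps batch
        # standard errors honest
        sample = sample_lattice(2.3, p, 60, sweeps=30000, seed=7)
        assert abs(sample.mean_cluster_size - exact) <= 3 * sample.mean_cluster_size_se

    def test_monte_carlo_coverage_matches_isotherm(self, binding_params):
        # grand-canonical sampler must reproduce the analytic occupancy
        sample = sample_lattice(2.3, binding_params, 520, sweeps=600, seed=3)
        theta = mvh_theta(2.3, binding_params)
        # finite lattice depresses coverage slightly; allow 3 SE + edge term
        edge = binding_params.n / 520
        assert abs(sample.theta - theta) <= 3 * sample.theta_se + edge

    def test_exact_route_size_cap(self, binding_params):
        with pytest.raises(ValueError):
            mean_cluster_size(2.3, binding_params, method="exact", lattice_sites=10**7)

    def test_clustering_grows_with_cooperativity(self):
        lo = lattice_cluster_stats(0.1, BindingParams(2.3, 2.0, 4), 200)
        hi = lattice_cluster_stats(0.1, BindingParams(2.3, 200.0, 4), 200)
        assert hi["mean_cluster_size"] > lo["mean_cluster_size"]
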
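"""Cooperative large-ligand binding to a one-dimensional DNA lattice.

The McGhee-von Hippel model describes a ligand that covers ``n`` contiguous
lattice sites (base pairs) binding with dissociation constant ``K_D`` and
nearest-neighbour cooperativity ``omega`` (statistical weight per pair of
exactly-adjacent bound ligands). With the fractional site occupancy
``theta`` (fraction of base pairs covered) the isotherm reads

    theta = (c n / K_D) (1 - theta)
            * [((2w-1)(1-theta) + theta/n - R) / (2(w-1)(1-theta))]^(n-1)
            * [(1 - (n+1) theta/n + R) / (2(1-theta))]^2

    R = sqrt((1 - (n+1) theta/n)^2 + 4 w theta (1 - theta) / n)

where ``c`` is the free ligand concentration (taken equal to the bulk
concentration: flow-cell excess, no depletion correction). At ``omega = 1``
the first bracket is 0/0; the documented non-cooperative closed form

    theta = (c n / K_D) (1 - theta) [(1 - theta) / (1 - (n-1) theta/n)]^(n-1)

is used instead for ``|omega - 1| < 1e-6``.

Occupancy maps the mechanical observables between their protein-free (D)
and protein-saturated (L) endpoints: persistence length composes
harmonically, contour length and overstretching force linearly.

Cluster statistics (mean number of ligands per maximal run of contiguous
footprints) are computed two ways: exactly, by a transfer-matrix recursion
on a finite lattice, and by seeded grand-canonical Monte Carlo; the two
must agree within sampling error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "BindingParams",
    "OccupancySolution",
    "SaturationEndpoints",
    "mvh_occupancy",
    "mvh_theta",
    "occupancy_map_P",
    "occupancy_map_linear",
    "invert_occupancy_from_P",
    "lattice_cluster_stats",
    "mean_cluster_size",
    "sample_lattice",
    "LatticeSample",
]

_EXACT_LATTICE_MAX = 1_000_000


@dataclass(frozen=True)
class BindingParams:
    """Lattice-binding parameters: K_D (nM), cooperativity omega, site size n (bp)."""

    K_D: float
    omega: float
    n: int = 26

    def __post_init__(self) -> None:
        if not (np.isfinite(self.K_D) and self.K_D > 0):
            raise ValueError(f"K_D must be positive, got {self.K_D!r}")
        if not (np.isfinite(self.omega) and self.omega > 0):
            raise ValueError(f"omega must be positive, got {self.omega!r}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be an integer >= 1, got {self.n!r}")


@dataclass(frozen=True)
class OccupancySolution:
    """Solved occupancy at one concentration, with the auxiliary root term."""

    theta: float
    R: float
    c: float
    residual: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise ValueError("theta must lie in [0, 1)")
        if self.R < 0:
            raise ValueError("R must be non-negative")


@dataclass(frozen=True)
class SaturationEndpoints:
    """Protein-free (D) and protein-saturated (L) observable endpoints.

    Any pair may be None when that observable is not analysed.
    """

    P_D: float | None = None
    P_L: float | None = None
    B_D: float | None = None
    B_L: float | None = None
    F_ov_D: float | None = None
    F_ov_L: float | None = None

    def __post_init__(self) -> None:
        for name in ("P_D", "P_L", "B_D", "B_L", "F_ov_D", "F_ov_L"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when supplied")


def _R_of_theta(theta, omega: float, n: int):
    return np.sqrt((1.0 - (n + 1) * theta / n) ** 2 + 4.0 * omega * theta * (1.0 - theta) / n)


def _isotherm_rhs(theta, c, params: BindingParams):
    """Right-hand side of the isotherm; vectorized over theta and/or c."""
    n, w = params.n, params.omega
    one_m = 1.0 - theta
    base = c * n / params.K_D * one_m
    if abs(w - 1.0) < 1e-6:
        # non-cooperative closed form (the cooperative bracket is 0/0 at w=1)
        return base * (one_m / (1.0 - (n - 1) * theta / n)) ** (n - 1)
    R = _R_of_theta(theta, w, n)
    b1 = ((2 * w - 1) * one_m + theta / n - R) / (2 * (w - 1) * one_m)
    b2 = (1.0 - (n + 1) * theta / n + R) / (2 * one_m)
    return base * b1 ** (n - 1) * b2**2


def mvh_theta(c, params: BindingParams, *, iterations: int = 80):
    """Fractional occupancy theta(c), vectorized over concentrations (nM).

    Fixed-iteration bisection of the monotone residual ``theta - rhs(theta)``
    on [0, 1); after 80 halvings the bracket width is far below 1e-16, so the
    result is converged to machine precision. Used in model evaluation where
    many concentrations are solved at once.
    """
    c_arr = np.atleast_1d(np.asarray(c, dtype=float))
    if np.any(c_arr < 0):
        raise ValueError("concentration must be non-negative")
    lo = np.zeros_like(c_arr)
    hi = np.full_like(c_arr, 1.0 - 1e-9)
    with np.errstate(all="ignore"):
        for _ in range(iterations):
            mid = 0.5 * (lo + hi)
            g = mid - _isotherm_rhs(mid, c_arr, params)
            g = np.where(np.isnan(g), 1.0, g)  # near-saturation noise: push down
            hi = np.where(g > 0, mid, hi)
            lo = np.where(g > 0, lo, mid)
    theta = 0.5 * (lo + hi)
    theta[c_arr == 0] = 0.0
    return theta if np.ndim(c) else float(theta[0])


def mvh_occupancy(c: float, params: BindingParams) -> OccupancySolution:
    """Solve the isotherm at one concentration, with a built-in self-check.

    Returns the unique theta in [0, 1) together with the auxiliary root term
    R and the relative residual of the isotherm at the solution (always
    <= 1e-8, enforced).
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if c == 0:
        return OccupancySolution(theta=0.0, R=1.0, c=0.0, residual=0.0)

    def g(theta: float) -> float:
        return theta - float(_isotherm_rhs(theta, c, params))

    hi = 1.0 - 1e-9
    g_hi = g(hi)
    if not np.isfinite(g_hi) or g(0.0) * g_hi > 0:
        # retreat from saturation until the bracket is clean
        while hi > 0.5 and (not np.isfinite(g(hi)) or g(hi) <= 0):
            hi = 1.0 - 2.0 * (1.0 - hi)
        if g(0.0) * g(hi) > 0:
            raise RuntimeError(
                f"no sign change bracketing theta for c={c!r}, params={params!r}"
            )
    theta = optimize.brentq(g, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    rhs = float(_isotherm_rhs(theta, c, params))
    residual = abs(theta - rhs) / max(theta, 1e-300)
    if residual > 1e-8:
        raise RuntimeError(f"isotherm residual {residual:.3g} exceeds 1e-8 at c={c!r}")
    return OccupancySolution(
        theta=theta, R=float(_R_of_theta(theta, params.omega, params.n)), c=c,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# occupancy -> observable maps


def occupancy_map_P(theta, P_D: float, P_L: float):
    """Persistence length at occupancy theta: P_L*P_D / (P_L + theta*(P_D - P_L))."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("theta must lie in [0, 1]")
    if P_D <= 0 or P_L <= 0:
        raise ValueError("endpoint persistence lengths must be positive")
    denom = P_L + theta * (P_D - P_L)
    if np.any(denom == 0):
        raise ValueError("zero denominator in persistence-length map")
    out = P_L * P_D / denom
    return out if out.ndim else float(out)


def occupancy_map_linear(theta, x_D: float, x_L: float):
    """Linear endpoint interpolation x_D + theta*(x_L - x_D) (contour length,
    overstretching force)."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("theta must lie in [0, 1]")
    out = x_D + theta * (x_L - x_D)
    return out if out.ndim else float(out)


def invert_occupancy_from_P(P_obs: float, P_D: float, P_L: float) -> float:
    """Occupancy back-calculated from an observed persistence length.

    Algebraic inverse of the harmonic map:
    theta = P_L*(P_D - P_obs) / (P_obs*(P_D - P_L)).
    """
    lo, hi = min(P_D, P_L), max(P_D, P_L)
    if not (lo <= P_obs <= hi):
        raise ValueError(
            f"P_obs={P_obs!r} outside the endpoint range [{lo!r}, {hi!r}]"
        )
    if P_D == P_L:
        raise ValueError("endpoints coincide; occupancy is indeterminate")
    return P_L * (P_D - P_obs) / (P_obs * (P_D - P_L))


# ---------------------------------------------------------------------------
# cluster statistics on a finite lattice


def lattice_cluster_stats(
    c: float, params: BindingParams, lattice_sites: int
) -> dict[str, float]:
    """Exact finite-lattice ensemble averages by transfer-matrix recursion.

    States distinguish whether a lattice position is empty or the last site
    of a ligand footprint; alongside the partition function two linear
    accumulators carry the weighted ligand count and weighted contact count
    (contact = two footprints exactly adjacent). All recursions are linear in
    the joint state, so the rolling window is rescaled freely to avoid
    overflow; only ratios are reported.

    Returns a dict with mean ligand count, mean contact count, mean cluster
    count (ligands - contacts), mean cluster size (ratio of means), and the
    mean fractional occupancy theta = n*ligands/lattice_sites.
    """
    M, n = int(lattice_sites), params.n
    if M < n:
        raise ValueError("lattice must hold at least one ligand footprint")
    if M > _EXACT_LATTICE_MAX:
        raise ValueError(f"exact route capped at {_EXACT_LATTICE_MAX} sites")
    z = c / params.K_D
    w = params.omega
    # rolling states indexed 0..M; rescaled jointly when large
    Ze = np.zeros(M + 1)
    Zb = np.zeros(M + 1)
    Ne = np.zeros(M + 1)
    Nb = np.zeros(M + 1)
    Ce = np.zeros(M + 1)
    Cb = np.zeros(M + 1)
    Ze[0] = 1.0
    for i in range(1, M + 1):
        Ze[i] = Ze[i - 1] + Zb[i - 1]
        Ne[i] = Ne[i - 1] + Nb[i - 1]
        Ce[i] = Ce[i - 1] + Cb[i - 1]
        if i >= n:
            j = i - n
            Zb[i] = z * (Ze[j] + w * Zb[j])
            Nb[i] = z * (Ne[j] + w * Nb[j]) + Zb[i]
            Cb[i] = z * (Ce[j] + w * Cb[j]) + z * w * Zb[j]
        if Ze[i] > 1e250:
            for arr in (Ze, Zb, Ne, Nb, Ce, Cb):
                arr *= 1e-250
    Z = Ze[M] + Zb[M]
    mean_ligands = (Ne[M] + Nb[M]) / Z
    mean_contacts = (Ce[M] + Cb[M]) / Z
    mean_clusters = mean_ligands - mean_contacts
    return {
        "mean_ligands": mean_ligands,
        "mean_contacts": mean_contacts,
        "mean_clusters": mean_clusters,
        "mean_cluster_size": mean_ligands / mean_clusters if mean_clusters > 0 else math.nan,
        "theta": n * mean_ligands / M,
    }


def _integrated_autocorr_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time by Sokal's automatic windowing.

    tau = 1/2 + sum of the normalised autocovariance up to the smallest
    window W with W >= 5 tau(W); clipped to [0.5, len(x)/10].
    """
    n = x.size
    if n < 10:
        return 0.5
    xc = x - x.mean()
    var = float(np.dot(xc, xc) / n)
    if var == 0:
        return 0.5
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / var
    tau = 0.5
    for t in range(1, n):
        tau += rho[t]
        if t >= 5.0 * tau:
            break
    return float(min(max(tau, 0.5), n / 10.0))


@dataclass
class LatticeSample:
    """Monte-Carlo sample of lattice configurations.

    ``configurations`` holds ligand start positions per saved sweep;
    ``theta`` / ``theta_se`` the empirical coverage and its standard error;
    cluster statistics as in :func:`lattice_cluster_stats`.
    """

    configurations: list[np.ndarray]
    lattice_sites: int
    theta: float
    theta_se: float
    mean_cluster_size: float
    mean_cluster_size_se: float


def sample_lattice(
    c: float,
    params: BindingParams,
    lattice_sites: int,
    *,
    sweeps: int = 400,
    burn_in_sweeps: int | None = None,
    seed: int | None = None,
    keep_configurations: bool = False,
) -> LatticeSample:
    """Grand-canonical Monte Carlo of the finite binding lattice.

    Moves mix single-ligand insertions/deletions at a uniformly chosen start
    site (Metropolis acceptance with statistical weights c/K_D per ligand and
    omega per exactly-adjacent contact) with single-site ligand shifts, which
    decorrelate dense, strongly cooperative configurations that insertion/
    deletion alone leaves frozen. A sweep is ``lattice_sites`` moves; burn-in
    defaults to ``max(10, sweeps // 10)`` sweeps. Standard errors come from
    10 batch means over the post-burn-in sweeps.
    """
    M, n = int(lattice_sites), params.n
    if M < 2 * n:
        raise ValueError("Monte-Carlo lattice must hold at least two ligand footprints")
    if M < 10 * n:
        warnings.warn(
            "Monte-Carlo lattice shorter than 10 footprints; finite-size effects "
            "will be large",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    z = c / params.K_D
    w = params.omega
    if burn_in_sweeps is None:
        burn_in_sweeps = max(10, sweeps // 10)
    covered = np.zeros(M, dtype=bool)
    is_start = np.zeros(M, dtype=bool)

    def contacts_at(s: int) -> int:
        k = 0
        if s - n >= 0 and is_start[s - n]:
            k += 1
        if s + n < M and is_start[s + n]:
            k += 1
        return k

    n_total = burn_in_sweeps + sweeps
    thetas = np.empty(sweeps)
    cluster_counts = np.empty(sweeps, dtype=int)
    ligand_counts = np.empty(sweeps, dtype=int)
    configs: list[np.ndarray] = []
    n_bound = 0
    for sweep in range(n_total):
        sites = rng.integers(0, M, size=M)
        accept = rng.random(M)
        kinds = rng.random(M)
        shift_dirs = rng.integers(0, 2, size=M) * 2 - 1
        for s, u, kind, d in zip(sites, accept, kinds, shift_dirs):
            if kind < 0.5:
                # grand-canonical insertion/deletion at site s
                if is_start[s]:
                    ratio = 1.0 / (z * w ** contacts_at(s))
                    if u < ratio:
                        is_start[s] = False
                        covered[s : s + n] = False
                        n_bound -= 1
                elif s + n <= M and not covered[s : s + n].any():
                    ratio = z * w ** contacts_at(s)
                    if u < ratio:
                        is_start[s] = True
                        covered[s : s + n] = True
                        n_bound += 1
            elif is_start[s]:
                # shift the ligand starting at s by one site
                t = s + d
                edge = s if d > 0 else s + n - 1  # site vacated
                lead = s + n if d > 0 else s - 1  # site newly covered
                if 0 <= t <= M - n and 0 <= lead < M and not covered[lead]:
                    dk = 0
                    if 0 <= t - n < M and is_start[t - n] and t - n != s:
                        dk += 1
                    if 0 <= t + n < M and is_start[t + n] and t + n != s:
                        dk += 1
                    dk -= contacts_at(s)
                    if dk >= 0 or u < w**dk:
                        is_start[s] = False
                        covered[edge] = False
                        is_start[t] = True
                        covered[lead] = True
        if sweep >= burn_in_sweeps:
            k = sweep - burn_in_sweeps
            starts = np.flatnonzero(is_start)
            ligand_counts[k] = n_bound
            thetas[k] = n_bound * n / M
            if n_bound:
                cluster_counts[k] = 1 + int(np.count_nonzero(np.diff(starts) != n))
            else:
                cluster_counts[k] = 0
            if keep_configurations:
                configs.append(starts.copy())

    tau = _integrated_autocorr_time(thetas)
    theta_mean = float(thetas.mean())
    theta_se = float(thetas.std(ddof=1) * math.sqrt(2.0 * tau / sweeps))
    # cluster size as a ratio of means over batches of ~10 autocorrelation
    # times of the per-sweep ratio (at least 5 batches)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_series = np.where(
            cluster_counts > 0, ligand_counts / np.maximum(cluster_counts, 1), np.nan
        )
    if np.isnan(r_series).all():
        tau_r = tau
    else:
        fill = float(np.nanmean(r_series))
        tau_r = _integrated_autocorr_time(np.nan_to_num(r_series, nan=fill))
    batch = max(1, min(int(round(10 * max(tau, tau_r))), sweeps // 5))
    nb = sweeps // batch
    usable = nb * batch
    lc = ligand_counts[:usable].reshape(nb, -1).sum(axis=1).astype(float)
    cc = cluster_counts[:usable].reshape(nb, -1).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(cc > 0, lc / np.maximum(cc, 1), np.nan)
    good = ~np.isnan(ratios)
    if good.sum() >= 2:
        cs_mean = float(np.nanmean(ratios))
        cs_se = float(np.nanstd(ratios, ddof=1) / math.sqrt(good.sum()))
    else:
        cs_mean, cs_se = math.nan, math.nan
    return LatticeSample(
        configurations=configs,
        lattice_sites=M,
        theta=theta_mean,
        theta_se=theta_se,
        mean_cluster_size=cs_mean,
        mean_cluster_size_se=cs_se,
    )


def mean_cluster_size(
    c: float,
    params: BindingParams,
    method: str = "exact",
    lattice_sites: int | None = None,
    seed: int | None = None,
    **mc_kwargs,
) -> float:
    """Mean ligands per maximal contiguous cluster at equilibrium.

    ``method='exact'`` uses the transfer-matrix recursion;
    ``method='montecarlo'`` the seeded grand-canonical sampler. Footprints
    belong to one cluster iff they are exactly adjacent (zero free sites
    between), mirroring the cooperativity contact definition.
    """
    if method == "exact":
        if lattice_sites is None:
            lattice_sites = 100 * params.n
        return lattice_cluster_stats(c, params, lattice_sites)["mean_cluster_size"]
    if method == "montecarlo":
        if lattice_sites is None:
            lattice_sites = 20 * params.n
        sample = sample_lattice(c, params, lattice_sites, seed=seed, **mc_kwargs)
        return sample.mean_cluster_size
    raise ValueError("method must be 'exact' or 'montecarlo'")
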
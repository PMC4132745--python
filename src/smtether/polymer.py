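"""Worm-like-chain polymer mechanics.

Two models live here:

* the extensible worm-like chain (WLC) used for force spectroscopy of
  double-stranded DNA at forces above ~0.5 pN, in its high-force
  interpolation form

      b(F) = B * [1 - (1/2) * sqrt(kT / (P F)) + F / S]

  where ``b`` is the extension per base pair (nm/bp), ``P`` the persistence
  length (nm), ``B`` the contour length per base pair (nm/bp) and ``S`` the
  elastic stretch modulus (pN);

* the two-dimensional WLC tangent-correlation law for molecules
  equilibrated on a surface,

      <cos theta(L)> = exp(-L / (2 p)),

  used to extract a persistence length ``p`` from traced AFM polylines.

The extensible-WLC interpolation is accurate in fits up to ~30 pN; callers
that evaluate it beyond that range get a result but should treat it as an
extrapolation (see :func:`wlc_extension`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "KT_ROOM",
    "WLCParams",
    "ForceExtensionCurve",
    "TangentCorrelation",
    "wlc_extension",
    "wlc_force",
    "resample_trace",
    "tangent_correlation",
    "PersistenceLength2D",
    "fit_persistence_2d",
]

#: thermal energy at T = 298 K, pN nm
KT_ROOM = 4.11

#: force range (pN) within which the extensible-WLC interpolation is trusted
WLC_FIT_FMAX = 30.0


@dataclass(frozen=True)
class WLCParams:
    """Mechanical parameter set of the extensible worm-like chain.

    Attributes
    ----------
    P_ds : float
        Persistence length, nm.
    B_ds : float
        Contour length per base pair, nm/bp.
    S_ds : float
        Elastic stretch modulus, pN.
    kT : float
        Thermal energy, pN nm. Defaults to 4.11 (298 K).
    """

    P_ds: float
    B_ds: float
    S_ds: float
    kT: float = KT_ROOM

    def __post_init__(self) -> None:
        for name in ("P_ds", "B_ds", "S_ds", "kT"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"WLCParams.{name} must be positive, got {v!r}")


@dataclass
class ForceExtensionCurve:
    """One stretching (or release) record of a single tether.

    ``extension`` is the total tether extension in nm; per-bp extension is
    always derived as ``extension / n_bp``, never stored.
    """

    extension: np.ndarray
    force: np.ndarray
    n_bp: int
    concentration: float = 0.0
    pulling_rate: float = float("nan")
    direction: str = "extend"

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension.ndim != 1 or self.extension.shape != self.force.shape:
            raise ValueError("extension and force must be 1-D arrays of equal length")
        if self.extension.size < 2:
            raise ValueError("a force-extension curve needs at least 2 samples")
        if self.n_bp <= 0:
            raise ValueError("n_bp must be positive")
        if self.direction not in ("extend", "release"):
            raise ValueError("direction must be 'extend' or 'release'")
        if self.direction == "extend" and not np.all(np.diff(self.extension) > 0):
            raise ValueError("extension must be strictly increasing for direction='extend'")

    @property
    def extension_per_bp(self) -> np.ndarray:
        return self.extension / self.n_bp


@dataclass
class TangentCorrelation:
    """Binned tangent-tangent correlation of surface-equilibrated traces."""

    L: np.ndarray
    mean_cos_theta: np.ndarray
    counts: np.ndarray
    #: standard error of the mean cos(theta) per bin
    sem: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.mean_cos_theta = np.asarray(self.mean_cos_theta, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.sem is None:
            self.sem = np.full_like(self.L, np.nan)
        else:
            self.sem = np.asarray(self.sem, dtype=float)
        if np.any(np.abs(self.mean_cos_theta) > 1 + 1e-12):
            raise ValueError("|mean_cos_theta| must not exceed 1")
        if np.any(self.L < 0):
            raise ValueError("contour separations must be non-negative")
        if np.any(self.counts < 1):
            raise ValueError("every retained bin needs at least one sample")


def _check_force(F) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if np.any(~np.isfinite(F)) or np.any(F <= 0):
        raise ValueError("force must be finite and positive")
    return F


def wlc_extension(F, params: WLCParams, *, warn_outside_fit_range: bool = False):
    """Extension per base pair (nm/bp) of the extensible WLC at force ``F`` (pN).

    Scalar in, scalar out; array in, array out. The interpolation formula is
    used for fitting only up to 30 pN; pass ``warn_outside_fit_range=True``
    to be warned when evaluating beyond that.
    """
    F = _check_force(F)
    if warn_outside_fit_range and np.any(F > WLC_FIT_FMAX):
        warnings.warn(
            f"extensible-WLC evaluated above {WLC_FIT_FMAX:g} pN; "
            "the interpolation is an extrapolation there",
            stacklevel=2,
        )
    b = params.B_ds * (1.0 - 0.5 * np.sqrt(params.kT / (params.P_ds * F)) + F / params.S_ds)
    return b if b.ndim else float(b)


def wlc_force(b, params: WLCParams, *, f_bracket: tuple[float, float] = (1e-6, 1e5)):
    """Invert the extensible WLC: force (pN) at extension per bp ``b`` (nm/bp).

    The model extension is strictly increasing in F, so the inverse is
    unique. Raises ``ValueError`` when ``b`` lies outside the extension range
    reachable within ``f_bracket``.
    """
    b_arr = np.atleast_1d(np.asarray(b, dtype=float))
    if np.any(~np.isfinite(b_arr)) or np.any(b_arr <= 0):
        raise ValueError("extension per bp must be finite and positive")
    lo, hi = f_bracket
    b_lo = wlc_extension(lo, params)
    b_hi = wlc_extension(hi, params)
    if np.any(b_arr <= b_lo) or np.any(b_arr >= b_hi):
        raise ValueError(
            f"extension {b_arr.min():.4g}..{b_arr.max():.4g} nm/bp outside the "
            f"invertible range ({b_lo:.4g}, {b_hi:.4g}) for the given bracket"
        )
    # vectorized bisection on log10(F) to localise the root, then Newton
    # polish (db/dF is analytic) to machine precision
    lo_l = np.full_like(b_arr, np.log10(lo))
    hi_l = np.full_like(b_arr, np.log10(hi))
    for _ in range(30):
        mid = 0.5 * (lo_l + hi_l)
        too_low = wlc_extension(10.0**mid, params) < b_arr
        lo_l = np.where(too_low, mid, lo_l)
        hi_l = np.where(too_low, hi_l, mid)
    out = 10.0 ** (0.5 * (lo_l + hi_l))
    for _ in range(4):
        resid = wlc_extension(out, params) - b_arr
        slope = params.B_ds * (
            0.25 * np.sqrt(params.kT / params.P_ds) * out**-1.5 + 1.0 / params.S_ds
        )
        out = np.clip(out - resid / slope, lo, hi)
    return out if np.ndim(b) else float(out[0])


# ---------------------------------------------------------------------------
# 2D trace statistics


def resample_trace(points: np.ndarray, step: float) -> np.ndarray:
    """Resample an ordered 2D polyline at uniform arc-length spacing.

    Linear interpolation along the cumulative contour; the last partial
    segment (< step) is dropped.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("trace must be an (n, 2) array with n >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("consecutive trace points must be distinct")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.arange(0.0, s[-1] + 1e-9, step)
    x = np.interp(grid, s, pts[:, 0])
    y = np.interp(grid, s, pts[:, 1])
    return np.column_stack([x, y])


def _trace_points(trace) -> np.ndarray:
    """Accept a bare (n, 2) array or any object with a ``points`` attribute."""
    return np.asarray(getattr(trace, "points", trace), dtype=float)


def tangent_correlation(traces, step: float = 5.0, max_L: float = 150.0) -> TangentCorrelation:
    """Pooled tangent-tangent correlation <cos theta(L)> of 2D traces.

    Each trace is resampled at uniform ``step`` (nm); unit tangents come from
    central differences of the resampled points; for each separation
    L = k*step up to ``max_L`` the cosine of the tangent-tangent angle is
    averaged over all positions of all traces (per-position pooling).

    Parameters
    ----------
    traces : array or object with .points, or a list of such
    step : float
        Resampling arc-length step, nm.
    max_L : float
        Largest contour separation, nm.
    """
    if hasattr(traces, "points") or (
        isinstance(traces, np.ndarray) and traces.ndim == 2
    ):
        traces = [traces]
    k_max = int(round(max_L / step))
    per_trace_sums: list[np.ndarray] = []
    per_trace_counts: list[np.ndarray] = []
    for trace in traces:
        pts = _trace_points(trace)
        try:
            rs = resample_trace(pts, step)
        except ValueError:
            warnings.warn("skipping degenerate trace", stacklevel=2)
            continue
        if rs.shape[0] < 3:
            warnings.warn("skipping trace shorter than 2 resampling steps", stacklevel=2)
            continue
        # secant (chord) tangents of consecutive resampled points; wider
        # differences would smooth the walk and bias the correlation upward
        t = rs[1:] - rs[:-1]
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        n_t = t.shape[0]
        s = np.zeros(k_max + 1)
        n = np.zeros(k_max + 1, dtype=int)
        for k in range(0, min(k_max, n_t - 1) + 1):
            c = np.einsum("ij,ij->i", t[: n_t - k], t[k:])
            s[k] = c.sum()
            n[k] = c.size
        per_trace_sums.append(s)
        per_trace_counts.append(n)
    if not per_trace_sums:
        raise ValueError("no usable traces: all were shorter than 2 steps")
    S = np.vstack(per_trace_sums)
    N = np.vstack(per_trace_counts)
    counts = N.sum(axis=0)
    keep = counts > 0
    mean = S.sum(axis=0)[keep] / counts[keep]
    # standard error from between-molecule variation: positions within one
    # trace are strongly correlated, molecules are independent
    sem = np.zeros(keep.sum())
    for j, k in enumerate(np.flatnonzero(keep)):
        nk = N[:, k]
        used = nk > 0
        if used.sum() < 2:
            sem[j] = np.nan
            continue
        w = nk[used] / nk[used].sum()
        m_t = S[used, k] / nk[used]
        T = used.sum()
        sem[j] = np.sqrt(np.sum(w**2 * (m_t - mean[j]) ** 2) * T / (T - 1))
    L = np.arange(k_max + 1)[keep] * step
    # clip tiny float excursions past |1|
    mean = np.clip(mean, -1.0, 1.0)
    return TangentCorrelation(L=L, mean_cos_theta=mean, counts=counts[keep], sem=sem)


class PersistenceLength2D(BaseEstimator, RegressorMixin):
    """Persistence length from the 2D WLC decay ``<cos theta> = exp(-L/2p)``.

    A weighted least-squares regressor in the scikit-learn idiom:
    ``fit(L, mean_cos_theta, sample_weight=...)`` where the sample weights
    are inverse variances of the bin means. The fit is performed on the
    correlation directly (not log-transformed) to avoid bias from
    near-zero bins. By default a free amplitude multiplies the decay:
    tangents measured from finite chords of a resampled trace rescale the
    correlation by a constant factor at L >= step, and the nuisance
    amplitude absorbs that offset instead of letting it bias p
    (``fit_amplitude=False`` pins the amplitude at 1).

    Attributes
    ----------
    persistence_length_ : float
        Fitted p, nm.
    persistence_length_se_ : float
        Standard error of p from the fit covariance.
    amplitude_ : float
        Fitted (or pinned) amplitude.
    diverged_ : bool
        True when the correlation does not decay (straight-line input);
        ``persistence_length_`` is +inf in that case.
    """

    def __init__(self, p0: float = 50.0, fit_amplitude: bool = True):
        self.p0 = p0
        self.fit_amplitude = fit_amplitude

    def fit(self, X, y, sample_weight=None):
        L = np.asarray(X, dtype=float).reshape(-1)
        cos = np.asarray(y, dtype=float).reshape(-1)
        if L.size != cos.size or L.size < 3:
            raise ValueError("need >= 3 (L, <cos theta>) bins of equal length")
        if sample_weight is None:
            sigma = np.ones_like(L)
        else:
            w = np.asarray(sample_weight, dtype=float).reshape(-1)
            if np.any(w <= 0):
                raise ValueError("sample_weight must be positive")
            sigma = 1.0 / np.sqrt(w)

        # non-decaying input: flag divergence instead of chasing p -> inf
        mask = L > 0
        if not mask.any() or np.all(cos[mask] > 1.0 - 1e-12):
            self.diverged_ = True
            self.persistence_length_ = float("inf")
            self.persistence_length_se_ = float("nan")
            self.amplitude_ = 1.0
            return self

        abs_sigma = sample_weight is not None
        if self.fit_amplitude:
            def model(Lv, p, A):
                return A * np.exp(-Lv / (2.0 * p))

            popt, pcov = optimize.curve_fit(
                model, L, cos, p0=[self.p0, 1.0], sigma=sigma, absolute_sigma=abs_sigma,
                bounds=([1e-6, 1e-6], [np.inf, 2.0]), maxfev=10000,
            )
            self.amplitude_ = float(popt[1])
        else:
            def model(Lv, p):
                return np.exp(-Lv / (2.0 * p))

            popt, pcov = optimize.curve_fit(
                model, L, cos, p0=[self.p0], sigma=sigma, absolute_sigma=abs_sigma,
                bounds=(1e-6, np.inf), maxfev=10000,
            )
            self.amplitude_ = 1.0
        self.diverged_ = False
        self.persistence_length_ = float(popt[0])
        self.persistence_length_se_ = float(np.sqrt(pcov[0, 0]))
        return self

    def predict(self, X):
        L = np.asarray(X, dtype=float).reshape(-1)
        return self.amplitude_ * np.exp(-L / (2.0 * self.persistence_length_))


def fit_persistence_2d(corr: TangentCorrelation) -> tuple[float, float]:
    """Fit p (nm) and its standard error from a :class:`TangentCorrelation`.

    Bins are weighted by their inverse variance when per-bin standard errors
    are available. Returns ``(inf, nan)`` for non-decaying input.
    """
    # the L = 0 bin is identically 1 and carries no information about the
    # decay (and would fight the nuisance amplitude); drop it
    keep = corr.L > 0
    L, cos, sem = corr.L[keep], corr.mean_cos_theta[keep], corr.sem[keep]
    if L.size < 3:
        raise ValueError("need at least 3 non-zero separation bins")
    if sem is not None and np.all(np.isfinite(sem)) and np.any(sem > 0):
        sem = np.where(sem > 0, sem, sem[sem > 0].min())
        weight = 1.0 / sem**2
    else:
        weight = None
    est = PersistenceLength2D().fit(L, cos, sample_weight=weight)
    return est.persistence_length_, est.persistence_length_se_
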
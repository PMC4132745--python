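"""Per-curve optical-tweezers analyses.

Covers the stretch-curve pipeline for a single tether: extensible-WLC
fitting of the low-force branch (up to 30 pN by default), extraction of
the overstretching plateau force, detection of discrete force drops
("sawtooth" loop-rupture events), sizing of the released loops from the
contour-length change across each jump, histogramming of loop sizes and
breaking forces, and constant-force compaction measurements (single-
exponential extension decay, compaction force at low extension).

A loop of ``delta_B`` nm/bp contour-length change on a molecule of
``n_bp`` base pairs corresponds to ``delta_B * n_bp / 0.34`` base pairs
of released DNA, with 0.34 nm the B-form rise per base pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .polymer import KT_ROOM, ForceExtensionCurve, WLCParams, wlc_extension, wlc_force

__all__ = [
    "NM_PER_BP",
    "LoopEvent",
    "CompactionResult",
    "ExtensibleWLC",
    "fit_force_extension",
    "overstretch_force",
    "detect_loop_jumps",
    "size_loop",
    "analyze_loops",
    "loop_histograms",
    "ExponentialDecay",
    "compaction_fit",
    "compaction_force",
    "FitRangeError",
    "SizingError",
    "NonDecayingError",
]

#: rise per base pair of B-form DNA, nm
NM_PER_BP = 0.34


class FitRangeError(ValueError):
    """Curve does not span the force range needed for a WLC fit."""


class SizingError(RuntimeError):
    """A detected jump could not be sized (flanking segment too short)."""


class NonDecayingError(RuntimeError):
    """A compaction series shows no decay; the exponential fit is rejected."""


@dataclass
class LoopEvent:
    """One loop-rupture event on a stretching curve."""

    extension_at_jump: float
    F_before: float
    F_after: float
    delta_F: float
    B_before: float
    B_after: float
    delta_B: float
    loop_bp: float
    jump_index: int = -1

    def __post_init__(self) -> None:
        if not np.isclose(self.delta_F, self.F_before - self.F_after, atol=1e-9):
            raise ValueError("delta_F must equal F_before - F_after")
        if self.B_after <= self.B_before:
            raise ValueError("contour length must increase across a loop release")
        if not np.isclose(self.delta_B, self.B_after - self.B_before, atol=1e-12):
            raise ValueError("delta_B must equal B_after - B_before")


@dataclass
class CompactionResult:
    """Single-exponential compaction fit and optional compaction force."""

    k: float
    k_se: float
    tau: float
    tau_se: float
    amplitude: float
    baseline: float
    delta_F_c: float = float("nan")
    delta_F_c_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("rate k must be positive")
        if not np.isclose(self.tau * self.k, 1.0, rtol=1e-9):
            raise ValueError("tau must equal 1/k")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


# ---------------------------------------------------------------------------
# WLC fitting


class ExtensibleWLC(BaseEstimator, RegressorMixin):
    """Extensible-WLC force-extension regressor (extension per bp vs force).

    ``fit(F, b)`` least-squares fits persistence length, contour length per
    bp and stretch modulus; ``predict(F)`` returns the model extension per
    bp. Only forces in [``f_min``, ``f_max``] enter the fit: the high-force
    interpolation degrades below ~1 pN. Because measurement noise lives on
    the force channel while the extension grid is commanded by the stage,
    the residuals are formed in force space -- F_model(b) is obtained by
    numerically inverting the extension relation -- which keeps the fit
    unbiased where a naive extension-space fit attenuates the persistence
    length. ``sample_weight`` (per-point inverse variances on force) is
    optional.

    Attributes
    ----------
    persistence_length_, persistence_length_se_ : nm
    contour_per_bp_, contour_per_bp_se_ : nm/bp
    stretch_modulus_, stretch_modulus_se_ : pN
    params_ : WLCParams
    """

    def __init__(
        self,
        f_max: float = 30.0,
        f_min: float = 1.0,
        kT: float = KT_ROOM,
        p0: tuple[float, float, float] = (50.0, 0.34, 1200.0),
    ):
        self.f_max = f_max
        self.f_min = f_min
        self.kT = kT
        self.p0 = p0

    def fit(self, X, y, sample_weight=None):
        F = np.asarray(X, dtype=float).reshape(-1)
        b = np.asarray(y, dtype=float).reshape(-1)
        weights = None
        if sample_weight is not None:
            weights = np.asarray(sample_weight, dtype=float).reshape(-1)
        coarse = (F >= self.f_min) & (F <= self.f_max)
        if coarse.sum() < 10:
            raise FitRangeError(
                f"need >= 10 samples with {self.f_min} <= F <= {self.f_max} pN, "
                f"have {coarse.sum()}"
            )
        if F[coarse].max() < 5.0:
            raise FitRangeError(
                f"maximum force {F[coarse].max():.2f} pN < 5 pN: insufficient "
                "range to separate persistence length from stretch modulus"
            )

        def model(bv, P, B, S):
            return wlc_force(bv, WLCParams(P_ds=P, B_ds=B, S_ds=S, kT=self.kT))

        # two passes: the force window is mapped onto the (noise-free)
        # extension axis using the current parameters, so truncation never
        # selects on the force noise
        popt = list(self.p0)
        for _ in range(2):
            pars = WLCParams(P_ds=popt[0], B_ds=popt[1], S_ds=popt[2], kT=self.kT)
            b_lo = wlc_extension(self.f_min, pars)
            b_hi = wlc_extension(self.f_max, pars)
            mask = (b >= b_lo) & (b <= b_hi)
            if mask.sum() < 10:
                mask = coarse
            sigma = None if weights is None else 1.0 / np.sqrt(weights[mask])
            popt, pcov = optimize.curve_fit(
                model, b[mask], F[mask], p0=popt, sigma=sigma,
                bounds=([1e-3, 1e-4, 1.0], [1e4, 10.0, 1e6]), maxfev=20000,
            )
        se = np.sqrt(np.diag(pcov))
        self.persistence_length_ = float(popt[0])
        self.persistence_length_se_ = float(se[0])
        self.contour_per_bp_ = float(popt[1])
        self.contour_per_bp_se_ = float(se[1])
        self.stretch_modulus_ = float(popt[2])
        self.stretch_modulus_se_ = float(se[2])
        self.params_ = WLCParams(P_ds=popt[0], B_ds=popt[1], S_ds=popt[2], kT=self.kT)
        return self

    def predict(self, X):
        F = np.asarray(X, dtype=float).reshape(-1)
        return wlc_extension(F, self.params_)


def fit_force_extension(
    curve: ForceExtensionCurve, f_max: float = 30.0, kT: float = KT_ROOM
) -> tuple[WLCParams, dict[str, float]]:
    """Fit the extensible WLC to a curve up to ``f_max`` pN.

    Returns the fitted parameter set and a dict of standard errors
    (keys ``P_ds``, ``B_ds``, ``S_ds``).
    """
    est = ExtensibleWLC(f_max=f_max, kT=kT).fit(curve.force, curve.extension_per_bp)
    ses = {
        "P_ds": est.persistence_length_se_,
        "B_ds": est.contour_per_bp_se_,
        "S_ds": est.stretch_modulus_se_,
    }
    return est.params_, ses


def overstretch_force(
    curve: ForceExtensionCurve, b_lo: float = 0.42, b_hi: float = 0.48
) -> tuple[float, float]:
    """Mean +- SE of the force over the overstretching extension window.

    The window is expressed in extension per bp (default 0.42-0.48 nm/bp).
    """
    b = curve.extension_per_bp
    mask = (b >= b_lo) & (b <= b_hi)
    if mask.sum() < 3:
        raise ValueError(
            f"overstretch window [{b_lo}, {b_hi}] nm/bp holds {mask.sum()} samples; "
            "need >= 3"
        )
    F = curve.force[mask]
    return float(F.mean()), float(F.std(ddof=1) / np.sqrt(F.size))


# ---------------------------------------------------------------------------
# loop-rupture events


def _step_filter(F: np.ndarray, window: int) -> np.ndarray:
    """Estimated downward force discontinuity between samples i and i+1.

    Each flank of ``window`` samples is fitted by a line and both lines are
    evaluated at the shared boundary (i + 1/2); the filter output is the
    pre-minus-post difference. This is the least-squares estimate of a step
    on a locally linear baseline, so a rising sawtooth does not bias it the
    way a raw max-to-min difference would. Entries without a full flank on
    both sides are -inf.
    """
    L = window
    k = np.arange(L, dtype=float)
    xbar = (L - 1) / 2.0
    sxx = np.sum((k - xbar) ** 2)
    coef_pre = 1.0 / L + (L - 0.5 - xbar) * (k - xbar) / sxx
    coef_post = 1.0 / L + (-0.5 - xbar) * (k - xbar) / sxx
    out = np.full(F.size, -np.inf)
    if F.size < 2 * L:
        return out
    # windows[i] = F[i:i+L]
    windows = np.lib.stride_tricks.sliding_window_view(F, L)
    pre = windows @ coef_pre  # value at right edge of F[i..i+L-1]
    post = windows @ coef_post  # value at left edge of F[i..i+L-1]
    # boundary between i and i+1: pre-window ends at i, post-window starts at i+1
    out[L - 1 : F.size - L] = pre[: F.size - 2 * L + 1] - post[L:]
    return out


def detect_loop_jumps(
    curve: ForceExtensionCurve,
    min_delta_F: float = 1.0,
    window: int = 16,
) -> list[int]:
    """Indices of candidate loop-rupture jumps on a stretching curve.

    A candidate is the last point before a downward force discontinuity of
    at least ``min_delta_F`` pN, as estimated by the linear-trend step
    filter (:func:`_step_filter`) over ``window``-sample flanks, embedded
    in a locally rising trend (sawtooth pattern). Candidates are local
    maxima of the filter response, ordered and non-overlapping.
    """
    if curve.direction != "extend":
        raise ValueError("loop-rupture detection applies to stretching curves only")
    F = curve.force
    drop = _step_filter(F, window)
    above = np.flatnonzero(drop >= min_delta_F)
    events: list[int] = []
    for i in above:
        # keep only the locally strongest response for each discontinuity
        lo, hi = max(0, i - window), min(F.size, i + window + 1)
        if drop[i] < drop[lo:hi].max():
            continue
        # rising trend before the jump (stretching sawtooth)
        pre = F[max(0, i - window + 1) : i + 1]
        if pre.size >= 2 and pre[-1] <= pre[0]:
            continue
        if events and i - events[-1] <= window:
            continue
        events.append(int(i))
    return events


def _fit_contour_only(
    F: np.ndarray, b: np.ndarray, fixed_P: float, fixed_S: float, kT: float
) -> float:
    """Closed-form LS for the contour length per bp with P and S held fixed.

    The model is linear in B: b = B * g(F), so B = sum(b g) / sum(g^2).
    Non-positive forces (possible in noisy low-force data) are excluded.
    """
    ok = F > 0
    if ok.sum() < 2:
        raise SizingError("flanking segment has fewer than 2 positive-force samples")
    F, b = F[ok], b[ok]
    g = 1.0 - 0.5 * np.sqrt(kT / (fixed_P * F)) + F / fixed_S
    return float(np.sum(b * g) / np.sum(g**2))


def size_loop(
    curve: ForceExtensionCurve,
    jump_index: int,
    fixed_P: float,
    fixed_S: float,
    n_bp: int | None = None,
    kT: float = KT_ROOM,
    segment: int = 15,
    segment_before: int | None = None,
    segment_after: int | None = None,
    min_segment: int = 5,
    window: int = 10,
) -> LoopEvent:
    """Size the loop released at a detected jump.

    The WLC is refitted to up to ``segment`` samples flanking the jump with
    only the contour length free (persistence length and stretch modulus
    held at ``fixed_P`` / ``fixed_S``); the released length in bp is
    ``delta_B * n_bp / 0.34``.

    Raises :class:`SizingError` when either flank holds fewer than
    ``min_segment`` samples.
    """
    if n_bp is None:
        n_bp = curve.n_bp
    F = curve.force
    b = curve.extension_per_bp
    # the force minimum after the drop marks the start of the post-release branch
    ahead = F[jump_index + 1 : jump_index + 1 + window]
    if ahead.size == 0:
        raise SizingError("jump at the end of the curve cannot be sized")
    j_after = jump_index + 1 + int(np.argmin(ahead))
    seg_b = segment if segment_before is None else segment_before
    seg_a = segment if segment_after is None else segment_after
    lo_before = max(0, jump_index - seg_b + 1)
    hi_after = min(F.size, j_after + seg_a)
    before = slice(lo_before, jump_index + 1)
    after = slice(j_after, hi_after)
    n_before = before.stop - before.start
    n_after = after.stop - after.start
    if n_before < min_segment or n_after < min_segment:
        raise SizingError(
            f"flanking segments of {n_before}/{n_after} samples are too short "
            f"(need >= {min_segment} each)"
        )
    B_before = _fit_contour_only(F[before], b[before], fixed_P, fixed_S, kT)
    B_after = _fit_contour_only(F[after], b[after], fixed_P, fixed_S, kT)
    delta_B = B_after - B_before
    return LoopEvent(
        extension_at_jump=float(curve.extension[jump_index]),
        F_before=float(F[jump_index]),
        F_after=float(F[j_after]),
        delta_F=float(F[jump_index] - F[j_after]),
        B_before=B_before,
        B_after=B_after,
        delta_B=delta_B,
        loop_bp=delta_B * n_bp / NM_PER_BP,
        jump_index=jump_index,
    )


def analyze_loops(
    curve: ForceExtensionCurve,
    fixed_P: float,
    fixed_S: float,
    min_delta_F: float = 1.0,
    kT: float = KT_ROOM,
    **size_kwargs,
) -> list[LoopEvent]:
    """Detect and size all loop-rupture events on one stretching curve.

    Flanking fit segments are clipped to half the gap between neighbouring
    events so one release never contaminates the sizing of the next. Jumps
    whose flanks are too short to size are dropped with a warning.
    """
    indices = detect_loop_jumps(curve, min_delta_F=min_delta_F)
    segment = size_kwargs.pop("segment", 15)
    events = []
    for k, idx in enumerate(indices):
        seg_b = segment
        seg_a = segment
        if k > 0:
            seg_b = min(seg_b, (idx - indices[k - 1]) // 2)
        if k + 1 < len(indices):
            seg_a = min(seg_a, (indices[k + 1] - idx) // 2)
        try:
            events.append(
                size_loop(
                    curve, idx, fixed_P=fixed_P, fixed_S=fixed_S, kT=kT,
                    segment_before=seg_b, segment_after=seg_a, **size_kwargs,
                )
            )
        except SizingError as exc:
            warnings.warn(f"jump at index {idx} left unsized: {exc}", stacklevel=2)
    return events


def loop_histograms(
    events: list[LoopEvent],
    bp_bin: float = 200.0,
    force_bin: float = 5.0,
    min_delta_F: float = 1.0,
) -> dict:
    """Binned loop-size and breaking-force distributions.

    Events with a force drop below ``min_delta_F`` (the instrument noise
    ceiling) are censored from the histograms; the censoring is reported in
    the output. Returns a dict with bin edges, counts and the modal bin for
    each of loop size (bp) and breaking force (F before the jump, pN).
    """
    if not events:
        warnings.warn("no loop events: returning empty histograms", stacklevel=2)
        return {
            "loop_bp": {"edges": [], "counts": [], "modal_bin": None},
            "break_force": {"edges": [], "counts": [], "modal_bin": None},
            "n_events": 0,
            "n_censored": 0,
        }
    kept = [e for e in events if e.delta_F >= min_delta_F]
    n_censored = len(events) - len(kept)

    def hist(values: np.ndarray, width: float) -> dict:
        if values.size == 0:
            return {"edges": [], "counts": [], "modal_bin": None}
        lo = np.floor(values.min() / width) * width
        hi = np.ceil(values.max() / width) * width + width / 2
        edges = np.arange(lo, hi + width, width)
        counts, edges = np.histogram(values, bins=edges)
        k = int(np.argmax(counts))
        return {
            "edges": edges.tolist(),
            "counts": counts.tolist(),
            "modal_bin": (float(edges[k]), float(edges[k + 1])),
        }

    return {
        "loop_bp": hist(np.array([e.loop_bp for e in kept]), bp_bin),
        "break_force": hist(np.array([e.F_before for e in kept]), force_bin),
        "n_events": len(kept),
        "n_censored": n_censored,
    }


# ---------------------------------------------------------------------------
# compaction


class ExponentialDecay(BaseEstimator, RegressorMixin):
    """Single-exponential decay regressor x(t) = baseline + amplitude*exp(-k t).

    Attributes: ``rate_``, ``rate_se_``, ``tau_``, ``tau_se_``,
    ``amplitude_``, ``baseline_``.
    """

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        x = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 10:
            raise ValueError("need >= 10 samples for an exponential fit")
        amp0 = x[0] - x[-1]
        if amp0 <= 0:
            raise NonDecayingError("series does not decay (final value >= initial)")

        def model(tv, baseline, amplitude, k):
            return baseline + amplitude * np.exp(-k * tv)

        span = t[-1] - t[0]
        popt, pcov = optimize.curve_fit(
            model, t, x, p0=[x[-1], amp0, 3.0 / max(span, 1e-12)],
            bounds=([-np.inf, 0.0, 1e-12], [np.inf, np.inf, np.inf]), maxfev=20000,
        )
        baseline, amplitude, k = popt
        if k <= 0 or amplitude <= 0:
            raise NonDecayingError("fitted decay is degenerate (k or amplitude <= 0)")
        se = np.sqrt(np.diag(pcov))
        if span < 2.0 / k:
            warnings.warn(
                f"series spans {span:.3g} s < 2 tau = {2.0 / k:.3g} s; "
                "the rate is poorly constrained",
                stacklevel=2,
            )
        self.baseline_ = float(baseline)
        self.amplitude_ = float(amplitude)
        self.rate_ = float(k)
        self.rate_se_ = float(se[2])
        self.tau_ = 1.0 / float(k)
        self.tau_se_ = float(se[2] / k**2)
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.baseline_ + self.amplitude_ * np.exp(-self.rate_ * t)


def compaction_fit(times, extensions) -> CompactionResult:
    """Fit the constant-force compaction transient to a single exponential."""
    est = ExponentialDecay().fit(times, extensions)
    return CompactionResult(
        k=est.rate_,
        k_se=est.rate_se_,
        tau=est.tau_,
        tau_se=est.tau_se_,
        amplitude=est.amplitude_,
        baseline=est.baseline_,
    )


def compaction_force(
    release_protein: ForceExtensionCurve,
    release_naked: ForceExtensionCurve,
    low_ext_fraction: float = 0.2,
    contour_nm: float | None = None,
) -> tuple[float, float]:
    """Compaction force: mean force excess (protein - naked) at low extension.

    Both release curves are interpolated onto the protein curve's extension
    samples below ``low_ext_fraction`` of the naked contour length (default
    ``n_bp * 0.34`` nm). Returns (mean difference, SE) in pN.
    """
    if contour_nm is None:
        contour_nm = release_naked.n_bp * NM_PER_BP
    cutoff = low_ext_fraction * contour_nm
    xp = release_protein.extension
    xn = release_naked.extension
    lo = max(xp.min(), xn.min())
    hi = min(xp.max(), xn.max(), cutoff)
    if hi <= lo:
        raise ValueError(
            "curves do not overlap below the low-extension cutoff "
            f"({cutoff:.1f} nm); cannot align"
        )
    mask = (xp >= lo) & (xp <= hi)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 protein-curve samples in the low-extension window")
    order = np.argsort(xn)
    f_naked = np.interp(xp[mask], xn[order], release_naked.force[order])
    diff = release_protein.force[mask] - f_naked
    return float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(diff.size))
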
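"""Concentration-series (titration) fits of tether observables.

A protein titration changes a mechanical observable of the tether --
persistence length, contour length per bp, or overstretching force -- from
its protein-free value toward a protein-saturated value as the lattice
occupancy theta(c) rises. The model composes the cooperative binding
isotherm (``smtether.binding.mvh_theta``) with the observable's occupancy
map: harmonic for persistence length, linear for contour length and
overstretching force.

Three parameters are fitted by weighted chi-square minimisation: K_D,
omega, and the saturated observable value; the binding site size n is held
fixed (default 26 bp) and the protein-free value is fixed from the c = 0
measurement, never fitted. The (K_D, omega) surface is ridge-prone, so the
fit is multi-started from a grid in (log10 K_D, log10 omega).

Independent per-observable estimates are combined by inverse-variance
weighting (weighted mean with the standard error of the weighted mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .binding import BindingParams, mvh_theta, occupancy_map_linear, occupancy_map_P

__all__ = [
    "TitrationSeries",
    "TitrationFit",
    "CombinedEstimate",
    "TitrationBindingCurve",
    "fit_titration",
    "combine_weighted",
    "FitConvergenceError",
]

OBSERVABLES = ("persistence", "contour", "overstretch")


class FitConvergenceError(RuntimeError):
    """Raised when the multi-start chi-square minimisation fails to converge."""


@dataclass
class TitrationSeries:
    """One observable measured across protein concentrations.

    ``points`` rows are (c [nM], y [observable units], sigma [SE], N
    [replicates]). At least 4 distinct concentrations including the c = 0
    protein-free anchor are required; all sigma must be positive.
    """

    observable: str
    points: np.ndarray

    def __post_init__(self) -> None:
        if self.observable not in OBSERVABLES:
            raise ValueError(f"observable must be one of {OBSERVABLES}")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 4:
            raise ValueError("points must be an (m, 4) array of (c, y, sigma, N)")
        if np.unique(pts[:, 0]).size < 4:
            raise ValueError("need >= 4 distinct concentrations")
        if not np.any(pts[:, 0] == 0):
            raise ValueError("series must include the c = 0 protein-free anchor")
        if np.any(pts[:, 2] <= 0):
            raise ValueError("all sigma must be positive")
        self.points = pts

    @property
    def c(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def sigma(self) -> np.ndarray:
        return self.points[:, 2]

    def protein_free_value(self) -> float:
        """Inverse-variance weighted mean of the c = 0 measurements."""
        anchor = self.points[self.points[:, 0] == 0]
        w = 1.0 / anchor[:, 2] ** 2
        return float(np.sum(w * anchor[:, 1]) / np.sum(w))


@dataclass
class TitrationFit:
    """Result of a three-parameter titration fit (n held fixed)."""

    K_D: float
    K_D_se: float
    omega: float
    omega_se: float
    saturated_value: float
    saturated_value_se: float
    chi2: float
    n_fixed: int
    observable: str
    omega_flat: bool = False
    covariance: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")
        for name in ("K_D_se", "omega_se", "saturated_value_se"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CombinedEstimate:
    """Inverse-variance weighted combination of independent estimates."""

    value: float
    uncertainty: float
    inputs: list[tuple[float, float]]

    def __post_init__(self) -> None:
        values = [v for v, _ in self.inputs]
        if not (min(values) - 1e-12 <= self.value <= max(values) + 1e-12):
            raise ValueError("combined value must lie within the input range")
        if self.uncertainty > min(s for _, s in self.inputs) + 1e-12:
            raise ValueError("combined uncertainty cannot exceed the smallest input sigma")


def combine_weighted(estimates: list[tuple[float, float]]) -> CombinedEstimate:
    """Weighted mean and its standard error from (value, sigma) pairs.

    value = sum(v_i / s_i^2) / sum(1 / s_i^2);
    uncertainty = 1 / sqrt(sum(1 / s_i^2)).
    """
    if not estimates:
        raise ValueError("need at least one estimate to combine")
    v = np.array([e[0] for e in estimates], dtype=float)
    s = np.array([e[1] for e in estimates], dtype=float)
    if np.any(s <= 0):
        raise ValueError("all sigma must be positive")
    w = 1.0 / s**2
    value = float(np.sum(w * v) / np.sum(w))
    unc = float(1.0 / np.sqrt(np.sum(w)))
    return CombinedEstimate(value=value, uncertainty=unc, inputs=list(map(tuple, estimates)))


def _observable_map(observable: str):
    if observable == "persistence":
        return occupancy_map_P
    return occupancy_map_linear


class TitrationBindingCurve(BaseEstimator, RegressorMixin):
    """Cooperative-binding titration model as a scikit-learn regressor.

    ``fit(c, y, sigma=...)`` minimises
    chi2 = sum(((y_i - model(c_i; K_D, omega, saturated)) / sigma_i)^2)
    where model(c) maps theta(c) from the binding isotherm through the
    observable's endpoint interpolation. The protein-free endpoint is a
    fixed hyperparameter, matching the three-parameter fit convention.

    Parameters
    ----------
    observable : {'persistence', 'contour', 'overstretch'}
    protein_free_value : float
        Fixed protein-free endpoint (P_D, B_D or F_ov^D).
    n : int
        Binding site size in bp, held fixed (default 26).
    log_kd_range, log_omega_range : (float, float)
        Multi-start grid ranges in log10 nM and log10, defaults
        (-2, 3) and (0, 3).
    n_starts : int
        Grid points per axis (default 5: a 5x5 start grid).
    n_polish : int
        Number of best-screened starts from which local optimisation is
        actually run (default 4).

    Attributes
    ----------
    kd_, kd_se_ : float -- dissociation constant, nM
    omega_, omega_se_ : float -- cooperativity
    saturated_value_, saturated_value_se_ : float
    chi2_ : float -- minimised chi-square
    omega_flat_ : bool -- unidentifiable-omega warning flag
    covariance_ : (3, 3) array in (K_D, omega, saturated) order
    """

    def __init__(
        self,
        observable: str = "persistence",
        protein_free_value: float = 50.0,
        n: int = 26,
        log_kd_range: tuple[float, float] = (-2.0, 3.0),
        log_omega_range: tuple[float, float] = (0.0, 3.0),
        n_starts: int = 5,
        n_polish: int = 4,
    ):
        self.observable = observable
        self.protein_free_value = protein_free_value
        self.n = n
        self.log_kd_range = log_kd_range
        self.log_omega_range = log_omega_range
        self.n_starts = n_starts
        self.n_polish = n_polish

    # -- model ------------------------------------------------------------
    def _model(self, c: np.ndarray, kd: float, omega: float, sat: float) -> np.ndarray:
        theta = mvh_theta(c, BindingParams(K_D=kd, omega=omega, n=self.n))
        return _observable_map(self.observable)(theta, self.protein_free_value, sat)

    def _screen_sat(self, theta: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
        """Closed-form weighted LS estimate of the saturated endpoint at fixed theta.

        Linear maps are linear in x_L; the harmonic persistence map is linear
        in 1/P_L, so screening solves in reciprocal space there.
        """
        free = self.protein_free_value
        if self.observable == "persistence":
            with np.errstate(divide="ignore"):
                target = 1.0 / y - (1.0 - theta) / free
            denom = np.sum(w * theta**2)
            if denom == 0:
                return free
            inv_sat = np.sum(w * theta * target) / denom
            return 1.0 / inv_sat if inv_sat > 0 else free * 0.1
        denom = np.sum(w * theta**2)
        if denom == 0:
            return free
        return float(np.sum(w * theta * (y - free)) / denom + free)

    def fit(self, X, y, sigma=None):
        c = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if sigma is None:
            sigma = np.ones_like(y)
        else:
            sigma = np.asarray(sigma, dtype=float).reshape(-1)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        if self.observable not in OBSERVABLES:
            raise ValueError(f"observable must be one of {OBSERVABLES}")
        w = 1.0 / sigma**2

        lo_k, hi_k = self.log_kd_range
        lo_w, hi_w = self.log_omega_range
        kd_starts = np.logspace(lo_k, hi_k, self.n_starts)
        om_starts = np.logspace(lo_w, hi_w, self.n_starts)

        # screen: chi2 at each grid start with the closed-form saturated value
        screened = []
        for kd0 in kd_starts:
            for om0 in om_starts:
                theta = mvh_theta(c, BindingParams(K_D=kd0, omega=om0, n=self.n))
                sat0 = self._screen_sat(theta, y, w)
                if not np.isfinite(sat0) or sat0 <= 0:
                    sat0 = max(y.min(), 1e-6) if self.observable == "persistence" else y.max()
                resid = (y - _observable_map(self.observable)(
                    np.clip(theta, 0, 1), self.protein_free_value, sat0)) / sigma
                screened.append((float(np.sum(resid**2)), kd0, om0, sat0))
        screened.sort(key=lambda t: t[0])

        def residuals(p):
            kd, om, sat = 10.0 ** p[0], 10.0 ** p[1], p[2]
            return (y - self._model(c, kd, om, sat)) / sigma

        best = None
        for chi0, kd0, om0, sat0 in screened[: self.n_polish]:
            try:
                res = optimize.least_squares(
                    residuals,
                    x0=[np.log10(kd0), np.log10(om0), sat0],
                    bounds=([lo_k - 2, lo_w - 1, 1e-9], [hi_k + 2, hi_w + 2, np.inf]),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            chi2 = float(np.sum(res.fun**2))
            if best is None or chi2 < best[0] - 1e-12:
                best = (chi2, res)
        if best is None:
            raise FitConvergenceError(
                f"no start of the {self.n_starts}x{self.n_starts} grid converged; "
                f"best screened chi2 {screened[0][0]:.4g} at "
                f"K_D={screened[0][1]:.3g} nM, omega={screened[0][2]:.3g}"
            )
        chi2, res = best
        log_kd, log_om, sat = res.x
        kd, om = 10.0**log_kd, 10.0**log_om

        # covariance in fit space (absolute sigmas), then delta method to
        # linear (K_D, omega, sat)
        J = res.jac
        try:
            cov_log = np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            cov_log = np.linalg.pinv(J.T @ J)
        ln10 = np.log(10.0)
        scale = np.diag([kd * ln10, om * ln10, 1.0])
        cov = scale @ cov_log @ scale
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        # guard against exactly-zero SEs on noiseless data
        se = np.maximum(se, 1e-12 * np.abs([kd, om, sat]))

        self.kd_ = float(kd)
        self.kd_se_ = float(se[0])
        self.omega_ = float(om)
        self.omega_se_ = float(se[1])
        self.saturated_value_ = float(sat)
        self.saturated_value_se_ = float(se[2])
        self.chi2_ = chi2
        self.covariance_ = cov
        self.omega_flat_ = bool(self.omega_se_ > 10 * self.omega_)
        if self.omega_flat_:
            warnings.warn(
                "chi-square is nearly flat in omega; the cooperativity is "
                "unidentifiable on these data",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        c = np.asarray(X, dtype=float).reshape(-1)
        return self._model(c, self.kd_, self.omega_, self.saturated_value_)


def fit_titration(
    series: TitrationSeries,
    n: int = 26,
    protein_free_value: float | None = None,
    **estimator_kwargs,
) -> TitrationFit:
    """Three-parameter (K_D, omega, saturated value) fit of a titration series.

    The protein-free value defaults to the inverse-variance mean of the
    series' c = 0 measurements and is held fixed during the fit.
    """
    if protein_free_value is None:
        protein_free_value = series.protein_free_value()
    est = TitrationBindingCurve(
        observable=series.observable,
        protein_free_value=protein_free_value,
        n=n,
        **estimator_kwargs,
    ).fit(series.c, series.y, sigma=series.sigma)
    return TitrationFit(
        K_D=est.kd_,
        K_D_se=est.kd_se_,
        omega=est.omega_,
        omega_se=est.omega_se_,
        saturated_value=est.saturated_value_,
        saturated_value_se=est.saturated_value_se_,
        chi2=est.chi2_,
        n_fixed=n,
        observable=series.observable,
        omega_flat=est.omega_flat_,
        covariance=est.covariance_,
    )
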
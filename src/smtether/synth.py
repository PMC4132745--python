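"""Seeded synthetic-data generators.

Raw single-molecule records (pulling curves, compaction transients,
titration tables, traced AFM polylines, lattice configurations) are bulky
and instrument-bound; every analysis stage here is instead exercised by
generators that produce data with exactly the statistical structure the
analysis assumes:

* stretching curves of a 48,500 bp lambda-DNA tether following the
  extensible WLC, with discrete loop-release events (sequestered contour
  returned to the tether when the force first reaches the loop's rupture
  force), an optional overstretching plateau, and i.i.d. Gaussian force
  noise;
* titration tables generated by composing the cooperative binding isotherm
  with the observable endpoint maps, plus Gaussian noise;
* discrete 2D wormlike chains whose tangent angle performs a Gaussian walk
  with variance step/p, so the ensemble satisfies <cos theta(L)> =
  exp(-L/2p); programmed kinks can be inserted for bend-angle tests;
* single-exponential compaction transients;
* grand-canonical lattice-binding configurations (via
  :func:`smtether.binding.sample_lattice`).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import binding
from .afm import Annotation, Trace2D
from .binding import BindingParams, LatticeSample, SaturationEndpoints, mvh_theta
from .polymer import ForceExtensionCurve, WLCParams, wlc_force
from .pulling import NM_PER_BP
from .titration import TitrationSeries

__all__ = [
    "SimulationSpec",
    "simulate_fec",
    "simulate_titration",
    "simulate_chain_2d",
    "simulate_compaction",
    "simulate_lattice",
]

#: lambda phage genome length, bp
LAMBDA_BP = 48_500
#: linearized pBR322 plasmid length, bp
PBR322_BP = 4_361

DEFAULT_WLC = WLCParams(P_ds=50.0, B_ds=0.34, S_ds=1200.0)
DEFAULT_BINDING = BindingParams(K_D=2.3, omega=23.0, n=26)
DEFAULT_ENDPOINTS = SaturationEndpoints(
    P_D=50.0, P_L=8.0, B_D=0.34, B_L=0.40, F_ov_D=62.0, F_ov_L=68.0
)
#: nM; log-spaced through the binding transition plus the protein-free anchor
DEFAULT_CONCENTRATIONS = (0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)


@dataclass
class SimulationSpec:
    """Bundle of generator settings for config-driven (CLI) simulation runs.

    Each section is a keyword dict passed to the matching ``simulate_*``
    function; the seed governs every generator drawn from the spec.
    """

    seed: int = 0
    fec: dict = field(default_factory=dict)
    titration: dict = field(default_factory=dict)
    chains: dict = field(default_factory=dict)
    compaction: dict = field(default_factory=dict)
    lattice: dict = field(default_factory=dict)


def simulate_fec(
    n_bp: int = LAMBDA_BP,
    params: WLCParams = DEFAULT_WLC,
    loops: list[tuple[float, float]] | None = None,
    b_min: float = 0.15,
    b_max: float = 0.41,
    n_points: int = 600,
    noise_force: float = 0.3,
    f_ov: float | None = None,
    concentration: float = 0.0,
    pulling_rate: float = 970.0,
    seed: int | None = None,
) -> ForceExtensionCurve:
    """Synthetic stretching curve with programmed loop-release events.

    ``loops`` is a roster of (size_bp, rupture_force_pN). While a loop is
    intact its base pairs are sequestered, shortening the effective contour;
    when the tether force first reaches the loop's rupture force the loop
    opens and its length returns to the contour, dropping the force at fixed
    extension. The extension grid spans ``b_min``..``b_max`` nm/bp of the
    full molecule. ``f_ov`` caps the force at an overstretching plateau.
    Gaussian force noise (``noise_force`` pN, 1 sigma) is added last.
    """
    loops = list(loops or [])
    if sum(bp for bp, _ in loops) >= n_bp:
        raise ValueError("loop roster sequesters the whole molecule")
    if any(bp <= 0 or f <= 0 for bp, f in loops):
        raise ValueError("loop sizes and rupture forces must be positive")
    rng = np.random.default_rng(seed)
    extension = np.linspace(b_min * n_bp, b_max * n_bp, n_points)
    active = sorted(loops, key=lambda t: t[1])  # weakest first
    force = np.empty(n_points)
    sequestered = sum(bp for bp, _ in active)

    def tether_force(x: float, seq: float) -> float:
        return wlc_force(x / (n_bp - seq), params)

    f0 = tether_force(extension[0], sequestered)
    if active and active[0][1] <= f0:
        raise ValueError(
            f"rupture force {active[0][1]} pN not above the initial tether "
            f"force {f0:.3g} pN; the event would predate the scan"
        )
    for i, x in enumerate(extension):
        F = tether_force(x, sequestered)
        while active and F >= active[0][1]:
            sequestered -= active.pop(0)[0]
            F = tether_force(x, sequestered)
        force[i] = F
    if f_ov is not None:
        force = np.minimum(force, f_ov)
    if noise_force > 0:
        force = force + rng.normal(0.0, noise_force, size=n_points)
    return ForceExtensionCurve(
        extension=extension,
        force=force,
        n_bp=n_bp,
        concentration=concentration,
        pulling_rate=pulling_rate,
        direction="extend",
    )


def simulate_titration(
    params: BindingParams = DEFAULT_BINDING,
    endpoints: SaturationEndpoints = DEFAULT_ENDPOINTS,
    concentrations=DEFAULT_CONCENTRATIONS,
    noise_frac: float = 0.05,
    replicates: int = 4,
    seed: int | None = None,
) -> dict[str, TitrationSeries]:
    """Noisy titration tables for every observable with supplied endpoints.

    The noise per point is Gaussian with sigma = ``noise_frac`` times the
    endpoint-to-endpoint range of the observable; that sigma is recorded in
    the series, emulating plotted standard errors.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations, dtype=float)
    theta = np.atleast_1d(mvh_theta(c, params))
    out: dict[str, TitrationSeries] = {}
    specs = {
        "persistence": (endpoints.P_D, endpoints.P_L, binding.occupancy_map_P),
        "contour": (endpoints.B_D, endpoints.B_L, binding.occupancy_map_linear),
        "overstretch": (endpoints.F_ov_D, endpoints.F_ov_L, binding.occupancy_map_linear),
    }
    for name, (free, sat, mapper) in specs.items():
        if free is None or sat is None:
            continue
        truth = np.atleast_1d(mapper(theta, free, sat))
        sigma = max(noise_frac * abs(sat - free), 1e-12)
        y = truth + rng.normal(0.0, sigma, size=truth.size)
        pts = np.column_stack([c, y, np.full_like(c, sigma), np.full_like(c, replicates)])
        out[name] = TitrationSeries(observable=name, points=pts)
    return out


def simulate_chain_2d(
    p: float = 59.0,
    contour_length: float = PBR322_BP * NM_PER_BP,
    step: float = 2.0,
    kinks: list[tuple[float, float]] | None = None,
    n_bp: int = PBR322_BP,
    molecule_id: str = "sim",
    seed: int | None = None,
) -> Trace2D:
    """Discrete 2D wormlike chain at persistence length ``p`` (nm).

    The tangent angle performs a Gaussian walk with per-step variance
    ``step / p``, giving <cos theta(L)> = exp(-L / 2p). ``kinks`` inserts
    deterministic extra turns of the given size (degrees) at the given arc
    positions (nm); each kinked vertex is annotated as a protein site.
    """
    if step >= p:
        raise ValueError("step must be well below the persistence length")
    n_steps = int(round(contour_length / step))
    if n_steps < 2:
        raise ValueError("contour shorter than two steps")
    rng = np.random.default_rng(seed)
    turns = rng.normal(0.0, np.sqrt(step / p), size=n_steps - 1)
    annotations: list[Annotation] = []
    for arc, angle_deg in kinks or []:
        idx = int(round(arc / step))
        if not (1 <= idx <= n_steps - 1):
            raise ValueError(f"kink at {arc} nm outside the chain")
        sign = 1.0 if rng.random() < 0.5 else -1.0
        turns[idx - 1] += sign * np.radians(angle_deg)
        annotations.append(Annotation(kind="protein_site", start_index=idx, end_index=idx))
    phi0 = rng.uniform(0, 2 * np.pi)
    angles = phi0 + np.concatenate([[0.0], np.cumsum(turns)])
    headings = np.column_stack([np.cos(angles), np.sin(angles)])
    points = np.vstack([[0.0, 0.0], np.cumsum(step * headings, axis=0)])
    return Trace2D(
        molecule_id=molecule_id, points=points, n_bp=n_bp, annotations=annotations
    )


def simulate_compaction(
    k: float = 0.64,
    amplitude: float = 500.0,
    baseline: float = 12_000.0,
    t_max: float = 10.0,
    n_points: int = 100,
    noise_frac: float = 0.05,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Constant-force compaction transient x(t) = baseline + amplitude e^{-kt}.

    Gaussian noise with sigma = ``noise_frac * amplitude`` is added.
    Defaults emulate a tether compacting on a ~1.6 s timescale.
    """
    if k <= 0:
        raise ValueError("rate k must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_points)
    x = baseline + amplitude * np.exp(-k * t)
    if noise_frac > 0:
        x = x + rng.normal(0.0, noise_frac * amplitude, size=n_points)
    return t, x


def simulate_lattice(
    c: float = 2.3,
    params: BindingParams = DEFAULT_BINDING,
    lattice_sites: int = 20 * 26,
    sweeps: int = 400,
    seed: int | None = None,
) -> LatticeSample:
    """Equilibrium lattice-binding configurations by grand-canonical MC.

    Returns the sample with configurations kept, empirical coverage and
    cluster statistics. Warns when the first and second halves of the
    post-burn-in record disagree by more than 5 combined standard errors
    (crude non-equilibration diagnostic).
    """
    sample = binding.sample_lattice(
        c, params, lattice_sites, sweeps=sweeps, seed=seed, keep_configurations=True
    )
    half = len(sample.configurations) // 2
    if half >= 10:
        n = params.n
        th1 = np.mean([len(s) * n / lattice_sites for s in sample.configurations[:half]])
        th2 = np.mean([len(s) * n / lattice_sites for s in sample.configurations[half:]])
        if sample.theta_se > 0 and abs(th1 - th2) > 5 * sample.theta_se * np.sqrt(2):
            import warnings

            warnings.warn(
                "lattice sampler halves disagree; chain may not be equilibrated",
                stacklevel=2,
            )
    return sample


# re-exported for convenience in simulation specs
DEFAULTS = {
    "fec": dict(n_bp=LAMBDA_BP, noise_force=0.3),
    "titration": dict(noise_frac=0.05),
    "chains": dict(p=59.0, step=2.0),
    "compaction": dict(k=0.64, noise_frac=0.05),
    "lattice": dict(c=2.3, lattice_sites=520),
}
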
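# Methods

This note documents the models `smtether` implements, the conditions its
synthetic-data generators emulate, and the numerical choices that shape the
results the test suite and `scripts/acceptance.py` compute.

## Tether mechanics

The extensible worm-like chain describes a dsDNA tether above ~1 pN:
`b(F) = B_ds [1 - (1/2)(kT/(P_ds F))^(1/2) + F/S_ds]`, with extension per
base pair `b` (nm/bp), persistence length `P_ds` (nm), contour length per
base pair `B_ds` (nm/bp) and stretch modulus `S_ds` (pN). Thermal energy
defaults to `kT = 4.11 pN nm` (298 K) and is overridable everywhere.
`b(F)` is strictly increasing, so the inverse `F(b)` is unique; it is
computed by vectorized bisection on `log10 F` plus Newton polishing, to
machine precision (round-trip agreement ~1e-14 relative).

**Fitting window and direction.** Curves are fitted for `(P_ds, B_ds,
S_ds)` over 1–30 pN. The 30 pN ceiling keeps the fit below the
overstretching transition; the 1 pN floor is where the high-force
interpolation itself degrades and where force noise acquires enormous
leverage. Two choices matter for bias and were validated on synthetic
curves with sigma_F = 0.3 pN:

1. residuals are formed on the force channel (`F - F_model(b)`), because
   the extension grid is commanded by the stage while the noise lives on
   the measured force; the naive extension-space fit is an
   errors-in-variables regression that attenuated the recovered `P_ds` by
   10–25%;
2. the 1–30 pN window is mapped onto the extension axis (two passes,
   using the current parameter estimate), because truncating on the noisy
   force selects on the noise and biases the edges of the window.

With both, `P_ds` recovery on 50 synthetic lambda-DNA curves is unbiased
with ~3% scatter.

**Overstretching force.** Mean +- SE of the force over the extension
window 0.42–0.48 nm/bp (at least 3 samples required).

## Loop-rupture events

A protein-stabilised loop sequesters contour length; its rupture during
stretching drops the force at fixed extension ("sawtooth"). Detection uses
a least-squares step filter: straight lines are fitted to the two
`window`-sample flanks (default 16) of every sample boundary and evaluated
at the shared boundary; the response is the pre-minus-post difference.
This is the matched estimator for a discontinuity on a locally linear
baseline. A raw local-max-to-local-min rule was rejected because the
extreme values of short noisy windows are biased upward by ~2.3 sigma
(~0.7 pN at sigma_F = 0.3 pN), which cannot satisfy a zero-false-positive
requirement at a 1.0 pN threshold. Candidates are local maxima of the
response above `min_delta_F` (default 1.0 pN, the instrument noise ceiling
in the presence of protein) with a rising pre-trend; events closer than
one window are merged. On 100 synthetic loop-free curves at
sigma_F = 0.3 pN the detector reports zero events, while recall for
injected ruptures with discontinuities >= 1.5 pN is 100%.

Note that the physical discontinuity exceeds the raw consecutive-sample
drop whenever the baseline rises between samples; thresholds refer to the
discontinuity.

**Sizing.** Each jump is re-fitted with only the contour length free
(`b = B g(F)` is linear in `B`), persistence length and stretch modulus
held fixed; flanking segments default to 15 samples and are clipped to
half the gap between neighbouring events. The released length is
`delta_B * N_bp / 0.34 nm`, with 0.34 nm/bp the B-form rise — used exactly
as stated even though the fitted `B_ds` may differ slightly. Events below
the 1.0 pN threshold are excluded from histograms (censoring is counted
and reported). Total sequestered length on synthetic multi-loop curves is
conserved within ~1%.

## Cooperative lattice binding

The McGhee–von Hippel isotherm for a ligand covering `n = 26` bp with
cooperativity `omega` is solved for the covered fraction Θ in [0, 1) by
bracketed root finding (scalar brentq with a built-in residual self-check
of 1e-8, and a fixed-iteration vectorized bisection inside model
evaluation). `omega = 1` makes the cooperative bracket 0/0, so
`|omega - 1| < 1e-6` switches to the documented non-cooperative closed
form; at `n = 1` this reduces to the Langmuir isotherm exactly. The free
ligand concentration is taken as the bulk concentration (flow-cell excess,
no depletion).

**Observable maps.** Persistence length interpolates harmonically between
protein-free and saturated endpoints,
`P(Θ) = P_L P_D / (P_L + Θ (P_D - P_L))`; contour length and
overstretching force interpolate linearly. The inverse of the harmonic map
recovers Θ from an observed persistence length.

**Titration fits.** Three parameters `(K_D, omega, saturated value)` are
fitted by weighted chi-square (weights = plotted standard errors); the
binding site size stays fixed at 26 bp and the protein-free value is fixed
from the c = 0 anchor, never fitted. The (K_D, omega) surface is
ridge-prone, so fits multi-start from a 5x5 grid over
`log10 K_D in [-2, 3]` (nM) and `log10 omega in [0, 3]`; starts are
screened by their closed-form-saturation chi-square and local optimisation
runs from the best four. Uncertainties come from the local covariance at
the chi-square minimum (inverse Gauss-Newton curvature), transformed from
log to linear parameters; a flat-omega flag is raised when the omega SE
exceeds 10x the estimate. Independent per-observable estimates combine by
inverse-variance weighting: `v = sum(v_i/s_i^2)/sum(1/s_i^2)`,
`s = 1/sqrt(sum(1/s_i^2))`.

**Cluster statistics.** On a finite lattice of M sites the ensemble with
weight `(c/K_D)` per bound ligand and `omega` per exactly-adjacent pair is
summed exactly by a linear transfer-matrix recursion (states: site empty
vs footprint end, with ligand- and contact-count accumulators; jointly
rescaled against overflow; verified against brute-force enumeration to
1e-10). The mean cluster size is the ratio of means
`<ligands>/<ligands - contacts>`. A grand-canonical Metropolis sampler
(insertion/deletion at a uniform site plus single-site ligand shifts,
which decorrelate the dense cooperative phase) cross-checks every exact
number; its standard errors use the integrated autocorrelation time
(Sokal windowing) of the occupancy series, and cluster-size errors use
batch means with batches of ~10 autocorrelation times. The dense phase
(Θ ≳ 0.9) mixes slowly; runs of >= 12000 sweeps keep the error bars honest
there, and shorter runs trigger no failure but carry wider true errors
than reported.

**The "dimer" estimate.** At `c = K_D` (2.3 nM) with `omega = 23` and
`n = 26` the package evaluates the mean bound-cluster size on a small,
three-footprint (78-site) lattice, where it is ~1.9 proteins per cluster —
consistent with dimer formation. This estimate grows with lattice size
(~2.2 at 80 sites, ~4.2 in the thermodynamic limit, where the same
ensemble sits at Θ = 0.93): on long lattices the strongly-bound phase at
`c = K_D` is dense enough that clusters merge. The small-lattice
convention is therefore part of the estimate's definition here, not an
approximation to the infinite-lattice value, and the lattice size is an
explicit argument everywhere.

## Compaction

Constant-force compaction transients are fitted to
`x(t) = baseline + amplitude exp(-k t)`; non-decaying input (final value
above initial, or degenerate fitted parameters) is rejected with a
dedicated error, and a warning is raised when the record spans less than
2/k. The compaction force is the mean force excess (protein minus naked
release curve, interpolated to common extensions) below 20% of the naked
contour length; the window fraction is configurable because the
"low-extension limit" is not sharply defined.

## AFM trace analysis

Traces are ordered polylines in nm from an external tracing tool; no image
processing happens here.

**Persistence length.** Traces are resampled by arc length (default step
5 nm, linear interpolation), tangents are the secants of consecutive
resampled points, and `<cos theta(L)>` is pooled over all positions of all
molecules at separations L = k·step (default up to 150 nm). Standard
errors per bin come from between-molecule variation — positions within a
molecule are strongly correlated, molecules are independent. The decay is
fitted as `A exp(-L/2p)` with a free nuisance amplitude: chord tangents
rescale the correlation by a constant factor at L >= step, and pinning
A = 1 converted that offset into an 8–17% upward bias in p at step 5 nm;
with the nuisance amplitude, recovery at p = 20/39/59 nm is unbiased
within ~1%. The identically-1 bin at L = 0 is excluded. Non-decaying
input raises a divergence flag instead of returning a finite p. Central-
difference tangents (spanning two steps) were rejected: they smooth the
walk twice and inflated p by ~20%.

**Bend angles.** The angle at an annotated site is the turn between the
incoming and outgoing tangent directions, each from a principal-axis line
fit over 10 nm of contour (~2 tip radii; configurable); 0 deg = straight,
angles folded into [0, 180]. The bend-angle distribution is summarised by
a bi-Gaussian — one peak with distinct left/right widths, fitted by
maximum likelihood of the two-piece normal on the raw angles (the
histogram-count fit was unstable at realistic sample sizes). A
sum-of-two-Gaussians alternative is available (`mode='two_gaussians'`).
Sample mean and SD are always reported; degenerate input skips the fit.

**Loops and bridges.** Loops are closed circuits of annotated trace
indices; their perimeter converts to bp at 0.34 nm/bp (or the molecule's
own contour/n_bp calibration). Bridges are annotation-driven counts:
fraction of molecules with at least one bridge, and mean bridges per
molecule.

## Synthetic-data generators

All generators are deterministic given a seed. Defaults define the
conditions under which the recovery properties are measured:

- **Pulling curves**: 48,500 bp lambda-DNA, `P = 50 nm`, `B = 0.34 nm/bp`,
  `S = 1200 pN`, extension grid 0.15–0.41 nm/bp (600 points), Gaussian
  force noise 0.3 pN (the stated noise ceiling is 1.0 pN; 0.3 pN
  represents a clean protein-containing record). Loops rupture
  deterministically when the tether force first reaches their assigned
  force — no rate-dependent (Bell) kinetics, because the analysis targets
  event sizes, not kinetics. The overstretching plateau is a hard force
  cap, sufficient for window-average tests.
- **Titrations**: truth `K_D = 2.3 nM`, `omega = 23`, `n = 26`; endpoints
  50 -> 8 nm (persistence), 0.34 -> 0.40 nm/bp (contour), 62 -> 68 pN
  (overstretch); eight concentrations 0–10 nM spanning the transition;
  noise 5% of the endpoint range, recorded as the per-point sigma.
- **2D chains**: tangent-angle Gaussian walk with per-step variance
  step/p (step 2 nm), contour 1 µm or the 4361 bp plasmid equivalent;
  optional deterministic kinks annotated as protein sites.
- **Compaction**: `k = 0.64 1/s`, amplitude 500 nm on a 12 µm baseline,
  10 s record, 5% amplitude noise.
- **Lattice**: the Monte-Carlo sampler above, with configurations kept.

What these generators do *not* emulate: instrument drift and baseline
wander, bead/trap compliance, surface-deposition artefacts in AFM,
heterogeneous or sequence-dependent binding, rate-dependent loop kinetics,
and ligand depletion. Recovery tests therefore demonstrate correctness of
the estimators under the models' own assumptions, not robustness to every
artefact of real records.

## Problem sizes in the shipped checks

The test suite and acceptance script use: 100 titration replicates
(observables round-robin), 100–120 chains of 1 µm per persistence
recovery, 100 loop-free curves plus 30 three-loop curves, 100 compaction
replicates, a 5-point concentration grid at 12000 Monte-Carlo sweeps on a
520-site lattice, and 30000-sweep cross-checks on 60–78-site lattices —
sizes chosen so every stochastic comparison has calibrated error bars
while a full run stays in the minutes range on one CPU.

## Known limitations

- The cluster-size estimate depends explicitly on lattice size (above).
- The titration chi-square ridge means omega is weakly identified when
  the data saturate early; the flat-omega flag marks such fits.
- The step filter assumes a locally linear baseline over one window
  (~16 samples); extremely dense event trains (closer than one window)
  merge.
- The 2D-chain persistence estimate carries a small chord-discretisation
  amplitude which the nuisance parameter absorbs; step sizes approaching p
  would break that approximation.
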
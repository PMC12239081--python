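# Methods

This note documents the models, estimators and numerical choices behind
`scperm`, and what the synthetic ground truth does and does not establish
about real simulation data.

## Transport model

Water transport across a bilayer is described by the inhomogeneous
solubility–diffusion (ISD) model: the membrane is a stack of slabs, each
contributing a local resistance `exp(ΔG(z)/RT) / D_z(z)`, and

    1/P = ∫_{z_lo}^{z_hi} exp(ΔG(z)/RT) / D_z(z) dz .

Assumptions inherited from the model: transport is diffusive and locally
Markovian along z, lateral heterogeneity is averaged out, and ΔG is
referenced to bulk water so the exponent vanishes outside the membrane
(this makes the flat-membrane limit P = D/L exact). Integration bounds
default to the entire sampled coordinate rather than a nominal membrane
thickness: bulk slabs contribute negligible resistance, and this avoids an
arbitrary membrane-edge cut. An override is provided, and resistance is
additive across any interior split point by construction.

Internal units are nm, ps, kJ/mol and K (R = 8.31446×10⁻³ kJ mol⁻¹ K⁻¹,
default temperature 303.15 K); permeabilities are reported in cm/s
(1 nm/ps = 10⁵ cm/s).

## Sampling design

The reaction coordinate (default 9 nm, 0.1 nm windows → 90 windows) is
covered by configurations of tracers spaced 1.5 nm apart so they cannot
interact; each window is covered 4 times (60 configurations of 6 tracers).
Configurations enumerate grid offsets deterministically, so plans are
reproducible without an RNG; only the z positions matter to the analysis,
and lateral placement is left to whatever engine executes the insertions.
The tracer fade-in coupling schedule (λ = 0.25, 0.5, 0.75, 1) is carried as
plan metadata only — executing insertions and equilibration is outside this
package's scope.

## Free energy (PMcF)

The mean constraint force per window is integrated along z with the
trapezoidal rule, anchored to zero at the most bulk-ward window. Before
integration the force profile is replaced by its odd part,
F_sym(z) = (F(z) − F(−z))/2 — symmetrization acts on forces, not on ΔG —
which averages the two leaflets and makes the resulting ΔG exactly even.

Error model: raw force samples are heavily autocorrelated, so the coverage
repeats of a window are the independence unit; the window standard error is
the spread of replicate means (a window sampled only once falls back to a
5-block partition of its series). Errors propagate through the trapezoid
weights assuming window independence, hence grow monotonically away from
the anchor. For real pull-force input, the analysis window defaults to the
last half of production (e.g. the last 20 ns of a 40 ns run) to drop the
noisier early segment; synthetic series start in the stationary law and
are analyzed in full.

Noiseless input converges at second order in the window spacing; the test
suite verifies the ~4× error reduction per halving.

## Local diffusion (Kubo)

D_z(z₀) = (RT)² / ∫ C(t) dt, with C the autocovariance of the constraint
force. Numerical choices:

- unbiased ACF estimator (1/(N−k) divisor), computed by FFT and verified
  against the direct sum to 1e-10;
- replicate ACFs are averaged before the single trapezoidal integral
  (variance reduction before the nonlinear 1/x step);
- truncation lag: 50 ps default for real MD force records, 5 ps for the
  synthetic runs (≈50 correlation times in both regimes — the validity
  criterion is the decay, not the constant);
- convergence: accepted when the final 10% of the lag range stays below 5%
  (configurable) of C(0); zero-variance series raise a distinct degenerate
  signal rather than returning false, and a non-positive ACF integral is a
  hard "nonphysical" error rather than a number;
- error bars: no standard recipe exists for this estimator, so the package
  uses the spread of D over a 5-block partition of each series (blocks
  averaged across replicates before integrating);
- the profile entering the ISD integral is leaflet-symmetrized,
  D_sym(z) = (D(z)+D(−z))/2, consistent with the even ΔG; the raw profile
  is available via a flag.

## Permeability uncertainty and comparison

No closed-form error propagation through the double nonlinearity
(exp, then 1/x) is attempted. Instead, seeded Monte Carlo: ΔG and D are
perturbed per window by independent Gaussians scaled to their standard
errors, P is re-evaluated per draw, and the spread of draws is reported.
This ignores the correlation that trapezoid integration induces between
neighbouring ΔG windows, so it is a per-window error model, not a full
posterior; with only small ΔG errors it agrees with first-order (delta
method) propagation, which the tests check. Draw counts below 100 are
refused as unstable. Two systems are compared with a two-sided Student
t test on their P draws (or replicate-wise estimates); p < 0.05 is flagged.

## Synthetic ground truth

Constraint forces are emulated per window by a stationary
Ornstein–Uhlenbeck process with the exact discretization
F ← μ + (F−μ)e^(−dt/τ) + σ√(1−e^(−2dt/τ)) ξ, eliminating time-step bias so
downstream error is attributable to the estimators. The window mean is the
true mean force μ = −dG/dz(z₀) and the variance satisfies the
fluctuation–dissipation constraint σ² = (RT)²/(D(z₀) τ(z₀)), so the Kubo
route recovers exactly D(z₀). Streams are seeded per (seed, window,
replicate): identical seeds are bit-reproducible, replicates independent.

Defaults (chosen once as the desk-scale study conditions):

- τ = 0.1 ps everywhere — the order of solvent force decorrelation, far
  below the ACF truncation lag;
- D_bulk = 0.002 nm²/ps — the scale of water self-diffusion at ~303 K;
- dt = 0.05 ps (= τ/2) — the sampling interval trades ACF resolution
  against total simulated time per window; at τ/2 the trapezoidal ACF
  integral carries a known ≈ +2% bias (hence ≈ −2% in D), which is small
  against the ≤15% recovery targets;
- n = 10⁵ samples per window series, 4 replicates → 5 ns per series,
  20 ns aggregated per window.

Preset landscapes (shapes chosen to be qualitatively representative; all
expose their exact permeability via adaptive quadrature):

- `flat` — G ≡ 0, uniform D: the closed-form D/L limit;
- `gauss_barrier` — a single 12 kJ/mol Gaussian barrier (width 0.8 nm);
- `sc_like` — twin 16 kJ/mol barriers at ±1.5 nm (width 0.4 nm) over an
  8 kJ/mol central plateau, with D dipping one order of magnitude inside
  the membrane: the qualitative signature of a dense ceramide bilayer.

Sampling-error budget: the standard error of a window's mean force depends
only on D(z₀) and the aggregated time, SE ≈ RT √(2/(D T)); integrating
these errors makes ΔG a random walk peaking mid-membrane at ~0.5 kJ/mol
under the defaults, which maps to a one-sigma permeability recovery error
of ~8% for the barrier presets (measured across seeds; unbiased). A single
seeded campaign therefore recovers P typically within ~10%, occasionally
worse — the quantity to compare against is the run's own Monte-Carlo error
bar.

What the toy membranes emulate: exact marker-plane separations, box-area /
lipid-count arithmetic, straight tilted chains (so S_z is exactly
(3cos²θ−1)/2), fixed lateral chain separations, and countable
donor–hydrogen–acceptor triplets. What they do not: conformational
disorder, interdigitation, undulations, water structure, or realistic
hydrogen-bond networks — passing structural tests validates the metrics'
geometry and bookkeeping, not force-field realism.

## Structural metrics

- Bilayer center: mass-weighted mean z of the (selected) atoms per frame;
  all z are center-relative, which removes drift and makes every metric
  invariant under rigid translation.
- Histograms along z place bin centers on multiples of the bin width
  (default 0.02 nm) relative to the center, so ideal fixtures land exactly
  on bin centers; thickness peaks are refined by a quadratic fit through
  the three bins around the mode (sub-bin precision without a parametric
  lineshape), with errors from 6-block averaging over frames.
- Masses are guessed from the leading letter of the atom name (H/C/N/O/P/S;
  unknown → carbon-like), consistently between the density metric and the
  toy-membrane fixtures.
- APL = Lx·Ly/n per frame; the error is the spread of the frame series.
- S_z uses the vector from atom i−1 to i+1 as the molecular axis of carbon
  i, averaged over lipids and frames; bounds −0.5 ≤ S_z ≤ 1 are asserted.
- Chain–chain distances are xy-projected ("lateral") by default, with a 3-D
  mode for cross-checks; the distribution is smoothed with a fixed-width
  Gaussian kernel (default 0.025 nm bandwidth, reported in metadata) on a
  grid extending 6 bandwidths past the data, and modes are read off sign
  changes of the finite-difference derivative.
- Hydrogen bonds use the conventional geometric criterion
  (donor–acceptor ≤ 0.35 nm and hydrogen–donor–acceptor angle ≤ 30° by
  default) under the minimum-image convention; donors without an
  identifiable hydrogen are a definition error. Counts are reported per
  frame and per lipid; because "per lipid" is ambiguous between all lipids
  and the named class, the normalizer is an explicit argument and both
  normalizations can be emitted.

## Degenerate inputs and tie-breaks

Ragged or empty force tables, off-grid windows, grid gaps, asymmetric
grids, unconverged or non-positive ACF integrals, non-positive D inside the
integration bounds, and geometrically impossible fixtures all raise typed
errors rather than propagating NaNs; the pipeline tags failures with the
stage name and writes a machine-readable error manifest. A window exactly
at z = 0 symmetrizes to zero force by definition. Flat-topped histogram
peaks fall back to the bin center.

## Known limitations

- The Monte-Carlo P uncertainty treats windows as independent (see above).
- The Kubo estimator inherits the trapezoidal ACF bias (−2% in D at
  dt = τ/2); negligible for real force records sampled every timestep.
- The per-window OU surrogate models only the z-force statistics, not 3-D
  tracer dynamics or cross-window correlations.
- Only orthorhombic boxes are supported throughout.
- Noise streams are keyed by (seed, window, replicate) only, so campaigns
  run on different landscapes at the same seed share their noise
  realizations; this is deliberate (paired comparisons) but means such
  runs are not statistically independent of each other.
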
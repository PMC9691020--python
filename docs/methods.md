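# Methods

This note documents the models implemented in `srxfret`, their
assumptions, the numerical choices behind the fitters, what the synthetic
data emulate, and the package's known limitations.

## Exponential-sum transient model

Fluorescence transients are modelled as `F(t) = F∞ + Σᵢ Aᵢ exp(−kᵢ t)`
with one or two components. The DRX/SRX interpretation assigns the fast
component to uninhibited (disordered-relaxed) heads and the slow component
to super-relaxed heads; population fractions are the fractional amplitudes
`Aᵢ / ΣAⱼ`, computed from the amplitudes only (the offset `F∞` is
instrument baseline plus fully-quenched signal and carries no population
information). Normalising by `ΣAᵢ` is a choice: whether amplitudes should
be normalised before or after photobleaching correction is ambiguous in
practice, and no bleaching model is applied here.

**Fitting.** The fitter uses variable projection: for any trial rate set
the amplitudes and offset are the solution of a linear least-squares
problem, so the nonlinear search runs over rates only. A multi-start grid
(default 5 log-spaced rates spanning 1e-4–1 s⁻¹, all pairs for the
two-component model) selects the best start, which is polished by a
bounded trust-region step on log-rates (rate bounds 1e-5–1e3 s⁻¹,
objective tolerance 1e-10 on the residual sum of squares). Standard
errors come from the full analytic Jacobian at the optimum. The default
grid targets single-turnover rates; callers fitting faster processes
(e.g. binding transients) pass a grid matched to their time base, which
`extract_kobs` derives from the trace duration.

**Model selection (`n_components="auto"`).** Two components are reported
only when AICc improves by at least 2 over the single-exponential model,
the minor fractional amplitude is at least 0.02, and the rate separation
is at least threefold. A requested two-component fit collapses to one
component (with a warning) when the rates are within 5% of each other,
a component's amplitude vanishes, or the second component does not reduce
the residual — the degenerate, unidentifiable regimes.

**Time base.** The generator's default single-turnover grid is 2000
log-spaced points from 0.1 s to 1000 s: log spacing resolves the fast
phase without starving the slow phase, and 0.1 s is a realistic first
usable sample for a stopped-flow record of a process with rates below
0.1 s⁻¹ (instrument dead time ~1 ms is negligible at these rates, so no
dead-time correction is applied; time zero is the first sample).

**Replicate statistics.** Salt profiles average measurements over
preparations; WT-vs-mutant comparisons use unpaired, two-tailed,
equal-variance t-tests at each KCl level. Identical groups report p = 1.
Single-replicate conditions report no SD and skip the test.

## Kinetic schemes for Cy3ATP binding

Both candidate mechanisms are linear mass-action systems under
pseudo-first-order binding (nucleotide in excess over heads, its
depletion ignored — an exact bimolecular mode is available for checking
this approximation). Scheme 1 has two binding-competent apo
conformations: Open binds with second-order constant `k_T`, the
alternate (ALT) conformation 10–20-fold slower (`k'_T`), and both
ATP-bound states relax quickly into the IHM (`k_IHM`, `k'_IHM`). The
Open↔ALT interconversion is off on the transient time scale: the slow
observed phase is nucleotide-dependent, which implies direct binding from
ALT rather than conversion through Open. Scheme 2 instead posits a
binding-incompetent conformation in slow equilibrium with Open
(`k_iso±`); the isomerisation is the mechanism's defining feature and
stays on. Binding is treated as irreversible over the fit window
(single-turnover conditions).

FRET visibility defaults to the IHM state only: donor quenching grows
with the summed occupancy of FRET-visible states, and the simulated
signal is `S(t) = S₀ − ΔS·f_FRET(t)`.

Integration uses LSODA at rtol 1e-8 / atol 1e-10 with occupancy
conservation checked at every output time; the test suite cross-checks
trajectories against the matrix-exponential solution of the same linear
system. Phenomenological analysis (`extract_kobs`) fits each transient,
regresses fast and slow observed rates linearly on concentration, and
reports slopes as apparent second-order constants plus the mean relative
fast amplitude; a slope whose 95% CI spans zero is flagged
concentration-independent rather than suppressed. Global fitting shares
rate constants (and optionally the initial Open fraction) across
concentrations, solves per-transient signal scales linearly at each
iteration, and compares mechanisms by AICc. Parameters with a flat
profile at the optimum are flagged unidentifiable, not silently fixed —
with fast IHM entry (≫ binding rates) `k_IHM` is intrinsically poorly
identified, which is expected and reported.

One reported phenomenological constant (the high-salt slow phase) is a
first-order rate (s⁻¹) rather than a slope; such rates are carried
through as intercept-like constants and never forced through the linear
concentration fit.

## FRET and the SRX→FRET correlation model

Efficiencies are stored as fractions and only rendered as percentages in
reports. Steady state: `E = 1 − (F_DA − bg)/(F_D − bg)` with a scalar
background per spectrum (no spectral unmixing). Time-resolved: both
decays are fitted to two-exponential models under Poisson weighting
(weights `1/√max(c,1)`, no instrument-response convolution), reduced to
an amplitude-weighted mean lifetime `τ = ΣAᵢτᵢ/ΣAᵢ` (intensity weighting
available behind a flag), then `E = 1 − τ_DA/τ_D`; `τ_DA > τ_D` clips to
zero with a warning. Distances use `r = R₀((1−E)/E)^{1/6}` and its exact
inverse; `R₀ = 63 Å` for the GFP/Cy3 pair is an input, not computed from
overlap integrals, and no orientation-factor modelling is attempted.

The correlation model assumes the SRX biochemical state and the IHM
structural state coincide one-to-one, the open state shows no FRET, and a
fully folded population has ensemble efficiency `E_IHM`. The default
`E_IHM = 0.060` corresponds to a ~100 Å effective distance and is a
configurable constant rather than a derived quantity: the measured
low-salt efficiency (5.5% at ~89% SRX) is consistent with values near
0.06 but does not pin it down, so the constant is exposed in
`PipelineConfig` and `predict_fret_from_srx`. The ensemble efficiency of
the structural model averages per-pair efficiencies over the closed-state
donor–acceptor distances (default set 100/130/135/140 Å spanning the
free-head and blocked-head pairs) without occupancy weights, since the
structural model supplies none. Predicted-vs-measured comparisons are
reported, never asserted: the prediction is expected to diverge for WT at
high salt, where the folded fraction (and hence the measurable signal)
is small.

## Supporting assays

ATPase curves fit `v(a) = v₀ + k_cat·a/(K + a)` by bounded least squares
with v₀ fitted (not fixed) because it is reported per construct; a
zero-actin point is required. Flat curves degenerate to the basal rate
with K flagged unconstrained; K beyond 10× the largest actin
concentration is flagged poorly constrained. The NH₄⁺ assay regresses
[Pi] on time and divides the slope by head concentration; the phosphate
standard curve is ordinary least squares with intercept retained.
Motility aggregation is SuperPlot-style: stuck filaments (exactly
0 nm/s) are excluded from velocity means, and the grand mean ± SD is
computed over preparation means, making it invariant to per-prep sample
size. EM percentages are computed over classifiable molecules only, with
Wilson 95% intervals on the closed proportion; mutant/WT ratios round
half-away-from-zero to one decimal for reporting while retaining the
unrounded value.

## Synthetic data

The generators reproduce the statistical structure the analysis assumes —
Gaussian noise (default 0.5% of total amplitude) on analogue stopped-flow
channels, Poisson counts in TCSPC histograms, binomial EM tallies with an
independently drawn unclear class (default odds corresponding to ~20%
unclear, within the observed 70–85% classifiable range), Gaussian
motility velocities with an exact-zero stuck subpopulation — at parameter
sets taken from reported measurements for the WT and E525K constructs.
They do **not** emulate photobleaching, instrument-response convolution,
shot-to-shot drift, filament-tracking artifacts or grid-surface effects
in EM; passing recovery tests therefore demonstrate estimator
correctness under the assumed noise model, not robustness to every
instrument pathology. Donor-only GFP lifetimes are generator placeholders
(2.6/0.9 ns two-exponential), chosen as typical GFP values rather than
measured ones. Every generator call derives an independent RNG stream
from `(seed, kind, stream)`, so outputs are bit-reproducible and adding
generators never perturbs existing streams.

## Problem sizes and determinism

Recovery experiments in the tests and the acceptance script use 50–200
replicates per condition at 1000–2000 samples per transient, sizes at
which the median SRX-fraction error is comfortably inside ±0.02 while
the full suite stays fast. All stochastic tests fix seeds; the pipeline
report is byte-identical across runs for a fixed configuration.

## Known limitations

- Three-or-more exponential models and global fitting across salt
  conditions are out of scope; so are distance distributions from
  time-resolved FRET.
- The schemes cap at five states and do not model temperature dependence
  or Bayesian posteriors over rate constants.
- EM analysis starts from counts; image processing and 2D classification
  happen upstream in dedicated EM software.
- The correlation model's `E_IHM` is an assumption, and the FRET distances
  involved lie above the reliable 0.5–1.5 R₀ range, so distances are best
  read as relative, not absolute.
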
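# Methods

## The assay being modelled

A dSi-loaded aluminium-oxide particle (the "bead") sits in a shallow
observation chamber. Starved cells glide around it; a camera records
600 s at 1 frame/s. All spatial statistics are organised into three
concentric 112-μm rings (bins A–C) centred on the bead, covering a disc
of radius 336 μm (area π·0.336² ≈ 0.355 mm²). Tracks are tabular
(track id, frame, time, x, y in μm) or a TrackMate-style XML subset;
bead centre and radius must be supplied in the assay config, since they
are not recoverable from tracks alone.

## Bead gradient model

The bead is a continuous point source with total diffusive flux *i*
(measured colorimetrically; default 1.21×10⁻¹³ mol s⁻¹), solute
diffusivity D_c = 10⁻⁵ cm² s⁻¹ and load L = 1.40 nmol. Two steady-state
profiles are implemented and always labelled in output:

* `literal` (default): C(r) = i/(4π√r·D_c), r in cm, read as mol cm⁻³.
  This flat-chamber form (√r correcting the gradient shape in a shallow
  chamber) is dimensionally anomalous but reproduces the assay's ~5 μM
  edge concentration; it is retained as the description of record of the
  assay gradient.
* `spherical`: C(r) = i/(4π·D_c·r), the textbook 3-D point source.

Time to steady state is the diffusive scale d²/D_c for the field
diameter d (672 μm → ≈452 s), and the released fraction is min(1, i·t/L)
(≈5% over 600 s). Transient solutions and dissolution kinetics of the
adsorbed silicate are out of scope. Lengths in this module are cm to
match the units the constants are quoted in; helpers accept μm.

Known tension, surfaced rather than resolved: the printed per-particle
loadings imply ≈2,514 particles/mg where the direct count gives
2,640 ± 660, so `bead_loading` keeps particles-per-mg as an explicit
parameter; and no variant reproduces a ~100 μM surface concentration at
plausible bead radii (the literal form gives ~14 μM at r = 50 μm), so
surface values are reported but never asserted.

## Run-and-reverse walker

Each cell glides at speed s along its heading θ; θ diffuses with
intensity σ_θ (rad/√s); runs terminate as a Poisson process with hazard
λ_stop, and a stop reverses the heading with probability q (else the
heading is kept). Gradient information enters only through run length:
λ_stop = λ0·exp(−κu), where u ∈ [−1,1] is the cosine between the heading
and the up-gradient (inward radial) direction. κ > 0 prolongs
up-gradient runs (attractant), κ < 0 truncates them (repellent); turning
is never biased, matching the observation that orientation angles do not
differ between treatments. Chemokinesis: under starvation the speed is
s0·(1 + g/(1 + C/C_half)) with C the local dSi concentration and
C_half = 20 μM, i.e. a (1+g)-fold boost far from any source relaxing to
s0 as the cell nears saturating dSi. The arena wall and the bead surface
both reflect; integration uses dt = 0.1 s internally with output sampled
at the camera's 1-s interval so simulated step speeds carry the same
sampling bias as real tracking data; all draws come from one seeded
generator, making runs bit-reproducible.

For an unbiased walker the velocity autocorrelation is exponential with
rate 2qλ0 + σ_θ²/2, so the process is exactly a Taylor walker with
τ = 1/(2qλ0 + σ_θ²/2) and D = s²τ/2 — which is what makes the simulator
a ground-truth oracle for the fitting code.

Defaults (chosen once, to match the observed control population):
s0 = 2.3 μm/s and τ ≈ 4.7 s reproduce the control condition's measured
effective speed (λ/τ ≈ 2.29 μm/s) and decorrelation time; q = 0.8
(reversal-dominated gliding), σ_θ = 0.3 rad/√s, λ0 = 0.105 s⁻¹. The
attractant/repellent presets use κ = ±1.5, consistent with the ~3-fold
decorrelation-time increase measured in the dSi gradient; the
starved/replete presets differ by g = 1.5, giving the >2-fold speed
ratio seen under silicon starvation. The arena radius is 500 μm with 200
cells, which puts ~90 cells in the 336-μm observation disc — the
recorded movies' density — while letting cells cross the field boundary
as in a real well. κ, g and C_half are behavioural knobs for testing
estimators, not inferred properties of the organism.

What the simulator does *not* emulate: cell–cell interactions, EPS/raphe
mechanics, hydrodynamics, Si uptake (the gradient is static), pauses of
finite duration, heterogeneous per-cell speeds, and tracking artefacts
(broken tracks, localisation noise, missed detections). Estimator
validations on simulated data therefore demonstrate correctness of the
computational chain, not robustness to real tracking noise.

## RMS net displacement and Taylor fitting

Two estimators of the dispersal curve:

* `origin` (default, the description of record): each track's net
  displacement at elapsed time t is measured from its own first point,
  positions linearly interpolated; tracks shorter than t drop out.
* `all_lag` (opt-in): the mean squared displacement over every same-lag
  frame pair (overlapping windows) — far lower variance, serially
  correlated across lags; used for parameter-recovery validation.

The Taylor curve rms(t) = [2v²τ(t − τ(1 − e^(−t/τ)))]^0.5 is fitted by
bounded nonlinear least squares with residuals whitened by the predicted
sampling error of each point: SD(rms) ∝ rms, divided by √(contributing
tracks) and, for the all-lag estimator, √(T/lag) for the effective
number of independent windows. This weighting matters: unweighted, the
hundreds of late correlated points dominate and the optimizer runs onto
the degenerate pure-diffusion ridge (v → ∞, τ → 0 at fixed v²τ), which
is the global unweighted minimum for realistic noisy data.
Initialisation is deterministic (v0 from the first grid point's secant,
τ0 = 10 s, multi-start over τ0 ∈ {1, 5, 20, 60} s on a poor fit); a τ at
its upper bound (10⁴·T) marks the fit non-identifiable, which is what a
purely ballistic series produces. Validation conditions use a 2000-μm
arena: motility-parameter estimation assumes free dispersal, and the
500-μm assay arena visibly bends the late-time curve.

Derived parameters follow λ = vτ, D = v²τ/n and β = 4πRD. n defaults
to 2: re-deriving the control condition's diffusivity from its printed λ
and τ gives λ²/(2τ) = 12.23 (matching the printed 12.22 to rounding)
where n = 3 would give 8.15. β has no default bead radius — back-solving
published values gives R ≈ 53–62 μm depending on condition, so R must be
supplied and is echoed in every report. Whether the original analysis
interpolated positions or used frame-exact sampling is unknowable from
the text; we interpolate linearly.

## Per-bin metrics

Ring boundaries are half-open, lower-inclusive (ρ = 112 μm is bin B;
ρ = 336 μm is outside); positions on the bead count as bin A since cells
physically contact the bead. Snapshot metrics (counts, sum distance) are
evaluated at 60-s sample times with linear interpolation; step metrics
(sine angle, speed) attribute each step to the ring of its midpoint and
the window containing its midpoint time, so a boundary-crossing step
contributes to exactly one ring. Windows with fewer than two distinct
contributing tracks are missing — the single-track exclusion rule of the
original analysis. Count normalisation pools all counts of one treatment
within one ring (over time points and replicate series) as the Z
population, uses the population (ddof = 0) standard deviation, and
subtracts each series' Z at T = 0 so every series starts at exactly 0;
a constant population yields zeros with a warning. The sine angle of a
step is (ρ_from − ρ_to)/‖step‖ — the stated sign semantics (+ toward
the bead) admit more than one trigonometric realisation; this one is
bounded in [−1,1] by the triangle inequality and antisymmetric under
step reversal. The motile-fraction tolerance defaults to 1 μm rather
than literal position identity, which would misread localisation noise
as motility; the tolerance is part of the reported provenance.

`trend_slope` is deliberately plain OLS with the classical standard
error — a descriptive summary, not inference. The original study fitted
mixed models with AR-1 correlation structures precisely because these
series are serially correlated; those are out of scope here, and the
OLS standard errors should not be read as calibrated. Concretely: cell
positions mix across the field over hours, so consecutive 60-s samples
of a sum-distance series are strongly correlated and the classical SE
understates the slope's sampling variance several-fold; in a 20-seed
null suite, |slope| < 2·SE holds in only about half the runs (the
acceptance suite records this honestly as a failing calibration check).
The sine-angle null summary instead clusters by track (SE over per-track
means), which is calibrated because tracks are independent units.

## Pipeline and provenance

`run_experiment` drives simulate→analyze→report from one config mapping
(unknown keys are rejected by name). A scenario config simulates a
treatment arm and a blank-bead control arm (seed, seed+1); a tracks
config analyses recorded files. Reports contain one tidy CSV per metric,
Taylor fits and their comparison, the gradient profile, OLS trend
summaries, and a provenance block (full config echo, seed, version,
gradient variant, observation area). Given the same config, reruns are
byte-identical; nothing in a report depends on the clock.

## Sizes and runtimes

Defaults everywhere mirror the recorded assays: 600-s runs at 1 frame/s,
200 simulated cells, 60-s metric intervals, 30-s speed windows. The
validation suites use 100-cell populations for fitting checks and 20
seeds for null calibration; these sizes put every Monte-Carlo tolerance
(10% on v, 15% on D, 3 clustered SEs on sine angles) several estimated
standard errors away from its threshold under the measured estimator
spread, while a full test run stays in the tens of seconds.
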
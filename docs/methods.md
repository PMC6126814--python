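# Methods

## Circular run-and-tumble model

Bacteria swimming in quasi-2D near a surface experience hydrodynamic torques
that bend their runs into circular arcs.  The model treats each cell as
moving at constant tangential speed v on a circle of radius s with angular
velocity ψ = v/s, fully reorienting (heading redrawn uniformly on [0, 2π))
at exponentially distributed waiting times of rate λ_T.

Closed forms used throughout:

- orientational autocorrelation of uniform circular motion: ⟨ĉ(0)·ĉ(t)⟩ = cos(ψt);
- mean square displacement: ⟨r²⟩ = 2s²[1 − cos(ψt)], ballistic (v²t²) at short
  times and bounded by the squared diameter 4s²;
- population average over ψ ~ Exponential(λ), P(ψ) = λe^(−λψ):
  ∫cos(ψt)λe^(−λψ)dψ = λ²/(λ² + t²), a Lorentzian that never crosses zero;
- with tumbling, ACF(t) = e^(−λ_T t)·cos(ψt).  The derivation is elementary:
  a run survives to lag t with probability e^(−λ_T t); conditioned on survival
  the heading has rotated by ψt; after any tumble the expected projection is
  zero because reorientation is uniform.  Because this factorization assumes
  *complete* reorientation, the test suite gates the form against a
  Monte-Carlo ensemble of the simulator (2000 tracks, every lag within 3
  standard errors).  Partial reorientation would multiply the rate by
  (1 − ⟨cos θ_turn⟩) and is deliberately not modelled.

### Fitting

`fit_circular_rt` fits (ψ, λ_T) — or (λ, λ_T) in population mode — to the
empirical ACF by bounded least squares, weighting each lag by √(n_pairs) to
downweight noisy long lags, with 20 multistarts of ψ on [0, π/Δ] (the Nyquist
band of the lag grid).  v comes from the first MSD point as √MSD(Δ)/Δ
(ballistic short-time assumption; a 3-point quadratic-through-origin option
is provided for robustness), and s = v/ψ.  Empirical headings are chord
(displacement) directions: for exact circles the chord heading differs from
the instantaneous heading only by the constant offset ψΔ/2, which cancels in
heading *differences*, so the chord-based ACF of a circle is exactly
cos(ψkΔ).

## Simulator

`simulate_circular_rt` advances the heading by exact rotation ψ·dt per step
plus Gaussian rotational noise of variance 2·D_r·dt, and integrates the
position along the *arc* implied by the step's total heading change (not an
Euler step along the velocity), so noiseless trajectories lie exactly on the
circle of radius v/ψ — which keeps the analytic oracles sharp.  Tumble times
are drawn as exact exponential waiting times and recorded in the ground
truth; the reorientation is applied at the end of the frame containing the
event.  Per-cell speeds follow a Schulz (gamma) law with mean `speed_mean`
and relative width S = σ/v; ψ is either fixed or Exponential(λ), all
positive by default (one handedness, as surface swimming imposes), with a
flag for mixed signs.

Defaults mirror the standard tracking experiment: 10 fps, 100 s, ~1.3 mm²
field (box 1140 μm, periodic), 25 μm/s mean speed, S = 0.2, tumble rate
0.5 /s, rotational diffusion 0.06 rad²/s.  Positions are reported wrapped
into the periodic box; unwrapped coordinates live in the ground truth and
`TrackSet.unwrapped()` is the canonical input to MSD/ACF analyses of
simulated data (empirical data never wrap).

**Finite-duration tumbles** (`tumble_duration_mean > 0`, default off) exist
for detector-training realism: during a tumble (exponential duration, mean
0.15 s) the speed drops to 0.3·v and the heading diffuses with an extra
5 rad²/s of angular noise, reorienting by ~1.2 rad RMS over a mean tumble —
comparable to measured bacterial tumble angles.  No additional heading jump
is applied at the tumble end, so the kinematic anomaly is confined to the
tumble interval.  Instantaneous mode keeps the exact uniform reorientation
that the closed-form ACF assumes.

**Bulk swimmers for imaging** (`simulate_swimmers_3d`): directions are
isotropic on the 3D sphere (redrawn uniformly at tumbles) and only the
in-plane coordinates are rendered.  This matters: for 2D image analysis with
in-plane wavevectors q, the per-speed intermediate scattering function of
isotropic 3D swimmers is exactly sinc(qvτ), matching the DDM fit model,
whereas purely in-plane directions would give J₀(qvτ) and bias fitted
speeds.  The quasi-2D circular process remains the fixture for the tracking
modules.

## Tumble detection

The two-state HMM (swimming/tumbling) has bivariate Gaussian emissions over
(relative acceleration, |angular acceleration|).  The feature definitions —
the literature names them without formulas — are: relative acceleration =
frame-to-frame speed change per unit time normalized by the track-mean speed
(units 1/s, scale-free across slow and fast cells); angular acceleration =
frame-to-frame change of the wrapped angular velocity (rad/s²), used in
absolute value so left and right turns are equivalent.  Features align on
interior frames (an n-point track yields n − 3 feature frames).

Training is Baum–Welch on features pooled over the reference population
(hence order-invariant), initialized deterministically by splitting frames
at the 90th percentile of |angular acceleration|; convergence at log-
likelihood gain < 1e-6 per frame or 500 iterations; covariances floored at
1e-8.  States are labelled by emission means: tumbling = larger mean
|angular acceleration| (ties keep state 0 as swimming, logged).

Decoding is Viterbi, so tumble events are contiguous runs.  Because the
features are finite differences, a state change at frame k contaminates
features at k ± 1 and the raw Viterbi runs over-extend by about one frame
per side; each run is therefore eroded by the stencil radius (1 frame per
side, never below one frame).  With this calibration the decoded tumble bias
tracks the generative occupancy within ±0.02 at the default conditions, and
event counts within ~5%.

Population summaries filter tracks shorter than 10 s or slower than 5 μm/s
(non-motile cells); both thresholds are arguments.

## Diffusion and persistence

The CVE uses displacements subsampled at Δ = 10 s — beyond the rotational-
diffusion timescale, where trajectories are diffusive — so a 100-s track
contributes only ~10 displacements and single-track estimates are noisy and
occasionally negative; they are returned as-is (flagged) and meaningful in
the ensemble, where the estimator is unbiased and static localization noise
cancels through the adjacent-displacement covariance term.  Persistence is
τ = 2D/v₀²; for ideal run-and-tumble with uniform reorientation τ = 1/λ_T,
which the suite recovers within 15%.  With curvature, τ → λ_T/(λ_T² + ψ²),
so curved populations cap the attainable persistence — the reason the
synthetic mutant sweep keeps a small common ψ when it varies tumble rate.

## DDM

The image structure function g(q,τ) is the time-averaged power of Fourier-
differenced frames, radially averaged into annular bins one FFT pixel wide
(bins with < 8 modes dropped; q = 2π × spatial frequency in μm⁻¹; up to 200
start frames per lag, ~40 log-spaced lags).  The per-q model is
g = A(q)[1 − f] + B(q) with f = e^(−Dq²τ)[(1−α) + α·Ws(qv̄τ; Z)] and

    Ws(x; Z) = (Z+1)/(Zx) · sin(Z·atan(x/(Z+1))) / (1 + (x/(Z+1))²)^(Z/2),

the orientation-averaged swimming term for a Schulz speed distribution,
Z = (v̄/σ)² − 1; it reduces to sinc(x) as σ → 0 (checked numerically to
1e-3).  Fits are bounded least squares over (A, B, D, v̄, S, α) with σ
parameterized as S·v̄ (S ∈ [0.02, 0.95], enforcing the Schulz validity σ < v̄),
initialized from the long-τ plateau (A) and short-τ floor (B), multistarted
over v̄ ∈ {5, 15, 30} μm/s; a q bin is rejected when the best relative RMS
residual exceeds 15% and is excluded from band averages, logged.

Summaries average v̄ and σ over 0.5 ≤ q ≤ 2 μm⁻¹ (length scales 3–13 μm);
R = v(L1)/v(L2) uses the accepted bins nearest 2π/L1 and 2π/L2 without
interpolation (bins logged).  For pure diffusers α is unidentifiable (α → 1
with v̄ → 0 collapses onto the diffusive model), so only D is meaningful
there.  The 10–60 min acquisition window of repeated real experiments is a
config no-op for single synthetic stacks.

Known recovery characteristics at the rendered-movie scale: v̄ within ~2%,
σ biased low by ~15–20% (finite τ range and per-q noise), α within ±0.1
for a 50/50 mixture, R within ~2% of 1 for straight swimmers.

## DFM

Cells are segmented by Otsu threshold on the temporal-mean image (connected
regions ≥ 4 px; high-contrast fixtures make this reliable); the flicker
observable is each cell's integrated intensity (mean-subtracted, Hann-
windowed), and one-sided power spectra are averaged over cells.  The body
angular velocity is Ω = 2π·f_peak with f_peak the lowest-frequency local
maximum whose prominence above a median-filtered background exceeds both 5%
of the maximum excess and 8 robust standard deviations of the excess — the
SNR gate makes pure-noise spectra return "no peak" instead of a spurious Ω,
and taking the *lowest* qualifying peak ignores harmonics.  The virtual
microscope's wobble (intensity modulation 1 + depth·sin(2πft + φ_cell))
stands in for the image flicker of a wobbling body; frequencies at or above
Nyquist are rejected at render time.

Processivity is P = v/Ω in μm/rad (2πP per revolution); normalization to a
designated wild-type reference divides each of (v, Ω, P) by the reference
value.

## Virtual microscope

Cells render as Gaussian spots (σ = 0.6 μm default) at their wrapped
positions; phase mode uses constant per-cell intensity, dark-field mode the
wobble modulation above with a random per-cell phase; per-pixel Gaussian
read noise is added and intensities clip at zero.  Not emulated: defocus and
the 3D point-spread function, phase-contrast halos, cell shape and
orientation, photobleaching, and finite exposure blur.  Passing recovery
tests therefore validates the estimators' mathematics and their coupling,
not robustness to those optical artifacts.

## Problem sizes

Default experiment sizes were chosen as the smallest at which the ensemble
estimators are comfortably inside their tolerance bands: 1000–2000 tracks
for ACF/MSD recovery, 1000 × 100 s tracks for CVE, 150–300 cells for HMM
work, 2000-frame 256-px movies (200 cells) for DDM, 2000-frame 128-px
dark-field movies (40 cells) for DFM.

## Open design choices made here

- The empirical curvature distribution of real populations is not asserted;
  the simulator exposes both fixed-ψ and Exponential(λ) modes.
- DFM's flicker observable (integrated intensity) is validated only against
  the virtual microscope.
- R is computed from per-q fit values at the two nearest bins rather than a
  two-scale reanalysis.
- The ruler fit regresses per-mutant mean hook lengths (matching how such
  calibrations are reported); raw-measurement regression is a flag away.
  Mutants flagged as having uncontrolled hook length are excluded by
  default.
- The flagellar bundle rotation speed ω is out of scope: nothing here
  measures it.
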
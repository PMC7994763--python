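# Methods

## The generative model

The synthetic generator exists so that every analysis stage can be tested
against known ground truth; it is deliberately the *minimal* model that
produces the three regimes of interest — no effect (sham), single-pulse
phase reset, and progressive entrainment.

Each cortical source is a noisy phase oscillator

    φ(t + Δ) = φ(t) + 2π f₀ Δ + ε,      ε ~ N(0, σ² Δ)

with natural frequency f₀ (Hz) and phase-noise SD σ (rad/√s; default
1.5, giving a phase coherence time of order a second, typical of
resting alpha/beta rhythms).  A stimulation pulse applies the circular
vector-pull update

    φ ← φ + arg((1 − κ) + κ e^{i(ψ − φ)}),      ψ = 0

with coupling strength κ ∈ [0, 1].  For small κ this reduces to the
circle map φ ← φ + κ sin(ψ − φ); at κ = 1 it is an exact one-pulse phase
reset.  We chose the vector-pull form over the bare sine map because the
sine map does not fully collapse phase in one kick (a single κ = 1 sine
kick from uniform phase leaves across-trial PLF ≈ 0.44), whereas one
parameter should span partial entrainment through full reset.  The
pulse-target phase ψ is fixed at 0 in stimulus time: only its
*consistency* across trials is observable at the sensors.

Pulse updates propagate to remote sources (scaled by a gain, after a
conduction lag of ~10 ms) only when the remote natural frequency lies
within 3 Hz of the local one.  This encodes frequency-specific
large-scale coupling: a visual alpha oscillator recruits a remote alpha
partner, not a beta one, so topographic spread analyses have ground
truth.

Default sources: visual oscillator at Oz with f₀ = 10.5 Hz and a remote
occipito-parietal alpha partner (10 Hz), motor oscillator at C3 with
f₀ = 21 Hz and a remote right-motor beta partner (20 Hz), amplitudes
5 µV (3 µV remote), κ = 0.4.  With these values an 11 Hz train is inside
the visual oscillator's synchronisation region (detuning 0.5 Hz) while a
23 Hz train drives the motor oscillator from slightly outside
(detuning 2 Hz) — so visual stimulation shows textbook entrainment at
the drive frequency while motor locking concentrates near the
oscillator's own frequency; analyses of the motor condition should
therefore expect a beta-band, not exactly 23 Hz, peak.

Sensor signals are a Gaussian-leadfield projection (FWHM 60° of arc —
deliberately smooth, since the surface-Laplacian transform later
sharpens topographies) of a·cos φ for each source, plus:

* 1/f background noise (SD 5 µV, exponent 1);
* an optional pulse-locked evoked kernel — a damped 10 Hz sinusoid
  (decay 100 ms, latency 30 ms, amplitude 2 µV, centred at the vertex),
  identical in real and sham blocks, which deliberately produces the
  "spurious phase locking from repeated evoked components" confound so
  tests can exercise it; its per-pulse amplitude multiplier is a
  parameter (default constant — whether real evoked responses attenuate
  over a train is unknown, so the generator does not presume it);
* over the stimulated site only, a pulse artifact: an instantaneous
  spike decaying exponentially with τ = 2 ms and amplitude 10× the
  source, so it is essentially confined to the first ~8 ms that the
  interpolation stage excises.

What the generator does **not** emulate: realistic volume conduction
(no BEM head model), auditory/somatosensory co-stimulation beyond the
generic kernel, amplitude dynamics of the oscillators, non-stationary
background, eye/muscle artifacts, or continuous (non-epoched) sessions.
Tests passing on this data therefore demonstrate correctness of the
*measures and inference*, not robustness to every real-data nuisance.

## Preprocessing

Stage order is fixed and enforced by the driver: segment → earlobe
re-reference ((A1+A2)/2) → pulse-window interpolation → ICA decay
suppression → amplitude-based trial rejection → spherical-spline surface
Laplacian → downsampling.

* **Interpolation** replaces the samples in (onset, onset + w] with the
  line joining the onset sample to the first post-window sample;
  w = round(8 ms · fs) (40 samples at 5 kHz), with a 12 ms fallback for
  late artifacts.  Overlapping windows are an error, not silently
  merged.
* **ICA decay suppression** fits a seeded FastICA on the concatenated
  epochs.  Each component's trial-averaged waveform is z-scored against
  its own full-epoch mean/SD and summarised by max |z| within 0–100 ms
  after any pulse.  Because the maximum of ~50 z-scored samples exceeds
  1.65 for almost any component, that summary is then standardized
  *across components* and the 1.65 threshold applied to the result:
  removed components are those whose post-pulse extremeness is a
  1.65-sigma outlier among components.  This keeps the "extremely large
  amplitude" semantics, gives a ~5% one-sided null removal rate
  (verified by Monte-Carlo in the tests), and still removes an injected
  20× decay pattern with >90% residual-energy reduction.
* **Trial rejection** drops a trial iff any channel exceeds 200 µV
  absolute anywhere in [first pulse − 1 s, last pulse + 1 s].
* **Surface Laplacian (CSD)**: Perrin spherical-spline interpolation
  with spline flexibility m = 4, smoothing λ = 1e−5, 50 Legendre terms,
  head radius 92 mm; the bordered spline system is solved once per
  montage and applied as a linear operator, returning µV/m².  The
  operator annihilates constants (reference-free by construction).  With
  electrodes covering only the upper hemisphere, zonal harmonics are
  poorly constrained at the cap rim, so closed-form validation uses
  sectoral harmonics Y_l^l (azimuthal variation, fully sampled), where
  the estimate correlates > 0.99 with l(l+1)Y/R².
* **Downsampling** applies a zero-phase FIR low-pass (cutoff 0.4× the
  target rate, i.e. 400 Hz for 5 kHz → 1 kHz) before decimation — phase
  is the measurand, so the anti-alias filter must be zero-phase.

## Time–frequency analysis

Morlet wavelets with cycles constant m = 3 on a 3–45 Hz grid in 1 Hz
steps (the coarsest grid containing 5, 11 and 23 Hz exactly);
σ_t = m/2πf and σ_f = f/m, so σ_t σ_f = 1/2π at every frequency (the
Fourier uncertainty bound).  Amplitude is normalised so a unit cosine at
an analysis frequency has modulus 1.  Wavelet support is truncated at
±4σ_t (>99.99% of mass); samples whose support exceeds the epoch are
masked, never zero-padded — padding would fabricate phase.  The
temporal-leakage bound follows from the envelope: the one-sided Gaussian
mass beyond one period is the normal tail beyond 2π/m σ ≈ 1.8% for
m = 3, under the 5% bound used when interpreting post-train persistence.

## Phase-locking statistics

PLF is the modulus of the across-trial mean unit phasor; masked or
zero-amplitude samples propagate as undefined, never as zeros.  ZPLF =
N·PLF² removes the 1/√N small-sample bias (mean ZPLF ≈ 1 under uniform
phase for every N; the tests verify the mean is flat in N to Monte-Carlo
precision).  ZPLF_norm standardizes over the frequency axis per
(channel, time) for per-pulse profiles, or over time per (channel,
frequency) for individual-alpha analyses; zero-SD slices are masked with
a warning.

Per-pulse profiles average ZPLF_norm over ±0.5 cycles of each analysis
frequency around each pulse, at the stimulated electrode (C3 for motor,
Oz for visual; a neighbourhood mean is available by passing any other
channel or aggregating maps).  The baseline (ctrl) is the mean over −5
to −2 *stimulation-frequency* cycles before the first pulse — the
window stays in stimulation-frequency cycles even when the profile is
read at other frequencies.  Persistence is the longest criterion-true
run starting at the last pulse, in stimulation-frequency cycles; the
criterion defaults to the cluster-test significance mask, with a plain
ZPLF threshold available.  The individual alpha frequency is the 8–13 Hz
maximum of the trial-averaged pre-stimulus amplitude spectrum over
posterior channels, accepted only if it exceeds a log-log linear 1/f fit
(3–30 Hz, excluding 7–14 Hz) by 20%; ties resolve to the lower
frequency.

## Statistical inference

The cluster-permutation test thresholds the elementwise paired t-map at
two-tailed uncorrected p < 0.05 (df = n participants − 1), forms
clusters connected over ±1 time bin, ±1 frequency bin and
montage-adjacent channels at the same (f, t), scores clusters by summed
t, and builds the null from within-participant condition flips (sign
flips of paired differences; 500 by default, exhaustive enumeration with
a warning when 2^n ≤ n_perm).  Positive and negative clusters are tested
against their own signed nulls at the 97.5th percentile (two-tailed 5%);
permutation p uses the (1 + count)/(n_perm + 1) convention, counting
floating-point ties as exceedances so exhaustive p-values are exact.
Channel adjacency is a 0.5 rad great-circle threshold on the fitted unit
sphere — chosen because realistic 10/10 coordinates have nearest-
neighbour arcs of 0.29–0.44 rad, so each channel links to its immediate
ring (2–8 neighbours) without bridging across the cap.

Significant-electrode counts per (frequency, time) count each channel
once regardless of how many clusters cover it; frequency specificity is
assessed by an exact binomial test (minlike two-sided rule) of the
stimulation-frequency count against p₀ = 0.5 of the combined count, on
counts averaged over four stimulation cycles.  The per-electrode paired
indicator alternative can be built from the same count maps.  The pulse
battery is a one-way fixed-effects ANOVA over (ctrl, pulse 1..5) —
df = (5, 6(n−1)) — Dunnett's many-to-one comparisons against ctrl
(scipy's multivariate-t implementation, seeded; family-wise error
calibrated in the tests), and the Pearson correlation of phase locking
with pulse number over all (participant, pulse) points.

## Problem sizes and numerical choices

Simulation defaults mirror the emulated recordings: 63 scalp channels +
A1/A2, 5 kHz native rate, 30 trials, epochs from 2 s before the first
pulse to 3 s after the last, inter-train interval 10 ± 1.5 s.  The test
suite and examples run the same pipeline at reduced sizes chosen as the
smallest that keep every effect unambiguous: 500 Hz simulation rate
(the analysis band ends at 45 Hz), 6–10 trials per block, 8–14
synthetic participants, statistics matrices cropped to −0.5..1.5 s
around the first pulse at 10–20 ms resolution, and ICA disabled in
cohort-scale runs (the generator's τ = 2 ms artifact is fully excised by
the 8 ms interpolation; the ICA stage has its own dedicated tests).
The cohort stats window must include the ctrl baseline, so 5 Hz-train
analyses need the window extended to at least −1.1 s.

Degenerate inputs are masked with warnings rather than silently zeroed:
zero-variance t-map voxels, zero-SD standardization slices, empty
binomial counts, constant ANOVA tables and zero-variance correlations
all yield NaN.  Identical seeds give bit-identical TrialSets, maps and
manifest checksums (HDF5 is written without timestamps).

## Known limitations

The generator's phase dynamics are event-driven (instantaneous kicks),
not a continuously forced oscillator; persistence after the train
reflects pure phase diffusion, with no amplitude envelope or
re-synchronisation to an ongoing network.  The leadfield is spherical
and smooth, so topographic ground truth is coarse.  The binomial
construction treats electrode counts as independent trials, which real
spatial correlation violates; it is used, as intended, as a descriptive
frequency-specificity contrast rather than a calibrated test.  EDF/
BrainVision export is not provided; the HDF5 container is the on-disk
interchange format.
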
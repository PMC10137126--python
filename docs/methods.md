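# Methods

## The experimental model being emulated

The package simulates a two-stimulus temporal discrimination experiment.
Every trial contains a first and a second stimulus; all analysis epochs are
time-locked to the **second** stimulus (time zero), with the first stimulus
at −400 ms (the short-interval trials that carry the timing-prediction
manipulation). Two within-subject factors are crossed:

- **Modality attention (MA)** — whether the modality under analysis is the
  attended one (2 levels: attended, unattended);
- **Timing prediction (TP)** — the relation between the predicted and the
  actual onset moment of the second stimulus (3 levels: NTP no prediction,
  MTP matched, VTP violated).

Default geometry: 200 Hz sampling, epochs −1.0 s to +0.8 s, channels
O1/OZ/O2 (occipital, used for visual measures) and F1/FZ/F2 (frontal,
auditory measures), 27 subjects, 38 trials per cell (the midpoint of the
35–40 qualified trials the emulated protocol retains).

## Generative model

Each trial is the sum of three independently seeded parts.

**Evoked components** are Gaussian-windowed monophasic deflections
`A·exp(−(t−τ)²/2w²)` with per-trial amplitude and latency jitter. The
Gaussian is the minimal parameterization that reproduces window-mean
amplitudes; no claim is made about realistic waveform shape outside the
measurement windows. Defaults (visual scenario): first-stimulus N1 (−4 µV,
peak +170 ms after the first stimulus), second-stimulus N1 (−5 µV, peak
155 ms, width 20 ms) and N2 (peak 250 ms, width 30 ms). In attended cells
VTP shrinks the N1 to −3.5 µV and deepens the N2 to −3 µV; unattended cells
carry no TP differences and a globally smaller N1 (−3 µV), modeling
attentional enhancement.

**Oscillatory components** are fixed-frequency cosines whose per-trial phase
at the locking stimulus is drawn von Mises(µ, κ); κ = 0 gives uniform
phases (no locking) and the expected inter-trial resultant is I₁(κ)/I₀(κ).
The amplitude envelope is a boxcar with 20 ms Gaussian-cdf edges to avoid
spectral splatter. Defaults: a 6 Hz theta component locked to the second
stimulus (envelope 30–350 ms) whose κ carries the TP effect in attended
cells (2.0/2.0/0.7 for NTP/MTP/VTP; 1.0 everywhere unattended); a 10 Hz
alpha component locked to the first stimulus (attention effect on κ); a
non-phase-locked (κ = 0) 22 Hz beta burst at 200–400 ms whose amplitude is
reduced under attended VTP. Oscillation amplitudes (6 µV theta, 8 µV delta
in the auditory scenario) were sized so the measured band-window ITC spans
roughly 0.25–0.55 against the 1/f background — the range comparable
recordings show — rather than to any statistical outcome; at these levels
the single-trial spectral SNR, not the amplitude itself, determines how much
of the programmed κ contrast survives into measured ITC.

**Noise** is 1/f-shaped Gaussian noise (default exponent 1.0, broadband SD
10 µV per channel), synthesized by spectrally shaping white noise with a
unit-RMS-gain filter. No ocular or muscle artifacts and no cross-channel
correlation are simulated; channel "topography" is just per-component
channel gains. Consequently, passing tests demonstrate correctness of the
measurement and testing chain under the assumed signal model — they say
nothing about artifact robustness or realistic spatial structure.

**Behavior.** Per cell, correctness is Bernoulli and RT is a normal
distribution truncated at the 80 ms anticipation floor. Attended-cell
defaults use the emulated study's reported means (RT 292/442/607 ms and
accuracy 99.9/98.2/91.2 % for NTP/MTP/VTP in the visual task; the analogous
values in the auditory task), SD 60 ms.

**Randomness** is routed through `numpy.random.SeedSequence` streams named
by (seed, subject, cell, role, component). Adding a component or cell never
perturbs existing draws, which also gives the additivity property used in
tests (evoked-only + noise-only specs sum to the merged spec exactly).

## Preprocessing

- Low-pass: odd-length (Type I, hence exactly linear-phase) Hamming-window
  FIR, cutoff 40 Hz, transition width 10 Hz (≈ 67 taps at 200 Hz), applied
  forward–backward so component latencies are not shifted. DC gain is 1
  within 1e-3 and attenuation at 1.25 x cutoff exceeds 30 dB.
- Downsampling: integer factors only; anti-alias FIR at 80 % of the new
  Nyquist, then decimation with the offset chosen so the zero point stays
  exactly on a sample.
- Trial qualification: correct response and RT ≥ 80 ms. The 80 ms bound is
  read as an anticipation floor (responses launched before the stimulus
  could be discriminated are rejected); no upper RT cap is imposed.
- Baseline: window-mean subtraction per trial and channel; measures locked
  to the first stimulus use the 100 ms before it (−0.5 to −0.4 s), measures
  locked to the second use −0.1 to 0 s.
- Ocular-artifact removal is a pass-through hook: the simulation generates
  no such artifacts, and the hook marks where an ICA step would slot in.

## ERP measures

Component amplitude = mean over samples in a closed window of the
condition-average waveform (a sample belongs to the window if its timestamp
is within a quarter sample period of it), then an unweighted mean over the
component's three electrodes. Default windows — visual: first-stimulus N1
140–200 ms after the first stimulus (−260 to −200 ms in zero-point time;
stimulus-relative numbers are taken as primary since they are the
physiological definition), second N1 120–190 ms, N2 200–300 ms; auditory:
first P2 −230 to −180 ms, second P2 110–250 ms.

Note that the window mean of a condition average includes every
phase-locked signal in the window, not just the nominal component: the
theta component contributes `I₁(κ)/I₀(κ)`-weighted oscillatory structure to
the visual N1/N2 windows. The generator-ground-truth tests therefore check
window means against the full analytic expectation (jitter-widened
templates plus resultant-weighted oscillations), not against the bare
template.

## Time–frequency measures

Complex Morlet decomposition, frequencies on a 1 Hz grid, cycles rising
linearly from 3 (at and below 3 Hz) to 8 at 40 Hz. Wavelets are zero-mean,
unit-energy, truncated at ±3 temporal SD; the cycle count is capped so the
truncated wavelet fits the epoch (relevant at 1–2 Hz in a 1.8 s epoch).
Time bins closer than the wavelet half-support to an epoch edge are flagged
invalid; band-window means use valid bins only and raise an error when a
band-window is fully edge-contaminated, rather than silently returning
contaminated values.

ITC is the standard inter-trial phase coherence (modulus of the mean
unit-normalized coefficient; trials with exactly zero magnitude at a bin
are excluded from that bin, since their phase is undefined). ERSP is mean
power in dB relative to the mean baseline power per frequency over −0.5 to
−0.4 s (the 100 ms before the first stimulus). ITC maps are not
baseline-corrected. Band definitions: delta 1–3, theta 4–8 (the
methods-level definition is used where narrower informal definitions
exist), alpha 8–14, beta 15–30 Hz.

## Statistics

Two-way fully within-subject ANOVA on one value per subject x cell: each
effect is tested against its own subject x effect interaction mean square
with uncorrected df — with 27 subjects, df (1, 26) for MA and (2, 52) for
TP and the interaction. No sphericity correction is applied by default (an
optional Greenhouse–Geisser flag exists, applied to the TP main effect and
one-way tests). Effect size is partial eta squared
SS_eff/(SS_eff + SS_err); classical eta squared is reported alongside since
published "η²" values are often ambiguous between the two.

The gated scheme runs the interaction test first at α = 0.05 (the
conventional level; the emulated procedure never states the gate's α).
If significant: one-way repeated ANOVA of TP within each MA level, and
Bonferroni-corrected paired t contrasts (p_adj = min(1, 3p) for the three
TP pairs) where the simple effect is significant. Otherwise: the two main
effects, with TP pairwise contrasts following a significant TP main effect.
Bonferroni correction is applied within each family of pairwise contrasts,
not across measures. Degenerate zero-variance contrasts report p = 1 (and
F = 0 for all-identical tables) so batch simulations stay total; sums of
squares below a rounding-dust floor (1e-24 relative to the squared data
scale) are treated as exactly zero for the same reason.

## Calibration experiments and problem sizes

- *Pattern recovery*: repeated runs of the visual scenario at its default
  size (27 subjects, 38 trials/cell), restricted to the occipital channels
  and the theta-band decomposition that the tested measure (200–300 ms
  theta ITC) needs; each run applies the gated scheme and scores whether
  the attended-only pattern was recovered (interaction significant, TP
  simple effect significant in attended and not in unattended). Note the
  score's ceiling is set by the unattended false-positive rate (~5 %), not
  by power.
- *Type-I control*: the gated procedure on measure-level null tables
  (subject random intercept plus per-trial noise averaged over 20
  trials/cell, 12 subjects, 2000 datasets); the rate of datasets with any
  significant final pairwise claim is compared to α + 2 SE. The null is
  simulated at the measure level because this experiment tests the
  statistical procedure; the signal chain contributes nothing to it.

## Numerical and design choices

- Epoch container: a directory with JSON metadata, a little-endian float
  blob in trial-major order, and a CSV trial table — chosen over an opaque
  binary monolith for inspectability. The blob preserves the in-memory
  dtype (float32 or float64) so round trips are bit-exact.
- Time is stored as (sampling rate, zero-point index), never per-sample
  floats, so grid uniformity holds by construction and exactly one sample
  sits at time zero (validated).
- Window endpoints are inclusive with a quarter-sample tolerance;
  tie-breaks at sample boundaries are therefore deterministic.
- The ITC/ERSP implementations are vectorized; the test suite checks them
  to 1e-10 against naive per-trial loops, and the ANOVA against an
  independent brute-force sums-of-squares oracle (and against pingouin).

## Known limitations

- No subject-level random effects in the generator: subjects differ only
  through sampling noise, so between-subject variance in measures is
  estimation noise, not trait variance. F statistics on simulated data are
  correspondingly larger than field data would give at the same κ/amplitude
  contrasts.
- Single-channel-gain "topography"; no volume conduction, reference
  effects, or channel covariance.
- The Morlet backend is the only decomposition (by design); no multitaper
  or Hilbert alternatives, no cluster-based permutation statistics over
  full maps, no cross-frequency coupling.
- At 1–2 Hz the capped wavelets have coarse spectral resolution and most of
  the epoch is edge-flagged; delta-band windows are averaged over the few
  valid low-frequency bins (mostly 3 Hz), which is reported honestly by the
  validity machinery rather than hidden.
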
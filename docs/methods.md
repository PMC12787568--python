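# Methods

This note documents the models, the numerical choices, and what the
synthetic test bed does and does not demonstrate.

## Problem setting

A triaxial MEMS accelerometer (±16 g) is taped to the running-prosthesis
socket or foot pylon and records at 12.5 Hz for weeks. The goal is to label
every moment of the recording as Stop, Walk, Jog or Sprint and to count the
strides (full gait cycles of the prosthetic limb, i.e. one prosthesis
contact each) accumulated per activity. Because sensor placement varies
with socket geometry, raw device axes are remapped to an anatomical frame
(anterior–posterior, caudal–cranial, medio-lateral) by a per-athlete
permutation-with-sign mounting configuration; residual tilt of a few
degrees (foot-pylon mounting) is not corrected, consistent with the
feature set below being insensitive to it.

At 12.5 Hz individual gait events cannot be resolved reliably — elite
sprint stride rates reach 2 Hz with harmonics beyond the 6.25 Hz Nyquist
frequency — so both algorithms work on short-time statistics rather than
event detection, and stride counts come from cadence × time rather than
peak finding.

## Features

Windows are 48 frames (~3.8 s) advancing by 24 (~1.9 s, the labelling
resolution). The window length is fixed at twice the step; this half
overlap is what lets each window label one 24-frame block (below).

* `cc_max`: max |CC| in the window, in g. The absolute value matters: at
  rest the CC axis reads +1 g (gravity), and an inverted mounting would
  read −1 g; a signed maximum would also sit below the gravity line for
  athletes whose impacts are mostly negative-going.
* `l_ap`: the mean-CWT low-frequency peak. For each analysis frequency
  `f` in a linear grid (0.1 to 6.25 Hz in 0.05 Hz steps, 124 bins, 19 of
  them at or below 1 Hz), the complex Morlet wavelet `cmor1.0-0.5`
  (bandwidth B = 1.0, centre frequency C = 0.5 cycles/sample,
  `psi(t) = (pi B)^(-1/2) exp(-t^2/B) exp(j 2 pi C t)`) is scaled so its
  centre frequency maps to `f` (`a = C·f_s/f`), the transform modulus is
  averaged over all 48 translations in the window, and `l_ap` is the
  largest mean modulus at frequencies in (0, 1] Hz.

The mean spectrum of a locomotion window shows two peaks — one below 1 Hz
(slow propulsion/speed-fluctuation content plus the nonzero local mean of
an impact train) and one at 1–4 Hz (the stride fundamental) — and the
low-frequency peak grows essentially linearly with movement vigour, which
is what makes it a monotone intensity feature even when the stride
fundamental itself (jogging ≈ 1.3 Hz, sprinting ≈ 2 Hz) lies above the
1 Hz band edge.

### CWT evaluation

Two numerical decisions deviate from what a PyWavelets one-liner would do,
both verified empirically during development:

1. **Normalization is 1/a (amplitude-true), not 1/sqrt(a).** Under the
   L2-preserving 1/sqrt(a) convention the mean-modulus spectrum of a pure
   tone in a 48-sample window peaks *below* the tone (a 2 Hz tone peaks at
   1.85 Hz on this grid) because the sqrt(a) factor tilts the spectrum
   towards low frequencies. With 1/a the peak lands exactly on the tone
   for every grid frequency tested, so "the amplitude of the peak in the
   0–1 Hz band" is a well-defined, amplitude-proportional quantity. The
   absolute scale of `l_ap` (hence of thresholds T2/T3) depends on this
   convention; the time-domain threshold T1 does not.
2. **The transform is evaluated as an exact Riemann sum**, `W(a,b) =
   (1/a) Σ_n x[n] psi*((n−b)/a)` with the signal taken as zero outside the
   window, vectorized as one precomputed 48×48 complex matrix per scale
   (~4.5 MB for the default grid, cached) and applied to all windows of a
   signal with a single tensor contraction. Library CWT routines that
   convolve with an integrated-wavelet table leave boundary artifacts of
   several percent on windows this short when the wavelet has a nonzero
   mean (cmor1.0-0.5 has `psî(0) ≈ 0.085`), concentrated above ~1 Hz
   where the discrete filter becomes shorter than the window. The test
   suite checks the implementation against an independent brute-force
   Riemann sum at every grid frequency ≥ 0.2 Hz (1% tolerance) and
   against `pywt.cwt` within the ≤ 1 Hz band actually used by the
   classifier (5% tolerance covering the quadrature-order difference).

Zero padding outside the window is the boundary rule; windows are short
and treated as self-contained.

## Threshold calibration

Per activity, the window features of the training intervals are pooled and
summarized by Tukey boxplot whiskers: quartiles by linear interpolation
between order statistics, fences at 1.5 IQR, whiskers the most extreme
data within the fences. A threshold between two adjacent-intensity
activities is the midpoint of the facing whiskers (upper whisker of the
lower-intensity activity, lower whisker of the higher). When the whiskers
overlap the calibration warns — the feature pair no longer separates those
activities for this athlete — but still returns the midpoint rather than
failing, since a long-term run with a slightly degraded threshold is more
useful than none.

T1 uses `cc_max` (Stop vs Walk); T2 and T3 use `l_ap` (Walk vs Jog, Jog vs
Sprint). Athletes without Sprint data (triathletes) get no T3 and the
classifier simply never emits Sprint. Ties at a threshold go to the
lower-intensity class.

Features are extracted per motion interval, so no training window
straddles two activities; every labelled interval type is long enough for
at least one window (Stop ≥ 20 s, Walk/Jog 10–15 strides, Sprint from
standstill to peak speed).

## Cadence calibration

Each labelled interval gives `cadence = strides / (L/(f_s·60))` in
strides/min. Within a training set the per-interval cadences of one
activity are combined by their arithmetic mean (default); a pooled
variant — total strides over total time, which weights long intervals more
— is available (`cadence_aggregation="pooled"`) and agrees with the mean
to well under 1% whenever the athlete's cadence is stable, which is the
regime in which cadence-based counting is valid at all (human walking
cadence varies by ≲ 2% within a subject).

## Stratified Monte-Carlo cross-validation

50 iterations; each draws, without replacement per activity, 4 Stop +
4 Walk + 4 Jog + 2 Sprint intervals into training (from sessions holding
8/8/8/5). Train and test signals are rebuilt by concatenating the chosen
intervals in the fixed order Stop, Walk, Jog, Sprint (chronological within
a block). Because concatenation creates physically impossible step
transitions at block boundaries, the first and last interval of every test
block is duplicated at the block edge and flagged `ignore`: those frames
make the transitions land on sacrificial copies but are excluded from all
metrics and stride totals.

The final calibration is the arithmetic mean of the 50 per-iteration
thresholds and cadences. A single seeded NumPy generator drives the
sampling; the same seed reproduces the whole result bit for bit.

Three error estimates come out of the same run:

* **Classification**: per-frame gold vs predicted labels, pooled over all
  iterations' scored test frames; one-vs-all precision/recall/F1 per
  class, macro and support-weighted averages, accuracy, confusion matrix
  (scikit-learn under the module surface; an exhaustive counting loop
  serves as the test oracle). Undefined per-class metrics (zero
  denominators) are reported as 0 with an explicit flag.
* **Stride counting** (counter in isolation): detected strides =
  iteration cadence × gold-labelled durations; relative error per activity
  on totals summed over all iterations, so each interval contributes in
  proportion to its length.
* **Overall workflow**: as above but with durations taken from the frames
  the *detector* assigned to each activity, so transition mislabelling
  propagates into the count.

Inter-subject metrics concatenate the raw gold/predicted arrays of all
athletes into one pair before scoring (a micro average); they are not
averages of per-athlete metrics.

## Long-term application

The evaluation array assigns window k's label to its first 24-frame half;
the last window also labels its second half and any trailing frames
(< 24) inherit the final label, so labels tile the signal exactly with
zero latency. No post-hoc smoothing is applied. Maximal constant-label
runs become motion intervals with absolute timestamps; intervals are split
at local midnight for the daily report. A calendar day counts as a *day of
use* when it contains ≥ 60 s of non-Stop activity (configurable — the
operational definition of "meaningful use" is a reporting choice, not a
property of the signal); per-day stride means are taken over days of use
only. Stride counts are carried as reals and rounded only in reports.

## The synthetic test bed

Real recordings of this population are privacy-restricted, so the test bed
is a parametric gait generator (`prosport.synthetic`). Per stride it
places one raised-cosine-shaped impact (`sin^4`, i.e. mean 3/8 + a
fundamental at the stride frequency + one harmonic — band-limited, so a
120 strides/min sprint at 12.5 Hz stays below Nyquist) on the CC axis atop
the +1 g gravity offset, and the same train plus a 0.5 Hz
propulsion/sway oscillation on the AP axis, with white Gaussian noise per
axis and a linear half-to-full amplitude ramp over the first 2 s of every
sprint (constant cadence, so gold stride counts stay integral). Segment
durations snap to whole stride counts; the gold count equals
`round(cadence × duration)` and is recoverable from the noiseless
waveform by peak counting, which the tests use as an independent oracle.

Default conditions: cadences 53/80/120 strides/min (Walk/Jog/Sprint,
typical elite running-prosthesis values); AP amplitudes 0.55/1.2/3.5 g and
CC impact amplitudes 0.5/2.2/4.5 g, chosen once so that the two features
separate adjacent activities with ≥ ~35% margins at noise SDs of
0.02–0.12 g and so the Stop/Walk threshold lands near 1.2–1.3 g; the
default short session holds 8 Stop (20–30 s), 8 Walk and 8 Jog (10–15
strides) and 5 Sprint (16–24 strides) intervals in shuffled order, and a
triathlon variant omits Sprint.

What passing on this test bed shows: the whole chain — windowing,
features, whisker thresholds, MCCV bookkeeping, classification, counting —
is internally correct, recovers known parameters (cadences to < 0.5%,
thresholds stable to a few 0.01 g across iterations), and achieves the
intended error regime (≥ 98% pooled held-out accuracy, ≤ 1% per-activity
stride error on gold spans) when the features genuinely separate the
activities. What it does not show: that real prosthetic-gait signals are
this separable. The generator has stationary cadence and amplitude within
an interval, Gaussian noise, and no unmodelled activities; real sessions
contain amplitude drift, surface changes, and atypical movements that land
on whichever class the tree assigns them. Separability on real data must
be checked per athlete — the overlap warning during calibration is the
built-in guard.

## Known limitations

* Subject-specific calibration is required; no pooled/inter-subject
  thresholds are provided (the inter-subject pooling here evaluates, it
  does not calibrate).
* The classifier is a fixed-order tree over two features; activities
  outside {Stop, Walk, Jog, Sprint} are absorbed into the nearest class.
* Stride counting assumes stable within-activity cadence; interval-level
  cadence drift biases counts proportionally.
* Timestamps assume uniform sampling from `t0`; logger clock drift over
  multi-week recordings is not modelled.
* The 24-frame labelling block at 12.5 Hz is 1.92 s, reported nominally
  as ~2 s resolution.
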
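# Methods

This note documents the models, conventions and numerical choices behind
`eegdfc`, in the order the pipeline applies them, together with the design
decisions that were genuinely open and the limits of what the synthetic
studies demonstrate.

## The dynamic connectivity model

Functional connectivity between two EEG channels is usually summarized by a
single static number per recording. `eegdfc` instead treats amplitude
coupling as a time series. For one frequency band, let `a_i(t)` be the
analytic signal (Hilbert construction) of channel *i*'s band-limited trace
and `E_i(t) = |a_i(t)|` its envelope. After normalizing each envelope over
the retained span to `Ê_i(t)`, the instantaneous amplitude correlation is
the per-sample Hadamard product

    IAC_ij(t) = Ê_i(t) · Ê_j(t),

one symmetric adjacency matrix per temporal sample — 30,000 matrices for a
60 s recording at 500 Hz. Its per-pair time average is the familiar static
amplitude-envelope correlation; the dynamic information lives in how the
products fluctuate around that average.

**Envelope normalization.** The normalization of `Ê` is z-scoring over the
retained span (per channel). This is a deliberate choice among plausible
conventions (division by the mean, unit norm): with z-scoring the time mean
of `IAC_ij` is *exactly* the Pearson correlation of the two envelopes, which
gives the whole dynamic metric an analytic oracle that the test suite
checks to 1e-10. The alternatives remain switchable
(`normalization="mean"`/`"none"`).

**Leakage correction.** Volume conduction mixes one source into several
electrodes instantaneously, inflating zero-lag envelope correlation. Before
envelope extraction, each ordered pair is orthogonalized per sample:

    y⊥x(t) = imag( y(t) · conj(x(t)) / |x(t)| ),

the component of `y` with zero phase lag to `x` is discarded and
`|y⊥x(t)|` is the leakage-corrected envelope. The operation is directional,
so both directions are computed and the two per-sample products averaged —
this keeps the tensor exactly symmetric. Orthogonalization is applied per
band on the analytic signals (time-resolved), not as a single static
regression, because a per-sample metric needs per-sample correction.

Two numerical edge cases are defined explicitly. Near-zero denominators
`|x(t)|` are floored at 1e-12 times the median magnitude. A channel that is
*exactly* collinear with the reference leaves an identically-zero residual
whose envelope cannot be z-scored; inside the IAC computation such a
residual contributes zero to the pair product (a fully leakage-explained
channel has no residual amplitude dynamics), while the public
`normalize_envelope` keeps its strict zero-variance error.

A measured property worth knowing: for *independent* narrowband signals,
the per-sample orthogonalized envelope `|y⊥x| = |y|·|sin Δφ(t)|` carries
the fast `|sin|` factor, so its correlation with the uncorrected envelope
is about 0.6–0.8, not ≈1. That is intrinsic to per-sample (unsmoothed)
correction, not an implementation artifact; windowed-envelope methods hide
it by averaging.

**Edge handling.** Forward-backward FIR transients contaminate roughly one
filter length at each end. The `trim` parameter drops that many samples per
end before normalization and statistics. The default is `trim=0`, which
preserves the one-matrix-per-sample count of the recording; the tradeoff is
recorded in the run manifest either way.

## Average strength and its descriptors

At each sample, node strength is the *mean* (not sum) of a channel's
connectivity to the other channels — scale-free in channel count — and the
global average strength `aS(t)` is the grand mean, equivalently the mean of
the upper-triangle entries. The aS series is summarized by four
moment-based descriptors: mean μ, standard deviation σ, skewness φ and
kurtosis κ (level, variability, asymmetry, tailedness of connectivity
fluctuations). Estimators are plain population moments (n denominators); at
the series lengths involved (thousands of samples) bias corrections are
immaterial. Kurtosis is reported in the Pearson convention (Gaussian = 3)
by default with the excess value carried alongside; the convention is named
in the output metadata. Although the group-level literature sometimes calls
these "cumulants", σ is a standard deviation and κ a standardized moment —
the implementation follows that operational definition rather than formal
cumulant algebra. A zero-variance series yields NaN φ/κ with a
`moments_defined` flag; never a silent zero.

## Preprocessing

Filters are linear-phase FIR designs, Hamming window, order 500 (501 taps):
a 0.5–98 Hz broadband pass, a 48–52 Hz band-stop for power-line
interference, and one band-pass per canonical band (delta 0.5–4, theta
4–8, alpha 8–13, beta 13–30, gamma 30–98 Hz; the open-ended gamma band is
closed at the broadband edge, and capped below Nyquist for low sampling
rates). Bands are extracted from the broadband-filtered signal.

Application is zero-phase (forward–backward): per-sample connectivity must
not see relative delays between channels. It is implemented as one FFT
convolution with the composite kernel `h*reverse(h)` after odd-reflection
edge padding — identical to direct-form forward–backward filtering away
from the edges (verified against `scipy.signal.filtfilt` in the tests) and
much faster for 501-tap kernels, which matters when thousands of synthetic
subjects are filtered in the replicated-cohort studies. The effective
magnitude response is the squared design response; at order 500 the design
transition width is ≈1.6 Hz at 500 Hz sampling, so the delta band's
geometric-center gain stays within −1 dB single-pass while the 0.5 Hz
broadband edge necessarily leaves DC only partially attenuated.

No re-referencing is applied (recordings are used as referenced), and
artifact removal is out of scope: the synthetic data are artifact-free by
construction.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
not biophysics. Per band and channel:

* **Carrier**: white noise filtered to the band, then normalized to unit
  instantaneous amplitude (cosine of its Hilbert phase) and re-filtered;
  two normalize–filter passes leave a phase-randomized, essentially
  band-limited carrier whose intrinsic envelope is nearly flat. This keeps
  the broadband-within-band character of resting EEG while making the
  *imposed* envelope the dominant measured envelope — without the
  flattening, carrier-intrinsic envelope noise caps measurable coupling
  well below 1 even when channels share an identical modulator.
* **Envelope**: `E_ch = √(1−c)·ε_ch + √c·m`, with `m` a shared and `ε_ch`
  independent positive processes (rectified, < 1 Hz low-pass-filtered
  Gaussian noise, mean-normalized). The coupling `c ∈ [0,1]` is the
  fraction of envelope variance shared across channels; measured envelope
  correlation comes out ≈ 0.85·c (the attenuation is residual carrier
  noise). The modulators are generated with several-time-constant burn-in
  margins that are trimmed after filtering — without that, filter edge
  transients appear as a spurious *shared* envelope component across
  channels.
* **Bursts**: Poisson-timed 250 ms raised-cosine gain bumps of height
  `burst_gain` multiply the shared modulator, steering the skewness of
  connectivity fluctuations upward.
* **Mixing**: optional instantaneous leakage `(1−s)·I + s·M` with `M` a
  fixed symmetric nonnegative row-normalized random matrix shared by a
  cohort (electrode geometry is deliberately not modeled; only the
  existence of zero-lag leakage matters for exercising orthogonalization).
* **Noise**: white Gaussian sensor noise, `noise_sd`.

Defaults describe a plausible resting-state cohort member: 31 channels
(the standard 10-20 montage list), 500 Hz, 60 s, unit band amplitudes,
coupling 0.3 in every band, burst rate 0.2 /s with gain 2, no mixing,
noise SD 0.05. Cohort generation derives per-subject seeds from the cohort
seed (`numpy` seed sequences), so cohorts are bit-reproducible. The
optional dose covariate (chlorpromazine-equivalent-like, truncated normal
per group) is drawn *independently* of the dynamics, so the covariate
screen's null behavior is itself testable.

What the generator does **not** emulate: 1/f spectra, nonstationary band
power, cross-frequency coupling, realistic electrode geometry or artifact
topographies. Passing tests therefore demonstrate the pipeline's internal
correctness and its sensitivity/calibration under the stated statistical
structure — not performance on clinical EEG.

## Group statistics

Contrasts are two-sided Mann-Whitney U tests of each patient group against
the control group, per band and descriptor. `U` counts pairs `a > b` plus
half-ties (the convention under which fully separated samples with smaller
`a` give `U = 0`); p-values are exact (full null distribution) for
`n1+n2 ≤ 20` without ties and tie-corrected normal approximations
otherwise. The effect size is `r = |Z|/√(n1+n2)` with `Z` the
tie-corrected normal approximation of `U` — the standard Mann-Whitney
effect size, fixed here because published usage rarely defines it.
Multiple testing is controlled by Benjamini–Hochberg FDR within one
*family per contrast* (the 5 bands × 4 descriptors = 20 tests of one
patient-vs-control comparison); a global family across contrasts is
available by configuration, and the chosen family is recorded in the
output. Significance is annotated below 0.05, "tendency" between 0.05
and 0.1. The dose screen is a Pearson correlation of each band ×
descriptor metric against the per-subject dose, p from the t-distribution,
computed per patient group when at least three dosed subjects are present.

## Replicated-cohort studies and problem sizes

`eegdfc.simstudies` packages three experiments, each over independent
replicate cohorts of 20 vs 20 subjects at a reduced per-subject scale of
12 channels, 250 Hz, 12 s — small enough to afford hundreds of cohorts on
one CPU, large enough (3000 samples, 66 pairs) for stable descriptor
estimates:

* **Coupling power** — groups differ only in beta-band coupling (0.2 vs
  0.5): fraction of cohorts whose FDR-corrected beta aS μ comparison is
  significant.
* **Burst direction** — groups differ only in burst gain (1 vs 3): fraction
  of cohorts where the burstier group has the larger median aS φ.
* **Null calibration** — identically generated groups: fraction of cohorts
  with *any* FDR-significant result among the 20 family tests.

The full 31-channel, 500 Hz, 60 s scale is exercised by the structural and
oracle checks (matrix count, static-AEC equality, leakage suppression).

## Known limitations

* Synthetic effect sizes are free parameters; nothing calibrates them to
  clinical effect magnitudes.
* The per-sample orthogonalization attenuates genuine coupling as well as
  leakage (envelope fidelity ≈ 0.6–0.8 for independent signals); group
  *contrasts* survive, absolute aS levels are convention-dependent.
* EDF files are read (via MNE) but not written; synthetic cohorts are
  stored as delimited matrices with JSON sidecars plus a manifest.
* Recordings are analyzed as referenced; no montage handling.
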
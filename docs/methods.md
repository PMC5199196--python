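# Methods

This note records the models, conventions, and numerical choices behind
`nmlock`, and what the synthetic test beds do and do not establish about
real recordings.

## Signals and phase conventions

All signals are uniformly sampled, single-channel, real-valued
(`TimeSeries`). Instantaneous phase (`PhaseSeries`) is wrapped to
(−π, π] with the analytic-signal convention: phase 0 at the waveform
peak of a cosine, ±π at the trough, increasing with time. All module
outputs respect this wrapping; `wrap_phase` maps −π to +π so the
interval is half-open.

## Filtering

The default band-pass is a least-squares linear-phase FIR filter whose
order follows the rule **order = 3·fs/f_low** (rounded to the nearest
even integer so the tap count is odd), applied forward and backward
(`scipy.signal.filtfilt`) for zero phase distortion. Transition bands
are 15% of each cutoff. This reproduces the standard EEG/LFP protocol
(the EEGLAB `eegfilt` + `filtfilt` chain) that most published
phase-phase analyses used. Passband ripple of the forward-backward
response is ≈1% — amplitudes through the passband are preserved to about
that level, not exactly.

The order rule makes the filter long (751 taps for a 4 Hz low cutoff at
1 kHz), so short epochs cannot be filtered directly: `bandpass` raises
`EpochTooShortError` rather than silently truncating, and the intended
workflow is *filter the whole session, drop 0.5 s at each end (edge
transients), then cut epochs from the phase series*. All built-in
scenarios follow it.

Alternative families — 4th-order Butterworth and Bessel (forward-
backward), and a complex-Morlet convolution — sit behind
`bandpass(..., method=...)` as robustness checks. Conclusions should not
depend on the family; only the FIR path is validated quantitatively.

Band presets: theta 4–12 Hz (4–20 Hz broad preset for asymmetric real
waveforms), slow/middle/fast gamma 30–50/50–90/90–150 Hz.

## Phase extraction

`hilbert_phase` takes the argument of the Hilbert analytic signal and
also returns the amplitude envelope. `waveform_theta_phase` is the
interpolation alternative for asymmetric waves: ascending zero-crossing,
peak, descending zero-crossing, and trough are detected per cycle on the
4–20 Hz filtered trace (extrema optionally refined on a lightly smoothed
raw copy), assigned anchor phases −π/2, 0, π/2, π, and phase is linear
between anchors. The anchor assignment matches the Hilbert convention so
the two methods agree on a sinusoid; on an asymmetric wave the
interpolated phase advances faster on the short flank, by design.

## The coupling statistic and its biases

R_n:m is the mean resultant length of Δφ_nm = n·φ_γ − m·φ_θ. Exact
properties used as test oracles: R is rotation-invariant (adding a
constant to all Δφ changes nothing); R over concatenated epochs equals R
over the pooled sample multiset; for N i.i.d. uniform phases
E[R] ≈ (√π/2)·N^(−1/2). The latter is the *small-sample bias*: chance R
depends on the effective number of independent samples, which for
filtered signals is set by the filter bandwidth, not the sample count.
Two practical consequences, both reproduced by the `whitenoise_bias` and
`plot_significance` scenarios:

* chance R falls with epoch length (medians over 0.3/1/10/100 s epochs
  are strictly decreasing), so R values from different epoch lengths are
  incomparable;
* narrower filters inflate chance R (the slow band dominates, since its
  phase enters multiplied by m).

PPC (pairwise phase consistency) is computed by the closed form
(k·R²−1)/(k−1), identical to the O(k²) mean pairwise cosine; it is
bias-free in expectation but still assumes independent samples, so
subsampling (random with a seed, or regular with a spacing of at least
one fast-band cycle) is exposed on the estimator.

Phase-phase plots are 120×120 joint histograms on half-open uniform bins
over (−π, π] (+π folds into the last bin), smoothed with a σ = 10-bin
Gaussian kernel that wraps circularly on both axes (phases are circular;
boundary handling is otherwise arbitrary). `count_stripes` recovers the
number of diagonal stripes as the m ∈ 1..25 maximizing the
histogram-weighted resultant of φ_γ − m·φ_θ at bin centers, ties toward
smaller m.

## Surrogates and inference

All surrogate methods keep the theta phase intact and replace gamma with
a relocation/permutation of recorded gamma phases, so the gamma marginal
is preserved exactly:

* **time shift** — window displaced by a uniform integer lag of 1–200 ms
  (forward by default; a `symmetric` flag enables ±);
* **random permutation** — contiguous window at a uniform random
  position in the session (the exact original window is excluded;
  overlap is allowed);
* **phase scrambling** — timestamps shuffled, destroying continuity.
  Scrambling removes the filter-induced dependence, so its chance values
  collapse to the independent-uniform level and comparisons against it
  are false positives by construction.

Chance distributions: *single-run* (one R per realization — matched to
the original statistic, hence calibrated) and *pooled* (one R on the
union of n_runs realizations' Δφ — equivalent to a longer epoch, hence
a deflated chance level). Per-run randomness derives deterministically
from (seed, run index), so distributions are reproducible and runs
independent.

`test_rnm` is a one-tailed two-sample t-test of original R values
exceeding surrogate values, with the original's percentile in the
surrogate distribution reported alongside; degenerate (zero-variance)
comparisons are flagged instead of returning a p-value. The calibration
scenario (`pvalue_uniformity`) verifies that p-values are uniform under
the null. Its design cuts the original and surrogate groups from
disjoint, gap-separated session segments: the two-sample t-test assumes
independent groups, and overlapping windows correlate the group means
and make the test conservative.

Bin-wise plot testing (`phase_phase_significance`) computes, per bin,
z = (original − surrogate mean)/surrogate SD on the smoothed counts,
upper-tail normal p, then Holm-Bonferroni (or Benjamini-Hochberg FDR)
jointly over all 14,400 bins; an empirical-rank mode is available
(resolution 1/(n_runs+1)). Smoothed counts are used because the plot
being interpreted is the smoothed one; with ≥200 surrogate runs the
normal approximation is adequate at Holm-corrected thresholds, and the
family-wise error rate stays at or below α on pure-noise experiments.

## Synthetic generators (what they emulate, and what they don't)

* **White noise** — i.i.d. standard Gaussian; the "no structure at all"
  control for everything filtering induces.
* **Kuramoto pair** — forward-Euler integration (dt = 1 ms) of
  dφ_θ/dt = 2π·ω_θ(t) + ε·sin(nφ_γ − mφ_θ) and the symmetric gamma
  equation, with the natural frequencies redrawn i.i.d. from
  Gaussian(ω̄, σ = 5 Hz) at every step (white frequency noise — a
  deliberately literal reading of "jitter at each time step"; holding
  draws over longer intervals would give slower frequency drift).
  ε is in rad/s and the Hz natural frequencies are converted by 2π
  inside the ODE; with the defaults (ε = 10, 1:5, ω̄ = 8/43 Hz) the
  locked state satisfies sin ψ* = 2π·Δ/((n+m)ε) and the mean frequencies
  align to 8.5/42.5 Hz, with Δφ precessing at ±17 Hz for m = 3/7 —
  the analytic anchor for the frequency tests. Initial phases are
  uniform on (−π, π].
* **Sawtooth** — unit peak-to-peak linear ramps with a sharp falling
  edge (polarity flag available); frequency drawn once per cycle from
  Gaussian(mean, σ), truncated at 1 Hz so a draw cannot stall or invert
  a cycle; additive Gaussian noise on top. Defaults (8 Hz, σ = 5 Hz,
  noise 0.1) emulate an asymmetric theta-like wave; σ = 0 gives the
  clean harmonic ladder (power at k·f₀, k-th harmonic 1:(k+1) locked to
  the fundamental with R > 0.99, k+1 diagonal stripes).
* **Sinusoid** — unit cosine; the perfect-locking control (R_1:5 = 1
  for 8 and 40 Hz).

None of these emulate real LFPs' nonstationarity, 1/f background,
transient gamma bursts, volume conduction, or state changes. Passing
tests on them establishes that the *statistics and their controls behave
as designed* — that genuine locking is detected, that known artifacts
are produced and correctly flagged by calibrated surrogates, and that
miscalibrated procedures (pooled surrogates, scrambling, uncorrected
bin tests) produce the expected false positives. They do not establish
anything about whether a given real dataset exhibits coupling; for real
data the package supplies the machinery (flat binary/text I/O with a
JSON sidecar, CSD −A+2B−C, 2-SD burst masking, 20 Hz phase subsampling)
but bundles no recordings.

## Scenario scales and determinism

Built-in scenarios run at desk scale by default — e.g. 20–100 R values
per distribution, 200 surrogate plots, 200 calibration tests — chosen so
each completes in minutes on one CPU; `full=True` (CLI `--full`)
restores field-scale counts (300 values per condition, 1000 surrogate
plots, 10,000 calibration tests, 2100-sample boxplots). Every scenario
is bit-reproducible given its seed; per-run generators derive from
(seed, index) so no result depends on execution order. The acceptance
script uses 120 s oscillator runs, one 100 s noise realization for the
modal phase steps, and 20 × 1200 s realizations for the long-epoch
chance level.

## Known limitations

* The Euler step at dt = 1 ms is the conventional choice for phase
  oscillators at these frequencies but adds O(dt) bias; it is part of
  the model definition here, not a numerical approximation to refine.
* `waveform_theta_phase` assumes at least two detectable cycles and a
  dominant oscillation in the landmark band; on broadband or bursty
  signals landmark detection is unreliable.
* The normal approximation in bin-wise testing understates tail
  probabilities when very few surrogate runs are used; prefer ≥200 runs
  or the empirical-rank mode.
* Group-level statistics across animals (Friedman/Nemenyi) are out of
  scope; the package tests single signals.
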
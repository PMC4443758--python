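# Methods

This note documents the models, estimators and numerical choices behind
`nmjphys`, and what the synthetic-data generators do and do not emulate.

## Units and conventions

Time is in seconds, membrane potential in mV, current in nA, fluorescence in
arbitrary units. All amplitudes are reported as magnitudes: an inward EPSC of
−3.2 nA has amplitude 3.2. Trace files are two-column CSV (`time_s,value`)
with a JSON sidecar, lossless at 12 significant digits; stimulus alignment is
always explicit through a SweepSet's stimulus-time vectors, never inferred
from the data. "Digitally filtered at 2 kHz" is implemented as a zero-phase
4-pole low-pass (2nd-order Butterworth run forward and backward); at the
standard 4-kHz Arch sampling rate that cutoff coincides with Nyquist, where a
digital low-pass is undefined, so the averaging stage applies the filter only
when the data are sampled above ~4.2 kHz and is otherwise a no-op. The
generic `lowpass` utility always refuses cutoffs at or above Nyquist.

## Release model and train analysis

Evoked release follows the classical binomial quantal model: a pool of `N`
vesicles, each released per stimulus with probability `p`, with quantal
amplitudes lognormal with mean `q` and coefficient of variation `q_cv`
(default 0.3 — positivity and realistic skew; only means ± SEM are usually
reported for real quanta). Between stimuli the pool refills at a continuous
rate `R` (vesicles/s), capped at `N`. Release probability couples to
external calcium as `p_eff = p · (Ca/Ca_ref)^n` with cooperativity `n = 3`
by default; `p_eff > 1` raises unless clipping is requested explicitly.

The RRP estimator accumulates the 30 per-stimulus amplitudes of a 60-Hz
train (baseline for stimulus *i* is the 2-ms window before its onset, the
peak is the extremum before the next onset), fits an OLS line to cumulative
points 21–30 on the stimulus-index axis, and evaluates it at index 0. With
uniform spacing the index and time axes give identical intercepts; the index
axis is used. `RRP(quanta) = intercept / q` with `q` the same-cell mean
mEPSC amplitude — the divisor convention is configurable because published
"RRP size" values do not always print it.

A property worth knowing (and verified in the test suite): with
replenishment the pool recursion `pool' = (1−p)·pool + R·Δt` gives
`cumulative(n) = RΔt·n + (N − RΔt/p)(1 − (1−p)^n)`, so the back-extrapolated
intercept converges to `N − RΔt/p`, not `N`. The estimator is exact only for
replenishment-free depletion; with refilling it carries a deterministic
downward offset of `RΔt/p` quanta that the tests measure against the closed
form rather than against `N`.

`P_train = EPSC₁ / intercept` (the fraction of the total RRP released by the
first AP). The intercept rather than the final cumulative EPSC is the
denominator — "fraction of the *total* pool" — with the alternative
available by using the last cumulative value directly. Values above 1 are
reported clipped with a flag; non-positive intercepts make P_train undefined
(NaN, flagged). Depression kinetics are fit as
`a(i) = plateau + span·exp(−(i−2)/τ)` on stimuli 2–10 (1-based); for pure
depletion the analytic decay constant is `τ = −1/ln(1−p)`. A non-positive
fitted span flags "no-decay"; non-convergence is flagged, never raised.
Per-synapse analysis averages amplitudes across at least five trains before
fitting; per-train values remain available.

## Quantal analysis

Quantal content is the raw ratio of mean evoked to mean miniature amplitude;
no nonlinear-summation correction is applied. Genotype-level quantal content
is the mean of per-recording ratios (never the ratio of genotype means — the
two differ on heterogeneous populations, and a regression test enforces the
former). The resting-potential rule reads "more positive than −60 mV" and
"more depolarized than −55 mV" strictly: −60 exactly records at Vm, −55
exactly clamps to −65 mV.

Mini detection is deliberately simple and fully specified (published
analyses often rely on interactive tools whose settings go unreported):
candidates are contiguous runs where the derivative of the 1-kHz-filtered
trace exceeds 3× its robust SD (1.4826·MAD); each candidate's amplitude is
its local peak minus a 2.5-ms pre-onset baseline mean; amplitudes below the
threshold (default 4× the robust noise SD estimated from median absolute
first differences, with a 5%-of-range floor on noise-free records) are
dropped, and events closer than 10 ms are merged keeping the larger. On
noiseless synthetic events amplitudes are recovered within 5%; at realistic
noise (SD ≈ 4–5% of the mean amplitude) recall and precision exceed 0.95.
These defaults are configuration, not constants of nature.

## Calcium imaging

`ΔF/F = (F(t) − F_baseline)/(F_baseline − F_background)` with both reference
values averaged over the 300 ms before the stimulus; the ratio form makes the
result gain-invariant. Exclusion rules are pure functions of the ROI trace:
F_baseline > 650 a.u. (hardware-specific, configurable) or resting-
fluorescence drift > 15%, both strict at the boundary. Drift is measured by
fitting a straight line to the trace with the transient window (default
750 ms from the stimulus) masked, and taking the fractional decrease of that
line across the whole record — an estimator chosen because windowed-mean
variants systematically understate the start-to-end decrease the rule is
about. Bouton averages are pointwise means of 8–12 scans (fewer is flagged,
still computed); shape comparison divides by the peak so curves from
different genotypes can be overlaid amplitude-free.

## Arch voltage imaging

Sweeps are modelled as tissue photobleach (single exponential) + the Arch
photocycle brightening over the first ~10 ms + the AP transient. The
photocycle is never modelled explicitly: the exponential fit window starts
10 ms after imaging onset and ends 5 ms before the stimulus, so the fit
captures tissue bleach plus baseline Arch fluorescence, and its
extrapolation is subtracted from the whole sweep. Sweeps whose residual
carries a second peak ≥ 50% of the stimulus-locked peak outside the
stimulus ± 5 ms window (searched after the photocycle segment) are rejected
as extra-AP artifacts; the 50%/5-ms operationalization is configurable since
the underlying rule is qualitative. Accepted residuals are averaged; widths
are measured on the average with linear interpolation between the bracketing
samples at each level crossing. WHM uses 50% of peak; "full width" uses 10%
of peak — published full widths rarely state their threshold, so this is an
explicit, configurable choice. Absolute amplitudes are not reported: baseline
Arch fluorescence cannot be separated from tissue fluorescence. Group
averages normalize each bouton's waveform to peak 1, align peaks with
parabolic sub-sample refinement plus linear resampling, average over the
common extent, and renormalize.

## Population statistics

Calcium cooperativity is the OLS slope on (log Ca, log QC); R² is reported
from three points up. The homeostasis curve is fit two ways: the
one-parameter reciprocal set-point model `QC = E₀/mEPSP` (what perfect
compensation implies; E₀ has a closed-form least-squares solution) and a
two-parameter exponential `QC = a·e^{b·mEPSP}` as a descriptive alternative.
`predicted_release_change(f, n) = 100·(1 − fⁿ)` converts a fractional
calcium signal into the percent release decrease the power law implies.
Group comparisons are two-sided Student's t-tests with pooled variance
(Welch by flag), SEM error bars, and no multiple-testing correction — raw
p-values only.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic under their seed and share the trace dialect
the pipelines read, so every stage can be tested end-to-end through files.
Design choices:

* Electrophysiology is rendered at 10 kHz (a digitization-rate choice, not a
  measured fact); Arch at 4 kHz and line scans at 313 Hz per their
  protocols. Stimulus onsets and event times are snapped to the sample grid
  so noiseless round-trips are exact.
* Evoked EPSCs use a difference-of-exponentials kinetic (0.5 ms rise, 4 ms
  decay) tapered to exactly zero within 12 ms, so successive train stimuli
  do not overlap each other's baseline windows and noiseless amplitude
  recovery is exact to machine precision.
* Mini records draw Poisson event times and unit-amplitude factors before
  applying the quantal scale, so two records differing only in the
  vGlut-overexpression factor (default 1.55×) share event times exactly and
  differ in amplitude by exactly that factor. Event rate is independent of
  quantal scale by default.
* Calcium transients rise instantaneously at the stimulus and decay
  exponentially (τ = 150 ms); bleaching multiplies the indicator component
  linearly. The Arch AP is Gaussian, parameterized by its WHM (1.2 ms
  default); for a Gaussian the 10%-threshold full width is determined by the
  WHM (factor √(ln10/ln2) ≈ 1.823), so the generator's full width is derived
  rather than independently settable. Tissue bleach uses τ = 50 ms so the
  photobleach fit window spans about one time constant — with much slower
  bleach the three-parameter exponential becomes ill-conditioned on a 45-ms
  window and its extrapolation unreliable, a real limitation of the
  subtraction method worth remembering with slowly-bleaching tissue.
* Extra-AP artifacts are injected as a second, equal-amplitude AP at a
  uniform offset ≥ 20 ms after the stimulus, exercising the rejection rule.
* The homeostasis population generator emits recordings with
  `QC = setpoint/mEPSP` under multiplicative lognormal noise (default CV
  0.15 in the acceptance computations) — a construction, not a mechanism.

What the generators do not emulate: biophysical AP shapes
(Hodgkin–Huxley), calcium microdomains or dye buffering, vesicle-size →
release-probability coupling, correlated or non-stationary recording noise,
electrode drift, and muscle-contraction artifacts. Passing tests therefore
demonstrate correct estimator behaviour under the stated stochastic models,
not robustness to every pathology of real recordings.

## Problem sizes in the standard runs

The test suite and the acceptance script size their simulations for sharp
statistics at interactive runtimes: 50-seed ensembles for RRP and Arch-WHM
recovery, 100 seeds for P_train and paired-pulse oracles, 250 single-AP
sweeps (50 per calcium level) for the cooperativity fit, and 100 simulated
recordings per group for the homeostatic-doubling ratio (sized so the
Monte-Carlo SE of the ratio is ~2%). The full suite runs in well under a
minute on one CPU.

## Known limitations

* The cumulative-EPSC intercept is biased by `−RΔt/p` under replenishment
  (see above); reported RRP values inherit this, as do all published uses of
  the method.
* Mini detection is not deconvolution-based and will undercount overlapping
  events at high rates; the merge rule keeps the larger of two events closer
  than 10 ms.
* The photobleach model is a single exponential; multi-component bleach
  leaves structured residuals that inflate width estimates at low AP
  amplitude.
* The 650 a.u. imaging-exclusion threshold is tied to a specific detector
  configuration and should be re-calibrated per rig.
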
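# Methods

## Stimulus model

A pulse is one period of a raised cosine, `p(t) = A(1 − cos 2πft)` for
`t ∈ [0, 1/f]`: it leaves the 1 mm base indentation with zero velocity,
peaks at `2A`, and returns smoothly. `A` is the amplitude of the
underlying sinusoid (default 40 µm, peak excursion 80 µm); `f` is the
waveform frequency that sets the pulse width `1/f` (5.882 ms at 170 Hz,
4.167 ms at 240 Hz). Waveforms are sampled at 40 kHz and stored relative
to the base; sampling below the Nyquist rate of `f` is rejected.

Discretization: a pulse occupies `floor(fs/f)` samples evaluated at
`t = k/fs`; the first rest sample is the exact zero that would continue
the cosine. This floor convention guarantees that pulses never overlap
at the highest admissible rate (`rate ≤ f` is enforced on train specs).
The residual at the last pulse sample is below 0.03 µm for all stimuli
in the experimental range, within the sample-to-sample continuity bound
`2πfA/fs`.

A train places `n = floor(rate × duration)` pulses with onsets at
`k/rate`; the reference (90 Hz, 500 ms) contains 45 pulses. A trial is
reference ∥ gap (0 or 1000 ms of zeros) ∥ comparison, the comparison
differing in `f` (shape condition) or rate (rate condition) only.

Session schedules reproduce the experimental design: 14 shape levels
(175–240 Hz step 5; the reference value is excluded from the change set,
the only reading consistent with the 840/540 totals) or 9 rate levels
(95–135 step 5), 30 change trials per level plus an equal number of
no-change trials, split evenly over 3 blocks (280 or 180 trials each)
and shuffled within block from a seeded generator — so equal level
counts per block are guaranteed by construction. Twenty practice trials
(half change) can be prepended; they carry `block_index = -1` and a
practice flag and are excluded from all analysis. `build_schedule`
defaults to `include_practice=False` so the schedule length equals the
printed session totals; the flag adds them when a full session replica
is wanted.

## Intensity formulations

Six temporally global intensity candidates: the time-mean of `|v|`,
`v²`, `|v|³`, `|a|`, `a²`, `|a|³` over the entire 500 ms stimulus, rest
periods included. Derivatives are central finite differences
(`np.gradient`) of the commanded trajectory; the analysis never sees a
measured trajectory, so commanded kinematics are the definition here. A
"summed" variant (mean × sample count) is exposed for plotting
conventions that accumulate over the stimulus; the factor cancels in any
within-formulation comparison, and the mean is canonical.

Closed forms for the raised-cosine pulse bound the numerical error and
serve as test oracles: per-pulse path length `4A` gives mean speed
`4An/D` (14,400 µm/s for the reference train); `∫v² = (2πfA)²/2f` per
pulse gives mean squared velocity `2π²fA²n/D`; peak `|v| = 2πfA`, peak
`|a| = (2πf)²A`. Mean speed is invariant to `f` at fixed rate — the
shape-change family lies on a mean-speed iso-feature line, numerically
flat to ~5×10⁻⁵ relative; the tolerance used to call a family
iso-feature (and an intensity axis degenerate) is 0.5% relative, leaving
ample room for pulse-boundary discretization.

## Psychometric model and fitting

Detection probability `P(x) = γ + (1 − δ − γ) S(x; m, w)`, `S` a
cumulative Gaussian (default) or logistic. The width `w` is defined by
`S` rising from 0.05 to 0.95, hence `σ = w/(2z₀.₉₅)` with
`z₀.₉₅ = Φ⁻¹(0.95) ≈ 1.6449`, and logistic scale `w/(2 ln 19)`.

Fitting is bounded maximum likelihood: the binomial negative
log-likelihood with probabilities clamped at 1e−9, minimized by L-BFGS-B
from a moment-style start plus Latin-hypercube starts (16 by default,
seeded; ties broken by lower NLL then lower width). The level axis is
standardized to unit span inside the optimizer so that axes of any units
(Hz, ms, or intensity values spanning many orders of magnitude) are
equally well-conditioned; reported parameters are in native units, and
fits are affine-equivariant in the level axis. Default bounds: `m`
within the level range padded by the width cap, `w ∈ (0, 2×span]`, `γ`
and `δ` in [0, 0.1] (a psignifit-like lapse cap; configurable). This is
deliberately a point-estimation reimplementation of the stated mixture
model, not a Bayesian treatment; parametric-bootstrap percentile
intervals are available on the results object.

No-change trials can inform the fit three ways: as a binomial data point
at the reference level with `γ` free (default — the reference level sits
just below the first change level on the native axis), as a frozen `γ`
equal to the empirical false-alarm rate, or ignored. Both active modes
are tested.

Validity of a fit follows two exclusion rules: the fitted curve must
reach `P = 0.5` within the tested range (`did_not_reach_half`
otherwise), and the false-alarm-corrected threshold must lie strictly
inside the range (`threshold_on_limit` otherwise; the boundary tolerance
is 1e−6 of the span — a threshold is rejected only when it is
effectively at or beyond the edge). The correction is the standard
high-threshold form `(P − γ)/(1 − γ)`; the threshold is the corrected
0.5 crossing, solved in closed form through the sigmoid inverse and
confirmed by bracketed root-finding. A consequence worth stating
explicitly: when `δ = 0` the corrected curve equals `S`, so the
threshold is exactly `m` for any `γ`; a positive lapse rate shifts the
threshold above `m` (corrected-0.5 is `S = ½(1−γ)/(1−δ−γ) > ½` iff
`δ > 0`).

## Synthetic observers

An observer codes one axis — pulse width (ms), pulse rate (Hz), or an
intensity formulation — and answers Yes on change trials with
probability `P(|axis(comparison) − axis(reference)|)` under its own
mixture parameters, and with probability `γ` on no-change trials. All
changes in this design are one-sided, so the absolute difference loses
nothing. Lapses enter as the upper asymptote by default, matching the
fitted model; an optional full-lapse mode instead flips any response
with probability `δ`. Memory degradation in gap sessions is a single
multiplicative inflation of `w` — the simplest mechanism that can
express both intact storage (inflation 1) and graded loss.

An observer coding only mean speed is blind to shape changes by
construction (the iso-feature property), yielding a flat yes-rate at `γ`
and an invalid fit — the pipeline-level reproduction of why the
mean-speed axis is degenerate for this stimulus family.

The default population, chosen once as this package's study conditions:
shape thresholds `m ~ N(0.9, 0.45)` ms and widths `w ~ N(0.9, 0.25)` ms
on the |Δwidth| axis (range of available changes 0.17–1.72 ms); rate
thresholds `m ~ N(55, 15)` Hz and widths `w ~ N(25, 8)` Hz on |Δrate|
(available 5–45 Hz); `γ ~ U(0.02, 0.08)`, `δ ~ U(0.01, 0.04)`; width
inflation 1.0; and a 0.15 probability that a participant is a
non-performer on every axis (threshold far beyond any range). With 25
participants this yields roughly 21 valid shape and 3–8 valid rate
participants: nearly everyone resolves pulse shape, a minority resolves
rate, non-performers fail both — the qualitative structure the task
design is meant to expose. Cohorts counterbalance the four session types
over their 24 orderings, assigned sequentially.

What the generator does *not* emulate: session-to-session parameter
variability (each participant keeps one observer per axis, so simulated
gap/no-gap thresholds correlate near 1, unlike the low correlations real
participants show), learning or fatigue across blocks, response bias
drift, and any neural or biomechanical front-end (Pacinian filtering,
skin mechanics). Passing tests therefore demonstrate that the analysis
chain is correct and calibrated on the stated model family — not that
the model family captures all structure of human data.

## Analysis pipeline

Aggregation collapses trials to per-level binomial counts per
participant × condition × gap; the empirical false-alarm rate comes from
the no-change trials. Fits run on the native axis (waveform frequency
for shape, pulse rate for rate). Thresholds convert to percent change
against the reference: `100(r* − 90)/90` for rate, width-based
`100(1 − 170/f*)` for shape.

The gap/no-gap comparison admits only participants valid in both
members of the pair: paired t-test (two-sided, raw p — no
multiple-testing correction is applied), the probability-of-superiority
effect size (share of pairs with gap > no-gap, ties ½; reported as
"AUC" in the output with its definition attached, since ROC-style
effect sizes have several conventions), and the Pearson correlation of
paired thresholds.

Intensity rescaling maps each native level to its intensity under a
formulation and refits with a logistic sigmoid on that axis; an axis
whose relative span is below the 0.5% iso-feature tolerance is flagged
degenerate and not fitted. Population-level overlays pool trials across
participants (per-participant refits are available through the same
function).

## Validation simulations and problem sizes

Two simulation checks gate the chain. Parameter recovery: 200 replicates
of the 14-level × 30-trial shape design from ground truth
`(m=205 Hz, w=40 Hz, γ=0.1, δ=0.02)`; the median absolute error of `m̂`
stays under `w/4` (measured ≈ 1 Hz — the design estimates the threshold
an order of magnitude more precisely than the exclusion criteria
require). Calibration: 200 null-hypothesis cohorts (12 participants,
shape gap + no-gap, width inflation 1, a fully capable population) run
through the entire aggregate → fit → paired-t chain; the rejection rate
at α = 0.05 must lie in [0.03, 0.07]. The replication loop uses 8
optimizer starts per fit (16 elsewhere); 12 participants per null cohort
and 200 replicates keep the two checks at a few minutes of one-CPU time
while the binomial error on a 0.05 rate at 200 draws (±0.015) still
resolves the acceptance band.

## Known limitations

- Commanded, not measured, trajectories define the kinematics; actuator
  dynamics and 12-bit DAC quantization are not modelled.
- The "amplitude 40 µm" of the source design is read as the sinusoid
  amplitude `A` (80 µm excursion); if it denoted total excursion, halve
  `A` — every intensity scales by a power of `A`, and nothing in the
  psychometric chain changes.
- ML point estimates only; no Bayesian posterior, no deviance-based
  goodness-of-fit beyond the likelihood itself.
- The observer population is a simulation input, not an estimate from
  human data; cohort-level numbers (validity counts, t statistics)
  characterize the configured population, not any empirical cohort.
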
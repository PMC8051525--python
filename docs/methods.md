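# Methods

This note documents the models and estimators implemented in `eegfx`, the
conventions they pin down, the defaults and why, and what the synthetic
cohorts do and do not establish.

## Data model and epoching

An `EEGRecord` is a leads × timepoints matrix of voltages in microvolts with
one sampling rate and unique ordered lead labels. Microvolts everywhere is a
hard convention, not cosmetics: the within-lead κ statistic takes
log |ΔV|, so its value depends on the voltage unit, and reproducibility
requires fixing one. Readers convert on ingest (the EDF reader converts
mne's SI volts back to µV; the matrix reader assumes µV).

Epochs are half-open windows [start, end) with sample indices
round(start·fs) to round(end·fs), so a 30 s window at 250 Hz is exactly
7500 samples. The study convention is a training epoch at 90–120 s and a
testing epoch at 210–240 s of a ~5 min resting recording. No artifact
rejection, filtering or re-referencing is performed: the input is taken as
already referenced, and all leads are used as recorded.

For between-lead analysis the default montage is a ten-lead subset covering
the scalp: leads 3, 56 (right frontal), 9, 19 (left frontal), 6, 36
(anterior/posterior midline), 40, 46 (right parietal), 26, 31 (left
parietal). With 64 leads the ordered-pair feature space (20,480 values)
dwarfs a 12-subject cohort; ten leads give 500 features, which a tree
learner can at least search.

## Information transfer modeling

Per instant and lag Δt (in samples, converted to ms):

    κ(t) = ln|V(t+Δt) − V(t)| / ln(Δt_ms)

The ratio of logs is base-invariant. Conventions and their reasons:

* **|ΔV| inside the log** — the only reading under which κ is real-valued.
* **Δt in milliseconds** — with Δt in samples the denominator vanishes at a
  one-sample lag, yet one-sample (4 ms at 250 Hz) features are meaningful
  and used; in ms the denominator is ln 4 there. A lag whose duration is
  exactly 1 ms is rejected (singular denominator).
* **Exclusions counted, never silently zeroed** — timepoints with
  |ΔV| = 0 carry no defined κ and are excluded; a segment with no valid
  timepoints yields NaN plus a warning, and `n_valid` is reported beside
  every mean.

Between leads at a shared lag, κ_itcr(t) = ln|ΔV_l1| / ln|ΔV_l2|; the lag
aligns the differences but cancels out of the value. Timepoints where either
difference is zero, or where |ΔV_l2| = 1 µV (denominator |ln|ΔV_l2|| below
ε = 1e−8), are excluded and counted. Identical leads give κ_itcr ≡ 1
exactly — used as a pipeline identity test. Pairs are **ordered**:
mean-of-ratios l1/l2 is not the reciprocal of l2/l1, and both directions
are informative; ordered pairs are also what makes 64 leads × 5 lags come
to 64·63·5 + 64·5 = 20,480 features.

Segment features are arithmetic means over valid timepoints (sum divided by
n_valid, i.e. mean-of-ratios, not ratio-of-means). Default lag grids:
{1, 2, 4, 8, 16} samples within-lead (4–64 ms at 250 Hz) and
{1, 6, 32, 178, 1000} samples between-lead — five integer lags log-spaced
over 4 ms–4 s. Both grids are configurable end to end; analyses of real
recordings may well need different ranges, and nothing downstream assumes
the defaults.

## MF-DFA

Standard multifractal DFA: profile Y(i) = Σ_{k≤i}(x_k − ⟨x⟩); windows of
scale s taken from **both ends** (2⌊N/s⌋ windows, so trailing samples are
not discarded); least-squares polynomial detrending of order m in each
window; F²(ν,s) the mean squared residual;

    F_q(s) = {mean_ν [F²]^{q/2}}^{1/q}   (q ≠ 0),
    F_0(s) = exp(½ mean_ν ln F²).

h(q) is the ordinary least-squares slope of ln F_q(s) on ln s over the
scale grid; τ(q) = q·h(q) − 1; α = dτ/dq by central differences on the q
grid; f(α) = qα − τ. The four per-lead features (mean, min, max, width of
the Hölder exponents) are taken over the α values on the interior q grid
(central differences drop the endpoints); "mean Hölder exponent" is their
arithmetic mean.

Defaults: q ∈ {−5, …, 5} (integer steps), 12 log-spaced integer scales in
[16, N/8] deduplicated after rounding, m = 1. These are the standard
published MF-DFA defaults; all are configurable. A window detrended exactly
(zero residual) would make ln F² diverge; F² is floored at 1e−20 µV² with a
warning. Note the empirical spectrum width on a finite q grid estimates
α(q_min) − α(q_max), which is narrower than the q → ±∞ theoretical width;
validation against the binomial-cascade closed form compares h(q) per q,
where the correspondence is exact.

## Spectral analysis

Raw (unsmoothed, untapered by default) periodogram of the demeaned epoch:
ordinates P_k = |FFT_k|²/N at Fourier frequencies k·fs/N, k = 1…⌊N/2⌋. Any
fixed normalization would do — the features feed a scale-equivariant tree
learner — but this one is stated so results are reproducible; it satisfies
Parseval in the form Σx_d² = 2Σ interior P_k + P_Nyquist (even N). An
optional split-cosine taper over a fraction of each end is provided, since
common periodogram routines taper by default and the choice is otherwise
invisible in a band-power number.

Band power is the sum of ordinates in the **closed** interval
[f_lo, f_hi]. The study bands are alpha 8–14, beta 16–31, delta 0.1–4,
gamma 32–50, theta 4–7 Hz, kept exactly as printed: the inter-band gaps
(7–8, 14–16, 31–32 Hz) stay unassigned, and 4 Hz belongs to both delta and
theta. On a 30 s epoch the Fourier spacing is 1/30 Hz, so the delta band
effectively starts at 2/15 ≈ 0.133 Hz.

## CART modeling and the 1-SE rule

Greedy binary regression trees: a node with ≥ `minsplit` rows (default 4;
with 12 subjects anything stricter forbids splitting altogether, so the
minimum leaf size is 1) is split on the (feature, threshold) pair maximising
the reduction in within-node sum of squares. Thresholds sit at midpoints of
adjacent distinct values; rows with value < threshold go left, ≥ goes
right; ties are broken toward the lower feature index, then the lower
threshold — all purely for determinism, since the reference algorithm
leaves ties unspecified.

The full tree's weakest-link (cost-complexity) pruning sequence is recorded,
with complexity expressed relative to the root risk (cp = α / SS_root).
Cross-validation uses seeded random near-equal folds (k = 10 by default;
fewer subjects than folds degrades to leave-one-out with a warning); each
fold's tree is pruned at the geometric mean of adjacent cp interval
endpoints, and pooled out-of-fold squared errors give the relative error
`xerror` and its standard error `xstd` = √Σ(e_i − ē)² / SS_root (the
population-sd convention of the reference implementation's complexity
table). The 1-SE rule picks the largest cp whose xerror is within one
standard error of the minimum; exact ties favor parsimony. Surrogate splits
are not implemented; missing feature values are imputed upstream with the
feature's training-set median (a feature missing for every training subject
is dropped from both epochs with a warning).

Out-of-sample performance is Pearson r between predicted and actual
subscores with t = r√(n−2)/√(1−r²), two-sided p from the t distribution on
n − 2 df. A tree pruned to the root predicts a constant, leaving r
undefined: this is reported as NaN with a warning (and treated as zero
association when aggregating null distributions), never silently as r = 0.
With n = 12 this happens regularly — on replicate synthetic cohorts the
1-SE rule prunes the *driven* subscore's tree to the root in roughly one
draw in eight, and the reference implementation does the same on identical
feature tables. That is a property of cross-validating 12 observations, and
it is why the acceptance script reports the median driven-subscore r across
seven replicate cohorts rather than one draw.

## Synthetic cohorts

`gen_cohort` builds per-subject recordings whose leads are
unit-variance f^−β noise (β = 1 by default, the 1/f-like background of
resting EEG) scaled to 10 µV, plus a 10 Hz oscillation of ~2 µV with random
phase per lead. Subject-level latents are drawn once per subject and persist
across the whole recording, so the training (90–120 s) and testing
(210–240 s) windows share them — without that persistence out-of-sample
prediction would be impossible by construction. A driver links a latent to a
subscore: with the default `alpha_power` driver, the latent
(uniform on [0.5, 2.5]) scales the 10 Hz amplitude on one lead and the
subscore is intercept + effect·latent + N(0, 0.5) with effect 4 — a strong,
nearly linear association whose feature-space footprint (alpha band power on
that lead) is known exactly. A `hurst` driver instead sets the lead's noise
memory, visible to MF-DFA. Undriven subscores are standard-normal noise.
Optional couplings rebuild a destination lead as gain × lagged source +
independent noise; the coupling graph must be acyclic (a zero-lag cycle is
unbuildable, and cycles are rejected outright).

Reference generators with known truth: spectral-synthesis f^−β noise
(β ∈ [−1, 3]); fractional Gaussian noise by exact Davies–Harte circulant
embedding (monofractal, h(2) = H); and the random binomial multiplicative
cascade (p, levels), whose closed form
h(q) = 1/q − ln(p^q + (1−p)^q)/(q ln 2) and theoretical width
log₂(p/(1−p)) are attached as metadata. All generators are bit-reproducible
under a fixed seed.

**What synthetic validation does not show.** The cohorts contain no
artifacts, no impedance problems, no volume-conduction geometry, no
physiologically realistic cross-frequency structure, and their score-feature
links are planted. Passing tests establish that the estimators recover known
ground truth and that the pipeline is internally correct and deterministic —
not that any feature family predicts cognition from real EEG.

## Problem sizes and numerical choices

Tests and the acceptance script run on 12-subject cohorts (10 or fewer
leads, 250 Hz, 25–300 s records), 2¹³-sample cascades (20 replicates) and
7500-sample fGn — sizes at which every closed-form recovery in the suite is
already stable. Other fixed numerics: the κ_itcr denominator guard
ε = 1e−8; the F² floor 1e−20 µV²; split-gain and pruning tolerances 1e−12;
EDF serialisation quantises to the 16-bit digital range with a text-round-
tripped physical maximum so read-back error is bounded by half an LSB.

## Known limitations

* Within-lead κ depends on the voltage unit (µV, fixed) and on signal
  scale generally; between-lead ratios of identical leads are
  scale-invariant only when both leads scale together.
* The empirical Hölder-spectrum width underestimates the theoretical
  (q → ±∞) width on any finite q grid; comparisons should be per-q or
  against matched-grid values.
* CV-based pruning at n = 12 is high-variance; per-draw out-of-sample
  correlations should be read with that in mind (see above).
* EDF writing supports one rate and 16-bit samples only; mixed-rate files
  are read-rejected by design.
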
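# Methods

## Decoding model

The decoder is the classical two-class motor-imagery chain. A continuous
multichannel recording is band-pass filtered per channel with a zero-phase
(forward–backward) 4th-order Butterworth filter, default band 8–30 Hz. The
filter family and order are a design choice — only the band itself is part
of the protocol being modelled — and zero-phase filtering of the
*continuous* signal was chosen so that filter transients never overlap
trial windows. Epochs are cut from the half-open window [0.4, 2.4) s after
cue onset with `sample = floor(t · rate)`; no baseline correction,
re-referencing or artifact handling is applied.

Per-trial channel covariances are computed with per-channel demeaning and
an n−1 denominator, normalized by their trace before averaging within each
class (robust to trial-to-trial amplitude drifts; the unnormalized
"pooled" average is available as an option, and is the variant under which
CSP's invariance to common linear mixing is exact). CSP solves
`Σ_left w = λ (Σ_left + Σ_right) w` via `scipy.linalg.eigh`; with the
B-normalization this gives `W (Σ_left + Σ_right) Wᵀ = I` and eigenvalues
in [0, 1] equal to the left-class variance ratio. The m "most significant"
filters are taken as m/2 from each end of the spectrum (5 + 5 for session
analyses, 3 + 3 run-wise) — the universal CSP pairing convention. Filter
signs are fixed by making the first non-negligible coefficient positive.
Features are `log var(wᵀx)` per trial, computed through the exact identity
`var(wᵀx) = wᵀ C w` from the cached per-trial covariances. Fisher LDA uses
the pooled within-class scatter, `w ∝ S_w⁻¹(μ_L − μ_R)`, with the decision
threshold at the midpoint of the projected class means; a score exactly on
the boundary is assigned to the first class of `class_order` ("left").
Singular composite covariances or scatters raise an error suggesting the
optional ridge term (`ε · trace/dim` on the diagonal), which is off by
default.

## Cross-validation

Trials are grouped once per accuracy estimate into k = 10 subsets of equal
size (±1) by a seeded permutation, stratified by class by default. All
C(10, 3) = 120 assignments of 3 subsets to the test side are enumerated in
lexicographic order; each separation refits CSP and LDA on the training
trials only. The session accuracy is the mean of the 120 correct rates
(×100), its spread the population SD over the 120 rates (the SD definition
behind the reference table's spread column is unstated; population SD over
separations is our documented choice). Each subset is on the test side in
C(9, 2) = 36 separations, so every trial is tested exactly 36 times. The
"120 repetitions" are the separations of one grouping — the grouping is
not re-randomized. Stratification is on by default because unstratified
subsets of small runs (subsets of 4 trials) can lose a class entirely and
void the decoder's preconditions; the literal unstratified reading is
available as a switch. Run-wise accuracy applies the identical scheme to
each run's 40 trials with 6 filters.

## Statistics

Pearson correlations are tested non-parametrically: the accuracy vector is
shuffled (n = 2,500 by default) and the two-sided p-value is the add-one
estimator `(1 + #{|r_perm| ≥ |r_obs|}) / (n_perm + 1)`, with floor
1/2501. Constant inputs raise an explicit degenerate-data error rather
than returning NaN. Families of correlations are corrected with
Benjamini–Hochberg FDR at q = 0.1 (Benjamini–Yekutieli available);
group contrasts use the two-sided Wilcoxon rank-sum test — exact
enumeration when both groups have ≤ 10 tie-free observations, otherwise
the normal approximation with tie-corrected variance and no continuity
correction (so identical groups give p = 1 exactly). RMSE is in
percentage points; descriptive statistics use the sample SD (n − 1) and
the midpoint median. The below-chance count uses strict `accuracy < 60 %`.

The evolution analysis correlates each stage's predictions (pre-task, then
each run) with the single session-wise accuracy, and reports the |r|
thresholds for p = 0.05 and 0.01 as upper quantiles of the permutation
null at the given n (computed by correlating the accuracy vector with
shuffles of itself; the null law of r depends on the data only weakly
through n).

The reference table stores the 1–5 rating items exactly as printed.
Whether that orientation is pre- or post-flip is not documented in the
source; correlations of the printed columns already carry the signs of the
published analysis (e.g. calmness +0.25), so values are kept as printed
and `flip_scale` (x → 6 − x, an involution that exactly negates
correlations) is left to the caller. Substance splits use a literal
"within 24 h" reading: 0 < hours ≤ 24, with 0 encoding non-consumption.
Out-of-range pre-task answers (e.g. one subject answering 0 %) are
retained, not clipped — keeping all 52 records is what reproduces the
printed pre-task RMSE.

## Synthetic data generator

The generator produces the *minimal* process a CSP decoder can exploit:
two fixed unit-norm lateralized topographies (Gaussian bumps at 1/4 and
3/4 of the channel axis, standing in for sources under C3/C4), each
carrying a band-limited mu oscillation (white noise band-passed to
8–12 Hz), linearly mixed over spatially white 1/f background noise
(power ∝ f^−1, flat below 1 Hz). During the imagery interval (cue to cue
+ 3 s of a 7 s trial) the source contralateral to the cued hand is scaled
by (1 − d), where d = `erd_depth` ∈ [0, 1] is the subject's latent skill;
the 0.4–2.4 s analysis window lies fully inside this interval.
Inter-trial intervals are uniform on [0.1, 0.8] s. Defaults are 5 runs of
20 trials per class (64 channels at 512 Hz nominally; all operations are
rate-agnostic and the test suite uses 16 channels at 128 Hz for speed).

The source-to-background amplitude ratio defaults to `snr = 0.4`,
calibrated once so that skills on [0.1, 0.9] map monotonically onto
roughly 50–93 % decoded accuracy — the spread observed in real
motor-imagery cohorts (≈ 47–96 %) — without saturating at the top.
"High-SNR" test scenarios pass `snr ≥ 1` explicitly.

Cohorts draw skill uniformly from [0.1, 0.9] by default. Per-run
self-predictions are `clamp(50 + 50·skill + noise, 50, 100)` with a
per-run noise SD that may shrink across runs (emulating self-insight
sharpening with task experience); the run-averaged prediction AP is their
mean, and the pre-task prediction is drawn independently of skill on
[50, 90] — subjects have no basis for prediction before the task.

What the generator does **not** emulate: volume conduction or any forward
model, ocular/muscular artifacts, non-stationarities other than the ERD
envelope, inter-channel background correlation, beta-band or bilateral
ERD components, and feedback effects. Tests passing on this model
therefore validate the *pipeline* (filter extraction, fold bookkeeping,
statistics) — they are not evidence about decoding performance on real
EEG, whose per-subject accuracies cannot be regenerated without the raw
recordings.

## Problem sizes and determinism

The test suite and the acceptance script use 16-channel, 128 Hz subjects
(200 trials) and cohorts of 12–20 subjects; permutation tests use
n = 2,500 except where a cheaper n is noted. One master seed determines
the trial layout, source noise, subset assignment and permutation draws;
identical seeds give bit-identical recordings and reports. All
percentages are reported on the 0–100 scale.

## Known limitations

* CSP here is strictly two-class; no shrinkage-LDA or multi-class
  extensions.
* The run-wise accuracy at 40 trials has a very wide chance band (~35–65 %);
  interpreting single-run accuracies requires that caution.
* The permutation |r| thresholds are themselves Monte-Carlo estimates with
  ~±0.01 jitter at n_perm = 2,500.
* Real-EEG file formats are out of scope; the synthetic container
  (`.npy` + JSON sidecar) and the table CSV/TSV are the only I/O formats.
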
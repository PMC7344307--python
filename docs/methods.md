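# Methods

## Signal model and decoding chain

The package decodes two-class motor imagery from epoched EEG
(trials × channels × samples, labels in {1, 2}, cue-locked).  The chain
is: five overlapping 2-s windows referenced to the cue onset (shift T₀,
default 0.5 s, so window i spans [T₀(i−1), 2+T₀(i−1)] s) → third-order
Butterworth band-pass 8–30 Hz → per-window CSP → concatenated
log-variance features (5 windows × 4 filters = 20 columns) → feature
selection down to k = 4 → standardization → linear SVM (C = 1).  All
data-dependent fitting happens on the training split of each
cross-validation fold.

### Filtering

The filter is designed in second-order sections and applied zero-phase
(forward–backward) by default: CSP consumes variances, which zero-phase
filtering preserves without group-delay misalignment, and the effective
squared magnitude response does not change which band survives.  Two
open choices are exposed rather than guessed: `zero_phase=False` gives a
causal single pass, and `mode="per_segment"` filters each 2-s window
separately instead of filtering the whole trial once and slicing.  The
default filters the whole trial because a third-order transient occupies
a substantial fraction of a 2-s window; the per-segment mode is the
literal per-window reading and differs only near window edges.

Window starts are rounded to the nearest sample; windows are half-open
`[start, start+round(2·fs))` so every window has identical length and a
shift of exactly 2 s would tile the trial without gap or overlap.

### CSP

Class covariances are averages of per-trial trace-normalized spatial
covariances E·Eᵀ/tr(E·Eᵀ) (the standard estimator; pooling samples
instead is a one-line change isolated in `class_covariance`).  Filters
come from whitening the composite covariance and eigendecomposing the
whitened class-1 covariance; eigenvalues are sorted descending and lie
in [0, 1], and every filter satisfies wᵀ(C₁+C₂)w = 1.  `W_2m` keeps the
m largest- and m smallest-eigenvalue filters (m = 2); filter j pairs
with filter 2m+1−j.  Eigenvector signs are fixed by making each
filter's largest-magnitude coefficient positive; ties between equal
eigenvalues keep the eigensolver's order (documented as non-unique).
Rank-deficient montages raise, with optional shrinkage
C ← (1−γ)C + γ(trC/c)I (default γ = 0) as the documented remedy.

Features are f_j = log(var(w_jᵀE)) as such, without dividing by the
summed variance; the conventional normalized variant is available via
`normalized=True`.  The un-normalized form changes features by an
additive constant under global rescaling (2·log a), which the
per-fold standardization absorbs.

### Feature selection

All three column selectors return pair-closed sets built by walking a
ranking and adding (column, partner) pairs until k columns; ties break
toward the lower column index, and because additions are always whole
pairs the set size grows by exactly 2 per step.

**MUIN.**  I(v; ω) = H(ω) − H(ω|v) in bits.  Class priors are empirical
(n_ω/n); p(v|ω) is a Gaussian Parzen estimate over the class-ω training
values with Silverman bandwidth h = (4/(3n_ω))^{1/5}·σ_ω, where σ_ω is
the sample standard deviation of the class-ω feature values — applying
the rule per class is the only reading under which the bandwidth depends
on the feature at all.  The conditional entropy is the empirical average
over training trials of −Σ_ω p(ω|v_i)log₂p(ω|v_i) (a sum without the
1/n would not be an entropy), and the result is clipped to [0, H(ω)].
A constant within-class column (h = 0) is an error, as is single-class
input.

**LASSO.**  β̂ = argmin ‖y − β₀ − Fβ‖₂² + λ‖β‖₁ with labels coded
numerically (1/2) and an unpenalized intercept (equivalently, centered
y); the solver is coordinate descent behind `solve_lasso`, with λ = 0
falling back to least squares.  The λ grid is geometric, 50 points from
λ_max = max_j|2f_jᵀ(y−ȳ)| (the smallest all-zero penalty) down to
10⁻⁴λ_max; the grid is walked downward to the first λ whose nonzero
coefficients number at least k and span at least k/2 pairs, then columns
are ranked by CD_j = |β̂_j| and pair-completed.  Exhausting the grid
raises, reporting the nonzero count.

**PCA.**  Top-k right singular vectors of the column-centered table;
rows orthonormal, signs fixed as for CSP filters.  PCA is unsupervised
and returns a projection, so the pairing constraint does not apply; for
the window-usage tallies each component is attributed to the window of
its largest-magnitude loading (an interpretation, recorded as such).

**SWLDA.**  Forward steps add the candidate with the smallest partial-F
p-value when it is below 0.1; backward steps drop included features with
p above 0.15, worst first; iteration stops at k features or when no move
is legal (which termination fired is recorded, along with the full
trace).  Partial-F tests use df (1, n − p_full) with p_full the
parameter count of the larger model including its intercept.  The final
set is pair-completed afterwards (the stepwise steps themselves operate
on single columns): whole pairs are ranked by their best member's entry
p-value, refilled from the marginal single-column ranking if the loop
stalled early, and truncated to k/2 pairs — truncation is by whole pairs
so closure is never broken.  If nothing enters, the selection is empty
and flagged; the pipeline then falls back to the marginal pair ranking
so the classifier still receives k features.

### Classification and evaluation

The SVM is LIBSVM-backed with a linear kernel and C = 1 on features
standardized by training-split mean/sd: 4-dimensional log-variance
features are near-linearly separable, and a linear default removes an
unreported tuning dimension (kernel and C are configurable).  The
comparator (`selector="none"`) is a single CSP on a fixed window
(default cue+0 to cue+4 s) with its 4 features passed straight to the
SVM.

Cross-validation is repeated stratified k-fold (default 10×10);
stratification guards against single-class training splits.  Method
comparisons require the identical fold partition (verified, and hashed
into reports) and use two-sided paired t-tests per fold; zero-variance
differences are degenerate and return p = 1 with a flag.  Window-usage
summaries tally the selected columns' window indices over all folds and
the fraction of folds whose selection spans ≥ 2 distinct windows.

### ERSP

ERSP(f,t) = (1/N)ΣᵢGᵢ(f,t)² where Gᵢ is the STFT magnitude with a 0.5-s
Hann window and 90% overlap (both configurable).  No baseline
normalization is applied by default because the defining average has
none; a dB-relative-to-baseline mode exists for ERD visualization and
the mode is recorded in the output metadata so maps are never silently
mixed.  The definition gives two exact laws used as checks: quadratic
scaling under amplitude scaling, and N·ERSP of a union equal to the
weighted sum of the parts.

## Synthetic data

The generator emulates exactly the structure the method targets: each
channel carries a sinusoidal rhythm (amplitude 10 µV, frequency drawn
per trial uniformly inside the band, random phase) over i.i.d. Gaussian
noise (2 µV), and the ERD channels of a trial's class have the rhythm
amplitude multiplied by 1−depth during the active windows, with 100-ms
raised-cosine ramps at window edges so no step discontinuity leaks
broadband energy into the filters.  The single-sinusoid choice makes
band power closed-form: outside ERD windows the per-channel variance is
noise_sd² + amplitude²/2, which the tests check directly.  Defaults
mirror a competition-style calibration run: 100 trials/class, 8
channels, 100 Hz, 8-s trials with the cue at 2 s, depth 0.8 on one
contralateral channel per class for the whole 4-s imagery period.

`early_erd_config()` is the early-window study condition: ERD on two
channels per class, active only 0–1.5 s after the cue — entirely inside
the span of windows 1–3 and invisible to windows 4–5 (window 4 starts at
1.5 s).  Two spatial sources per class matter: with a single source
there is only one independent discriminative dimension, and a selector
needing two pairs must pick its second arbitrarily; two sources give two
genuinely informative early pairs, the regime in which early windows
should dominate the selection.

What the generator does *not* model: 1/f background spectra, ocular/EMG
artifacts, volume conduction and spatially correlated noise (an optional
mixing matrix can induce correlation), non-sinusoidal rhythm waveforms,
and between-trial nonstationarity.  Passing tests on this data show the
chain recovers planted spatio-temporal band-power structure and stays at
chance without it — not that real-EEG accuracies are reproduced.

## Null calibration

The chance control permutes labels against unchanged signals.  Its CV
accuracy is compared to the exact binomial 95% interval at the number of
*independent* test predictions, which means one repetition of 10-fold CV
(every trial tested exactly once, n = 200): averaging over repeats
re-tests the same trials with nearly deterministic per-trial outcomes
and shrinks the nominal interval without shrinking the true variance.
Even at one repetition the permutation null is mildly overdispersed
relative to a binomial (measured sd ≈ 4.8% vs 3.5% across 20 seeds) —
selection can latch onto dataset-level chance associations present in
both splits — so this check is slightly anti-conservative; it is kept at
the stated 95% level.

## Numerical choices and problem sizes

Filter design in second-order sections; eigendecompositions via
symmetric solvers; LASSO coordinate-descent tolerance 10⁻¹²; SWLDA
capped at 200 stepwise steps against cycling.  The test suite and the
reproduction script run the study at 100 trials/class with 8 channels at
100 Hz, sizes at which the full 10×10-fold study of all five methods
completes in well under a minute on one CPU while every statistical
check retains its power.

## Known limitations

Two-class only (the multi-class CSP extensions are out of scope); one
fixed frequency band (no filter-bank variant); loaders cover the
package's HDF5 container and MAT-style continuous recordings with cue
markers, not GDF/EDF/BrainVision; no artifact rejection or
re-referencing; ERSP produces the numbers behind time-frequency and
topography figures but no scalp interpolation or rendering.
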
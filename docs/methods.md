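# Methods

## Model and objective

The regularizer operates on the feature layer `Z ∈ R^{N×F}` of a classifier
(the input of the final dense layer; for multi-branch architectures, each
branch's own pre-dense layer). Class separability of each scalar feature is
measured with the 1-D silhouette under absolute distance. For a batch, the
target position `t_if` of sample `i` along feature `f` is the batch value
`z_jf` that maximizes sample `i`'s silhouette when `i` is relocated there
with every other sample fixed. The training objective during fine-tuning is

    L = L_CE + ω · 1[L_CE < Loss_min] · L_pos

with `L_pos` the mean squared deviation of `Z` from `t`. The gate is a hard
indicator on the batch's own cross-entropy (no running average); it opens
strictly below `Loss_min`, so `Loss_min = 0` disables the term entirely.
Targets are constants for gradient purposes: the position term pulls
features toward fixed values and contributes no gradient through the argmax.
Because targets depend on batch composition and data are reshuffled every
epoch, the auxiliary objective is stochastic across iterations, which is the
intended regularization mechanism.

Two conventions close gaps the definitions leave open:

* zero denominator: `s = 0` when `max(a, b) = 0` (constant feature within
  the relevant classes);
* the class-mean distance of a candidate position includes the candidate
  sample's own (zero) distance when that sample belongs to the class being
  averaged — this is exactly what "all other samples fixed" implies, since
  the relocated sample and the candidate then coincide.

## Target-search implementation and tie-breaking

The vectorized search materializes the per-feature pairwise distance tensor
`D[f,j,k] = |z_jf − z_kf|` (`O(F·N²)` entries) and derives all relocation
silhouettes by class-indexed sums, then takes an argmax over candidates.
Ties are broken by the candidate value closest to the sample's current
value, then by lowest candidate index; candidates whose scores differ by
less than `1e-9` (scores live in `[−1, 1]`) are treated as tied so that the
vectorized path and the brute-force oracle — which evaluate mathematically
identical quantities in different floating-point orders — agree exactly.
The brute-force oracle literally copies a feature column, overwrites one
entry per candidate, and recomputes that sample's silhouette from the
definitions; a 100-batch random sweep asserts elementwise equality.

Approximations for larger batches: per-class candidate subsampling draws
`min(m, class size)` candidates per class per feature (each sample's own
position always included; exact whenever `m` reaches the largest class
size — sampling is shared across samples within a feature, which preserves
every contract at lower bookkeeping cost), and a top-K restriction keeps
the K features with highest mean current 1-D silhouette (ties to the lowest
feature index).

## Batch eligibility

A batch supports the silhouette only if at least two classes are present
and no present class is a singleton (the intra-class mean needs two
members; the nearest-other-class term needs another class). Ineligible
batches are optimized with cross-entropy alone and never raise; eligibility
is evaluated per batch after each epoch's shuffle.

## Backbone and optimization

No deep-learning framework is used: models are plain NumPy with
hand-written backpropagation, verified against central finite differences.
The reference backbone is a band-power-style network: a bank of 8 temporal
convolution kernels spanning all channels (joint spectral-spatial
filtering, kernel 49 samples ≈ 0.38 s at 128 Hz — about four cycles of a
10 Hz rhythm, enough spectral selectivity to resolve the simulated band),
squared activations averaged over time, log compression, a dense ELU layer
to the F = 16 feature layer, and a dense classifier (~3 k parameters). It
is a desk-scale stand-in honoring the `(logits, features)` contract, not a
reimplementation of any published EEG architecture; a trivial
flatten-affine model exercises the same contract in tests. The optimizer is
Adam with coupled L2 weight decay (decay added to the gradient), learning
rate 1e-3, weight decay 0.009 — the protocol's fixed settings. Pretraining
uses cross-entropy only; the gate hyperparameters default to ω = 1,
`Loss_min` = 0.2.

## Transfer protocol

Leave-one-subject-out: for each target subject the backbone is pretrained
on the pooled training trials of all other subjects, then fine-tuned on the
target's training trials; accuracy is measured on the target's held-out
test trials. All fine-tuning strategies for a given (seed, target) share
one pretrained model, so strategy comparisons differ only in the
fine-tuning objective. The subject-dependent baseline ("original") trains
a fresh model on the target training set for the combined
pretrain + fine-tune epoch budget, making the comparison one of
initialization rather than compute. Hyperparameter selection splits each
target's training trials per class into two random halves (fit/validation;
odd counts give the extra trial to the fit half) and picks the grid point
with the highest subject-mean validation accuracy (ties: first in grid
order). Few-shot budgets keep `floor(fraction × count)` trials per class
(minimum 1), sampled uniformly without replacement.

## Synthetic benchmark

The generator emulates the decodable structure of motor-imagery EEG:
per-trial 10 Hz oscillations on class-assigned channel groups over
1/f-shaped background noise (10 µV std), with the trial's own class group
attenuated by `effect_size` from the cue sample onward
(desynchronization-like), and per-subject fixed channel gains
(std `subject_shift`) and offsets (std `10·subject_shift` µV) standing in
for inter-subject variability. Defaults: 4 subjects, 2 classes, 6 channels,
128 samples at 128 Hz (cue at sample 32), 24 trials/class/subject,
`effect_size` 0.4, `subject_shift` 0.25, oscillation 8 µV. These defaults
put single-subject decodability clearly between chance and ceiling and
create a measurable within/cross-subject gap, so transfer effects have room
to show. Deliberately absent: artifacts, within-session non-stationarity,
beta-band structure, volume conduction, realistic spatial covariance —
results on this benchmark validate the mechanics of the pipeline, not
real-EEG performance.

Benchmark protocol sizes (desk scale, one CPU): 8 training + 16 test trials
per class per subject, fine-tuning batch 16 — i.e. all 8 trials/class in a
batch, mirroring the ~16-per-class batch occupancy of the full-scale
protocol (batch 64); with only 4 samples per class, per-batch silhouette
estimates become too noisy to be meaningful. Pretraining 100 epochs,
fine-tuning 150, 10 run seeds for stochastic comparisons.

## Numerical choices and degenerate inputs

Cross-entropy uses natural log, mean reduction, and a log-softmax
formulation (no overflow); labels are validated against `{1..K}`. Feature
batches reject non-finite entries. Trial epoching uses the half-open window
`[cue − round(pre·fs), cue + round(post·fs))`, which reproduces the
standard 1125-sample motor-imagery trial (0.5 s pre, 4 s post, 250 Hz)
exactly; out-of-bounds cues are dropped per trial with a warning. The
epoched-trial container is HDF5 (`X`, `y` datasets; `fs`, `subject`,
`channels` attributes), lossless at 64-bit. Wilcoxon comparisons drop zero
differences, use the exact null for n ≤ 25, and return p = 1 when every
difference is zero.

## Known limitations

On the desk-scale benchmark the random-target ablation is a strong
regularizer in its own right — with 16 target trials and a mild
gain/offset subject shift, both target strategies act mainly as restraints
on overfitting drift, and uniform noise restrains at least as hard as
silhouette-clustered targets. The benchmark therefore reproduces the
direction transfer > subject-only and regularized ≥ plain fine-tuning, but
not a silhouette-vs-random ordering; separating those two at this scale
would need richer feature-level class structure than the generator
provides. The gate also opens almost immediately here (a pretrained
two-class model starts near the threshold), so gated and ungated variants
behave similarly, unlike in long full-scale fine-tuning.
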
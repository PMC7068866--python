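# Methods

## Model and procedure

A dataset is a genes × samples matrix of (assumed already normalised,
typically log-scale) expression values with binary sample labels.  A
*genetic network* **g** is a gene subset used as the input of a k-nearest-
neighbour classifier; its accuracy is the percentage of correctly classified
samples, estimated either by leave-one-out cross-validation (each sample
predicted from all others) or by blind prediction of a held-out validation
split from a training split.  Because the problem is strongly
underdetermined (genes ≫ samples), many networks reach near-maximal
accuracy; the package treats the set of high-accuracy networks as the object
to be sampled, and summarises it by each gene's *posterior sampling
frequency* — its share of all gene occurrences across retained networks.

The three samplers differ only in their prior over networks:

1. **FRS** weights each discriminatory gene by its Fisher's ratio
   FRⱼ = (μⱼ₁−μⱼ₂)²/(σ²ⱼ₁+σ²ⱼ₂), splits the pool into headers
   (FR ≥ FR_min) and helpers, and draws, per network, a uniform length, a
   uniform header count (at least one header — helpers alone cannot
   discriminate), and the genes themselves by inverse-cdf draws without
   replacement within each pool.
2. **HS** resamples the evidence instead of the genes: independent
   stratified 75/25 train/validation partitions, full feature selection and
   minimum-scale search on the training split, blind scoring on the
   validation split.
3. **RS** draws networks uniformly from the discriminatory pool.

Retention is a hard accuracy cutoff (default 85%), not a soft weight; the
retained set is a sampled realisation of the uncertainty set of
high-predictive networks.

## Feature selection

Genes pass two screens: |difference of class means| ≥ `fold_change_threshold`
(interpreted as log2 fold change, default 1.0) and Fisher's ratio strictly
greater than `fr_cutoff` (default 0.8, automatically relaxed to 0.5 with a
logged warning when fewer than `relax_floor` = 10 genes survive).  Survivors
are ranked by descending FR (ties: larger |fold change|, then probe id).
The *minimum-scale signature* is found by recursive backward elimination
over that ranking, implemented as evaluation of all nested prefixes —
dropping the lowest-FR gene at each step never changes the remaining order,
so the prefix sweep is the exact deterministic equivalent.  The profile is
computed incrementally (squared Euclidean distances accumulate gene by
gene), costing O(L·n²) for L prefixes; L is capped at `prefix_cap` = 200 to
bound runtime on very wide matrices.  Ties on the maximum accuracy resolve
to the shortest prefix.

Estimator choices: class centers are arithmetic means; dispersions are
unbiased sample variances (ddof = 1), the standard choice for Fisher-ratio
feature scoring (population variances would shift FR values slightly but
not the ranking).  Genes with zero total dispersion get FR = +∞ when their
means differ (they separate perfectly and rank first) and FR = 0 otherwise.

## Classification details

Distances are Euclidean over the signature's genes on the loaded values.
k defaults to 1 ("nearest neighbour"); any odd k is accepted.  All tie
rules are deterministic: equidistant neighbours resolve to the smallest
training-sample index (stable argsort), vote ties resolve to class 1.  In
blind validation, neighbours are drawn from the training split only, and
validation labels are used solely for scoring — perturbing them provably
cannot change a bag's signature (tested).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `fold_change_threshold` | 1.0 (log2 units) | differential-expression screen |
| `fr_cutoff` / `fr_cutoff_relaxed` | 0.8 / 0.5 | Fisher's-ratio screen (strict >) |
| `fr_min_header` | `"auto"` | header/helper split; auto = FR of the last minimum-scale gene, so headers coincide with the minimum-scale genes |
| `accuracy_threshold` | 85 (%) | retention cutoff for sampled networks |
| `n_samples` | 10⁵ | FRS/RS networks per run |
| `n_bags` | 1000 | holdout bags |
| `holdout_fraction` | 0.25 | validation share per bag (floor per class, min 1, ≥ 2 kept in training) |
| `knn_k` | 1 | neighbourhood size (odd) |
| `prefix_cap` | 200 | longest ranked prefix examined |

Network lengths default to [1, len(minimum-scale signature)].  For FRS the
upper bound is floored at 2 (when the pool allows): when a single gene
already attains the maximal accuracy the minimum-scale length is 1, and a
[1, 1] bound would reduce the sampler to repeatedly drawing one header —
no helper could ever be drawn, contradicting the sampler's defining
header+helper mixture.  The floor keeps the mixture realizable; RS keeps
the plain [1, len(mss)] bound since it has no header/helper structure.

Seeding: one integer seed spawns per-iteration substreams
(`numpy.random.SeedSequence`), so runs are bit-reproducible and
iteration-order independent.

## Synthetic data

The generator emulates the statistical skeleton of a two-class expression
study: independent Gaussian genes (sd `noise_sd`), a planted subset whose
class means differ by `effect_size · noise_sd` with alternating sign
(over/under-expression).  A planted gene's population Fisher's ratio is
analytically effect²/2, which the tests verify empirically at large n.  An
optional block-correlation mode gives planted genes a shared within-class
latent factor, making them partially interchangeable — the "equivalent
networks" phenomenon in miniature.  Default scale is 1000 genes × 80
samples (40 per class), 10 planted at effect size 3: it preserves the
genes ≫ samples regime at desk scale.

What the generator does *not* emulate: probe-level noise, batch effects,
heavy-tailed expression distributions, gene–gene correlation outside the
planted block, class imbalance beyond what the spec of a run sets.  Passing
recovery tests therefore demonstrate correctness of the machinery under the
idealised model, not performance on real microarray data.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on small fixtures (hundreds of genes, tens of
samples, ≤ 10⁴ draws).  The acceptance script runs the default synthetic
benchmark with 10⁴ FRS/RS networks and 1000 holdout bags, and averages
planted-gene recovery over three independent dataset realisations — at the
default strong effect size, per-bag holdout signatures are only 1–2 genes
long, so a single realisation's top-10 recovery varies noticeably
(typically 7–10 of 10); the three-realisation mean is the stable quantity.
The full 10⁵-draw setting is the library default and runs in a few minutes.

## Known limitations and open choices

- The per-draw header/helper counts of the FRS are uniform by choice; other
  mixtures (e.g. fixed header fraction) would concentrate the posterior
  differently.
- The holdout bags are stratified by class by default (unstratified mode is
  available) so that small classes survive in both splits.
- The loader performs no normalisation; an optional log2(x+1) transform and
  per-gene class-mean imputation are available behind flags.
- The RS pool applies both the fold-change and FR screens by default; a
  flag (`pool_fr_cutoff`) can restrict it to fold change only.
- No multiple-testing correction is applied in the screens — the samplers'
  retention step, not a per-gene p-value, is what controls false genes.
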
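# Methods

## Problem and model

Driver genes fall into two functional classes with distinct mutation-type
profiles: tumour suppressor genes (TSGs) are inactivated — truncating
mutations (nonsense, frameshift) and splice-site disruption dominate —
while oncogenes (OGs) are activated by recurrent missense mutations at a
few hotspot positions.  `ctag` encodes this contrast in 37 per-gene
features computed from a somatic mutation table and learns the mapping
from features to class on a catalogue of known drivers.  The classifier is
deliberately two-class: neutral genes are never labelled positively at
prediction time; they are filtered out by the top-percentile consensus
rule instead (see *Consensus calling*).

## Preprocessing

Input is a tab-separated mutation table (one row per mutation: sample,
gene, type annotation, coding position, alleles, somatic status, primary
tissue) with a configurable column dialect.  Steps, in order:

1. **Somatic-status filter** — only records whose status is in the accepted
   set (default `{"Confirmed somatic variant"}`) are kept.  The filter is
   applied to all record types, substitutions and indels alike.
2. **Hypermutator removal** — samples with *more than* 2,000 mutations are
   dropped entirely; a sample with exactly 2,000 is kept.  These samples'
   mutational noise would otherwise dominate per-gene counts.
3. **Splice re-annotation** — with an exon model available, any record at
   `exon_end+1`, `exon_end+2`, `exon_start−1` or `exon_start−2` (1-based
   inclusive coding coordinates; the convention is fixed here because
   border offsets are meaningless without one) is retyped `splicing`.
   Genes absent from the exon model are left untouched and counted in a
   provenance warning.
4. **Impact-score attachment** — PolyPhen2-style scores in [0, 1] are
   joined onto missense records by (gene, position, ref, alt); when a
   variant has several scores their arithmetic mean is attached.  Scores
   are never attached to non-missense records.
5. **Tissue restriction (optional)** — a tissue with ≤ 1,000 distinct
   samples yields an explicit "excluded" outcome rather than a table, so a
   thin cohort can never silently produce a feature matrix.

Gene identifiers are kept verbatim, including `gene_transcript` composites:
distinct transcripts are treated as distinct genes throughout.

## Features

Categories: the 11 base categories (silent, missense, splicing, HiFI,
MiFI, LoFI, nonsense, frameshift, inframe, nonstop, complex) and 4 derived
ones (`LOF`, `damaging`, `benign`, `compound`; definitions in the README).
Missense records with no impact score fall into MiFI by default — the
least-informative bin — with a `drop` mode that excludes them from the
impact bins instead.

The 37 columns comprise counts (`Total Missense`, `Total MiFI`, …),
per-kilobase rates (count / (length_bp/1000)), twelve ratio-metric
features, the mean impact score over scored missense records (0 when there
are none), three `X/Total` shares (plain division — the total is at least
1 for any gene in the matrix), and entropy / highest-identity-frequency
pairs for missense, frameshift, splicing and nonsense spectra.

Numerical choices:

* **Zero-denominator ratios** substitute `2·max(A)`, where `max(A)` is the
  maximum numerator count over the genes of the matrix *currently being
  built* (training matrix during training, prediction matrix during
  prediction).  This needs no stored state and keeps the substitute on the
  scale of the observed counts.
* **Entropy** uses the natural logarithm and is computed exactly as
  `log k − Σ f_i log f_i`.  Because `Σ f_i log f_i ≤ 0`, this equals
  `log k` *plus* the Shannon entropy and grows with the number of distinct
  identities; an alternative `deficit` mode (`log k` minus Shannon
  entropy, i.e. the concentration excess over a uniform spectrum) is
  available behind a flag but off by default.  The log base only rescales
  features and is irrelevant to tree models.  Both entropy and maximum
  frequency are 0 for an empty spectrum (k = 0).
* **`High X frequency`** is `max_i f_i`, the share of the most recurrent
  identity — the natural scalar summary of hotspot recurrence.
* Missense identities are (position, ref, alt) tuples; frameshift,
  splicing and nonsense identities are positions only.
* Genes enter the matrix only with ≥ 1 mutation and a known positive
  coding length; genes without a length are dropped with a warning.

## Labels, folds, standardisation

Driver labels come from a CGC-style catalogue; a gene is usable when its
role annotation names TSG or OG, is not fusion-associated, and is not
annotated as both classes (ambiguous genes are excluded with a warning).
Transcript-level matrix rows of a labelled gene do *not* inherit the label:
only exact identifier matches train the model, and transcripts join the
prediction pool — so per-transcript calls remain possible.

Cross-validation uses stratified folds that preserve the TSG:OG ratio to
within one gene per class; five folds give the 8:2 train:test split.  Fold
assignment is deterministic given the label set and a seed.

Features are standardised to zero mean and unit *population* standard
deviation (ddof = 0; the choice is arbitrary but fixed), with the moments
estimated on the training split only.  A zero-variance feature is flagged
and its divisor replaced by 1, turning it into a centred constant.  Each
fold model stores its own training-split moments and applies them to
anything it later scores, including tissue matrices — the model's input
distribution is thereby the one it was fitted on.

## Hyperparameter stability selection

Grid: `n_estimators ∈ {5,10,…,40}` (the published range is 5–40; a step
of 5 keeps the grid at 96 points and is configurable), `max_features ∈
{sqrt, log2}`, `max_depth ∈ {2,3,4}`, `criterion ∈ {gini, entropy}`.

One grid search = exhaustive evaluation of all 96 points by stratified
fivefold CV on accuracy, fully seeded.  The search is repeated under
`n_seeds` random seeds (default 10); the `n_estimators` value recurring
most often among per-seed winners is selected, with count ties broken by
the higher best inner-CV accuracy and then by the smaller tree count;
among the runs whose winner carries the selected tree count, the grid
point with maximal accuracy is returned.  Small training sets make a
single grid search seed-sensitive; the recurrence vote removes that
sensitivity, and the resulting small, shallow forests trade a little
training accuracy for a much smaller train-to-test gap than an
unconstrained forest (500 trees, unlimited depth) shows on identical
folds.

Implementation note: grid evaluation grows each forest tree by tree,
replaying `RandomForestClassifier`'s exact per-tree seeding and bootstrap
draws, and scores every tree-count checkpoint from cumulative per-tree
probabilities.  This is provably identical to fitting each grid point from
scratch (a test asserts exact agreement with naive per-point forest fits)
at about a fifth of the cost; a public-API warm-start fallback handles any
future change to those internals.

All randomness in `train_ensemble` — outer fold assignment, the per-fold
seed lists, the final forest fits — derives from one `master_seed`, so a
training run is replayable from a single integer.

Feature importances are impurity-based (the forest's native measure);
features are ranked 1–37 per fold (ties share their average rank) and
reported as the mean rank across the five fold models.

## Consensus calling

Each fold model scores every gene in the prediction pool with TSG and OG
probabilities.  Per model and class, the candidate cutoff is the
(100 − p)-th linear-interpolation percentile (default p = 5) of that
class's probabilities over the pool; a model nominates a gene for its
argmax class only (a 0.5/0.5 tie nominates nothing).  A gene is labelled
when at least `min_models` models nominate the same class — all five by
default, with 4 and 3 available to reproduce relaxed lists.  Raising
`min_models` or shrinking the percentile can only remove calls, never add
them.

The percentile pool is the supplied prediction matrix only; training genes
are not re-scored alongside candidates.  Tissue-specific prediction
rebuilds the 37-feature matrix from one tissue's mutations (per-matrix
ratio maxima recomputed), drops the ensemble's training genes from the
pool, applies each fold model's stored standardisation, and runs the same
consensus rule.

## Evaluation utilities

Per-class metrics are one-vs-rest confusion-table identities (accuracy,
precision, recall, F1 as the harmonic mean); zero-denominator quotients
are reported as 0 and flagged.  In the two-class setting the one-vs-rest
accuracies of TSG and OG coincide by symmetry.  Mutation-rate
distributions of two gene sets are compared with the two-sample
Kolmogorov–Smirnov statistic (asymptotic p-value by default, exact mode
optional) and cumulative-fraction curves over log₁₀ rates.  The package
does not estimate background mutation rates; any external per-gene rate
vector can be supplied, and a self-contained fallback (mutations per gene
per sample per kb) serves the synthetic fixtures.

## Synthetic cohorts

The generator targets the sufficient statistics of the features, not
empirical mutational signatures (no trinucleotide context, no real
mutation-type proportions).  Defaults define the strong-signal study
cohort: 100 TSG-like, 60 OG-like and 500 neutral genes over 1,000 samples;
coding lengths log-normal around 1.5 kb; a background of 0.02 mutations
per gene per sample at 1.5 kb, length-scaled, with 25 % log-normal
per-gene rate noise; drivers mutated at twice the background.

* **Neutral genes** draw mostly silent (40 %) and missense (50 %)
  mutations at uniform positions; their missense scores come from a
  low-skew Beta(2, 25), mostly below the 0.15 LoFI threshold.
* **TSG-like genes** shift half their mass to truncating and splice types
  (nonsense 28 %, frameshift 22 %, splicing 8 %), with half of the
  truncations recurring at four per-gene sites and missense scores from
  Beta(4, 2).
* **OG-like genes** are missense-dominated (75 %); 70 % of their missense
  load lands on three hotspot (position, ref, alt) identities with
  Dirichlet(0.4) weights and high-skew Beta(40, 3) scores (mostly above
  the 0.85 HiFI threshold).
* **Penetrance.**  Each driver draws p ~ Beta(2.5, 1.5) and emits a
  p-weighted mixture of its class mixture and the neutral mixture (hotspot
  and recurrence shares scale with p).  Without this, every driver is a
  textbook case, the classes separate perfectly and the overfitting
  contrast between the stability-selected and the unconstrained forest
  becomes vacuous; with it the cohort contains weak, hard-to-call drivers,
  as real cohorts do.
* **Options** exercise the preprocessing paths: hypermutator samples
  topped up beyond the 2,000-mutation threshold, and a tissue-private TSG
  whose driver composition appears only in its host tissue while a heavy
  passenger load elsewhere dilutes its pan-cancer profile (the
  tissue-specific discovery scenario).

Because mutation burden inflates the printed entropy (it grows with the
number of distinct identities), the generator's hotspot effect on entropy
is demonstrated at a matched mutation rate; at the default 2× driver rate
the recurrence signal appears in `High Missense frequency` instead.  What
passing tests on these cohorts show is that the pipeline recovers the
compositional and recurrence signals it models; they say nothing about
annotation noise, subclonal structure, coverage bias or signature-driven
hotspots in real data.

## Problem sizes and runtimes

The test suite trains ensembles on the default 660-gene cohort with
stability seed sets of 10, 20 and 40 (the robustness check), and the
acceptance script uses seed sets of 10 and 20; one grid search costs a few
seconds on one CPU, so these runs complete in minutes.  Smaller cohorts
(≈ 120 genes, 150–400 samples) back the determinism, CLI and
tissue-discovery tests.

## Known limitations

* Two-class design: a gene genuinely neither TSG nor OG can only be
  protected by the consensus rule, not modelled.
* The unscored-missense default (MiFI) biases the damaging count upward
  in cohorts with sparse score coverage; use `drop` mode there.
* The printed entropy convention conflates recurrence with burden (see
  above); both conventions are computed, only the default is used by the
  shipped feature set.
* The generator's independence assumptions (Poisson counts, independent
  positions) make its cohorts easier than real data at equal signal
  strength.
* On the strong-signal cohort even the unconstrained 500-tree comparator
  generalises well (held-out accuracy ≈ 0.95), so its train-test gap
  exceeds the stability ensemble's only modestly and the contrast varies
  with the random seed.  The regime where stability selection pays off
  decisively is the harder, heavily overlapping one real cohorts occupy;
  the synthetic contrast should be read as directional, not as an effect
  size.
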
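# ctag — classify tumour suppressor genes and oncogenes

`ctag` identifies cancer driver genes from somatic mutation tables and
assigns them to the two functional driver classes: **tumour suppressor
genes (TSGs)**, which are inactivated by truncating mutations, and
**oncogenes (OGs)**, which are activated by recurrent missense mutations at
hotspots.  It is aimed at cancer genomicists who have per-sample somatic
mutation calls (COSMIC-style exports) and want a ranked, class-labelled
shortlist of candidate drivers — including low-mutation-rate genes that
frequency-based callers miss — at pan-cancer or per-tissue level.

## The method

Rather than testing mutation *rates* against a background model, `ctag`
summarises each gene's mutation *composition* and *recurrence* into 37
features and learns the TSG/OG signatures from known drivers:

* **Mutation categories.**  Mutations are binned into 11 base categories —
  silent, missense, splicing, nonsense, frameshift, in-frame, nonstop,
  complex, and the missense impact bins HiFI (score ≥ 0.85), MiFI and LoFI
  (score ≤ 0.15) from PolyPhen2-style scores — plus four derived
  categories:

  ```
  LOF      = nonsense + frameshift
  damaging = HiFI + MiFI
  benign   = silent + LoFI
  compound = missense + complex + inframe + nonstop − LoFI
  ```

* **Ratio-metric features.**  For categories A, B of gene g:

  ```
  ratio(A/B)_g = A_g / B_g        if B_g ≠ 0
               = 2 · max(A)       if B_g = 0
  ```

  with max(A) over the genes of the matrix being built.

* **Recurrence features.**  Within a gene, each distinct mutation identity
  M (a (position, ref, alt) tuple for missense; the position for nonsense,
  frameshift and splicing) has frequency `f_i = n_M / n`.  With k distinct
  identities,

  ```
  S = Σ_i f_i log f_i        Entropy = log k − S
  ```

  and `High X frequency = max_i f_i`.  Recurrent hotspots give low entropy
  and a high maximum frequency.

* **Classifier.**  A five-fold cross-validated random-forest ensemble
  (TSG:OG ratio preserved in every split).  Hyperparameters
  (`n_estimators` 5–40, `max_features` sqrt/log2, `max_depth` 2–4,
  `criterion` gini/entropy) are chosen by a *stability* procedure: the
  inner fivefold grid search is repeated under many random seeds, the
  modal `n_estimators` across seeds is kept, and the accuracy-best grid
  point among those runs wins.  This deliberately small forest avoids the
  overfitting an unconstrained forest exhibits on a ~200-gene training
  set.

* **Consensus prediction.**  Every fold model scores every unlabelled
  gene; a model nominates a gene when its argmax-class probability reaches
  the top 5 percentile of that class.  A gene is called TSG or OG only
  when enough models (default all five; four reproduces the relaxed
  published lists) agree — everything else stays unlabelled, reflecting
  that most mutated genes are passengers.

A synthetic-cohort generator (`ctag.simulate_cohort`) plants TSG-like,
OG-like and neutral genes with known truth so the whole pipeline is
testable without any external download.

## Worked example

```python
import ctag

config = ctag.CohortConfig(n_tsg=25, n_og=15, n_neutral=80, n_samples=250, seed=7)
bundle = ctag.simulate_cohort(config)
matrix = ctag.featurize(bundle.mutations, bundle.lengths, scores=bundle.scores)
roles = bundle.truth.set_index("gene_id")["role"].reindex(matrix.genes)
print(matrix.df["LOF/Benign"].groupby(roles).mean().round(3))
```

prints

```
role
OG         1.191
TSG        1.706
neutral    0.456
```

— planted TSGs carry about four times the loss-of-function load of neutral
genes relative to their benign mutations, the signature the classifier
exploits.  Training and calling drivers:

```python
ensemble = ctag.train_ensemble(matrix, bundle.label_set(), n_seeds=5, master_seed=1)
print(ctag.rank_features(ensemble).head(3).to_string(index=False))
```

```
       feature  average_rank
     LOF/Total           3.6
Missense/Total           4.6
   Damaging/kb           8.6
```

The same steps are available from the shell
(`ctag simulate | featurize | train | predict | predict-tissue`), and the
scripts in `examples/` walk through each capability: feature separation,
training and feature ranking, consensus driver discovery, and
tissue-specific prediction of a driver the pan-cancer run misses.

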
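"""Consensus TSG/OG calling from the cross-validation ensemble.

Every fold model scores every gene of a prediction matrix with TSG and OG
probabilities.  Within each model and class, the top-percentile cutoff
(default: top 5 percent) is taken over that class's probabilities across the
scored genes; a model nominates a gene for its argmax class when the
probability meets the cutoff.  A gene receives a final label only when at
least ``min_models`` models nominate the same class; everything else stays
unlabelled, reflecting that most mutated genes are neither TSGs nor OGs.

Tissue-specific discovery applies the same pan-cancer ensemble to a feature
matrix rebuilt from one primary tissue's mutations (subject to the
minimum-sample gate), surfacing drivers whose signal is diluted in the
pan-cancer pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix, build_feature_matrix
from .io import MutationTable, TissueExcluded, ValidationError, filter_by_tissue
from .labels import apply_standardiser
from .training import Ensemble

CLASSES = ("TSG", "OG")


@dataclass
class ProbabilityTable:
    """Per-gene, per-model class probabilities.

    ``probs`` has a two-level column index (model index, class); rows with
    any non-finite feature were rejected before scoring and are listed in
    ``rejected``.
    """

    probs: pd.DataFrame
    rejected: list[str] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.probs.columns.levels[0])

    def model_probs(self, model: int) -> pd.DataFrame:
        return self.probs[model]


def predict_probabilities(ensemble: Ensemble, matrix: FeatureMatrix) -> ProbabilityTable:
    """Score a feature matrix with every fold model of the ensemble.

    Each model standardises the matrix with its own training statistics.
    Raises on a feature-name mismatch; rows containing non-finite values are
    dropped and reported.
    """
    have = list(matrix.df.columns)
    want = ensemble.feature_names
    if have != want:
        missing = sorted(set(want) - set(have))
        extra = sorted(set(have) - set(want))
        raise ValidationError(
            f"feature mismatch: missing {missing}, unexpected {extra}"
        )
    values = matrix.df.to_numpy(dtype=float)
    finite = np.isfinite(values).all(axis=1)
    rejected = sorted(matrix.df.index[~finite])
    df = matrix.df[finite]
    blocks = {}
    for m, fm in enumerate(ensemble.fold_models):
        std = apply_standardiser(df, fm.stats)
        p = fm.predict_proba(std)
        for cls in CLASSES:
            blocks[(m, cls)] = p[cls]
    probs = pd.DataFrame(blocks, index=df.index)
    probs.columns = pd.MultiIndex.from_tuples(probs.columns, names=["model", "class"])
    return ProbabilityTable(probs, rejected)


@dataclass
class ConsensusPrediction:
    """Final consensus labels with per-model nominations.

    ``table`` columns: ``label`` (TSG/OG/unlabelled), ``consensus`` (number
    of models nominating the winning class), ``mean_probability`` (mean
    winning-class probability over all models), plus the per-model class
    probabilities.
    """

    table: pd.DataFrame
    percentile: float
    min_models: int
    n_models: int

    def labelled(self) -> pd.DataFrame:
        return self.table[self.table["label"] != "unlabelled"]

    def genes_labelled(self, cls: str) -> pd.Index:
        return self.table.index[self.table["label"] == cls]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def consensus_labels(
    probs: ProbabilityTable | pd.DataFrame,
    percentile: float = 5.0,
    min_models: int | None = None,
) -> ConsensusPrediction:
    """Assign consensus labels from per-model probabilities.

    Per model and class, the candidate cutoff is the (100 - percentile)-th
    linear-interpolation percentile of that class's probabilities over the
    scored genes; a gene is a model's candidate for its argmax class only (a
    0.5/0.5 tie nominates nothing).  A final label requires at least
    ``min_models`` (default: all) models to nominate the same class.
    """
    table = probs.probs if isinstance(probs, ProbabilityTable) else probs
    if not 0 < percentile < 100:
        raise ValidationError("percentile must lie strictly between 0 and 100")
    models = list(table.columns.levels[0])
    n_models = len(models)
    if min_models is None:
        min_models = n_models
    if not 1 <= min_models <= n_models:
        raise ValidationError("min_models must lie in 1..n_models")

    if len(table) == 0:
        empty = pd.DataFrame(
            columns=["label", "consensus", "mean_probability"], index=table.index
        )
        return ConsensusPrediction(empty, percentile, min_models, n_models)

    nominations = {cls: np.zeros(len(table), dtype=int) for cls in CLASSES}
    for m in models:
        p_tsg = table[(m, "TSG")].to_numpy(dtype=float)
        p_og = table[(m, "OG")].to_numpy(dtype=float)
        for cls, p_cls, p_other in (("TSG", p_tsg, p_og), ("OG", p_og, p_tsg)):
            cutoff = np.percentile(p_cls, 100.0 - percentile)
            nominations[cls] += (p_cls > p_other) & (p_cls >= cutoff)

    n_tsg, n_og = nominations["TSG"], nominations["OG"]
    label = np.where(
        n_tsg >= min_models, "TSG", np.where(n_og >= min_models, "OG", "unlabelled")
    )
    consensus = np.where(label == "OG", n_og, n_tsg)
    consensus = np.where(label == "unlabelled", np.maximum(n_tsg, n_og), consensus)

    mean_tsg = table.xs("TSG", axis=1, level="class").mean(axis=1).to_numpy()
    mean_og = table.xs("OG", axis=1, level="class").mean(axis=1).to_numpy()
    mean_prob = np.where(label == "OG", mean_og, mean_tsg)
    mean_prob = np.where(
        label == "unlabelled", np.maximum(mean_tsg, mean_og), mean_prob
    )

    out = pd.DataFrame(
        {
            "label": label,
            "consensus": consensus.astype(int),
            "mean_probability": mean_prob,
        },
        index=table.index,
    )
    flat = table.copy()
    flat.columns = [f"model{m}_{cls}" for m, cls in table.columns]
    out = pd.concat([out, flat], axis=1)
    return ConsensusPrediction(out, percentile, min_models, n_models)


def tissue_specific_predict(
    ensemble: Ensemble,
    mutations: MutationTable,
    tissue: str,
    lengths: pd.Series,
    percentile: float = 5.0,
    min_models: int | None = None,
    min_samples: int = 1000,
    unscored: str = "mifi",
    exclude_training: bool = True,
) -> ConsensusPrediction | TissueExcluded:
    """Consensus predictions on the feature matrix of one primary tissue.

    The mutation table is restricted to the tissue (an explicit exclusion
    outcome is returned when the tissue fails the sample gate), the
    37-feature matrix is rebuilt on the subset (per-matrix ratio maxima
    recomputed), and the pan-cancer ensemble scores it with its stored
    standardisation statistics.  Genes the ensemble trained on are dropped
    from the prediction pool by default, so the top-percentile cutoffs are
    taken over unlabelled candidates only.
    """
    subset = filter_by_tissue(mutations, tissue, min_samples=min_samples)
    if isinstance(subset, TissueExcluded):
        return subset
    matrix = build_feature_matrix(subset, lengths, unscored=unscored)
    if exclude_training:
        trained = ensemble.labelled_genes()
        pool = [g for g in matrix.df.index if g not in trained]
        matrix = FeatureMatrix(
            matrix.df.loc[pool], matrix.length_kb.loc[pool], matrix.dropped
        )
    probs = predict_probabilities(ensemble, matrix)
    return consensus_labels(probs, percentile=percentile, min_models=min_models)
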
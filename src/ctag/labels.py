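"""Training labels, ratio-preserving cross-validation folds and standardisation.

Labels come from a CGC-style catalogue restricted to the two driver classes:
a gene is usable when its role annotation names exactly one of TSG or OG and
is not fusion-associated.  Cross-validation folds are stratified so every
fold preserves the global TSG:OG ratio to within one gene per class, giving
the 8:2 train:test split at five folds.  Standardisation statistics (per
feature mean and population standard deviation) are fitted on a training
matrix and reused verbatim for any prediction matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix
from .io import ValidationError

CLASSES = ("TSG", "OG")


@dataclass
class LabelSet:
    """gene_id -> {TSG, OG} mapping with a provenance note."""

    labels: pd.Series
    provenance: str = ""

    def __post_init__(self):
        bad = set(self.labels.unique()) - set(CLASSES)
        if bad:
            raise ValidationError(f"labels restricted to {CLASSES}; got {sorted(bad)}")
        self.labels = self.labels.sort_index()

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def genes(self) -> pd.Index:
        return self.labels.index

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts()

    def restrict(self, genes) -> "LabelSet":
        keep = self.labels.index.intersection(genes)
        return LabelSet(self.labels.loc[keep], self.provenance + " (restricted)")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"gene_id": self.labels.index, "role": self.labels.to_numpy()}).to_csv(
            path, sep="\t", index=False
        )


def _parse_role(role: str) -> str | None:
    """Extract a usable class from a free-text role annotation.

    Fusion-associated genes and genes annotated as both TSG and OG yield
    ``None`` (excluded).
    """
    tokens = role.upper()
    if "FUSION" in tokens:
        return None
    is_tsg = "TSG" in tokens
    is_og = "OG" in tokens.replace("TSG", "")  # do not let "TSG" shadow "OG"
    if is_tsg and is_og:
        return None
    if is_tsg:
        return "TSG"
    if is_og:
        return "OG"
    return None


def load_labels(source) -> LabelSet:
    """Load a driver-gene catalogue (TSV: gene_id, role) into a :class:`LabelSet`.

    Keeps genes whose role names TSG or OG and not Fusion; ambiguous genes
    (both TSG and OG) are excluded with a warning.
    """
    if isinstance(source, pd.DataFrame):
        df = source
        origin = "dataframe"
    else:
        df = pd.read_csv(source, sep="\t")
        origin = str(source)
    if df.shape[1] < 2:
        raise ValidationError("label table needs gene and role columns")
    gene_col, role_col = df.columns[:2]
    parsed = df[role_col].astype(str).map(_parse_role)
    ambiguous = df[
        parsed.isna()
        & df[role_col].str.upper().str.contains("TSG")
        & df[role_col].str.upper().str.replace("TSG", "", regex=False).str.contains("OG")
        & ~df[role_col].str.upper().str.contains("FUSION")
    ]
    if len(ambiguous):
        warnings.warn(
            f"{len(ambiguous)} genes annotated both TSG and OG excluded: "
            f"{sorted(ambiguous[gene_col])}"
        )
    keep = parsed.notna()
    if not keep.any():
        raise ValidationError(f"no usable TSG/OG labels in {origin}")
    labels = pd.Series(
        parsed[keep].to_numpy(), index=df.loc[keep, gene_col], name="role"
    )
    labels = labels[~labels.index.duplicated()]
    counts = labels.value_counts().to_dict()
    return LabelSet(labels, f"loaded from {origin}: {counts}")


def training_pool_split(genes, labels: LabelSet) -> tuple[list[str], list[str]]:
    """Split matrix genes into training genes and the prediction pool.

    Only rows whose identifier exactly matches a labelled gene train the
    model; transcript-level rows of labelled genes (``symbol_transcript``)
    and all unlabelled genes go to the prediction pool.
    """
    labelled = set(labels.genes)
    train = [g for g in genes if g in labelled]
    pool = [g for g in genes if g not in labelled]
    return train, pool


@dataclass
class FoldAssignment:
    """Partition of the labelled genes into k stratified folds."""

    fold: pd.Series  # gene_id -> fold index
    k_folds: int

    def __post_init__(self):
        if set(self.fold.unique()) - set(range(self.k_folds)):
            raise ValidationError("fold indices out of range")

    def test_genes(self, i: int) -> pd.Index:
        return self.fold.index[self.fold == i]

    def train_genes(self, i: int) -> pd.Index:
        return self.fold.index[self.fold != i]

    def class_counts(self, labels: LabelSet) -> pd.DataFrame:
        return pd.crosstab(self.fold, labels.labels.loc[self.fold.index])


def stratified_folds(labels: LabelSet, k_folds: int = 5, seed: int = 0) -> FoldAssignment:
    """Deterministic stratified k-fold assignment preserving the TSG:OG ratio.

    Per-fold class counts differ from class_size / k by at most one gene.
    Genes are processed in sorted order, so the assignment depends only on
    the label set and the seed.
    """
    counts = labels.class_counts()
    small = counts[counts < k_folds]
    if len(small):
        raise ValidationError(
            f"classes smaller than k_folds={k_folds}: {small.to_dict()}"
        )
    genes = np.array(sorted(labels.genes))
    y = labels.labels.loc[genes].to_numpy()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold = np.empty(len(genes), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(genes, y)):
        fold[test_idx] = i
    return FoldAssignment(pd.Series(fold, index=genes, name="fold"), k_folds)


@dataclass
class StandardisationStats:
    """Per-feature mean and population standard deviation from a training matrix."""

    mean: pd.Series
    sd: pd.Series
    zero_variance: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def fit_standardiser(matrix: FeatureMatrix | pd.DataFrame) -> StandardisationStats:
    """Estimate per-feature mean and population sd; zero-variance features are flagged
    and their sd replaced by 1 so they standardise to a centred constant."""
    df = matrix.df if isinstance(matrix, FeatureMatrix) else matrix
    if len(df) == 0:
        raise ValidationError("cannot standardise an empty matrix")
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    zero = sorted(sd.index[sd == 0.0])
    sd = sd.mask(sd == 0.0, 1.0)
    return StandardisationStats(mean, sd, zero)


def apply_standardiser(
    matrix: FeatureMatrix | pd.DataFrame, stats: StandardisationStats
) -> pd.DataFrame:
    """Transform each feature to (x - mean) / sd using fitted statistics."""
    df = matrix.df if isinstance(matrix, FeatureMatrix) else matrix
    if list(df.columns) != list(stats.mean.index):
        raise ValidationError("feature columns do not match standardisation stats")
    return (df - stats.mean) / stats.sd
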
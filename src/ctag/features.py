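"""The 37-feature engine: ratio-metric, entropy and frequency features per gene.

Somatic mutations are tallied into 11 base categories (silent, missense,
splicing, HiFI, MiFI, LoFI, nonsense, frameshift, inframe, nonstop, complex)
and 4 derived categories:

    compound = missense + complex + inframe + nonstop - LoFI
    LOF      = nonsense + frameshift
    damaging = HiFI + MiFI
    benign   = silent + LoFI

HiFI/MiFI/LoFI bin missense mutations by their functional-impact score
(>= 0.85 / between / <= 0.15).  Ratio features of two categories A and B use

    ratio(A/B) = A_g / B_g          if B_g != 0
               = 2 * max(A)         if B_g == 0

with max(A) taken over the genes of the matrix being built.  Recurrence is
captured per mutation type by frequency and entropy statistics over distinct
mutation identities: a missense identity is the (position, ref, alt) tuple,
while nonsense, frameshift and splicing identities are the position alone.
With ``f_i = n_M / n`` the identity frequencies, the dispersion statistic is

    S = sum_i f_i log f_i,      entropy = log k - S    (natural log)

so a gene with a single recurrent identity scores 0 and a gene with k
uniformly spread identities scores 2 log k.  "High X frequency" is the share
of the most recurrent identity, max_i f_i.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MutationTable, ValidationError

#: Score thresholds binning missense mutations by functional impact.
HIFI_THRESHOLD = 0.85
LOFI_THRESHOLD = 0.15

#: Features carried over from the ratio-metric literature (18).
LITERATURE_FEATURES = [
    "Silent/kb",
    "Total Missense",
    "Total Splicing",
    "Total LOF",
    "Missense/kb",
    "LOF/kb",
    "LOF/Silent",
    "Splicing/Silent",
    "Missense/Silent",
    "LOF/Benign",
    "Splicing/Benign",
    "Missense/Benign",
    "average Polyphen2 score",
    "LOF/Total",
    "Missense/Total",
    "Splicing/Total",
    "LOF/Missense",
    "Missense entropy",
]

#: Newly defined features (19).
NOVEL_FEATURES = [
    "HiFI/LoFI",
    "HiFI/Benign",
    "MiFI/kb",
    "Nonstop/kb",
    "Inframe/kb",
    "Complex/kb",
    "Compound/Benign",
    "Compound/kB",
    "Damaging/kb",
    "Damaging/Benign",
    "Damaging/LoFI",
    "High Missense frequency",
    "Frameshift entropy",
    "High Frameshift frequency",
    "Splicing entropy",
    "High Splicing frequency",
    "Nonsense entropy",
    "High Nonsense frequency",
    "Total MiFI",
]

#: All 37 feature names, in canonical column order.
FEATURE_NAMES = LITERATURE_FEATURES + NOVEL_FEATURES

#: Ratio features and their (numerator, denominator) categories.  The
#: zero-denominator branch substitutes 2 * max(numerator) over the matrix.
RATIO_FEATURES = {
    "LOF/Silent": ("LOF", "silent"),
    "Splicing/Silent": ("splicing", "silent"),
    "Missense/Silent": ("missense", "silent"),
    "LOF/Benign": ("LOF", "benign"),
    "Splicing/Benign": ("splicing", "benign"),
    "Missense/Benign": ("missense", "benign"),
    "LOF/Missense": ("LOF", "missense"),
    "HiFI/LoFI": ("HiFI", "LoFI"),
    "HiFI/Benign": ("HiFI", "benign"),
    "Compound/Benign": ("compound", "benign"),
    "Damaging/Benign": ("damaging", "benign"),
    "Damaging/LoFI": ("damaging", "LoFI"),
}

#: Per-kilobase features and their category.  "Compound/kB" keeps the
#: canonical (idiosyncratic) capitalisation of its published name.
PER_KB_FEATURES = {
    "Silent/kb": "silent",
    "Missense/kb": "missense",
    "LOF/kb": "LOF",
    "MiFI/kb": "MiFI",
    "Nonstop/kb": "nonstop",
    "Inframe/kb": "inframe",
    "Complex/kb": "complex",
    "Compound/kB": "compound",
    "Damaging/kb": "damaging",
}

#: Mutation types with entropy/frequency statistics and their identity columns.
SPECTRUM_TYPES = {
    "missense": ["position", "ref_allele", "alt_allele"],
    "frameshift": ["position"],
    "splicing": ["position"],
    "nonsense": ["position"],
}

_BASE_CATEGORIES = [
    "silent",
    "missense",
    "splicing",
    "HiFI",
    "MiFI",
    "LoFI",
    "nonsense",
    "frameshift",
    "inframe",
    "nonstop",
    "complex",
]


def categorize_missense(score: float | None) -> str:
    """Bin a missense impact score into HiFI (>= 0.85), LoFI (<= 0.15) or MiFI.

    An absent score falls into MiFI, the least-informative bin.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return "MiFI"
    if score >= HIFI_THRESHOLD:
        return "HiFI"
    if score <= LOFI_THRESHOLD:
        return "LoFI"
    return "MiFI"


def ratio_feature(a_count: float, b_count: float, max_a: float) -> float:
    """Ratio of category counts with the zero-denominator substitute 2*max_a."""
    if b_count != 0:
        return a_count / b_count
    return 2.0 * max_a


def per_kb(count: float, length_bp: float) -> float:
    """Count normalised per kilobase of coding sequence."""
    if length_bp <= 0:
        raise ValidationError("length_bp must be positive")
    return count / (length_bp / 1000.0)


def entropy_features(counts) -> tuple[float, float]:
    """Entropy and highest identity frequency for one gene and mutation type.

    ``counts`` are the occurrence counts n_M of the k distinct identities.
    Returns ``(log k - sum f_i log f_i, max_i f_i)``; both are 0 when k = 0.
    """
    counts = [int(c) for c in counts]
    if any(c < 1 for c in counts):
        raise ValidationError("identity counts must be >= 1")
    k = len(counts)
    if k == 0:
        return 0.0, 0.0
    n = sum(counts)
    f = [c / n for c in counts]
    s = sum(fi * math.log(fi) for fi in f)
    return math.log(k) - s, max(f)


def count_categories(table: MutationTable, unscored: str = "mifi") -> pd.DataFrame:
    """Tally the 11 base and 4 derived mutation categories per gene.

    ``unscored`` controls missense records without an impact score:
    ``"mifi"`` (default) bins them as MiFI, ``"drop"`` leaves them out of the
    impact bins (they still count as missense).  Genes with zero records are
    absent from the result.  The ``total`` column is the gene's overall
    record count, used as the denominator of the X/Total features.
    """
    if unscored not in ("mifi", "drop"):
        raise ValidationError("unscored must be 'mifi' or 'drop'")
    df = table.df
    cat = df["mutation_type"].copy()
    is_mis = cat == "missense"
    score = df["impact_score"]
    bins = pd.Series("MiFI", index=df.index, dtype=object)
    bins[score >= HIFI_THRESHOLD] = "HiFI"
    bins[score <= LOFI_THRESHOLD] = "LoFI"
    if unscored == "drop":
        bins[score.isna()] = None
    impact = cat.where(~is_mis, bins)

    counts = (
        pd.crosstab(df["gene_id"], impact)
        .reindex(index=pd.Index(sorted(df["gene_id"].unique()), name="gene_id"),
                 columns=["silent", "splicing", "HiFI", "MiFI", "LoFI",
                          "nonsense", "frameshift", "inframe", "nonstop", "complex"],
                 fill_value=0)
        .fillna(0)
    )
    counts.insert(1, "missense", df[is_mis].groupby("gene_id").size()
                  .reindex(counts.index, fill_value=0))
    counts = counts[_BASE_CATEGORIES].astype(int)
    counts["LOF"] = counts["nonsense"] + counts["frameshift"]
    counts["damaging"] = counts["HiFI"] + counts["MiFI"]
    counts["benign"] = counts["silent"] + counts["LoFI"]
    counts["compound"] = (
        counts["missense"] + counts["complex"] + counts["inframe"]
        + counts["nonstop"] - counts["LoFI"]
    )
    counts["total"] = df.groupby("gene_id").size().reindex(counts.index, fill_value=0)
    counts.index.name = "gene_id"
    return counts.sort_index()


def _spectrum_stats(df: pd.DataFrame, mtype: str, entropy_mode: str) -> pd.DataFrame:
    """Per-gene entropy and high-frequency statistics for one mutation type."""
    keys = SPECTRUM_TYPES[mtype]
    sub = df[df["mutation_type"] == mtype]
    if len(sub) == 0:
        return pd.DataFrame(columns=["entropy", "high_frequency"], dtype=float)
    ident = sub.groupby(["gene_id", *keys]).size().rename("n_M").reset_index()
    grp = ident.groupby("gene_id")["n_M"]
    n = grp.sum()
    k = grp.size()
    f = ident["n_M"] / ident["gene_id"].map(n)
    s = (f * np.log(f)).groupby(ident["gene_id"]).sum()
    if entropy_mode == "printed":
        entropy = np.log(k) - s
    else:  # deficit from the uniform spectrum: log k minus Shannon entropy
        entropy = np.log(k) + s
    high = grp.max() / n
    return pd.DataFrame({"entropy": entropy, "high_frequency": high})


@dataclass
class FeatureMatrix:
    """Genes x 37 feature table plus per-gene coding length metadata (kb)."""

    df: pd.DataFrame
    length_kb: pd.Series
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self):
        if list(self.df.columns) != FEATURE_NAMES:
            raise ValidationError(
                "feature matrix must carry exactly the 37 canonical columns"
            )
        if not np.isfinite(self.df.to_numpy(dtype=float)).all():
            raise ValidationError("feature matrix contains non-finite entries")

    @property
    def genes(self) -> pd.Index:
        return self.df.index

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path, lengths: pd.Series | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t").set_index("gene_id")
        if lengths is None:
            lengths = pd.Series(np.nan, index=df.index)
        return cls(df[FEATURE_NAMES].astype(float), lengths.reindex(df.index) / 1000.0)


def build_feature_matrix(
    table: MutationTable,
    lengths: pd.Series,
    unscored: str = "mifi",
    entropy_mode: str = "printed",
) -> FeatureMatrix:
    """Build the genes x 37 feature matrix from a preprocessed mutation table.

    One row per mutated gene with a known coding length; genes missing from
    ``lengths`` are dropped with a warning.  All zero-denominator ratio
    branches use the maximum numerator count over the genes of *this* matrix.

    ``entropy_mode="printed"`` (default) computes ``log k - sum f log f``;
    ``"deficit"`` computes ``log k`` minus the Shannon entropy instead.
    """
    if entropy_mode not in ("printed", "deficit"):
        raise ValidationError("entropy_mode must be 'printed' or 'deficit'")
    counts = count_categories(table, unscored=unscored)
    if counts.empty:
        raise ValidationError("no genes with mutations: empty feature matrix")
    lengths = pd.Series(lengths)
    known = counts.index.intersection(lengths.dropna().index)
    dropped = sorted(set(counts.index) - set(known))
    if dropped:
        warnings.warn(
            f"{len(dropped)} genes without coding length dropped from feature matrix"
        )
    counts = counts.loc[known]
    if counts.empty:
        raise ValidationError("no genes with mutations and known length")
    length_bp = lengths.loc[counts.index].astype(float)
    if (length_bp <= 0).any():
        bad = sorted(length_bp.index[length_bp <= 0])
        raise ValidationError(f"non-positive gene lengths: {bad}")
    length_kb = length_bp / 1000.0

    df = table.df[table.df["gene_id"].isin(counts.index)]
    out = pd.DataFrame(index=counts.index)

    out["Silent/kb"] = counts["silent"] / length_kb
    out["Total Missense"] = counts["missense"]
    out["Total Splicing"] = counts["splicing"]
    out["Total LOF"] = counts["LOF"]
    for name, cat in PER_KB_FEATURES.items():
        out[name] = counts[cat] / length_kb
    for name, (a, b) in RATIO_FEATURES.items():
        max_a = counts[a].max()
        a_cnt = counts[a].to_numpy(dtype=float)
        b_cnt = counts[b].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(b_cnt != 0, a_cnt / np.where(b_cnt != 0, b_cnt, 1.0),
                            2.0 * max_a)
        out[name] = vals

    mis = df[(df["mutation_type"] == "missense") & df["impact_score"].notna()]
    avg_score = mis.groupby("gene_id")["impact_score"].mean()
    out["average Polyphen2 score"] = avg_score.reindex(counts.index).fillna(0.0)

    total = counts["total"].astype(float)
    out["LOF/Total"] = counts["LOF"] / total
    out["Missense/Total"] = counts["missense"] / total
    out["Splicing/Total"] = counts["splicing"] / total

    for mtype, prefix in (
        ("missense", "Missense"),
        ("frameshift", "Frameshift"),
        ("splicing", "Splicing"),
        ("nonsense", "Nonsense"),
    ):
        stats = _spectrum_stats(df, mtype, entropy_mode)
        out[f"{prefix} entropy"] = stats["entropy"].reindex(counts.index).fillna(0.0)
        out[f"High {prefix} frequency"] = (
            stats["high_frequency"].reindex(counts.index).fillna(0.0)
        )

    out["Total MiFI"] = counts["MiFI"]
    out = out[FEATURE_NAMES].astype(float)
    return FeatureMatrix(out, length_kb, dropped)
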
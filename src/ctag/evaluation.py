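"""Per-class classification metrics and mutation-rate distribution comparison.

Metrics follow the standard confusion-table identities, computed one-vs-rest
per class (T true, F false, P positive, N negative):

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = harmonic mean of precision and recall

Quotients with a zero denominator are reported as 0 and flagged.  The
mutation-rate comparison contrasts the per-gene rate distributions of two
gene sets (e.g. predicted drivers vs training drivers) with the two-sample
Kolmogorov-Smirnov statistic and cumulative-fraction curves over log rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MutationTable, ValidationError


@dataclass
class ClassMetrics:
    """One-vs-rest confusion counts and derived metrics for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)
    flags: list[str] = field(init=False, default_factory=list)

    def __post_init__(self):
        def safe(num, den, name):
            if den == 0:
                self.flags.append(name)
                return 0.0
            return num / den

        total = self.tp + self.fp + self.tn + self.fn
        self.accuracy = safe(self.tp + self.tn, total, "accuracy")
        self.precision = safe(self.tp, self.tp + self.fp, "precision")
        self.recall = safe(self.tp, self.tp + self.fn, "recall")
        self.f1 = safe(
            2 * self.precision * self.recall, self.precision + self.recall, "f1"
        )


def classification_metrics(
    true_labels, predicted_labels, classes=("TSG", "OG")
) -> dict[str, ClassMetrics]:
    """One-vs-rest :class:`ClassMetrics` per class for two aligned label vectors."""
    true = np.asarray(true_labels)
    pred = np.asarray(predicted_labels)
    if true.shape != pred.shape:
        raise ValidationError("label vectors must have equal length")
    out = {}
    for cls in classes:
        t = true == cls
        p = pred == cls
        out[cls] = ClassMetrics(
            tp=int((t & p).sum()),
            fp=int((~t & p).sum()),
            tn=int((~t & ~p).sum()),
            fn=int((t & ~p).sum()),
        )
    return out


def ks_two_sample(rates_a, rates_b, method: str = "asymp") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic D = sup|ECDF_a - ECDF_b| and p-value.

    D is invariant under any common strictly monotone transform of both
    vectors (e.g. taking logs).  The asymptotic p-value is the default; pass
    ``method="exact"`` for the small-sample distribution.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("rate vectors must be non-empty")
    res = sps.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def cumulative_rate_curve(rates, log_base: float = 10.0) -> pd.DataFrame:
    """Cumulative-fraction curve of a per-gene rate vector on a log axis.

    Rates are sorted ascending; the fraction at the i-th sorted rate is i/n
    (fraction of genes at or below that rate).  Returns columns
    ``log_rate`` and ``fraction``.
    """
    rates = pd.Series(rates, dtype=float)
    bad = rates.index[rates <= 0]
    if len(bad):
        raise ValidationError(f"non-positive rates for: {list(bad)}")
    sorted_rates = rates.sort_values(kind="stable")
    n = len(sorted_rates)
    return pd.DataFrame(
        {
            "log_rate": np.log(sorted_rates.to_numpy()) / np.log(log_base),
            "fraction": np.arange(1, n + 1) / n,
        },
        index=sorted_rates.index,
    )


def mutation_rate_per_gene(table: MutationTable, lengths: pd.Series) -> pd.Series:
    """Fallback per-gene mutation rate: mutations per sample per kb of coding sequence.

    A self-contained substitute axis for comparing rate distributions when no
    external background-rate estimates are supplied.
    """
    n_samples = table.df["sample_id"].nunique()
    if n_samples == 0:
        raise ValidationError("empty mutation table")
    counts = table.df.groupby("gene_id").size()
    genes = counts.index.intersection(pd.Series(lengths).dropna().index)
    length_kb = pd.Series(lengths).loc[genes] / 1000.0
    return counts.loc[genes] / n_samples / length_kb
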
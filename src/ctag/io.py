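"""Reading, validation and preprocessing of COSMIC-style somatic mutation tables.

The canonical in-memory carrier is :class:`MutationTable`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per somatic mutation.  All
preprocessing steps (hypermutator removal, somatic-status filtering,
splice-site re-annotation, functional-impact score attachment, tissue
restriction) consume and return :class:`MutationTable` objects and append a
human-readable line to its provenance log.

Coordinates are 1-based inclusive coding-sequence positions throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: The eight source-annotated mutation types.
MUTATION_TYPES = (
    "silent",
    "missense",
    "splicing",
    "nonsense",
    "frameshift",
    "inframe",
    "nonstop",
    "complex",
)

#: Canonical column order of the in-memory table and of the TSV serialisation.
CANONICAL_COLUMNS = [
    "sample_id",
    "gene_id",
    "mutation_type",
    "position",
    "ref_allele",
    "alt_allele",
    "impact_score",
    "somatic_status",
    "tissue",
]

#: Somatic-status values accepted by default, as spelled in COSMIC exports.
DEFAULT_SOMATIC_STATUS = frozenset({"Confirmed somatic variant"})


class ConfigurationError(ValueError):
    """A required column or dialect entry is missing or inconsistent."""


class ValidationError(ValueError):
    """An input value violates a documented invariant (e.g. score outside [0,1])."""


class TissueLookupError(KeyError):
    """The requested tissue does not occur in the table."""

    def __init__(self, tissue: str, available: Sequence[str]):
        self.tissue = tissue
        self.available = sorted(available)
        super().__init__(
            f"tissue {tissue!r} not present; available tissues: {self.available}"
        )


class EmptyTableError(ValueError):
    """No usable rows survived parsing or filtering."""


def normalize_mutation_type(raw: str) -> str | None:
    """Map a source annotation onto one of the eight canonical mutation types.

    COSMIC spellings vary across versions ("Substitution - Missense",
    "Deletion - Frameshift", "coding silent", ...).  Matching is by
    case-insensitive substring; insertions/deletions are routed to
    ``frameshift`` or ``inframe`` by their reading-frame annotation.
    Returns ``None`` when the annotation cannot be mapped.
    """
    if not isinstance(raw, str):
        return None
    s = raw.strip().lower()
    if not s:
        return None
    if "frameshift" in s or "frame shift" in s:
        return "frameshift"
    if "inframe" in s or "in frame" in s or "in-frame" in s:
        return "inframe"
    if "missense" in s:
        return "missense"
    if "silent" in s or "synonymous" in s:
        return "silent"
    if "nonsense" in s or "stop gained" in s:
        return "nonsense"
    if "nonstop" in s or "stop lost" in s:
        return "nonstop"
    if "splic" in s:
        return "splicing"
    if "complex" in s:
        return "complex"
    return None


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation.

    ``gene_id`` is kept verbatim, including ``gene_transcript`` suffixes, so
    distinct transcripts of one gene symbol are handled as separate genes.
    ``impact_score`` is a PolyPhen2-style probability of functional damage in
    [0, 1]; it is only meaningful for missense mutations and may be absent.
    """

    sample_id: str
    gene_id: str
    mutation_type: str
    position: int
    ref_allele: str = ""
    alt_allele: str = ""
    impact_score: float | None = None
    somatic_status: str = ""
    tissue: str = ""

    def __post_init__(self):
        if self.mutation_type not in MUTATION_TYPES:
            raise ValidationError(f"unknown mutation type {self.mutation_type!r}")
        if self.position < 1:
            raise ValidationError("position must be >= 1")
        if self.impact_score is not None and not (0.0 <= self.impact_score <= 1.0):
            raise ValidationError("impact_score must lie in [0, 1]")


@dataclass
class MutationTable:
    """An ordered collection of mutation records with a provenance log."""

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    rejections: pd.DataFrame | None = None

    def __post_init__(self):
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"mutation table lacks columns: {missing}")
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[MutationRecord]:
        for row in self.df.itertuples(index=False):
            score = row.impact_score
            yield MutationRecord(
                sample_id=row.sample_id,
                gene_id=row.gene_id,
                mutation_type=row.mutation_type,
                position=int(row.position),
                ref_allele=row.ref_allele,
                alt_allele=row.alt_allele,
                impact_score=None if pd.isna(score) else float(score),
                somatic_status=row.somatic_status,
                tissue=row.tissue,
            )

    @property
    def samples(self) -> pd.Index:
        return pd.Index(self.df["sample_id"].unique())

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.df["gene_id"].unique())

    def _derive(self, df: pd.DataFrame, note: str) -> "MutationTable":
        return MutationTable(
            df.reset_index(drop=True), self.provenance + [note], self.rejections
        )

    @classmethod
    def from_records(cls, records: Iterable[MutationRecord]) -> "MutationTable":
        rows = [
            {
                "sample_id": r.sample_id,
                "gene_id": r.gene_id,
                "mutation_type": r.mutation_type,
                "position": r.position,
                "ref_allele": r.ref_allele,
                "alt_allele": r.alt_allele,
                "impact_score": np.nan if r.impact_score is None else r.impact_score,
                "somatic_status": r.somatic_status,
                "tissue": r.tissue,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        return cls(df, ["constructed from records"])

    def to_tsv(self, path) -> None:
        """Write the canonical TSV serialisation (columns ``ref``/``alt``)."""
        out = self.df.rename(columns={"ref_allele": "ref", "alt_allele": "alt"})
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Dialect:
    """Mapping of semantic column roles onto TSV header names.

    The default dialect reads the canonical serialisation written by
    :meth:`MutationTable.to_tsv`.  Override individual entries to point at
    COSMIC-export-like headers (e.g. ``sample_id="Sample name"``).
    """

    sample_id: str = "sample_id"
    gene_id: str = "gene_id"
    mutation_type: str = "mutation_type"
    position: str = "position"
    ref_allele: str = "ref"
    alt_allele: str = "alt"
    impact_score: str = "impact_score"
    somatic_status: str = "somatic_status"
    tissue: str = "tissue"

    #: Columns that must be present in the file.
    REQUIRED = ("sample_id", "gene_id", "mutation_type", "position")
    #: Columns filled with defaults when absent.
    OPTIONAL = ("ref_allele", "alt_allele", "impact_score", "somatic_status", "tissue")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "Dialect":
        unknown = set(mapping) - set(cls.REQUIRED) - set(cls.OPTIONAL)
        if unknown:
            raise ConfigurationError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**mapping)


def read_mutation_table(path, dialect: Dialect | None = None) -> MutationTable:
    """Read a tab-separated mutation table into a :class:`MutationTable`.

    Rows whose mutation-type annotation cannot be mapped onto the eight
    canonical types, or whose position is missing or < 1, are rejected and
    reported in ``table.rejections`` (original row index plus reason).
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for key in Dialect.REQUIRED:
        col = getattr(dialect, key)
        if col not in raw.columns:
            raise ConfigurationError(
                f"required column {col!r} (role {key!r}) missing from {path}"
            )

    df = pd.DataFrame(index=raw.index)
    for key in Dialect.REQUIRED + Dialect.OPTIONAL:
        col = getattr(dialect, key)
        if col in raw.columns:
            df[key] = raw[col]
        else:
            df[key] = np.nan if key == "impact_score" else ""

    reasons = pd.Series("", index=df.index, dtype=object)
    mapped = df["mutation_type"].map(normalize_mutation_type)
    reasons[mapped.isna()] = "unmappable mutation type"

    pos = pd.to_numeric(df["position"], errors="coerce")
    bad_pos = pos.isna() | (pos < 1)
    reasons[bad_pos & (reasons == "")] = "invalid position"

    score = pd.to_numeric(df["impact_score"], errors="coerce")
    if ((score < 0) | (score > 1)).any():
        raise ValidationError("impact scores must lie in [0, 1]")

    keep = reasons == ""
    rejections = pd.DataFrame(
        {"row": df.index[~keep], "reason": reasons[~keep].to_numpy()}
    ).reset_index(drop=True)

    out = df[keep].copy()
    out["mutation_type"] = mapped[keep]
    out["position"] = pos[keep].astype(int)
    out["impact_score"] = score[keep]
    for c in ("ref_allele", "alt_allele", "somatic_status", "tissue"):
        out[c] = out[c].fillna("")
    table = MutationTable(
        out.reset_index(drop=True),
        [f"read {keep.sum()} records from {path} ({len(rejections)} rejected)"],
        rejections if len(rejections) else None,
    )
    return table


def filter_hypermutators(table: MutationTable, threshold: int = 2000) -> MutationTable:
    """Drop every record of samples carrying strictly more than ``threshold`` mutations.

    A sample with exactly ``threshold`` mutations is retained.  Idempotent.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if len(table) == 0:
        return table._derive(table.df, "hypermutator filter: empty table")
    counts = table.df.groupby("sample_id").size()
    hyper = counts.index[counts > threshold]
    kept = table.df[~table.df["sample_id"].isin(hyper)]
    return table._derive(
        kept, f"hypermutator filter (>{threshold}): removed {len(hyper)} samples"
    )


def filter_somatic_status(
    table: MutationTable, accepted: frozenset[str] | set[str] = DEFAULT_SOMATIC_STATUS
) -> MutationTable:
    """Keep only records whose somatic status is in ``accepted``."""
    if not accepted:
        raise ValidationError("accepted status set must be non-empty")
    kept = table.df[table.df["somatic_status"].isin(accepted)]
    return table._derive(
        kept,
        f"somatic-status filter {sorted(accepted)}: kept {len(kept)}/{len(table)}",
    )


@dataclass
class ExonModel:
    """Per-gene ordered, non-overlapping exon intervals in 1-based coding coordinates."""

    exons: dict[str, list[tuple[int, int]]]

    def __post_init__(self):
        for gene, ivs in self.exons.items():
            ivs = sorted((int(s), int(e)) for s, e in ivs)
            prev_end = -math.inf
            for s, e in ivs:
                if s > e:
                    raise ValidationError(f"{gene}: exon start {s} > end {e}")
                if s <= prev_end:
                    raise ValidationError(f"{gene}: overlapping exons")
                prev_end = e
            self.exons[gene] = ivs

    def splice_positions(self, gene: str) -> set[int]:
        """The four border-offset positions per exon: end+1, end+2, start-1, start-2."""
        out: set[int] = set()
        for s, e in self.exons.get(gene, ()):
            out.update((e + 1, e + 2, s - 1, s - 2))
        return {p for p in out if p >= 1}

    @classmethod
    def read_tsv(cls, path) -> "ExonModel":
        df = pd.read_csv(path, sep="\t")
        exons: dict[str, list[tuple[int, int]]] = {}
        for row in df.itertuples(index=False):
            exons.setdefault(row.gene_id, []).append((row.exon_start, row.exon_end))
        return cls(exons)

    def to_tsv(self, path) -> None:
        rows = [
            {"gene_id": g, "exon_start": s, "exon_end": e}
            for g in sorted(self.exons)
            for s, e in self.exons[g]
        ]
        pd.DataFrame(rows, columns=["gene_id", "exon_start", "exon_end"]).to_csv(
            path, sep="\t", index=False
        )


def annotate_splice_sites(table: MutationTable, exons: ExonModel) -> MutationTable:
    """Retype records sitting 1-2 bp outside an exon border as ``splicing``.

    A record at ``exon_end+1``, ``exon_end+2``, ``exon_start-1`` or
    ``exon_start-2`` of any exon of its gene becomes ``splicing``; all other
    records (including those of genes absent from the exon model, which are
    counted into a provenance warning) are left untouched.  The record count
    is preserved exactly.
    """
    df = table.df.copy()
    cache: dict[str, set[int]] = {}
    flags = np.zeros(len(df), dtype=bool)
    missing_genes: set[str] = set()
    for i, (gene, pos) in enumerate(zip(df["gene_id"], df["position"])):
        if gene not in exons.exons:
            missing_genes.add(gene)
            continue
        sites = cache.get(gene)
        if sites is None:
            sites = cache[gene] = exons.splice_positions(gene)
        flags[i] = pos in sites
    df.loc[flags, "mutation_type"] = "splicing"
    note = f"splice annotation: {int(flags.sum())} records retyped"
    if missing_genes:
        note += f"; {len(missing_genes)} genes absent from exon model"
    return table._derive(df, note)


def attach_impact_scores(table: MutationTable, scores: pd.DataFrame) -> MutationTable:
    """Attach PolyPhen2-style impact scores to missense records.

    ``scores`` has columns ``gene_id, position, ref, alt, score``; multiple
    scores for one variant key are averaged before attachment (arithmetic
    mean), mirroring how duplicate predictions are reconciled.  Non-missense
    records never receive a score; missense records with no matching key keep
    their score absent.
    """
    req = {"gene_id", "position", "ref", "alt", "score"}
    missing = req - set(scores.columns)
    if missing:
        raise ConfigurationError(f"score table lacks columns: {sorted(missing)}")
    if ((scores["score"] < 0) | (scores["score"] > 1)).any():
        raise ValidationError("impact scores must lie in [0, 1]")
    mean_scores = (
        scores.groupby(["gene_id", "position", "ref", "alt"], sort=False)["score"]
        .mean()
        .rename("_score")
        .reset_index()
    )
    df = table.df.copy()
    merged = df.merge(
        mean_scores,
        how="left",
        left_on=["gene_id", "position", "ref_allele", "alt_allele"],
        right_on=["gene_id", "position", "ref", "alt"],
    )
    is_mis = df["mutation_type"].to_numpy() == "missense"
    new = np.where(is_mis, merged["_score"].to_numpy(), df["impact_score"].to_numpy())
    df["impact_score"] = new
    n = int((is_mis & merged["_score"].notna().to_numpy()).sum())
    return table._derive(df, f"impact scores attached to {n} missense records")


@dataclass(frozen=True)
class TissueExcluded:
    """Outcome of a tissue query that fails the minimum-sample gate."""

    tissue: str
    n_samples: int
    min_samples: int

    def __str__(self) -> str:
        return (
            f"tissue {self.tissue!r} excluded: {self.n_samples} samples "
            f"<= required minimum {self.min_samples}"
        )


def filter_by_tissue(
    table: MutationTable, tissue: str, min_samples: int = 1000
) -> MutationTable | TissueExcluded:
    """Restrict the table to one primary tissue, subject to a sample-count gate.

    Tissues represented by ``min_samples`` or fewer distinct samples are
    excluded (an explicit :class:`TissueExcluded` outcome is returned instead
    of a table); a tissue with ``min_samples + 1`` samples passes.
    """
    observed = table.df["tissue"].unique()
    if tissue not in observed:
        raise TissueLookupError(tissue, list(observed))
    sub = table.df[table.df["tissue"] == tissue]
    n_samples = sub["sample_id"].nunique()
    if n_samples <= min_samples:
        return TissueExcluded(tissue, n_samples, min_samples)
    return table._derive(
        sub, f"tissue filter {tissue!r}: {len(sub)} records, {n_samples} samples"
    )


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column TSV (gene_id, length_bp) into a Series indexed by gene."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ConfigurationError("gene-length table needs two columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="length_bp")
    return s


def write_gene_lengths(lengths: pd.Series, path) -> None:
    pd.DataFrame({"gene_id": lengths.index, "length_bp": lengths.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )
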
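"""Synthetic somatic-mutation cohorts with planted TSG-like, OG-like and neutral genes.

The generator targets the sufficient statistics the 37 features measure
rather than any empirical mutational signature: per sample and gene,
mutation counts are Poisson with a length-scaled rate; neutral genes emit
mostly silent and low-impact missense mutations at uniformly random
positions; TSG-like genes are enriched for truncating mutations (nonsense,
frameshift, splice) with a recurrent-truncation mixture; OG-like genes
concentrate missense mutations on a few hotspot (position, ref, alt)
identities carrying high functional-impact scores.  Impact scores come from
two Beta distributions (high-skew for damaging, low-skew for benign) so the
0.85/0.15 bin thresholds separate them with known expected proportions.

Everything — mutations, per-gene coding lengths, per-variant impact scores,
planted truth labels, an exon model and tissue assignments — is emitted as
one :class:`CohortBundle`, fully deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CANONICAL_COLUMNS,
    Dialect,
    ExonModel,
    MutationTable,
    ValidationError,
    read_gene_lengths,
    read_mutation_table,
    write_gene_lengths,
)
from .labels import LabelSet, load_labels

_NUCS = np.array(list("ACGT"))

#: Mutation-type mixtures per gene class (order matters for reproducibility).
_TYPES = ("silent", "missense", "splicing", "nonsense", "frameshift",
          "inframe", "nonstop", "complex")
_NEUTRAL_MIX = (0.40, 0.50, 0.02, 0.02, 0.02, 0.015, 0.005, 0.02)
_TSG_MIX = (0.12, 0.22, 0.08, 0.28, 0.22, 0.03, 0.01, 0.04)
_OG_MIX = (0.12, 0.75, 0.02, 0.03, 0.03, 0.02, 0.01, 0.02)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a strong-signal cohort: 100 TSG-like, 60 OG-like and
    500 neutral genes over 1000 samples, background 0.02 mutations per gene
    per sample for an average-length (1.5 kb) gene, drivers mutated at twice
    the background, half of a TSG's truncations recurring at a handful of
    sites, and 70 % of an OG's missense load on three hotspot identities.
    """

    n_tsg: int = 100
    n_og: int = 60
    n_neutral: int = 500
    n_samples: int = 1000
    tissues: tuple[tuple[str, float], ...] = (
        ("breast", 0.4),
        ("large_intestine", 0.35),
        ("lung", 0.25),
    )
    background_rate: float = 0.02  # mutations / gene / sample at 1.5 kb
    driver_rate_mult: float = 2.0
    rate_dispersion: float = 0.25  # lognormal sigma of per-gene rate noise
    tsg_recurrent_sites: int = 4
    tsg_recurrence: float = 0.5  # share of truncations at recurrent sites
    og_hotspots: int = 3
    og_hotspot_share: float = 0.7  # share of missense at hotspots
    og_hotspot_concentration: float = 0.4  # Dirichlet concentration
    # Per-driver penetrance: each driver draws p ~ Beta(a, b) and emits a
    # p-weighted mixture of its class mixture and the neutral mixture, so
    # cohorts contain weak-signal drivers alongside textbook ones.
    driver_penetrance_beta: tuple[float, float] = (2.5, 1.5)
    damaging_beta: tuple[float, float] = (40.0, 3.0)  # mostly >= 0.85
    benign_beta: tuple[float, float] = (2.0, 25.0)  # mostly <= 0.15
    tsg_missense_beta: tuple[float, float] = (4.0, 2.0)
    length_log_mean: float = 7.313  # ln(1500)
    length_log_sigma: float = 0.45
    hypermutator_fraction: float = 0.0
    hypermutator_burden: int = 2500
    tissue_private_tsg: str | None = None  # tissue name hosting a private TSG
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_tsg, self.n_og, self.n_neutral) < 0 or self.n_samples < 1:
            raise ValidationError("gene and sample counts must be non-negative")
        if self.n_tsg + self.n_og + self.n_neutral == 0:
            raise ValidationError("at least one gene class must be non-empty")
        shares = [
            self.tsg_recurrence,
            self.og_hotspot_share,
            self.hypermutator_fraction,
        ]
        if any(not 0.0 <= s <= 1.0 for s in shares):
            raise ValidationError("shares must lie in [0, 1]")
        if abs(sum(w for _, w in self.tissues) - 1.0) > 1e-9:
            raise ValidationError("tissue shares must sum to 1")
        if self.background_rate <= 0:
            raise ValidationError("background rate must be positive")


@dataclass
class CohortBundle:
    """All inputs a pipeline run needs, with the planted ground truth."""

    mutations: MutationTable
    lengths: pd.Series
    scores: pd.DataFrame
    truth: pd.DataFrame  # gene_id, role in {TSG, OG, neutral}
    exons: ExonModel
    config: CohortConfig

    def label_set(self) -> LabelSet:
        """Planted TSG/OG labels (neutral genes are not part of the label set)."""
        return load_labels(self.truth[self.truth["role"].isin(("TSG", "OG"))])

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.mutations.to_tsv(directory / "mutations.tsv")
        write_gene_lengths(self.lengths, directory / "lengths.tsv")
        self.scores.to_csv(directory / "scores.tsv", sep="\t", index=False,
                           float_format="%.10g")
        self.truth.to_csv(directory / "labels.tsv", sep="\t", index=False)
        self.exons.to_tsv(directory / "exons.tsv")
        (directory / "config.json").write_text(
            json.dumps(dataclasses.asdict(self.config), indent=1, sort_keys=True)
        )

    @classmethod
    def read(cls, directory) -> "CohortBundle":
        directory = Path(directory)
        cfg = CohortConfig(**{
            k: tuple(tuple(t) if isinstance(t, list) else t for t in v)
            if isinstance(v, list) else v
            for k, v in json.loads((directory / "config.json").read_text()).items()
        })
        return cls(
            mutations=read_mutation_table(directory / "mutations.tsv", Dialect()),
            lengths=read_gene_lengths(directory / "lengths.tsv"),
            scores=pd.read_csv(directory / "scores.tsv", sep="\t"),
            truth=pd.read_csv(directory / "labels.tsv", sep="\t"),
            exons=ExonModel.read_tsv(directory / "exons.tsv"),
            config=cfg,
        )


def _draw_alleles(rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=size)
    alt_idx = (ref_idx + rng.integers(1, 4, size=size)) % 4
    return _NUCS[ref_idx], _NUCS[alt_idx]


def simulate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate one deterministic cohort bundle under the given study conditions."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = (
        [f"TSG{i:03d}" for i in range(config.n_tsg)]
        + [f"OG{i:03d}" for i in range(config.n_og)]
        + [f"NEU{i:03d}" for i in range(config.n_neutral)]
    )
    roles = (
        ["TSG"] * config.n_tsg + ["OG"] * config.n_og + ["neutral"] * config.n_neutral
    )
    lengths = np.maximum(
        300,
        rng.lognormal(config.length_log_mean, config.length_log_sigma, len(genes)),
    ).astype(int)
    length_s = pd.Series(lengths, index=pd.Index(genes, name="gene_id"),
                         name="length_bp")

    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    tissue_names = [t for t, _ in config.tissues]
    tissue_shares = np.array([w for _, w in config.tissues])
    sample_tissue = rng.choice(tissue_names, size=config.n_samples, p=tissue_shares)

    # Per-gene expected rate: length-scaled background with lognormal noise,
    # drivers elevated by a constant multiplier.
    noise = rng.lognormal(0.0, config.rate_dispersion, len(genes))
    mult = np.where(np.array(roles) == "neutral", 1.0, config.driver_rate_mult)
    rates = config.background_rate * (lengths / 1500.0) * noise * mult

    private = config.tissue_private_tsg
    mix_by_role = {"neutral": np.array(_NEUTRAL_MIX), "TSG": np.array(_TSG_MIX),
                   "OG": np.array(_OG_MIX)}

    rows: list[dict] = []
    score_rows: list[dict] = []
    sample_arr = np.array(samples)
    for gi, (gene, role) in enumerate(zip(genes, roles)):
        length = lengths[gi]
        # counts per sample for this gene
        counts = rng.poisson(rates[gi], size=config.n_samples)
        private_gene = private is not None and role == "TSG" and gi == 0
        if private_gene:
            # recurrently mutated within its host tissue; elsewhere it carries a
            # heavy passenger load that drowns the driver composition pan-cancer
            counts = np.where(sample_tissue == private, counts * 2, counts * 3)
        total = int(counts.sum())
        if total == 0:
            continue
        sample_ids = np.repeat(sample_arr, counts)
        tissues = np.repeat(sample_tissue, counts)
        if role == "neutral":
            penetrance = 1.0
            mix = mix_by_role[role]
        else:
            penetrance = float(rng.beta(*config.driver_penetrance_beta))
            if private_gene:
                penetrance = 1.0  # the showcase tissue driver is fully penetrant
            mix = penetrance * mix_by_role[role] + (1 - penetrance) * mix_by_role["neutral"]
        types = rng.choice(_TYPES, size=total, p=mix)
        in_tissue = np.ones(total, dtype=bool)
        if private_gene:
            # TSG-like selection acts only in the private tissue; elsewhere the
            # gene accumulates neutral passengers, diluting its pan-cancer profile
            in_tissue = tissues == private
            types[~in_tissue] = rng.choice(
                _TYPES, size=int((~in_tissue).sum()), p=mix_by_role["neutral"]
            )
        positions = rng.integers(1, length + 1, size=total)
        ref, alt = _draw_alleles(rng, total)
        ref = ref.astype(object)
        alt = alt.astype(object)

        if role == "TSG":
            # recurrent truncation sites shared by nonsense/frameshift records
            sites = rng.choice(length, size=min(config.tsg_recurrent_sites, length),
                               replace=False) + 1
            trunc = np.isin(types, ("nonsense", "frameshift"))
            hit = trunc & in_tissue & (rng.random(total) < config.tsg_recurrence * penetrance)
            positions[hit] = rng.choice(sites, size=int(hit.sum()))
        is_mis = types == "missense"
        hotspot_ident: list[tuple[int, str, str]] = []
        if role == "OG":
            n_hot = min(config.og_hotspots, length)
            hot_pos = rng.choice(length, size=n_hot, replace=False) + 1
            hot_ref, hot_alt = _draw_alleles(rng, n_hot)
            hotspot_ident = list(zip(hot_pos, hot_ref, hot_alt))
            weights = rng.dirichlet([config.og_hotspot_concentration] * n_hot)
            at_hot = is_mis & (rng.random(total) < config.og_hotspot_share * penetrance)
            idx = rng.choice(n_hot, size=int(at_hot.sum()), p=weights)
            positions[at_hot] = hot_pos[idx]
            ref[at_hot] = hot_ref[idx]
            alt[at_hot] = hot_alt[idx]

        # indels: represent frameshift/inframe alleles as insertions/deletions
        fs = types == "frameshift"
        alt[fs] = "-"
        inf = types == "inframe"
        alt[inf] = "---"

        for s, t, ty, pos, r, a in zip(sample_ids, tissues, types, positions, ref, alt):
            rows.append(
                {"sample_id": s, "gene_id": gene, "mutation_type": ty,
                 "position": int(pos), "ref_allele": r, "alt_allele": a,
                 "impact_score": np.nan,
                 "somatic_status": "Confirmed somatic variant", "tissue": t}
            )

        # one impact score per distinct missense identity
        idents = sorted(
            {(int(p), r, a) for p, r, a in
             zip(positions[is_mis], ref[is_mis], alt[is_mis])}
        )
        idents_selected = {
            (int(p), r, a) for p, r, a in
            zip(positions[is_mis & in_tissue], ref[is_mis & in_tissue],
                alt[is_mis & in_tissue])
        }
        hot_set = set(hotspot_ident)
        for pos, r, a in idents:
            if role == "OG" and (pos, r, a) in hot_set:
                a_b, b_b = config.damaging_beta
            elif (role == "TSG" and (pos, r, a) in idents_selected
                  and rng.random() < penetrance):
                a_b, b_b = config.tsg_missense_beta
            else:
                a_b, b_b = config.benign_beta
            score_rows.append(
                {"gene_id": gene, "position": pos, "ref": r, "alt": a,
                 "score": float(rng.beta(a_b, b_b))}
            )

    # hypermutator samples: top up with benign passenger mutations
    n_hyper = int(round(config.hypermutator_fraction * config.n_samples))
    if n_hyper > 0:
        df_tmp = pd.DataFrame(rows)
        burden_now = df_tmp.groupby("sample_id").size()
        hyper_samples = rng.choice(samples, size=n_hyper, replace=False)
        for s in hyper_samples:
            need = config.hypermutator_burden - int(burden_now.get(s, 0))
            if need <= 0:
                continue
            g_idx = rng.integers(0, len(genes), size=need)
            pos = rng.integers(1, lengths[g_idx] + 1)
            r, a = _draw_alleles(rng, need)
            t = sample_tissue[samples.index(s)]
            ty = rng.choice(["silent", "missense"], size=need, p=[0.5, 0.5])
            for gidx, typ, p_, r_, a_ in zip(g_idx, ty, pos, r, a):
                rows.append(
                    {"sample_id": s, "gene_id": genes[gidx], "mutation_type": typ,
                     "position": int(p_), "ref_allele": r_, "alt_allele": a_,
                     "impact_score": np.nan,
                     "somatic_status": "Confirmed somatic variant", "tissue": t}
                )

    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    table = MutationTable(df, [f"simulated cohort (seed={config.seed})"])
    scores = pd.DataFrame(score_rows, columns=["gene_id", "position", "ref", "alt",
                                               "score"])
    truth = pd.DataFrame({"gene_id": genes, "role": roles})
    exons = ExonModel({g: [(1, int(l))] for g, l in zip(genes, lengths)})
    return CohortBundle(table, length_s, scores, truth, exons, config)


def make_hypermutator_fixture(config: CohortConfig | None = None) -> CohortBundle:
    """A cohort guaranteed to contain hypermutated samples (> 2000 mutations)."""
    config = config or CohortConfig(
        n_tsg=5, n_og=5, n_neutral=30, n_samples=50, hypermutator_fraction=0.02
    )
    if int(round(config.hypermutator_fraction * config.n_samples)) < 1:
        raise ValidationError("config must request at least one hypermutator")
    if config.hypermutator_burden <= 2000:
        raise ValidationError("hypermutator burden must exceed 2000")
    return simulate_cohort(config)
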
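"""End-to-end convenience wrappers tying preprocessing to the feature engine."""

from __future__ import annotations

import pandas as pd

from .features import FeatureMatrix, build_feature_matrix
from .io import (
    DEFAULT_SOMATIC_STATUS,
    ExonModel,
    MutationTable,
    TissueExcluded,
    annotate_splice_sites,
    attach_impact_scores,
    filter_by_tissue,
    filter_hypermutators,
    filter_somatic_status,
)


def preprocess(
    table: MutationTable,
    scores: pd.DataFrame | None = None,
    exons: ExonModel | None = None,
    accepted_status: frozenset[str] | set[str] = DEFAULT_SOMATIC_STATUS,
    max_sample_mutations: int = 2000,
    tissue: str | None = None,
    min_tissue_samples: int = 1000,
) -> MutationTable | TissueExcluded:
    """Standard preprocessing chain: somatic-status filter, hypermutator
    removal, optional splice re-annotation, impact-score attachment and
    optional tissue restriction."""
    table = filter_somatic_status(table, accepted_status)
    table = filter_hypermutators(table, max_sample_mutations)
    if exons is not None:
        table = annotate_splice_sites(table, exons)
    if scores is not None:
        table = attach_impact_scores(table, scores)
    if tissue is not None:
        return filter_by_tissue(table, tissue, min_samples=min_tissue_samples)
    return table


def featurize(
    table: MutationTable,
    lengths: pd.Series,
    scores: pd.DataFrame | None = None,
    exons: ExonModel | None = None,
    unscored: str = "mifi",
    entropy_mode: str = "printed",
    **preprocess_kwargs,
) -> FeatureMatrix | TissueExcluded:
    """Preprocess a raw mutation table and build the 37-feature matrix."""
    prepped = preprocess(table, scores=scores, exons=exons, **preprocess_kwargs)
    if isinstance(prepped, TissueExcluded):
        return prepped
    return build_feature_matrix(prepped, lengths, unscored=unscored,
                                entropy_mode=entropy_mode)
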
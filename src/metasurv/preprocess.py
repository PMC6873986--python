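"""Probeset collapsing, common-gene intersection and the percentile-rank transform."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort_io import Cohort, CohortCollection, DataError, ExpressionMatrix

log = logging.getLogger(__name__)


def read_probe_gene_map(path) -> dict[str, str]:
    """Read a two-column delimited file (probeset_id, gene_id) into a dict."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=None, names=["probeset_id", "gene_id"],
                     dtype=str, comment="#")
    if df["probeset_id"].duplicated().any():
        dup = df["probeset_id"][df["probeset_id"].duplicated()].iloc[0]
        raise DataError(f"{path}: probeset {dup!r} maps to more than one gene")
    return dict(zip(df["probeset_id"], df["gene_id"]))


def collapse_probesets(expr: ExpressionMatrix, mapping: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse a probeset-level matrix to gene level.

    For each gene measured by several probesets, the probeset with the
    largest mean expression across samples is retained (ties broken by
    lexicographically smallest probeset id).  Unmapped probesets are dropped.
    """
    means = expr.values.mean(axis=1)
    best: dict[str, tuple[float, str, int]] = {}  # gene -> (mean, probeset, row)
    n_unmapped = 0
    for row, probe in enumerate(expr.feature_ids):
        gene = mapping.get(probe)
        if gene is None:
            n_unmapped += 1
            continue
        # tie on mean -> keep the lexicographically smaller probeset id
        cand = (means[row], probe, row)
        cur = best.get(gene)
        if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
            best[gene] = cand
    if not best:
        raise DataError("no probeset maps to any gene")
    if n_unmapped:
        log.info("collapse_probesets: dropped %d unmapped probeset(s)", n_unmapped)
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    return ExpressionMatrix(genes, list(expr.sample_ids), expr.values[rows, :])


def intersect_genes(cohorts: Sequence[Cohort]) -> CohortCollection:
    """Restrict all cohorts to their common genes, sorted lexicographically."""
    if not cohorts:
        raise DataError("intersect_genes requires at least one cohort")
    universe = set(cohorts[0].feature_ids)
    for c in cohorts[1:]:
        universe &= set(c.feature_ids)
    if not universe:
        raise DataError("empty gene intersection across cohorts")
    genes = sorted(universe)
    log.info("gene intersection: %d common gene(s) across %d cohort(s)", len(genes), len(cohorts))
    return CohortCollection(
        [c.with_expression(c.expression.subset_features(genes)) for c in cohorts]
    )


def percentile_rank_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each sample's values by within-sample ranks divided by the
    gene count.

    Ranks are ascending (highest expression -> 1.0) with midranks for ties;
    output values lie in (0, 1].  The result depends only on the within-sample
    ordering, so any strictly increasing per-sample distortion of the raw
    values leaves it unchanged.
    """
    p = expr.n_features
    ranks = rankdata(expr.values, method="average", axis=0)
    return ExpressionMatrix(list(expr.feature_ids), list(expr.sample_ids), ranks / p)


def rank_transform_collection(collection: CohortCollection) -> CohortCollection:
    """Apply the percentile-rank transform to every cohort of a collection."""
    return CohortCollection(
        [c.with_expression(percentile_rank_transform(c.expression)) for c in collection]
    )
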
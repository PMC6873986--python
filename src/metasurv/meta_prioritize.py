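"""Gene prioritization across cohorts: per-gene c-index z-scores, Stouffer
meta-z combination, Benjamini-Hochberg selection."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort_io import CohortCollection, DataError
from .survival_metrics import cindex_ztest_from_pairs, comparable_pairs

log = logging.getLogger(__name__)


def per_gene_z(collection: CohortCollection) -> pd.DataFrame:
    """Per-gene, per-cohort concordance z-scores.

    Entry (g, k) is the z-statistic of gene g's (rank-transformed) expression
    used as a risk score against cohort k's survival, so positive z means
    higher expression goes with shorter survival.  A gene constant within a
    cohort gets z = 0 there (with a warning).
    """
    genes = collection.gene_universe
    zmat = np.zeros((len(genes), len(collection)))
    for k, cohort in enumerate(collection):
        pairs = comparable_pairs(cohort.clinical.time, cohort.clinical.event)
        if pairs.m < 2:
            raise DataError(f"cohort {cohort.name!r}: fewer than 2 comparable pairs")
        X = cohort.expression.values
        n_degenerate = 0
        for g in range(len(genes)):
            scores = X[g, :]
            if np.ptp(scores) == 0.0:
                n_degenerate += 1
                zmat[g, k] = 0.0
                continue
            zmat[g, k] = cindex_ztest_from_pairs(scores, pairs).z
        if n_degenerate:
            warnings.warn(
                f"cohort {cohort.name!r}: {n_degenerate} gene(s) constant; z set to 0",
                stacklevel=2,
            )
    return pd.DataFrame(zmat, index=genes, columns=collection.names)


def stouffer_combine(z_matrix, denominator: str = "sqrt_k") -> np.ndarray:
    """Combine per-cohort z-scores per gene.

    ``denominator="sqrt_k"`` (default) is the standard unweighted Stouffer
    combination sum(z_k)/sqrt(K); ``denominator="k"`` divides by K instead
    (a pure rescaling that preserves the gene ranking).
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[1] < 1:
        raise DataError("z_matrix must be genes x cohorts with K >= 1")
    if not np.isfinite(z).all():
        raise DataError("z_matrix contains missing entries")
    k = z.shape[1]
    denom = np.sqrt(k) if denominator == "sqrt_k" else float(k)
    if denominator not in ("sqrt_k", "k"):
        raise ValueError(f"unknown denominator {denominator!r}")
    return z.sum(axis=1) / denom


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("pvals must be a nonempty 1-D vector")
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def build_priority_table(collection: CohortCollection, alpha: float = 0.05,
                         denominator: str = "sqrt_k",
                         p_mode: str = "two_sided") -> pd.DataFrame:
    """Full prioritization table: z per cohort, meta_z, meta_p, adj_p, rank,
    selected flag.

    Rank 1 is the largest ``|meta_z|``; ties broken by gene id.  ``selected``
    marks the genes with BH-adjusted p below ``alpha``.  ``p_mode`` may be
    ``"two_sided"`` (default, p from |meta_z|) or ``"one_sided_literal"``
    (p = Phi(meta_z)).
    """
    zdf = per_gene_z(collection)
    meta_z = stouffer_combine(zdf.to_numpy(), denominator=denominator)
    if p_mode == "two_sided":
        meta_p = 2.0 * norm.sf(np.abs(meta_z))
    elif p_mode == "one_sided_literal":
        meta_p = norm.cdf(meta_z)
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")
    adj_p = bh_adjust(meta_p)
    table = zdf.rename(columns=lambda c: f"z_{c}").copy()
    table.insert(0, "gene", zdf.index)
    table["meta_z"] = meta_z
    table["meta_p"] = meta_p
    table["adj_p"] = adj_p
    order = np.lexsort((table["gene"].to_numpy(), -np.abs(meta_z)))
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    table["selected"] = adj_p < alpha
    return table.reset_index(drop=True)


def select_genes(table: pd.DataFrame, alpha: float = 0.05,
                 min_genes: int = 0) -> list[str]:
    """Top-d genes by |meta_z|, with d = #{genes : adj_p < alpha}.

    Under the two-sided p convention the d significant genes and the top d
    by |meta_z| coincide.  ``min_genes`` (off by default) provides a floor
    when no gene clears alpha.
    """
    d = int((table["adj_p"].to_numpy() < alpha).sum())
    if d == 0 and min_genes <= 0:
        raise DataError(
            "no gene passes the BH threshold; raise alpha or set min_genes to force a floor"
        )
    d = max(d, min_genes)
    order = np.lexsort((table["gene"].to_numpy(),
                        -np.abs(table["meta_z"].to_numpy())))
    return table["gene"].to_numpy()[order][:d].tolist()


def write_priority_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
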
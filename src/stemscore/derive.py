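"""Derivation of a correlated mRNA signature from a per-sample score.

Every coding gene in the supplied matrix is ranked by the Pearson correlation
of its expression with the signature score across the cohort; the top-N
positively correlated genes form the derived (all-"up") mRNA signature.
"Protein coding" filtering is the caller's responsibility: supply a matrix
restricted to coding genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DirectionalSignature, ExpressionMatrix
from .scoring import ScoreVector

__all__ = ["RankedGeneList", "correlate_genes_with_score", "derive_top_signature",
           "pairwise_gene_correlation"]


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by a non-increasing ranking statistic (here: Pearson r)."""

    gene_ids: tuple[str, ...]
    statistic: np.ndarray
    n_samples_used: int
    excluded_zero_variance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        stat = np.asarray(self.statistic, dtype=float)
        object.__setattr__(self, "statistic", stat)
        if len(self.gene_ids) != len(stat):
            raise ValueError("gene_ids and statistic lengths differ")
        if np.any(np.diff(stat) > 1e-12):
            raise ValueError("statistic must be non-increasing down the list")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "statistic": self.statistic})


def correlate_genes_with_score(mat: ExpressionMatrix, scores: ScoreVector) -> RankedGeneList:
    """Rank genes by Pearson correlation with the score over the common samples.

    Genes with zero variance across the used samples have no defined
    correlation; they are excluded and reported.  Ties in r are broken
    lexicographically by gene id so the ranking is deterministic.
    """
    score_by_sample = dict(zip(scores.sample_ids, scores.score))
    common = [s for s in mat.sample_ids if s in score_by_sample]
    if len(common) < 3:
        raise ValueError(
            f"need >=3 samples common to matrix and scores, got {len(common)}"
        )
    x = mat.data[common].to_numpy(dtype=float)
    y = np.array([score_by_sample[s] for s in common])
    if np.std(y) == 0:
        raise ValueError("score vector is constant; correlation undefined")

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    x_ss = np.einsum("ij,ij->i", xc, xc)
    zero_var = x_ss == 0
    if zero_var.all():
        raise ValueError("all genes have zero variance across the used samples")
    r = np.full(len(x), np.nan)
    ok = ~zero_var
    r[ok] = (xc[ok] @ yc) / np.sqrt(x_ss[ok] * (yc @ yc))
    np.clip(r, -1.0, 1.0, out=r)

    genes = np.array(mat.feature_ids, dtype=object)
    excluded = tuple(sorted(genes[zero_var]))
    genes, r = genes[ok], r[ok]
    order = np.lexsort((genes, -r))  # descending r, then lexicographic gene id
    return RankedGeneList(
        gene_ids=tuple(genes[order]),
        statistic=r[order],
        n_samples_used=len(common),
        excluded_zero_variance=excluded,
    )


def derive_top_signature(
    ranked: RankedGeneList, n: int = 500, name: str = "derived_mrna_signature"
) -> DirectionalSignature:
    """Take the ``n`` most positively correlated genes as an all-"up" signature.

    Only positively correlated genes qualify: if fewer than ``n`` genes have
    a positive statistic the derivation fails rather than padding with
    anti-correlated genes.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if n > len(ranked):
        raise ValueError(f"n={n} exceeds ranked-list length {len(ranked)}")
    if ranked.statistic[n - 1] <= 0:
        n_positive = int(np.sum(ranked.statistic > 0))
        raise ValueError(
            f"only {n_positive} genes with positive correlation; cannot take top {n}"
        )
    return DirectionalSignature(name=name, up=frozenset(ranked.gene_ids[:n]))


def pairwise_gene_correlation(mat: ExpressionMatrix, genes: set[str]) -> pd.DataFrame:
    """Symmetric Pearson-correlation table for a gene subset (unit diagonal).

    Zero-variance genes are dropped from the table; they are listed in the
    returned frame's ``attrs["excluded_zero_variance"]``.
    """
    missing = sorted(set(genes) - set(mat.feature_ids))
    if missing:
        raise ValueError(f"genes not in matrix: {missing}")
    if mat.n_samples < 3:
        raise ValueError("need >=3 samples for pairwise correlation")
    keep = [g for g in mat.feature_ids if g in genes]
    sub = mat.data.loc[keep]
    variances = sub.to_numpy(dtype=float).var(axis=1)
    excluded = tuple(g for g, v in zip(keep, variances) if v == 0)
    sub = sub.drop(index=list(excluded))
    table = sub.T.corr(method="pearson")
    table.attrs["excluded_zero_variance"] = excluded
    return table
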
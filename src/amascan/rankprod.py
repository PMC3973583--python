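"""Rank-product differential expression with a permutation null.

The two-class rank product compares every replicate of one group against
every replicate of the other: for K = |A| x |B| pairwise comparisons each
gene is ranked by its pairwise fold change (rank 1 = most changed in the
tested direction, ties sharing the average rank), and the statistic is the
geometric mean of the gene's K ranks.  A consistently regulated gene
collects small ranks in every comparison and hence a rank product near 1,
whatever the intensity scale — the statistic is nonparametric and robust for
the small replicate numbers (5/5/6) typical of microarray designs.

Significance comes from a permutation null that permutes *sample labels*:
the pooled replicates of the two groups are randomly reallocated, the
statistic is recomputed on each of n_perm relabelled datasets, and the
observed value is referred to the null pool across all genes and
permutations.  Relabelling whole samples is essential here: the K pairwise
comparisons share replicates, so their rank vectors are positively
correlated, and a null that draws each comparison's ranks independently
(as if the comparisons were separate experiments) grossly understates the
variance of the statistic and floods the gene list with false positives.
A +1 pseudocount keeps p-values strictly positive.  Both directions (up and
down) are tested; the per-gene summary p is the smaller of the two, doubled
(Bonferroni over the two one-sided tests) before Benjamini-Hochberg
correction across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix
from .stats import bh_fdr

__all__ = [
    "fold_change",
    "rank_product",
    "rank_product_pvalues",
    "rank_product_table",
    "call_degs",
    "bh_fdr",
]

Q_CUTOFF = 0.05
FOLD_CUTOFF = 2.0


def _pairwise_log_folds(expr: ExpressionMatrix, group_a: str, group_b: str) -> np.ndarray:
    """(genes, K) array of log fold changes b/a over all replicate pairs."""
    a = expr.submatrix(group_a)
    b = expr.submatrix(group_b)
    logs = np.log(b[:, None, :]) - np.log(a[:, :, None])
    return logs.reshape(expr.n_genes, -1)


def fold_change(expr: ExpressionMatrix, group_a: str, group_b: str) -> pd.Series:
    """Signed linear fold change of group_b relative to group_a.

    The ratio r = mean(b)/mean(a) is reported as +r when r >= 1 and as -1/r
    when r < 1, so a 4-fold drop prints as -4.0 rather than 0.25.
    """
    mean_a = expr.submatrix(group_a).mean(axis=1)
    mean_b = expr.submatrix(group_b).mean(axis=1)
    r = mean_b / mean_a
    signed = np.where(r >= 1.0, r, -1.0 / r)
    return pd.Series(signed, index=expr.gene_ids, name="fold")


def _ranks(log_folds: np.ndarray, direction: str) -> np.ndarray:
    """Per-comparison ranks, rank 1 = most changed in ``direction``."""
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    keyed = -log_folds if direction == "up" else log_folds
    return rankdata(keyed, axis=0, method="average")


def rank_product(
    expr: ExpressionMatrix, group_a: str, group_b: str, direction: str = "up"
) -> pd.Series:
    """Geometric mean of a gene's fold-change ranks over all replicate pairs."""
    log_folds = _pairwise_log_folds(expr, group_a, group_b)
    ranks = _ranks(log_folds, direction)
    rp = np.exp(np.mean(np.log(ranks), axis=1))
    return pd.Series(rp, index=expr.gene_ids, name=f"rp_{direction}")


def _stat_from_logs(log_a: np.ndarray, log_b: np.ndarray) -> dict[str, np.ndarray]:
    """Mean-log-rank statistic in both directions for one dataset."""
    log_folds = (log_b[:, None, :] - log_a[:, :, None]).reshape(log_a.shape[0], -1)
    out = {}
    for d in ("up", "down"):
        out[d] = np.mean(np.log(_ranks(log_folds, d)), axis=1)
    return out


def rank_product_pvalues(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample-permutation p-values for both directions of the rank product.

    Each of the ``n_perm`` null datasets reallocates the pooled replicates
    of the two groups at random (whole samples move, preserving the
    correlation between comparisons that share a replicate) and recomputes
    the statistic for every gene.  Per gene,
    p = (1 + #{null RP <= observed RP}) / (1 + G * n_perm), with the null
    pooled over genes and permutations within each direction.
    Columns: rp_up, rp_down, p_up, p_down.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    log_a = np.log(expr.submatrix(group_a))
    log_b = np.log(expr.submatrix(group_b))
    n_a, n_b = log_a.shape[1], log_b.shape[1]
    n_genes = log_a.shape[0]
    obs = _stat_from_logs(log_a, log_b)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([log_a, log_b], axis=1)
    null = {d: np.empty((n_perm, n_genes)) for d in ("up", "down")}
    for i in range(n_perm):
        order = rng.permutation(n_a + n_b)
        stat = _stat_from_logs(pooled[:, order[:n_a]], pooled[:, order[n_a:]])
        null["up"][i] = stat["up"]
        null["down"][i] = stat["down"]

    denom = 1 + n_genes * n_perm
    eps = 1e-9  # nudge right so exact float ties count as <=
    pcols = {}
    for d in ("up", "down"):
        pool = np.sort(null[d].ravel())
        pcols[f"p_{d}"] = (1 + np.searchsorted(pool, obs[d] + eps, side="right")) / denom
    return pd.DataFrame(
        {
            "rp_up": np.exp(obs["up"]),
            "rp_down": np.exp(obs["down"]),
            **pcols,
        },
        index=expr.gene_ids,
    )


def rank_product_table(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    q_cutoff: float = Q_CUTOFF,
) -> pd.DataFrame:
    """Full DEG table: fold, RP statistics, p-values, BH q, is_deg flag.

    The per-gene p is min(p_up, p_down); the BH correction is applied to
    2*min(p_up, p_down) capped at 1 (Bonferroni over the two directions).
    """
    tab = rank_product_pvalues(expr, group_a, group_b, n_perm=n_perm, seed=seed)
    tab.insert(0, "fold", fold_change(expr, group_a, group_b))
    tab["p"] = tab[["p_up", "p_down"]].min(axis=1)
    tab["q"] = bh_fdr(np.minimum(2.0 * tab["p"].to_numpy(), 1.0))
    tab["is_deg"] = tab["q"] < q_cutoff
    tab.index.name = "gene"
    return tab


def call_degs(
    deg_table: pd.DataFrame,
    q_cutoff: float = Q_CUTOFF,
    fold_cutoff: float = FOLD_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a DEG table into the DEG set and the reported set.

    DEG set: q strictly below ``q_cutoff``.  Reported set: additionally at
    least ``fold_cutoff``-fold changed in either direction.
    """
    if deg_table.empty:
        raise ValueError("DEG table is empty")
    degs = deg_table[deg_table["q"] < q_cutoff]
    reported = degs[degs["fold"].abs() >= fold_cutoff]
    return degs, reported
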
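"""Relative qPCR quantification against reference genes, with a
randomization test.

A target's expression ratio between two groups is computed from cycle
thresholds (Ct): ratio = E_t^dCt_t / geomean_r(E_r^dCt_r), where
dCt = mean Ct(group A) - mean Ct(group B), E is the per-gene amplification
efficiency (2.0 = perfect doubling each cycle), and the denominator is the
geometric mean over the designated reference genes — transcripts assumed
equally expressed in both groups, which cancel loading and run offsets.
Technical replicates are averaged into their biological replicate before any
group statistics.

Significance comes from a randomization test: biological replicates are
reallocated between the two group labels (all genes of a replicate move
together, so reference normalization is preserved), and the two-sided
p-value is the fraction of B reallocations whose |log ratio| meets or
exceeds the observed one, with a +1 pseudocount.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["expression_ratio", "randomization_test", "quantify"]

DEFAULT_EFFICIENCY = 2.0
DEFAULT_B = 2000


def _bio_means(data: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates: one Ct per (gene, group, bio_rep)."""
    req = {"gene", "group", "bio_rep", "Ct"}
    if not req.issubset(data.columns):
        raise ValueError(f"qPCR data needs columns {sorted(req)}")
    return data.groupby(["gene", "group", "bio_rep"], as_index=False)["Ct"].mean()


def _ratio_from_means(
    bio: pd.DataFrame,
    target: str,
    references: list[str],
    group_a: str,
    group_b: str,
    efficiencies: dict[str, float] | None,
) -> float:
    def eff(gene: str) -> float:
        e = (efficiencies or {}).get(gene, DEFAULT_EFFICIENCY)
        if not 1.0 < e <= 2.0:
            raise ValueError(f"amplification efficiency of {gene!r} must be in (1, 2], got {e}")
        return e

    def delta_ct(gene: str) -> float:
        sub = bio[bio["gene"] == gene]
        ct_a = sub.loc[sub["group"] == group_a, "Ct"]
        ct_b = sub.loc[sub["group"] == group_b, "Ct"]
        if ct_a.empty or ct_b.empty:
            raise ValueError(f"gene {gene!r} not measured in both groups")
        return float(ct_a.mean() - ct_b.mean())

    log_num = np.log(eff(target)) * delta_ct(target)
    log_den = np.mean([np.log(eff(r)) * delta_ct(r) for r in references])
    return float(np.exp(log_num - log_den))


def expression_ratio(
    data: pd.DataFrame,
    target: str,
    references,
    group_a: str,
    group_b: str,
    efficiencies: dict[str, float] | None = None,
) -> float:
    """Reference-normalized expression ratio of ``target``, group B over A."""
    references = list(references)
    if not references:
        raise ValueError("at least one reference gene is required")
    if target in references:
        raise ValueError(f"target {target!r} cannot also be a reference")
    return _ratio_from_means(_bio_means(data), target, references, group_a, group_b, efficiencies)


def randomization_test(
    data: pd.DataFrame,
    target: str,
    references,
    group_a: str,
    group_b: str,
    B: int = DEFAULT_B,
    seed: int = 0,
    efficiencies: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Two-sided randomization p-value for a target's expression ratio.

    Returns (ratio, p).  Each of the B randomizations reallocates the
    biological replicates between the group labels, keeping group sizes and
    moving every gene's Ct values of a replicate jointly;
    p = (1 + #{|log ratio*| >= |log ratio|}) / (B + 1).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    references = list(references)
    bio = _bio_means(data)

    # replicate units: (group, bio_rep) pairs present for the target
    units = bio[bio["group"].isin([group_a, group_b])][["group", "bio_rep"]].drop_duplicates()
    n_a = (units["group"] == group_a).sum()
    n_b = (units["group"] == group_b).sum()
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 biological replicates per group")

    observed = _ratio_from_means(bio, target, references, group_a, group_b, efficiencies)
    obs_stat = abs(np.log(observed))

    genes = [target, *references]
    log_eff = np.array(
        [np.log((efficiencies or {}).get(g, DEFAULT_EFFICIENCY)) for g in genes]
    )
    # Ct matrix (genes x replicate units); a unit is one biological replicate
    wide = bio[bio["gene"].isin(genes)].pivot_table(
        index="gene", columns=["group", "bio_rep"], values="Ct"
    )
    wide = wide.loc[genes, list(units.itertuples(index=False, name=None))]
    ct = wide.to_numpy()
    if np.isnan(ct).any():
        raise ValueError("every gene must be measured in every biological replicate")

    rng = np.random.default_rng(seed)
    n_units = n_a + n_b
    # B random reallocations: each row permutes the units, first n_a -> group A
    perms = np.argsort(rng.random((B, n_units)), axis=1)
    in_a = np.zeros((B, n_units))
    np.put_along_axis(in_a, perms[:, :n_a], 1.0, axis=1)
    mean_a = in_a @ ct.T / n_a            # (B, genes)
    mean_b = (1.0 - in_a) @ ct.T / n_b
    dct = mean_a - mean_b
    log_ratios = log_eff[0] * dct[:, 0] - (log_eff[1:] * dct[:, 1:]).mean(axis=1)
    hits = int(np.sum(np.abs(log_ratios) >= obs_stat - 1e-12))
    return observed, (1 + hits) / (B + 1)


def quantify(
    data: pd.DataFrame,
    targets,
    references,
    group_a: str,
    group_b: str,
    B: int = DEFAULT_B,
    seed: int = 0,
    efficiencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Ratio and randomization p for each target gene; one row per target."""
    rows = []
    for i, t in enumerate(targets):
        ratio, p = randomization_test(
            data, t, references, group_a, group_b, B=B, seed=seed + i, efficiencies=efficiencies
        )
        rows.append((t, ratio, p, B))
    return pd.DataFrame(rows, columns=["gene", "ratio", "p", "B"])
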
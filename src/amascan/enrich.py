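"""Hypergeometric enrichment of DEG lists: GO-style terms and protein domains.

Two counting modes are exposed because they answer different questions and
give different numbers:

* **gene mode** — classical term enrichment.  The unit is the gene: N is the
  background gene count, M the background genes carrying the term, n the DEG
  genes in the background, k the DEG genes carrying the term.
* **domain-instance mode** — the unit is the domain *instance*, so a protein
  with two copies of a domain contributes two: N is the total number of
  domain instances genome-wide, M the instances of the specific domain, n the
  instances on DEG-encoded proteins, k the instances of the specific domain
  among those.

For each term or domain the enrichment factor EF = k / (n*M/N) is the
observed-over-expected count, and the E-score is the exact upper-tail
hypergeometric probability of at least k annotated items among the n drawn.
BH correction is applied across all rows of one run; rows with corrected
p < 0.05 are flagged significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GeneCatalog
from .stats import bh_fdr, hypergeom_tail

__all__ = [
    "hypergeom_tail",
    "enrichment_factor",
    "gene_mode_counts",
    "domain_mode_counts",
    "run_enrichment",
]


def enrichment_factor(k: int, n: int, M: int, N: int) -> float:
    """EF = k/(n*M/N): observed over expected annotated count among DEGs."""
    if n <= 0 or M <= 0:
        raise ValueError(f"need n > 0 and M > 0, got n={n}, M={M}")
    return k * N / (n * M)


def gene_mode_counts(
    deg_set, catalog: GeneCatalog, term: str, whole_genome_background: bool = False
) -> tuple[int, int, int, int]:
    """(k, n, M, N) counting genes.

    By default the background N is restricted to genes with at least one term
    annotation (the convention of term-enrichment tools, which cannot score
    unannotated genes); ``whole_genome_background=True`` uses every catalog
    gene instead.
    """
    terms = catalog.terms
    if terms.empty:
        raise ValueError("catalog has no term annotations")
    if term not in set(terms["term"]):
        raise KeyError(f"term {term!r} not in catalog")
    if whole_genome_background:
        background = set(catalog.genes["gene"])
    else:
        background = set(terms["gene"])
    deg_in_bg = set(deg_set) & background
    with_term = set(terms.loc[terms["term"] == term, "gene"])
    N = len(background)
    M = len(with_term & background)
    n = len(deg_in_bg)
    k = len(deg_in_bg & with_term)
    return k, n, M, N


def domain_mode_counts(deg_set, catalog: GeneCatalog, domain: str) -> tuple[int, int, int, int]:
    """(k, n, M, N) counting domain instances (repeated rows = multiplicity)."""
    domains = catalog.domains
    if domains.empty:
        raise ValueError("catalog has no domain annotations")
    if domain not in set(domains["domain"]):
        raise KeyError(f"domain {domain!r} not in catalog")
    deg_set = set(deg_set)
    on_deg = domains["gene"].isin(deg_set)
    is_dom = domains["domain"] == domain
    N = len(domains)
    M = int(is_dom.sum())
    n = int(on_deg.sum())
    k = int((on_deg & is_dom).sum())
    return k, n, M, N


def run_enrichment(
    deg_set,
    catalog: GeneCatalog,
    mode: str = "gene",
    alpha: float = 0.05,
    whole_genome_background: bool = False,
) -> pd.DataFrame:
    """Score every term (or domain) in the background against a DEG list.

    Returns one row per annotation id with columns (id, k, n, M, N, EF,
    p_raw, q, significant), sorted by ascending raw p then id.
    """
    deg_set = set(deg_set)
    if not deg_set:
        raise ValueError("DEG set is empty")
    missing = deg_set - set(catalog.genes["gene"])
    if missing:
        raise ValueError(f"DEG genes absent from catalog: {sorted(missing)[:5]}")

    if mode == "gene":
        ids = sorted(set(catalog.terms["term"])) if not catalog.terms.empty else []
        counter = lambda t: gene_mode_counts(
            deg_set, catalog, t, whole_genome_background=whole_genome_background
        )
    elif mode == "domain_instance":
        ids = sorted(set(catalog.domains["domain"])) if not catalog.domains.empty else []
        counter = lambda d: domain_mode_counts(deg_set, catalog, d)
    else:
        raise ValueError(f"mode must be 'gene' or 'domain_instance', got {mode!r}")
    if not ids:
        raise ValueError(f"catalog has no annotations for mode {mode!r}")

    rows = []
    for ident in ids:
        k, n, M, N = counter(ident)
        ef = enrichment_factor(k, n, M, N) if (n > 0 and M > 0) else np.nan
        p_raw = hypergeom_tail(k, n, M, N) if n > 0 else 1.0
        rows.append((ident, k, n, M, N, ef, p_raw))
    out = pd.DataFrame(rows, columns=["id", "k", "n", "M", "N", "EF", "p_raw"])
    out["q"] = bh_fdr(out["p_raw"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out.sort_values(["p_raw", "id"], kind="mergesort").reset_index(drop=True)
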
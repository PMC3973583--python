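"""End-to-end driver chaining DEG calling, the genome scan and enrichment.

One global seed drives the whole run; each stage receives a seed derived
deterministically from the global seed and the stage name (CRC32 hashing),
so stages are individually reproducible and reordering stages cannot change
their streams.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__, io, rankprod, scan, enrich
from .synthetic import SimulationConfig, simulate_catalog, simulate_expression

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed", "format_percent", "percent_string"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name mixed with the
    global seed, reduced below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def format_percent(k: int, n: int) -> float:
    """Share of ``k`` out of ``n`` as a percentage rounded to one decimal."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, 1)


def percent_string(k: int, n: int) -> str:
    """The report's rendering, e.g. 20 of 234 -> '8.5%'."""
    return f"{format_percent(k, n):.1f}%"


@dataclass
class PipelineConfig:
    """Parameters of a full synthetic-data pipeline run."""

    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    group_a: str = "group1"
    group_b: str = "group2"
    n_perm: int = 1000
    q_cutoff: float = 0.05
    fold_cutoff: float = 2.0
    q_frac: float = 0.01
    width: int = 500_000
    step: int = 250_000
    cutoff: float = 2.0
    derive_sim_seed: bool = True  # replace sim.seed with a seed derived from the global one

    def __post_init__(self) -> None:
        if not 0 < self.q_frac < 1:
            raise ValueError("q_frac must be in (0, 1)")
        if not 0 < self.q_cutoff < 1:
            raise ValueError("q_cutoff must be in (0, 1)")
        if self.fold_cutoff < 1:
            raise ValueError("fold_cutoff must be >= 1")
        if self.derive_sim_seed:
            self.sim = SimulationConfig(**{**asdict(self.sim), "seed": derive_seed(self.seed, "simulate")})


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Simulate -> DEG -> genome scan -> enrichment (both modes) -> report.

    Returns the run report as a dict; when ``outdir`` is given, every stage
    output and the report are also written as TSV/JSON with provenance
    headers.  Deterministic for a fixed config.
    """
    expr, truth = simulate_expression(config.sim)
    catalog = simulate_catalog(config.sim, truth)

    deg_table = rankprod.rank_product_table(
        expr,
        config.group_a,
        config.group_b,
        n_perm=config.n_perm,
        seed=derive_seed(config.seed, "deg"),
        q_cutoff=config.q_cutoff,
    )
    degs, reported = rankprod.call_degs(
        deg_table, q_cutoff=config.q_cutoff, fold_cutoff=config.fold_cutoff
    )

    grid = scan.make_bins(catalog.arm_lengths, width=config.width, step=config.step)
    top = scan.select_top_fraction(deg_table, q_frac=config.q_frac)
    track = scan.score_bins(grid, catalog, top, p=config.q_frac)
    clusters = scan.call_clusters(track, catalog, top, cutoff=config.cutoff)

    deg_ids = list(degs.index)
    empty_cols = ["id", "k", "n", "M", "N", "EF", "p_raw", "q", "significant"]
    if deg_ids:
        term_enrich = enrich.run_enrichment(deg_ids, catalog, mode="gene")
        domain_enrich = enrich.run_enrichment(deg_ids, catalog, mode="domain_instance")
    else:  # a null run with no DEGs has nothing to enrich
        term_enrich = pd.DataFrame(columns=empty_cols)
        domain_enrich = pd.DataFrame(columns=empty_cols)

    report = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "n_perm": config.n_perm,
            "q_cutoff": config.q_cutoff,
            "fold_cutoff": config.fold_cutoff,
            "q_frac": config.q_frac,
            "width": config.width,
            "step": config.step,
            "cutoff": config.cutoff,
        },
        "n_genes": int(expr.n_genes),
        "n_degs": int(len(degs)),
        "n_reported_degs": int(len(reported)),
        "pct_reported_of_degs": format_percent(len(reported), len(degs)) if len(degs) else 0.0,
        "n_top_set": len(top),
        "n_clusters": len(clusters),
        "clusters": [
            {"arm": c.arm, "start": c.start, "end": c.end,
             "peak_score": round(c.peak_score, 3), "n_genes": len(c.genes)}
            for c in clusters
        ],
        "n_significant_terms": int(term_enrich["significant"].sum()),
        "n_significant_domains": int(domain_enrich["significant"].sum()),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seed = config.seed
        io.write_expression(expr, outdir / "expression.tsv", seed=seed)
        io.write_groups(dict(expr.groups), outdir / "groups.tsv")
        io.write_catalog(catalog, outdir / "catalog.tsv", seed=seed)
        io.write_annotations(catalog.terms, outdir / "terms.tsv", seed=seed)
        io.write_annotations(catalog.domains, outdir / "domains.tsv", seed=seed)
        io.write_table(deg_table, outdir / "deg.tsv", params=report["parameters"], seed=seed, index=True)
        io.write_table(track, outdir / "bins.tsv", params=report["parameters"], seed=seed)
        cluster_rows = [
            {"arm": c.arm, "start": c.start, "end": c.end,
             "peak_score": c.peak_score, "genes": ",".join(c.genes)}
            for c in clusters
        ]
        io.write_table(
            pd.DataFrame(cluster_rows, columns=["arm", "start", "end", "peak_score", "genes"]),
            outdir / "clusters.tsv", params=report["parameters"], seed=seed,
        )
        (outdir / "scan.bedgraph").write_text(scan.to_bedgraph(track))
        io.write_table(term_enrich, outdir / "enrichment_terms.tsv", seed=seed)
        io.write_table(domain_enrich, outdir / "enrichment_domains.tsv", seed=seed)
        (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")

    return report
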
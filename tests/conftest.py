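"""Shared fixtures: synthetic datasets at the default study design.

The ``default_run`` fixture is session-scoped because the full-size
rank-product permutation run is the most expensive step in the suite; every
test that asks about the default study conditions (5/5/6 replicates,
11,890 genes, planted folds 2-300x, a 40-gene cluster in a 500-kb window)
shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

from amascan import rankprod, scan
from amascan.synthetic import SimulationConfig, simulate_catalog, simulate_expression


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline state on the default planted simulation."""
    cfg = SimulationConfig(seed=1)
    expr, truth = simulate_expression(cfg)
    catalog = simulate_catalog(cfg, truth)
    deg_table = rankprod.rank_product_table(expr, "group1", "group2", n_perm=200, seed=3)
    degs, reported = rankprod.call_degs(deg_table)
    grid = scan.make_bins(catalog.arm_lengths)
    top = scan.select_top_fraction(deg_table)
    track = scan.score_bins(grid, catalog, top)
    clusters = scan.call_clusters(track, catalog, top)
    return {
        "config": cfg,
        "expr": expr,
        "truth": truth,
        "catalog": catalog,
        "deg_table": deg_table,
        "degs": degs,
        "reported": reported,
        "top": top,
        "track": track,
        "clusters": clusters,
    }


@pytest.fixture
def small_config():
    """A light configuration for tests that only need structure, not power."""
    return SimulationConfig(
        seed=11,
        n_genes=400,
        n_de_genes=20,
        cluster_spec=("3L", 12_000_000, 500_000, 5),
        n_terms=30,
        n_domains=20,
    )


@pytest.fixture
def tiny_expr():
    """4 genes x (2+2) samples with hand-set values, noise-free."""
    import pandas as pd
    from amascan.containers import ExpressionMatrix

    values = pd.DataFrame(
        {
            "a1": [10.0, 10.0, 40.0, 5.0],
            "a2": [10.0, 10.0, 40.0, 5.0],
            "b1": [10.0, 40.0, 10.0, 5.0],
            "b2": [10.0, 40.0, 10.0, 5.0],
        },
        index=pd.Index(["flat", "up4", "down4", "low"], name="gene"),
    )
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return ExpressionMatrix(values=values, groups=groups)
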
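"""Term and domain-instance enrichment: counts, EF, tails, BH behaviour."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from amascan import enrich
from amascan.containers import GeneCatalog


def build_catalog(terms=None, domains=None, n_genes=20):
    genes = [f"g{i:02d}" for i in range(n_genes)]
    gene_df = pd.DataFrame(
        {
            "gene": genes,
            "arm": "2L",
            "start": [1000 * i for i in range(n_genes)],
            "end": [1000 * i + 500 for i in range(n_genes)],
        }
    )
    term_df = pd.DataFrame(terms or [], columns=["gene", "term"])
    dom_df = pd.DataFrame(domains or [], columns=["gene", "domain"])
    return GeneCatalog(
        genes=gene_df, arm_lengths={"2L": 10**6}, terms=term_df, domains=dom_df
    )


class TestEnrichmentFactor:
    def test_expectation_case_is_one(self):
        # k = n*M/N exactly: 5 = 10*10/20
        assert enrich.enrichment_factor(5, 10, 10, 20) == pytest.approx(1.0)

    def test_reduces_to_k_over_n_when_every_gene_annotated(self):
        assert enrich.enrichment_factor(3, 12, 30, 30) == pytest.approx(3 / 12)

    def test_printed_p450_counts(self):
        # 48 domain instances among 2609 on DEGs vs 91 among 11890 genome-wide
        assert enrich.enrichment_factor(48, 2609, 91, 11890) == pytest.approx(2.404, abs=5e-4)

    def test_rejects_degenerate_denominators(self):
        with pytest.raises(ValueError):
            enrich.enrichment_factor(0, 0, 5, 10)
        with pytest.raises(ValueError):
            enrich.enrichment_factor(0, 5, 0, 10)


class TestGeneModeCounts:
    def test_deg_equals_background_gives_ef_one_everywhere(self):
        terms = [(f"g{i:02d}", "T1") for i in range(6)] + [
            (f"g{i:02d}", "T2") for i in range(3, 12)
        ]
        cat = build_catalog(terms=terms)
        background = sorted({g for g, _ in terms})
        for term in ("T1", "T2"):
            k, n, M, N = enrich.gene_mode_counts(background, cat, term)
            assert (k, n) == (M, N)
            assert enrich.enrichment_factor(k, n, M, N) == pytest.approx(1.0)

    def test_term_absent_from_degs(self):
        terms = [("g00", "T1"), ("g01", "T1"), ("g02", "T2")]
        cat = build_catalog(terms=terms)
        k, n, M, N = enrich.gene_mode_counts(["g02"], cat, "T1")
        assert k == 0
        assert enrich.hypergeom_tail(k, n, M, N) == 1.0

    def test_whole_genome_background_flag(self):
        terms = [("g00", "T1"), ("g01", "T1")]
        cat = build_catalog(terms=terms, n_genes=20)
        _, _, _, N_annot = enrich.gene_mode_counts(["g00"], cat, "T1")
        _, _, _, N_all = enrich.gene_mode_counts(
            ["g00"], cat, "T1", whole_genome_background=True
        )
        assert N_annot == 2
        assert N_all == 20

    def test_unknown_term_rejected(self):
        cat = build_catalog(terms=[("g00", "T1")])
        with pytest.raises(KeyError):
            enrich.gene_mode_counts(["g00"], cat, "T9")


class TestDomainModeCounts:
    def test_single_instance_per_gene_reduces_to_gene_mode(self):
        rows = [(f"g{i:02d}", "D1" if i < 4 else "D2") for i in range(10)]
        cat = build_catalog(terms=[(g, d) for g, d in rows], domains=rows)
        deg = [f"g{i:02d}" for i in range(5)]
        assert enrich.domain_mode_counts(deg, cat, "D1") == enrich.gene_mode_counts(
            deg, cat, "D1"
        )

    def test_multiplicity_counted_as_instances(self):
        domains = [("g00", "D1"), ("g00", "D1"), ("g00", "D1"), ("g01", "D2")]
        cat = build_catalog(domains=domains)
        k, n, M, N = enrich.domain_mode_counts(["g00"], cat, "D1")
        assert (k, n, M, N) == (3, 3, 3, 4)

    def test_background_totals_round_trip(self):
        """A catalog built to the printed background geometry (N instances,
        n on DEGs) reproduces those totals exactly from the counting rule."""
        rng = np.random.default_rng(0)
        n_genes, N_target = 120, 600
        genes = [f"g{i:03d}" for i in range(n_genes)]
        dom_rows = [
            (genes[rng.integers(n_genes)], f"D{rng.integers(8)}") for _ in range(N_target)
        ]
        gene_df = pd.DataFrame(
            {"gene": genes, "arm": "2L", "start": range(n_genes), "end": [x + 1 for x in range(n_genes)]}
        )
        cat = GeneCatalog(
            genes=gene_df, arm_lengths={"2L": 10**6},
            domains=pd.DataFrame(dom_rows, columns=["gene", "domain"]),
        )
        deg = genes[:30]
        dom = dom_rows[0][1]
        k, n, M, N = enrich.domain_mode_counts(deg, cat, dom)
        tab = cat.domains
        assert N == N_target
        assert n == int(tab["gene"].isin(deg).sum())
        assert M == int((tab["domain"] == dom).sum())
        assert k == int((tab["gene"].isin(deg) & (tab["domain"] == dom)).sum())


class TestRunEnrichment:
    def test_perfectly_coextensive_term_attains_minimum_p(self):
        terms = [(f"g{i:02d}", "HIT") for i in range(5)]
        terms += [(f"g{i:02d}", "BG") for i in range(20)]
        cat = build_catalog(terms=terms)
        out = enrich.run_enrichment([f"g{i:02d}" for i in range(5)], cat, mode="gene")
        hit = out[out["id"] == "HIT"].iloc[0]
        assert hit["p_raw"] == pytest.approx(
            enrich.hypergeom_tail(hit["k"], hit["n"], hit["M"], hit["N"])
        )
        assert out["p_raw"].min() == hit["p_raw"]

    def test_planted_overrepresented_term_ranks_first(self):
        rng = np.random.default_rng(42)
        n_genes = 500
        genes = [f"g{i:02d}" for i in range(n_genes)]
        terms = []
        for t in range(20):
            for g in rng.choice(genes, size=40, replace=False):
                terms.append((g, f"T{t:02d}"))
        planted = list(rng.choice(genes, size=40, replace=False))
        terms += [(g, "PLANTED") for g in planted]
        cat = build_catalog(terms=terms, n_genes=n_genes)
        # DEG list = 30 planted carriers + 30 random others: ~5x over-representation
        others = [g for g in genes if g not in planted]
        deg = planted[:30] + list(rng.choice(others, size=30, replace=False))
        out = enrich.run_enrichment(deg, cat, mode="gene")
        assert out.iloc[0]["id"] == "PLANTED"
        assert out.iloc[0]["q"] == out["q"].min()

    def test_null_significance_rate_controlled(self):
        """Random DEG draws against a null catalog: on average at most ~5%
        of terms reach q < 0.05."""
        rng = np.random.default_rng(3)
        n_genes = 300
        genes = [f"g{i:02d}" for i in range(n_genes)]
        terms = []
        for t in range(30):
            for g in rng.choice(genes, size=30, replace=False):
                terms.append((g, f"T{t:02d}"))
        cat = build_catalog(terms=terms, n_genes=n_genes)
        rates = []
        for _ in range(200):
            deg = list(rng.choice(genes, size=40, replace=False))
            out = enrich.run_enrichment(deg, cat, mode="gene")
            rates.append(out["significant"].mean())
        mean_rate = float(np.mean(rates))
        se = float(np.std(rates) / np.sqrt(len(rates)))
        assert mean_rate <= 0.05 + 3 * se

    def test_q_never_below_raw_p(self, default_run):
        out = enrich.run_enrichment(
            list(default_run["degs"].index), default_run["catalog"], mode="domain_instance"
        )
        assert (out["q"] >= out["p_raw"] - 1e-12).all()
        assert (out["p_raw"] < 1).equals(out["k"] >= 1)

    def test_empty_deg_set_rejected(self):
        cat = build_catalog(terms=[("g00", "T1")])
        with pytest.raises(ValueError):
            enrich.run_enrichment([], cat, mode="gene")
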
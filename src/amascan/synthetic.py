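"""Synthetic data generators mirroring the study design the pipeline assumes.

Everything downstream of raw arrays is testable against known ground truth:
the generators produce (i) a gene-by-sample intensity matrix for three larval
groups (5/5/6 biological replicates) over a ~11,890-gene transcriptome with
planted differentially expressed genes, (ii) a gene catalog on the five major
Drosophila chromosome arms with a planted 500-kb cluster of strong DEGs and
realistic term/domain annotation catalogs, (iii) binomial survival counts
from a known dose-response truth curve, and (iv) qPCR Ct tables from known
expression ratios.

Design defaults emulate the emulated study: groups of 5, 5 and 6 replicates;
planted fold changes spanning 2- to 300-fold (half up, half down, recorded
with the signed convention +r / -1/r); log-normal baseline intensities;
multiplicative log-normal noise per sample.  Clustered DE genes draw their
folds from the top of the fold range so that they land in the top-1% set the
genome scan consumes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneCatalog

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_catalog",
    "simulate_dose_response",
    "simulate_qpcr",
    "DEFAULT_ARMS",
]

# Five major arms, lengths within the 22-28 Mb range of the fly genome build
DEFAULT_ARMS: tuple[tuple[str, int], ...] = (
    ("X", 22_400_000),
    ("2L", 23_000_000),
    ("2R", 25_300_000),
    ("3L", 24_500_000),
    ("3R", 27_900_000),
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults reproduce the emulated design."""

    seed: int = 0
    n_genes: int = 11_890
    arms: tuple[tuple[str, int], ...] = DEFAULT_ARMS
    group_sizes: tuple[int, ...] = (5, 5, 6)
    group_names: tuple[str, ...] = ("group1", "group2", "group3")
    n_de_genes: int = 300
    de_fold_range: tuple[float, float] = (2.0, 300.0)
    de_group: str = "group2"  # group whose mean is multiplied by the planted fold
    noise_cv: float = 0.2
    baseline_meanlog: float = 6.0
    baseline_sdlog: float = 1.0
    # planted cluster: (arm, start bp, width bp, number of clustered DE genes)
    cluster_spec: tuple[str, int, int, int] = ("3L", 12_000_000, 500_000, 40)
    # minimum |fold| for clustered genes, so they reach the top-1% selection
    cluster_min_fold: float = 50.0
    n_terms: int = 200
    term_size_range: tuple[int, int] = (5, 400)
    n_domains: int = 150
    domain_rate: float = 1.5  # mean domain instances per gene (Poisson)
    gene_span: int = 1_000  # bp; genes are stored as midpoint +/- span/2

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if any(s < 2 for s in self.group_sizes):
            raise ValueError("every group needs at least 2 replicates")
        if len(self.group_sizes) != len(self.group_names):
            raise ValueError("group_sizes and group_names must align")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if self.n_de_genes < 0 or self.noise_cv < 0:
            raise ValueError("n_de_genes and noise_cv must be non-negative")
        lo, hi = self.de_fold_range
        if not 1.0 < lo <= hi:
            raise ValueError("de_fold_range must satisfy 1 < min <= max")
        if self.de_group not in self.group_names:
            raise ValueError(f"de_group {self.de_group!r} not among group_names")
        arm, start, width, n_clustered = self.cluster_spec
        arm_lengths = dict(self.arms)
        if arm not in arm_lengths:
            raise ValueError(f"cluster arm {arm!r} not among arms")
        if not (0 <= start and start + width <= arm_lengths[arm]):
            raise ValueError("cluster window must lie within its arm")
        if n_clustered > self.n_de_genes:
            raise ValueError("clustered genes must be a subset of DE genes")
        if width < n_clustered * self.gene_span:
            raise ValueError("cluster window too narrow for the requested gene count")

    def gene_ids(self) -> list[str]:
        digits = len(str(self.n_genes))
        return [f"g{i:0{digits}d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """What was planted, for recovery checks downstream."""

    de_folds: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))  # signed
    clustered_gene_ids: list[str] = field(default_factory=list)
    de_group: str = "group2"
    baseline_group: str = "group1"


def _planted_folds(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """Signed folds for the DE genes; clustered genes get the strongest ones."""
    genes = config.gene_ids()
    de_ids = list(rng.choice(genes, size=config.n_de_genes, replace=False))
    lo, hi = config.de_fold_range
    magnitudes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_de_genes))
    # clustered genes occupy the first slots and draw from the top of the range
    n_clustered = config.cluster_spec[3]
    if n_clustered:
        c_lo = min(max(lo, config.cluster_min_fold), hi)
        magnitudes[:n_clustered] = np.exp(
            rng.uniform(np.log(c_lo), np.log(hi), size=n_clustered)
        )
    # half up, half down; signed convention: +m = m-fold up, -m = m-fold down
    signs = rng.permuted(np.resize([1.0, -1.0], config.n_de_genes))
    return pd.Series(signs * magnitudes, index=de_ids, name="true_fold")


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Intensity matrix for all groups plus the planted truth.

    Per gene: a log-normal baseline mean; in ``de_group`` the mean of each DE
    gene is multiplied by its true linear fold; every sample then receives
    independent multiplicative log-normal noise with the configured
    coefficient of variation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    truth_folds = _planted_folds(config, rng)

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, config.n_genes)
    linear_fold = np.ones(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, f in truth_folds.items():
        linear_fold[gene_pos[g]] = f if f > 0 else -1.0 / f

    if config.noise_cv > 0:
        sdlog = np.sqrt(np.log1p(config.noise_cv**2))
        mulog = -(sdlog**2) / 2  # unit-mean multiplicative noise
    else:
        sdlog = mulog = 0.0

    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for name, size in zip(config.group_names, config.group_sizes):
        mean = baseline * linear_fold if name == config.de_group else baseline
        for r in range(1, size + 1):
            sample = f"{name}_r{r}"
            noise = rng.lognormal(mulog, sdlog, config.n_genes) if sdlog else 1.0
            columns[sample] = mean * noise
            groups[sample] = name
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    truth = GroundTruth(
        de_folds=truth_folds,
        clustered_gene_ids=list(truth_folds.index[: config.cluster_spec[3]]),
        de_group=config.de_group,
        baseline_group=next(n for n in config.group_names if n != config.de_group),
    )
    return ExpressionMatrix(values=values, groups=groups), truth


def simulate_catalog(config: SimulationConfig, truth: GroundTruth | None = None) -> GeneCatalog:
    """Gene coordinates and term/domain catalogs consistent with the truth.

    Non-clustered genes get uniform-random midpoints across the five arms
    (proportional to arm length); the clustered DE gene ids are placed inside
    the configured window.  Terms are gene sets of log-uniform random size;
    domain instances are assigned per gene with Poisson multiplicity and
    skewed domain popularity, so a few domains are common and most are rare.
    """
    config.validate()
    # independent stream so catalog and expression can be generated in any order
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    genes = config.gene_ids()
    arm_names = [a for a, _ in config.arms]
    arm_lengths = dict(config.arms)
    half = config.gene_span // 2

    clustered = list(truth.clustered_gene_ids) if truth else []
    c_arm, c_start, c_width, _ = config.cluster_spec
    clustered_set = set(clustered)

    weights = np.array([arm_lengths[a] for a in arm_names], dtype=float)
    weights /= weights.sum()
    rows = []
    arm_draw = rng.choice(arm_names, size=len(genes), p=weights)
    for g, arm in zip(genes, arm_draw):
        if g in clustered_set:
            arm = c_arm
            mid = int(rng.integers(c_start + half, c_start + c_width - half))
        else:
            mid = int(rng.integers(half, arm_lengths[arm] - half))
        rows.append((g, arm, mid - half, mid + half))
    gene_df = pd.DataFrame(rows, columns=["gene", "arm", "start", "end"])

    lo, hi = config.term_size_range
    term_rows = []
    for t in range(config.n_terms):
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        term_rows += [(g, f"T{t:04d}") for g in members]
    term_df = pd.DataFrame(term_rows, columns=["gene", "term"])

    # skewed domain popularity (Zipf-like), Poisson instance count per gene
    dom_ids = [f"D{d:04d}" for d in range(config.n_domains)]
    popularity = 1.0 / np.arange(1, config.n_domains + 1)
    popularity /= popularity.sum()
    counts = rng.poisson(config.domain_rate, size=len(genes))
    dom_rows = []
    for g, c in zip(genes, counts):
        for d in rng.choice(dom_ids, size=c, p=popularity):
            dom_rows.append((g, d))
    dom_df = pd.DataFrame(dom_rows, columns=["gene", "domain"])

    return GeneCatalog(
        genes=gene_df, arm_lengths=arm_lengths, terms=term_df, domains=dom_df
    )


def true_survival(concentration, lc50: float, hill: float = 2.0):
    """Monotone-decreasing truth curve: survival = 1 / (1 + (C/LC50)^h).

    Passes through (LC50, 0.5) for every slope h; h defaults to 2 so the
    curve is smooth and differentiable at C = 0.
    """
    c = np.asarray(concentration, dtype=float)
    return 1.0 / (1.0 + (c / lc50) ** hill)


def simulate_dose_response(
    true_lc50: float,
    concentrations,
    n_per_vial: int = 10,
    n_vials: int = 10,
    seed: int = 0,
    hill: float = 2.0,
) -> pd.DataFrame:
    """Binomial survivor counts per vial from the truth curve.

    Emulates the assay layout: ``n_vials`` tubes of ``n_per_vial`` larvae at
    each toxin concentration (default 10 x 10 = 100 larvae per dose).
    """
    if true_lc50 <= 0:
        raise ValueError("true_lc50 must be positive")
    concentrations = np.asarray(list(concentrations), dtype=float)
    if (concentrations < 0).any():
        raise ValueError("concentrations must be >= 0")
    if n_per_vial < 1 or n_vials < 1:
        raise ValueError("vial counts must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for c in concentrations:
        p = float(true_survival(c, true_lc50, hill))
        for v in range(1, n_vials + 1):
            rows.append((c, v, int(rng.binomial(n_per_vial, p)), n_per_vial))
    return pd.DataFrame(rows, columns=["concentration", "vial", "survivors", "total"])


def simulate_qpcr(
    true_ratios: dict[str, float],
    references: list[str] | None = None,
    n_replicates: tuple[int, int] = (5, 5),
    n_tech: int = 3,
    efficiency: float = 2.0,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
    group_names: tuple[str, str] = ("group1", "group2"),
    intercept: float = 40.0,
) -> pd.DataFrame:
    """Ct table from known expression ratios (group2 over group1).

    Ct = intercept - log_E(expression) + Gaussian noise; reference genes
    (appended automatically with ratio 1) have equal expected expression in
    both groups.  Three technical replicates per biological replicate by
    default.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    references = ["Sucb", "alpha-Tub84B"] if references is None else list(references)
    overlap = set(references) & set(true_ratios)
    if overlap:
        raise ValueError(f"reference genes cannot have planted ratios: {sorted(overlap)}")

    rng = np.random.default_rng(seed)
    all_genes = {**true_ratios, **{r: 1.0 for r in references}}
    base_expr = {g: float(np.exp(rng.uniform(np.log(100), np.log(10_000)))) for g in all_genes}
    log_e = np.log(efficiency)

    rows = []
    for gname, n_bio, is_b in (
        (group_names[0], n_replicates[0], False),
        (group_names[1], n_replicates[1], True),
    ):
        for gene, ratio in all_genes.items():
            expr = base_expr[gene] * (ratio if is_b else 1.0)
            ct_mean = intercept - np.log(expr) / log_e
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    ct = ct_mean + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0)
                    rows.append((gene, gname, b, t, float(ct)))
    return pd.DataFrame(rows, columns=["gene", "group", "bio_rep", "tech_rep", "Ct"])
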
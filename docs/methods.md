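# Methods notes

This note records the models implemented in `amascan`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generators do and do not emulate.

## Rank-product differential expression (`amascan.rankprod`)

The two-class rank product compares every replicate of one group against
every replicate of the other: K = n_A·n_B pairwise fold-change rankings,
statistic RP = geometric mean of a gene's K ranks, computed separately for
up- and down-regulation. Ties share the average rank. The statistic is
scale-free: any monotone per-sample transformation of intensities leaves it
unchanged, which is why it is popular for small-replicate microarray
designs.

**Permutation null.** Significance is assessed by reallocating whole
samples between the two group labels, recomputing the statistic, and
pooling the null values across genes and permutations:

    p = (1 + #{null RP <= observed RP}) / (1 + G * n_perm).

Two properties of this choice matter.

* *Why whole samples:* the K pairwise comparisons are not independent —
  every pair of comparisons sharing a replicate is positively correlated.
  A null that redraws each comparison's rank vector independently (as if
  the K comparisons were separate experiments) understates the variance of
  the mean log rank by roughly the factor (1 + 8ρ) at 5×5 replicates and is
  dramatically anti-conservative: on pure-noise data it put ~12% of genes
  below p = 0.01 and its q-values called hundreds of false DEGs.
  Sample-label permutation preserves the correlation structure by
  construction; on pure-noise simulations the resulting p-values are
  uniform to KS < 0.01 and BH q-values control the false call rate.
* *Pooling across genes:* pooling gives p-value resolution 1/(1+G·n_perm)
  rather than 1/(1+n_perm), which BH needs at genome scale. It assumes the
  null distribution of the statistic is shared across genes; for a rank
  statistic under exchangeable noise this holds exactly.

The +1 pseudocount keeps p strictly positive (required for logs and BH).
With 5v5 groups there are only C(10,5) = 252 distinct reallocations;
permutations are sampled with replacement, which leaves the estimator
unbiased and is simpler than enumerating, and the granularity is covered by
the pooling over genes.

**Direction combination.** Each gene is tested one-sided in both
directions; the summary p is min(p_up, p_down), and 2·min(...) (capped at
1) enters the BH step — a Bonferroni factor over the two tests. DEGs are
q < 0.05 (strict); the reported set additionally requires |fold| ≥ 2 on the
signed linear fold (+r for up, −1/r for down, so magnitudes are always
≥ 1).

Defaults: n_perm = 1000 (CLI and library); the test suite and the
acceptance script use 100–500 permutations, which at ~12,000 genes already
gives p-value resolution below 10⁻⁶ — entirely sufficient for the q < 0.05
decisions they check.

## Binomial coincidence scan (`amascan.scan`)

Arms are tiled from coordinate 0 with bins of width w = 500 kb every
s = 250 kb; terminal bins are truncated at the arm end and scored like any
other (the binomial model conditions on the resident count, so a short
bin simply has less power). Genes enter a bin by their midpoint — per-bin
counts are then independent of gene length, and with w = 2s every interior
gene is counted in exactly two bins.

The null probability is fixed at the selection fraction 0.01, not at the
realized fraction ⌊G·q⌋/G; the realized fraction is never larger, so the
fixed value is (marginally) conservative. Scores are log₁₀(1/P(X ≥ k_b))
with the exact binomial tail; bins score above the cutoff only with
score > 2 (strict), and flagged bins that overlap or touch merge into one
cluster call per arm. Arms are scanned independently.

Top-gene selection ranks by the per-gene p-value with ties broken by larger
|fold| then gene id; a flag (`by="fold"`) ranks by fold change instead,
since either reading of "most differentially expressed" is defensible.

## Enrichment (`amascan.enrich`)

Gene mode and domain-instance mode are deliberately separate operations:
term enrichment counts genes, domain enrichment counts domain *instances*
(a two-copy domain architecture contributes two), and conflating the two
changes every number. The gene-mode background defaults to genes with at
least one annotation — the convention of term-enrichment tools, which
cannot score unannotated genes — with a whole-genome option. EF = k·N/(n·M)
and the E-score is the exact hypergeometric upper tail. BH is applied
across all annotations tested in one run (one mode, one DEG list); no
ontology-graph propagation is performed — annotations are taken as given.

## Dose-response and LC50 (`amascan.dose`)

Vial-level survival fractions are averaged per concentration; the s.e.m. is
the sample standard deviation (ddof = 1) over vials divided by √(number of
vials). The LC50 fit is ordinary least squares of mean survival fraction on
ln(concentration) — the spreadsheet "logarithmic trendline" — excluding
zero-dose points, solved at survival 0.5. A probit/logit fit would be the
textbook alternative; the log-linear fit is kept as the primary method
because it is what the emulated assay procedure used, and on an exactly
log-linear truth both agree. Guard rails: the fitted slope must be
negative, and an LC50 extrapolated beyond a decade outside the tested
concentration range is rejected. Zero-dose vials feed a QC flag
(experiment fails when baseline survival < 80%) rather than the fit.

## qPCR quantification (`amascan.qpcr`)

Technical replicates are averaged into their biological replicate first.
The ratio estimator is the efficiency-corrected double normalization
against the geometric mean of the reference genes; efficiencies default to
2.0 (perfect doubling) since none are supplied by the emulated assay. The
randomization test reallocates biological replicates between group labels,
moving all genes of a replicate jointly so that reference normalization is
preserved under the null, and is two-sided on |log ratio| with a +1
pseudocount. With 5+5 biological replicates the attainable p-value floor is
about 2/C(10,5) ≈ 0.008 — consistent with reporting significance thresholds
of 0.01 at that design, while p < 0.001 claims require more replicates or
finer randomization units.

## Synthetic data (`amascan.synthetic`)

The generators reproduce the statistical structure the analysis assumes:

* **Expression:** 11,890 genes; three groups of 5/5/6 replicates; baseline
  intensities log-normal (meanlog 6, sdlog 1 — heavy-tailed positive, the
  shape of summarized microarray intensities); 300 planted DEGs with
  log-uniform fold magnitudes in [2, 300], half up / half down, applied to
  the designated group's mean; independent multiplicative log-normal noise
  with CV 0.2 per sample (unit-mean, so planted folds are exact in
  expectation). With zero noise every planted effect is recovered exactly
  by group-mean arithmetic, which the tests exploit.
* **Catalog:** five arms (X, 2L, 2R, 3L, 3R; 22.4–27.9 Mb), gene midpoints
  uniform per arm proportional to arm length; a planted cluster of 40 DEGs
  in one 500-kb window on 3L, drawn from the top of the fold range
  (≥ 50-fold) so they land in the top-1% list the scan consumes; 200 terms
  with log-uniform sizes 5–400; 150 domains with Zipf-like popularity and
  Poisson(1.5) instances per gene.
* **Dose-response:** survival truth 1/(1 + (C/LC50)^h) with h = 2 — any
  monotone curve through (LC50, 0.5) would do; this one is smooth and
  differentiable at 0. Counts are binomial per vial (10 vials × 10 larvae
  per concentration, 11 concentrations 0–10 µg/g).
* **qPCR:** Ct = 40 − log_E(expression) + N(0, 0.15) per technical
  replicate, two reference genes with ratio 1, three technical replicates
  per biological replicate.

The generators intentionally omit probe-level effects, batch structure,
missing values, gene–gene expression correlation, and annotation bias
toward well-studied genes. Passing tests therefore demonstrate that the
statistics behave as designed under their own assumptions — calibrated
nulls, planted-truth recovery — not that those assumptions hold for any
particular real array dataset.

## Numerics and conventions

* Coordinates are 0-based half-open everywhere; cluster/bin intervals print
  as such.
* All cutoff comparisons mirror the stated rules: q < 0.05 strict,
  score > 2 strict, |fold| ≥ 2 inclusive.
* Permutation-null lookups use a 10⁻⁹ right-nudge before binary search so
  float-equal null values count as "≤ observed".
* One global seed drives a run; per-stage seeds derive from it by CRC32 of
  the stage name (stable across processes, unlike `hash()`), kept below
  2³¹.
* Every output file starts with `#` comment lines recording version,
  parameters and seed.

## Problem sizes used by the test suite and the reproduction script

The full planted simulation (11,890 genes) is run once per session with
200 permutations in the tests and 500 in `scripts/acceptance.py`; the
scan's null calibration uses 50 random placements in the tests and 20 in
the script; enrichment null rates average 200 random DEG draws on a
300-gene catalog. These sizes give Monte-Carlo standard errors well inside
the asserted tolerances.

## Known limitations

* The rank-product p-values assume exchangeable replicates within groups;
  paired designs and batch effects are out of scope.
* The scan's binomial null treats genes as independently flagged; physical
  gene density is modelled (via n_b) but co-expression of neighbouring
  genes is not — real clusters of co-regulated paralogs will score high by
  design, which is precisely what the method is for, but the "1 in 100"
  guarantee applies only to positionally random flags.
* The log-trendline LC50 is a descriptive fit, not a likelihood model; no
  confidence interval is reported for it.
* Domain-instance enrichment treats instances of a domain within one
  protein as independent draws, which overstates evidence for domains that
  occur in long tandem arrays.
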
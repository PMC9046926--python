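# Methods

`degvenn` demonstrates, on fully synthetic data with known truth, why the
common "significant in one group but not the other" definition of
group-specific differential expression is statistically invalid, and what
the correct analysis — a group × condition interaction contrast — reports
instead.

## The design and the fallacy

The data are a 2×2 factorial: two patient groups (G1, G2), each with
control and treated samples. The naive workflow tests treatment vs control
*separately* in each group, calls DEGs per group (FDR < 0.05 and
|log2 fold change| > 1), draws the Venn diagram, and treats the
non-overlapping parts as "group-specific" genes — often feeding them into
an overrepresentation analysis to find "group-specific pathways". But the
difference between significant and non-significant is not itself
significant: each per-group test has substantial false-negative rate
(1 − power), so genes responding identically in both groups routinely land
in the "specific" parts purely because one of the two tests missed them.
Because those genes are genuine treatment responders, the downstream
enrichment returns pathways genuinely related to the treatment — results
that look biologically plausible while demonstrating nothing about
group-specificity. The correct question is whether the treatment effect
*differs* between groups: the interaction coefficient in a joint model.

## Simulator

Counts for gene g in sample j are negative binomial with mean

    m_gj = s_j · μ_g · 2^(x_jᵀ β_g),   Var = m + α_g m²,

where x_j encodes condition, group and their product. Defaults describe a
noisy human patient cohort (the archetype is upper-airway swab RNA-seq):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 5000 | transcriptome after abundance filtering |
| `n_per_cell` | 20 | samples per group×condition cell (total 80) |
| `de_fraction` | 0.1 | genes with a *shared* treatment effect |
| `lfc_location/scale` | 1.0 / 0.5 | effect size sign·\|N(1, 0.5)\| in log2 |
| `interaction_fraction/lfc` | 0 / 0 | no true group-specificity (the null) |
| `baseline_log_mean_location/scale` | 4.5 / 1.5 | log-normal baseline means, median ≈ 90 counts |
| `dispersion_a0`, `dispersion_a1` | 0.8, 5 | trend α = a0 + a1/μ |
| `dispersion_log_sd` | 0 | optional log-normal scatter around the trend |
| `size_factor_log_sd` | 0.3 | log-normal depth variation, median-centred |

Two default choices deserve justification:

* **Dispersion a0 = 0.8** (biological CV ≈ 0.9). Patient cohorts — unlike
  cell lines or inbred models — show large between-subject variability, and
  swab-type specimens are at the high end. This value places per-gene tests
  in the *power-limited* regime at n = 20/cell, which is precisely the
  regime in which the false-negative artifact exists: with a0 ≈ 0.05 every
  simulated effect of 2-fold or more is detected in both groups and no
  "specific" genes arise at all. It also reproduces the empirical
  phenomenon that the number of spurious enrichment terms *grows* with
  sample size at the conventional |LFC| > 1 threshold.
* **Effect sizes sign·|N(1.0, 0.5)|**. The mode sits at the DEG threshold,
  so the flip-prone boundary population is well represented, and both up-
  and down-regulation occur.

With only 10% of genes carrying signal at this noise level, the Pearson
correlation between the two groups' estimated LFC vectors across *all*
genes is ≈ 0.35–0.45; the strongly correlated regime (r > 0.5, as seen in
real infection cohorts where a much larger fraction of the transcriptome
responds) is reproduced by raising the shared-signal fraction (e.g.
`de_fraction = 0.3`, effects |N(1.5, 1.0)| give r ≈ 0.8). The tests
exercise the correlation property at that stronger-signal configuration;
among significant genes the correlation exceeds 0.9 in either world.

Gene-set catalogs are generated alongside: *response* sets draw each
member from the true-DE pool with probability `response_purity` (default
0.8) and uniformly otherwise — stand-ins for GO terms genuinely related to
the treatment response; *background* sets draw uniformly. Truth labels are
retained so tests can ask whether artifacts preferentially hit
"relevant-looking" sets (they do).

What the generator does **not** emulate: gene–gene correlation (sets are
enriched by construction, not by co-expression), batch effects, outlier
samples, library-composition bias, or any single-cell structure. A green
test therefore establishes the false-negative mechanism under idealised
independence, not the full messiness of a real cohort — in real data,
co-expression makes enrichment artifacts *more* severe, not less.

## Differential expression engine

A deliberate re-implementation of the canonical count-GLM workflow, fitted
jointly for all genes:

1. **Size factors**: median-of-ratios over genes positive in all samples.
2. **Dispersions**: per-gene profile maximum likelihood with the Cox–Reid
   adjustment (−½ log det XᵀWX), maximised on log α by a 31-point grid plus
   golden-section refinement, clamped to [1e−8, 10]. No shrinkage toward
   the trend by default: with thousands of truth-known simulated genes the
   MLE is adequate, and shrinkage would entangle the calibration checks.
3. **GLM**: log link, offsets = log size factors, design
   `1 + group + condition + group:condition`, batched IRLS across genes
   (shared design ⇒ one einsum per iteration), ridge 1e−6 for genes with a
   degenerate cell (all-zero counts), linear predictor clamped to ±30.
4. **Wald contrasts** against the standard normal: `trt_in_G1` (0,0,1,0),
   `trt_in_G2` (0,0,1,1), `interaction` (0,0,0,1); estimates reported in
   log2. BH step-up within each contrast across genes passing the
   ≥ 10-total-counts pre-filter.
5. **DEG calling** strict: fdr < 0.05 AND |lfc| > 1.

Numerical notes: the interaction Wald test is mildly anticonservative with
plug-in dispersions (fraction of null p < 0.05 ≈ 0.057 at the default
world, n = 80), uniformly across expression strata — the same behaviour as
the standard tools' Wald default, and inside the calibration band the
acceptance checks demand. Equal treatment contrasts under group relabeling
agree to ~1e−4 log2 units (IRLS tolerance).

## Enrichment

* **ORA**: upper-tail hypergeometric P(X ≥ k) with the universe defined as
  all tested (pre-filter-passing) genes; sets first intersected with the
  universe, then size-filtered to [10, 50] inclusive; BH across sets.
* **CERNO**: for a set S in a list of N genes ranked by ascending raw
  p-value (ties: descending |LFC|, then gene id), the statistic
  −2 Σ_{i∈S} ln(r_i/N) is χ² with 2|S| df under the null. Exact singleton
  identity p = r/N is used as an oracle. The χ² null assumes continuous
  ranks; discreteness biases the statistic by ≈ ln(2πN)/N per member,
  negligible at transcriptome N.
* **disco**: lfc_A · lfc_B · (|log10 p_A| + |log10 p_B|), positive =
  concordant. A visualization/prioritisation heuristic, not a test.

## Harness

`run_replicate` = simulate → fit → call DEGs per group → Venn partition →
ORA on each "specific" list (the incorrect pipeline) → interaction DEG
count and CERNO on the interaction p-ordering (the correct pipeline) →
truth-table accounting of the specific lists. `run_grid` sweeps LFC
thresholds × total sample sizes × replicates; one dataset is simulated per
(size, replicate) and all thresholds are evaluated on the same fit,
mirroring a study that re-thresholds one cohort. All randomness flows from
`base_seed + running index`; a rerun reproduces every count exactly.

The headline behaviour at the default world (20 replicates): every
replicate yields non-empty "specific" lists and, in ≥ 70% of replicates,
at least one BH-significant enrichment term on them, with response-labelled
sets vastly overrepresented among those terms; the median number of
interaction-significant genes is 0 and interaction-CERNO finds nothing in
excess of its FDR. About 75–85% of "specific" DEGs are truly DE in both
groups. The sample-size effect (more data ⇒ more artifacts at the |LFC| > 1
threshold) is assessed at the conventional threshold of 1; at threshold 0
the artifact instead shrinks with n, because with no LFC cut the FDR
boundary is the only flip zone and it narrows as power grows.

## Power module

Two-sample pooled-variance t-test power from the noncentral t
(df = 2n − 2, ncp = d√(n/2)); required n by Brent root-finding on the
continuous power curve plus an integer step. At α = 0.05 and 80% power the
per-group requirement is 26 (fractional 25.52) for d = 0.8 and 394
(fractional 393.41) for d = 0.2 — the FNR at 80% power is by definition
20%, and in genome-scale settings with BH control the effective FNR is far
higher. These numbers quantify why false negatives, not false positives,
dominate "specific gene" lists.

## Known limitations

* The Wald/plug-in-dispersion combination is slightly liberal at very high
  dispersion (α ≳ 2) and small n; a quasi-likelihood F-test would be the
  conservative alternative and is out of scope.
* `real-data mode` accepts any counts+annotation TSV in the documented
  shape, but no GEO retrieval is provided; replicate resampling of a real
  cohort is the user's responsibility (subsampling without replacement per
  replicate is the assumption the harness documents).
* No LFC shrinkage: thresholds act on raw estimates, which is exactly the
  setting in which the threshold-flip artifact lives; shrunken estimates
  would change the numbers but not the mechanism.
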
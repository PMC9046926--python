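"""Replicated demonstration of the "group-specific DEG" artifact.

One replicate runs the full study on a fresh draw from the synthetic
world: per-group differential expression, DEG calling, the Venn partition
into shared and "specific" genes, hypergeometric enrichment of each
specific list (the naive pipeline), the interaction contrast with CERNO
enrichment (the correct pipeline), and a truth-table accounting of how
many "specific" genes are in fact false negatives of the other group's
test. A grid sweep repeats this over LFC thresholds and sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from degvenn.datatypes import CountMatrix, GeneSetCollection, GroundTruth
from degvenn.diffexp import (
    DEGCriteria,
    DEResults,
    call_degs,
    fit_and_test,
    venn_partition,
)
from degvenn.enrichment import (
    disco_table,
    filter_gene_sets,
    rank_genes,
    run_cerno,
    run_ora,
)
from degvenn.errors import ConfigError
from degvenn.simulate import SimulationConfig, make_gene_sets, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class ReplicateSummary:
    """Counts collected from one replicate of the incorrect-vs-correct study."""

    replicate_id: int
    seed: int
    lfc_threshold: float
    n_total_samples: int
    degs_g1: int
    degs_g2: int
    degs_both: int
    degs_only_g1: int
    degs_only_g2: int
    ora_sig_only_g1: int
    ora_sig_only_g2: int
    spurious_response_terms: int
    spurious_background_terms: int
    interaction_degs: int
    cerno_sig_sets: int
    fn_composition: float

    def __post_init__(self) -> None:
        assert self.degs_only_g1 + self.degs_both == self.degs_g1
        assert self.degs_only_g2 + self.degs_both == self.degs_g2

    @property
    def spurious_terms(self) -> int:
        """Significant enrichment terms over both "specific" lists combined."""
        return self.ora_sig_only_g1 + self.ora_sig_only_g2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spurious_terms"] = self.spurious_terms
        return d


@dataclass
class ReplicateDetail:
    """Full per-replicate objects, for plotting or inspection."""

    summary: ReplicateSummary
    counts: CountMatrix
    truth: GroundTruth
    results: DEResults
    ora_g1: pd.DataFrame
    ora_g2: pd.DataFrame
    cerno: pd.DataFrame


def _enrichment_significant(ora: pd.DataFrame, fdr_threshold: float):
    if len(ora) == 0:
        return ora.iloc[0:0]
    return ora[ora["fdr"] < fdr_threshold]


def _ora_or_empty(foreground, universe, collection: GeneSetCollection) -> pd.DataFrame:
    """ORA, but an empty foreground yields an empty table instead of warnings."""
    if not foreground:
        return run_ora(frozenset(), universe, GeneSetCollection(sets=[]))
    return run_ora(foreground, universe, collection)


def run_replicate(
    config: SimulationConfig,
    criteria: DEGCriteria | None = None,
    collection: GeneSetCollection | None = None,
    seed: int | None = None,
    *,
    replicate_id: int = 0,
    gene_set_kwargs: dict | None = None,
    set_size_bounds: tuple[int, int] = (10, 50),
    return_detail: bool = False,
):
    """Run one simulate → test → partition → enrich replicate.

    When ``collection`` is None a fresh synthetic catalog is built from this
    replicate's ground truth (seeded from the replicate seed), so response
    sets always concentrate that replicate's truly responsive genes.
    """
    criteria = criteria or DEGCriteria()
    if seed is not None:
        config = config.replace(seed=seed)
    cm, truth = simulate_dataset(config)
    results = fit_and_test(cm, criteria)
    universe = results.universe

    if collection is None:
        collection = make_gene_sets(
            truth, seed=config.seed + 1, **(gene_set_kwargs or {})
        )
    filtered = filter_gene_sets(collection, universe, *set_size_bounds)

    degs_g1 = call_degs(results, "trt_in_G1", criteria)
    degs_g2 = call_degs(results, "trt_in_G2", criteria)
    vp = venn_partition(degs_g1, degs_g2, universe)

    ora_g1 = _ora_or_empty(vp.only_a, universe, filtered)
    ora_g2 = _ora_or_empty(vp.only_b, universe, filtered)
    sig_g1 = _enrichment_significant(ora_g1, criteria.fdr_threshold)
    sig_g2 = _enrichment_significant(ora_g2, criteria.fdr_threshold)

    interaction_tab = results.table("interaction")
    interaction_degs = int(
        (interaction_tab["fdr"] < criteria.fdr_threshold).sum()
    )
    ranked = rank_genes(interaction_tab)
    cerno = run_cerno(ranked, filtered)
    cerno_sig = int((cerno["fdr"] < criteria.fdr_threshold).sum()) if len(cerno) else 0

    specific = vp.only_a | vp.only_b
    truly_both = truth.de_genes
    fn_comp = (
        len(specific & truly_both) / len(specific) if specific else float("nan")
    )

    n_response = int((sig_g1["label"] == "response").sum()) + int(
        (sig_g2["label"] == "response").sum()
    )
    n_background = int((sig_g1["label"] == "background").sum()) + int(
        (sig_g2["label"] == "background").sum()
    )

    summary = ReplicateSummary(
        replicate_id=replicate_id,
        seed=config.seed,
        lfc_threshold=criteria.lfc_threshold,
        n_total_samples=cm.n_samples,
        degs_g1=len(degs_g1),
        degs_g2=len(degs_g2),
        degs_both=len(vp.both),
        degs_only_g1=len(vp.only_a),
        degs_only_g2=len(vp.only_b),
        ora_sig_only_g1=len(sig_g1),
        ora_sig_only_g2=len(sig_g2),
        spurious_response_terms=n_response,
        spurious_background_terms=n_background,
        interaction_degs=interaction_degs,
        cerno_sig_sets=cerno_sig,
        fn_composition=fn_comp,
    )
    if return_detail:
        return ReplicateDetail(
            summary=summary,
            counts=cm,
            truth=truth,
            results=results,
            ora_g1=ora_g1,
            ora_g2=ora_g2,
            cerno=cerno,
        )
    return summary


@dataclass
class GridResult:
    """Replicate-level and aggregated results of a threshold x size sweep."""

    replicates: pd.DataFrame
    base_seed: int
    failed: list[int] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        g = self.replicates.groupby(["n_total_samples", "lfc_threshold"])
        agg = g.agg(
            n_replicates=("replicate_id", "size"),
            mean_specific=("n_specific", "mean"),
            median_specific=("n_specific", "median"),
            mean_spurious=("spurious_terms", "mean"),
            median_spurious=("spurious_terms", "median"),
            frac_ge1_spurious=("spurious_terms", lambda s: float((s >= 1).mean())),
            frac_ge5_spurious=("spurious_terms", lambda s: float((s >= 5).mean())),
            mean_interaction_degs=("interaction_degs", "mean"),
            mean_fn_composition=("fn_composition", "mean"),
        )
        return agg.reset_index()


def run_grid(
    base_config: SimulationConfig,
    thresholds=(0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
    total_sample_sizes=(40, 80, 160),
    n_replicates: int = 100,
    base_seed: int = 0,
    *,
    fdr_threshold: float = 0.05,
    gene_set_kwargs: dict | None = None,
    set_size_bounds: tuple[int, int] = (10, 50),
) -> GridResult:
    """Full factorial sweep over LFC thresholds and total sample sizes.

    One dataset is simulated per (size, replicate) pair — seed =
    ``base_seed + running index`` — and all thresholds are evaluated on the
    same fitted model, mirroring a study that re-thresholds one cohort. A
    replicate that fails outright is logged with its seed and skipped.
    """
    if any(t < 0 for t in thresholds):
        raise ConfigError("thresholds must be nonnegative")
    for size in total_sample_sizes:
        if size % 4 != 0 or size // 4 < 2:
            raise ConfigError(
                f"total sample size {size} not divisible into 4 cells of >= 2"
            )
    rows = []
    failed: list[int] = []
    running = 0
    for size in total_sample_sizes:
        config_size = base_config.replace(n_per_cell=size // 4)
        for rep in range(n_replicates):
            seed = base_seed + running
            running += 1
            try:
                config = config_size.replace(seed=seed)
                cm, truth = simulate_dataset(config)
                results = fit_and_test(cm)
                universe = results.universe
                collection = make_gene_sets(
                    truth, seed=seed + 1, **(gene_set_kwargs or {})
                )
                filtered = filter_gene_sets(collection, universe, *set_size_bounds)
                interaction_tab = results.table("interaction")
                interaction_degs = int(
                    (interaction_tab["fdr"] < fdr_threshold).sum()
                )
                ranked = rank_genes(interaction_tab)
                cerno = run_cerno(ranked, filtered)
                cerno_sig = (
                    int((cerno["fdr"] < fdr_threshold).sum()) if len(cerno) else 0
                )
                truly_both = truth.de_genes
            except Exception:  # noqa: BLE001 - a bad replicate must not kill the sweep
                logger.exception("replicate with seed %d failed; skipped", seed)
                failed.append(seed)
                continue
            for thr in thresholds:
                criteria = DEGCriteria(fdr_threshold=fdr_threshold, lfc_threshold=thr)
                degs_g1 = call_degs(results, "trt_in_G1", criteria)
                degs_g2 = call_degs(results, "trt_in_G2", criteria)
                vp = venn_partition(degs_g1, degs_g2, universe)
                ora_g1 = _ora_or_empty(vp.only_a, universe, filtered)
                ora_g2 = _ora_or_empty(vp.only_b, universe, filtered)
                sig_g1 = _enrichment_significant(ora_g1, fdr_threshold)
                sig_g2 = _enrichment_significant(ora_g2, fdr_threshold)
                specific = vp.only_a | vp.only_b
                fn_comp = (
                    len(specific & truly_both) / len(specific)
                    if specific
                    else float("nan")
                )
                summary = ReplicateSummary(
                    replicate_id=rep,
                    seed=seed,
                    lfc_threshold=thr,
                    n_total_samples=cm.n_samples,
                    degs_g1=len(degs_g1),
                    degs_g2=len(degs_g2),
                    degs_both=len(vp.both),
                    degs_only_g1=len(vp.only_a),
                    degs_only_g2=len(vp.only_b),
                    ora_sig_only_g1=len(sig_g1),
                    ora_sig_only_g2=len(sig_g2),
                    spurious_response_terms=int(
                        (sig_g1["label"] == "response").sum()
                    )
                    + int((sig_g2["label"] == "response").sum()),
                    spurious_background_terms=int(
                        (sig_g1["label"] == "background").sum()
                    )
                    + int((sig_g2["label"] == "background").sum()),
                    interaction_degs=interaction_degs,
                    cerno_sig_sets=cerno_sig,
                    fn_composition=fn_comp,
                )
                row = summary.to_dict()
                row["n_specific"] = summary.degs_only_g1 + summary.degs_only_g2
                rows.append(row)
    replicates = pd.DataFrame(rows)
    return GridResult(replicates=replicates, base_seed=base_seed, failed=failed)


def export_lfc_scatter(
    table_g1: pd.DataFrame,
    table_g2: pd.DataFrame,
    degs_g1,
    degs_g2,
    disco: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Paired-LFC table, the grand-overview alternative to a Venn diagram.

    Returns (table, correlations): per tested gene its two LFC estimates, a
    significance class in {only_G1, only_G2, both, neither} and the disco
    score; Pearson correlations between the two LFC vectors are reported
    overall and within each class (NaN where a class has < 2 genes).
    """
    if disco is None:
        disco = disco_table(table_g1, table_g2)
    mask = ~(table_g1["pvalue"].isna() | table_g2["pvalue"].isna())
    genes = table_g1.index[mask]
    a, b = frozenset(degs_g1), frozenset(degs_g2)

    def classify(g: str) -> str:
        if g in a and g in b:
            return "both"
        if g in a:
            return "only_G1"
        if g in b:
            return "only_G2"
        return "neither"

    out = pd.DataFrame(
        {
            "lfc_G1": table_g1.loc[genes, "lfc"],
            "lfc_G2": table_g2.loc[genes, "lfc"],
            "significance": [classify(g) for g in genes],
            "disco_score": disco.loc[genes, "disco_score"],
        },
        index=genes,
    )
    correlations: dict[str, float] = {}
    x, y = out["lfc_G1"].to_numpy(), out["lfc_G2"].to_numpy()
    correlations["overall"] = (
        float(np.corrcoef(x, y)[0, 1]) if len(out) > 1 else float("nan")
    )
    for cls in ("only_G1", "only_G2", "both", "neither"):
        sub = out[out["significance"] == cls]
        correlations[cls] = (
            float(np.corrcoef(sub["lfc_G1"], sub["lfc_G2"])[0, 1])
            if len(sub) > 1
            else float("nan")
        )
    return out, correlations
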
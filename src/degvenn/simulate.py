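"""Synthetic NB count matrices for the 2x2 design, with known ground truth.

The simulator emulates the statistical structure of a two-cohort infection
study: two patient groups (G1, G2) each split into control and treated
samples, negative-binomial counts with a per-gene dispersion trend and
per-sample size factors, and a configurable fraction of genes carrying a
treatment effect *shared* between the groups. With zero true interaction
(the default) every apparent group-specific finding downstream is an
artifact of false negatives, which is the phenomenon the package
demonstrates.

Counts for gene g in sample j are drawn NB with mean

    m_gj = s_j * mu_g * 2**(x_j' beta_g)

where x_j encodes condition, group and their product, and variance
m + alpha_g * m**2 with alpha_g = a0 + a1 / mu_g.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from degvenn.datatypes import CountMatrix, GeneSet, GeneSetCollection, GroundTruth
from degvenn.errors import ConfigError, GeneSetError


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic 2x2 NB-count world.

    Attributes
    ----------
    n_genes
        Number of simulated genes.
    n_per_cell
        Samples per group x condition cell (balanced design; a total of
        ``4 * n_per_cell`` samples).
    de_fraction
        Fraction of genes with a nonzero treatment effect shared between the
        two groups.
    lfc_location, lfc_scale
        The treatment log2 fold change of a DE gene is drawn as
        ``sign * |Normal(lfc_location, lfc_scale)|`` with a random sign, so
        both up- and down-regulation occur.
    interaction_fraction, interaction_lfc
        Fraction of genes with a true group x condition interaction and the
        magnitude (log2) of that interaction; the default of zero makes the
        correct analysis a strict null.
    baseline_log_mean_location, baseline_log_mean_scale
        Per-gene baseline means are log-normal:
        ``mu_g = exp(Normal(location, scale))``.
    dispersion_a0, dispersion_a1
        Dispersion-mean trend ``alpha_g = a0 + a1 / mu_g``.
    dispersion_log_sd
        Log-normal scatter of per-gene dispersions around the trend:
        ``alpha_g = (a0 + a1 / mu_g) * exp(Normal(0, dispersion_log_sd))``.
        Real cohorts show substantial gene-level biological variability
        around any mean-dispersion trend; zero disables the scatter.
    size_factor_log_sd
        Per-sample size factors are log-normal with this log-sd, then
        median-centred to 1 so the truth matches the median-of-ratios
        estimand.
    seed
        Root RNG seed; identical config + seed gives byte-identical output.
    """

    n_genes: int = 5000
    n_per_cell: int = 20
    de_fraction: float = 0.1
    lfc_location: float = 1.0
    lfc_scale: float = 0.5
    interaction_fraction: float = 0.0
    interaction_lfc: float = 0.0
    baseline_log_mean_location: float = 4.5
    baseline_log_mean_scale: float = 1.5
    dispersion_a0: float = 0.8
    dispersion_a1: float = 5.0
    dispersion_log_sd: float = 0.0
    size_factor_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_per_cell < 2:
            raise ConfigError("n_per_cell must be at least 2")
        for name in ("de_fraction", "interaction_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.dispersion_a0 <= 0 or self.dispersion_a1 < 0:
            raise ConfigError("dispersion trend must be strictly positive")
        if self.lfc_scale < 0 or self.baseline_log_mean_scale < 0:
            raise ConfigError("scale parameters must be nonnegative")
        if self.size_factor_log_sd < 0:
            raise ConfigError("size_factor_log_sd must be nonnegative")
        if self.dispersion_log_sd < 0:
            raise ConfigError("dispersion_log_sd must be nonnegative")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def simulate_dataset(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw one count matrix plus its ground truth from the configured world.

    Returns
    -------
    (CountMatrix, GroundTruth)
        Counts are NB with mean ``s_j * mu_g * 2**(x_j' beta_g)`` and
        dispersion from the configured mean trend; the truth table carries
        the per-gene coefficients the interaction analysis estimates.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    npc = config.n_per_cell

    genes = [f"g{i:05d}" for i in range(G)]
    groups, conds = [], []
    for g in ("G1", "G2"):
        for c in ("Ctrl", "Treated"):
            groups += [g] * npc
            conds += [c] * npc
    n_samples = len(groups)
    samples = [f"s{i:03d}" for i in range(n_samples)]
    annotation = pd.DataFrame(
        {"group": groups, "condition": conds}, index=pd.Index(samples, name="sample_id")
    )

    mu = np.exp(
        rng.normal(
            config.baseline_log_mean_location, config.baseline_log_mean_scale, G
        )
    )
    alpha = config.dispersion_a0 + config.dispersion_a1 / mu
    if config.dispersion_log_sd > 0:
        alpha = alpha * np.exp(rng.normal(0.0, config.dispersion_log_sd, G))

    beta_trt = np.zeros(G)
    n_de = int(round(config.de_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    beta_trt[de_idx] = signs * np.abs(
        rng.normal(config.lfc_location, config.lfc_scale, n_de)
    )

    beta_int = np.zeros(G)
    n_int = int(round(config.interaction_fraction * G))
    if n_int > 0:
        int_idx = rng.choice(G, size=n_int, replace=False)
        beta_int[int_idx] = rng.choice([-1.0, 1.0], size=n_int) * config.interaction_lfc

    size_factors = np.exp(rng.normal(0.0, config.size_factor_log_sd, n_samples))
    size_factors /= np.median(size_factors)

    is_g2 = (annotation["group"] == "G2").to_numpy(float)
    is_trt = (annotation["condition"] == "Treated").to_numpy(float)
    # per-gene, per-sample log2 treatment effect: beta_trt in G1, beta_trt+beta_int in G2
    log2_effect = np.outer(beta_trt, is_trt) + np.outer(beta_int, is_trt * is_g2)
    mean = size_factors[None, :] * mu[:, None] * np.exp2(log2_effect)

    p = 1.0 / (1.0 + alpha[:, None] * mean)
    counts = rng.negative_binomial(1.0 / alpha[:, None], p)

    cm = CountMatrix(
        counts=pd.DataFrame(
            counts, index=pd.Index(genes, name="gene_id"), columns=samples
        ),
        annotation=annotation,
    )
    truth_genes = pd.DataFrame(
        {
            "mu": mu,
            "lfc_g1": beta_trt,
            "lfc_g2": beta_trt + beta_int,
            "is_de_shared": beta_trt != 0,
            "has_interaction": beta_int != 0,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    truth = GroundTruth(
        genes=truth_genes,
        size_factors=pd.Series(
            size_factors,
            index=pd.Index(samples, name="sample_id"),
            name="size_factor",
        ),
    )
    return cm, truth


def make_gene_sets(
    truth: GroundTruth,
    n_response_sets: int = 50,
    n_background_sets: int = 50,
    set_size_range: tuple[int, int] = (15, 40),
    response_purity: float = 0.8,
    seed: int = 0,
) -> GeneSetCollection:
    """Build a synthetic gene-set catalog concentrated on true-DE genes.

    Response sets draw each member from the true-DE pool with probability
    ``response_purity`` (and from the non-DE pool otherwise), mimicking GO
    terms genuinely related to the treatment response; background sets draw
    uniformly from all genes. With such a catalog, enrichment artifacts on
    falsely "group-specific" DEG lists look biologically relevant.
    """
    if not 0.0 <= response_purity <= 1.0:
        raise GeneSetError("response_purity must lie in [0, 1]")
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise GeneSetError(f"invalid set_size_range {set_size_range}")
    all_genes = np.asarray(truth.genes.index)
    de_mask = (truth.genes["lfc_g1"] != 0) | (truth.genes["lfc_g2"] != 0)
    de_pool = all_genes[de_mask.to_numpy()]
    if n_response_sets > 0:
        needed = int(np.ceil(response_purity * hi))
        if len(de_pool) < needed:
            raise GeneSetError(
                f"only {len(de_pool)} true-DE genes available but response sets "
                f"of size up to {hi} at purity {response_purity} need up to {needed}"
            )
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    labels: dict[str, str] = {}
    for i in range(n_response_sets):
        size = int(rng.integers(lo, hi + 1))
        k = int(rng.binomial(size, response_purity))
        k = min(k, len(de_pool))
        de_members = rng.choice(de_pool, size=k, replace=False)
        # remainder uniform over the rest of the universe, so purity=0 reduces
        # exactly to a background set
        remaining = np.setdiff1d(all_genes, de_members, assume_unique=True)
        rest = min(size - k, len(remaining))
        members = np.concatenate(
            [de_members, rng.choice(remaining, size=rest, replace=False)]
        )
        name = f"RSP_{i:04d}"
        sets.append(
            GeneSet(name, "synthetic treatment-response set", tuple(members))
        )
        labels[name] = "response"
    for i in range(n_background_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(all_genes, size=min(size, len(all_genes)), replace=False)
        name = f"BG_{i:04d}"
        sets.append(GeneSet(name, "synthetic background set", tuple(members)))
        labels[name] = "background"
    return GeneSetCollection(sets=sets, labels=labels)
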
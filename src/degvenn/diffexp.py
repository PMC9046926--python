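"""Negative-binomial GLM differential expression for the 2x2 design.

The engine mirrors the canonical count-based DE workflow: median-of-ratios
size factors, per-gene dispersion by Cox-Reid adjusted profile maximum
likelihood, an NB GLM with log link and size-factor offsets on the design
``intercept + group + condition + group:condition``, Wald tests of linear
contrasts against the standard normal, and Benjamini-Hochberg adjustment
within each contrast. All fits are vectorized across genes (batched IRLS
with shared design), which keeps a 5,000-gene x 160-sample fit in the
low seconds.

Three canonical contrasts are predefined:

==============  ==========================  =====================================
name            coefficients                meaning (log2 scale)
==============  ==========================  =====================================
trt_in_G1       (0, 0, 1, 0)                treatment effect within group G1
trt_in_G2       (0, 0, 1, 1)                treatment effect within group G2
interaction     (0, 0, 0, 1)                difference of the two effects
==============  ==========================  =====================================

A gene is called a DEG for a contrast when ``fdr < fdr_threshold`` and
``|lfc| > lfc_threshold`` (both strict).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from degvenn.datatypes import CountMatrix, VennPartition
from degvenn.errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)

#: canonical contrasts over design columns (intercept, group, condition, group:condition)
CONTRASTS: dict[str, np.ndarray] = {
    "trt_in_G1": np.array([0.0, 0.0, 1.0, 0.0]),
    "trt_in_G2": np.array([0.0, 0.0, 1.0, 1.0]),
    "interaction": np.array([0.0, 0.0, 0.0, 1.0]),
}

RESULT_COLUMNS = ["baseMean", "lfc", "se", "stat", "pvalue", "fdr", "filtered"]


@dataclass(frozen=True)
class DEGCriteria:
    """DEG thresholds: FDR below ``fdr_threshold`` and |LFC| above ``lfc_threshold``."""

    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold <= 1:
            raise ConfigError("fdr_threshold must lie in (0, 1]")
        if self.lfc_threshold < 0:
            raise ConfigError("lfc_threshold must be nonnegative")


def estimate_size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For every gene with strictly positive counts in all samples, form the
    ratio of each sample's count to the gene's geometric mean; the size
    factor of a sample is the median of its ratios.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    values = counts.to_numpy(float)
    usable = (values > 0).all(axis=1)
    if not usable.any():
        raise ValidationError(
            "no gene has positive counts in every sample; relax the count "
            "filter or check the input matrix"
        )
    logc = np.log(values[usable])
    log_ratios = logc - logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _nb_loglik(alpha, y, mu, X=None, cr_adjust=True):
    """Per-gene NB2 log likelihood at dispersion ``alpha`` (vector over genes).

    ``alpha``: (G,), ``y``/``mu``: (G, n). Optionally subtracts the Cox-Reid
    adjustment 0.5 * logdet(X' W X) which removes the downward bias of the
    plain MLE caused by fitting the mean parameters.
    """
    alpha = np.asarray(alpha, float)
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-10)
    rc = r[:, None]
    ll = (
        gammaln(y + rc)
        - gammaln(rc)
        + rc * np.log(r[:, None] / (rc + mu))
        + y * np.log(mu / (rc + mu))
    ).sum(axis=1)
    if cr_adjust and X is not None:
        w = mu / (1.0 + alpha[:, None] * mu)
        M = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True)
        _, logdet = np.linalg.slogdet(M)
        ll -= 0.5 * logdet
    return ll


def _cell_fitted_means(values: np.ndarray, design: np.ndarray, sf: np.ndarray):
    """Cell-wise Poisson fitted means s_j * (sum_cell y) / (sum_cell s)."""
    # unique design rows define the 2x2 cells
    _, cell_idx = np.unique(design, axis=0, return_inverse=True)
    n_cells = cell_idx.max() + 1
    mu = np.zeros_like(values, dtype=float)
    for c in range(n_cells):
        mask = cell_idx == c
        rate = values[:, mask].sum(axis=1) / sf[mask].sum()
        mu[:, mask] = sf[mask][None, :] * rate[:, None]
    return mu


def estimate_dispersions(
    counts: pd.DataFrame | CountMatrix,
    design: pd.DataFrame | np.ndarray,
    size_factors: pd.Series | np.ndarray,
    *,
    cr_adjust: bool = True,
    bounds: tuple[float, float] = (1e-8, 10.0),
    grid_size: int = 31,
    refine_iter: int = 30,
) -> pd.Series:
    """Per-gene NB dispersion by (Cox-Reid adjusted) profile maximum likelihood.

    The profile likelihood in ``log alpha`` is maximised by a coarse grid
    search followed by golden-section refinement, vectorized over genes;
    estimates are clamped to ``bounds``. Genes whose counts are constant
    (e.g. all zero) get the lower bound and should be pre-filtered.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    y = counts.to_numpy(float)
    X = np.asarray(design, float)
    sf = np.asarray(size_factors, float)
    mu = _cell_fitted_means(y, X, sf)

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    grid = np.linspace(lo, hi, grid_size)
    best_ll = np.full(y.shape[0], -np.inf)
    best_i = np.zeros(y.shape[0], dtype=int)
    for i, la in enumerate(grid):
        ll = _nb_loglik(np.full(y.shape[0], np.exp(la)), y, mu, X, cr_adjust)
        better = ll > best_ll
        best_ll[better] = ll[better]
        best_i[better] = i

    step = grid[1] - grid[0]
    a = grid[best_i] - step
    b = grid[best_i] + step
    a = np.clip(a, lo, hi)
    b = np.clip(b, lo, hi)

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1 = _nb_loglik(np.exp(x1), y, mu, X, cr_adjust)
    f2 = _nb_loglik(np.exp(x2), y, mu, X, cr_adjust)
    for _ in range(refine_iter):
        left = f1 > f2  # maximum bracketed in [a, x2]; otherwise in [x1, b]
        a = np.where(left, a, x1)
        b = np.where(left, x2, b)
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        # one probe point is inherited (invphi^2 = 1 - invphi); only the
        # other needs a fresh likelihood evaluation
        eval_x = np.where(left, x1, x2)
        f_eval = _nb_loglik(np.exp(eval_x), y, mu, X, cr_adjust)
        f1, f2 = np.where(left, f_eval, f2), np.where(left, f1, f_eval)
    alpha = np.exp((a + b) / 2.0)
    alpha = np.clip(alpha, bounds[0], bounds[1])

    # method-of-moments fallback for genes where the profile is flat/degenerate
    degenerate = ~np.isfinite(alpha)
    if degenerate.any():
        logger.warning(
            "dispersion optimisation degenerate for %d genes; using moments",
            int(degenerate.sum()),
        )
        norm_counts = y / sf[None, :]
        m = norm_counts.mean(axis=1)
        v = norm_counts.var(axis=1, ddof=1)
        mom = np.clip((v - m) / np.maximum(m, 1e-10) ** 2, *bounds)
        alpha[degenerate] = mom[degenerate]
    index = counts.index
    return pd.Series(alpha, index=index, name="dispersion")


def _fit_nbglm_batched(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    *,
    ridge: float = 1e-6,
    max_iter: int = 60,
    tol: float = 1e-8,
):
    """Batched IRLS for NB GLMs with log link and shared design.

    ``y``: (G, n) counts, ``X``: (n, p) design, ``offset``: (n,) log size
    factors, ``alpha``: (G,) fixed dispersions. A small ridge penalty keeps
    degenerate genes (e.g. an all-zero design cell) finite; their inflated
    standard errors make them non-significant rather than crashing the fit.

    Returns (beta (G,p) natural-log scale, cov (G,p,p), mu (G,n), converged (G,)).
    """
    G, n = y.shape
    p = X.shape[1]
    eye = ridge * np.eye(p)

    # exact start from cell-wise Poisson rates (design is saturated per cell)
    sf = np.exp(offset)
    mu0 = _cell_fitted_means(y, X, sf)
    eta0 = np.log(np.maximum(mu0 / sf[None, :], 1e-8))
    beta = eta0 @ np.linalg.pinv(X).T

    converged = np.zeros(G, dtype=bool)
    A = None
    for _ in range(max_iter):
        eta = np.clip(offset[None, :] + beta @ X.T, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        A = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True) + eye
        b = np.einsum("gn,gn,ni->gi", w, z, X, optimize=True)
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        step = beta_new - beta
        # damp huge steps from near-degenerate genes
        norm_step = np.max(np.abs(step), axis=1)
        scale = np.minimum(1.0, 5.0 / np.maximum(norm_step, 1e-300))
        beta = beta + step * scale[:, None]
        converged = norm_step < tol
        if converged.all():
            break
    eta = np.clip(offset[None, :] + beta @ X.T, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True) + eye
    cov = np.linalg.inv(A)
    return beta, cov, mu, converged


@dataclass
class DEResults:
    """Per-contrast differential expression tables plus fit metadata.

    ``tables[contrast]`` is a DataFrame over *all* input genes with columns
    ``baseMean, lfc, se, stat, pvalue, fdr, filtered`` (LFC and SE in log2
    units); genes failing the count pre-filter carry NaN statistics and
    ``filtered=True``. ``universe`` is the list of tested genes — the
    default background for enrichment.
    """

    tables: dict[str, pd.DataFrame]
    size_factors: pd.Series
    dispersions: pd.Series
    criteria: DEGCriteria = field(default_factory=DEGCriteria)
    flagged: pd.Series | None = None

    @property
    def contrasts(self) -> list[str]:
        return list(self.tables)

    @property
    def universe(self) -> frozenset[str]:
        t = next(iter(self.tables.values()))
        return frozenset(t.index[~t["filtered"]])

    def table(self, contrast: str) -> pd.DataFrame:
        if contrast not in self.tables:
            raise KeyError(
                f"unknown contrast {contrast!r}; have {sorted(self.tables)}"
            )
        return self.tables[contrast]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Step-up: adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1, where m is
    the number of non-missing p-values. NaNs are excluded from the family
    and propagated.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[mask] = result
    return out


def fit_and_test(
    cm: CountMatrix,
    criteria: DEGCriteria | None = None,
    *,
    min_total_count: int = 10,
    cr_adjust: bool = True,
    dispersions: pd.Series | None = None,
) -> DEResults:
    """Fit the joint NB GLM and report the three canonical contrasts.

    Genes with fewer than ``min_total_count`` reads over all samples are
    filtered before testing and excluded from the BH family. One joint model
    is fitted (``intercept + group + condition + group:condition``) so the
    two per-group treatment contrasts share dispersion estimates; the Wald
    statistic of each contrast is referred to the standard normal, and BH is
    applied per contrast across unfiltered genes.
    """
    criteria = criteria or DEGCriteria()
    design = cm.design_matrix()
    X = design.to_numpy(float)
    size_factors = estimate_size_factors(cm.counts)
    sf = size_factors.to_numpy()
    offset = np.log(sf)

    all_genes = cm.counts.index
    totals = cm.counts.sum(axis=1)
    keep = totals >= min_total_count
    y = cm.counts.loc[keep].to_numpy(float)

    if dispersions is None:
        dispersions = estimate_dispersions(
            cm.counts.loc[keep], X, sf, cr_adjust=cr_adjust
        )
    else:
        dispersions = dispersions.loc[keep[keep].index]
    alpha = dispersions.to_numpy(float)

    beta, cov, mu, converged = _fit_nbglm_batched(y, X, offset, alpha)
    if not converged.all():
        logger.warning("IRLS not fully converged for %d genes", int((~converged).sum()))

    # genes with an entirely zero design cell have unidentified coefficients;
    # the ridge keeps them finite but they are flagged
    _, cell_idx = np.unique(X, axis=0, return_inverse=True)
    zero_cell = np.zeros(y.shape[0], dtype=bool)
    for c in range(cell_idx.max() + 1):
        zero_cell |= (y[:, cell_idx == c] == 0).all(axis=1)

    base_mean_kept = (y / sf[None, :]).mean(axis=1)
    base_mean = pd.Series(np.nan, index=all_genes)
    base_mean[keep] = base_mean_kept

    tables: dict[str, pd.DataFrame] = {}
    for name, cvec in CONTRASTS.items():
        est = beta @ cvec
        var = np.einsum("i,gij,j->g", cvec, cov, cvec)
        se = np.sqrt(np.maximum(var, 0.0))
        stat = np.where(se > 0, est / np.maximum(se, 1e-300), 0.0)
        pval = 2.0 * norm.sf(np.abs(stat))
        fdr = bh_adjust(pval)
        tab = pd.DataFrame(
            {
                "baseMean": base_mean,
                "lfc": np.nan,
                "se": np.nan,
                "stat": np.nan,
                "pvalue": np.nan,
                "fdr": np.nan,
                "filtered": ~keep,
            },
            index=all_genes,
        )
        tab.loc[keep, "lfc"] = est / LN2
        tab.loc[keep, "se"] = se / LN2
        tab.loc[keep, "stat"] = stat
        tab.loc[keep, "pvalue"] = pval
        tab.loc[keep, "fdr"] = fdr
        tables[name] = tab

    flagged = pd.Series(False, index=all_genes)
    flagged[keep] = zero_cell
    return DEResults(
        tables=tables,
        size_factors=size_factors,
        dispersions=dispersions,
        criteria=criteria,
        flagged=flagged,
    )


def call_degs(
    results: DEResults | pd.DataFrame,
    contrast: str | None = None,
    criteria: DEGCriteria | None = None,
) -> frozenset[str]:
    """Genes with ``fdr < fdr_threshold`` and ``|lfc| > lfc_threshold`` (strict)."""
    if isinstance(results, DEResults):
        criteria = criteria or results.criteria
        table = results.table(contrast)
    else:
        table = results
        criteria = criteria or DEGCriteria()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        mask = (table["fdr"].to_numpy() < criteria.fdr_threshold) & (
            np.abs(table["lfc"].to_numpy()) > criteria.lfc_threshold
        )
    return frozenset(table.index[np.nan_to_num(mask.astype(float)).astype(bool)])


def venn_partition(degs_a, degs_b, universe) -> VennPartition:
    """Partition ``universe`` by membership in two DEG lists."""
    a, b, u = frozenset(degs_a), frozenset(degs_b), frozenset(universe)
    stray = (a | b) - u
    if stray:
        raise ValidationError(
            f"DEGs outside the universe: {sorted(stray)[:5]}{'...' if len(stray) > 5 else ''}"
        )
    return VennPartition(
        only_a=a - b, only_b=b - a, both=a & b, neither=u - (a | b)
    )
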
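"""Gene-set statistics: hypergeometric ORA, the CERNO rank test, disco scores.

Two generations of gene-set enrichment are provided. Overrepresentation
analysis (ORA, "generation I") tests a hard-thresholded gene list against
each set with the hypergeometric upper tail. The CERNO test ("generation
II") needs no threshold: it combines the ranks of a set's genes in a
p-value-ordered list via Fisher's method,

    S = -2 * sum_{i in set} ln(r_i / N)  ~  chi2(2 * |set|)  under the null,

which is the natural choice for the interaction contrast, where typically
no single gene clears an FDR threshold. The disco score summarises
concordance of a gene's behaviour across two comparisons:

    disco = lfc_A * lfc_B * (|log10 p_A| + |log10 p_B|),

positive when the effects agree in sign, negative when they oppose.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom

from degvenn.datatypes import GeneSet, GeneSetCollection
from degvenn.diffexp import bh_adjust
from degvenn.errors import ValidationError

logger = logging.getLogger(__name__)


def filter_gene_sets(
    collection: GeneSetCollection,
    universe,
    min_size: int = 10,
    max_size: int = 50,
) -> GeneSetCollection:
    """Intersect sets with the universe, then drop those outside [min_size, max_size].

    Bounds are inclusive: a set is retained iff
    ``min_size <= |members ∩ universe| <= max_size``. Surviving sets keep
    only their in-universe members.
    """
    u = frozenset(universe)
    kept: list[GeneSet] = []
    labels: dict[str, str] = {}
    for s in collection:
        members = tuple(g for g in s.members if g in u)
        if min_size <= len(members) <= max_size:
            kept.append(GeneSet(s.name, s.description, members))
            lab = collection.label(s.name)
            if lab is not None:
                labels[s.name] = lab
    return GeneSetCollection(sets=kept, labels=labels)


def hypergeom_test(foreground, universe, gene_set):
    """Upper-tail hypergeometric overlap test.

    Returns ``(p_value, overlap, set_size_in_universe, expected_overlap)``
    where p = P(X >= overlap) for X ~ Hypergeom(N=|universe|,
    K=|set ∩ universe|, n=|foreground|). An empty foreground yields p = 1
    with a warning.
    """
    u = frozenset(universe)
    fg = frozenset(foreground)
    if not fg <= u:
        raise ValidationError("foreground must be a subset of the universe")
    s = frozenset(gene_set) & u
    N, K, n = len(u), len(s), len(fg)
    k = len(fg & s)
    expected = n * K / N if N else 0.0
    if n == 0:
        warnings.warn("empty foreground; returning p = 1", stacklevel=2)
        return 1.0, 0, K, expected
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(p, 1.0), k, K, expected


def run_ora(foreground, universe, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric ORA over a (pre-filtered) collection, BH across sets.

    Returns a DataFrame sorted by p-value with columns ``set_name, n_set,
    n_overlap, expected, p_value, fdr`` and, where the collection is
    labelled, a ``label`` column.
    """
    rows = []
    for s in collection:
        p, k, K, expected = hypergeom_test(foreground, universe, s.members)
        rows.append(
            {
                "set_name": s.name,
                "n_set": K,
                "n_overlap": k,
                "expected": expected,
                "p_value": p,
                "label": collection.label(s.name),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set_name", "n_set", "n_overlap", "expected", "p_value", "label"],
    )
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def rank_genes(table: pd.DataFrame) -> list[str]:
    """Deterministic CERNO ordering of a DE result table.

    Ascending raw p-value; ties broken by descending |LFC|, then by gene
    identifier. Filtered genes (NaN p) are excluded.
    """
    t = table.loc[~table["pvalue"].isna()].copy()
    t["_abs_lfc"] = -t["lfc"].abs()
    t["_gene"] = t.index
    t = t.sort_values(["pvalue", "_abs_lfc", "_gene"], kind="mergesort")
    return list(t.index)


def cerno_test(ranked_genes, gene_set):
    """CERNO statistic and p-value for one set against a ranked gene list.

    Returns ``(statistic, df, p_value, n_in_list)`` or ``None`` when the
    set does not intersect the list (logged, not an error).
    """
    positions = {g: i + 1 for i, g in enumerate(ranked_genes)}
    N = len(ranked_genes)
    ranks = np.array([positions[g] for g in gene_set if g in positions], dtype=float)
    if ranks.size == 0:
        logger.info("gene set has no members in the ranked list; skipped")
        return None
    stat = float(-2.0 * np.log(ranks / N).sum())
    df = 2 * ranks.size
    p = float(chi2.sf(stat, df))
    return stat, df, p, int(ranks.size)


def run_cerno(ranked_genes, collection: GeneSetCollection) -> pd.DataFrame:
    """CERNO over every set in a collection, BH across the tested sets."""
    rows = []
    for s in collection:
        res = cerno_test(ranked_genes, s.members)
        if res is None:
            continue
        stat, df, p, k = res
        rows.append(
            {
                "set_name": s.name,
                "n_in_list": k,
                "cerno_statistic": stat,
                "df": df,
                "p_value": p,
                "label": collection.label(s.name),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set_name", "n_in_list", "cerno_statistic", "df", "p_value", "label"],
    )
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def disco_score(lfc_a, lfc_b, p_a, p_b):
    """Signed concordance/discordance score for two comparisons.

    ``lfc_a * lfc_b * (|log10 p_a| + |log10 p_b|)``; positive for effects
    of the same sign, negative for opposing signs, zero when either LFC is
    zero or both p-values equal one. Zero p-values are clamped to the
    smallest positive float with a warning.
    """
    lfc_a = np.asarray(lfc_a, float)
    lfc_b = np.asarray(lfc_b, float)
    p_a = np.asarray(p_a, float)
    p_b = np.asarray(p_b, float)
    if ((p_a < 0) | (p_a > 1) | (p_b < 0) | (p_b > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    if (p_a == 0).any() or (p_b == 0).any():
        warnings.warn("p = 0 clamped to the smallest positive float", stacklevel=2)
    p_a = np.maximum(p_a, tiny)
    p_b = np.maximum(p_b, tiny)
    score = lfc_a * lfc_b * (np.abs(np.log10(p_a)) + np.abs(np.log10(p_b)))
    if score.ndim == 0:
        return float(score)
    return score


def disco_table(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene disco table from two DE result tables on the same universe."""
    genes = table_a.index
    if not genes.equals(table_b.index):
        raise ValidationError("result tables must share the same gene index")
    mask = ~(table_a["pvalue"].isna() | table_b["pvalue"].isna())
    out = pd.DataFrame(
        {
            "lfc_a": table_a["lfc"],
            "lfc_b": table_b["lfc"],
            "p_a": table_a["pvalue"],
            "p_b": table_b["pvalue"],
        },
        index=genes,
    )
    out["disco_score"] = np.nan
    out.loc[mask, "disco_score"] = disco_score(
        out.loc[mask, "lfc_a"],
        out.loc[mask, "lfc_b"],
        out.loc[mask, "p_a"],
        out.loc[mask, "p_b"],
    )
    return out
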
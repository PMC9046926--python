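"""Gene-set statistics: size filter, hypergeometric ORA, CERNO, disco."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from degvenn import (
    cerno_test,
    disco_score,
    disco_table,
    filter_gene_sets,
    hypergeom_test,
    rank_genes,
    run_cerno,
    run_ora,
)
from degvenn.datatypes import GeneSet, GeneSetCollection
from degvenn.errors import ValidationError


def _make_collection(sizes, universe_prefix="g"):
    sets = []
    start = 0
    for i, size in enumerate(sizes):
        members = tuple(f"{universe_prefix}{j}" for j in range(start, start + size))
        sets.append(GeneSet(f"S{i}", "", members))
        start += size
    return GeneSetCollection(sets=sets)


class TestFilterGeneSets:
    def test_inclusive_bounds(self):
        universe = {f"g{i}" for i in range(200)}
        coll = _make_collection([9, 10, 50, 51])
        kept = filter_gene_sets(coll, universe)
        assert kept.names() == ["S1", "S2"]  # 9 and 51 removed, 10 and 50 kept

    def test_intersection_first(self):
        universe = {f"g{i}" for i in range(15)}  # only 15 of S0's 30 members
        coll = _make_collection([30])
        kept = filter_gene_sets(coll, universe)
        assert len(kept) == 1 and len(kept["S0"].members) == 15

    def test_labels_survive(self):
        coll = GeneSetCollection(
            sets=[GeneSet("A", "", tuple(f"g{i}" for i in range(20)))],
            labels={"A": "response"},
        )
        kept = filter_gene_sets(coll, {f"g{i}" for i in range(100)})
        assert kept.label("A") == "response"


def _hypergeom_tail_oracle(N, K, n, k):
    """Exhaustive enumeration of P(X >= k) from the pmf via binomials."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestHypergeomTest:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(5)}
        foreground = {"g0", "g1", "g2", "g10", "g11"}  # overlap 3
        p, k, K, expected = hypergeom_test(foreground, universe, gene_set)
        assert k == 3 and K == 5
        assert p == pytest.approx(1126 / 15504, abs=1e-10)
        assert expected == pytest.approx(5 * 5 / 20)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        p, k, _, _ = hypergeom_test({"g0"}, universe, {"g5", "g6"})
        assert k == 0 and p == pytest.approx(1.0)

    def test_degenerate_certainty(self):
        u = {f"g{i}" for i in range(6)}
        p, k, _, _ = hypergeom_test(u, u, u)
        assert k == 6 and p == pytest.approx(1.0)

    def test_empty_foreground_warns(self):
        u = {"a", "b", "c"}
        with pytest.warns(UserWarning, match="empty foreground"):
            p, *_ = hypergeom_test(set(), u, {"a"})
        assert p == 1.0

    def test_foreground_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_test({"z"}, {"a"}, {"a"})

    def test_matches_enumeration_oracle_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            N = int(rng.integers(5, 26))
            universe = {f"g{i}" for i in range(N)}
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            gene_set = set(rng.choice(sorted(universe), K, replace=False))
            foreground = set(rng.choice(sorted(universe), n, replace=False))
            p, k, *_ = hypergeom_test(foreground, universe, gene_set)
            assert p == pytest.approx(_hypergeom_tail_oracle(N, K, n, k), abs=1e-12)


class TestRunOra:
    def test_empty_collection(self):
        out = run_ora({"a"}, {"a", "b"}, GeneSetCollection(sets=[]))
        assert len(out) == 0

    def test_constructed_positive_control(self):
        universe = {f"g{i}" for i in range(100)}
        target = GeneSet("hit", "", tuple(f"g{i}" for i in range(10, 25)))
        decoys = [
            GeneSet(f"bg{j}", "", tuple(f"g{i}" for i in range(30 + 10 * j, 45 + 10 * j)))
            for j in range(4)
        ]
        coll = GeneSetCollection(sets=[target, *decoys])
        foreground = set(target.members)
        out = run_ora(foreground, universe, coll)
        assert out.iloc[0]["set_name"] == "hit"

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(400)]
        coll = GeneSetCollection(
            sets=[
                GeneSet(f"S{j}", "", tuple(rng.choice(universe, 25, replace=False)))
                for j in range(20)
            ]
        )
        hits = 0
        draws = 200
        for _ in range(draws):
            fg = set(rng.choice(universe, 40, replace=False))
            out = run_ora(fg, set(universe), coll)
            hits += int((out["p_value"] < 0.05).sum())
        frac = hits / (draws * 20)
        assert 0.02 < frac < 0.08  # discrete test is conservative-ish


class TestCerno:
    def test_top_rank_singleton(self):
        ranked = [f"g{i}" for i in range(100)]
        stat, df, p, k = cerno_test(ranked, {"g0"})
        assert stat == pytest.approx(-2 * np.log(0.01))
        assert df == 2 and k == 1
        assert p == pytest.approx(0.01, abs=1e-12)

    def test_bottom_rank_singleton(self):
        ranked = [f"g{i}" for i in range(50)]
        stat, df, p, _ = cerno_test(ranked, {"g49"})
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_singleton_identity_over_grid(self):
        # for a singleton at rank r, p = r/N exactly
        for N in (10, 100, 1234):
            ranked = [f"g{i}" for i in range(N)]
            for r in (1, 2, N // 3, N // 2, N):
                _, _, p, _ = cerno_test(ranked, {f"g{r - 1}"})
                assert p == pytest.approx(r / N, abs=1e-12)

    def test_empty_intersection_skipped(self):
        assert cerno_test(["a", "b"], {"z"}) is None

    def test_null_uniformity_ks(self):
        # p-values of a fixed set under random orderings are uniform; N is
        # transcriptome-sized because the chi-squared null is continuous and
        # rank discreteness biases the statistic by ~ln(2*pi*N)/N per member
        rng = np.random.default_rng(9)
        N, m, draws = 5000, 15, 10_000
        from scipy.stats import chi2

        u = rng.random((draws, N))
        # indices of the m smallest uniforms = a uniform random m-subset of ranks
        ranks = np.argpartition(u, m, axis=1)[:, :m] + 1.0
        stat = -2.0 * np.log(ranks / N).sum(axis=1)
        p = chi2.sf(stat, 2 * m)
        assert kstest(p, "uniform").pvalue > 0.01

    def test_run_cerno_positive_control(self):
        ranked = [f"g{i}" for i in range(500)]
        top = GeneSet("top", "", tuple(f"g{i}" for i in range(12)))
        mid = GeneSet("mid", "", tuple(f"g{i}" for i in range(200, 212)))
        out = run_cerno(ranked, GeneSetCollection(sets=[top, mid]))
        assert out.iloc[0]["set_name"] == "top"
        assert out.iloc[0]["df"] == 24
        assert (out["cerno_statistic"] >= 0).all()


class TestDisco:
    def test_concordant_positive(self):
        assert disco_score(2.0, 1.0, 0.01, 0.2) > 0

    def test_discordant_negative(self):
        assert disco_score(2.0, -1.0, 0.01, 0.2) < 0

    def test_unit_pvalues_zero_score(self):
        assert disco_score(3.0, -5.0, 1.0, 1.0) == 0.0

    def test_antisymmetry_and_swap(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=50), rng.normal(size=50)
        pa, pb = rng.random(50), rng.random(50)
        s = disco_score(a, b, pa, pb)
        np.testing.assert_allclose(disco_score(-a, b, pa, pb), -s)
        np.testing.assert_allclose(disco_score(b, a, pb, pa), s)

    def test_zero_pvalue_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            s = disco_score(1.0, 1.0, 0.0, 0.5)
        assert np.isfinite(s) and s > 0

    def test_invalid_pvalue_rejected(self):
        with pytest.raises(ValidationError):
            disco_score(1.0, 1.0, -0.1, 0.5)


class TestRanking:
    def test_rank_genes_deterministic_tiebreak(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "pvalue": [0.5, 0.01, 0.5, np.nan, 0.5],
                "lfc": [1.0, 0.2, -3.0, 2.0, 1.0],
            },
            index=["b", "z", "a", "x", "c"],
        )
        ranked = rank_genes(table)
        # z first (smallest p); among the 0.5 ties |lfc| desc: a(3.0), then b/c tie -> lexicographic
        assert ranked == ["z", "a", "b", "c"]

    def test_disco_table_matches_scalar_scores(self):
        import pandas as pd

        ta = pd.DataFrame({"lfc": [1.0, -2.0], "pvalue": [0.1, 0.01]}, index=["a", "b"])
        tb = pd.DataFrame({"lfc": [0.5, 1.0], "pvalue": [0.2, 0.3]}, index=["a", "b"])
        out = disco_table(ta, tb)
        assert out.loc["a", "disco_score"] == pytest.approx(
            disco_score(1.0, 0.5, 0.1, 0.2)
        )
        assert out.loc["b", "disco_score"] < 0
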
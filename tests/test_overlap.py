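"""Hypergeometric overlap, Fisher exact test, BH adjustment, DEU analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from prcdeconv import (
    SchemaError,
    benjamini_hochberg,
    deu_overlap_analysis,
    fisher_exact_2x2,
    hypergeom_overlap,
    ora_collections,
    read_gene_set,
    read_gmt,
    significant_deu_genes,
)


def bh_bruteforce(p):
    """Literal step-up rule: adj_(i) = min over j >= i of min(1, p_(j) m / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for i in range(m - 1, -1, -1):
        prev = min(prev, p[order[i]] * m / (i + 1), 1.0)
        adj[order[i]] = prev
    return adj


class TestHypergeom:
    def test_full_overlap_small_universe(self):
        """N=10, K=5, n=5, k=5: only one of C(10,5)=252 draws achieves it."""
        uni = set(range(10))
        ref = set(range(5))
        res = hypergeom_overlap(ref, ref, uni)
        assert res.p_value == pytest.approx(1 / 252)
        assert (res.k, res.K, res.n, res.N) == (5, 5, 5, 10)

    def test_zero_overlap_is_total_probability(self):
        res = hypergeom_overlap({0, 1}, {5, 6}, set(range(10)))
        assert res.k == 0
        assert res.p_value == 1.0

    def test_subset_validation(self):
        with pytest.raises(ValueError, match="query"):
            hypergeom_overlap({99}, {1}, {1, 2})
        with pytest.raises(ValueError, match="reference"):
            hypergeom_overlap({1}, {99}, {1, 2})
        with pytest.raises(ValueError, match="universe"):
            hypergeom_overlap(set(), set(), set())

    def test_matches_one_sided_fisher(self):
        """Upper-tail hypergeometric equals one-sided Fisher on the 2x2 table."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            N = int(rng.integers(4, 200))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            uni = list(range(N))
            ref = set(uni[:K])
            query = set(rng.choice(uni, n, replace=False).tolist())
            res = hypergeom_overlap(query, ref, set(uni))
            k = res.k
            table = [[k, n - k], [K - k, N - K - n + k]]
            p_fisher = stats.fisher_exact(table, alternative="greater")[1]
            assert res.p_value == pytest.approx(p_fisher, rel=1e-9)

    def test_p_nonincreasing_in_k(self):
        N, K, n = 40, 15, 12
        sf = [float(stats.hypergeom.sf(k - 1, N, K, n)) for k in range(0, 13)]
        assert all(a >= b - 1e-12 for a, b in zip(sf, sf[1:]))


class TestFisher:
    def test_enumerated_symmetric_table(self):
        """Margins (4,4,4,4) admit 5 tables; those with point probability
        <= the observed one sum to 34/70."""
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70)

    def test_zero_margin_gives_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0
        assert fisher_exact_2x2([[2, 0], [3, 0]]) == 1.0

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fisher_exact_2x2([[1, -1], [0, 2]])

    @given(
        a=st.integers(0, 20), b=st.integers(0, 20),
        c=st.integers(0, 20), d=st.integers(0, 20),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_symmetric_under_transposition(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            fisher_exact_2x2([[a, c], [b, d]])
        )

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 30, (2, 2))
            if t.sum() == 0:
                continue
            ours = fisher_exact_2x2(t)
            ref = stats.fisher_exact(t)[1]
            assert ours == pytest.approx(ref, rel=1e-9)


class TestBH:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_all_equal_collapse_to_the_common_value(self):
        out = benjamini_hochberg([0.2] * 7)
        assert np.allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])

    @given(
        p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_monotone_order_preserving_and_bounded(self, p):
        adj = benjamini_hochberg(p)
        p = np.asarray(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_bruteforce_step_up(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 60)))
            assert np.allclose(benjamini_hochberg(p), bh_bruteforce(p), atol=1e-12)


def deu_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "exon_id", "p_value"])


class TestDeu:
    def test_all_p_one_yields_no_deu_genes(self):
        deu = deu_frame([(f"g{i}", "e1", 1.0) for i in range(20)])
        assert significant_deu_genes(deu, 0.05) == frozenset()

    def test_gene_with_two_significant_exons_counted_once(self):
        deu = deu_frame(
            [("gA", "e1", 1e-8), ("gA", "e2", 1e-9), ("gB", "e1", 0.9)]
        )
        assert significant_deu_genes(deu, 0.05) == {"gA"}

    def test_duplicate_gene_exon_pair_rejected(self):
        deu = deu_frame([("g", "e", 0.1), ("g", "e", 0.2)])
        with pytest.raises(SchemaError, match="duplicated"):
            significant_deu_genes(deu)

    def test_empty_table_rejected(self):
        with pytest.raises(SchemaError, match="empty"):
            deu_overlap_analysis(deu_frame([]), {})

    def test_planted_overlap_reproduces_hypergeometric_p(self):
        """362 planted DEU genes, 60 inside a 700-gene reference, universe
        12000: k = 60 and p equals the direct hypergeometric computation."""
        universe = [f"g{i}" for i in range(12000)]
        deu_genes = universe[:362]
        reference = set(universe[:60]) | set(universe[5000:5640])
        rows = [(g, "e1", 1e-9) for g in deu_genes]
        rows += [(g, "e1", 1.0) for g in universe[362:]]
        res, sig = deu_overlap_analysis(
            deu_frame(rows), {"as_gbm": reference}, alpha=0.05
        )
        assert sig == frozenset(deu_genes)
        assert res.loc["as_gbm", "k"] == 60
        direct = hypergeom_overlap(frozenset(deu_genes), reference, set(universe))
        assert res.loc["as_gbm", "p"] == pytest.approx(direct.p_value)
        assert res.loc["as_gbm", "p"] < 1e-3


class TestOra:
    def test_collection_equal_to_query_is_maximal_overlap(self):
        uni = {f"g{i}" for i in range(50)}
        query = {f"g{i}" for i in range(10)}
        other = {f"g{i}" for i in range(40, 50)} | {f"g{i}" for i in range(5)}
        out = ora_collections(query, {"self": query, "half": other}, uni)
        assert out.loc["self", "k"] == 10
        assert out.loc["self", "p"] < out.loc["half", "p"]

    def test_disjoint_collection_p_one(self):
        uni = {f"g{i}" for i in range(30)}
        out = ora_collections(
            {"g0", "g1"}, {"far": {"g20", "g21"}}, uni
        )
        assert out.loc["far", "p"] == 1.0

    def test_q_matches_manual_composition(self):
        uni = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(15)}
        colls = {
            "a": {f"g{i}" for i in range(10)},
            "b": {f"g{i}" for i in range(50, 70)},
            "c": {f"g{i}" for i in range(5, 30)},
        }
        out = ora_collections(query, colls, uni)
        manual = benjamini_hochberg(out["p"].to_numpy())
        assert np.allclose(out["q"].to_numpy(), manual)


class TestGeneSetIO:
    def test_one_id_per_line_with_comments(self, tmp_path):
        f = tmp_path / "set.txt"
        f.write_text("# header\nGENE1\n\nGENE2\nGENE1\n")
        assert read_gene_set(f) == {"GENE1", "GENE2"}

    def test_gmt_parsing(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("s1\tdesc\tA\tB\ns2\tdesc\tC\n")
        out = read_gmt(f)
        assert out == {"s1": frozenset({"A", "B"}), "s2": frozenset({"C"})}

    def test_malformed_gmt_rejected(self, tmp_path):
        f = tmp_path / "bad.gmt"
        f.write_text("only_name\n")
        with pytest.raises(SchemaError, match="GMT"):
            read_gmt(f)
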
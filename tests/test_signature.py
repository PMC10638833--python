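"""Spearman screening, candidate selection and connectivity pruning."""

import itertools
import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from atrasens.signature import (SensitivitySignature, SensitivitySignatureScreen,
                                connectivity_filter, correlate_expression,
                                derive_signature, select_candidates)


def _expr(matrix, genes, samples):
    return pd.DataFrame(matrix, index=genes, columns=samples)


def _scores(values, samples):
    return pd.Series(values, index=samples, dtype=float)


def brute_spearman(x, y):
    """Rank-then-Pearson, coded independently of the implementation."""
    def rank(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = rank(list(x)), rank(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def permutation_pvalue(x, y):
    """Exhaustive two-sided permutation p for Spearman rho (tiny n, no ties).

    Uses the classical 1 - 6*sum(d^2)/(n(n^2-1)) form, a different route
    than the implementation's Pearson-on-ranks.
    """
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1.0
    ry = np.argsort(np.argsort(y)) + 1.0
    perms = np.array(list(itertools.permutations(ry)))
    denom = n * (n * n - 1)
    null = 1.0 - 6.0 * ((rx - perms) ** 2).sum(axis=1) / denom
    obs = 1.0 - 6.0 * ((rx - ry) ** 2).sum() / denom
    return float(np.mean(np.abs(null) >= abs(obs) - 1e-12))


class TestCorrelateExpression:
    def test_perfect_monotone_and_antitone(self):
        samples = list("abcdefgh")
        y = np.arange(8.0)
        expr = _expr([y, -y], ["up", "dn"], samples)
        stats = correlate_expression(expr, _scores(y, samples)).set_index("gene")
        assert stats.loc["up", "rho"] == pytest.approx(1.0)
        assert stats.loc["dn", "rho"] == pytest.approx(-1.0)
        # minimal attainable two-sided permutation p at n=8: both tails
        assert stats.loc["up", "p"] == pytest.approx(2 / math.factorial(8), abs=1e-9)

    def test_matches_exhaustive_permutation_oracle_n8(self, rng):
        samples = [f"s{i}" for i in range(8)]
        X = rng.normal(size=(5, 8))
        y = rng.normal(size=8)
        stats = correlate_expression(_expr(X, [f"g{i}" for i in range(5)], samples),
                                     _scores(y, samples))
        for i, row in stats.iterrows():
            assert row["rho"] == pytest.approx(brute_spearman(X[i], y), abs=1e-12)
            assert row["p"] == pytest.approx(permutation_pvalue(X[i], y), abs=1e-12)

    def test_ties_use_average_ranks(self):
        samples = list("abcdef")
        x = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
        y = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        stats = correlate_expression(_expr([x], ["g"], samples), _scores(y, samples))
        assert stats.loc[0, "rho"] == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_too_few_shared_samples_rejected(self):
        expr = _expr(np.ones((1, 3)), ["g"], ["a", "b", "c"])
        with pytest.raises(ValueError, match=">=3 shared"):
            correlate_expression(expr, _scores([1.0, 2.0], ["a", "b"]))

    def test_constant_gene_flagged_and_excluded_downstream(self):
        samples = list("abcdef")
        y = np.arange(6.0)
        expr = _expr([np.ones(6), y], ["const", "ok"], samples)
        stats = correlate_expression(expr, _scores(y, samples))
        assert np.isnan(stats.set_index("gene").loc["const", "rho"])
        sig = select_candidates(stats, p_max=1.0, rho_min=0.0)
        assert "const" not in sig.genes and "ok" in sig.genes

    def test_alignment_uses_shared_samples_only(self, rng):
        samples = [f"s{i}" for i in range(10)]
        X = rng.normal(size=(3, 10))
        y = rng.normal(size=12)
        scores = _scores(y, [f"s{i}" for i in range(12)])
        stats = correlate_expression(_expr(X, list("abc"), samples), scores)
        assert (stats["n"] == 10).all()

    @given(st.integers(0, 6))
    def test_invariant_under_monotone_transforms(self, case):
        rng = np.random.default_rng(case)
        samples = [f"s{i}" for i in range(12)]
        x = rng.normal(size=12)
        y = rng.uniform(size=12)
        base = correlate_expression(_expr([x], ["g"], samples), _scores(y, samples))
        warped = correlate_expression(_expr([np.exp(x)], ["g"], samples),
                                      _scores(3.0 * y + 1.0, samples))
        assert warped.loc[0, "rho"] == pytest.approx(base.loc[0, "rho"], abs=1e-12)
        assert warped.loc[0, "p"] == pytest.approx(base.loc[0, "p"], abs=1e-12)


class TestSelectCandidates:
    def test_direct_and_inverse_examples(self):
        stats = pd.DataFrame({"gene": ["a", "b"], "rho": [0.9, -0.5],
                              "p": [0.001, 0.005], "n": 27})
        sig = select_candidates(stats)
        assert sig.direct == ["a"] and sig.inverse == ["b"]

    def test_quadrant_toy_table_matches_brute_filter(self):
        stats = pd.DataFrame({
            "gene": list("abcdef"),
            "rho": [0.9, -0.9, 0.2, -0.2, 0.5, -0.5],
            "p": [0.001, 0.001, 0.001, 0.001, 0.5, 0.5],
            "n": 27,
        })
        sig = select_candidates(stats, p_max=0.01, rho_min=0.4)
        brute = {row.gene for row in stats.itertuples()
                 if row.p < 0.01 and abs(row.rho) > 0.4}
        assert set(sig.genes) == brute == {"a", "b"}

    def test_empty_result_allowed(self):
        stats = pd.DataFrame({"gene": ["a"], "rho": [0.1], "p": [0.9], "n": 10})
        sig = select_candidates(stats)
        assert sig.genes == []


class TestConnectivityFilter:
    def _sig(self, genes):
        stats = pd.DataFrame({"gene": genes, "direction": ["direct"] * len(genes),
                              "rho": 0.5, "p": 0.001})
        return SensitivitySignature(direct=list(genes), inverse=[], stats=stats)

    def test_hand_enumerated_induced_degrees(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("D", "E")])
        out = connectivity_filter(self._sig(list("ABCDE")), g, min_degree=2)
        assert set(out.genes) == {"A", "B", "C"}
        assert dict(zip(out.stats.gene, out.stats.degree)) == {"A": 2, "B": 2, "C": 2}

    def test_empty_edge_set_empties_signature(self):
        g = nx.Graph()
        g.add_nodes_from("ABC")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = connectivity_filter(self._sig(list("ABC")), g, min_degree=2)
        assert out.genes == []

    def test_complete_graph_retains_everything(self):
        g = nx.complete_graph(list("ABCD"))
        out = connectivity_filter(self._sig(list("ABCD")), g, min_degree=2)
        assert set(out.genes) == set("ABCD")

    def test_degree_counted_within_candidates_not_whole_graph(self):
        # B has degree 3 in the full graph but only 1 among candidates
        g = nx.Graph([("A", "B"), ("B", "X"), ("B", "Y")])
        out = connectivity_filter(self._sig(["A", "B"]), g, min_degree=2)
        assert out.genes == []

    def test_missing_genes_warned_and_degree_zero(self):
        g = nx.Graph([("A", "B")])
        with pytest.warns(UserWarning, match="absent from the interaction graph"):
            out = connectivity_filter(self._sig(["A", "B", "Z"]), g, min_degree=0)
        assert set(out.genes) == {"A", "B", "Z"}

    @given(st.integers(0, 20), st.integers(0, 4))
    def test_subset_and_monotone_in_min_degree(self, seed, k):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(10)]
        g = nx.gnp_random_graph(10, 0.3, seed=seed)
        g = nx.relabel_nodes(g, dict(enumerate(genes)))
        sig = self._sig(genes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            small = set(connectivity_filter(sig, g, min_degree=k).genes)
            large = set(connectivity_filter(sig, g, min_degree=k + 1).genes)
        assert large <= small <= set(genes)


class TestDeriveSignature:
    def test_disabled_filters_keep_all_nonconstant_genes(self, rng):
        samples = [f"s{i}" for i in range(6)]
        X = rng.normal(size=(5, 6))
        expr = _expr(np.vstack([X, np.ones(6)]), [f"g{i}" for i in range(5)] + ["const"],
                     samples)
        g = nx.Graph()
        g.add_nodes_from(expr.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig = derive_signature(expr, _scores(rng.uniform(size=6), samples), g,
                                   p_max=1.01, rho_min=0.0, min_degree=0)
        assert set(sig.genes) == {f"g{i}" for i in range(5)}

    def test_isolated_planted_genes_yield_empty_signature(self):
        samples = [f"s{i}" for i in range(8)]
        y = np.arange(8.0)
        expr = _expr([y, -y], ["a", "b"], samples)
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])  # present but unconnected
        sig = derive_signature(expr, _scores(y, samples), g)
        assert sig.genes == []

    def test_deterministic_given_identical_inputs(self, rng):
        samples = [f"s{i}" for i in range(10)]
        expr = _expr(rng.normal(size=(20, 10)), [f"g{i}" for i in range(20)], samples)
        scores = _scores(rng.uniform(size=10), samples)
        g = nx.gnp_random_graph(20, 0.2, seed=1)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(20)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = derive_signature(expr, scores, g, p_max=0.5, rho_min=0.1, min_degree=1)
            b = derive_signature(expr, scores, g, p_max=0.5, rho_min=0.1, min_degree=1)
        assert a.genes == b.genes
        pd.testing.assert_frame_equal(a.stats, b.stats)


class TestEstimator:
    def test_screen_matches_function_path(self, rng):
        samples = [f"s{i}" for i in range(12)]
        expr = _expr(rng.normal(size=(30, 12)), [f"g{i}" for i in range(30)], samples)
        scores = _scores(rng.uniform(size=12), samples)
        g = nx.complete_graph([f"g{i}" for i in range(30)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = SensitivitySignatureScreen(graph=g, p_max=0.5, rho_min=0.1).fit(
                expr.T, scores.loc[samples])
            ref = derive_signature(expr, scores, g, p_max=0.5, rho_min=0.1)
        assert est.direct_ == ref.direct and est.inverse_ == ref.inverse

    def test_graph_required(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"))
        with pytest.raises(ValueError, match="graph"):
            SensitivitySignatureScreen().fit(X, np.arange(5.0))
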
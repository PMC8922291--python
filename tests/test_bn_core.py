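import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from interatlas.bn_core import (
    BICScore,
    DAG,
    DiscreteDataset,
    bic_score,
    bootstrap_strengths,
    fit_cpts,
    hill_climb,
    infer_posterior,
    significance_threshold,
)


def dataset(cols: dict[str, np.ndarray], arity=2) -> DiscreteDataset:
    names = tuple(cols)
    vals = np.column_stack([cols[n] for n in names])
    ar = (arity,) * len(names) if isinstance(arity, int) else tuple(arity)
    return DiscreteDataset(names, ar, vals)


def enumerate_dags(variables):
    """Brute-force oracle: every labelled DAG on the given nodes."""
    arcs_all = [(u, v) for u in variables for v in variables if u != v]
    for r in range(len(arcs_all) + 1):
        for combo in itertools.combinations(arcs_all, r):
            try:
                yield DAG(variables, combo)
            except ValueError:
                continue


# ---------------------------------------------------------------------------
# BIC


class TestBicScore:
    def test_closed_form_single_binary_variable(self):
        d = dataset({"x": np.array([0, 0, 1, 1])})
        expected = 4 * math.log(0.5) - math.log(4) / 2
        assert bic_score(DAG(("x",)), d) == pytest.approx(expected)

    def test_uninformative_parent_never_helps(self):
        # exactly independent counts: all four (x, y) cells equal
        x = np.array([0, 0, 1, 1] * 25)
        y = np.array([0, 1, 0, 1] * 25)
        d = dataset({"x": x, "y": y})
        empty = bic_score(DAG(("x", "y")), d)
        with_arc = bic_score(DAG(("x", "y"), [("x", "y")]), d)
        assert with_arc < empty

    def test_deterministic_dependence_beats_empty_model(self):
        x = np.array([0, 1] * 50)
        d = dataset({"x": x, "y": x})
        empty = bic_score(DAG(("x", "y")), d)
        arc = bic_score(DAG(("x", "y"), [("x", "y")]), d)
        # likelihood gain 100*log 2; one extra free parameter costs
        # log(100)/2
        assert arc - empty == pytest.approx(
            100 * math.log(2) - math.log(100) / 2
        )
        assert arc > empty

    def test_decomposability(self, rng):
        cols = {n: rng.integers(0, 2, 60) for n in "abc"}
        d = dataset(cols)
        dag = DAG(("a", "b", "c"), [("a", "b"), ("b", "c")])
        score = BICScore(d)
        total = sum(
            score.local(i, frozenset(d.variables.index(p)
                                     for p in dag.parents(v)))
            for i, v in enumerate(d.variables)
        )
        assert bic_score(dag, d) == pytest.approx(total)

    def test_vectorised_add_deltas_match_scalar_locals(self, rng):
        cols = {n: rng.integers(0, 3, 80) for n in "abcd"}
        d = dataset(cols, arity=3)
        score = BICScore(d)
        for v in range(4):
            for parents in (frozenset(), frozenset({(v + 1) % 4})):
                vec = score.add_child_deltas(v, parents)
                for u in range(4):
                    if u == v or u in parents:
                        assert vec[u] == -np.inf
                    else:
                        expected = score.local(v, parents | {u}) \
                            - score.local(v, parents)
                        assert vec[u] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# hill climbing


class TestHillClimb:
    def test_independent_variables_give_empty_graph(self, rng):
        x = np.array([0, 0, 1, 1] * 100)
        y = np.array([0, 1, 0, 1] * 100)
        assert hill_climb(dataset({"x": x, "y": y}), seed=1).arcs == frozenset()

    def test_deterministic_copy_gives_single_arc(self, rng):
        x = rng.integers(0, 2, 400)
        dag = hill_climb(dataset({"x": x, "y": x}), seed=1)
        assert dag.skeleton() == {("x", "y")}

    def test_noisy_chain_recovers_skeleton_without_shortcut(self, rng):
        x = rng.integers(0, 2, 500)
        y = np.where(rng.random(500) < 0.9, x, 1 - x)
        z = np.where(rng.random(500) < 0.9, y, 1 - y)
        dag = hill_climb(dataset({"x": x, "y": y, "z": z}), seed=1)
        assert dag.skeleton() == {("x", "y"), ("y", "z")}

    def test_result_is_local_optimum(self, rng):
        cols = {n: rng.integers(0, 2, 120) for n in "abcd"}
        d = dataset(cols)
        dag = hill_climb(d, seed=3)
        base = bic_score(dag, d)
        for move_dag in _neighbourhood(dag):
            assert bic_score(move_dag, d) <= base + 1e-9

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_search_on_three_variables(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, 80)
        y = np.where(rng.random(80) < 0.8, x, rng.integers(0, 2, 80))
        z = rng.integers(0, 2, 80)
        d = dataset({"x": x, "y": y, "z": z})
        best = max(enumerate_dags(d.variables),
                   key=lambda g: bic_score(g, d))
        found = hill_climb(d, restarts=5, seed=seed)
        assert bic_score(found, d) == pytest.approx(bic_score(best, d))

    def test_never_scores_below_empty_graph(self, rng):
        cols = {n: rng.integers(0, 2, 50) for n in "abcde"}
        d = dataset(cols)
        dag = hill_climb(d, seed=0)
        assert bic_score(dag, d) >= bic_score(DAG(d.variables), d) - 1e-9

    def test_max_parents_respected(self, rng):
        cols = {n: rng.integers(0, 2, 200) for n in "abcdef"}
        d = dataset(cols)
        dag = hill_climb(d, seed=0, max_parents=1)
        for v in dag.nodes:
            assert len(dag.parents(v)) <= 1


def _neighbourhood(dag: DAG):
    nodes = dag.nodes
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if (u, v) in dag.arcs:
                yield DAG(nodes, dag.arcs - {(u, v)})  # delete
                try:
                    yield DAG(nodes, (dag.arcs - {(u, v)}) | {(v, u)})
                except ValueError:
                    pass
            elif (v, u) not in dag.arcs:
                try:
                    yield DAG(nodes, dag.arcs | {(u, v)})
                except ValueError:
                    pass


# ---------------------------------------------------------------------------
# bootstrap strengths


class TestBootstrapStrengths:
    def test_single_replicate_strengths_are_binary(self, rng):
        x = rng.integers(0, 2, 100)
        st_ = bootstrap_strengths(dataset({"x": x, "y": x}), B=1, seed=0)
        assert set(st_.pairs.values()) <= {0.0, 1.0}

    def test_deterministic_dependence_always_recovered(self, rng):
        x = rng.integers(0, 2, 200)
        st_ = bootstrap_strengths(dataset({"x": x, "y": x}), B=12, seed=0)
        assert st_.strength("x", "y") == 1.0

    def test_absent_pair_scores_zero(self, rng):
        x = np.array([0, 0, 1, 1] * 50)
        y = np.array([0, 1, 0, 1] * 50)
        st_ = bootstrap_strengths(dataset({"x": x, "y": y}), B=8, seed=0)
        assert st_.strength("x", "y") == 0.0

    def test_invariant_to_row_order(self, rng):
        x = rng.integers(0, 2, 120)
        y = np.where(rng.random(120) < 0.8, x, 1 - x)
        d = dataset({"x": x, "y": y})
        perm = rng.permutation(120)
        d_perm = DiscreteDataset(d.variables, d.arity, d.values[perm])
        s1 = bootstrap_strengths(d, B=10, seed=4)
        s2 = bootstrap_strengths(d_perm, B=10, seed=4)
        assert s1.pairs == s2.pairs

    def test_deterministic_given_seed(self, rng):
        x = rng.integers(0, 2, 100)
        y = np.where(rng.random(100) < 0.7, x, 1 - x)
        d = dataset({"x": x, "y": y})
        assert bootstrap_strengths(d, B=15, seed=7).pairs == \
            bootstrap_strengths(d, B=15, seed=7).pairs


# ---------------------------------------------------------------------------
# significance threshold


class TestSignificanceThreshold:
    def test_two_step_set_thresholds_between(self):
        t = significance_threshold([0, 0, 1, 1])
        assert 0 < t < 1
        assert sum(s > t for s in [0, 0, 1, 1]) == 2

    def test_separated_set_keeps_high_values(self):
        vals = [0.05, 0.1, 0.9, 0.95]
        t = significance_threshold(vals)
        assert sorted(s for s in vals if s > t) == [0.9, 0.95]

    def test_single_value_retained(self):
        with pytest.warns(RuntimeWarning):
            t = significance_threshold([0.7])
        assert t < 0.7
        assert 0.7 > t

    def test_identical_values_warn_and_retain(self):
        with pytest.warns(RuntimeWarning):
            t = significance_threshold([0.4, 0.4, 0.4])
        assert t < 0.4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold([])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_threshold_always_within_range(self, vals):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = significance_threshold(vals)
        assert min(vals) - 1e-9 <= t <= max(vals)


# ---------------------------------------------------------------------------
# CPTs and inference


class TestFitCpts:
    def test_laplace_smoothing(self):
        d = dataset({"x": np.array([0, 0, 0, 1])})
        cpts = fit_cpts(DAG(("x",)), d, pseudo=1.0)
        parents, table = cpts["x"]
        assert parents == ()
        assert table[0] == pytest.approx([4 / 6, 2 / 6])

    def test_zero_pseudo_degenerate(self):
        d = dataset({"x": np.zeros(5, dtype=int)})
        _, table = fit_cpts(DAG(("x",)), d, pseudo=0.0)["x"]
        assert table[0] == pytest.approx([1.0, 0.0])

    def test_unseen_parent_configuration_uniform(self):
        x = np.zeros(4, dtype=int)  # parent never takes state 1
        y = np.array([0, 1, 0, 1])
        d = dataset({"x": x, "y": y})
        _, table = fit_cpts(DAG(("x", "y"), [("x", "y")]), d, pseudo=1.0)["y"]
        assert table[1] == pytest.approx([0.5, 0.5])


def joint_enumeration_posterior(dag, cpts, evidence, query, arity):
    """Independent oracle: sum the full joint table."""
    nodes = list(dag.nodes)
    dist = np.zeros(arity[query])
    for assignment in itertools.product(
        *[range(arity[n]) for n in nodes]
    ):
        state = dict(zip(nodes, assignment))
        if any(state[e] != v for e, v in evidence.items()):
            continue
        p = 1.0
        for n in nodes:
            parents, table = cpts[n]
            row = 0
            for par in parents:
                row = row * arity[par] + state[par]
            p *= table[row, state[n]]
        dist[state[query]] += p
    return dist / dist.sum()


class TestInferPosterior:
    def test_hand_computed_bayes_flip(self):
        dag = DAG(("E", "GI"), [("GI", "E")])
        cpts = {
            "GI": ((), np.array([[0.7, 0.3]])),
            "E": (("GI",), np.array([[0.9, 0.1], [0.1, 0.9]])),
        }
        post = infer_posterior(dag, cpts, {"E": 1}, "GI")
        assert post[1] == pytest.approx(0.27 / 0.34)

    def test_no_evidence_returns_prior_marginal(self):
        dag = DAG(("E", "GI"), [("GI", "E")])
        cpts = {
            "GI": ((), np.array([[0.7, 0.3]])),
            "E": (("GI",), np.array([[0.9, 0.1], [0.1, 0.9]])),
        }
        assert infer_posterior(dag, cpts, {}, "GI")[1] == pytest.approx(0.3)

    def test_d_separated_evidence_leaves_marginal(self):
        dag = DAG(("A", "Q"))  # disconnected
        cpts = {
            "A": ((), np.array([[0.5, 0.5]])),
            "Q": ((), np.array([[0.2, 0.8]])),
        }
        assert infer_posterior(dag, cpts, {"A": 1}, "Q")[1] == \
            pytest.approx(0.8)

    def test_contradictory_evidence_raises(self):
        dag = DAG(("x", "y"), [("x", "y")])
        cpts = {
            "x": ((), np.array([[1.0, 0.0]])),
            "y": (("x",), np.array([[1.0, 0.0], [0.0, 1.0]])),
        }
        with pytest.raises(ValueError, match="zero probability"):
            infer_posterior(dag, cpts, {"x": 1}, "y")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_joint_enumeration_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        names = tuple(f"v{i}" for i in range(n))
        arcs = [
            (names[i], names[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.4
        ]
        dag = DAG(names, arcs)
        rows = rng.integers(0, 2, size=(60, n))
        data = DiscreteDataset(names, (2,) * n, rows)
        cpts = fit_cpts(dag, data, pseudo=1.0)
        arity = {v: 2 for v in names}
        n_ev = int(rng.integers(0, n - 1))
        ev_vars = list(rng.choice(n, size=n_ev, replace=False))
        query = next(
            names[i] for i in range(n) if i not in ev_vars
        )
        evidence = {names[i]: int(rng.integers(0, 2)) for i in ev_vars}
        got = infer_posterior(dag, cpts, evidence, query)
        want = joint_enumeration_posterior(dag, cpts, evidence, query, arity)
        assert got == pytest.approx(want, abs=1e-10)
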
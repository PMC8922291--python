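import numpy as np
import pandas as pd
import pytest

from interatlas.bn_core import DAG, StrengthTable
from interatlas.bnp_prior import (
    GI,
    BNPModel,
    EvidenceMatrix,
    add_coexpression,
    cross_validate_gi,
    graph_log_prior,
    label_gi,
    learn_bnp,
    pair_prior_matrix,
)
from interatlas.synthetic_data import (
    EvidenceSpec,
    generate_evidence,
)


def evidence_from_rows(rows, columns, experimental=()):
    df = pd.DataFrame(
        [r[1] for r in rows],
        index=pd.MultiIndex.from_tuples([r[0] for r in rows]),
        columns=columns,
    )
    return EvidenceMatrix(df, experimental_types=frozenset(experimental))


class TestLabelGi:
    @pytest.mark.parametrize(
        "vector,expected",
        [([1, 0, 0], 0), ([1, 1, 0], 1), ([0, 0, 0], 0), ([1, 1, 1], 1)],
    )
    def test_two_or_more_evidence_types_rule(self, vector, expected):
        E = evidence_from_rows([(("a", "b"), vector)], ["t1", "t2", "t3"])
        labeled = label_gi(E)
        assert labeled.data.loc[("a", "b"), GI] == expected

    def test_idempotent(self):
        E = evidence_from_rows(
            [(("a", "b"), [1, 1]), (("a", "c"), [1, 0])], ["t1", "t2"]
        )
        once = label_gi(E)
        twice = label_gi(once)
        assert once.data.equals(twice.data)

    def test_counts_knowledge_columns_only(self):
        E = evidence_from_rows(
            [(("a", "b"), [1, 0, 1])], ["t1", "t2", "coexpression"],
            experimental=["coexpression"],
        )
        labeled = label_gi(E)
        # one knowledge type + one experimental type: below the 2-type rule
        assert labeled.data.loc[("a", "b"), GI] == 0


def synthetic_labeled_evidence(n_rows, n_types, sensitivity, fpr, seed,
                               edge_fraction=0.3):
    rng = np.random.default_rng(seed)
    is_edge = rng.random(n_rows) < edge_fraction
    prob = np.where(is_edge[:, None], sensitivity, fpr)
    draws = (rng.random((n_rows, n_types)) < prob).astype(int)
    pairs = [(f"g{2 * i:05d}", f"g{2 * i + 1:05d}") for i in range(n_rows)]
    cols = [f"t{j}" for j in range(n_types)]
    return label_gi(evidence_from_rows(list(zip(pairs, draws)), cols))


class TestLearnBnp:
    def test_perfect_evidence_connects_types_to_gi(self):
        E = synthetic_labeled_evidence(400, 3, 1.0, 0.0, seed=1)
        model = learn_bnp(E, B=20, seed=2)
        # with evidence identical to the edge indicator, every type must end
        # up in GI's connected component of the consensus skeleton
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(model.dag.nodes)
        g.add_edges_from(model.dag.skeleton())
        comp = nx.node_connected_component(g, GI)
        assert set(E.type_names) <= comp

    def test_independent_evidence_gives_only_weak_gi_links(self):
        """With evidence independent of GI, any arcs touching GI are noise:
        their bootstrap strengths stay near the noise floor, far below the
        support deterministic dependence earns (strength 1)."""
        means = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            draws = rng.integers(0, 2, size=(300, 3))
            pairs = [(f"a{i:04d}", f"b{i:04d}") for i in range(300)]
            df = pd.DataFrame(
                draws, index=pd.MultiIndex.from_tuples(pairs),
                columns=["t0", "t1", "t2"],
            )
            df[GI] = rng.integers(0, 2, 300)  # independent of evidence
            E = EvidenceMatrix(df)
            model = learn_bnp(E, B=20, seed=seed + 50)
            gi_strengths = [
                s for p, s in model.strengths.pairs.items() if GI in p
            ]
            means.append(np.mean(gi_strengths))
        assert np.mean(means) < 0.2

    def test_deterministic_given_seed(self):
        E = synthetic_labeled_evidence(300, 4, 0.9, 0.05, seed=3)
        m1 = learn_bnp(E, B=15, seed=9)
        m2 = learn_bnp(E, B=15, seed=9)
        assert m1.dag == m2.dag
        assert m1.strengths.pairs == m2.strengths.pairs
        for node in m1.dag.nodes:
            assert np.allclose(m1.cpts[node][1], m2.cpts[node][1])

    def test_requires_two_evidence_types(self):
        E = label_gi(
            evidence_from_rows([(("a", "b"), [1]), (("a", "c"), [0])], ["t1"])
        )
        with pytest.raises(ValueError, match="two evidence types"):
            learn_bnp(E, B=5, seed=0)

    def test_retained_arcs_exceed_threshold(self):
        E = synthetic_labeled_evidence(400, 4, 0.9, 0.05, seed=5)
        model = learn_bnp(E, B=20, seed=6)
        for u, v in model.dag.arcs:
            assert model.strengths.strength(u, v) > model.threshold


class TestCrossValidateGi:
    def test_strong_evidence_is_highly_predictive(self):
        E = synthetic_labeled_evidence(600, 5, 0.95, 0.02, seed=7)
        auroc = cross_validate_gi(E, folds=3, B=10, seed=8)
        assert auroc > 0.9

    def test_shuffled_labels_near_chance(self):
        aurocs = []
        for seed in range(3):
            E = synthetic_labeled_evidence(400, 4, 0.9, 0.05, seed=seed)
            rng = np.random.default_rng(seed + 10)
            df = E.data.copy()
            df[GI] = rng.permutation(df[GI].to_numpy())
            aurocs.append(
                cross_validate_gi(EvidenceMatrix(df), folds=3, B=8,
                                  seed=seed)
            )
        assert abs(np.mean(aurocs) - 0.5) < 0.1


def hand_built_bnp(p_gi=0.3, hit=0.9, miss=0.1, eps=1e-3):
    """GI -> t0, GI -> t1 with symmetric monotone CPTs."""
    dag = DAG((GI, "t0", "t1"), [(GI, "t0"), (GI, "t1")])
    cpts = {
        GI: ((), np.array([[1 - p_gi, p_gi]])),
        "t0": ((GI,), np.array([[1 - miss, miss], [1 - hit, hit]])),
        "t1": ((GI,), np.array([[1 - miss, miss], [1 - hit, hit]])),
    }
    strengths = StrengthTable(
        {(GI, "t0"): 1.0, (GI, "t1"): 1.0, ("t0", "t1"): 0.0}, B=10
    )
    return BNPModel(
        dag=dag, cpts=cpts, strengths=strengths, threshold=0.5,
        type_names=("t0", "t1"), clamp_eps=eps,
    )


class TestPairPriorMatrix:
    def test_disconnected_gi_yields_constant_marginal(self, small_expr):
        dag = DAG((GI, "t0", "t1"))
        cpts = {
            GI: ((), np.array([[0.6, 0.4]])),
            "t0": ((), np.array([[0.5, 0.5]])),
            "t1": ((), np.array([[0.5, 0.5]])),
        }
        model = BNPModel(
            dag=dag, cpts=cpts, strengths=StrengthTable({}, B=1),
            threshold=0.5, type_names=("t0", "t1"),
        )
        genes = small_expr.genes[:4]
        pi = pair_prior_matrix(model, None, small_expr, genes)
        assert all(v == pytest.approx(0.4) for v in pi.values())

    def test_strong_evidence_beats_absent_evidence(self, small_expr):
        model = hand_built_bnp()
        genes = sorted(small_expr.genes[:3])
        a, b, c = genes
        E = evidence_from_rows([((a, b), [1, 1])], ["t0", "t1"])
        pi = pair_prior_matrix(model, E, small_expr, genes)
        assert pi[(a, b)] > pi[(a, c)]
        # by-hand enumeration for the all-hit pair
        num = 0.3 * 0.9 * 0.9
        den = num + 0.7 * 0.1 * 0.1
        assert pi[(a, b)] == pytest.approx(num / den)

    def test_posteriors_clamped(self, small_expr):
        model = hand_built_bnp(hit=1.0, miss=0.0, eps=1e-3)
        genes = sorted(small_expr.genes[:2])
        E = evidence_from_rows([(tuple(genes), [1, 1])], ["t0", "t1"])
        pi = pair_prior_matrix(model, E, small_expr, genes)
        assert pi[tuple(genes)] == pytest.approx(1 - 1e-3)

    def test_missing_gene_rejected(self, small_expr):
        model = hand_built_bnp()
        with pytest.raises(KeyError):
            pair_prior_matrix(model, None, small_expr,
                              ["not_a_gene", small_expr.genes[0]])

    def test_mean_prior_separates_true_edges(self, small_atlas, small_expr):
        """Monotone synthetic evidence must give true edges higher priors."""
        gaps = []
        for seed in range(5):
            E = generate_evidence(
                small_atlas,
                EvidenceSpec(n_types=5, sensitivity=0.9, fpr=0.05,
                             seed=seed),
            )
            model = learn_bnp(label_gi(E), B=10, seed=seed + 20)
            genes = sorted(small_atlas.nodes)[:15]
            pi = pair_prior_matrix(model, E, small_expr, genes)
            on_edges = [v for p, v in pi.items() if small_atlas.has_edge(*p)]
            off_edges = [v for p, v in pi.items()
                         if not small_atlas.has_edge(*p)]
            if on_edges and off_edges:
                gaps.append(np.mean(on_edges) - np.mean(off_edges))
        assert gaps and np.mean(gaps) > 0


class TestAddCoexpression:
    def test_column_marks_correlated_pairs(self, small_atlas, small_expr,
                                           small_evidence):
        E = add_coexpression(small_evidence, small_expr, rho0=0.5)
        assert "coexpression" in E.type_names
        assert "coexpression" in E.experimental_types
        col = E.data["coexpression"]
        assert set(col.unique()) <= {0, 1}
        gidx = {g: i for i, g in enumerate(small_expr.genes)}
        a, b = list(E.data.index)[0]
        r = np.corrcoef(small_expr.values[gidx[a]],
                        small_expr.values[gidx[b]])[0, 1]
        assert col.loc[(a, b)] == int(abs(r) >= 0.5)


class TestGraphLogPrior:
    def test_uniform_prior_is_structure_independent(self):
        nodes = ("a", "b", "c")
        pi = {p: 0.5 for p in [("a", "b"), ("a", "c"), ("b", "c")]}
        empty = graph_log_prior(DAG(nodes), pi)
        chain = graph_log_prior(DAG(nodes, [("a", "b"), ("b", "c")]), pi)
        assert empty == pytest.approx(3 * np.log(0.5))
        assert chain == pytest.approx(empty)

    def test_single_pair_toggle_changes_by_log_odds(self):
        nodes = ("a", "b")
        pi = {("a", "b"): 0.9}
        absent = graph_log_prior(DAG(nodes), pi, kappa=2.0)
        present = graph_log_prior(DAG(nodes, [("a", "b")]), pi, kappa=2.0)
        assert present - absent == pytest.approx(2.0 * np.log(0.9 / 0.1))

    def test_edge_decomposability(self, rng):
        nodes = ("a", "b", "c", "d")
        pairs = [(x, y) for i, x in enumerate(nodes) for y in nodes[i + 1:]]
        pi = {p: float(rng.uniform(0.05, 0.95)) for p in pairs}
        g1 = DAG(nodes, [("a", "b")])
        g2 = DAG(nodes, [("a", "b"), ("c", "d"), ("b", "c")])
        diff = graph_log_prior(g2, pi) - graph_log_prior(g1, pi)
        expected = sum(
            np.log(pi[p]) - np.log(1 - pi[p])
            for p in [("b", "c"), ("c", "d")]
        )
        assert diff == pytest.approx(expected)

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            graph_log_prior(DAG(("a", "b")), {("a", "b"): 1.0})


class TestBnpSerialisation:
    def test_round_trip_preserves_model_and_posteriors(self, tmp_path):
        E = synthetic_labeled_evidence(300, 4, 0.9, 0.05, seed=2)
        model = learn_bnp(E, B=10, seed=3)
        from interatlas.bnp_prior import read_bnp, write_bnp

        a, c, m = (tmp_path / "arcs.tsv", tmp_path / "cpts.tsv",
                   tmp_path / "meta.yaml")
        write_bnp(model, a, c, m)
        back = read_bnp(a, c, m)
        assert back.dag == model.dag
        assert back.threshold == pytest.approx(model.threshold)
        ev = {t: 1 for t in model.type_names}
        assert back.posterior_gi(ev) == pytest.approx(
            model.posterior_gi(ev), abs=1e-8
        )
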
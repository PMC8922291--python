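"""Discrete Bayesian-network machinery.

Everything downstream — the knowledge prior over evidence types and the
within-cluster gene networks — is built on the same four primitives: a
decomposable BIC score, steepest-ascent hill climbing over DAGs, bootstrap
model averaging of arc strengths, and exact posterior inference by variable
elimination. Networks handled here are small (tens of nodes), which is what
makes the divide-and-conquer workflow viable in the first place.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DiscreteDataset",
    "DAG",
    "StrengthTable",
    "BICScore",
    "bic_score",
    "hill_climb",
    "bootstrap_strengths",
    "significance_threshold",
    "fit_cpts",
    "infer_posterior",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class DiscreteDataset:
    """Fully observed discrete data: ``values[i, j]`` is the state of
    ``variables[j]`` in observation ``i``; states are ``0 .. arity[j]-1``."""

    variables: tuple[str, ...]
    arity: tuple[int, ...]
    values: np.ndarray  # (N, n) integer array

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2 or vals.shape[1] != len(self.variables):
            raise ValueError("values must be N x n_variables")
        if vals.shape[0] < 1:
            raise ValueError("dataset needs at least one observation")
        if len(self.arity) != len(self.variables):
            raise ValueError("arity must match variables")
        for j, r in enumerate(self.arity):
            if r < 1:
                raise ValueError(f"arity of {self.variables[j]} must be >= 1")
            col = vals[:, j]
            if col.min() < 0 or col.max() >= r:
                raise ValueError(
                    f"values of {self.variables[j]} outside 0..{r - 1}"
                )
        object.__setattr__(self, "values", vals.astype(np.int64, copy=False))

    @property
    def n_obs(self) -> int:
        return int(self.values.shape[0])

    def subset_rows(self, idx: np.ndarray) -> "DiscreteDataset":
        return DiscreteDataset(self.variables, self.arity, self.values[idx])

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variables.index(name)]


class DAG:
    """Directed acyclic graph over named nodes; arcs are ordered pairs."""

    def __init__(self, nodes: Iterable[str], arcs: Iterable[tuple[str, str]] = ()):
        self.nodes: tuple[str, ...] = tuple(nodes)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        self.arcs: frozenset[tuple[str, str]] = frozenset(
            (str(u), str(v)) for u, v in arcs
        )
        for u, v in self.arcs:
            if u not in node_set or v not in node_set:
                raise ValueError(f"arc ({u}, {v}) references undeclared node")
            if u == v:
                raise ValueError(f"self-loop on {u}")
        if self.topological_order() is None:
            raise ValueError("arcs contain a cycle")

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(u for (u, w) in self.arcs if w == v))

    def topological_order(self) -> list[str] | None:
        indeg = {v: 0 for v in self.nodes}
        out: dict[str, list[str]] = {v: [] for v in self.nodes}
        for u, v in self.arcs:
            indeg[v] += 1
            out[u].append(v)
        stack = sorted(v for v in self.nodes if indeg[v] == 0)
        order: list[str] = []
        while stack:
            v = stack.pop()
            order.append(v)
            for w in out[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    stack.append(w)
        return order if len(order) == len(self.nodes) else None

    def skeleton(self) -> frozenset[tuple[str, str]]:
        """Undirected edge set with lexicographically ordered endpoints."""
        return frozenset(tuple(sorted(a)) for a in self.arcs)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DAG)
            and set(self.nodes) == set(other.nodes)
            and self.arcs == other.arcs
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.nodes), self.arcs))

    def __repr__(self) -> str:  # pragma: no cover
        return f"DAG(nodes={len(self.nodes)}, arcs={sorted(self.arcs)})"


@dataclass
class StrengthTable:
    """Bootstrap arc strengths: fraction of replicate networks containing an
    arc between each unordered pair (either direction)."""

    pairs: dict[tuple[str, str], float]
    B: int
    direction_counts: dict[tuple[str, str], tuple[int, int]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for pair, s in self.pairs.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"strength of {pair} outside [0, 1]: {s}")
            if pair != tuple(sorted(pair)):
                raise ValueError(f"pair {pair} not in lexicographic order")

    def strength(self, a: str, b: str) -> float:
        return self.pairs.get(tuple(sorted((a, b))), 0.0)


# ---------------------------------------------------------------------------
# scoring


class BICScore:
    """Decomposable BIC: sum over nodes of the multinomial log-likelihood at
    the MLE minus (log N / 2) * free parameters. Natural logarithms."""

    def __init__(self, data: DiscreteDataset):
        self.data = data
        self.arity = np.asarray(data.arity, dtype=np.int64)
        self._cols = data.values
        self._n = data.n_obs
        self._log_n = math.log(self._n)
        self._cache: dict[tuple[int, frozenset[int]], float] = {}
        self._onehot_flat: np.ndarray | None = None  # (n * r_max, N)

    def _flat_onehot(self) -> np.ndarray:
        if self._onehot_flat is None:
            n = len(self.data.variables)
            r_max = int(self.arity.max())
            oh = np.zeros((n, self._n, r_max), dtype=np.float32)
            for j in range(n):
                oh[j, np.arange(self._n), self._cols[:, j]] = 1.0
            self._onehot_flat = oh.transpose(0, 2, 1).reshape(
                n * r_max, self._n
            )
        return self._onehot_flat

    def add_child_deltas(self, v: int, parents: frozenset[int]) -> np.ndarray:
        """Vector over u of local(v, parents | {u}) - local(v, parents),
        computed for all candidate parents at once (entries for u == v or
        u in parents are meaningless and masked to -inf)."""
        n = len(self.data.variables)
        r_max = int(self.arity.max())
        r = int(self.arity[v])
        cfg = np.zeros(self._n, dtype=np.int64)
        q = 1
        for p in sorted(parents):
            cfg = cfg * self.arity[p] + self._cols[:, p]
            q *= int(self.arity[p])
        joint = cfg * r + self._cols[:, v]
        joint_oh = np.zeros((self._n, q * r), dtype=np.float32)
        joint_oh[np.arange(self._n), joint] = 1.0
        # counts[u, a, j, b] = #rows with u=a and (parent cfg, v) = (j, b)
        counts = (self._flat_onehot() @ joint_oh).astype(np.float64)
        counts = counts.reshape(n, r_max, q, r)
        with np.errstate(divide="ignore", invalid="ignore"):
            xlogx = np.where(counts > 0,
                             counts * np.log(np.where(counts > 0, counts, 1.0)),
                             0.0)
        row_tot = counts.sum(axis=3)
        with np.errstate(divide="ignore", invalid="ignore"):
            xlogx_rows = np.where(
                row_tot > 0,
                row_tot * np.log(np.where(row_tot > 0, row_tot, 1.0)),
                0.0,
            )
        ll = xlogx.sum(axis=(1, 2, 3)) - xlogx_rows.sum(axis=(1, 2))
        penalty = 0.5 * self._log_n * (r - 1) * q * self.arity
        base = self.local(v, parents)
        deltas = (ll - penalty) - base
        deltas[v] = -np.inf
        for p in parents:
            deltas[p] = -np.inf
        return deltas

    # edge-wise prior hooks; zero for plain BIC
    def edge_delta(self, u: int, v: int) -> float:
        return 0.0

    def edge_delta_matrix(self) -> np.ndarray:
        return np.zeros((len(self.data.variables),) * 2)

    def local(self, v: int, parents: frozenset[int]) -> float:
        key = (v, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        r = int(self.arity[v])
        if parents:
            cfg = np.zeros(self._n, dtype=np.int64)
            q = 1
            for p in sorted(parents):
                cfg = cfg * self.arity[p] + self._cols[:, p]
                q *= int(self.arity[p])
        else:
            cfg = np.zeros(self._n, dtype=np.int64)
            q = 1
        joint = cfg * r + self._cols[:, v]
        counts = np.bincount(joint, minlength=q * r).reshape(q, r)
        row_tot = counts.sum(axis=1)
        nz = counts > 0
        ll = float(np.sum(counts[nz] * np.log(counts[nz])))
        rnz = row_tot > 0
        ll -= float(np.sum(row_tot[rnz] * np.log(row_tot[rnz])))
        penalty = 0.5 * self._log_n * (r - 1) * q
        val = ll - penalty
        self._cache[key] = val
        return val

    def pairwise_add_deltas(self) -> np.ndarray:
        """Matrix D with D[u, v] = local(v, {u}) - local(v, {}) +
        edge_delta(u, v): the score gain of every single-arc addition to the
        empty graph, computed for all pairs at once via one-hot contingency
        products."""
        n = len(self.data.variables)
        r_max = int(self.arity.max())
        onehot = np.zeros((n, self._n, r_max))
        for j in range(n):
            onehot[j, np.arange(self._n), self._cols[:, j]] = 1.0
        flat = onehot.reshape(n * r_max, self._n)
        # joint[u, a, v, b] = #rows with u=a and v=b
        joint = (flat @ flat.T).reshape(n, r_max, n, r_max)
        marg = joint[np.arange(n), :, np.arange(n), :].diagonal(
            axis1=1, axis2=2
        )  # (n, r_max) marginal counts

        def _entropy_term(c: np.ndarray, axis) -> np.ndarray:
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(c > 0, c * np.log(np.where(c > 0, c, 1.0)), 0.0)
            return t.sum(axis=axis)

        ll_joint = _entropy_term(joint, axis=(1, 3))  # (n, n)
        ll_marg = _entropy_term(marg, axis=1)  # (n,)
        # local(v | parent u) = sum_ab N_ab log N_ab - sum_a N_a. log N_a.
        #                      - penalty(v, q=r_u)
        # local(v | {})       = sum_b N_b log N_b - N log N - penalty(v, 1)
        n_tot = float(self._n)
        ll_cond = ll_joint - ll_marg[:, None]  # [u, v]
        ll_empty = ll_marg - n_tot * math.log(n_tot)  # [v]
        pen_cond = 0.5 * self._log_n * (self.arity[None, :] - 1) \
            * self.arity[:, None]
        pen_empty = 0.5 * self._log_n * (self.arity - 1)
        d = (ll_cond - pen_cond) - (ll_empty - pen_empty)[None, :]
        d += self.edge_delta_matrix()
        np.fill_diagonal(d, -np.inf)
        return d

    def total(self, parent_sets: Sequence[frozenset[int]]) -> float:
        s = sum(self.local(v, ps) for v, ps in enumerate(parent_sets))
        s += sum(
            self.edge_delta(u, v)
            for v, ps in enumerate(parent_sets)
            for u in ps
        )
        return s


def bic_score(dag: DAG, data: DiscreteDataset) -> float:
    """BIC of ``dag`` on ``data`` (natural log, decomposable per node)."""
    if set(dag.nodes) != set(data.variables):
        raise ValueError("DAG nodes must equal dataset variables")
    idx = {name: j for j, name in enumerate(data.variables)}
    score = BICScore(data)
    total = 0.0
    for v in dag.nodes:
        ps = frozenset(idx[p] for p in dag.parents(v))
        total += score.local(idx[v], ps)
    return total


# ---------------------------------------------------------------------------
# hill climbing


def _reachability(parents: list[set[int]], n: int) -> np.ndarray:
    """reach[u, v] == True iff a directed path u -> ... -> v exists;
    boolean-matrix transitive closure (repeated squaring)."""
    adj = np.zeros((n, n), dtype=bool)
    for v, ps in enumerate(parents):
        for u in ps:
            adj[u, v] = True
    reach = adj.astype(np.float32)
    while True:
        nxt = np.minimum(reach + reach @ reach, 1.0)
        if (nxt == reach).all():
            return reach.astype(bool)
        reach = nxt


_MOVE_RANK = {"delete": 0, "reverse": 1, "add": 2}


def _climb_from(
    score: BICScore,
    parents: list[set[int]],
    names: tuple[str, ...],
    max_iter: int,
    max_parents: int,
) -> tuple[list[set[int]], float]:
    """Steepest-ascent local search from the given starting parent sets.

    Add-move deltas are cached in an (u, v) matrix and refreshed only for
    nodes whose family the last applied move changed; acyclicity is checked
    against a reachability matrix rebuilt once per applied move.
    """
    n = len(names)
    neg_inf = -np.inf
    reach = _reachability(parents, n)
    adj = np.zeros((n, n), dtype=bool)
    children: list[set[int]] = [set() for _ in range(n)]
    for v, ps in enumerate(parents):
        for u in ps:
            adj[u, v] = adj[v, u] = True
            children[u].add(v)

    def local(v: int, ps: set[int]) -> float:
        return score.local(v, frozenset(ps))

    local_cur = np.array([local(v, parents[v]) for v in range(n)])

    edge_mat = score.edge_delta_matrix()

    def refresh_add_into(v: int) -> None:
        delta_add[:, v] = score.add_child_deltas(
            v, frozenset(parents[v])
        ) + edge_mat[:, v]

    if not any(parents):  # empty start: vectorised initialisation
        delta_add = score.pairwise_add_deltas()
    else:
        delta_add = np.full((n, n), neg_inf)
        for v in range(n):
            refresh_add_into(v)

    pcount = np.array([len(ps) for ps in parents])
    eye = np.eye(n, dtype=bool)
    iters = 0
    while True:
        if iters >= max_iter:
            logger.warning("hill climb stopped at max_iter=%d", max_iter)
            break
        iters += 1
        best = None  # (delta, rank, tiebreak_names, kind, u, v)
        # best addition via the cached delta matrix
        valid = ~adj & ~reach.T & ~eye & (pcount < max_parents)[None, :]
        masked = np.where(valid, delta_add, neg_inf)
        top = masked.max()
        if top > 1e-9:
            ua, va = min(
                ((int(i), int(j)) for i, j in zip(*np.nonzero(masked == top))),
                key=lambda uv: (names[uv[0]], names[uv[1]]),
            )
            best = (float(top), _MOVE_RANK["add"],
                    (names[ua], names[va]), "add", ua, va)
        # deletions and reversals of existing arcs
        for v in range(n):
            base_v = local_cur[v]
            for u in sorted(parents[v]):
                d_del = local(v, parents[v] - {u}) - base_v \
                    - score.edge_delta(u, v)
                cand = (d_del, _MOVE_RANK["delete"], (names[u], names[v]),
                        "delete", u, v)
                if d_del > 1e-9 and (best is None or _better(cand, best)):
                    best = cand
                if pcount[u] < max_parents and not any(
                    x != v and reach[x, v] for x in children[u]
                ):
                    d_rev = (
                        local(v, parents[v] - {u}) - base_v
                        + local(u, parents[u] | {v}) - local_cur[u]
                    )
                    cand = (d_rev, _MOVE_RANK["reverse"],
                            (names[u], names[v]), "reverse", u, v)
                    if d_rev > 1e-9 and (best is None or _better(cand, best)):
                        best = cand
        if best is None:
            break
        _, _, _, kind, u, v = best
        if kind == "add":
            parents[v].add(u)
            children[u].add(v)
            adj[u, v] = adj[v, u] = True
            touched = (v,)
        elif kind == "delete":
            parents[v].discard(u)
            children[u].discard(v)
            adj[u, v] = adj[v, u] = False
            touched = (v,)
        else:  # reverse u -> v  becomes  v -> u
            parents[v].discard(u)
            children[u].discard(v)
            parents[u].add(v)
            children[v].add(u)
            touched = (u, v)
        for t in touched:
            pcount[t] = len(parents[t])
            local_cur[t] = local(t, parents[t])
            refresh_add_into(t)
        reach = _reachability(parents, n)
    return parents, score.total([frozenset(ps) for ps in parents])


def _better(cand: tuple, best: tuple) -> bool:
    # higher delta first; then delete > reverse > add; then lexicographic arc
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] < best[1]
    return cand[2] < best[2]


def _random_parent_sets(
    rng: np.random.Generator, n: int, max_parents: int
) -> list[set[int]]:
    order = rng.permutation(n)
    p = min(0.3, 2.0 / max(n - 1, 1))
    parents: list[set[int]] = [set() for _ in range(n)]
    for j in range(1, n):
        for i in range(j):
            if rng.random() < p and len(parents[order[j]]) < max_parents:
                parents[order[j]].add(int(order[i]))
    return parents


def hill_climb(
    data: DiscreteDataset,
    score_fn: BICScore | None = None,
    restarts: int = 2,
    max_iter: int | None = None,
    seed: int = 0,
    max_parents: int = 4,
) -> DAG:
    """Learn a DAG by steepest-ascent search over add/delete/reverse moves.

    The first climb starts from the empty graph, so the result never scores
    below it; ``restarts`` additional climbs start from random sparse DAGs
    and the best-scoring local optimum is returned. Deterministic given
    ``seed``.
    """
    if score_fn is None:
        score_fn = BICScore(data)
    n = len(data.variables)
    if max_iter is None:
        max_iter = 10 * n * n
    rng = np.random.default_rng(seed)
    best_parents, best_score = _climb_from(
        score_fn, [set() for _ in range(n)], data.variables, max_iter, max_parents
    )
    for _ in range(restarts):
        start = _random_parent_sets(rng, n, max_parents)
        parents, s = _climb_from(
            score_fn, start, data.variables, max_iter, max_parents
        )
        if s > best_score + 1e-12:
            best_parents, best_score = parents, s
    arcs = [
        (data.variables[u], data.variables[v])
        for v, ps in enumerate(best_parents)
        for u in ps
    ]
    return DAG(data.variables, arcs)


# ---------------------------------------------------------------------------
# bootstrap model averaging


def bootstrap_strengths(
    data: DiscreteDataset,
    score_factory: Callable[[DiscreteDataset], BICScore] | None = None,
    B: int = 1000,
    seed: int = 0,
    restarts: int = 0,
    max_parents: int = 4,
) -> StrengthTable:
    """Arc strengths by model averaging over ``B`` bootstrap resamples.

    Each replicate consumes one child seed spawned from the master seed, so
    increasing ``B`` extends the replicate stream without reshuffling earlier
    replicates. Rows are canonicalised (lexicographically sorted) before
    resampling, making the result independent of input row order.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if score_factory is None:
        score_factory = BICScore
    order = np.lexsort(data.values.T[::-1])
    canon = data.subset_rows(order)
    children = np.random.SeedSequence(seed).spawn(B)
    pair_counts: dict[tuple[str, str], int] = {}
    dir_counts: dict[tuple[str, str], list[int]] = {}
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, canon.n_obs, canon.n_obs)
        boot = canon.subset_rows(idx)
        dag = hill_climb(
            boot,
            score_factory(boot),
            restarts=restarts,
            seed=int(rng.integers(0, 2**31 - 1)),
            max_parents=max_parents,
        )
        for u, v in dag.arcs:
            pair = tuple(sorted((u, v)))
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
            d = dir_counts.setdefault(pair, [0, 0])
            d[0 if (u, v) == pair else 1] += 1
    strengths = {p: c / B for p, c in pair_counts.items()}
    return StrengthTable(
        pairs=strengths,
        B=B,
        direction_counts={p: (c[0], c[1]) for p, c in dir_counts.items()},
    )


# ---------------------------------------------------------------------------
# significance threshold on strengths


def significance_threshold(strengths: Sequence[float]) -> float:
    """Data-driven cutoff on bootstrap strengths.

    Picks the threshold t minimising the L1 distance between the empirical
    CDF of the strengths and the ideal one-step CDF (0 below t, 1 at and
    above t), with candidate t restricted to observed strength values; ties
    between minimising candidates are resolved by their mean. Edges are
    significant iff strength > t.
    """
    vals = np.asarray(sorted(strengths), dtype=float)
    if vals.size == 0:
        raise ValueError("empty strength list")
    uniq = np.unique(vals)
    if uniq.size == 1:
        warnings.warn(
            "all strengths identical; thresholding just below the value",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(uniq[0]) - 1e-12
    ecdf = np.searchsorted(vals, uniq, side="right") / vals.size
    widths = np.append(np.diff(uniq), 0.0)
    costs = np.array(
        [np.sum(np.abs(ecdf - (uniq >= t)) * widths) for t in uniq]
    )
    winners = uniq[np.isclose(costs, costs.min())]
    return float(winners.mean())


# ---------------------------------------------------------------------------
# parameters and inference


def fit_cpts(
    dag: DAG, data: DiscreteDataset, pseudo: float = 1.0
) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Per-node CPTs with additive pseudo-counts.

    Returns ``{node: (parents, table)}`` where ``table`` has shape
    ``(prod parent arities, arity)``; the row index is the mixed-radix code
    of the parent states in the stored parent order (first parent most
    significant). Rows normalise to one; with ``pseudo == 0`` an unseen
    parent configuration yields a zero row left as-is by convention of the
    caller (inference treats it as contradictory evidence).
    """
    if set(dag.nodes) != set(data.variables):
        raise ValueError("DAG nodes must equal dataset variables")
    if pseudo < 0:
        raise ValueError("pseudo must be nonnegative")
    idx = {name: j for j, name in enumerate(data.variables)}
    arity = data.arity
    cpts: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        r = arity[idx[node]]
        q = 1
        cfg = np.zeros(data.n_obs, dtype=np.int64)
        for p in parents:
            cfg = cfg * arity[idx[p]] + data.values[:, idx[p]]
            q *= arity[idx[p]]
        joint = cfg * r + data.values[:, idx[node]]
        counts = np.bincount(joint, minlength=q * r).reshape(q, r).astype(float)
        counts += pseudo
        tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            table = np.where(tot > 0, counts / np.where(tot > 0, tot, 1.0), 0.0)
        cpts[node] = (parents, table)
    return cpts


def infer_posterior(
    dag: DAG,
    cpts: Mapping[str, tuple[tuple[str, ...], np.ndarray]],
    evidence: Mapping[str, int],
    query: str,
    arity: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Exact posterior over ``query`` given ``evidence`` by variable
    elimination; returns a probability vector summing to one."""
    if query in evidence:
        raise ValueError("query variable cannot also be evidence")
    for e in evidence:
        if e not in dag.nodes:
            raise ValueError(f"evidence variable {e} not in network")
    if arity is None:
        arity = {
            node: cpts[node][1].shape[1] for node in dag.nodes
        }

    # build factors, reducing by evidence as we go
    factors: list[tuple[tuple[str, ...], np.ndarray]] = []
    for node in dag.nodes:
        parents, table = cpts[node]
        shape = tuple(arity[p] for p in parents) + (arity[node],)
        arr = table.reshape(shape)
        fvars = parents + (node,)
        keep_vars = []
        index: list = []
        for var in fvars:
            if var in evidence:
                index.append(int(evidence[var]))
            else:
                index.append(slice(None))
                keep_vars.append(var)
        factors.append((tuple(keep_vars), arr[tuple(index)]))

    hidden = [v for v in dag.nodes if v != query and v not in evidence]
    # eliminate smallest-degree first (nets are tiny; heuristic keeps factors small)
    while hidden:
        hidden.sort(key=lambda v: sum(1 for fv, _ in factors if v in fv))
        var = hidden.pop(0)
        involved = [f for f in factors if var in f[0]]
        rest = [f for f in factors if var not in f[0]]
        prod = _factor_product(involved)
        fvars, arr = prod
        ax = fvars.index(var)
        summed = arr.sum(axis=ax)
        rest.append((tuple(v for v in fvars if v != var), summed))
        factors = rest

    fvars, arr = _factor_product(factors)
    if fvars != (query,):
        # stray scalar factors multiply in; reorder axes if needed
        if query in fvars:
            ax = fvars.index(query)
            arr = np.moveaxis(arr, ax, 0).reshape(arity[query], -1).sum(axis=1)
        else:
            raise ValueError("query eliminated unexpectedly")
    z = arr.sum()
    if z <= 0:
        raise ValueError(
            f"evidence {dict(evidence)} has zero probability under the model"
        )
    return np.asarray(arr, dtype=float) / z


def _factor_product(
    factors: Sequence[tuple[tuple[str, ...], np.ndarray]]
) -> tuple[tuple[str, ...], np.ndarray]:
    all_vars: list[str] = []
    for fvars, _ in factors:
        for v in fvars:
            if v not in all_vars:
                all_vars.append(v)
    out = np.ones([1] * len(all_vars)) if all_vars else np.ones(())
    for fvars, arr in factors:
        shape = [1] * len(all_vars)
        src_axes = [all_vars.index(v) for v in fvars]
        expanded = arr
        # move factor axes into global order
        order = np.argsort(src_axes)
        expanded = np.transpose(arr, order) if fvars else arr
        for pos, ax in enumerate(sorted(src_axes)):
            shape[ax] = expanded.shape[pos]
        expanded = expanded.reshape(shape)
        out = out * expanded
    return tuple(all_vars), out
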
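"""Bayesian Network Prior (BNP) over interaction evidence.

The BNP is a small discrete Bayesian network whose nodes are binary evidence
types (affinity capture, two-hybrid, co-citation, ...) plus one "GI" node
meaning "these two genes interact". Learned from an evidence matrix by
bootstrap model averaging, it serves two purposes: given a pair's evidence
vector it yields P(GI=1 | evidence), and those per-pair probabilities define
a log prior P(G) over candidate gene-network structures used during MAP
search.

One evidence type may be *experimental*: computed from the supplied
expression data rather than looked up in a knowledge base. The default such
type is "coexpression", the indicator |Pearson r| >= rho0 between the two
genes' profiles. This is how expression profiles are injected into GI
inference; the dichotomisation threshold is configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .bn_core import (
    DAG,
    DiscreteDataset,
    StrengthTable,
    bootstrap_strengths,
    fit_cpts,
    infer_posterior,
    significance_threshold,
)

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import ExpressionMatrix

__all__ = [
    "EvidenceMatrix",
    "BNPModel",
    "label_gi",
    "add_coexpression",
    "learn_bnp",
    "cross_validate_gi",
    "pair_prior_matrix",
    "graph_log_prior",
    "write_evidence",
    "read_evidence",
    "write_bnp",
    "read_bnp",
]

GI = "GI"


@dataclass
class EvidenceMatrix:
    """Binary evidence table: unordered gene pairs x evidence types.

    ``data`` is indexed by a (gene_a, gene_b) MultiIndex with lexicographic
    endpoints; all columns are 0/1. ``experimental_types`` marks columns
    computed from expression data at run time rather than from knowledge
    bases; the GI labelling rule counts knowledge columns only.
    """

    data: pd.DataFrame
    experimental_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.nlevels != 2:
            raise ValueError("index must be (gene_a, gene_b) pairs")
        if idx.has_duplicates:
            raise ValueError("duplicate gene pairs")
        for a, b in idx:
            if not a < b:
                raise ValueError(f"pair ({a}, {b}) not in lexicographic order")
        arr = self.data.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("evidence values must be 0/1")
        self.data = self.data.astype(np.int8)

    @property
    def type_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c != GI)

    @property
    def knowledge_types(self) -> tuple[str, ...]:
        return tuple(
            c for c in self.type_names if c not in self.experimental_types
        )

    @property
    def has_gi(self) -> bool:
        return GI in self.data.columns

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.data.index)

    def row(self, a: str, b: str) -> pd.Series | None:
        key = (a, b) if a < b else (b, a)
        try:
            return self.data.loc[key]
        except KeyError:
            return None


@dataclass
class BNPModel:
    """Learned BNP: consensus DAG over evidence types + GI, with CPTs."""

    dag: DAG
    cpts: dict[str, tuple[tuple[str, ...], np.ndarray]]
    strengths: StrengthTable
    threshold: float
    type_names: tuple[str, ...]
    experimental_types: frozenset[str] = frozenset()
    clamp_eps: float = 1e-3
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if GI not in self.dag.nodes:
            raise ValueError("BNP network must contain the GI node")
        for u, v in self.dag.arcs:
            if self.strengths.strength(u, v) <= self.threshold:
                raise ValueError(
                    f"arc ({u}, {v}) retained below threshold"
                )

    def posterior_gi(self, evidence: Mapping[str, int]) -> float:
        """P(GI = 1 | evidence), clamped to [eps, 1 - eps]; memoised."""
        key = tuple(sorted(evidence.items()))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        dist = infer_posterior(self.dag, self.cpts, evidence, GI)
        p = float(np.clip(dist[1], self.clamp_eps, 1.0 - self.clamp_eps))
        self._cache[key] = p
        return p


# ---------------------------------------------------------------------------
# labelling and feature construction


def label_gi(E: EvidenceMatrix) -> EvidenceMatrix:
    """Attach the GI label: 1 iff the pair carries two or more knowledge
    evidence types, else 0. Idempotent — an existing GI column is
    recomputed, never double counted."""
    knowledge = list(E.knowledge_types)
    if len(knowledge) < 1:
        raise ValueError("evidence matrix has no knowledge columns")
    df = E.data.drop(columns=[GI], errors="ignore").copy()
    df[GI] = (df[knowledge].sum(axis=1) >= 2).astype(np.int8)
    return EvidenceMatrix(df, experimental_types=E.experimental_types)


def _abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def add_coexpression(
    E: EvidenceMatrix,
    expr: "ExpressionMatrix",
    rho0: float = 0.5,
    name: str = "coexpression",
) -> EvidenceMatrix:
    """Append the experimental coexpression evidence type: 1 iff the
    absolute Pearson correlation of the two genes' expression profiles is at
    least ``rho0``."""
    gidx = {g: i for i, g in enumerate(expr.genes)}
    vals = expr.values
    col = []
    for a, b in E.data.index:
        if a not in gidx or b not in gidx:
            col.append(0)
            continue
        col.append(int(_abs_corr(vals[gidx[a]], vals[gidx[b]]) >= rho0))
    df = E.data.copy()
    df[name] = np.asarray(col, dtype=np.int8)
    if GI in df.columns:  # keep GI as the last column
        df = df[[c for c in df.columns if c != GI] + [GI]]
    return EvidenceMatrix(
        df, experimental_types=E.experimental_types | {name}
    )


# ---------------------------------------------------------------------------
# learning


def _to_dataset(E: EvidenceMatrix) -> DiscreteDataset:
    cols = list(E.type_names) + [GI]
    return DiscreteDataset(
        variables=tuple(cols),
        arity=(2,) * len(cols),
        values=E.data[cols].to_numpy(dtype=np.int64),
    )


def _consensus_dag(
    variables: Sequence[str], table: StrengthTable, threshold: float
) -> DAG:
    """Keep arcs above threshold; direction by bootstrap majority (ties
    lexicographic); arcs added in decreasing strength, skipping any
    orientation that would close a cycle."""
    ranked = sorted(
        (p for p, s in table.pairs.items() if s > threshold),
        key=lambda p: (-table.pairs[p], p),
    )
    arcs: list[tuple[str, str]] = []
    for a, b in ranked:
        n_ab, n_ba = table.direction_counts.get((a, b), (0, 0))
        first = (a, b) if n_ab >= n_ba else (b, a)
        second = (b, a) if first == (a, b) else (a, b)
        for u, v in (first, second):
            try:
                DAG(variables, arcs + [(u, v)])
            except ValueError:
                continue
            arcs.append((u, v))
            break
    return DAG(variables, arcs)


def learn_bnp(
    E_labeled: EvidenceMatrix,
    B: int = 1000,
    seed: int = 0,
    clamp_eps: float = 1e-3,
) -> BNPModel:
    """Learn the BNP from a GI-labelled evidence matrix.

    Bootstrap model averaging (``B`` replicates of hill climbing under BIC)
    yields arc strengths; the consensus keeps arcs with strength above the
    data-driven significance threshold, oriented by bootstrap majority; CPTs
    are fit on the full dataset with one pseudo-count per cell.
    """
    if not E_labeled.has_gi:
        raise ValueError("evidence matrix must carry a GI column; run label_gi")
    if len(E_labeled.type_names) < 2:
        raise ValueError("need at least two evidence types")
    data = _to_dataset(E_labeled)
    table = bootstrap_strengths(data, B=B, seed=seed)
    # threshold over all candidate pairs; pairs never seen count as zero
    all_pairs = [
        (a, b)
        for i, a in enumerate(data.variables)
        for b in data.variables[i + 1:]
    ]
    full = {tuple(sorted(p)): table.pairs.get(tuple(sorted(p)), 0.0)
            for p in all_pairs}
    threshold = significance_threshold(list(full.values()))
    dag = _consensus_dag(data.variables, table, threshold)
    cpts = fit_cpts(dag, data, pseudo=1.0)
    return BNPModel(
        dag=dag,
        cpts=cpts,
        strengths=StrengthTable(full, table.B, table.direction_counts),
        threshold=threshold,
        type_names=E_labeled.type_names,
        experimental_types=E_labeled.experimental_types,
        clamp_eps=clamp_eps,
    )


def cross_validate_gi(
    E_labeled: EvidenceMatrix,
    folds: int = 5,
    B: int = 100,
    seed: int = 0,
) -> float:
    """AUROC of held-out GI prediction under k-fold cross-validation.

    Rows are shuffled and split into ``folds``; for each fold the BNP is
    learned on the remainder and P(GI=1 | evidence) inferred for the
    held-out rows; scores are pooled and ranked against the held-out labels.
    """
    from sklearn.metrics import roc_auc_score

    if folds < 2:
        raise ValueError("need at least 2 folds")
    if not E_labeled.has_gi:
        raise ValueError("evidence matrix must carry a GI column")
    n = len(E_labeled.data)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    splits = np.array_split(perm, folds)
    scores: list[float] = []
    labels: list[int] = []
    for f, test_idx in enumerate(splits):
        y_test = E_labeled.data[GI].to_numpy()[test_idx]
        if len(np.unique(y_test)) < 2:
            warnings.warn(
                f"fold {f} has a single GI class; skipped", RuntimeWarning,
                stacklevel=2,
            )
            continue
        train_idx = np.setdiff1d(perm, test_idx)
        E_train = EvidenceMatrix(
            E_labeled.data.iloc[np.sort(train_idx)],
            experimental_types=E_labeled.experimental_types,
        )
        bnp = learn_bnp(E_train, B=B, seed=seed + f + 1)
        held = E_labeled.data.iloc[test_idx]
        for (_, row), y in zip(held.iterrows(), y_test):
            ev = {t: int(row[t]) for t in E_labeled.type_names}
            scores.append(bnp.posterior_gi(ev))
            labels.append(int(y))
    if not labels:
        raise ValueError("every fold was single-class; cannot compute AUROC")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# per-pair priors and the graph log prior


def pair_prior_matrix(
    bnp: BNPModel,
    E: EvidenceMatrix | None,
    expr: "ExpressionMatrix",
    genes: Sequence[str],
    rho0: float = 0.5,
) -> dict[tuple[str, str], float]:
    """P(GI=1) for every unordered pair of ``genes``.

    Knowledge evidence is looked up in ``E`` (pairs absent from the matrix
    carry all-zero knowledge evidence); experimental types are computed from
    the expression profiles. Posteriors are clamped to
    [eps, 1 - eps] by the model.
    """
    gidx = {g: i for i, g in enumerate(expr.genes)}
    for g in genes:
        if g not in gidx:
            raise KeyError(f"gene {g} missing from expression matrix")
    vals = expr.values
    out: dict[tuple[str, str], float] = {}
    knowledge = [t for t in bnp.type_names if t not in bnp.experimental_types]
    experimental = [t for t in bnp.type_names if t in bnp.experimental_types]
    genes_sorted = sorted(set(genes))
    for i, a in enumerate(genes_sorted):
        for b in genes_sorted[i + 1:]:
            ev: dict[str, int] = {}
            row = E.row(a, b) if E is not None else None
            for t in knowledge:
                ev[t] = int(row[t]) if row is not None and t in row else 0
            for t in experimental:
                ev[t] = int(
                    _abs_corr(vals[gidx[a]], vals[gidx[b]]) >= rho0
                )
            out[(a, b)] = bnp.posterior_gi(ev)
    return out


def graph_log_prior(
    dag: DAG, pi: Mapping[tuple[str, str], float], kappa: float = 1.0
) -> float:
    """Log prior of a candidate structure under per-pair interaction
    probabilities: kappa * sum over unordered node pairs of log pi if the
    pair is joined by an arc (either direction) else log(1 - pi)."""
    skeleton = dag.skeleton()
    nodes = sorted(dag.nodes)
    total = 0.0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            p = pi[(a, b)]
            if not (0.0 < p < 1.0):
                raise ValueError(
                    f"pi({a}, {b}) = {p} outside (0, 1); clamp upstream"
                )
            total += math.log(p) if (a, b) in skeleton else math.log(1.0 - p)
    return kappa * total


# ---------------------------------------------------------------------------
# serialisation


def write_evidence(E: EvidenceMatrix, path: str | Path) -> None:
    df = E.data.reset_index()
    df.columns = ["gene_a", "gene_b"] + list(E.data.columns)
    df.to_csv(path, sep="\t", index=False)


def read_evidence(
    path: str | Path, experimental_types: Sequence[str] = ()
) -> EvidenceMatrix:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(["gene_a", "gene_b"])
    df.index.names = [None, None]
    return EvidenceMatrix(df, experimental_types=frozenset(experimental_types))


def write_bnp(model: BNPModel, arcs_path: str | Path,
              cpts_path: str | Path, meta_path: str | Path) -> None:
    """Serialise a BNP model: arc list TSV, CPT table TSV (one row per
    parent configuration and child state), and a YAML header with the
    threshold, strengths, and column roles."""
    import yaml

    with open(arcs_path, "w") as fh:
        fh.write("from\tto\n")
        for u, v in sorted(model.dag.arcs):
            fh.write(f"{u}\t{v}\n")
    with open(cpts_path, "w") as fh:
        fh.write("node\tparents\tparent_config\tstate\tprobability\n")
        for node in sorted(model.dag.nodes):
            parents, table = model.cpts[node]
            pstr = ",".join(parents)
            for row in range(table.shape[0]):
                for state in range(table.shape[1]):
                    fh.write(
                        f"{node}\t{pstr}\t{row}\t{state}\t"
                        f"{table[row, state]:.10g}\n"
                    )
    meta = {
        "threshold": float(model.threshold),
        "type_names": list(model.type_names),
        "experimental_types": sorted(model.experimental_types),
        "clamp_eps": float(model.clamp_eps),
        "bootstrap_count": int(model.strengths.B),
        "strengths": {
            f"{a}--{b}": float(s)
            for (a, b), s in sorted(model.strengths.pairs.items())
        },
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_bnp(arcs_path: str | Path, cpts_path: str | Path,
             meta_path: str | Path) -> BNPModel:
    import yaml

    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    arcs_df = pd.read_csv(arcs_path, sep="\t")
    cpt_df = pd.read_csv(cpts_path, sep="\t", keep_default_na=False)
    nodes = tuple(list(meta["type_names"]) + [GI])
    dag = DAG(nodes, list(arcs_df.itertuples(index=False, name=None)))
    cpts: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for node, grp in cpt_df.groupby("node"):
        pstr = grp["parents"].iloc[0]
        parents = tuple(p for p in str(pstr).split(",") if p)
        q = int(grp["parent_config"].max()) + 1
        r = int(grp["state"].max()) + 1
        table = np.zeros((q, r))
        for _, row in grp.iterrows():
            table[int(row["parent_config"]), int(row["state"])] = \
                row["probability"]
        cpts[str(node)] = (parents, table)
    strengths = {
        tuple(key.split("--")): float(s)
        for key, s in meta["strengths"].items()
    }
    return BNPModel(
        dag=dag,
        cpts=cpts,
        strengths=StrengthTable(strengths, B=int(meta["bootstrap_count"])),
        threshold=float(meta["threshold"]),
        type_names=tuple(meta["type_names"]),
        experimental_types=frozenset(meta["experimental_types"]),
        clamp_eps=float(meta["clamp_eps"]),
    )
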
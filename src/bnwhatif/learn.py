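"""Score-based structure learning and Markov-blanket feature selection.

Learns an unrestricted ("general") Bayesian network from a categorical
dataset by greedy hill climbing over edge additions, deletions and
reversals, scored with BDeu (default) or BIC.  Both scores decompose over
families, so each move rescoring touches at most two (child, parents)
families; family scores are cached for the lifetime of a search.

The Markov blanket of the class node — its parents, children and its
children's other parents — d-separates the class from everything else, so
restricting the classifier to the blanket discards irrelevant survey
attributes without changing the class posterior under the true model.  The
MB-restricted classifier relearns a network over {class} ∪ blanket.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .bn import (
    CategoricalVariable,
    ConditionalProbabilityTable,
    DAGStructure,
    DiscreteBayesianNetwork,
)
from .errors import (
    DegenerateInputError,
    UncleanDataError,
    UnknownNodeError,
    UnknownStateError,
)

logger = logging.getLogger(__name__)

_SCORE_EPS = 1e-6  # minimum improvement for an accepted hill-climbing move


@dataclass(frozen=True)
class LearnerConfig:
    """Search and scoring settings.

    BDeu with equivalent sample size 1.0 is the default score; ``max_parents``
    keeps CPTs estimable at survey scale.  ``restarts`` counts additional
    random-DAG restarts beyond the greedy run from the empty graph.
    """

    score: str = "bdeu"
    equivalent_sample_size: float = 1.0
    max_parents: int = 3
    restarts: int = 4
    seed: int = 0
    smoothing_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.score not in ("bdeu", "bic"):
            raise ValueError(f"unknown score {self.score!r}")
        if self.equivalent_sample_size <= 0:
            raise ValueError("equivalent_sample_size must be > 0")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.restarts < 0:
            raise ValueError("restarts must be >= 0")
        if self.smoothing_alpha < 0:
            raise ValueError("smoothing_alpha must be >= 0")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "LearnerConfig":
        allowed = {
            "score",
            "equivalent_sample_size",
            "max_parents",
            "restarts",
            "seed",
            "smoothing_alpha",
        }
        unknown = set(payload) - allowed
        if unknown:
            raise ValueError(f"unknown learner settings: {sorted(unknown)}")
        return cls(**dict(payload))


@dataclass(frozen=True)
class MarkovBlanketSelection:
    """The blanket of a target node and the variables it discards."""

    target: str
    blanket: frozenset[str]
    discarded: frozenset[str]


# ---------------------------------------------------------------------------
# data encoding
# ---------------------------------------------------------------------------

def variables_from_data(data: pd.DataFrame) -> tuple[CategoricalVariable, ...]:
    """Derive variables from a DataFrame; states are the sorted unique values."""
    out = []
    for col in data.columns:
        series = data[col]
        if series.isna().any():
            raise UncleanDataError(f"column {col!r} contains missing values")
        states = tuple(sorted(str(v) for v in series.unique()))
        out.append(CategoricalVariable(str(col), states))
    return tuple(out)


def _encode(
    data: pd.DataFrame, variables: Sequence[CategoricalVariable]
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-code the columns named by ``variables``; (codes, cards)."""
    n = len(data)
    m = len(variables)
    codes = np.empty((n, m), dtype=np.int64)
    cards = np.empty(m, dtype=np.int64)
    for j, var in enumerate(variables):
        if var.name not in data.columns:
            raise UncleanDataError(f"data lacks column {var.name!r}")
        series = data[var.name]
        if series.isna().any():
            raise UncleanDataError(f"column {var.name!r} contains missing values")
        cat = pd.Categorical(series.astype(str), categories=var.states)
        col = np.asarray(cat.codes, dtype=np.int64)
        if (col < 0).any():
            bad = sorted(set(series.astype(str)) - set(var.states))
            raise UnknownStateError(
                f"column {var.name!r} contains states outside the variable's "
                f"roster: {bad[:5]}"
            )
        codes[:, j] = col
        cards[j] = var.n_states
    return codes, cards


def _family_counts(
    codes: np.ndarray, cards: np.ndarray, child: int, parents: tuple[int, ...]
) -> np.ndarray:
    """(q, r) count matrix; parent configs in odometer order, last fastest."""
    r = int(cards[child])
    if parents:
        idx = codes[:, parents[0]].copy()
        for p in parents[1:]:
            idx = idx * int(cards[p]) + codes[:, p]
        q = int(np.prod(cards[list(parents)], dtype=np.int64))
    else:
        idx = np.zeros(len(codes), dtype=np.int64)
        q = 1
    flat = idx * r + codes[:, child]
    return np.bincount(flat, minlength=q * r).reshape(q, r).astype(float)


# ---------------------------------------------------------------------------
# CPT estimation
# ---------------------------------------------------------------------------

def estimate_cpts(
    structure: DAGStructure,
    data: pd.DataFrame,
    smoothing_alpha: float = 1.0,
    variables: Sequence[CategoricalVariable] | None = None,
) -> DiscreteBayesianNetwork:
    """Maximum-likelihood CPTs with additive (Laplace) smoothing.

    Each row is ``(count + alpha) / (row_total + alpha * r)``; with
    ``alpha = 0`` unseen parent combinations fall back to a uniform row.
    """
    if variables is None:
        variables = variables_from_data(data[list(structure.nodes)])
    variables = tuple(variables)
    by_name = {v.name: v for v in variables}
    missing = set(structure.nodes) - set(by_name)
    if missing:
        raise UncleanDataError(f"no variables declared for nodes {sorted(missing)}")
    order = [v for v in variables if v.name in set(structure.nodes)]
    codes, cards = _encode(data, order)
    pos = {v.name: j for j, v in enumerate(order)}
    cpts = {}
    for name in structure.nodes:
        parents = structure.parents(name)
        counts = _family_counts(
            codes, cards, pos[name], tuple(pos[p] for p in parents)
        )
        r = by_name[name].n_states
        row_tot = counts.sum(axis=1, keepdims=True)
        if smoothing_alpha > 0:
            probs = (counts + smoothing_alpha) / (row_tot + smoothing_alpha * r)
        else:
            probs = np.full_like(counts, 1.0 / r)
            seen = row_tot[:, 0] > 0
            probs[seen] = counts[seen] / row_tot[seen]
        shape = tuple(by_name[p].n_states for p in parents) + (r,)
        cpts[name] = ConditionalProbabilityTable(name, parents, probs.reshape(shape))
    roster = tuple(v for v in variables if v.name in set(structure.nodes))
    return DiscreteBayesianNetwork(roster, structure, cpts)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _family_score(
    codes: np.ndarray,
    cards: np.ndarray,
    child: int,
    parents: tuple[int, ...],
    config: LearnerConfig,
) -> float:
    counts = _family_counts(codes, cards, child, parents)
    q, r = counts.shape
    if config.score == "bdeu":
        ess = config.equivalent_sample_size
        a_row = ess / q
        a_cell = ess / (q * r)
        row_tot = counts.sum(axis=1)
        return float(
            np.sum(gammaln(a_row) - gammaln(a_row + row_tot))
            + np.sum(gammaln(a_cell + counts) - gammaln(a_cell))
        )
    # BIC
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * (np.log(counts) - np.log(row_tot))
    ll = float(np.nansum(np.where(counts > 0, terms, 0.0)))
    n = len(codes)
    return ll - 0.5 * np.log(n) * q * (r - 1)


def network_score(
    structure: DAGStructure,
    data: pd.DataFrame,
    config: LearnerConfig,
    variables: Sequence[CategoricalVariable] | None = None,
) -> float:
    """Decomposable network score: sum of per-family BDeu or BIC terms."""
    if variables is None:
        variables = variables_from_data(data[list(structure.nodes)])
    order = [v for v in variables if v.name in set(structure.nodes)]
    codes, cards = _encode(data, order)
    pos = {v.name: j for j, v in enumerate(order)}
    return sum(
        _family_score(
            codes,
            cards,
            pos[name],
            tuple(pos[p] for p in structure.parents(name)),
            config,
        )
        for name in structure.nodes
    )


# ---------------------------------------------------------------------------
# hill climbing
# ---------------------------------------------------------------------------

def _has_path(parents: dict[str, set[str]], src: str, dst: str) -> bool:
    """Directed path src -> ... -> dst under the child->parents map."""
    # walk child->parent links backwards from dst
    stack = [dst]
    seen = {dst}
    while stack:
        node = stack.pop()
        if node == src:
            return True
        for p in parents[node]:
            if p not in seen:
                seen.add(p)
                stack.append(p)
    return False


def _climb(
    nodes: list[str],
    start_parents: dict[str, set[str]],
    fam,
    max_parents: int,
) -> tuple[dict[str, set[str]], float]:
    parents = {n: set(ps) for n, ps in start_parents.items()}
    scores = {n: fam(n, tuple(sorted(parents[n]))) for n in nodes}
    while True:
        accepted = False
        for op in ("add", "delete", "reverse"):
            for p in nodes:
                for c in nodes:
                    if p == c:
                        continue
                    if op == "add":
                        if p in parents[c] or len(parents[c]) >= max_parents:
                            continue
                        if _has_path(parents, c, p):
                            continue  # would close a cycle
                        new_c = tuple(sorted(parents[c] | {p}))
                        delta = fam(c, new_c) - scores[c]
                        if delta > _SCORE_EPS:
                            parents[c].add(p)
                            scores[c] += delta
                            accepted = True
                    elif op == "delete":
                        if p not in parents[c]:
                            continue
                        new_c = tuple(sorted(parents[c] - {p}))
                        delta = fam(c, new_c) - scores[c]
                        if delta > _SCORE_EPS:
                            parents[c].discard(p)
                            scores[c] += delta
                            accepted = True
                    else:  # reverse p->c into c->p
                        if p not in parents[c] or len(parents[p]) >= max_parents:
                            continue
                        parents[c].discard(p)
                        cycle = _has_path(parents, p, c)
                        parents[c].add(p)
                        if cycle:
                            continue
                        new_c = tuple(sorted(parents[c] - {p}))
                        new_p = tuple(sorted(parents[p] | {c}))
                        delta = (
                            fam(c, new_c)
                            + fam(p, new_p)
                            - scores[c]
                            - scores[p]
                        )
                        if delta > _SCORE_EPS:
                            parents[c].discard(p)
                            parents[p].add(c)
                            scores[c] = fam(c, new_c)
                            scores[p] = fam(p, new_p)
                            accepted = True
                    if accepted:
                        break
                if accepted:
                    break
            if accepted:
                break
        if not accepted:
            return parents, sum(scores.values())


def _random_dag(
    nodes: list[str], rng: np.random.Generator, max_parents: int
) -> dict[str, set[str]]:
    order = [nodes[i] for i in rng.permutation(len(nodes))]
    parents: dict[str, set[str]] = {n: set() for n in nodes}
    for j in range(1, len(order)):
        for i in range(j):
            if len(parents[order[j]]) < max_parents and rng.random() < 0.25:
                parents[order[j]].add(order[i])
    return parents


def learn_structure(
    data: pd.DataFrame,
    config: LearnerConfig | None = None,
    variables: Sequence[CategoricalVariable] | None = None,
) -> DiscreteBayesianNetwork:
    """Greedy hill climbing with restarts; deterministic for a fixed seed.

    Moves (add/delete/reverse) are scanned in lexicographic order and the
    first strictly improving move is taken; every move is checked for
    acyclicity and the ``max_parents`` bound before scoring.
    """
    config = config or LearnerConfig()
    if data.shape[1] < 2:
        raise DegenerateInputError("need at least 2 columns to learn a structure")
    if variables is None:
        variables = variables_from_data(data)
    variables = tuple(variables)
    nodes = sorted(v.name for v in variables)
    order = sorted(variables, key=lambda v: v.name)
    codes, cards = _encode(data, order)
    pos = {v.name: j for j, v in enumerate(order)}
    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def fam(child: str, parents: tuple[str, ...]) -> float:
        key = (child, parents)
        if key not in cache:
            cache[key] = _family_score(
                codes, cards, pos[child], tuple(pos[p] for p in parents), config
            )
        return cache[key]

    rng = np.random.default_rng(config.seed)
    best_parents: dict[str, set[str]] | None = None
    best_score = -np.inf
    for restart in range(config.restarts + 1):
        start = (
            {n: set() for n in nodes}
            if restart == 0
            else _random_dag(nodes, rng, config.max_parents)
        )
        parents, score = _climb(nodes, start, fam, config.max_parents)
        if score > best_score + _SCORE_EPS:
            best_parents, best_score = parents, score
    assert best_parents is not None
    edges = tuple(
        sorted((p, c) for c in nodes for p in best_parents[c])
    )
    structure = DAGStructure(tuple(nodes), edges)
    return estimate_cpts(structure, data, config.smoothing_alpha, variables)


# ---------------------------------------------------------------------------
# Markov blanket
# ---------------------------------------------------------------------------

def markov_blanket(structure: DAGStructure, node: str) -> MarkovBlanketSelection:
    """Parents, children and co-parents of children of ``node``."""
    if node not in structure.nodes:
        raise UnknownNodeError(f"unknown node {node!r}")
    parents = set(structure.parents(node))
    children = set(structure.children(node))
    co_parents = {
        p for c in children for p in structure.parents(c) if p != node
    }
    blanket = frozenset(parents | children | co_parents)
    discarded = frozenset(set(structure.nodes) - blanket - {node})
    return MarkovBlanketSelection(node, blanket, discarded)


def gbn_mb_classifier(
    data: pd.DataFrame,
    class_var: str,
    config: LearnerConfig | None = None,
    variables: Sequence[CategoricalVariable] | None = None,
) -> tuple[DiscreteBayesianNetwork, MarkovBlanketSelection]:
    """Full network, then a relearned network restricted to the class blanket.

    An empty blanket (class independent of everything at the chosen score)
    degrades to a prior-only classifier: a single-node network holding the
    class marginal.  A warning is logged when that happens.
    """
    config = config or LearnerConfig()
    if class_var not in data.columns:
        raise UnknownNodeError(f"class variable {class_var!r} not in data")
    if variables is None:
        variables = variables_from_data(data)
    full = learn_structure(data, config, variables)
    selection = markov_blanket(full.structure, class_var)
    if not selection.blanket:
        logger.warning(
            "Markov blanket of %r is empty; falling back to a prior-only "
            "classifier", class_var,
        )
        structure = DAGStructure((class_var,), ())
        restricted = estimate_cpts(
            structure,
            data[[class_var]],
            config.smoothing_alpha,
            [v for v in variables if v.name == class_var],
        )
        return restricted, selection
    keep = sorted(selection.blanket | {class_var})
    restricted = learn_structure(
        data[keep], config, [v for v in variables if v.name in set(keep)]
    )
    return restricted, selection
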
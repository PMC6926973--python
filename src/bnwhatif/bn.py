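"""Discrete Bayesian networks over categorical variables.

A network is a directed acyclic graph (DAG) whose nodes are categorical
variables, each carrying a conditional probability table (CPT) that gives
the node's distribution for every combination of parent states.  The joint
distribution factorises by the chain rule,

    P(x_1, ..., x_m) = prod_i P(x_i | parents(x_i)),

and any conditional query P(query | evidence) can be answered exactly.  Two
independent inference routes are provided:

* :func:`infer_posterior` — variable elimination with a min-degree
  elimination order (the production route), and
* :func:`brute_force_posterior` — full-joint enumeration over a plain
  ndarray (the reference oracle, deliberately sharing no code with the
  elimination engine).

Ancestral sampling (:func:`ancestral_sample`) draws joint samples by
sampling each node after its parents in topological order; it is the basis
of the synthetic survey generator.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping
from xml.sax.saxutils import escape

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    IncompleteAssignmentError,
    InconsistentEvidenceError,
    InvalidQueryError,
    InvalidSizeError,
    TooLargeError,
    UnknownNodeError,
    UnknownStateError,
)

#: Evidence is a mapping variable name -> observed state label.
Evidence = Mapping[str, str]

_PROB_TOL = 1e-9
_BRUTE_FORCE_CELL_GUARD = 10_000_000


@dataclass(frozen=True)
class CategoricalVariable:
    """A named variable with an ordered tuple of at least two state labels."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if not self.name:
            raise ValueError("variable name must be non-empty")
        if len(self.states) < 2:
            raise ValueError(f"variable {self.name!r} needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate state labels")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise UnknownStateError(
                f"state {state!r} is not legal for variable {self.name!r} "
                f"(states: {list(self.states)})"
            ) from None


@dataclass(frozen=True)
class DAGStructure:
    """Node names plus directed (parent, child) edges forming a DAG."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple((p, c) for p, c in self.edges))
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        node_set = set(self.nodes)
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        for p, c in self.edges:
            if p not in node_set or c not in node_set:
                raise ValueError(f"edge ({p!r}, {c!r}) references undeclared node")
            if p == c:
                raise ValueError(f"self-loop on {p!r}")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("graph contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        if node not in self.nodes:
            raise UnknownNodeError(f"unknown node {node!r}")
        return tuple(sorted(p for p, c in self.edges if c == node))

    def children(self, node: str) -> tuple[str, ...]:
        if node not in self.nodes:
            raise UnknownNodeError(f"unknown node {node!r}")
        return tuple(sorted(c for p, c in self.edges if p == node))

    def topological_order(self) -> list[str]:
        # lexicographic tie-break keeps the order deterministic
        return list(nx.lexicographical_topological_sort(self.to_networkx()))


@dataclass(frozen=True)
class ConditionalProbabilityTable:
    """P(child | parents) as an ndarray with one axis per parent plus the child.

    ``values`` has shape ``(card(p_1), ..., card(p_k), card(child))``; for a
    root node the shape is just ``(card(child),)``.  Flattening the parent
    axes in C order enumerates parent-state combinations in odometer order
    with the last parent fastest, which is also the JSON row order.
    """

    child: str
    parents: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(
            self, "values", np.ascontiguousarray(np.asarray(self.values, dtype=float))
        )
        if self.values.ndim != len(self.parents) + 1:
            raise ValueError(
                f"CPT for {self.child!r}: expected {len(self.parents) + 1} axes, "
                f"got {self.values.ndim}"
            )
        if np.any(self.values < 0):
            raise ValueError(f"CPT for {self.child!r} has negative entries")
        sums = self.values.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=_PROB_TOL, rtol=0):
            raise ValueError(
                f"CPT rows for {self.child!r} do not sum to 1 within {_PROB_TOL}"
            )

    @property
    def n_rows(self) -> int:
        return int(np.prod(self.values.shape[:-1], dtype=int)) if self.parents else 1


@dataclass(frozen=True)
class DiscreteBayesianNetwork:
    """Variables, DAG structure and one CPT per node."""

    variables: tuple[CategoricalVariable, ...]
    structure: DAGStructure
    cpts: Mapping[str, ConditionalProbabilityTable]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "cpts", dict(self.cpts))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if set(names) != set(self.structure.nodes):
            raise ValueError("variable roster does not match structure nodes")
        by_name = {v.name: v for v in self.variables}
        for name in names:
            cpt = self.cpts.get(name)
            if cpt is None:
                raise ValueError(f"missing CPT for node {name!r}")
            if set(cpt.parents) != set(self.structure.parents(name)):
                raise ValueError(
                    f"CPT parents for {name!r} do not match incoming edges"
                )
            expected = tuple(by_name[p].n_states for p in cpt.parents) + (
                by_name[name].n_states,
            )
            if cpt.values.shape != expected:
                raise ValueError(
                    f"CPT for {name!r} has shape {cpt.values.shape}, expected {expected}"
                )

    # -- lookups ------------------------------------------------------------

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> CategoricalVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise UnknownNodeError(f"unknown node {name!r}")

    def card(self, name: str) -> int:
        return self.variable(name).n_states


@dataclass(frozen=True)
class PosteriorReport:
    """Baseline marginals vs evidence-conditioned posteriors for every node.

    ``deltas`` maps (node, state) to posterior minus baseline; evidence nodes
    have degenerate (indicator) posteriors.
    """

    evidence: dict[str, str]
    states: dict[str, tuple[str, ...]]
    baseline: dict[str, np.ndarray]
    posterior: dict[str, np.ndarray]
    deltas: dict[tuple[str, str], float]
    target: tuple[str, str] | None = None

    @property
    def headline(self) -> tuple[float, float] | None:
        """(baseline, posterior) probability of the target state, if any."""
        if self.target is None:
            return None
        node, state = self.target
        i = self.states[node].index(state)
        return float(self.baseline[node][i]), float(self.posterior[node][i])


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _validate_evidence(net: DiscreteBayesianNetwork, evidence: Evidence) -> dict[str, int]:
    """Return {name: state index}; raises on unknown nodes/states."""
    out: dict[str, int] = {}
    for name, state in evidence.items():
        var = net.variable(name)  # UnknownNodeError if absent
        out[name] = var.index(state)
    return out


# ---------------------------------------------------------------------------
# joint probability
# ---------------------------------------------------------------------------

def joint_probability(net: DiscreteBayesianNetwork, assignment: Mapping[str, str]) -> float:
    """Chain-rule probability of one full state assignment."""
    idx: dict[str, int] = {}
    for var in net.variables:
        if var.name not in assignment:
            raise IncompleteAssignmentError(
                f"assignment is missing node {var.name!r}"
            )
        idx[var.name] = var.index(assignment[var.name])
    p = 1.0
    for var in net.variables:
        cpt = net.cpts[var.name]
        sel = tuple(idx[par] for par in cpt.parents) + (idx[var.name],)
        p *= float(cpt.values[sel])
    return p


# ---------------------------------------------------------------------------
# variable elimination
# ---------------------------------------------------------------------------

class _Factor:
    """A non-negative table over a tuple of variable names."""

    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[str, ...], values: np.ndarray):
        self.vars = vars
        self.values = values

    def restrict(self, name: str, index: int) -> "_Factor":
        ax = self.vars.index(name)
        values = np.take(self.values, index, axis=ax)
        return _Factor(self.vars[:ax] + self.vars[ax + 1:], values)

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        return _Factor(
            out_vars,
            _aligned(self, out_vars) * _aligned(other, out_vars),
        )

    def sum_out(self, name: str) -> "_Factor":
        ax = self.vars.index(name)
        return _Factor(
            self.vars[:ax] + self.vars[ax + 1:], self.values.sum(axis=ax)
        )


def _aligned(factor: _Factor, out_vars: tuple[str, ...]) -> np.ndarray:
    """Broadcast a factor's values onto the axis order ``out_vars``."""
    positions = [out_vars.index(v) for v in factor.vars]
    perm = np.argsort(positions)
    arr = np.transpose(factor.values, perm)
    shape = [1] * len(out_vars)
    for v, n in zip([factor.vars[i] for i in perm], arr.shape):
        shape[out_vars.index(v)] = n
    return arr.reshape(shape)


def infer_posterior(
    net: DiscreteBayesianNetwork, query: str, evidence: Evidence | None = None
) -> np.ndarray:
    """Exact posterior P(query | evidence) by variable elimination.

    The elimination order is min-degree on the moralized graph of the current
    factor scopes, ties broken lexicographically by variable name.  Raises
    :class:`InconsistentEvidenceError` when the evidence has probability zero
    and :class:`InvalidQueryError` when the query is itself observed.
    """
    evidence = evidence or {}
    net.variable(query)
    ev_idx = _validate_evidence(net, evidence)
    if query in ev_idx:
        raise InvalidQueryError(f"query {query!r} appears in the evidence")

    factors: list[_Factor] = []
    for var in net.variables:
        cpt = net.cpts[var.name]
        f = _Factor(cpt.parents + (var.name,), cpt.values)
        for name, index in ev_idx.items():
            if name in f.vars:
                f = f.restrict(name, index)
        factors.append(f)

    hidden = {n for n in net.node_names if n != query and n not in ev_idx}
    while hidden:
        # min-degree: neighbours are variables co-occurring in some factor
        neighbours: dict[str, set[str]] = {h: set() for h in hidden}
        for f in factors:
            scope = set(f.vars)
            for v in scope:
                if v in neighbours:
                    neighbours[v] |= scope - {v}
        victim = min(hidden, key=lambda v: (len(neighbours[v]), v))
        involved = [f for f in factors if victim in f.vars]
        factors = [f for f in factors if victim not in f.vars]
        if involved:
            prod = involved[0]
            for f in involved[1:]:
                prod = prod.multiply(f)
            factors.append(prod.sum_out(victim))
        hidden.remove(victim)

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    if result.vars != (query,):
        result = _Factor(
            (query,), _aligned(result, (query,)) * np.ones(net.card(query))
        )
    values = np.asarray(result.values, dtype=float)
    total = float(values.sum())
    if not np.isfinite(total) or total <= 0.0:
        raise InconsistentEvidenceError(
            f"evidence {dict(evidence)!r} has probability zero"
        )
    return values / total


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def full_joint_table(net: DiscreteBayesianNetwork) -> tuple[tuple[str, ...], np.ndarray]:
    """The full joint as one ndarray with one axis per variable.

    Guarded at 10^7 cells; intended for small networks and test oracles.
    """
    names = net.node_names
    cards = [net.card(n) for n in names]
    n_cells = int(np.prod(cards, dtype=np.int64))
    if n_cells > _BRUTE_FORCE_CELL_GUARD:
        raise TooLargeError(
            f"joint has {n_cells} cells, exceeding the {_BRUTE_FORCE_CELL_GUARD} guard"
        )
    pos = {n: i for i, n in enumerate(names)}
    joint = np.ones(cards)
    for var in net.variables:
        cpt = net.cpts[var.name]
        axes = [pos[p] for p in cpt.parents] + [pos[var.name]]
        order = np.argsort(axes)
        arr = np.transpose(cpt.values, order)
        shape = [1] * len(names)
        for a, n in zip(sorted(axes), arr.shape):
            shape[a] = n
        joint = joint * arr.reshape(shape)
    return names, joint


def brute_force_posterior(
    net: DiscreteBayesianNetwork, query: str, evidence: Evidence | None = None
) -> np.ndarray:
    """P(query | evidence) by full-joint enumeration (test oracle).

    Shares no machinery with :func:`infer_posterior` beyond CPT storage.
    """
    evidence = evidence or {}
    net.variable(query)
    ev_idx = _validate_evidence(net, evidence)
    if query in ev_idx:
        raise InvalidQueryError(f"query {query!r} appears in the evidence")
    names, joint = full_joint_table(net)
    pos = {n: i for i, n in enumerate(names)}
    # slice out the evidence, then marginalize everything but the query
    for name in sorted(ev_idx, key=lambda n: -pos[n]):
        joint = np.take(joint, ev_idx[name], axis=pos[name])
    remaining = [n for n in names if n not in ev_idx]
    qax = remaining.index(query)
    axes = tuple(i for i in range(len(remaining)) if i != qax)
    vec = joint.sum(axis=axes) if axes else joint
    total = float(vec.sum())
    if total <= 0.0:
        raise InconsistentEvidenceError(
            f"evidence {dict(evidence)!r} has probability zero"
        )
    return vec / total


# ---------------------------------------------------------------------------
# ancestral sampling
# ---------------------------------------------------------------------------

def ancestral_sample(
    net: DiscreteBayesianNetwork, n: int, seed: int
) -> pd.DataFrame:
    """Draw ``n`` joint samples in topological order; deterministic per seed."""
    if n < 1:
        raise InvalidSizeError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    codes: dict[str, np.ndarray] = {}
    for name in net.structure.topological_order():
        cpt = net.cpts[name]
        r = net.card(name)
        if cpt.parents:
            rows = cpt.values[tuple(codes[p] for p in cpt.parents)]
        else:
            rows = np.broadcast_to(cpt.values, (n, r))
        u = rng.random(n)
        cum = rows.cumsum(axis=1)
        codes[name] = np.minimum((u[:, None] >= cum).sum(axis=1), r - 1)
    data = {
        v.name: np.asarray(v.states, dtype=object)[codes[v.name]]
        for v in net.variables
    }
    return pd.DataFrame(data, columns=list(net.node_names))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def net_to_dict(net: DiscreteBayesianNetwork) -> dict:
    """JSON-ready dict: variables, edges, and row-major CPTs.

    CPT rows enumerate parent-state combinations in odometer order with the
    last parent fastest (C-order flattening of the parent axes).
    """
    return {
        "variables": [
            {"name": v.name, "states": list(v.states)} for v in net.variables
        ],
        "edges": [[p, c] for p, c in net.structure.edges],
        "cpts": [
            {
                "child": name,
                "parents": list(net.cpts[name].parents),
                "table": net.cpts[name]
                .values.reshape(-1, net.card(name))
                .tolist(),
            }
            for name in net.node_names
        ],
    }


def net_from_dict(payload: Mapping) -> DiscreteBayesianNetwork:
    variables = tuple(
        CategoricalVariable(v["name"], tuple(v["states"]))
        for v in payload["variables"]
    )
    by_name = {v.name: v for v in variables}
    structure = DAGStructure(
        tuple(v.name for v in variables),
        tuple((p, c) for p, c in payload["edges"]),
    )
    cpts = {}
    for entry in payload["cpts"]:
        child = entry["child"]
        parents = tuple(entry["parents"])
        shape = tuple(by_name[p].n_states for p in parents) + (
            by_name[child].n_states,
        )
        cpts[child] = ConditionalProbabilityTable(
            child, parents, np.asarray(entry["table"], dtype=float).reshape(shape)
        )
    return DiscreteBayesianNetwork(variables, structure, cpts)


def save_network(net: DiscreteBayesianNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(net_to_dict(net), fh, indent=1)


def load_network(path) -> DiscreteBayesianNetwork:
    with open(path, encoding="utf-8") as fh:
        return net_from_dict(json.load(fh))


def write_xmlbif(net: DiscreteBayesianNetwork, path) -> None:
    """Export in XMLBIF 0.3 for interchange with other toolkits."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<BIF VERSION="0.3">',
        "<NETWORK>",
        "<NAME>bnwhatif</NAME>",
    ]
    for v in net.variables:
        lines.append('<VARIABLE TYPE="nature">')
        lines.append(f"<NAME>{escape(v.name)}</NAME>")
        for s in v.states:
            lines.append(f"<OUTCOME>{escape(s)}</OUTCOME>")
        lines.append("</VARIABLE>")
    for name in net.node_names:
        cpt = net.cpts[name]
        lines.append("<DEFINITION>")
        lines.append(f"<FOR>{escape(name)}</FOR>")
        for p in cpt.parents:
            lines.append(f"<GIVEN>{escape(p)}</GIVEN>")
        flat = " ".join(repr(float(x)) for x in cpt.values.reshape(-1))
        lines.append(f"<TABLE>{flat}</TABLE>")
        lines.append("</DEFINITION>")
    lines += ["</NETWORK>", "</BIF>", ""]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
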
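"""What-if scenario engine: evidence propagation and effect decomposition.

A scenario fixes some variables to states ("evidence"), propagates it
through the network, and reads off how the posterior of a designated target
state moves relative to the no-evidence baseline — the "a → b" headline of
a scenario table.  The target quantity Y is the indicator of a single
target state, so every expectation E(Y | ·) is a posterior probability.

The decomposition splits the total shift E(Y | full evidence) − E(Y) into
main effects and interactions over the evidence variables:

    z_i(x_i)     = E(Y | x_i) − E(Y)
    z_ij(x_ij)   = E(Y | x_ij) − z_i − z_j − E(Y)
    z_ijk(x_ijk) = E(Y | x_ijk) − all lower-order z terms − E(Y)

and so on; terms above ``max_order`` are folded into a remainder, which is
identically zero when ``max_order`` equals the number of evidence
variables.  Main-effect terms are mean-zero under the marginal of their
variable: E[z_i(X_i)] = 0.

Scenario files may say "maximize"/"minimize" a variable; the tokens
``!max`` / ``!min`` resolve to the last/first state of the variable's
ordered state list at load time.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import yaml

from .bn import DiscreteBayesianNetwork, Evidence, PosteriorReport, infer_posterior
from .errors import ConfigError, InvalidQueryError

MAX_TOKEN = "!max"
MIN_TOKEN = "!min"


@dataclass(frozen=True)
class Scenario:
    """Named evidence assignment plus the (variable, state) to watch."""

    name: str
    evidence: dict[str, str]
    target: tuple[str, str]

    def __post_init__(self) -> None:
        if self.target[0] in self.evidence:
            raise InvalidQueryError(
                f"scenario {self.name!r}: target variable {self.target[0]!r} "
                "cannot also be evidence"
            )


@dataclass(frozen=True)
class WhatIfDecomposition:
    """Baseline expectation, z-terms keyed by variable subset, remainder."""

    target: tuple[str, str]
    evidence: dict[str, str]
    baseline: float
    terms: dict[tuple[str, ...], float]
    remainder: float
    max_order: int

    @property
    def total(self) -> float:
        """Reconstructed E(Y | full evidence)."""
        return self.baseline + sum(self.terms.values()) + self.remainder


def expected_target(
    net: DiscreteBayesianNetwork,
    target: tuple[str, str],
    evidence: Evidence | None = None,
) -> float:
    """E(Y | evidence) where Y indicates ``target = (variable, state)``."""
    variable, state = target
    idx = net.variable(variable).index(state)
    post = infer_posterior(net, variable, evidence or {})
    return float(post[idx])


def expected_score(
    net: DiscreteBayesianNetwork,
    variable: str,
    scores: dict[str, float],
    evidence: Evidence | None = None,
) -> float:
    """Optional multi-state target: expectation of user-supplied state scores."""
    var = net.variable(variable)
    weights = np.array([scores[s] for s in var.states], dtype=float)
    post = infer_posterior(net, variable, evidence or {})
    return float((weights * post).sum())


def apply_scenario(net: DiscreteBayesianNetwork, scenario: Scenario) -> PosteriorReport:
    """Propagate scenario evidence and report baseline/posterior per node."""
    evidence = dict(scenario.evidence)
    # validate up front so inconsistent evidence names the assignment
    for name, state in evidence.items():
        net.variable(name).index(state)
    states = {v.name: v.states for v in net.variables}
    baseline = {n: infer_posterior(net, n, {}) for n in net.node_names}
    posterior: dict[str, np.ndarray] = {}
    for n in net.node_names:
        if n in evidence:
            vec = np.zeros(net.card(n))
            vec[net.variable(n).index(evidence[n])] = 1.0
            posterior[n] = vec
        else:
            posterior[n] = infer_posterior(net, n, evidence)
    deltas = {
        (n, s): float(posterior[n][i] - baseline[n][i])
        for n in net.node_names
        for i, s in enumerate(states[n])
    }
    return PosteriorReport(
        evidence=evidence,
        states=states,
        baseline=baseline,
        posterior=posterior,
        deltas=deltas,
        target=scenario.target,
    )


def whatif_decomposition(
    net: DiscreteBayesianNetwork,
    target: tuple[str, str],
    evidence: Evidence,
    max_order: int = 2,
) -> WhatIfDecomposition:
    """Decompose the evidence effect on E(Y) into z-terms up to ``max_order``.

    Subsets are taken in the order the evidence mapping lists its variables.
    """
    names = list(evidence.keys())
    d = len(names)
    if not 1 <= max_order <= d:
        raise ValueError(f"max_order must be in [1, {d}], got {max_order}")
    baseline = expected_target(net, target, {})
    terms: dict[tuple[str, ...], float] = {}
    for size in range(1, max_order + 1):
        for subset in itertools.combinations(names, size):
            sub_evidence = {v: evidence[v] for v in subset}
            e_sub = expected_target(net, target, sub_evidence)
            lower = sum(
                terms[t]
                for k in range(1, size)
                for t in itertools.combinations(subset, k)
            )
            terms[subset] = e_sub - lower - baseline
    e_full = expected_target(net, target, dict(evidence))
    remainder = e_full - baseline - sum(terms.values())
    return WhatIfDecomposition(
        target=target,
        evidence=dict(evidence),
        baseline=baseline,
        terms=terms,
        remainder=remainder,
        max_order=max_order,
    )


def main_effect_profile(
    net: DiscreteBayesianNetwork, target: tuple[str, str], variable: str
) -> dict[str, float]:
    """z_i(x) tabulated over every state x of ``variable``.

    Used for the mean-zero diagnostic: sum_x P(X=x) z_i(x) = 0.
    """
    baseline = expected_target(net, target, {})
    return {
        state: expected_target(net, target, {variable: state}) - baseline
        for state in net.variable(variable).states
    }


# ---------------------------------------------------------------------------
# scenario files and reports
# ---------------------------------------------------------------------------

def resolve_directives(net: DiscreteBayesianNetwork, evidence: dict[str, str]) -> dict[str, str]:
    """Resolve ``!max``/``!min`` tokens to the last/first ordinal state."""
    out = {}
    for name, state in evidence.items():
        states = net.variable(name).states
        if state == MAX_TOKEN:
            out[name] = states[-1]
        elif state == MIN_TOKEN:
            out[name] = states[0]
        else:
            out[name] = state
    return out


def load_scenarios(path, net: DiscreteBayesianNetwork) -> list[Scenario]:
    """Read scenario YAML (one mapping or a list of mappings).

    Each scenario needs ``name``, ``evidence: {var: state}`` and
    ``target: "var=state"``; directive tokens are resolved here.
    """
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    if not isinstance(payload, list):
        raise ConfigError(f"scenario file {path} must hold a mapping or a list")
    scenarios = []
    for entry in payload:
        try:
            name = entry["name"]
            raw_evidence = dict(entry["evidence"])
            target_spec = entry["target"]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"scenario file {path}: missing field {exc}") from None
        if "=" not in str(target_spec):
            raise ConfigError(
                f"scenario {name!r}: target must look like 'Variable=state'"
            )
        t_var, t_state = str(target_spec).split("=", 1)
        evidence = resolve_directives(net, {str(k): str(v) for k, v in raw_evidence.items()})
        scenarios.append(Scenario(name, evidence, (t_var.strip(), t_state.strip())))
    return scenarios


def report_to_dict(report: PosteriorReport, name: str = "") -> dict:
    """JSON-ready scenario report: baseline/posterior/delta per node."""
    payload = {
        "scenario": name,
        "evidence": report.evidence,
        "nodes": {
            n: {
                "states": list(report.states[n]),
                "baseline": [float(x) for x in report.baseline[n]],
                "posterior": [float(x) for x in report.posterior[n]],
                "delta": [
                    float(report.posterior[n][i] - report.baseline[n][i])
                    for i in range(len(report.states[n]))
                ],
            }
            for n in report.states
        },
    }
    if report.target is not None:
        b, p = report.headline
        payload["target"] = {
            "variable": report.target[0],
            "state": report.target[1],
            "baseline_percent": round(100.0 * b, 1),
            "posterior_percent": round(100.0 * p, 1),
        }
    return payload


def format_arrow(report: PosteriorReport) -> str:
    """Human-readable headline, e.g. ``Obesity=Obese: 23.4 → 40.0``."""
    if report.target is None:
        return "(no target)"
    b, p = report.headline
    node, state = report.target
    return f"{node}={state}: {100 * b:.1f} → {100 * p:.1f}"


def save_report(report: PosteriorReport, path, name: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report, name), fh, indent=1)
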
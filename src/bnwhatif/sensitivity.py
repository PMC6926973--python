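"""Sensitivity-to-findings of a target node with respect to every other node.

For each candidate finding node X and target T the report carries three
measures computed from the exact pairwise joint P(T, X) (obtained by
inference, one pair at a time, so memory stays bounded):

* mutual information I(T; X) in bits (base-2 logs);
* entropy percentage 100 · I(T; X) / H(T), the share of the target's
  uncertainty the finding would remove — the self-row is exactly 100;
* variance of beliefs, the expected squared shift of the target's belief
  vector upon observing X, weighted by the posterior belief:

      sum_f P(X=f) sum_s P(T=s | X=f) · (P(T=s | X=f) − P(T=s))².

Rows are ordered self-row first, then by mutual information descending with
lexicographic tie-breaks, mirroring how such rankings are usually printed.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .bn import DiscreteBayesianNetwork, infer_posterior
from .errors import DegenerateTargetError

_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class SensitivityRow:
    node: str
    mutual_information: float
    entropy_percent: float
    variance_of_beliefs: float


def _entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz) / _LOG2).sum())


def node_entropy(net: DiscreteBayesianNetwork, node: str) -> float:
    """Shannon entropy (bits) of the node's no-evidence marginal."""
    return _entropy_bits(infer_posterior(net, node, {}))


def _pairwise(net, target, node):
    """Yield (p_f, posterior over target) for each state f of ``node``."""
    p_node = infer_posterior(net, node, {})
    states = net.variable(node).states
    if node == target:
        r = len(states)
        for f, p_f in enumerate(p_node):
            post = np.zeros(r)
            post[f] = 1.0
            yield float(p_f), post
        return
    for f, p_f in enumerate(p_node):
        if p_f <= 0:
            continue
        yield float(p_f), infer_posterior(net, target, {node: states[f]})


def mutual_information(net: DiscreteBayesianNetwork, target: str, node: str) -> float:
    """I(target; node) in bits from the exact pairwise joint."""
    prior = infer_posterior(net, target, {})
    h_prior = _entropy_bits(prior)
    h_cond = sum(p_f * _entropy_bits(post) for p_f, post in _pairwise(net, target, node))
    return max(0.0, h_prior - h_cond)


def variance_of_beliefs(net: DiscreteBayesianNetwork, target: str, node: str) -> float:
    """Posterior-weighted expected squared belief change of the target."""
    prior = infer_posterior(net, target, {})
    total = 0.0
    for p_f, post in _pairwise(net, target, node):
        total += p_f * float((post * (post - prior) ** 2).sum())
    return total


def sensitivity_to_findings(
    net: DiscreteBayesianNetwork, target: str
) -> list[SensitivityRow]:
    """One row per node, self-row first, then sorted by mutual information.

    Raises :class:`DegenerateTargetError` when the target marginal is
    degenerate (zero entropy), since entropy percentages are then undefined.
    """
    h_target = node_entropy(net, target)
    if h_target <= 0:
        raise DegenerateTargetError(
            f"target {target!r} has zero entropy; entropy percent is undefined"
        )
    rows = [
        SensitivityRow(
            node=target,
            mutual_information=h_target,
            entropy_percent=100.0,
            variance_of_beliefs=variance_of_beliefs(net, target, target),
        )
    ]
    others = []
    for name in net.node_names:
        if name == target:
            continue
        mi = mutual_information(net, target, name)
        others.append(
            SensitivityRow(
                node=name,
                mutual_information=mi,
                entropy_percent=100.0 * mi / h_target,
                variance_of_beliefs=variance_of_beliefs(net, target, name),
            )
        )
    others.sort(key=lambda r: (-r.mutual_information, r.node))
    return rows + others


def write_sensitivity_tsv(rows, path) -> None:
    """Four-column TSV: node, MI (bits), entropy %, variance of beliefs."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["Node", "Mutual_Information", "Entropy_Percent", "Variance_of_Beliefs"]
        )
        for row in rows:
            writer.writerow(
                [
                    row.node,
                    f"{row.mutual_information:.5f}",
                    f"{row.entropy_percent:.3g}",
                    f"{row.variance_of_beliefs:.7f}",
                ]
            )
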
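"""Function-level aggregation and differential networks.

Proteins in a stage network are grouped by a pathway/function catalog;
functions over-represented among the network's proteins (one-sided
hypergeometric test, Benjamini-Hochberg control) form the nodes of the
functional network, and the activity between two functions is the sum of the
identified interaction activities between their member proteins. Subtracting
two stages' networks edge-wise (and node-wise for core networks) yields the
differential networks whose up-/down-regulated links describe disease
progression between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import FunctionCatalog

Pair = tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def enrichment_table(network_proteins, catalog: FunctionCatalog, background):
    """Hypergeometric over-representation p-value per catalog function.

    For a function with K members in the background of size N, the p-value is
    P(X >= k) for the observed overlap k with the n foreground proteins,
    X ~ Hypergeom(N, K, n). Returns ``{function: (k, K, p)}``.
    """
    fg = set(network_proteins)
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    if not fg <= bg:
        raise ValueError("network proteins must be a subset of the background")
    out = {}
    for name in catalog.names:
        members = catalog.sets[name] & bg
        if not members:
            continue
        k = len(members & fg)
        out[name] = (k, len(members), float(stats.hypergeom.sf(k - 1, len(bg), len(members), len(fg))))
    return out


def enrich_functions(
    network_proteins,
    catalog: FunctionCatalog,
    background,
    fdr: float = 0.05,
) -> list[str]:
    """Functions significantly over-represented among the network proteins.

    Benjamini-Hochberg control of the hypergeometric p-values at level
    ``fdr``; returns the passing function names sorted. ``fdr = 0`` passes
    nothing.
    """
    table = enrichment_table(network_proteins, catalog, background)
    if not table or fdr <= 0:
        return []
    names = sorted(table)
    pvals = np.array([table[n][2] for n in names])
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return [n for n, r in zip(names, reject) if r]


@dataclass
class FunctionalNetwork:
    """Weighted undirected network over enriched functions.

    ``activity[(f, g)]`` (keys sorted, f may equal g) is the signed sum of
    member-pair interaction activities between functions f and g.
    """

    functions: list[str]
    activity: dict[Pair, float]
    stage: str = "C"


def functional_network(net, enriched, catalog: FunctionCatalog) -> FunctionalNetwork:
    """Aggregate a stage network's activities to the function level.

    For f != g, activity(f, g) sums alpha_ik over directed edges with i in f
    and k in g plus those with i in g and k in f; activity(f, f) sums edges
    with both endpoints in f. A protein belonging to both functions
    contributes its edges once per ordered containment. Sums are signed so
    the up/down direction of regulation is preserved.
    """
    enriched = sorted(set(enriched))
    missing = [f for f in enriched if f not in catalog.sets]
    if missing:
        raise ValueError(f"enriched functions not in catalog: {missing[:5]}")
    membership: dict[str, list[str]] = {}
    for f in enriched:
        for p in catalog.sets[f]:
            membership.setdefault(p, []).append(f)
    activity: dict[Pair, float] = {}
    for (i, k), a in net.adjacency.items():
        for f in membership.get(i, ()):
            for g in membership.get(k, ()):
                key = _pair(f, g)
                activity[key] = activity.get(key, 0.0) + a
    return FunctionalNetwork(functions=enriched, activity=activity, stage=net.stage)


@dataclass
class DifferentialNetwork:
    """Edge-wise (and optionally node-wise) difference between two stages.

    ``edge_delta`` maps a node pair to later-stage minus earlier-stage
    activity, with missing edges treated as zero; ``node_delta`` carries the
    basal-level changes when core networks are compared.
    """

    edge_delta: dict[tuple, float]
    node_delta: dict[str, float] | None
    from_stage: str
    to_stage: str
    kind: str = "functional"

    def __neg__(self) -> "DifferentialNetwork":
        return DifferentialNetwork(
            edge_delta={e: -d for e, d in self.edge_delta.items()},
            node_delta=None if self.node_delta is None else {p: -d for p, d in self.node_delta.items()},
            from_stage=self.to_stage,
            to_stage=self.from_stage,
            kind=self.kind,
        )


def differential_network(later, earlier) -> DifferentialNetwork:
    """Subtract two same-type networks (later minus earlier).

    Accepts two FunctionalNetworks or two core networks (anything exposing
    ``adjacency`` and ``beta``); edges absent on one side count as zero.
    Swapping the arguments negates every delta.
    """
    if type(later) is not type(earlier):
        raise TypeError("can only differentiate networks of the same type")
    if isinstance(later, FunctionalNetwork):
        keys = set(later.activity) | set(earlier.activity)
        edge_delta = {
            e: later.activity.get(e, 0.0) - earlier.activity.get(e, 0.0) for e in keys
        }
        return DifferentialNetwork(
            edge_delta=edge_delta,
            node_delta=None,
            from_stage=earlier.stage,
            to_stage=later.stage,
            kind="functional",
        )
    keys = set(later.adjacency) | set(earlier.adjacency)
    edge_delta = {
        e: later.adjacency.get(e, 0.0) - earlier.adjacency.get(e, 0.0) for e in keys
    }
    nodes = set(later.beta) | set(earlier.beta)
    node_delta = {
        p: later.beta.get(p, 0.0) - earlier.beta.get(p, 0.0) for p in nodes
    }
    return DifferentialNetwork(
        edge_delta=edge_delta,
        node_delta=node_delta,
        from_stage=earlier.stage,
        to_stage=later.stage,
        kind="core",
    )
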
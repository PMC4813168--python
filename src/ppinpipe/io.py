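"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (genes x samples, header row of sample
ids); candidate interactions as 2-column TSV; function catalogs as GMT (name,
description, tab-separated members); identified networks as weighted
edge-list TSV plus a per-protein table; GraphML export goes through networkx.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .corenet import CoreNetwork
from .funcnet import DifferentialNetwork, FunctionalNetwork
from .netbuild import StageNetwork
from .preprocess import ExpressionMatrix
from .synthetic import FunctionCatalog


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_expression_tsv(path, stage: str = "C") -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(values=values, stage=stage)


def read_geo_series_matrix(path, stage: str = "C") -> ExpressionMatrix:
    """Series-matrix-style TSV: metadata lines prefixed with '!' are skipped."""
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("!") and ln.strip()]
    from io import StringIO

    values = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    return ExpressionMatrix(values=values, stage=stage)


def write_edge_pairs_tsv(pairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(tuple(p) for p in pairs):
            fh.write(f"{a}\t{b}\n")


def read_edge_pairs_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [tuple(row) for row in df.iloc[:, :2].itertuples(index=False)]


def write_gmt(catalog: FunctionCatalog, path) -> None:
    with open(path, "w") as fh:
        for name in catalog.names:
            desc = catalog.groups.get(name, "na")
            members = "\t".join(sorted(catalog.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path) -> FunctionCatalog:
    sets: dict[str, set[str]] = {}
    groups: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {m for m in parts[2:] if m}
            if parts[1] and parts[1] != "na":
                groups[parts[0]] = parts[1]
    return FunctionCatalog(sets=sets, groups=groups)


def write_stage_network_tsv(net: StageNetwork, edges_path, proteins_path) -> None:
    with open(edges_path, "w") as fh:
        fh.write("target\tinteractor\talpha\n")
        for (i, k) in sorted(net.adjacency):
            fh.write(f"{i}\t{k}\t{net.adjacency[(i, k)]:.10g}\n")
    with open(proteins_path, "w") as fh:
        fh.write("protein\tbeta\torder\trss\taic\n")
        for p in net.proteins:
            fit = (net.fits or {}).get(p)
            order = fit.order if fit else sum(1 for (i, _) in net.adjacency if i == p)
            rss = f"{fit.rss:.10g}" if fit else "NA"
            aic = f"{fit.aic:.10g}" if fit else "NA"
            fh.write(f"{p}\t{net.beta.get(p, 0.0):.10g}\t{order}\t{rss}\t{aic}\n")


def read_stage_network_tsv(edges_path, proteins_path, stage: str = "C") -> StageNetwork:
    edges = pd.read_csv(edges_path, sep="\t", dtype={"target": str, "interactor": str})
    prot = pd.read_csv(proteins_path, sep="\t", dtype={"protein": str})
    adjacency = {
        (row.target, row.interactor): float(row.alpha)
        for row in edges.itertuples(index=False)
    }
    beta = {row.protein: float(row.beta) for row in prot.itertuples(index=False)}
    return StageNetwork(
        proteins=list(prot["protein"]), adjacency=adjacency, beta=beta, stage=stage
    )


def write_functional_network_tsv(fnet: FunctionalNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("function_a\tfunction_b\tactivity\n")
        for (f, g) in sorted(fnet.activity):
            fh.write(f"{f}\t{g}\t{fnet.activity[(f, g)]:.10g}\n")


def write_differential_network_tsv(diff: DifferentialNetwork, edges_path, nodes_path=None) -> None:
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\tdelta\n")
        for key in sorted(diff.edge_delta):
            a, b = key
            fh.write(f"{a}\t{b}\t{diff.edge_delta[key]:.10g}\n")
    if nodes_path is not None and diff.node_delta is not None:
        with open(nodes_path, "w") as fh:
            fh.write("node\tdelta_beta\n")
            for p in sorted(diff.node_delta):
                fh.write(f"{p}\t{diff.node_delta[p]:.10g}\n")


def read_mirna_targets_tsv(path) -> dict[str, list[str]]:
    """2-column TSV protein -> miRNA; one row per (protein, miRNA) pair."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row[0], []).append(row[1])
    return out


def stage_network_to_graphml(net: StageNetwork, path) -> None:
    G = nx.DiGraph(stage=net.stage)
    for p in net.proteins:
        G.add_node(p, beta=float(net.beta.get(p, 0.0)))
    for (i, k), a in net.adjacency.items():
        G.add_edge(k, i, alpha=float(a))  # direction: interactor -> target
    nx.write_graphml(G, path)


def core_network_to_graphml(core: CoreNetwork, path, node_delta=None, edge_delta=None) -> None:
    G = nx.DiGraph(stage=core.stage)
    for p in core.core_proteins:
        attrs = {"beta": float(core.beta.get(p, 0.0))}
        if core.similarity:
            attrs["similarity"] = float(core.similarity.get(p, 0.0))
        if node_delta is not None:
            attrs["delta_beta"] = float(node_delta.get(p, 0.0))
        G.add_node(p, **attrs)
    for (i, k), a in core.adjacency.items():
        attrs = {"alpha": float(a)}
        if edge_delta is not None:
            attrs["delta_alpha"] = float(edge_delta.get((i, k), 0.0))
        G.add_edge(k, i, **attrs)
    nx.write_graphml(G, path)


def functional_network_to_graphml(
    fnet: FunctionalNetwork, catalog: FunctionCatalog, path
) -> None:
    G = nx.Graph(stage=fnet.stage)
    for f in fnet.functions:
        G.add_node(f, group=catalog.groups.get(f, "general"))
    for (f, g), a in fnet.activity.items():
        if f == g:
            continue
        G.add_edge(f, g, activity=float(a))
    nx.write_graphml(G, path)
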
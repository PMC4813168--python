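"""End-to-end orchestration: preprocess -> network identification per stage
-> functional and core networks -> stage-to-stage differential networks."""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as pio
from .corenet import core_network, eigen_decompose, protein_similarity, select_core
from .funcnet import differential_network, enrich_functions, functional_network
from .netbuild import assemble_candidate_network, build_stage_network
from .preprocess import quantile_normalize

log = logging.getLogger("ppinpipe")


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one full run.

    ``stages`` maps stage label -> expression TSV, in progression order.
    """

    stages: dict[str, str]
    candidate_edges: str
    catalog: str | None = None
    enrichment_fdr: float = 0.05
    ttest_alpha: float = 0.05
    energy_threshold: float = 85.0
    similarity_threshold: float = 6.0
    beta_change_min: float = 0.5
    quantile_normalize: bool = False
    mirna_targets: str | None = None
    seed: int = 0
    outdir: str = "ppinpipe_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("config lists no stages")
        paths = list(self.stages.values()) + [self.candidate_edges]
        if self.catalog:
            paths.append(self.catalog)
        if self.mirna_targets:
            paths.append(self.mirna_targets)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file missing: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every pipeline step and write all artifacts under ``outdir``.

    Returns (and writes) a JSON manifest with per-stage node/edge counts, the
    per-stage functional/core summaries, the differential pairs produced, a
    config echo and the seed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = list(config.stages)
    if len(labels) < 2:
        warnings.warn("only one stage configured: no differential networks")

    edges = pio.read_edge_pairs_tsv(config.candidate_edges)
    catalog = pio.read_gmt(config.catalog) if config.catalog else None
    mirna = (
        pio.read_mirna_targets_tsv(config.mirna_targets)
        if config.mirna_targets
        else {}
    )

    manifest: dict = {
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "stages": {},
        "differential": [],
    }
    stage_nets = {}
    core_nets = {}
    func_nets = {}
    for label in labels:
        t0 = time.perf_counter()
        expr = pio.read_expression_tsv(config.stages[label], stage=label)
        if config.quantile_normalize:
            expr.values = quantile_normalize(expr.values)
        cand = assemble_candidate_network(edges, expr.gene_ids)
        net = build_stage_network(
            expr, cand, alpha_level=config.ttest_alpha, keep_fits=True
        )
        stage_nets[label] = net
        pio.write_stage_network_tsv(
            net, outdir / f"network_{label}_edges.tsv", outdir / f"network_{label}_proteins.tsv"
        )
        pio.stage_network_to_graphml(net, outdir / f"network_{label}.graphml")
        entry = {"proteins": len(net.proteins), "interactions": net.n_edges}

        if catalog is not None:
            background = set(expr.gene_ids)
            active = {i for (i, _) in net.adjacency} | {
                k for (_, k) in net.adjacency
            }
            enriched = enrich_functions(
                active or set(net.proteins), catalog, background, fdr=config.enrichment_fdr
            )
            fnet = functional_network(net, enriched, catalog)
            func_nets[label] = fnet
            pio.write_functional_network_tsv(
                fnet, outdir / f"functional_{label}.tsv"
            )
            if enriched:
                pio.functional_network_to_graphml(
                    fnet, catalog, outdir / f"functional_{label}.graphml"
                )
            entry["enriched_functions"] = len(enriched)

        if net.adjacency:
            eig = eigen_decompose(net, energy_threshold=config.energy_threshold)
            sim = protein_similarity(net, eig)
            core = select_core(sim, threshold=config.similarity_threshold)
            cnet = core_network(net, core, similarity=sim)
            core_nets[label] = cnet
            pio.core_network_to_graphml(cnet, outdir / f"core_{label}.graphml")
            entry["principal_modes"] = eig.n_principal
            entry["core_proteins"] = len(cnet.core_proteins)
        entry["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][label] = entry
        log.info("stage %s: %s", label, entry)

    for earlier, later in zip(labels, labels[1:]):
        pair = f"{earlier}_to_{later}"
        if earlier in func_nets and later in func_nets:
            fdiff = differential_network(func_nets[later], func_nets[earlier])
            pio.write_differential_network_tsv(
                fdiff, outdir / f"diff_functional_{pair}.tsv"
            )
        if earlier in core_nets and later in core_nets:
            cdiff = differential_network(core_nets[later], core_nets[earlier])
            pio.write_differential_network_tsv(
                cdiff,
                outdir / f"diff_core_{pair}_edges.tsv",
                outdir / f"diff_core_{pair}_nodes.tsv",
            )
            if mirna:
                from .corenet import flag_regulation_candidates

                mi, me = flag_regulation_candidates(
                    cdiff, mirna, beta_change_min=config.beta_change_min
                )
                with open(outdir / f"regulation_{pair}.json", "w") as fh:
                    json.dump(
                        {"mirna_candidates": mi, "methylation_candidates": me},
                        fh,
                        indent=1,
                        sort_keys=True,
                    )
        manifest["differential"].append(pair)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
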
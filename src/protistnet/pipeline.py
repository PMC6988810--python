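"""End-to-end orchestration of the analysis stages with one master seed.

Stage order: replicate pooling -> singleton removal -> rarefying ->
{diversity summaries, Venn partition, Hellinger/Bray-Curtis exports},
abundance filter -> MIC edge inference -> network topology / random null /
hubs, habitat pooling -> CLAM classification, and trophic annotation.
Each randomized stage receives a seed derived deterministically from the
master seed, and a manifest records every parameter, derived seed and
output shape so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import otu as io
from . import trophic as tr
from .clam import ClamParams, ClamTest
from .mic import MicParams
from .network import (
    MicNetworkModel,
    export_edge_tsv,
    export_graphml,
    habitat_edge_summary,
)

logger = logging.getLogger(__name__)

# Fixed offsets make every stage seed a deterministic function of the master
# seed while keeping the streams independent.
_STAGE_SEED_OFFSETS = {"rarefy": 1, "habitat_pool": 2, "mic": 3, "null": 4}


@dataclass
class PipelineConfig:
    """Everything a run needs; see module docstring for the stage order."""

    otu_table: str
    metadata: str
    taxonomy: str | None = None
    trophic_rules: str | None = None
    depth_policy: str | int = "second-lowest"
    clam_stations: list[str] | None = None
    clam_params: ClamParams = field(default_factory=ClamParams)
    mic_params: MicParams = field(default_factory=MicParams)
    null_model: str = "same_n_m"
    n_random: int = 100
    min_hub_degree: int = 20
    master_seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        for label, path in (("otu_table", self.otu_table), ("metadata", self.metadata),
                            ("taxonomy", self.taxonomy),
                            ("trophic_rules", self.trophic_rules)):
            if path is not None and not Path(path).exists():
                raise io.OtuTableError(f"{label} path does not exist: {path}")
        io.resolve_depth.__doc__  # depth policy checked when resolved

    def stage_seed(self, stage: str) -> int:
        return (self.master_seed * 1000 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; write all outputs plus a manifest under cfg.outdir.

    Returns a result bundle with the in-memory objects of each stage.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": cfg.master_seed, "stages": {}}

    table = io.read_otu_table(cfg.otu_table)
    metadata = io.read_metadata(cfg.metadata)
    taxonomy = io.read_taxonomy(cfg.taxonomy) if cfg.taxonomy else {}
    manifest["input_shape"] = list(table.shape)

    pooled, pooled_meta = io.pool_replicates(table, metadata)
    nosingle = io.remove_singletons(pooled)
    depth = io.resolve_depth(nosingle, cfg.depth_policy)
    rarefied = io.rarefy(nosingle, depth, seed=cfg.stage_seed("rarefy"))
    rare_meta = pooled_meta[pooled_meta["sample_id"].isin(rarefied.sample_ids)]
    manifest["stages"]["normalize"] = {
        "pooled_samples": pooled.shape[1],
        "otus_after_singleton_removal": nosingle.shape[0],
        "rarefaction_depth": depth,
        "depth_policy": str(cfg.depth_policy),
        "rarefy_seed": cfg.stage_seed("rarefy"),
        "samples_retained": rarefied.shape[1],
    }

    summary = dv.diversity_summary(rarefied)
    summary.to_csv(outdir / "diversity_summary.tsv", sep="\t")
    bc = dv.bray_curtis(rarefied)
    bc.to_csv(outdir / "bray_curtis.tsv", sep="\t")
    io.hellinger_transform(rarefied).to_csv(outdir / "hellinger.tsv", sep="\t")
    venn = dv.venn_partition(rarefied, rare_meta)
    (outdir / "venn_partition.json").write_text(json.dumps(venn.to_dict(), indent=2))
    manifest["stages"]["diversity"] = {"samples": int(summary.shape[0])}

    pools = io.pool_by_habitat(rarefied, rare_meta, stations=cfg.clam_stations,
                               seed=cfg.stage_seed("habitat_pool"))
    clam_res = ClamTest.from_pools(pools, params=cfg.clam_params).fit()
    clam_res.to_tsv(outdir / "clam.tsv")
    (outdir / "clam_summary.json").write_text(json.dumps(
        {"class_counts": clam_res.class_counts(),
         "read_fractions": clam_res.read_fractions()}, indent=2))
    manifest["stages"]["clam"] = {
        "K": cfg.clam_params.K, "alpha": cfg.clam_params.alpha,
        "ci_method": cfg.clam_params.ci_method,
        "habitat_pool_seed": cfg.stage_seed("habitat_pool"),
        "class_counts": clam_res.class_counts(),
    }

    trophic_rules = (tr.read_rules(cfg.trophic_rules) if cfg.trophic_rules
                     else tr.default_rules())
    categories = tr.assign_trophic(taxonomy, trophic_rules) if taxonomy else {}
    if categories:
        cats_full = {o: categories.get(o, "NA") for o in rarefied.otu_ids}
        composition = tr.trophic_composition(rarefied, rare_meta, cats_full)
        composition.to_csv(outdir / "trophic_composition.tsv", sep="\t")
        manifest["stages"]["trophic"] = {"n_rules": len(trophic_rules)}
    else:
        composition = None

    mic_params = MicParams(**{**asdict(cfg.mic_params), "seed": cfg.stage_seed("mic")})
    net_model = MicNetworkModel(
        rarefied, mic_params=mic_params, clam_classes=clam_res.classes,
        taxonomy=taxonomy or None, trophic=categories or None,
        null_model=cfg.null_model, n_random=cfg.n_random,
        min_hub_degree=cfg.min_hub_degree,
    )
    net = net_model.fit()
    net.edge_frame().to_csv(outdir / "edges.tsv", sep="\t", index=False)
    export_graphml(net.graph, outdir / "network.graphml")
    export_edge_tsv(net.graph, outdir / "network_edges.tsv")
    hab_summary = habitat_edge_summary(net.graph)
    hab_summary.to_csv(outdir / "habitat_edge_summary.tsv", sep="\t")
    stats_dict = net.stats.to_dict()
    stats_dict["hubs"] = net.hubs
    (outdir / "network_summary.json").write_text(
        json.dumps(_jsonable(stats_dict), indent=2))
    manifest["stages"]["network"] = {
        "mic_seed": mic_params.seed, "null_seed": mic_params.seed + 1,
        "null_model": cfg.null_model, "n_random": cfg.n_random,
        "min_hub_degree": cfg.min_hub_degree,
        "n_nodes": net.stats.n_nodes, "n_edges": net.stats.n_edges,
    }

    manifest["params"] = {
        "clam": asdict(cfg.clam_params), "mic": asdict(mic_params),
        "depth_policy": str(cfg.depth_policy),
    }
    (outdir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    logger.info("run_all: complete, outputs in %s", outdir)
    return {
        "table": rarefied, "metadata": rare_meta, "diversity": summary,
        "bray_curtis": bc, "venn": venn, "clam": clam_res,
        "trophic_composition": composition, "network": net,
        "habitat_edge_summary": hab_summary, "manifest": manifest,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
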
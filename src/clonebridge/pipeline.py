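"""End-to-end orchestration: chain the pipeline stages over one config.

Stages communicate through files only; each run writes its tables plus a
JSON manifest recording parameters, seeds, input checksums, and outputs, so
that a rerun with an identical manifest reproduces identical outputs for
the deterministic stages.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import clones as _clones
from . import io as _io
from . import phenotype as _phen
from . import sharing as _sharing
from . import spatial as _spatial
from . import simulate as _sim

log = logging.getLogger(__name__)

ALL_STAGES = ("clones", "share", "diversity", "concordance", "trm", "de", "spatial")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    "simulate": {"enabled": True, "cells_per_compartment": 300, "shared_occupancy": None},
    "inputs": {},
    "clones": {"resolution": "nt", "pairing": "strict"},
    "share": {"pair": ["skin", "joint"], "triple_with": "blood"},
    "trm": {"alpha": 0.05, "n_perm": 999},
    "spatial": {"method": "delaunay_capped", "cap_um": 30.0, "n_perm": 999},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: Optional[dict] = None, out_dir="out", seed: Optional[int] = None) -> dict:
    """Run the configured stages and return the run manifest.

    With ``simulate.enabled`` a synthetic cohort provides every input;
    otherwise the ``inputs`` section must point at contig, metadata and
    (optionally) expression/spatial files.  A missing required input is a
    validation error raised before any stage runs.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    root_seed = int(cfg["seed"])
    stage_rng = {s: np.random.default_rng([root_seed, i]) for i, s in enumerate(ALL_STAGES)}

    manifest: dict = {
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": root_seed,
        "inputs": {},
        "outputs": [],
        "stages_run": [],
    }

    def record(path: Path) -> None:
        manifest["outputs"].append({"path": str(path), "sha256": _sha256(path)})

    simulate = bool(cfg["simulate"].get("enabled"))
    if not simulate:
        inputs = cfg.get("inputs", {})
        for key in ("contigs", "meta"):
            if key not in inputs:
                raise ValueError(f"config inputs.{key} is required when simulate is disabled")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(inputs[key])
        manifest["inputs"] = {
            k: {"path": str(v), "sha256": _sha256(Path(v))}
            for k, v in inputs.items()
            if isinstance(v, str) and Path(v).exists()
        }

    # ------------------------------------------------------------------ data
    sim_truth = None
    if simulate:
        sim_kwargs = {
            k: v for k, v in cfg["simulate"].items() if k not in ("enabled",) and v is not None
        }
        sim_cfg = _sim.SimConfig(seed=root_seed, **sim_kwargs)
        rng = np.random.default_rng([root_seed, 100])
        contigs, meta, sim_truth = _sim.simulate_repertoire(sim_cfg, rng)
        _io.write_airr(contigs, out / "contigs.airr.tsv")
        _io.write_cell_meta(meta, out / "meta.tsv")
        record(out / "contigs.airr.tsv")
        record(out / "meta.tsv")
        matrix = None
        spatial_cells = None
        if "spatial" in stages:
            sim_cfg_sp = _sim.SimConfig(
                seed=root_seed, attraction={("CD8_Trm", "Macrophage"): 0.6}
            )
            spatial_cells, _ = _sim.simulate_spatial(sim_cfg_sp, np.random.default_rng([root_seed, 101]))
            _io.write_spatial(spatial_cells, out / "spatial.tsv")
            record(out / "spatial.tsv")
    else:
        inputs = cfg["inputs"]
        reader = _io.read_10x_contigs if inputs.get("format") == "10x" else _io.read_airr
        contigs = reader(inputs["contigs"])
        meta = _io.read_cell_meta(inputs["meta"])
        matrix = None
        if {"mtx", "features", "barcodes"} <= set(inputs.get("expression", {})):
            e = inputs["expression"]
            matrix = _io.read_expression(e["mtx"], e["features"], e["barcodes"])
        spatial_cells = _io.read_spatial(inputs["spatial"]) if inputs.get("spatial") else None

    # ---------------------------------------------------------------- stages
    profiles = _io.build_chain_profiles(contigs)
    table = pooled = shared = None
    if "clones" in stages:
        table = _clones.call_clones(
            profiles, meta, resolution=cfg["clones"]["resolution"], pairing=cfg["clones"]["pairing"]
        )
        table.to_frame().to_csv(out / "clonotypes.tsv", sep="\t", index=False)
        pd.DataFrame({"barcode": table.unassigned}).to_csv(
            out / "unassigned.tsv", sep="\t", index=False
        )
        record(out / "clonotypes.tsv")
        record(out / "unassigned.tsv")
        manifest["stages_run"].append("clones")

    if "share" in stages and table is not None:
        pooled = _clones.pool_joint(table)
        pair = tuple(cfg["share"]["pair"])
        shared = _sharing.find_shared_clones(
            pooled.subset(lineage="CD8"), pair=pair, triple_with=cfg["share"]["triple_with"]
        )
        shared.to_frame().to_csv(out / "shared_clones.tsv", sep="\t", index=False)
        record(out / "shared_clones.tsv")
        summary = _sharing.sharing_summary(pooled.subset(lineage="CD8"), [shared])
        summary["links"].to_csv(out / "alluvial_links.tsv", sep="\t", index=False)
        summary["bars"].to_csv(out / "clone_bars.tsv", sep="\t", index=False)
        record(out / "alluvial_links.tsv")
        record(out / "clone_bars.tsv")
        manifest["stages_run"].append("share")

    if "diversity" in stages and table is not None:
        pooled = pooled or _clones.pool_joint(table)
        _sharing.diversity_table(pooled).to_csv(out / "diversity.tsv", sep="\t", index=False)
        record(out / "diversity.tsv")
        if shared is not None:
            occ_rows = []
            for comp in shared.pair:
                o = _sharing.occupancy(pooled.subset(lineage="CD8"), shared, comp)
                for patient, pct in o.per_patient.items():
                    occ_rows.append(
                        {"compartment": comp, "patient": patient, "occupancy_pct": pct}
                    )
                occ_rows.append(
                    {"compartment": comp, "patient": "median", "occupancy_pct": o.median}
                )
            pd.DataFrame(occ_rows).to_csv(out / "occupancy.tsv", sep="\t", index=False)
            record(out / "occupancy.tsv")
        manifest["stages_run"].append("diversity")

    if "concordance" in stages and shared is not None:
        cell_clusters = {m.barcode: m.cluster_id for m in meta if m.cluster_id}
        cell_comps = {m.barcode: _clones.pooled_compartment(m.compartment) for m in meta}
        meta_map = _sim.default_meta_cluster_map("CD8")
        try:
            conc = _phen.concordance_table(
                pooled.subset(lineage="CD8"), shared, cell_clusters, meta_map, cell_comps
            )
            conc.to_csv(out / "concordance.tsv", sep="\t", index=False)
            record(out / "concordance.tsv")
            manifest["stages_run"].append("concordance")
        except (KeyError, ValueError) as err:
            log.warning("concordance stage skipped: %s", err)

    if "trm" in stages and simulate:
        sim_cfg_e = _sim.SimConfig(seed=root_seed)
        matrix, clusters, _ = _sim.simulate_expression(sim_cfg_e, stage_rng["trm"])
        decisions = _phen.classify_trm_clusters(
            matrix,
            clusters,
            _sim.core_trm_signature(),
            alpha=cfg["trm"]["alpha"],
            n_perm=cfg["trm"]["n_perm"],
            rng=np.random.default_rng([root_seed, 102]),
        )
        _phen.trm_decision_frame(decisions).to_csv(out / "trm_decisions.tsv", sep="\t", index=False)
        record(out / "trm_decisions.tsv")
        manifest["stages_run"].append("trm")

    if "de" in stages and simulate and shared is not None and table is not None:
        shared_bcs = {
            bc
            for c in pooled.subset(lineage="CD8").clones
            if c.clone_id in shared.clone_ids
            for bc in c.barcodes
        }
        skin_cd8 = [
            m.barcode for m in meta if m.lineage == "CD8" and m.compartment == "skin"
        ]
        skin_shared = [b for b in skin_cd8 if b in shared_bcs]
        skin_non = [b for b in skin_cd8 if b not in shared_bcs]
        if skin_shared and skin_non:
            sim_cfg_e = _sim.SimConfig(seed=root_seed)
            de_matrix, _, _ = _sim.simulate_expression(
                sim_cfg_e, stage_rng["de"], meta=list(meta), shared_barcodes=shared_bcs
            )
            de = _phen.shared_vs_nonshared_de(de_matrix, skin_shared, skin_non)
            de.to_csv(out / "de_shared_vs_nonshared_skin.tsv", sep="\t", index=False)
            record(out / "de_shared_vs_nonshared_skin.tsv")
            manifest["stages_run"].append("de")

    if "spatial" in stages and spatial_cells is not None:
        smap = _spatial.build_contact_graph(
            spatial_cells, method=cfg["spatial"]["method"], cap_um=cfg["spatial"]["cap_um"]
        )
        enr = _spatial.contact_enrichment(
            smap, n_perm=cfg["spatial"]["n_perm"], rng=stage_rng["spatial"]
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        edges = _spatial.composition_edges(smap)
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        record(out / "enrichment.tsv")
        record(out / "edges.tsv")
        manifest["stages_run"].append("spatial")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
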
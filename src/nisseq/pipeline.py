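"""End-to-end pipeline orchestration with provenance.

Runs simulate → align → call → match → assign → link → phenotype → screen
as one reproducible run from a YAML config, writing stage outputs as CSV
and a manifest with content hashes and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    PipelineParams,
    align_cycles,
    assign_spots_to_nuclei,
    build_index,
    call_stack,
    mapping_summary,
    match_nuclei,
    match_profiles,
    render_nis_scene,
    render_phenotype_scene,
    screen_test,
    segment_objects,
    simulate_library,
    speck_score,
    translocation_score,
)
from .assign import calls_to_frame
from .linking import FovPair, map_fov
from .simulate import NT_GENE, SimConfig

logger = logging.getLogger(__name__)

REQUIRED_SECTIONS = ("simulate", "screen")


class ConfigError(ValueError):
    pass


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    for section in REQUIRED_SECTIONS:
        if section not in cfg:
            raise ConfigError(f"config missing required section: {section!r}")
    return cfg


def run_pipeline(config_path, out_dir=None) -> dict:
    """Execute the full simulated-screen pipeline described by a YAML config.

    Returns the run manifest (also written to manifest.json in out_dir).
    """
    cfg = load_config(config_path)
    out = Path(out_dir or cfg.get("out_dir", "nisseq_run"))
    out.mkdir(parents=True, exist_ok=True)
    params = PipelineParams.from_dict(cfg.get("params", {}))
    seed = int(cfg.get("seed", 0))

    manifest: dict = {
        "config": cfg,
        "seed": seed,
        "stages": {},
        "outputs": {},
    }

    sim = cfg["simulate"]
    lib = simulate_library(
        n_genes=int(sim.get("n_genes", 10)),
        guides_per_gene=int(sim.get("guides_per_gene", 2)),
        n_nt=int(sim.get("n_nt", 4)),
        seed=seed,
    )
    lib_path = out / "library.csv"
    lib.entries.to_csv(lib_path, index=False)

    scene_cfg = SimConfig(
        n_nuclei=int(sim.get("n_nuclei", 120)),
        n_cycles=int(sim.get("n_cycles", 6)),
        noise_sd=float(sim.get("noise_sd", 0.0)),
        frac_unbarcoded=float(sim.get("frac_unbarcoded", 0.2)),
        drift_per_cycle=tuple(sim.get("drift_per_cycle", (1, -1))),
        seed=seed + 1,
    )
    stack, truth = render_nis_scene(lib, scene_cfg)
    truth.spots.to_csv(out / "truth_spots.csv", index=False)
    manifest["stages"]["simulate"] = {"n_nuclei": len(truth.nuclei), "n_spots": len(truth.spots)}

    aligned = align_cycles(stack, max_shift=params.max_shift)
    manifest["stages"]["align"] = {
        "shifts": [[s.dy, s.dx] for s in aligned.shifts]
    }

    profiles, crosstalk = call_stack(aligned, params)
    spots_df = pd.DataFrame(
        {
            "spot_id": [p.spot_id for p in profiles],
            "row": [p.position[0] for p in profiles],
            "col": [p.position[1] for p in profiles],
            "sequence": [p.sequence for p in profiles],
            "max_unmixed": [p.max_unmixed for p in profiles],
            "edge_flag": [p.edge_flag for p in profiles],
        }
    )
    spots_path = out / "spots.csv"
    spots_df.to_csv(spots_path, index=False)
    manifest["stages"]["call"] = {
        "n_spots": len(profiles),
        "crosstalk": np.round(crosstalk.M, 4).tolist(),
    }

    index = build_index(lib, scene_cfg.n_cycles)
    matches = match_profiles(profiles, index)
    spots_df["status"] = [m.status for m in matches]
    spots_df["guide_id"] = [m.guide_id for m in matches]
    spots_df["gene"] = [m.gene for m in matches]
    spots_df.to_csv(out / "matched.csv", index=False)
    manifest["stages"]["match"] = dict(
        pd.Series([m.status for m in matches]).value_counts().astype(int)
    )

    labels = segment_objects(aligned.nuclear[0], mode="nuclei")
    calls = assign_spots_to_nuclei(profiles, matches, labels, params)
    calls_to_frame(calls).to_csv(out / "nuclei.csv", index=False)
    summary = mapping_summary(calls, lib)
    manifest["stages"]["assign"] = {
        "n_nuclei": summary["n_nuclei"],
        "mapped_fraction": summary["mapped_fraction"],
        "status_fractions": summary["status_fractions"],
    }

    # phenotype the same field: planted speck effects for the first gene
    effects = {g: float(e) for g, e in cfg.get("effects", {}).items()}
    if not effects:
        effects = {lib.entries["gene"].iloc[0]: 0.6}
    pheno = render_phenotype_scene(
        truth,
        mode=cfg.get("phenotype_mode", "speck"),
        effects=effects,
        jitter_um=float(sim.get("jitter_um", 2.0)),
        seed=seed + 2,
    )
    pheno_labels = segment_objects(pheno["nuclear"], mode="nuclei")
    coarse, fine, corr = map_fov(pheno["nuclear"], aligned.nuclear[0], 1.0, params)
    pair = FovPair("pheno0", "fov0", 1.0, coarse, fine, corr)
    matched_cells = match_nuclei(
        pheno_labels, labels, pair, params, nis_pixel_size_um=scene_cfg.pixel_size_um
    )
    manifest["stages"]["link"] = {"n_matched_cells": len(matched_cells)}

    if pheno["mode"] == "speck":
        metrics = speck_score(pheno_labels, pheno["reporter"], params)
        metric_col, shift = "speck_ratio", 0.0
    else:
        metrics = translocation_score(
            pheno_labels, pheno["nuclear"], pheno["reporter"], params
        )
        metric_col, shift = "translocation_r", 1.0
    metrics.to_csv(out / "phenotypes.csv", index=False)

    nis_by_label = {c.label: c for c in calls if c.status == "assigned"}
    rows = []
    for mc in matched_cells:
        call = nis_by_label.get(mc.nis_label)
        if call is None:
            continue
        m = metrics[metrics["label"] == mc.pheno_label]
        if len(m) != 1 or not np.isfinite(m[metric_col].iloc[0]):
            continue
        rows.append(
            {
                "pheno_label": mc.pheno_label,
                "nis_label": mc.nis_label,
                "guide_id": call.guide_id,
                "gene": call.gene,
                "metric": float(m[metric_col].iloc[0]),
            }
        )
    cells = pd.DataFrame(rows)
    cells.to_csv(out / "matched_cells.csv", index=False)
    manifest["stages"]["phenotype"] = {"n_cells": len(cells)}

    scr = cfg["screen"]
    results_path = out / "gene_results.csv"
    if len(cells) and (cells["gene"] == NT_GENE).any():
        results = screen_test(
            cells.rename(columns={"metric": metric_col}),
            metric_col,
            nt_label=scr.get("nt_label", NT_GENE),
            params=params,
            metric_shift=shift,
        )
        results.to_csv(results_path, index=False)
        manifest["stages"]["screen"] = {
            "n_genes_tested": int(results["tested"].sum())
        }
    else:
        manifest["stages"]["screen"] = {"n_genes_tested": 0}

    for f in sorted(out.glob("*.csv")):
        manifest["outputs"][f.name] = _hash_file(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
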
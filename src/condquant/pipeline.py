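"""Stage implementations behind the command-line interface.

Each stage reads its inputs from the run directory (or from explicit paths
in the config), writes its artifacts into ``<outdir>/<stage>/`` and returns
the list of files written.  No stage mutates its inputs; reruns with the
same config and master seed reproduce deterministic artifacts byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc_profile, csi_motif, frap, puncta_quant, segmentation, synthetic_data
from ._runutils import stage_seed, write_manifest
from .io_images import ImageStack, read_stack, rescale_16bit, write_mask, write_stack

__all__ = ["DEFAULT_CONFIG", "merge_config", "run_stage", "run_all", "STAGES"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "box_size": 61,
    "central_size": 11,
    "volume_cutoff_um3": 200.0,
    "low_expression_fraction": 1.0 / 3.0,
    "k": 6,
    "loess_span": 0.3,
    "condition": "synthetic",
    "channels": {"reporter": "reporter", "partner": "partner", "dapi": "dapi"},
    "paths": {},
    "simulate": {"image": {}, "frap": {"n_cells": 19}, "selex": {}},
    "segmentation": {
        "min_volume_vox": 1000,
        "smoothing_sigma": 2.0,
        "threshold_quantile": 0.995,
        "min_spot_vox": 5,
    },
}

_REQUIRED_CHANNELS = ("reporter", "partner", "dapi")


def merge_config(user: dict | None) -> dict:
    """Overlay a user config onto the defaults (one level of nesting)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy, JSON-safe
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    missing = [c for c in _REQUIRED_CHANNELS if c not in cfg["channels"]]
    if missing:
        raise ValueError(f"channel role map is missing {missing}")
    return cfg


def _stage_dir(outdir: Path, stage: str) -> Path:
    d = Path(outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _load_stack(cfg: dict, outdir: Path) -> ImageStack:
    path = cfg["paths"].get("stack") or (Path(outdir) / "simulate" / "stack.ome.tif")
    return read_stack(path)


def stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "simulate")
    artifacts: list[Path] = []

    img_params = synthetic_data.SyntheticImageParams(
        **{**cfg["simulate"]["image"], "seed": stage_seed(cfg["seed"], "simulate-image")}
    )
    stack, truth = synthetic_data.generate_image(img_params)
    artifacts.append(write_stack(stack, d / "stack.ome.tif"))
    artifacts.append(truth.to_json(d / "ground_truth.json"))
    artifacts.append(write_mask(truth.nucleus_labels, d / "true_nuclei.tif"))

    frap_cfg = dict(cfg["simulate"]["frap"])
    n_cells = int(frap_cfg.pop("n_cells", 19))
    rows = []
    for i in range(n_cells):
        params = synthetic_data.SyntheticFrapParams(
            **{**frap_cfg, "seed": stage_seed(cfg["seed"], f"simulate-frap-{i}")}
        )
        trace, _ = synthetic_data.generate_frap(params)
        for j in range(len(trace.time)):
            rows.append(
                {
                    "cell_id": trace.cell_id,
                    "frame": j,
                    "time_s": trace.time[j],
                    "roi": trace.roi_mean[j],
                    "nucleus": trace.nucleus_mean[j],
                    "background": trace.background_mean[j],
                    "bleach_index": trace.bleach_index,
                }
            )
    frap_csv = d / "frap_traces.csv"
    pd.DataFrame(rows).to_csv(frap_csv, index=False)
    artifacts.append(frap_csv)

    selex_params = synthetic_data.SyntheticSelexParams(
        **{**cfg["simulate"]["selex"], "seed": stage_seed(cfg["seed"], "simulate-selex")}
    )
    paths, selex_truth = synthetic_data.generate_selex(selex_params, d / "selex")
    artifacts.extend(paths.values())
    design_json = d / "library_design.json"
    design_json.write_text(
        json.dumps(
            {
                "barcodes": selex_params.barcodes,
                "left_flank": selex_params.left_flank,
                "right_flank": selex_params.right_flank,
                "variable_length": selex_params.variable_length,
                "rounds": sorted({r for (_, r) in paths}),
                "positive_sample": selex_params.positive_sample,
                "negative_sample": selex_params.negative_sample,
                "motif": selex_truth["motif"],
            },
            indent=1,
        )
    )
    artifacts.append(design_json)
    return artifacts


def _segment(cfg: dict, outdir: Path):
    """Shared segmentation path: nuclei, puncta, PunctaSets."""
    stack = _load_stack(cfg, outdir)
    seg = cfg["segmentation"]
    ch = cfg["channels"]
    dapi = stack.channel(ch["dapi"])
    reporter = stack.channel(ch["reporter"])
    nuclei = segmentation.segment_nuclei(
        dapi, min_volume_vox=seg["min_volume_vox"], smoothing_sigma=seg["smoothing_sigma"]
    )
    mask_path = cfg["paths"].get("puncta_mask")
    reporter16 = rescale_16bit(reporter)
    if mask_path:
        puncta_mask = segmentation.import_puncta_mask(
            mask_path, nuclei, min_spot_vox=seg["min_spot_vox"]
        )
    else:
        puncta_mask = segmentation.segment_puncta_builtin(
            reporter16, nuclei,
            threshold_quantile=seg["threshold_quantile"],
            min_spot_vox=seg["min_spot_vox"],
        )
    puncta_sets = segmentation.extract_puncta(
        puncta_mask, nuclei, reporter, stack.voxel_size, condition=cfg["condition"]
    )
    return stack, nuclei, puncta_mask, puncta_sets


def stage_segment(cfg: dict, outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "segment")
    _, nuclei, puncta_mask, puncta_sets = _segment(cfg, outdir)
    artifacts = [
        write_mask(nuclei, d / "nuclei_mask.tif"),
        write_mask(puncta_mask, d / "puncta_mask.tif"),
    ]
    puncta_csv = d / "puncta.csv"
    segmentation.puncta_to_frame(puncta_sets).to_csv(puncta_csv, index=False)
    artifacts.append(puncta_csv)
    cells_csv = d / "cells.csv"
    pd.DataFrame(
        [
            {
                "nucleus_id": ps.cell.nucleus_id,
                "volume_um3": ps.cell.volume_um3,
                "n_puncta": len(ps.puncta),
                **{
                    f"mean_{k}": v
                    for k, v in ps.cell.mean_intensity_by_channel.items()
                },
            }
            for ps in puncta_sets
        ]
    ).to_csv(cells_csv, index=False)
    artifacts.append(cells_csv)
    return artifacts


def stage_quantify(cfg: dict, outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "quantify")
    _, _, _, puncta_sets = _segment(cfg, outdir)
    records = puncta_quant.compute_cell_metrics(puncta_sets, condition=cfg["condition"])
    kept, flagged = puncta_quant.apply_qc_filters(
        records,
        volume_cutoff_um3=cfg["volume_cutoff_um3"],
        low_expression_fraction=cfg["low_expression_fraction"],
    )
    qc_csv = d / "qc_records.csv"
    puncta_quant.records_to_frame(kept + flagged).to_csv(qc_csv, index=False)
    summary_csv = d / "condition_summary.csv"
    puncta_quant.condition_summary(kept).to_csv(summary_csv, index=False)
    return [qc_csv, summary_csv]


def _profile_pair(cfg: dict, outdir: Path, center_sets, target: np.ndarray,
                  target_label: str, mode: str, seed: int):
    box = cfg["box_size"]
    matrices, skipped = coloc_profile.condensate_profiles(center_sets, target, box)
    if not matrices:
        raise RuntimeError("no usable loci for profiling")
    centered = coloc_profile.average_profiles(matrices, mode=mode, channel=target_label)
    null_mats, loci = coloc_profile.null_profiles(center_sets, target, box, seed=seed)
    null = coloc_profile.average_profiles(null_mats, mode="random-null",
                                          channel=target_label)
    meta = {
        "n_loci": centered.n_loci,
        "n_null_loci": null.n_loci,
        "n_skipped_border": skipped,
        "centered_summary": dataclasses.asdict(
            coloc_profile.enrichment_summary(centered, cfg["central_size"])
        ),
        "null_summary": dataclasses.asdict(
            coloc_profile.enrichment_summary(null, cfg["central_size"])
        ),
    }
    return centered, null, meta


def stage_coloc(cfg: dict, outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "coloc")
    stack, _, _, puncta_sets = _segment(cfg, outdir)
    partner = stack.channel(cfg["channels"]["partner"])
    centered, null, meta = _profile_pair(
        cfg, outdir, puncta_sets, partner, "partner",
        "condensate-centered", stage_seed(cfg["seed"], "coloc-null"),
    )
    artifacts = [
        centered.save_csv(d / "condensate_profile.csv"),
        null.save_csv(d / "null_profile.csv"),
    ]
    meta_path = d / "coloc_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    artifacts.append(meta_path)
    return artifacts


def stage_fish(cfg: dict, outdir: Path) -> list[Path]:
    """FISH-locus-centered profiling: the partner channel plays the FISH
    probe, boxes gather reporter intensities."""
    d = _stage_dir(outdir, "fish")
    stack, nuclei, _, _ = _segment(cfg, outdir)
    seg = cfg["segmentation"]
    fish_chan = stack.channel(cfg["channels"]["partner"])
    reporter = stack.channel(cfg["channels"]["reporter"])
    fish_mask = segmentation.segment_puncta_builtin(
        rescale_16bit(fish_chan), nuclei,
        threshold_quantile=seg["threshold_quantile"],
        min_spot_vox=seg["min_spot_vox"],
    )
    fish_sets = segmentation.extract_puncta(
        fish_mask, nuclei, fish_chan, stack.voxel_size, condition=cfg["condition"]
    )
    fish_profile, fish_null = coloc_profile.fish_locus_profiles(
        fish_sets, reporter, box_size=cfg["box_size"],
        seed=stage_seed(cfg["seed"], "fish-null"),
    )
    artifacts = [
        fish_profile.save_csv(d / "fish_profile.csv"),
        fish_null.save_csv(d / "fish_null.csv"),
    ]
    meta = {
        "n_loci": fish_profile.n_loci,
        "centered_summary": dataclasses.asdict(
            coloc_profile.enrichment_summary(fish_profile, cfg["central_size"])
        ),
        "null_summary": dataclasses.asdict(
            coloc_profile.enrichment_summary(fish_null, cfg["central_size"])
        ),
    }
    meta_path = d / "fish_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    artifacts.append(meta_path)
    return artifacts


def stage_frap(cfg: dict, outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "frap")
    traces_csv = cfg["paths"].get("frap_traces") or (
        Path(outdir) / "simulate" / "frap_traces.csv"
    )
    df = pd.read_csv(traces_csv)
    traces = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        raw = frap.FrapTrace(
            time=grp["time_s"].to_numpy(),
            roi_mean=grp["roi"].to_numpy(),
            nucleus_mean=grp["nucleus"].to_numpy(),
            background_mean=grp["background"].to_numpy(),
            bleach_index=int(grp["bleach_index"].iloc[0]),
            cell_id=str(cell_id),
        )
        traces.append(frap.normalize_frap(raw))
    ensemble = frap.aggregate_frap(traces, loess_span=cfg["loess_span"])
    fit = frap.fit_recovery(ensemble)
    ens_csv = d / "frap_ensemble.csv"
    ensemble.to_frame().to_csv(ens_csv, index=False)
    percell_csv = d / "frap_normalized.csv"
    pd.concat(
        [
            pd.DataFrame({"cell_id": tr.cell_id, "time_s": tr.time, "value": tr.value})
            for tr in traces
        ]
    ).to_csv(percell_csv, index=False)
    fit_json = d / "frap_fit.json"
    fit_json.write_text(json.dumps({**fit, "n_cells": ensemble.n_cells}, indent=1))
    return [ens_csv, percell_csv, fit_json]


def stage_csi(cfg: dict, outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "csi")
    design_path = cfg["paths"].get("library_design") or (
        Path(outdir) / "simulate" / "library_design.json"
    )
    spec = json.loads(Path(design_path).read_text())
    design = csi_motif.LibraryDesign(
        barcodes=spec["barcodes"],
        left_flank=spec["left_flank"],
        right_flank=spec["right_flank"],
        variable_length=spec["variable_length"],
        rounds=tuple(spec["rounds"]),
    )
    pos_name, neg_name = spec["positive_sample"], spec["negative_sample"]
    fastq_dir = cfg["paths"].get("fastq_dir") or (Path(outdir) / "simulate" / "selex")
    fastq_dir = Path(fastq_dir)

    k = cfg["k"]
    pos_tables, neg_tables = {}, {}
    report = {"rounds": {}, "k": k}
    for r in design.rounds:
        tables = {}
        for sample in (pos_name, neg_name):
            path = fastq_dir / f"{sample}_round{r}.fastq.gz"
            reads, tally = csi_motif.demultiplex([path], design)
            regions, rejected = csi_motif.extract_regions(
                reads[sample], design, barcode_length=len(design.barcodes[sample])
            )
            tables[sample] = csi_motif.count_kmers(regions, k=k, sample=sample, round=r)
            report["rounds"][f"{sample}_r{r}"] = {**tally, "rejected_region": rejected}
        pos_tables[r], neg_tables[r] = tables[pos_name], tables[neg_name]

    artifacts = []
    for r in design.rounds:
        tsv = d / f"enrichment_round{r}.tsv"
        csi_motif.compute_enrichment(pos_tables[r], neg_tables[r]).to_csv(
            tsv, sep="\t", index=False
        )
        artifacts.append(tsv)
    traj_tsv = d / "round_trajectory.tsv"
    traj = csi_motif.round_trajectory(pos_tables, neg_tables)
    traj.to_csv(traj_tsv, sep="\t", index=False)
    artifacts.append(traj_tsv)

    final = csi_motif.compute_enrichment(
        pos_tables[design.rounds[-1]], neg_tables[design.rounds[-1]]
    )
    top = final.iloc[0]
    report["top_motif"] = {
        "kmer": top["kmer"],
        "enrichment": float(top["enrichment"]),
        "round": int(design.rounds[-1]),
    }
    report_json = d / "csi_report.json"
    report_json.write_text(json.dumps(report, indent=1))
    artifacts.append(report_json)
    summary = d / "top_motif.txt"
    summary.write_text(
        f"top {k}-mer in round {design.rounds[-1]}: {top['kmer']} "
        f"(enrichment {top['enrichment']:.3f} over the fusion-negative pool)\n"
    )
    artifacts.append(summary)
    return artifacts


STAGES = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "quantify": stage_quantify,
    "coloc": stage_coloc,
    "fish": stage_fish,
    "frap": stage_frap,
    "csi": stage_csi,
}


def run_stage(name: str, cfg: dict, outdir: str | Path) -> list[Path]:
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; have {sorted(STAGES)}")
    return STAGES[name](cfg, Path(outdir))


def run_all(cfg: dict, outdir: str | Path) -> Path:
    """Run every stage in order and write the reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    order = ["simulate", "segment", "quantify", "coloc", "fish", "frap", "csi"]
    for name in order:
        artifacts.extend(STAGES[name](cfg, outdir))
    seeds = {f"{name}": stage_seed(cfg["seed"], name) for name in order}
    return write_manifest(outdir, cfg, {"master": cfg["seed"], **seeds}, artifacts)
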
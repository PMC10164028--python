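"""Text-based persistence for study datasets and run artifacts.

Everything is plain text: time series and motion as TSV, metadata as JSON.
A study directory holds one TSV per (group, subject, condition, block) plus
a single ``manifest.json`` with ages, ground truth and the simulation config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np

from .parcellation import ParcellationTable, load_parcellation
from .synthetic import (BlockRecord, EffectSpec, MotionParams, ROITimeSeries,
                        SimulationConfig, StudyDataset)


def sim_config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    if d["effects"] is not None:
        d["effects"] = [dataclasses.asdict(e) for e in config.effects]
    d["n_subjects"] = dict(d["n_subjects"])
    d["group_scale"] = dict(d["group_scale"])
    d["age_mean_sd"] = {k: list(v) for k, v in d["age_mean_sd"].items()}
    return d


def sim_config_from_dict(d: dict[str, Any]) -> SimulationConfig:
    d = dict(d)
    if d.get("effects") is not None:
        d["effects"] = tuple(EffectSpec(**e) for e in d["effects"])
    if "age_mean_sd" in d:
        d["age_mean_sd"] = {k: tuple(v) for k, v in d["age_mean_sd"].items()}
    return SimulationConfig(**d)


def config_hash(payload: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _block_stem(b: BlockRecord) -> str:
    return f"{b.group}_{b.subject}_{b.condition}_{b.block}"


def save_study(study: StudyDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.parcellation.to_frame().to_csv(
        outdir / "parcellation.tsv", sep="\t", index=False)
    blocks_meta = []
    for b in study.blocks:
        stem = _block_stem(b)
        np.savetxt(outdir / f"ts_{stem}.tsv", b.ts.values,
                   delimiter="\t", fmt="%.8g")
        if b.motion is not None:
            np.savetxt(outdir / f"motion_{stem}.tsv", b.motion.values,
                       delimiter="\t", fmt="%.8g")
        if b.confounds is not None:
            np.savetxt(outdir / f"confounds_{stem}.tsv", b.confounds,
                       delimiter="\t", fmt="%.8g")
        blocks_meta.append({
            "group": b.group, "subject": b.subject, "condition": b.condition,
            "block": b.block, "usable": bool(b.usable), "tr": b.ts.tr,
            "has_motion": b.motion is not None,
            "has_confounds": b.confounds is not None,
        })
    manifest = {
        "blocks": blocks_meta,
        "ages": {f"{g}|{s}": a for (g, s), a in study.ages.items()},
        "true_dz": {g: v.tolist() for g, v in study.true_dz.items()},
        "config": sim_config_to_dict(study.config) if study.config else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest))


def load_study(indir: str | Path) -> StudyDataset:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    parcellation = load_parcellation(indir / "parcellation.tsv")
    blocks = []
    for meta in manifest["blocks"]:
        stem = f"{meta['group']}_{meta['subject']}_{meta['condition']}_{meta['block']}"
        values = np.loadtxt(indir / f"ts_{stem}.tsv", delimiter="\t", ndmin=2)
        ts = ROITimeSeries(values=values, tr=meta["tr"])
        motion = None
        if meta["has_motion"]:
            motion = MotionParams(values=np.loadtxt(
                indir / f"motion_{stem}.tsv", delimiter="\t", ndmin=2))
        confounds = None
        if meta["has_confounds"]:
            confounds = np.loadtxt(indir / f"confounds_{stem}.tsv",
                                   delimiter="\t", ndmin=2)
        blocks.append(BlockRecord(
            group=meta["group"], subject=meta["subject"],
            condition=meta["condition"], block=meta["block"],
            ts=ts, motion=motion, confounds=confounds,
            usable=meta["usable"]))
    ages = {tuple(k.split("|")): float(v)
            for k, v in manifest["ages"].items()}
    true_dz = {g: np.array(v) for g, v in manifest["true_dz"].items()}
    config = (sim_config_from_dict(manifest["config"])
              if manifest.get("config") else None)
    return StudyDataset(blocks=blocks, ages=ages, true_dz=true_dz,
                        parcellation=parcellation, config=config)
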
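"""End-to-end orchestration: synth → segment → voxelize → solve →
dielectric → (optional) uq, with file-based interchange and a run manifest.

Each stage writes its outputs under the run directory and is skipped on
rerun when its outputs already exist (resume-from-cache); the manifest
records the config snapshot, seeds, per-stage timings and a content hash
of every output file, so identical configs reproduce identical data.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from . import __version__
from .dielectric import extract_dielectric
from .geometry import voxelize_geometry
from .segmentation import SegmentationConfig, segment_stack
from .solver import MaterialProps, frequency_sweep
from .synthetic import NOISE_PRESETS, NoiseModel, render_stack, sample_population
from .uq import run_case1, run_case2

DEFAULT_CONFIG = {
    "seed": 0,
    "synth": {
        "n_cells": 2,
        "box": [60.0, 60.0, 60.0],
        "voxel_size": [0.5, 0.5, 0.5],
        "noise_preset": "clean",
        "allow_touching": False,
        "volume_mean": 2157.0,
        "volume_sd": 957.0,
    },
    "segment": {},
    "voxelize": {"voxel_size": 1.0, "electrode_axis": 0},
    "solve": {"f_min": 1e3, "f_max": 1e12, "points_per_decade": 10, "tol": 1e-10},
    "uq": None,  # or {"case": 1, ...}
}


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def record(self, stage: str, seconds: float, files: list[Path]) -> None:
        self.stages[stage] = {"seconds": round(seconds, 3)}
        for f in files:
            self.outputs[str(f.name)] = cio.sha256_of(f)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=1, default=str))


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def validate_config(config: dict) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if cfg["synth"]["n_cells"] < 0:
        raise ValueError("synth.n_cells must be non-negative")
    if cfg["synth"]["noise_preset"] not in NOISE_PRESETS:
        raise ValueError(f"unknown noise preset {cfg['synth']['noise_preset']!r}")
    if cfg["uq"] is not None and cfg["uq"].get("case") not in (1, 2):
        raise ValueError("uq.case must be 1 or 2")
    return cfg


def run_pipeline(config: dict | str | Path, outdir: str | Path, force: bool = False) -> RunManifest:
    """Execute the pipeline stages in order, resuming from cached outputs.

    On a stage failure the manifest records the failure point and the
    downstream stages are skipped.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=cfg)
    seed = int(cfg["seed"])

    try:
        # --- synth ------------------------------------------------------
        t0 = time.perf_counter()
        stack_path = outdir / "stack.tif"
        gt_path = outdir / "labels_gt.tif"
        s = cfg["synth"]
        if force or not (stack_path.exists() and gt_path.exists()):
            cells = sample_population(
                s["n_cells"], s["box"],
                volume_mean=s["volume_mean"], volume_sd=s["volume_sd"],
                allow_touching=s["allow_touching"], seed=seed,
            )
            preset = NOISE_PRESETS[s["noise_preset"]]
            noise = NoiseModel(**{**preset.__dict__,
                                  "illumination_gradient": preset.illumination_gradient.tolist(),
                                  "seed": seed})
            stack, gt = render_stack(cells, s["voxel_size"], noise, box=s["box"])
            cio.save_stack(stack_path, stack, extra={"seed": seed, "config": s})
            cio.save_labels(gt_path, gt)
            cio.ellipsoids_to_csv(outdir / "cells_gt.csv", cells)
        manifest.record("synth", time.perf_counter() - t0,
                        [stack_path, gt_path, outdir / "cells_gt.csv"])

        # --- segment ----------------------------------------------------
        t0 = time.perf_counter()
        labels_path = outdir / "labels_pred.tif"
        cells_path = outdir / "cells_pred.csv"
        if force or not (labels_path.exists() and cells_path.exists()):
            stack = cio.load_stack(stack_path)
            seg_cfg = SegmentationConfig(**cfg["segment"])
            labels, fitted = segment_stack(stack, seg_cfg)
            cio.save_labels(labels_path, labels)
            cio.ellipsoids_to_csv(cells_path, fitted)
        manifest.record("segment", time.perf_counter() - t0, [labels_path, cells_path])

        # --- voxelize ---------------------------------------------------
        t0 = time.perf_counter()
        geom_dir = outdir / "geom"
        v = cfg["voxelize"]
        if force or not (geom_dir / "materials.tif").exists():
            fitted = cio.ellipsoids_from_csv(cells_path, box=s["box"])
            geom = voxelize_geometry(fitted, s["box"], v["voxel_size"], v["electrode_axis"])
            cio.save_geometry(geom_dir, geom)
        manifest.record("voxelize", time.perf_counter() - t0,
                        [geom_dir / "materials.tif", geom_dir / "geometry.json"])

        # --- solve + dielectric ----------------------------------------
        t0 = time.perf_counter()
        spec_path = outdir / "spectrum.csv"
        diel_path = outdir / "dielectric.csv"
        geom = cio.load_geometry(geom_dir)
        if force or not (spec_path.exists() and diel_path.exists()):
            so = cfg["solve"]
            props = MaterialProps()
            spec = frequency_sweep(
                geom, props, so["f_min"], so["f_max"], so["points_per_decade"],
                tol=so["tol"],
            )
            cio.spectrum_to_csv(spec_path, spec)
            sep = geom.box[geom.electrode_axis] * 1e-6
            trans = [a for a in range(3) if a != geom.electrode_axis]
            area = geom.box[trans[0]] * geom.box[trans[1]] * 1e-12
            cio.dielectric_to_csv(diel_path, extract_dielectric(spec, sep, area))
        manifest.record("solve", time.perf_counter() - t0, [spec_path])
        manifest.record("dielectric", 0.0, [diel_path])

        # --- uq (optional) ----------------------------------------------
        if cfg["uq"] is not None:
            t0 = time.perf_counter()
            uq_path = outdir / "uq_results.csv"
            if force or not uq_path.exists():
                u = dict(cfg["uq"])
                case = u.pop("case")
                u.setdefault("seed", seed)
                if "frequencies" in u:
                    u["frequencies"] = np.asarray(u["frequencies"], dtype=float)
                if case == 1:
                    res = run_case1(**u)
                else:
                    res = run_case2(geom, **u)
                cio.uq_result_to_csv(uq_path, res)
            manifest.record("uq", time.perf_counter() - t0, [uq_path])
    except Exception as err:  # noqa: BLE001 - failure point recorded
        manifest.failed_stage = f"{type(err).__name__}: {err}"
        manifest.save(outdir / "manifest.json")
        raise

    manifest.save(outdir / "manifest.json")
    return manifest
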
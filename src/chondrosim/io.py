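"""File interchange: multi-page TIFF stacks, CSV tables, STL meshes, JSON.

Every pipeline stage is consumable standalone with these files as the only
interchange.  Stacks and label volumes are 16-bit multi-page TIFFs with a
JSON sidecar recording voxel size and provenance; ellipsoid tables use the
geometric-input-file convention: columns label, cx, cy, cz, a, b, c and
z-y-x Euler angles in degrees (lengths in µm).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh
from scipy.spatial.transform import Rotation

from .dielectric import DielectricSpectrum
from .geometry import TissueGeometry
from .solver import ImpedanceSpectrum, TMPMap
from .types import EllipsoidCell, EllipsoidSet, ImageStack, LabeledVolume
from .uq import UQResult


def sha256_of(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stack(path: Path | str, stack: ImageStack, extra: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.data)
    meta = {
        "voxel_size_um": list(stack.voxel_size),
        "bit_depth": stack.bit_depth,
        **(extra or {}),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_stack(path: Path | str) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return ImageStack(data, np.asarray(meta["voxel_size_um"]), meta.get("bit_depth", 16))


def save_labels(path: Path | str, labels: LabeledVolume, extra: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.int32))
    meta = {"voxel_size_um": list(labels.voxel_size), **(extra or {})}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_labels(path: Path | str) -> LabeledVolume:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return LabeledVolume(data.astype(np.int32), np.asarray(meta["voxel_size_um"]))


ELLIPSOID_COLUMNS = [
    "label", "cx", "cy", "cz", "a", "b", "c",
    "euler_z_deg", "euler_y_deg", "euler_x_deg",
]


def ellipsoids_to_csv(path: Path | str, cells: EllipsoidSet) -> None:
    rows = []
    for c in cells:
        ang = Rotation.from_matrix(c.rotation).as_euler("zyx", degrees=True)
        rows.append(
            {
                "label": c.label,
                "cx": c.center[2],
                "cy": c.center[1],
                "cz": c.center[0],
                "a": c.semi_axes[0],
                "b": c.semi_axes[1],
                "c": c.semi_axes[2],
                "euler_z_deg": ang[0],
                "euler_y_deg": ang[1],
                "euler_x_deg": ang[2],
            }
        )
    pd.DataFrame(rows, columns=ELLIPSOID_COLUMNS).to_csv(path, index=False)


def ellipsoids_from_csv(path: Path | str, box=None) -> EllipsoidSet:
    df = pd.read_csv(path)
    cells = []
    for _, r in df.iterrows():
        rot = Rotation.from_euler(
            "zyx", [r.euler_z_deg, r.euler_y_deg, r.euler_x_deg], degrees=True
        ).as_matrix()
        cells.append(
            EllipsoidCell(
                np.array([r.cz, r.cy, r.cx]),
                np.array([r.a, r.b, r.c]),
                rot,
                int(r.label),
            )
        )
    return EllipsoidSet(cells, None if box is None else np.asarray(box, dtype=float))


def spectrum_to_csv(path: Path | str, spec: ImpedanceSpectrum) -> None:
    pd.DataFrame(
        {
            "frequency_Hz": spec.frequencies,
            "ReZ_Ohm": spec.Z.real,
            "ImZ_Ohm": spec.Z.imag,
        }
    ).to_csv(path, index=False)


def spectrum_from_csv(path: Path | str, v_applied: float = 1.0) -> ImpedanceSpectrum:
    df = pd.read_csv(path)
    return ImpedanceSpectrum(
        df.frequency_Hz.values, df.ReZ_Ohm.values + 1j * df.ImZ_Ohm.values, v_applied
    )


def dielectric_to_csv(path: Path | str, diel: DielectricSpectrum) -> None:
    pd.DataFrame(
        {
            "frequency_Hz": diel.frequencies,
            "sigma_eff_S_per_m": diel.sigma_eff,
            "eps_r_eff": diel.eps_r_eff,
        }
    ).to_csv(path, index=False)


def tmp_to_csv(path: Path | str, tmp: TMPMap) -> None:
    pd.DataFrame(
        {
            "x_um": tmp.coords[:, 2],
            "y_um": tmp.coords[:, 1],
            "z_um": tmp.coords[:, 0],
            "ReTMP_V": tmp.tmp.real,
            "ImTMP_V": tmp.tmp.imag,
        }
    ).to_csv(path, index=False)


def save_geometry(dirpath: Path | str, geom: TissueGeometry) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(dirpath / "materials.tif", geom.materials)
    (dirpath / "geometry.json").write_text(
        json.dumps(
            {
                "voxel_size_um": list(geom.voxel_size),
                "electrode_axis": geom.electrode_axis,
            },
            indent=1,
        )
    )


def load_geometry(dirpath: Path | str) -> TissueGeometry:
    dirpath = Path(dirpath)
    meta = json.loads((dirpath / "geometry.json").read_text())
    materials = tifffile.imread(dirpath / "materials.tif")
    return TissueGeometry(
        materials, np.asarray(meta["voxel_size_um"]), meta["electrode_axis"]
    )


def save_meshes_stl(path: Path | str, meshes: dict[int, trimesh.Trimesh]) -> None:
    combined = trimesh.util.concatenate(list(meshes.values()))
    combined.export(path)


def uq_result_to_csv(path: Path | str, res: UQResult) -> None:
    """Tidy layout: one row per (frequency, quantity) with mean, percentiles
    and one Sobol column per parameter."""
    rows = []
    for qi, qty in enumerate(res.quantities):
        for fi, f in enumerate(res.frequencies):
            row = {
                "frequency_Hz": f,
                "quantity": qty,
                "mean": res.mean[qi, fi],
                "variance": res.variance[qi, fi],
                "p5": res.p5[qi, fi],
                "p95": res.p95[qi, fi],
            }
            for pi, pname in enumerate(res.parameter_names):
                row[f"sobol_{pname}"] = res.sobol[pi, qi, fi]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
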
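"""NIfTI / TSV / JSON interchange for geometries, masks, maps and phenotypes.

The template grid convention: 0-based voxel indices, isotropic voxels, voxel
center at (index + 0.5) x voxel_size mm, half-open volume bounds.  The NIfTI
affine is the corresponding diagonal scaling.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectome_db import MAX_SLOTS, FiberGeometry, SubjectRecord

PHENOTYPE_COLUMNS = ("id", "group", "ppvt4", "evt2", "wnv", "celfp")


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def save_volume(data: np.ndarray, voxel_size: float, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel_size = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj, dtype=float), voxel_size


def save_mask(mask: np.ndarray, voxel_size: float, path: str | Path) -> None:
    save_volume(np.asarray(mask, dtype=np.uint8), voxel_size, path)


def load_mask(path: str | Path) -> np.ndarray:
    data, _ = load_volume(path)
    return data > 0.5


def save_geometry(geometry: FiberGeometry, directory: str | Path) -> None:
    """Geometry = direction NIfTI (3 x slots components) + QA NIfTI + sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dirs_flat = geometry.directions.reshape(*geometry.dims, MAX_SLOTS * 3)
    save_volume(np.nan_to_num(dirs_flat), geometry.voxel_size, directory / "directions.nii.gz")
    save_volume(geometry.template_qa, geometry.voxel_size, directory / "template_qa.nii.gz")
    if geometry.slot_qa is not None:
        save_volume(geometry.slot_qa, geometry.voxel_size, directory / "slot_qa.nii.gz")
    sidecar = {
        "dims": list(geometry.dims),
        "voxel_size": geometry.voxel_size,
        "max_slots": MAX_SLOTS,
        "n_dirs_encoding": "n_dirs.nii.gz",
    }
    save_volume(geometry.n_dirs.astype(np.float32), geometry.voxel_size, directory / "n_dirs.nii.gz")
    (directory / "geometry.json").write_text(json.dumps(sidecar, indent=1))


def load_geometry(directory: str | Path) -> FiberGeometry:
    directory = Path(directory)
    sidecar = json.loads((directory / "geometry.json").read_text())
    dims = tuple(sidecar["dims"])
    voxel_size = float(sidecar["voxel_size"])
    dirs_flat, _ = load_volume(directory / "directions.nii.gz")
    directions = dirs_flat.reshape(*dims, MAX_SLOTS, 3)
    n_dirs, _ = load_volume(directory / "n_dirs.nii.gz")
    n_dirs = n_dirs.astype(np.uint8)
    qa, _ = load_volume(directory / "template_qa.nii.gz")
    slot_qa = None
    if (directory / "slot_qa.nii.gz").exists():
        slot_qa, _ = load_volume(directory / "slot_qa.nii.gz")
    # restore NaN padding in unused slots
    slots = np.arange(MAX_SLOTS)[None, None, None, :]
    absent = slots >= n_dirs[..., None]
    directions[absent] = np.nan
    return FiberGeometry(
        dims=dims,
        voxel_size=voxel_size,
        directions=directions,
        n_dirs=n_dirs,
        template_qa=qa,
        slot_qa=slot_qa,
    )


def save_phenotypes(records: list[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"id": r.id, "group": r.group}
        for col in PHENOTYPE_COLUMNS[2:]:
            row[col] = r.scores.get(col, np.nan)
        rows.append(row)
    pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS)).to_csv(path, sep="\t", index=False)


def load_phenotypes(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        scores = {
            col: float(row[col])
            for col in PHENOTYPE_COLUMNS[2:]
            if col in df.columns and pd.notna(row[col])
        }
        records.append(SubjectRecord(id=str(row["id"]), group=str(row["group"]), scores=scores))
    return records


def save_feature_tsv(values: np.ndarray, geometry: FiberGeometry, path: str | Path) -> None:
    """Per-feature table: voxel indices, slot, direction, value."""
    ijk, slot, vec = geometry.feature_table()
    df = pd.DataFrame(
        {
            "i": ijk[:, 0],
            "j": ijk[:, 1],
            "k": ijk[:, 2],
            "slot": slot,
            "dx": vec[:, 0],
            "dy": vec[:, 1],
            "dz": vec[:, 2],
            "value": np.asarray(values, dtype=float),
        }
    )
    df.to_csv(path, sep="\t", index=False)
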
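"""Dose grids and structure masks.

Axis convention: arrays are indexed ``(x, y, z)`` with x = left-right,
y = anterior-posterior, z = superior-inferior, all in patient-space mm.
Voxel *centers* sit at ``origin_mm + index * spacing_mm``; a mask voxel is
inside a structure when its center is inside the region (no partial-volume
weighting — structure volumes are whole-voxel counts times voxel volume).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DoseGrid", "StructureMask", "read_dose", "write_dose",
           "read_masks", "write_masks"]


@dataclass
class DoseGrid:
    """A 3-D scalar dose field (Gy) on a regular grid.

    Parameters
    ----------
    values
        Dose array, shape ``(nx, ny, nz)``, finite and non-negative.
    spacing_mm
        Per-axis voxel size in mm, all positive.
    origin_mm
        Patient-space position of the first voxel center.
    frame_id
        Free-text label of the frame of reference.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_id: str = "phantom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def same_geometry(self, other: "DoseGrid | StructureMask") -> bool:
        shape = other.mask.shape if isinstance(other, StructureMask) else other.shape
        return self.shape == tuple(shape)

    def copy_with(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(values, self.spacing_mm, self.origin_mm, self.frame_id)


@dataclass
class StructureMask:
    """A named boolean voxel set aligned to a :class:`DoseGrid`."""

    name: str
    mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask {self.name!r} must be 3-D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing_mm)) / 1000.0

    def require_nonempty(self) -> None:
        if self.voxel_count == 0:
            raise ValueError(f"structure {self.name!r} has no voxels")


# ---------------------------------------------------------------------------
# Text interchange IO
#
# Dose: <stem>.json header {shape, spacing_mm, origin_mm, frame_id, dtype}
#       next to <stem>.raw (C-order float32/float64 little-endian).
# Masks: one JSON file; each structure stored run-length encoded over the
#       flattened C-order boolean array as [run0, run1, ...] starting with
#       the length of the initial False run.
# ---------------------------------------------------------------------------

def write_dose(grid: DoseGrid, stem: str | Path) -> None:
    stem = Path(stem)
    header = {
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing_mm),
        "origin_mm": list(grid.origin_mm),
        "frame_id": grid.frame_id,
        "dtype": "float32",
        "order": "C",
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1))
    grid.values.astype("<f4").tofile(stem.with_suffix(".raw"))


def read_dose(stem: str | Path) -> DoseGrid:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    values = np.fromfile(stem.with_suffix(".raw"), dtype="<" + {"float32": "f4", "float64": "f8"}[header["dtype"]])
    values = values.reshape(header["shape"]).astype(np.float64)
    return DoseGrid(values, header["spacing_mm"], header["origin_mm"], header.get("frame_id", ""))


def _rle_encode(flat: np.ndarray) -> list[int]:
    # runs alternate False/True, first entry is the initial False run (may be 0)
    changes = np.flatnonzero(np.diff(flat))
    edges = np.concatenate(([0], changes + 1, [flat.size]))
    runs = np.diff(edges).tolist()
    if flat.size and flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: list[int], size: int) -> np.ndarray:
    flat = np.zeros(size, dtype=bool)
    pos, val = 0, False
    for run in runs:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    if pos != size:
        raise ValueError("run-length data does not match mask size")
    return flat


def write_masks(masks: dict[str, StructureMask], path: str | Path) -> None:
    any_mask = next(iter(masks.values()))
    doc = {
        "shape": list(any_mask.mask.shape),
        "spacing_mm": list(any_mask.spacing_mm),
        "structures": {name: _rle_encode(m.mask.ravel()) for name, m in masks.items()},
    }
    Path(path).write_text(json.dumps(doc))


def read_masks(path: str | Path) -> dict[str, StructureMask]:
    doc = json.loads(Path(path).read_text())
    shape = tuple(doc["shape"])
    size = int(np.prod(shape))
    spacing = tuple(doc["spacing_mm"])
    return {
        name: StructureMask(name, _rle_decode(runs, size).reshape(shape), spacing)
        for name, runs in doc["structures"].items()
    }
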
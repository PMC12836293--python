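"""Setup-uncertainty robustness analysis.

The canonical scenario set holds 30 rigid perturbations: 18 translations
(+-2, +-3, +-5 mm along each of LR, AP, SI) and 12 rotations (+-1, +-2
degrees of pitch, yaw and roll). Perturbed doses are produced by rigidly
transforming the static dose grid relative to the structure frame
(translation, then intrinsic rotations about the cranial isocenter) with
trilinear resampling — the standard isocenter-shift surrogate for a full
re-computation; it ignores surface-curvature dose changes.

The robustness index for a DVH metric over a scenario group is
``lambda = (best - worst) / nominal x 100`` where best/worst are the
extremes of the metric across the group's scenarios (nominal excluded).
A smaller lambda means a more robust plan.

Rotation convention: pitch about the LR (x) axis, yaw about the AP (y)
axis, roll about the SI (z) axis, applied intrinsically roll-pitch-yaw.
Voxels mapping outside the original grid take the nearest-edge value; the
out-of-field fraction inside each evaluated structure is reported and a
warning is attached when it exceeds 5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .dvh import CumulativeDVH, DoseMetricSpec, compute_dvh, dose_metric
from .grids import DoseGrid, StructureMask

__all__ = ["PerturbationScenario", "canonical_scenarios", "perturb_dose",
           "lambda_index", "robustness_study"]

TRANSLATION_MM = (2.0, 3.0, 5.0)
ROTATION_DEG = (1.0, 2.0)
_AXES = ("LR", "AP", "SI")          # x, y, z
_ROT_AXES = ("pitch", "yaw", "roll")  # about x, y, z


@dataclass(frozen=True)
class PerturbationScenario:
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)  # pitch, yaw, roll
    label: str = "nominal"
    group: str = "nominal"

    @property
    def is_identity(self) -> bool:
        return not (any(self.translation_mm) or any(self.rotation_deg))


def canonical_scenarios() -> list[PerturbationScenario]:
    """The 30 canonical setup-error scenarios, grouped by magnitude."""
    scenarios = []
    for mag in TRANSLATION_MM:
        for axis in range(3):
            for sign in (+1.0, -1.0):
                t = [0.0, 0.0, 0.0]
                t[axis] = sign * mag
                scenarios.append(PerturbationScenario(
                    tuple(t), (0.0, 0.0, 0.0),
                    label=f"{_AXES[axis]}{sign * mag:+g}mm",
                    group=f"+-{mag:g}mm"))
    for mag in ROTATION_DEG:
        for axis in range(3):
            for sign in (+1.0, -1.0):
                r = [0.0, 0.0, 0.0]
                r[axis] = sign * mag
                scenarios.append(PerturbationScenario(
                    (0.0, 0.0, 0.0), tuple(r),
                    label=f"{_ROT_AXES[axis]}{sign * mag:+g}deg",
                    group=f"+-{mag:g}deg"))
    return scenarios


def _rotation_matrix(rotation_deg: tuple[float, float, float]) -> np.ndarray:
    pitch, yaw, roll = (math.radians(a) for a in rotation_deg)
    cx, sx = math.cos(pitch), math.sin(pitch)
    cy, sy = math.cos(yaw), math.sin(yaw)
    cz, sz = math.cos(roll), math.sin(roll)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ rx @ ry            # intrinsic roll -> pitch -> yaw


def perturb_dose(dose: DoseGrid, scenario: PerturbationScenario,
                 isocenter_mm: tuple[float, float, float] | None = None,
                 ) -> tuple[DoseGrid, np.ndarray]:
    """Rigidly transform the dose field relative to the structure frame.

    Returns the perturbed grid and a boolean out-of-field map (voxels whose
    sample point fell outside the original grid and took the edge value).
    """
    if any(abs(t) > 10.0 for t in scenario.translation_mm):
        raise ValueError("translations beyond 10 mm are outside the sanity bounds")
    if any(abs(r) > 5.0 for r in scenario.rotation_deg):
        raise ValueError("rotations beyond 5 degrees are outside the sanity bounds")
    if scenario.is_identity:
        return dose.copy_with(dose.values.copy()), np.zeros(dose.shape, dtype=bool)

    spacing = np.array(dose.spacing_mm)
    origin = np.array(dose.origin_mm)
    if isocenter_mm is None:
        center_idx = (np.array(dose.shape) - 1) / 2.0
        isocenter_mm = origin + center_idx * spacing
    iso = np.asarray(isocenter_mm, dtype=float)

    rot = _rotation_matrix(scenario.rotation_deg)
    shift = np.asarray(scenario.translation_mm, dtype=float)
    # sample point in world space for output voxel x: R (x - iso) + iso + t
    s = np.diag(spacing)
    s_inv = np.diag(1.0 / spacing)
    matrix = s_inv @ rot @ s
    offset = s_inv @ (rot @ (origin - iso) + iso + shift - origin)

    out = ndimage.affine_transform(dose.values, matrix, offset=offset,
                                   order=1, mode="nearest")
    # voxels whose sample point left the grid (edge-extended)
    idx = np.indices(dose.shape).reshape(3, -1).T
    sample = idx @ matrix.T + offset
    oob = ((sample < -0.5) | (sample > np.array(dose.shape) - 0.5)).any(axis=1)
    return dose.copy_with(np.clip(out, 0.0, None)), oob.reshape(dose.shape)


def lambda_index(nominal_value: float, scenario_values: np.ndarray) -> float:
    """(max - min) / nominal x 100 over a scenario group's metric values."""
    if nominal_value <= 0:
        raise ValueError("nominal metric value must be positive")
    values = np.asarray(scenario_values, dtype=float)
    if values.size == 0:
        raise ValueError("no scenario values")
    return float((values.max() - values.min()) / nominal_value * 100.0)


def robustness_study(dose: DoseGrid, structures: dict[str, StructureMask],
                     metric_map: dict[str, DoseMetricSpec],
                     scenarios: list[PerturbationScenario] | None = None,
                     isocenter_mm: tuple[float, float, float] | None = None,
                     across_all: bool = False,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Perturb the dose under every scenario and summarize robustness.

    Returns ``(long, summary)``: the long table has one row per
    (structure, scenario) with the metric value and out-of-field fraction;
    the summary has one row per (structure, group) with the lambda index
    and band width (max - min). With ``across_all`` the extremes are taken
    over all scenarios instead of per magnitude group.
    """
    scenarios = canonical_scenarios() if scenarios is None else scenarios
    nominal = {name: dose_metric(compute_dvh(dose, structures[name]), spec)
               for name, spec in metric_map.items()}

    rows = []
    for sc in scenarios:
        pdose, oob = perturb_dose(dose, sc, isocenter_mm)
        for name, spec in metric_map.items():
            mask = structures[name].mask
            oof = float(oob[mask].mean())
            value = dose_metric(compute_dvh(pdose, structures[name]), spec)
            rows.append({"structure": name, "metric": spec.label(),
                         "group": sc.group, "scenario": sc.label,
                         "value": value, "out_of_field_fraction": oof,
                         "warning": oof > 0.05})
    long = pd.DataFrame(rows)

    summary_rows = []
    for name, spec in metric_map.items():
        sub = long[long["structure"] == name]
        groups = [("all", sub)] if across_all else list(sub.groupby("group", sort=False))
        for gname, g in groups:
            summary_rows.append({
                "structure": name, "metric": spec.label(), "group": gname,
                "nominal": nominal[name],
                "band_width": float(g["value"].max() - g["value"].min()),
                "lambda_percent": lambda_index(nominal[name], g["value"].to_numpy()),
            })
    return long, pd.DataFrame(summary_rows)
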
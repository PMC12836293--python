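"""Cumulative DVH computation and dosimetric plan-evaluation indices.

The DVH is kept bin-free: the full sorted vector of in-structure voxel doses
is retained and every D_x% / D_cc / V_xGy query interpolates linearly between
sorted voxel doses. D_x% follows the ICRU reading — the smallest dose received
by the hottest x% of the structure volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .grids import DoseGrid, StructureMask

__all__ = ["CumulativeDVH", "DoseMetricSpec", "GoalSheet", "Goal",
           "compute_dvh", "dose_metric", "homogeneity_index", "paddick_ci",
           "evaluate_goals"]


@dataclass
class CumulativeDVH:
    """Exact cumulative DVH of one structure.

    ``doses_Gy`` is the ascending-sorted vector of in-structure voxel doses;
    the cumulative curve (fraction of volume receiving at least a given dose)
    is derived from it on demand.
    """

    doses_Gy: np.ndarray
    structure_name: str
    total_volume_cc: float

    def __post_init__(self) -> None:
        self.doses_Gy = np.sort(np.asarray(self.doses_Gy, dtype=np.float64), kind="stable")
        if self.doses_Gy.size == 0:
            raise ValueError("DVH requires at least one voxel dose")

    @property
    def n_voxels(self) -> int:
        return self.doses_Gy.size

    def curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (dose_axis_Gy, volume_fraction receiving >= dose)."""
        n = self.n_voxels
        dose_axis = np.concatenate(([0.0], self.doses_Gy))
        # just below the k-th sorted dose, n-k+1 ... ; at dose 0 fraction is 1
        frac = np.concatenate(([1.0], 1.0 - (np.arange(1, n + 1) - 1) / n))
        return dose_axis, frac

    def volume_fraction_at(self, dose_Gy: float) -> float:
        """Fraction of the structure receiving at least ``dose_Gy``."""
        return float(np.mean(self.doses_Gy >= dose_Gy))

    def dose_at_volume_percent(self, x: float) -> float:
        """D_x%: smallest dose received by the hottest x% of the volume."""
        if not 0.0 < x <= 100.0:
            raise ValueError("volume percent must be in (0, 100]")
        return float(np.quantile(self.doses_Gy, 1.0 - x / 100.0, method="linear"))

    def dose_at_volume_cc(self, cc: float) -> float:
        if cc <= 0 or cc > self.total_volume_cc:
            raise ValueError(
                f"absolute volume {cc} cc outside (0, {self.total_volume_cc:.3f}] "
                f"for structure {self.structure_name!r}")
        return self.dose_at_volume_percent(100.0 * cc / self.total_volume_cc)

    def mean(self) -> float:
        return float(self.doses_Gy.mean())

    def min(self) -> float:
        return float(self.doses_Gy[0])

    def max(self) -> float:
        return float(self.doses_Gy[-1])

    def to_frame(self) -> pd.DataFrame:
        dose, frac = self.curve()
        return pd.DataFrame({"dose_Gy": dose, "volume_fraction": frac})


MetricKind = Literal["D_percent", "D_cc", "D_mean", "D_min", "D_max", "V_Gy", "gradient"]


@dataclass(frozen=True)
class DoseMetricSpec:
    """One DVH metric: kind plus its threshold (percent volume, cc or Gy)."""

    kind: MetricKind
    threshold: float | None = None

    def __post_init__(self) -> None:
        needs = {"D_percent", "D_cc", "V_Gy"}
        if self.kind in needs and self.threshold is None:
            raise ValueError(f"{self.kind} requires a threshold")
        if self.kind == "D_percent" and not 0 < self.threshold <= 100:
            raise ValueError("D_percent threshold must be in (0, 100]")
        if self.kind in {"D_cc", "V_Gy"} and self.threshold < 0:
            raise ValueError(f"{self.kind} threshold must be non-negative")

    def label(self) -> str:
        if self.kind == "D_percent":
            return f"D_{self.threshold:g}%"
        if self.kind == "D_cc":
            return f"D_{self.threshold:g}cc"
        if self.kind == "V_Gy":
            return f"V_{self.threshold:g}Gy"
        if self.kind == "gradient":
            return "D_2%-D_98%"
        return self.kind


def compute_dvh(dose: DoseGrid, structure: StructureMask) -> CumulativeDVH:
    """Exact cumulative DVH from the in-structure voxel doses."""
    structure.require_nonempty()
    if dose.shape != structure.mask.shape:
        raise ValueError(
            f"dose grid {dose.shape} and mask {structure.mask.shape} shapes differ")
    return CumulativeDVH(dose.values[structure.mask], structure.name,
                         structure.volume_cc)


def dose_metric(dvh: CumulativeDVH, spec: DoseMetricSpec) -> float:
    """Evaluate one DVH metric; doses in Gy, V_xGy as percent volume."""
    if spec.kind == "D_percent":
        return dvh.dose_at_volume_percent(spec.threshold)
    if spec.kind == "D_cc":
        return dvh.dose_at_volume_cc(spec.threshold)
    if spec.kind == "D_mean":
        return dvh.mean()
    if spec.kind == "D_min":
        return dvh.min()
    if spec.kind == "D_max":
        return dvh.max()
    if spec.kind == "V_Gy":
        return 100.0 * dvh.volume_fraction_at(spec.threshold)
    if spec.kind == "gradient":
        return dvh.dose_at_volume_percent(2.0) - dvh.dose_at_volume_percent(98.0)
    raise ValueError(f"unknown metric kind {spec.kind!r}")


def homogeneity_index(d2: float, d98: float, d50: float) -> float:
    """(D2% - D98%) / D50%; 0 means perfectly homogeneous."""
    if d50 <= 0:
        raise ValueError("D50% must be positive")
    if d2 < d98:
        raise ValueError("D2% must be >= D98%")
    return (d2 - d98) / d50


def paddick_ci(target_volume_cc: float, covered_target_volume_cc: float,
               prescription_isodose_volume_cc: float) -> float:
    """Paddick conformity index: covered^2 / (target x isodose), in [0, 1]."""
    if target_volume_cc <= 0 or prescription_isodose_volume_cc <= 0:
        raise ValueError("target and isodose volumes must be positive")
    if covered_target_volume_cc < 0:
        raise ValueError("covered volume must be non-negative")
    if covered_target_volume_cc > min(target_volume_cc,
                                      prescription_isodose_volume_cc) * (1 + 1e-12):
        raise ValueError("covered volume cannot exceed target or isodose volume")
    return covered_target_volume_cc ** 2 / (
        target_volume_cc * prescription_isodose_volume_cc)


@dataclass(frozen=True)
class Goal:
    structure: str
    metric: DoseMetricSpec
    comparator: Literal["<=", ">="]
    limit: float

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise ValueError("goal limits must be positive")
        if self.comparator not in ("<=", ">="):
            raise ValueError("comparator must be '<=' or '>='")


GoalSheet = list  # list[Goal]


def evaluate_goals(dose: DoseGrid, structures: dict[str, StructureMask],
                   sheet: Iterable[Goal]) -> pd.DataFrame:
    """Evaluate a goal sheet; missing structures are reported, never skipped.

    Returns one row per goal with columns structure, metric, comparator,
    limit, achieved, passed, evaluated.
    """
    rows = []
    dvh_cache: dict[str, CumulativeDVH] = {}
    for goal in sheet:
        rec = {"structure": goal.structure, "metric": goal.metric.label(),
               "comparator": goal.comparator, "limit": goal.limit,
               "achieved": np.nan, "passed": False, "evaluated": False}
        if goal.structure in structures:
            if goal.structure not in dvh_cache:
                dvh_cache[goal.structure] = compute_dvh(dose, structures[goal.structure])
            achieved = dose_metric(dvh_cache[goal.structure], goal.metric)
            ok = achieved <= goal.limit if goal.comparator == "<=" else achieved >= goal.limit
            rec.update(achieved=achieved, passed=bool(ok), evaluated=True)
        rows.append(rec)
    return pd.DataFrame(rows, columns=["structure", "metric", "comparator",
                                       "limit", "achieved", "passed", "evaluated"])
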
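"""VMAT plan and delivery-log data model with JSON/CSV interchange.

A beam is an ordered sequence of control points (CPs). Each CP carries its
segment monitor units (MU delivered between the previous CP and this one,
first CP zero by convention here segment weights are stored directly), the
two opposing MLC bank positions in mm at isocenter (bank A = left/negative
side, bank B = right), jaw positions and the gantry angle. Leaf pair i spans
``leaf_width_mm`` along the axis perpendicular to leaf travel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ControlPoint", "Beam", "BeamPlan", "DeliveryLog",
           "write_plan", "read_plan", "write_log", "read_log"]


@dataclass
class ControlPoint:
    mu: float                       # segment MU for this CP
    bank_a_mm: np.ndarray           # left leaf tips, one per pair
    bank_b_mm: np.ndarray           # right leaf tips
    jaws_mm: tuple[float, float, float, float] = (-200.0, 200.0, -200.0, 200.0)
    gantry_deg: float = 0.0

    def __post_init__(self) -> None:
        self.bank_a_mm = np.asarray(self.bank_a_mm, dtype=np.float64)
        self.bank_b_mm = np.asarray(self.bank_b_mm, dtype=np.float64)
        if self.bank_a_mm.shape != self.bank_b_mm.shape:
            raise ValueError("leaf banks must have equal length")
        if self.mu < 0:
            raise ValueError("segment MU must be non-negative")
        if np.any(self.bank_a_mm > self.bank_b_mm + 1e-9):
            raise ValueError("leaf crossing: bank A must not exceed bank B")
        self.jaws_mm = tuple(float(j) for j in self.jaws_mm)

    @property
    def n_pairs(self) -> int:
        return self.bank_a_mm.size


@dataclass
class Beam:
    name: str
    control_points: list[ControlPoint]
    isocenter: str = "iso-1"        # cranial vs spinal grouping label
    leaf_width_mm: float = 5.0
    collimator_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.control_points:
            raise ValueError(f"beam {self.name!r} has no control points")
        n = {cp.n_pairs for cp in self.control_points}
        if len(n) != 1:
            raise ValueError("all control points must share the leaf-pair count")

    @property
    def total_mu(self) -> float:
        return float(sum(cp.mu for cp in self.control_points))

    @property
    def n_cp(self) -> int:
        return len(self.control_points)


@dataclass
class BeamPlan:
    beams: list[Beam]
    plan_id: str = "plan"

    @property
    def total_mu(self) -> float:
        return float(sum(b.total_mu for b in self.beams))

    @property
    def n_cp(self) -> int:
        return int(sum(b.n_cp for b in self.beams))

    def isocenter_groups(self) -> dict[str, list[Beam]]:
        groups: dict[str, list[Beam]] = {}
        for beam in self.beams:
            groups.setdefault(beam.isocenter, []).append(beam)
        return groups


@dataclass
class DeliveryLog:
    """Per-CP actual machine state recorded during delivery.

    Mirrors the plan structure: one record per beam, aligned CP-for-CP with
    the planned control points.
    """

    plan_id: str
    beams: list[Beam]

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValueError("delivery log has no beams")


# --------------------------- JSON plan schema ------------------------------

def _cp_to_dict(cp: ControlPoint) -> dict:
    return {"mu": cp.mu, "bank_a_mm": cp.bank_a_mm.tolist(),
            "bank_b_mm": cp.bank_b_mm.tolist(), "jaws_mm": list(cp.jaws_mm),
            "gantry_deg": cp.gantry_deg}


def _cp_from_dict(d: dict) -> ControlPoint:
    return ControlPoint(d["mu"], np.array(d["bank_a_mm"]), np.array(d["bank_b_mm"]),
                        tuple(d["jaws_mm"]), d["gantry_deg"])


def write_plan(plan: BeamPlan, path: str | Path) -> None:
    doc = {"plan_id": plan.plan_id, "beams": [
        {"name": b.name, "isocenter": b.isocenter, "leaf_width_mm": b.leaf_width_mm,
         "collimator_deg": b.collimator_deg,
         "control_points": [_cp_to_dict(cp) for cp in b.control_points]}
        for b in plan.beams]}
    Path(path).write_text(json.dumps(doc))


def read_plan(path: str | Path) -> BeamPlan:
    doc = json.loads(Path(path).read_text())
    beams = [Beam(b["name"], [_cp_from_dict(cp) for cp in b["control_points"]],
                  b.get("isocenter", "iso-1"), b.get("leaf_width_mm", 5.0),
                  b.get("collimator_deg", 0.0))
             for b in doc["beams"]]
    return BeamPlan(beams, doc.get("plan_id", "plan"))


# --------------------------- CSV log format --------------------------------
# One row per (beam, control point, leaf pair) plus per-CP gantry columns.

def write_log(log: DeliveryLog, path: str | Path) -> None:
    rows = []
    for b in log.beams:
        for i, cp in enumerate(b.control_points):
            for pair in range(cp.n_pairs):
                rows.append({"beam": b.name, "cp": i, "pair": pair,
                             "bank_a_mm": cp.bank_a_mm[pair],
                             "bank_b_mm": cp.bank_b_mm[pair],
                             "jaw_x1_mm": cp.jaws_mm[0], "jaw_x2_mm": cp.jaws_mm[1],
                             "jaw_y1_mm": cp.jaws_mm[2], "jaw_y2_mm": cp.jaws_mm[3],
                             "gantry_deg": cp.gantry_deg,
                             "collimator_deg": b.collimator_deg, "mu": cp.mu})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_log(path: str | Path, plan_id: str = "plan") -> DeliveryLog:
    df = pd.read_csv(path)
    beams = []
    for name, bdf in df.groupby("beam", sort=False):
        cps = []
        colli = 0.0
        for _, cdf in bdf.groupby("cp", sort=True):
            cdf = cdf.sort_values("pair")
            row0 = cdf.iloc[0]
            jaws = tuple(float(row0[c]) for c in
                         ("jaw_x1_mm", "jaw_x2_mm", "jaw_y1_mm", "jaw_y2_mm")) \
                if "jaw_x1_mm" in cdf.columns else (-200.0, 200.0, -200.0, 200.0)
            colli = float(row0.get("collimator_deg", 0.0))
            cps.append(ControlPoint(float(row0["mu"]),
                                    cdf["bank_a_mm"].to_numpy(),
                                    cdf["bank_b_mm"].to_numpy(), jaws,
                                    gantry_deg=float(row0["gantry_deg"])))
        beams.append(Beam(str(name), cps, collimator_deg=colli))
    return DeliveryLog(plan_id, beams)
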
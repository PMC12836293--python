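"""VMAT plan-complexity metrics from MLC/jaw control-point geometry.

Implemented metrics (the canonical literature forms):

* PI   — plan-averaged beam irregularity: MU-weighted mean over control
  points of the aperture irregularity AI = perimeter^2 / (4 pi area),
  computed per connected aperture component and area-weighted.
* MCS  — modulation complexity score for VMAT: per-CP leaf-sequence
  variability (LSV, product of the two banks) and aperture-area variability
  (AAV, area relative to the beam's per-pair maximal openings), combined
  over adjacent CP pairs with segment-MU weights. 1 = static open field.
* SAS10 — small-aperture score: MU-weighted fraction of open leaf pairs
  with gap below 10 mm.
* MFA / MLG / MLT — MU-weighted mean field area (cm^2), mean leaf gap (cm),
  and mean leaf travel (cm, per-leaf total travel summed over CPs).

Apertures are jaw-clipped before any gap/area computation; a leaf pair is
"closed" when its clipped gap is at or below ``closed_threshold_mm``
(default 1 mm, the practical minimum gap of 5-mm-leaf MLCs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plans import Beam, BeamPlan, ControlPoint

__all__ = ["ApertureGeometry", "aperture_geometry", "aperture_irregularity",
           "beam_irregularity", "mcs", "small_aperture_score",
           "beam_metrics", "aggregate_metrics"]

CLOSED_THRESHOLD_MM = 1.0
SMALL_APERTURE_MM = 10.0


@dataclass
class ApertureGeometry:
    """Jaw-clipped aperture of one control point."""

    open_pairs: np.ndarray          # indices of open leaf pairs
    gaps_mm: np.ndarray             # clipped gap per open pair
    area_mm2: float
    perimeter_mm: float
    components: list[tuple[float, float]] = field(default_factory=list)  # (area, perimeter)

    @property
    def n_components(self) -> int:
        return len(self.components)


def _clip_cp(cp: ControlPoint, leaf_width_mm: float,
             jaws_mm: tuple[float, float, float, float] | None):
    """Jaw-clipped (left, right, active) leaf arrays for one CP."""
    jaws = jaws_mm if jaws_mm is not None else cp.jaws_mm
    x1, x2, y1, y2 = jaws
    if np.any(cp.bank_a_mm > cp.bank_b_mm + 1e-9):
        raise ValueError("leaf crossing beyond tolerance")
    left = np.clip(cp.bank_a_mm, x1, x2)
    right = np.clip(cp.bank_b_mm, x1, x2)
    n = cp.n_pairs
    centers = (np.arange(n) - (n - 1) / 2.0) * leaf_width_mm
    active = (centers >= y1) & (centers <= y2)
    return left, right, active


def aperture_geometry(cp: ControlPoint, leaf_width_mm: float = 5.0,
                      jaws_mm: tuple[float, float, float, float] | None = None,
                      closed_threshold_mm: float = CLOSED_THRESHOLD_MM) -> ApertureGeometry:
    """Area, perimeter and connected components of one CP's aperture.

    Each open pair i contributes a rectangle gap_i x leaf_width; the
    perimeter of a run of consecutive open pairs a..b is
    ``gap_a + gap_b + 2 w (b - a + 1) + sum(|dl| + |dr|)`` over the left and
    right edge steps between adjacent pairs inside the run.
    """
    left, right, active = _clip_cp(cp, leaf_width_mm, jaws_mm)
    gap = np.where(active, right - left, 0.0)
    is_open = gap > closed_threshold_mm
    open_idx = np.flatnonzero(is_open)
    if open_idx.size == 0:
        return ApertureGeometry(open_idx, np.array([]), 0.0, 0.0, [])

    components: list[tuple[float, float]] = []
    # split open pairs into runs of consecutive indices
    breaks = np.flatnonzero(np.diff(open_idx) > 1)
    runs = np.split(open_idx, breaks + 1)
    for run in runs:
        g = gap[run]
        area = float(g.sum() * leaf_width_mm)
        per = float(g[0] + g[-1] + 2.0 * leaf_width_mm * run.size
                    + np.abs(np.diff(left[run])).sum()
                    + np.abs(np.diff(right[run])).sum())
        components.append((area, per))
    area = sum(a for a, _ in components)
    perimeter = sum(p for _, p in components)
    return ApertureGeometry(open_idx, gap[open_idx], area, perimeter, components)


def aperture_irregularity(geom: ApertureGeometry) -> float:
    """Area-weighted AI = perimeter^2 / (4 pi area) over components."""
    if geom.area_mm2 <= 0:
        raise ValueError("aperture is closed")
    ai = 0.0
    for area, per in geom.components:
        ai += (area / geom.area_mm2) * per ** 2 / (4.0 * math.pi * area)
    return ai


def _cp_geoms(beam: Beam, closed_threshold_mm: float) -> list[ApertureGeometry]:
    return [aperture_geometry(cp, beam.leaf_width_mm, None, closed_threshold_mm)
            for cp in beam.control_points]


def beam_irregularity(beam: Beam,
                      closed_threshold_mm: float = CLOSED_THRESHOLD_MM) -> float:
    """MU-weighted mean aperture irregularity over the beam's open CPs."""
    geoms = _cp_geoms(beam, closed_threshold_mm)
    weights, values = [], []
    for cp, g in zip(beam.control_points, geoms):
        if g.area_mm2 > 0:
            weights.append(cp.mu)
            values.append(aperture_irregularity(g))
    if not values or sum(weights) == 0:
        raise ValueError(f"beam {beam.name!r} has no open, weighted aperture")
    return float(np.average(values, weights=weights))


def _lsv_bank(pos: np.ndarray) -> float:
    """Leaf-sequence variability of one bank over the open leaves of a CP."""
    if pos.size <= 1:
        return 1.0
    pos_max = float(pos.max() - pos.min())
    if pos_max <= 0:
        return 1.0
    diffs = np.abs(np.diff(pos))
    return float(np.sum(pos_max - diffs) / ((pos.size - 1) * pos_max))


def mcs(beam: Beam, closed_threshold_mm: float = CLOSED_THRESHOLD_MM) -> float:
    """Modulation complexity score in (0, 1]; lower = more modulated.

    AAV denominator is the aperture formed by each pair's maximal openings
    across the beam; segment weights are the mean MU of adjacent CP pairs.
    """
    if beam.n_cp < 2:
        # a single static segment is by definition unmodulated
        return 1.0
    cps = beam.control_points
    lefts, rights, actives = zip(*(_clip_cp(cp, beam.leaf_width_mm, None) for cp in cps))
    lefts = np.stack(lefts)
    rights = np.stack(rights)
    gaps = np.where(np.stack(actives), rights - lefts, 0.0)
    open_any = (gaps > closed_threshold_mm).any(axis=0)
    max_area = float(((rights[:, open_any].max(axis=0)
                       - lefts[:, open_any].min(axis=0)).clip(min=0.0)).sum()
                     * beam.leaf_width_mm)
    if max_area <= 0:
        raise ValueError(f"beam {beam.name!r} never opens")

    lsv = np.empty(len(cps))
    aav = np.empty(len(cps))
    for k in range(len(cps)):
        open_k = gaps[k] > closed_threshold_mm
        lsv[k] = (_lsv_bank(lefts[k, open_k]) * _lsv_bank(rights[k, open_k])
                  if open_k.any() else 1.0)
        aav[k] = gaps[k, open_k].sum() * beam.leaf_width_mm / max_area

    mu = np.array([cp.mu for cp in cps])
    seg_mu = 0.5 * (mu[:-1] + mu[1:])
    if seg_mu.sum() == 0:
        raise ValueError(f"beam {beam.name!r} delivers no MU")
    seg_w = seg_mu / seg_mu.sum()
    score = float(np.sum(0.5 * (aav[:-1] + aav[1:]) * 0.5 * (lsv[:-1] + lsv[1:]) * seg_w))
    return min(score, 1.0)


def small_aperture_score(beam: Beam, threshold_mm: float = SMALL_APERTURE_MM,
                         closed_threshold_mm: float = CLOSED_THRESHOLD_MM) -> float:
    """MU-weighted fraction of open leaf pairs with gap below ``threshold_mm``."""
    num = den = 0.0
    for cp, g in zip(beam.control_points, _cp_geoms(beam, closed_threshold_mm)):
        if g.gaps_mm.size == 0:
            continue
        frac = float(np.mean(g.gaps_mm < threshold_mm))
        num += cp.mu * frac
        den += cp.mu
    if den == 0:
        raise ValueError(f"beam {beam.name!r} has no open aperture")
    return num / den


def _beam_mlt_cm(beam: Beam) -> float:
    """Total |position change| over CPs, averaged over all leaves, in cm."""
    a = np.stack([cp.bank_a_mm for cp in beam.control_points])
    b = np.stack([cp.bank_b_mm for cp in beam.control_points])
    travel = np.abs(np.diff(a, axis=0)).sum(axis=0).sum() \
        + np.abs(np.diff(b, axis=0)).sum(axis=0).sum()
    return float(travel / (2 * a.shape[1]) / 10.0)


def beam_metrics(beam: Beam,
                 closed_threshold_mm: float = CLOSED_THRESHOLD_MM) -> dict:
    """All complexity metrics for one beam."""
    geoms = _cp_geoms(beam, closed_threshold_mm)
    mu = np.array([cp.mu for cp in beam.control_points])
    areas = np.array([g.area_mm2 for g in geoms])
    open_w = mu[areas > 0]
    mfa = float(np.average(areas[areas > 0], weights=open_w)) / 100.0 if open_w.sum() else 0.0
    gap_means = np.array([g.gaps_mm.mean() if g.gaps_mm.size else np.nan for g in geoms])
    ok = ~np.isnan(gap_means) & (mu > 0)
    mlg = float(np.average(gap_means[ok], weights=mu[ok])) / 10.0 if ok.any() else 0.0
    return {
        "MU": beam.total_mu,
        "CPs": beam.n_cp,
        "PI": beam_irregularity(beam, closed_threshold_mm),
        "MCS": mcs(beam, closed_threshold_mm),
        "SAS10": small_aperture_score(beam, closed_threshold_mm=closed_threshold_mm),
        "MFA_cm2": mfa,
        "MLG_cm": mlg,
        "MLT_cm": _beam_mlt_cm(beam),
    }


_MU_WEIGHTED = ["PI", "MCS", "SAS10", "MFA_cm2", "MLG_cm", "MLT_cm"]


def aggregate_metrics(plan: BeamPlan,
                      closed_threshold_mm: float = CLOSED_THRESHOLD_MM) -> pd.DataFrame:
    """Complexity report per beam, per isocenter group and for the plan.

    MU and CP counts are summed within a scope; all other metrics are
    MU-weighted means of the per-beam values.
    """
    per_beam = {b.name: beam_metrics(b, closed_threshold_mm) for b in plan.beams}
    rows = [{"scope": "beam", "label": name, **m} for name, m in per_beam.items()]

    def _agg(beams: list[Beam], scope: str, label: str) -> dict:
        ms = [per_beam[b.name] for b in beams]
        w = np.array([m["MU"] for m in ms])
        out = {"scope": scope, "label": label,
               "MU": float(w.sum()), "CPs": int(sum(m["CPs"] for m in ms))}
        for key in _MU_WEIGHTED:
            out[key] = float(np.average([m[key] for m in ms], weights=w))
        return out

    for iso, beams in plan.isocenter_groups().items():
        rows.append(_agg(beams, "isocenter", iso))
    rows.append(_agg(plan.beams, "plan", plan.plan_id))
    return pd.DataFrame(rows)
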
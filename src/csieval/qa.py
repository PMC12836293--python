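"""Planned-vs-delivered QA comparison: gamma analysis, delta-DVH, log RMS.

The gamma index combines a dose-difference criterion (percent of the global
reference maximum) with a distance-to-agreement (DTA) criterion: for every
reference point above the low-dose threshold,

    gamma = min over r in the search neighborhood of
            sqrt( (D_eval(r) - D_ref)^2 / dD^2  +  |r - r_ref|^2 / DTA^2 )

and the point passes when gamma <= 1. The evaluated distribution is sampled
on a local lattice of step DTA/10 (linear interpolation) out to a radius of
3 x DTA; offsets are visited nearest-first with a global early exit, which
makes the search deterministic and bounds the discretization error. Gamma
is not symmetric in its arguments; both directions can be computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .dvh import DoseMetricSpec, compute_dvh, dose_metric
from .grids import DoseGrid, StructureMask
from .plans import BeamPlan, DeliveryLog

__all__ = ["GammaCriteria", "GammaResult", "gamma_index",
           "delta_dvh", "log_rms", "LogRMSReport"]


@dataclass(frozen=True)
class GammaCriteria:
    dose_percent: float = 3.0
    distance_mm: float = 3.0
    low_dose_threshold_percent: float = 10.0
    search_radius_factor: float = 3.0
    upsample: int = 10

    def __post_init__(self) -> None:
        if min(self.dose_percent, self.distance_mm,
               self.low_dose_threshold_percent) <= 0:
            raise ValueError("gamma criteria must be positive")


@dataclass
class GammaResult:
    gamma: np.ndarray            # NaN below the low-dose threshold
    pass_rate_percent: float
    n_evaluated: int


def gamma_index(reference: np.ndarray, evaluated: np.ndarray,
                spacing_mm: tuple[float, ...],
                criteria: GammaCriteria = GammaCriteria()) -> GammaResult:
    """Global gamma analysis of two co-registered dose arrays (2-D or 3-D).

    Dose differences are normalized to the maximum of the reference
    distribution; points below ``low_dose_threshold_percent`` of that
    maximum are excluded from the pass rate.
    """
    reference = np.asarray(reference, dtype=np.float64)
    evaluated = np.asarray(evaluated, dtype=np.float64)
    if reference.shape != evaluated.shape:
        raise ValueError("reference and evaluated geometries differ")
    if len(spacing_mm) != reference.ndim:
        raise ValueError("spacing must match array dimensionality")

    ref_max = reference.max()
    if ref_max <= 0:
        raise ValueError("reference distribution is empty")
    dd_abs = criteria.dose_percent / 100.0 * ref_max
    dta = criteria.distance_mm
    threshold = criteria.low_dose_threshold_percent / 100.0 * ref_max

    axes = [np.arange(n) * s for n, s in zip(reference.shape, spacing_mm)]
    interp = RegularGridInterpolator(axes, evaluated, method="linear",
                                     bounds_error=False, fill_value=np.nan)
    sel = reference >= threshold
    pts = np.argwhere(sel).astype(np.float64) * np.asarray(spacing_mm)
    ref_vals = reference[sel]

    # candidate offsets on a DTA/10 lattice within the search radius,
    # nearest-first so the running minimum allows a global early exit
    step = dta / criteria.upsample
    radius = criteria.search_radius_factor * dta
    n_steps = int(np.floor(radius / step + 1e-9))
    grid_1d = step * np.arange(-n_steps, n_steps + 1)   # exact zero offset
    mesh = np.meshgrid(*([grid_1d] * reference.ndim), indexing="ij")
    offsets = np.stack([m.ravel() for m in mesh], axis=1)
    dist2 = (offsets ** 2).sum(axis=1)
    keep = dist2 <= radius ** 2
    offsets, dist2 = offsets[keep], dist2[keep]
    order = np.argsort(dist2, kind="stable")
    offsets, dist2 = offsets[order], dist2[order]

    best = np.full(ref_vals.shape, np.inf)
    for off, d2 in zip(offsets, dist2):
        geom2 = d2 / dta ** 2
        bmax = best.max()
        if np.isfinite(bmax) and geom2 >= bmax * bmax:
            break
        ev = interp(pts + off)
        ok = ~np.isnan(ev)
        cand = np.sqrt((ev[ok] - ref_vals[ok]) ** 2 / dd_abs ** 2 + geom2)
        best[ok] = np.minimum(best[ok], cand)

    gamma_map = np.full(reference.shape, np.nan)
    gamma_map[sel] = best
    n_eval = int(sel.sum())
    pass_rate = float(np.mean(best <= 1.0 + 1e-9) * 100.0) if n_eval else 0.0
    return GammaResult(gamma_map, pass_rate, n_eval)


def delta_dvh(planned: DoseGrid, delivered: DoseGrid,
              structures: dict[str, StructureMask],
              metric_map: dict[str, list[DoseMetricSpec]]) -> pd.DataFrame:
    """Delivered-minus-planned differences of per-structure DVH metrics."""
    if planned.shape != delivered.shape:
        raise ValueError("planned and delivered grids differ in shape")
    rows = []
    for name, specs in metric_map.items():
        dvh_p = compute_dvh(planned, structures[name])
        dvh_d = compute_dvh(delivered, structures[name])
        for spec in specs:
            p = dose_metric(dvh_p, spec)
            d = dose_metric(dvh_d, spec)
            rows.append({"structure": name, "metric": spec.label(),
                         "planned": p, "delivered": d, "delta": d - p})
    return pd.DataFrame(rows)


@dataclass
class LogRMSReport:
    mlc_rms_mm: float
    gantry_rms_deg: float
    jaw_rms_mm: float
    collimator_rms_deg: float


def log_rms(plan: BeamPlan, log: DeliveryLog) -> LogRMSReport:
    """RMS actual-minus-planned errors over all leaves x CPs and all CPs."""
    if len(plan.beams) != len(log.beams):
        raise ValueError("plan and log beam counts differ")
    mlc, gantry, jaw = [], [], []
    colli = []
    for pb, lb in zip(plan.beams, log.beams):
        if pb.n_cp != lb.n_cp:
            raise ValueError(f"CP count mismatch in beam {pb.name!r}")
        for pcp, lcp in zip(pb.control_points, lb.control_points):
            mlc.append(lcp.bank_a_mm - pcp.bank_a_mm)
            mlc.append(lcp.bank_b_mm - pcp.bank_b_mm)
            gantry.append(lcp.gantry_deg - pcp.gantry_deg)
            jaw.extend(l - p for l, p in zip(lcp.jaws_mm, pcp.jaws_mm))
        colli.append(lb.collimator_deg - pb.collimator_deg)

    def _rms(x) -> float:
        arr = np.concatenate([np.atleast_1d(v) for v in x]) if x else np.zeros(1)
        return float(np.sqrt(np.mean(arr ** 2)))

    return LogRMSReport(_rms(mlc), _rms([np.array(gantry)]),
                        _rms([np.array(jaw)]), _rms([np.array(colli)]))
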
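"""End-to-end evaluation pipeline and cohort-level statistics.

``run_pipeline`` generates (or loads) a paired cohort of functional-sparing
and standard CSI evaluations and writes five report tables: dosimetry, NTCP,
robustness, plan complexity and planned-vs-delivered delta-DVH, plus a JSON
manifest recording inputs, seeds and the operation behind every table.

Cohort comparisons follow paired-design reporting: mean +- SD per arm, a
paired t-test and a Wilcoxon signed-rank test (no multiple-testing
correction). Degenerate cases (all paired differences zero) are flagged
rather than propagated as NaNs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .complexity import aggregate_metrics
from .dvh import DoseMetricSpec, compute_dvh, dose_metric, homogeneity_index, paddick_ci
from .grids import DoseGrid, StructureMask
from .qa import delta_dvh, log_rms
from .radbio import (FractionationScheme, cochlear_ntcp, endocrine_ntcp, eqd2,
                     geud, hippocampal_ntcp, load_param_registry, scalp_ntcp)
from .robustness import canonical_scenarios, robustness_study
from .synth import (DoseRecipe, PhantomSpec, fp_recipe, generate_dose,
                    generate_log, generate_phantom, generate_plan, s_recipe)

__all__ = ["EvaluationConfig", "CohortSummary", "cohort_compare",
           "run_pipeline", "ROBUSTNESS_METRICS", "DELTA_METRICS"]

#: DVH index evaluated per structure in the robustness study
ROBUSTNESS_METRICS = {
    "PTV_cranial": DoseMetricSpec("D_percent", 95.0),
    "hippocampus": DoseMetricSpec("D_percent", 40.0),
    "hypothalamus": DoseMetricSpec("D_percent", 50.0),
    "pituitary": DoseMetricSpec("D_percent", 50.0),
    "cochlea": DoseMetricSpec("D_percent", 50.0),
    "scalp": DoseMetricSpec("D_percent", 50.0),
}

#: DVH deviations evaluated in the planned-vs-delivered comparison
DELTA_METRICS = {
    "PTV_cranial": [DoseMetricSpec("D_percent", 95.0), DoseMetricSpec("D_percent", 98.0),
                    DoseMetricSpec("D_percent", 2.0), DoseMetricSpec("D_mean")],
    "hippocampus": [DoseMetricSpec("D_percent", 40.0)],
    "hypothalamus": [DoseMetricSpec("D_percent", 50.0)],
    "pituitary": [DoseMetricSpec("D_percent", 50.0)],
    "cochlea": [DoseMetricSpec("D_percent", 50.0)],
    "scalp": [DoseMetricSpec("D_percent", 50.0)],
}


@dataclass
class EvaluationConfig:
    """Configuration of the synthetic-cohort pipeline."""

    n_patients: int = 2
    seed: int = 0
    grid_shape: tuple[int, int, int] = (50, 50, 125)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    ages_years: tuple[float, ...] = ()      # defaults drawn 3-17 y when empty
    registry_path: str | None = None
    robustness: bool = True
    output_dir: str = "csieval_report"

    @classmethod
    def from_file(cls, path: str | Path) -> "EvaluationConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        return cfg


@dataclass
class CohortSummary:
    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_difference: float
    t_p_value: float
    wilcoxon_p_value: float
    degenerate: bool = False


def cohort_compare(values_a, values_b, metric: str = "") -> CohortSummary:
    """Paired comparison of two equally long cohort value vectors."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired cohorts must be equal-length 1-D with n >= 2")
    diff = a - b
    if np.allclose(diff, 0.0):
        return CohortSummary(metric, a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1),
                             0.0, 1.0, 1.0, degenerate=True)
    t_res = stats.ttest_rel(a, b)
    t_p = float(t_res.pvalue) if np.isfinite(t_res.pvalue) else 0.0
    try:
        w_res = stats.wilcoxon(a, b, zero_method="wilcox",
                               method="exact" if a.size <= 25 else "approx")
        w_p = float(w_res.pvalue)
    except ValueError:
        w_p = 1.0
    return CohortSummary(metric, float(a.mean()), float(a.std(ddof=1)),
                         float(b.mean()), float(b.std(ddof=1)),
                         float(diff.mean()), t_p, w_p)


# ---------------------------------------------------------------------------

def _dosimetry_row(dose: DoseGrid, masks: dict[str, StructureMask],
                   rx: float) -> dict:
    ptv = StructureMask("PTV", masks["PTV_cranial"].mask | masks["PTV_spinal"].mask,
                        masks["PTV_cranial"].spacing_mm)
    dvh = {name: compute_dvh(dose, m) for name, m in masks.items()}
    dvh["PTV"] = compute_dvh(dose, ptv)
    d2 = dvh["PTV"].dose_at_volume_percent(2.0)
    d98 = dvh["PTV"].dose_at_volume_percent(98.0)
    d50 = dvh["PTV"].dose_at_volume_percent(50.0)
    vox_cc = ptv.volume_cc / ptv.voxel_count
    covered = float((dose.values[ptv.mask] >= rx).sum()) * vox_cc
    isodose = float((dose.values >= rx).sum()) * vox_cc
    ci = paddick_ci(ptv.volume_cc, covered, isodose) if isodose > 0 else 0.0
    return {
        "PTV D_2% (Gy)": d2, "PTV D_98% (Gy)": d98,
        "PTV HI": homogeneity_index(d2, d98, d50), "PTV CI": ci,
        "PTV_cranial D_95% (Gy)": dvh["PTV_cranial"].dose_at_volume_percent(95.0),
        "Hippocampus D_0.03cc (Gy)": dvh["hippocampus"].dose_at_volume_cc(0.03),
        "Hippocampus D_min (Gy)": dvh["hippocampus"].min(),
        "Hippocampus D_mean (Gy)": dvh["hippocampus"].mean(),
        "Hypothalamus D_mean (Gy)": dvh["hypothalamus"].mean(),
        "Pituitary D_mean (Gy)": dvh["pituitary"].mean(),
        "Vertebrae D_2%-D_98% (Gy)": dose_metric(dvh["vertebrae"], DoseMetricSpec("gradient")),
        "Cochlea D_mean (Gy)": dvh["cochlea"].mean(),
        "Scalp D_50% (Gy)": dvh["scalp"].dose_at_volume_percent(50.0),
    }


def _ntcp_row(dose: DoseGrid, masks: dict[str, StructureMask],
              age: float, registry: dict, scheme: FractionationScheme) -> dict:
    dvh = {n: compute_dvh(dose, masks[n])
           for n in ("hippocampus", "hypothalamus", "pituitary", "cochlea", "scalp")}
    d40 = dvh["hippocampus"].dose_at_volume_percent(40.0)
    hyp = dvh["hypothalamus"].dose_at_volume_percent(50.0)
    pit = dvh["pituitary"].dose_at_volume_percent(50.0)
    coch = dvh["cochlea"].dose_at_volume_percent(50.0)
    scalp_params = registry["scalp"]
    return {
        "Hippocampus D_40% (Gy)": d40,
        "Hippocampus EQD2(D_40) (Gy)": eqd2(d40, scheme),
        "Hippocampus NTCP (%)": 100 * hippocampal_ntcp(d40, scheme, registry["hippocampus"]),
        "Hypothalamus D_50% (Gy)": hyp,
        "Pituitary D_50% (Gy)": pit,
        "HPA NTCP (%)": 100 * endocrine_ntcp(hyp, pit, age, registry["hpa"]),
        "Cochlea D_50% (Gy)": coch,
        "Cochlea NTCP (%)": 100 * cochlear_ntcp(coch, registry["cochlea"]),
        "Scalp gEUD (Gy)": geud(dvh["scalp"], scalp_params.n),
        "Scalp NTCP (%)": 100 * scalp_ntcp(dvh["scalp"], scalp_params),
    }


def _delivered_surrogate(planned: DoseGrid, rms_mm: float,
                         rng: np.random.Generator) -> DoseGrid:
    """Desk-scale stand-in for a log-file Monte Carlo dose reconstruction.

    The delivered dose is modelled as the planned dose shifted by a small
    random systematic setup/aperture offset (sub-mm, scaled by the log MLC
    RMS) plus a smooth dose perturbation of matching amplitude. This is an
    approximation for exercising the comparison layer, not an emulation of
    transport physics.
    """
    from scipy import ndimage
    shift_mm = rng.normal(0.0, 0.4 * max(rms_mm, 1e-6), size=3)
    shift_vox = shift_mm / np.array(planned.spacing_mm)
    out = ndimage.shift(planned.values, shift_vox, order=1, mode="nearest")
    smooth = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, planned.shape), sigma=4.0)
    smooth *= 0.4 * rms_mm / max(np.abs(smooth).max(), 1e-9)
    return planned.copy_with(np.clip(out + smooth, 0.0, None))


def _paired_table(per_patient_fp: list[dict], per_patient_s: list[dict]) -> pd.DataFrame:
    rows = []
    n = len(per_patient_fp)
    for key in per_patient_fp[0]:
        a = [p[key] for p in per_patient_fp]
        b = [p[key] for p in per_patient_s]
        if n >= 2:
            summ = cohort_compare(a, b, key)
            rows.append({"metric": key, "FP_mean": summ.mean_a, "FP_sd": summ.sd_a,
                         "S_mean": summ.mean_b, "S_sd": summ.sd_b,
                         "t_p": summ.t_p_value, "wilcoxon_p": summ.wilcoxon_p_value,
                         "degenerate": summ.degenerate})
        else:
            rows.append({"metric": key, "FP_mean": a[0], "FP_sd": np.nan,
                         "S_mean": b[0], "S_sd": np.nan,
                         "t_p": np.nan, "wilcoxon_p": np.nan, "degenerate": False})
    return pd.DataFrame(rows)


def run_pipeline(config: EvaluationConfig) -> dict[str, Path]:
    """Run the full synthetic-cohort evaluation; returns written file paths.

    Writes dosimetry.csv, ntcp.csv, robustness.csv, complexity.csv,
    delta_dvh.csv and manifest.json into ``config.output_dir``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = load_param_registry(config.registry_path)
    scheme = FractionationScheme(13, 2.0)
    master = np.random.default_rng(config.seed)
    ages = list(config.ages_years) or [
        float(a) for a in master.uniform(3.0, 17.0, size=config.n_patients)]
    if len(ages) != config.n_patients:
        raise ValueError("ages_years length must match n_patients")

    manifest = {"version": __version__, "seed": config.seed,
                "config": asdict(config), "stages": []}

    def stage(name: str):
        t0 = time.perf_counter()

        def done(**extra):
            manifest["stages"].append(
                {"stage": name, "wall_s": round(time.perf_counter() - t0, 3), **extra})
        return done

    dosi_fp, dosi_s, ntcp_fp, ntcp_s = [], [], [], []
    delta_frames = []
    robust_frames = []
    for i in range(config.n_patients):
        pat_seed = config.seed * 1000 + i
        spec = PhantomSpec(grid_shape=config.grid_shape,
                           spacing_mm=config.spacing_mm, seed=pat_seed)
        template, masks = generate_phantom(spec)
        rng = np.random.default_rng(pat_seed + 1)
        dose_fp = generate_dose(template, masks, fp_recipe(), rng)
        dose_s = generate_dose(template, masks, s_recipe(), rng)

        done = stage(f"dosimetry_patient{i}")
        dosi_fp.append(_dosimetry_row(dose_fp, masks, fp_recipe().prescription_Gy))
        dosi_s.append(_dosimetry_row(dose_s, masks, s_recipe().prescription_Gy))
        done(operation="dvh.dose_metric/homogeneity_index/paddick_ci")

        done = stage(f"ntcp_patient{i}")
        ntcp_fp.append(_ntcp_row(dose_fp, masks, ages[i], registry, scheme))
        ntcp_s.append(_ntcp_row(dose_s, masks, ages[i], registry, scheme))
        done(operation="radbio.*_ntcp", age_years=ages[i])

        if config.robustness:
            done = stage(f"robustness_patient{i}")
            for arm, dose in (("FP", dose_fp), ("S", dose_s)):
                _, summary = robustness_study(dose, masks, ROBUSTNESS_METRICS)
                summary.insert(0, "arm", arm)
                summary.insert(0, "patient", i)
                robust_frames.append(summary)
            done(operation="robustness.robustness_study", n_scenarios=30)

        done = stage(f"delta_dvh_patient{i}")
        for arm, dose in (("FP", dose_fp), ("S", dose_s)):
            plan = generate_plan(modulation_level=0.8 if arm == "FP" else 0.3,
                                 seed=pat_seed + 2)
            log = generate_log(plan, mlc_sd_mm=0.5, gantry_sd_deg=0.3,
                               seed=pat_seed + 3)
            rms = log_rms(plan, log)
            delivered = _delivered_surrogate(
                dose, rms.mlc_rms_mm, np.random.default_rng(pat_seed + 4))
            ddvh = delta_dvh(dose, delivered, masks, DELTA_METRICS)
            ddvh.insert(0, "arm", arm)
            ddvh.insert(0, "patient", i)
            delta_frames.append(ddvh)
        done(operation="qa.delta_dvh on log-derived delivered surrogate")

    done = stage("complexity")
    comp_frames = []
    for arm, (mod_cranial, mod_spinal) in (("FP", (0.8, 0.3)), ("S", (0.4, 0.3))):
        cranial = generate_plan(n_beams=2, modulation_level=mod_cranial,
                                seed=config.seed + 10, isocenter="iso-1",
                                plan_id=f"{arm}")
        spinal = generate_plan(n_beams=2, modulation_level=mod_spinal,
                               seed=config.seed + 11, isocenter="iso-2",
                               plan_id=f"{arm}", beam_mu=200.0)
        from .plans import BeamPlan
        plan = BeamPlan(cranial.beams + spinal.beams, arm)
        for i, b in enumerate(plan.beams):
            b.name = f"{arm}_b{i}"
        report = aggregate_metrics(plan)
        report.insert(0, "arm", arm)
        comp_frames.append(report)
    done(operation="complexity.aggregate_metrics")

    paths = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6g")
        paths[name] = path

    write("dosimetry", _paired_table(dosi_fp, dosi_s))
    write("ntcp", _paired_table(ntcp_fp, ntcp_s))
    if robust_frames:
        write("robustness", pd.concat(robust_frames, ignore_index=True))
    write("complexity", pd.concat(comp_frames, ignore_index=True))
    write("delta_dvh", pd.concat(delta_frames, ignore_index=True))

    manifest["tables"] = {k: str(v) for k, v in paths.items()}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    paths["manifest"] = manifest_path
    return paths
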
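"""MLC aperture geometry and plan-complexity metric tests."""

import math

import numpy as np
import pytest

from csieval import (aggregate_metrics, aperture_geometry,
                     aperture_irregularity, beam_irregularity,
                     generate_plan, mcs, small_aperture_score)
from csieval.complexity import beam_metrics
from csieval.plans import Beam, BeamPlan, ControlPoint


def _rect_cp(n_pairs=10, gap=40.0, mu=1.0):
    half = gap / 2
    return ControlPoint(mu, np.full(n_pairs, -half), np.full(n_pairs, half))


def _raster_perimeter_oracle(left, right, width):
    """Brute-force perimeter of a union of pair rectangles on a fine raster.

    Rasterizes the aperture at 0.25 mm and counts exposed pixel edges; exact
    for axis-aligned staircase shapes when positions are multiples of the
    raster step.
    """
    step = 0.25
    x0 = min(left) - 2
    x1 = max(right) + 2
    nx = int(round((x1 - x0) / step))
    ny = int(round(len(left) * width / step))
    img = np.zeros((ny, nx), dtype=bool)
    rows_per_pair = int(round(width / step))
    for i, (l, r) in enumerate(zip(left, right)):
        c0 = int(round((l - x0) / step))
        c1 = int(round((r - x0) / step))
        img[i * rows_per_pair:(i + 1) * rows_per_pair, c0:c1] = True
    padded = np.pad(img, 1)
    edges = 0
    for axis in (0, 1):
        edges += np.abs(np.diff(padded.astype(int), axis=axis)).sum()
    return edges * step


class TestApertureGeometry:
    def test_rectangle(self):
        g = aperture_geometry(_rect_cp(), leaf_width_mm=5.0)
        assert g.area_mm2 == pytest.approx(2000.0)
        assert g.perimeter_mm == pytest.approx(180.0)
        assert g.n_components == 1

    def test_all_closed(self):
        cp = ControlPoint(1.0, np.zeros(8), np.zeros(8))
        g = aperture_geometry(cp, 5.0)
        assert g.area_mm2 == 0.0 and g.n_components == 0

    def test_staircase_matches_raster_oracle(self):
        rng = np.random.default_rng(5)
        left = np.round(rng.uniform(-30, -5, 12) * 4) / 4
        right = np.round(rng.uniform(5, 30, 12) * 4) / 4
        cp = ControlPoint(1.0, left, right)
        g = aperture_geometry(cp, 5.0)
        oracle = _raster_perimeter_oracle(left, right, 5.0)
        assert g.perimeter_mm == pytest.approx(oracle, rel=1e-9)

    def test_jaw_clipping_and_disjoint_components(self):
        left = np.array([-20.0, -20.0, 0.0, -20.0, -20.0])
        right = np.array([20.0, 20.0, 0.0, 20.0, 20.0])  # middle pair closed
        cp = ControlPoint(1.0, left, right)
        g = aperture_geometry(cp, 5.0)
        assert g.n_components == 2
        clipped = aperture_geometry(cp, 5.0, jaws_mm=(-10.0, 10.0, -50.0, 50.0))
        assert clipped.area_mm2 == pytest.approx(4 * 20 * 5)

    def test_leaf_crossing_rejected(self):
        with pytest.raises(ValueError):
            ControlPoint(1.0, np.array([5.0]), np.array([-5.0]))


class TestIrregularity:
    def test_square_is_four_over_pi(self):
        cp = _rect_cp(n_pairs=8, gap=40.0)  # 8 x 5 mm = 40 mm: a square
        g = aperture_geometry(cp, 5.0)
        assert aperture_irregularity(g) == pytest.approx(4 / math.pi, rel=1e-12)

    def test_rasterized_circle_approaches_staircase_limit(self):
        # staircase perimeter of a disc tends to 8r, so AI -> 16/pi^2
        r, lw = 50.0, 1.0
        n = int(2 * r / lw) + 20
        yc = (np.arange(n) - (n - 1) / 2) * lw
        half = np.sqrt(np.clip(r ** 2 - yc ** 2, 0.0, None))
        cp = ControlPoint(1.0, -half, half)
        ai = aperture_irregularity(aperture_geometry(cp, lw))
        assert ai >= 1.0
        assert ai == pytest.approx(16 / math.pi ** 2, rel=0.01)

    def test_ai_at_least_one_for_random_single_components(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(2, 15))
            left = rng.uniform(-30, -2, n)
            right = rng.uniform(2, 30, n)
            g = aperture_geometry(ControlPoint(1.0, left, right), 5.0)
            assert g.n_components == 1
            assert aperture_irregularity(g) >= 1.0 - 1e-12

    def test_mu_rescaling_leaves_pi_unchanged(self):
        plan = generate_plan(n_beams=1, modulation_level=0.6, seed=3)
        beam = plan.beams[0]
        pi1 = beam_irregularity(beam)
        scaled = Beam(beam.name, [ControlPoint(cp.mu * 10, cp.bank_a_mm,
                                               cp.bank_b_mm, cp.jaws_mm, cp.gantry_deg)
                                  for cp in beam.control_points],
                      beam.isocenter, beam.leaf_width_mm)
        assert beam_irregularity(scaled) == pytest.approx(pi1, rel=1e-12)


class TestMcs:
    def test_static_open_field_is_one(self):
        beam = Beam("static", [_rect_cp(mu=2.0) for _ in range(5)])
        assert mcs(beam) == pytest.approx(1.0)

    def test_modulated_plan_scores_lower(self):
        hi = generate_plan(n_beams=1, modulation_level=0.9, seed=7).beams[0]
        lo = generate_plan(n_beams=1, modulation_level=0.2, seed=7).beams[0]
        assert mcs(hi) < mcs(lo) <= 1.0
        assert 0.0 < mcs(hi)

    def test_mu_rescaling_invariance(self):
        beam = generate_plan(n_beams=1, modulation_level=0.5, seed=9).beams[0]
        scaled = Beam(beam.name, [ControlPoint(cp.mu * 7, cp.bank_a_mm, cp.bank_b_mm,
                                               cp.jaws_mm, cp.gantry_deg)
                                  for cp in beam.control_points])
        assert mcs(scaled) == pytest.approx(mcs(beam), rel=1e-12)


class TestSas10:
    def test_extremes(self):
        all_small = Beam("s", [ControlPoint(1.0, np.full(6, -2.5), np.full(6, 2.5))])
        all_large = Beam("l", [ControlPoint(1.0, np.full(6, -10.0), np.full(6, 10.0))])
        assert small_aperture_score(all_small) == 1.0
        assert small_aperture_score(all_large) == 0.0

    def test_mu_weighted_half(self):
        small = ControlPoint(5.0, np.full(6, -2.5), np.full(6, 2.5))
        large = ControlPoint(5.0, np.full(6, -10.0), np.full(6, 10.0))
        beam = Beam("b", [small, large])
        assert small_aperture_score(beam) == pytest.approx(0.5)


class TestAggregate:
    def test_static_field_report(self):
        beam = Beam("s", [ControlPoint(10.0, np.full(10, -15.0), np.full(10, 15.0))
                          for _ in range(3)])
        m = beam_metrics(beam)
        assert m["MLG_cm"] == pytest.approx(3.0)
        assert m["MFA_cm2"] == pytest.approx(15.0)
        assert m["MLT_cm"] == 0.0

    def test_merging_identical_beams_doubles_mu_only(self):
        plan1 = generate_plan(n_beams=1, modulation_level=0.5, seed=12)
        b = plan1.beams[0]
        twin = Beam("twin", b.control_points, b.isocenter, b.leaf_width_mm)
        plan2 = BeamPlan([b, twin], "double")
        r1 = aggregate_metrics(plan1)
        r2 = aggregate_metrics(plan2)
        p1 = r1[r1["scope"] == "plan"].iloc[0]
        p2 = r2[r2["scope"] == "plan"].iloc[0]
        assert p2["MU"] == pytest.approx(2 * p1["MU"])
        for key in ("PI", "MCS", "SAS10", "MFA_cm2", "MLG_cm", "MLT_cm"):
            assert p2[key] == pytest.approx(p1[key], rel=1e-12)

    def test_isocenter_group_direction(self):
        cranial = generate_plan(n_beams=2, modulation_level=0.9, seed=13,
                                isocenter="iso-1")
        spinal = generate_plan(n_beams=2, modulation_level=0.2, seed=14,
                               isocenter="iso-2")
        plan = BeamPlan(cranial.beams + spinal.beams)
        for i, b in enumerate(plan.beams):
            b.name = f"b{i}"
        report = aggregate_metrics(plan).set_index("label")
        iso1 = report.loc["iso-1"]
        iso2 = report.loc["iso-2"]
        assert iso1["MFA_cm2"] < iso2["MFA_cm2"]
        assert iso1["SAS10"] > iso2["SAS10"]
        assert iso1["MCS"] < iso2["MCS"]

    def test_modulation_monotonicity_over_seeds(self):
        for seed in range(10):
            levels = [0.1, 0.5, 1.0]
            ms = [beam_metrics(generate_plan(n_beams=1, modulation_level=m,
                                             seed=seed).beams[0])
                  for m in levels]
            pis = [m["PI"] for m in ms]
            sass = [m["SAS10"] for m in ms]
            mcss = [m["MCS"] for m in ms]
            assert pis[0] <= pis[1] <= pis[2], seed
            assert sass[0] <= sass[1] <= sass[2], seed
            assert mcss[0] >= mcss[1] >= mcss[2], seed
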
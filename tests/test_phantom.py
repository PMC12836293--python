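"""Synthetic generator tests: phantom geometry, dose recipes, plans, logs."""

import numpy as np
import pytest

from csieval import (DoseRecipe, PhantomSpec, fp_recipe, generate_dose,
                     generate_log, generate_phantom, generate_plan, s_recipe)
from csieval.qa import log_rms

COARSE = dict(grid_shape=(50, 50, 125), spacing_mm=(4.0, 4.0, 4.0))


class TestPhantomGeometry:
    def test_structure_inventory_and_containment(self, coarse_phantom):
        _, masks = coarse_phantom
        expected = {"PTV_cranial", "PTV_spinal", "scalp", "hippocampus",
                    "hypothalamus", "pituitary", "cochlea", "vertebrae"}
        assert expected <= set(masks)
        for name in ("hippocampus", "hypothalamus", "pituitary", "cochlea"):
            inside = masks[name].mask & masks["PTV_cranial"].mask
            assert inside.sum() == masks[name].voxel_count, name
        assert not (masks["scalp"].mask & masks["PTV_cranial"].mask).any()

    def test_hippocampus_volume_plausible(self):
        _, masks = generate_phantom(PhantomSpec(seed=0))  # 2 mm default
        assert 1.0 <= masks["hippocampus"].volume_cc <= 6.0

    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(**COARSE, seed=5)
        _, a = generate_phantom(spec)
        _, b = generate_phantom(spec)
        for name in a:
            np.testing.assert_array_equal(a[name].mask, b[name].mask)

    def test_volumes_stable_under_spacing_doubling(self):
        _, fine = generate_phantom(PhantomSpec(grid_shape=(100, 100, 250),
                                               spacing_mm=(2.0, 2.0, 2.0), seed=3))
        _, coarse = generate_phantom(PhantomSpec(**COARSE, seed=3))
        for name in fine:
            ratio = coarse[name].volume_cc / fine[name].volume_cc
            assert 0.85 <= ratio <= 1.15, (name, ratio)

    def test_empty_structure_names_culprit(self):
        params = {"speck": {"kind": "ellipsoid", "offset": (2.0, 2.0, 2.0),
                            "semi_axes": (0.5, 0.5, 0.5)}}
        spec = PhantomSpec(**COARSE, structure_params=params,
                           position_jitter_mm=0.0)
        with pytest.raises(ValueError, match="speck"):
            generate_phantom(spec)


class TestDoseRecipes:
    def test_standard_mode_targets_near_prescription(self, coarse_phantom, coarse_doses):
        _, masks = coarse_phantom
        _, dose_s = coarse_doses
        ptv = masks["PTV_cranial"].mask | masks["PTV_spinal"].mask
        assert dose_s.values[ptv].mean() == pytest.approx(23.4, rel=0.02)
        hip = dose_s.values[masks["hippocampus"].mask].mean()
        assert 22.7 <= hip <= 25.1
        for name in ("hypothalamus", "pituitary", "cochlea"):
            assert dose_s.values[masks[name].mask].mean() == pytest.approx(23.4, rel=0.05)

    def test_functional_sparing_hits_targets_with_coverage(self, coarse_phantom,
                                                           coarse_doses):
        _, masks = coarse_phantom
        dose_fp, _ = coarse_doses
        recipe = fp_recipe()
        for name, target in recipe.avoidance_targets.items():
            mean = dose_fp.values[masks[name].mask].mean()
            assert mean == pytest.approx(target, rel=0.10), name
        hip = dose_fp.values[masks["hippocampus"].mask].mean()
        assert 11.2 <= hip <= 13.6
        ptv = masks["PTV_cranial"].mask | masks["PTV_spinal"].mask
        d95 = np.quantile(dose_fp.values[ptv], 0.05)
        assert d95 >= 0.95 * recipe.prescription_Gy

    def test_noise_free_uniform_recipe_constant_inside_ptv(self, coarse_phantom):
        template, masks = coarse_phantom
        recipe = DoseRecipe(noise_sd_Gy=0.0, vertebral_gradient_Gy=None)
        dose = generate_dose(template, masks, recipe, np.random.default_rng(0))
        core = masks["hippocampus"].mask   # deep inside the target
        vals = dose.values[core]
        assert np.ptp(vals) < 1e-6 * vals.mean()

    def test_dose_finite_nonnegative_and_deterministic(self, coarse_phantom):
        template, masks = coarse_phantom
        a = generate_dose(template, masks, fp_recipe(), np.random.default_rng(9))
        b = generate_dose(template, masks, fp_recipe(), np.random.default_rng(9))
        np.testing.assert_array_equal(a.values, b.values)
        assert np.all(np.isfinite(a.values)) and np.all(a.values >= 0)

    def test_infeasible_recipe_rejected(self, coarse_phantom):
        template, masks = coarse_phantom
        bad = DoseRecipe(mode="functional_sparing",
                         avoidance_targets={"PTV_cranial": 10.0})
        with pytest.raises(ValueError, match="infeasible"):
            generate_dose(template, masks, bad, np.random.default_rng(0))

    def test_recipe_fidelity_across_seeds(self):
        # parameter-recovery surface for the downstream modules
        recipe = fp_recipe()
        for seed in range(5):
            template, masks = generate_phantom(PhantomSpec(**COARSE, seed=seed))
            dose = generate_dose(template, masks, recipe,
                                 np.random.default_rng(seed + 100))
            for name, target in recipe.avoidance_targets.items():
                mean = dose.values[masks[name].mask].mean()
                assert mean == pytest.approx(target, rel=0.10), (seed, name)

    def test_avoidance_target_above_prescription_rejected(self):
        with pytest.raises(ValueError, match="below the prescription"):
            DoseRecipe(mode="functional_sparing",
                       avoidance_targets={"hippocampus": 30.0})


class TestPlanGenerator:
    def test_zero_modulation_is_static_open_field(self):
        from csieval.complexity import beam_metrics
        plan = generate_plan(n_beams=1, n_cp_per_beam=20, modulation_level=0.0, seed=1)
        m = beam_metrics(plan.beams[0])
        assert m["MLT_cm"] == 0.0
        assert m["MCS"] == pytest.approx(1.0)

    def test_same_seed_identical_plan(self):
        a = generate_plan(modulation_level=0.7, seed=4, n_cp_per_beam=10)
        b = generate_plan(modulation_level=0.7, seed=4, n_cp_per_beam=10)
        for ba, bb in zip(a.beams, b.beams):
            for ca, cb in zip(ba.control_points, bb.control_points):
                np.testing.assert_array_equal(ca.bank_a_mm, cb.bank_a_mm)
                np.testing.assert_array_equal(ca.bank_b_mm, cb.bank_b_mm)
                assert ca.mu == cb.mu

    def test_bank_ordering_travel_limit_and_mu_budget(self):
        plan = generate_plan(n_beams=2, n_cp_per_beam=30, modulation_level=1.0,
                             seed=2, beam_mu=300.0)
        for beam in plan.beams:
            assert beam.total_mu == pytest.approx(300.0)
            prev = None
            for cp in beam.control_points:
                assert cp.mu > 0
                assert np.all(cp.bank_a_mm <= cp.bank_b_mm + 1e-9)
                if prev is not None:
                    assert np.max(np.abs(cp.bank_a_mm - prev.bank_a_mm)) <= 50.0 + 1e-9
                    assert np.max(np.abs(cp.bank_b_mm - prev.bank_b_mm)) <= 50.0 + 1e-9
                prev = cp

    def test_sas10_larger_at_high_modulation(self):
        from csieval.complexity import small_aperture_score
        hi = generate_plan(n_beams=1, modulation_level=1.0, seed=6)
        lo = generate_plan(n_beams=1, modulation_level=0.2, seed=6)
        assert small_aperture_score(hi.beams[0]) > small_aperture_score(lo.beams[0])


class TestLogGenerator:
    def test_zero_noise_log_equals_plan(self):
        plan = generate_plan(n_beams=1, n_cp_per_beam=15, modulation_level=0.5, seed=8)
        log = generate_log(plan, mlc_sd_mm=0.0, gantry_sd_deg=0.0, seed=8)
        report = log_rms(plan, log)
        assert report.mlc_rms_mm == 0.0
        assert report.gantry_rms_deg == 0.0

    def test_rms_recovers_injected_sd(self):
        plan = generate_plan(n_beams=2, n_cp_per_beam=120, modulation_level=0.4,
                             seed=10, n_pairs=60)
        log = generate_log(plan, mlc_sd_mm=0.5, gantry_sd_deg=0.3, seed=11)
        report = log_rms(plan, log)
        assert report.mlc_rms_mm == pytest.approx(0.5, rel=0.10)
        assert report.gantry_rms_deg == pytest.approx(0.3, rel=0.10)

    def test_same_seed_identical_log(self):
        plan = generate_plan(n_beams=1, n_cp_per_beam=10, modulation_level=0.5, seed=1)
        a = generate_log(plan, 0.5, 0.3, seed=2)
        b = generate_log(plan, 0.5, 0.3, seed=2)
        for ba, bb in zip(a.beams, b.beams):
            for ca, cb in zip(ba.control_points, bb.control_points):
                np.testing.assert_array_equal(ca.bank_a_mm, cb.bank_a_mm)
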
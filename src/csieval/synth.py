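"""Synthetic craniospinal phantom, dose, plan and delivery-log generation.

The generator emulates the statistical structure a craniospinal-irradiation
(CSI) evaluation assumes, so that every downstream stage (DVH metrics, NTCP,
robustness, complexity, QA) can be exercised without patient data:

* a head sphere with a 5 mm scalp shell, paired hippocampi, hypothalamus,
  pituitary and paired cochleae inside the cranial target, and a spinal
  target cylinder with a vertebral slab abutting it anteriorly;
* a 23.4 Gy / 13-fraction dose distribution, either "standard" (uniform
  coverage, all intracranial structures near prescription) or
  "functional_sparing" (avoidance dips steering each spared structure to a
  configured mean dose while keeping target coverage);
* VMAT-like control-point sequences of controllable modulation, and
  delivery logs with Gaussian mechanical noise.

Avoidance dips are smooth subtractive wells: each well kernel is the
Gaussian-blurred structure indicator (normalized to unit peak), and the
well amplitudes are obtained by solving the small linear system that makes
every spared structure's mean dose hit its target exactly — structure means
are linear in the amplitudes, and neighbouring wells couple. Dose is
clipped at zero afterwards.

Randomness is confined to ``numpy.random.Generator`` objects passed
explicitly; the same seed reproduces phantoms, doses, plans and logs
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import DoseGrid, StructureMask
from .plans import Beam, BeamPlan, ControlPoint, DeliveryLog

__all__ = ["PhantomSpec", "DoseRecipe", "generate_phantom", "generate_dose",
           "generate_plan", "generate_log", "fp_recipe", "s_recipe"]

PRESCRIPTION_GY = 23.4
N_FRACTIONS = 13

#: default per-structure descriptors: center offset from the head center
#: (mm; x, y, z with +z inferior) and ellipsoid semi-axes or shell radii.
DEFAULT_STRUCTURES = {
    "hippocampus": {"kind": "paired_ellipsoid", "offset": (30.0, 0.0, 5.0),
                    "semi_axes": (12.0, 6.0, 6.0)},
    "hypothalamus": {"kind": "ellipsoid", "offset": (0.0, -8.0, 18.0),
                     "semi_axes": (9.0, 6.0, 5.0)},
    "pituitary": {"kind": "ellipsoid", "offset": (0.0, -8.0, 32.0),
                  "semi_axes": (6.0, 5.0, 4.0)},
    "cochlea": {"kind": "paired_ellipsoid", "offset": (55.0, 0.0, 10.0),
                "semi_axes": (5.0, 5.0, 5.0)},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic head+spine phantom."""

    grid_shape: tuple[int, int, int] = (100, 100, 250)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    head_radius_mm: float = 80.0
    spine_length_mm: float = 320.0
    scalp_thickness_mm: float = 5.0
    spinal_radius_mm: float = 22.0
    structure_params: dict = field(default_factory=lambda: dict(DEFAULT_STRUCTURES))
    position_jitter_mm: float = 2.0   # per-seed anatomical variation
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacings must be positive")
        extent = [n * s for n, s in zip(self.grid_shape, self.spacing_mm)]
        if 2 * self.head_radius_mm > min(extent[0], extent[1]):
            raise ValueError("head does not fit inside the grid")
        if self.head_radius_mm * 2 + self.spine_length_mm > extent[2]:
            raise ValueError("head plus spine does not fit along z")


@dataclass(frozen=True)
class DoseRecipe:
    """Target dose structure for the synthetic distribution."""

    prescription_Gy: float = PRESCRIPTION_GY
    n_fractions: int = N_FRACTIONS
    mode: str = "standard"                      # or "functional_sparing"
    avoidance_targets: dict = field(default_factory=dict)   # structure -> mean Gy
    penumbra_sigma_mm: float = 6.0
    noise_sd_Gy: float = 0.05
    vertebral_gradient_Gy: float | None = None  # imposed D2%-D98% in the vertebrae
    well_sigma_mm: float = 6.0
    dilation_mm: float = 12.0

    def __post_init__(self) -> None:
        if self.prescription_Gy <= 0:
            raise ValueError("prescription must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.mode not in ("standard", "functional_sparing"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name, target in self.avoidance_targets.items():
            if target >= self.prescription_Gy:
                raise ValueError(
                    f"avoidance target for {name!r} must be below the prescription")


def fp_recipe() -> DoseRecipe:
    """Functional-sparing recipe: spared-structure mean-dose targets."""
    return DoseRecipe(
        mode="functional_sparing",
        avoidance_targets={"hippocampus": 12.4, "hypothalamus": 14.7,
                           "pituitary": 15.4, "cochlea": 21.4},
        vertebral_gradient_Gy=4.7)


def s_recipe() -> DoseRecipe:
    """Standard recipe: uniform coverage, no avoidance dips."""
    return DoseRecipe(mode="standard", vertebral_gradient_Gy=8.7)


# --------------------------------------------------------------------------

def _world_coords(spec: PhantomSpec):
    axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing_mm)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(x, y, z, center, semi) -> np.ndarray:
    return ((x - center[0]) / semi[0]) ** 2 + ((y - center[1]) / semi[1]) ** 2 \
        + ((z - center[2]) / semi[2]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """Build the phantom geometry: a zero dose-grid template plus masks.

    Structures: PTV_cranial (head sphere minus the scalp shell), scalp
    (outer 5 mm shell), hippocampus / hypothalamus / pituitary / cochlea
    inside the cranial target, PTV_spinal (cylinder) and a vertebral slab
    abutting it anteriorly. Small per-seed center jitter emulates
    inter-patient anatomical variation.
    """
    rng = np.random.default_rng(spec.seed)
    x, y, z = _world_coords(spec)
    extent = [n * s for n, s in zip(spec.grid_shape, spec.spacing_mm)]
    head_c = np.array([extent[0] / 2, extent[1] / 2, spec.head_radius_mm])

    r2 = (x - head_c[0]) ** 2 + (y - head_c[1]) ** 2 + (z - head_c[2]) ** 2
    inner = spec.head_radius_mm - spec.scalp_thickness_mm
    masks: dict[str, np.ndarray] = {
        "PTV_cranial": r2 <= inner ** 2,
        "scalp": (r2 <= spec.head_radius_mm ** 2) & (r2 > inner ** 2),
    }

    for name, p in spec.structure_params.items():
        jitter = rng.normal(0.0, spec.position_jitter_mm, size=3)
        off = np.asarray(p["offset"], dtype=float)
        semi = p["semi_axes"]
        if p["kind"] == "paired_ellipsoid":
            left = _ellipsoid(x, y, z, head_c + (-off[0] + jitter[0], off[1] + jitter[1],
                                                 off[2] + jitter[2]), semi)
            right = _ellipsoid(x, y, z, head_c + (off[0] + jitter[0], off[1] + jitter[1],
                                                  off[2] + jitter[2]), semi)
            masks[name] = left | right
        else:
            masks[name] = _ellipsoid(x, y, z, head_c + off + jitter, semi)

    # spine: target cylinder posterior, vertebral slab abutting anteriorly
    z0 = head_c[2] + inner - 10.0
    z1 = min(z0 + spec.spine_length_mm, extent[2] - 2.0)
    in_z = (z >= z0) & (z <= z1)
    cy = head_c[1] + spec.spinal_radius_mm * 0.4
    rxy2 = (x - head_c[0]) ** 2 + (y - cy) ** 2
    masks["PTV_spinal"] = in_z & (rxy2 <= spec.spinal_radius_mm ** 2)
    vert_back = cy - spec.spinal_radius_mm * 0.8
    masks["vertebrae"] = in_z & (np.abs(x - head_c[0]) <= 22.0) \
        & (y <= vert_back) & (y >= vert_back - 26.0) & np.ones_like(masks["PTV_spinal"])

    out = {}
    for name, m in masks.items():
        m = np.broadcast_to(m, spec.grid_shape).copy()
        if not m.any():
            raise ValueError(
                f"structure {name!r} is empty at spacing {spec.spacing_mm}")
        out[name] = StructureMask(name, m, spec.spacing_mm)
    template = DoseGrid(np.zeros(spec.grid_shape), spec.spacing_mm)
    return template, out


def _blur(arr: np.ndarray, sigma_mm: float,
          spacing: tuple[float, float, float]) -> np.ndarray:
    return ndimage.gaussian_filter(arr, sigma=[sigma_mm / s for s in spacing])


def generate_dose(template: DoseGrid, masks: dict[str, StructureMask],
                  recipe: DoseRecipe, rng: np.random.Generator) -> DoseGrid:
    """Synthesize a dose distribution realizing the recipe on the phantom.

    The base field is the prescription inside the (dilated) union of the
    targets with a Gaussian penumbra; functional-sparing mode subtracts the
    avoidance wells described in the module docstring; a linear
    anterior-posterior ramp inside the vertebrae imposes the requested
    D2%-D98% spread; zero-mean Gaussian noise is added last.
    """
    spacing = template.spacing_mm
    ptv = masks["PTV_cranial"].mask | masks["PTV_spinal"].mask

    if recipe.mode == "functional_sparing":
        for name in recipe.avoidance_targets:
            if name not in masks:
                raise ValueError(f"avoidance structure {name!r} not in phantom")
            inside = masks[name].mask & ptv
            if inside.sum() > 0.5 * ptv.sum():
                raise ValueError(
                    f"infeasible recipe: avoidance structure {name!r} "
                    "covers most of the target")

    dist = ndimage.distance_transform_edt(~ptv, sampling=spacing)
    region = (dist <= recipe.dilation_mm).astype(np.float64)
    base = 1.005 * recipe.prescription_Gy * _blur(region, recipe.penumbra_sigma_mm, spacing)

    if recipe.vertebral_gradient_Gy is not None and "vertebrae" in masks:
        vert = masks["vertebrae"].mask
        yy = np.broadcast_to(
            np.arange(template.shape[1])[None, :, None] * spacing[1], template.shape)
        yv = yy[vert]
        span = yv.max() - yv.min()
        if span > 0:
            # posterior face (largest y, abutting the spinal target) stays at
            # prescription; with whole-voxel discrete levels the D2%-D98%
            # spread of a linear ramp equals its full span
            g = recipe.vertebral_gradient_Gy
            ramp = recipe.prescription_Gy - g * (yv.max() - yv) / span
            base[vert] = ramp

    if recipe.mode == "functional_sparing" and recipe.avoidance_targets:
        names = list(recipe.avoidance_targets)
        kernels = []
        for name in names:
            k = _blur(masks[name].mask.astype(np.float64), recipe.well_sigma_mm, spacing)
            kernels.append(k / k.max())
        # exact linear solve: mean_s(base - sum_j A_j K_j) = target_s
        m = np.array([[kernels[j][masks[s].mask].mean() for j in range(len(names))]
                      for s in names])
        b = np.array([base[masks[s].mask].mean() - recipe.avoidance_targets[s]
                      for s in names])
        amps = np.linalg.solve(m, b)
        for a, k in zip(amps, kernels):
            base -= a * k

    if recipe.noise_sd_Gy > 0:
        base = base + rng.normal(0.0, recipe.noise_sd_Gy, size=base.shape)
    return template.copy_with(np.clip(base, 0.0, None))


# --------------------------------------------------------------------------

def generate_plan(n_beams: int = 2, n_cp_per_beam: int = 60,
                  modulation_level: float = 0.5, seed: int = 0,
                  n_pairs: int = 40, leaf_width_mm: float = 5.0,
                  isocenter: str = "iso-1", beam_mu: float = 300.0,
                  plan_id: str = "synthetic") -> BeamPlan:
    """Generate a VMAT-like plan of controllable modulation.

    ``modulation_level`` in [0, 1] scales a fixed per-seed jitter field, so
    at the same seed a higher level strictly produces more leaf travel,
    smaller apertures and more small gaps. Level 0 is a static rectangular
    field (identical control points).
    """
    if not 0.0 <= modulation_level <= 1.0:
        raise ValueError("modulation_level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = modulation_level
    half_open = 40.0
    beams = []
    for bi in range(n_beams):
        jitter_l = rng.normal(0.0, 10.0, size=(n_cp_per_beam, n_pairs))
        jitter_r = rng.normal(0.0, 10.0, size=(n_cp_per_beam, n_pairs))
        centers = rng.normal(0.0, 8.0, size=(n_cp_per_beam, n_pairs))
        order = np.stack([rng.permutation(n_pairs) for _ in range(n_cp_per_beam)])
        mu_raw = rng.uniform(0.5, 1.5, size=n_cp_per_beam)
        gantry = np.linspace(180.0, -175.0, n_cp_per_beam) % 360.0

        left = -half_open + m * jitter_l
        right = half_open + m * jitter_r
        # force k pairs per CP to a small (5 mm) gap; k grows with modulation
        k = int(round(m * 0.4 * n_pairs))
        for t in range(n_cp_per_beam):
            small = order[t, :k]
            c = m * centers[t, small]
            left[t, small] = c - 2.5
            right[t, small] = c + 2.5
        right = np.maximum(right, left)         # bank ordering
        # respect a maximum per-CP leaf travel of 50 mm
        for t in range(1, n_cp_per_beam):
            left[t] = left[t - 1] + np.clip(left[t] - left[t - 1], -50.0, 50.0)
            right[t] = right[t - 1] + np.clip(right[t] - right[t - 1], -50.0, 50.0)
        right = np.maximum(right, left)

        mu = mu_raw / mu_raw.sum() * beam_mu
        cps = [ControlPoint(float(mu[t]), left[t], right[t],
                            (-150.0, 150.0, -150.0, 150.0), float(gantry[t]))
               for t in range(n_cp_per_beam)]
        beams.append(Beam(f"beam{bi + 1}", cps, isocenter, leaf_width_mm))
    return BeamPlan(beams, plan_id)


def generate_log(plan: BeamPlan, mlc_sd_mm: float = 0.0,
                 gantry_sd_deg: float = 0.0, seed: int = 0) -> DeliveryLog:
    """Delivery log: planned values plus zero-mean Gaussian mechanical noise."""
    if mlc_sd_mm < 0 or gantry_sd_deg < 0:
        raise ValueError("noise standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    beams = []
    for b in plan.beams:
        cps = []
        for cp in b.control_points:
            a = cp.bank_a_mm + rng.normal(0.0, mlc_sd_mm, cp.n_pairs) if mlc_sd_mm else cp.bank_a_mm.copy()
            bb = cp.bank_b_mm + rng.normal(0.0, mlc_sd_mm, cp.n_pairs) if mlc_sd_mm else cp.bank_b_mm.copy()
            bb = np.maximum(bb, a)
            g = cp.gantry_deg + (rng.normal(0.0, gantry_sd_deg) if gantry_sd_deg else 0.0)
            cps.append(ControlPoint(cp.mu, a, bb, cp.jaws_mm, float(g)))
        beams.append(Beam(b.name, cps, b.isocenter, b.leaf_width_mm, b.collimator_deg))
    return DeliveryLog(plan.plan_id, beams)
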
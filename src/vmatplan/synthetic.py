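"""Deterministic thorax-like phantoms and synthetic case libraries.

The phantom generator emulates only the topology the planner cares about
(an external contour, two lungs, a heart blob, a spinal-cord column, an
esophagus tube, and a PTV that may penetrate its neighbors); there are no
CT intensities or tissue heterogeneities.  The library generator emulates
the statistical structure of a clinical knowledge base: per-organ achieved
DVH metrics that are approximately linear in the OVH/OZH AUC features with
Gaussian residuals, truncated at zero.  Defaults mirror the source cohort
scale: 103 cases, prescription 50.4 Gy, PTV volumes spanning roughly
85-1700 cc on the default grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dosimetry import MetricSpec
from .geometry import (
    DEFAULT_WINDOW,
    GeometrySignature,
    ROIMask,
    StructureSet,
    VoxelGrid,
    compute_signature,
)
from .prediction import (
    KBCase,
    KnowledgeBase,
    MODEL_FORMS,
    fit_interval_model,
    predict_interval,
)

DEFAULT_N_CASES = 103
DEFAULT_PRESCRIPTION = 50.4  # Gy in 28 fractions

# Generating coefficients (intercept, slope_ovh, slope_ozh, residual sigma)
# per metric, on the metric's clinical scale (Gy, or % for V20Gy).  Line
# metrics have slope_ozh = 0; the spinal-cord metric is geometry-free.
# Residual magnitudes are order-of-magnitude choices exposed in the spec
# of each library, never asserted by tests.
DEFAULT_GEN_COEFFS: dict[str, tuple[float, float, float, float]] = {
    "total_lung.mean": (3.0, 16.0, 6.0, 1.2),
    "total_lung.v_dose.20": (2.0, 35.0, 12.0, 2.5),
    "heart.mean": (2.0, 22.0, 7.0, 1.8),
    "breast_l.mean": (1.0, 9.0, 3.0, 0.8),
    "breast_r.mean": (1.0, 9.0, 3.0, 0.8),
    "esophagus.d_cc.0.5": (18.0, 55.0, 0.0, 3.0),
    "skin.d_cc.0.5": (14.0, 40.0, 0.0, 3.0),
    "spinal_cord.d_cc.0.01": (28.0, 0.0, 0.0, 3.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry template of one synthetic thorax case.

    All organ shapes are placed as fractions of the physical grid extent,
    so the same template scales from the full 3-D grid down to a planar
    slice.  ``seed`` drives the PTV placement/size jitter; identical spec
    and seed give bit-identical masks.
    """

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    seed: int = 0
    ptv_radius_range_mm: tuple[float, float] = (32.0, 60.0)
    ptv_center_mm: tuple[float, float, float] | None = None  # explicit placement
    ptv_offset_scale_mm: float = 30.0
    prescription_dose: float = DEFAULT_PRESCRIPTION

    @classmethod
    def default(cls, seed: int = 0) -> "PhantomSpec":
        return cls(seed=seed)

    @classmethod
    def planar(cls, seed: int = 0) -> "PhantomSpec":
        """Single-slice 64x64 template for fast planner-loop exercises."""
        return cls(
            shape=(64, 64, 1),
            spacing=(4.0, 4.0, 4.0),
            seed=seed,
            ptv_radius_range_mm=(24.0, 48.0),
            ptv_offset_scale_mm=20.0,
        )

    @classmethod
    def compact(cls, seed: int = 0) -> "PhantomSpec":
        """Coarse 3-D template for library-scale generation."""
        return cls(
            shape=(32, 32, 16),
            spacing=(8.0, 8.0, 8.0),
            seed=seed,
            ptv_radius_range_mm=(25.0, 55.0),
            ptv_offset_scale_mm=25.0,
        )


def _ellipsoid(grid: VoxelGrid, center_mm, radii_mm) -> np.ndarray:
    axes = [grid.axis_centers(k) for k in range(3)]
    terms = []
    for k in range(3):
        r = max(radii_mm[k], 1e-6)
        t = ((axes[k] - center_mm[k]) / r) ** 2
        shape = [1, 1, 1]
        shape[k] = -1
        terms.append(t.reshape(shape))
    return terms[0] + terms[1] + terms[2] <= 1.0


def generate_phantom(spec: PhantomSpec) -> StructureSet:
    """Build the structure set of one synthetic thorax case.

    Anterior is the low-y side; the spinal cord sits at the posterior
    midline with a one-voxel radius; the PTV is an ellipsoid jittered
    around one lung (mediastinal placements overlap heart and esophagus,
    mirroring clinical cases where the target penetrates its neighbors).
    """
    grid = VoxelGrid(spec.shape, spec.spacing)
    rng = np.random.default_rng(spec.seed)
    ext_mm = [spec.shape[k] * spec.spacing[k] for k in range(3)]
    cx, cy, cz = (0.5 * (n - 1) * s for n, s in zip(spec.shape, spec.spacing))
    z_full = max(ext_mm[2], spec.spacing[2])  # extrude along z (planar-safe)

    external = _ellipsoid(grid, (cx, cy, cz), (0.46 * ext_mm[0], 0.40 * ext_mm[1], 10 * z_full))

    lung_dx = 0.24 * ext_mm[0]
    lung_r = (0.17 * ext_mm[0], 0.26 * ext_mm[1], 0.45 * z_full)
    lung_l = _ellipsoid(grid, (cx - lung_dx, cy, cz), lung_r)
    lung_r_ = _ellipsoid(grid, (cx + lung_dx, cy, cz), lung_r)

    heart = _ellipsoid(
        grid,
        (cx - 0.07 * ext_mm[0], cy - 0.10 * ext_mm[1], cz),
        (0.13 * ext_mm[0], 0.11 * ext_mm[1], 0.25 * z_full),
    )
    cord = _ellipsoid(
        grid,
        (cx, cy + 0.30 * ext_mm[1], cz),
        (spec.spacing[0], spec.spacing[1], 10 * z_full),
    )
    esophagus = _ellipsoid(
        grid,
        (cx, cy + 0.16 * ext_mm[1], cz),
        (1.6 * spec.spacing[0], 1.6 * spec.spacing[1], 10 * z_full),
    )

    if spec.ptv_center_mm is not None:
        ptv_center = np.asarray(spec.ptv_center_mm, dtype=float)
    else:
        side = -1.0 if rng.random() < 0.5 else 1.0
        base = np.array([cx + side * lung_dx, cy, cz])
        ptv_center = base + rng.uniform(
            -spec.ptv_offset_scale_mm, spec.ptv_offset_scale_mm, size=3
        )
    r0 = rng.uniform(*spec.ptv_radius_range_mm)
    radii = r0 * rng.uniform(0.9, 1.15, size=3)
    if spec.shape[2] == 1:
        # planar case: pin the PTV to the single slice
        ptv_center[2] = cz
        radii[2] = 10 * z_full
    ptv = _ellipsoid(grid, tuple(ptv_center), tuple(radii))
    ptv &= external
    if not ptv.any():
        raise ValueError("PTV template falls outside the phantom grid/external contour")
    for k in range(3):
        if ptv_center[k] < -spec.spacing[k] or ptv_center[k] > ext_mm[k]:
            raise ValueError("PTV template exceeds the phantom grid")

    lungs = (lung_l | lung_r_) & ~heart & ~cord & ~esophagus
    rois = {
        "external": ROIMask(grid, external, "external", "external"),
        "ptv": ROIMask(grid, ptv, "ptv", "target"),
        "total_lung": ROIMask(grid, lungs & external, "total_lung", "oar"),
        "heart": ROIMask(grid, heart & external, "heart", "oar"),
        "spinal_cord": ROIMask(grid, cord & external, "spinal_cord", "oar"),
        "esophagus": ROIMask(grid, esophagus & external & ~cord, "esophagus", "oar"),
    }
    for name, roi in rois.items():
        if roi.is_empty():
            raise ValueError(f"phantom template produced an empty {name!r} mask")
    return StructureSet(grid, rois, spec.prescription_dose)


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryGenSpec:
    """Recipe for one synthetic knowledge base.

    ``coefficients`` maps ``MetricSpec.key`` to (intercept, slope_ovh,
    slope_ozh, sigma) on the metric's clinical scale.  In ``fast`` mode
    metric values are drawn directly from that linear model (truncated at
    zero); in ``planned`` mode they are measured from a dose actually
    optimized on each phantom by the bundled engine.
    """

    n_cases: int = DEFAULT_N_CASES
    metrics: tuple[MetricSpec, ...] = (
        MetricSpec("total_lung", "mean"),
        MetricSpec("total_lung", "v_dose", 20.0),
        MetricSpec("heart", "mean"),
        MetricSpec("spinal_cord", "d_cc", 0.01),
        MetricSpec("esophagus", "d_cc", 0.5),
    )
    coefficients: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GEN_COEFFS)
    )
    seed: int = 0
    mode: str = "fast"
    phantom: PhantomSpec = field(default_factory=PhantomSpec.compact)

    def __post_init__(self):
        if self.mode not in ("fast", "planned"):
            raise ValueError("mode must be 'fast' or 'planned'")
        for key, co in self.coefficients.items():
            if co[3] < 0:
                raise ValueError(f"negative residual sigma for {key}")


def _draw_metric(rng, coeffs, auc_ovh: float, auc_ozh: float) -> float:
    a, b, c, sigma = coeffs
    val = a + b * auc_ovh + c * auc_ozh + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
    return max(0.0, val)


def _planned_metrics(structures: StructureSet, metrics) -> dict[str, float]:
    # one default-objective engine pass; goal adaptation would itself need
    # a library, so planned-mode metrics come from the unadapted plan
    from .dosimetry import dvh_metric
    from .engine import BeamConfig, Objective, build_influence, inner_optimize

    dp = structures.prescription_dose
    influence = build_influence(structures, BeamConfig(n_angles=12, max_inner_iters=150))
    objectives = [
        Objective("ptv", "min_dose", 0.95 * dp, 100.0),
        Objective("ptv", "uniform_dose", dp, 100.0),
        Objective("ptv", "max_dose", 1.05 * dp, 100.0),
    ]
    for m in metrics:
        if m.organ in structures and not structures[m.organ].is_empty():
            objectives.append(Objective(m.organ, "mean_below", 0.3 * dp, 10.0))
    res = inner_optimize(influence, objectives, dict(structures.rois))
    out = {}
    for m in metrics:
        if m.organ in structures:
            out[m.key] = dvh_metric(res.dose, structures[m.organ], m)
    return out


def generate_library(spec: LibraryGenSpec) -> KnowledgeBase:
    """Generate a knowledge base of synthetic prior cases.

    Each case is a phantom with its true OVH/OZH signature; achieved
    metrics follow the generating linear model (fast mode) or an actual
    engine run (planned mode).
    """
    if spec.n_cases < 6:
        raise ValueError("a knowledge base needs at least 6 cases")
    rng = np.random.default_rng(spec.seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=spec.n_cases)
    organs = sorted({m.organ for m in spec.metrics})
    cases: list[KBCase] = []
    for i in range(spec.n_cases):
        ph = generate_phantom(replace(spec.phantom, seed=int(case_seeds[i])))
        sig = compute_signature(ph, organs=organs)
        if spec.mode == "planned":
            achieved = _planned_metrics(ph, spec.metrics)
        else:
            achieved = {}
            for m in spec.metrics:
                if m.organ not in sig:
                    continue
                co = spec.coefficients.get(m.key)
                if co is None:
                    raise KeyError(f"no generating coefficients for {m.key}")
                g = sig[m.organ]
                achieved[m.key] = _draw_metric(rng, co, g.auc_ovh, g.auc_ozh)
        cases.append(KBCase(f"case{i:03d}", sig, achieved))
    return KnowledgeBase(cases, DEFAULT_WINDOW)


# ---------------------------------------------------------------------------
# Interval-coverage Monte Carlo
# ---------------------------------------------------------------------------

def coverage_experiment(
    spec: LibraryGenSpec | None = None,
    metric: MetricSpec = MetricSpec("total_lung", "v_dose", 20.0),
    n_test: int = 10_000,
    seed: int = 0,
    n_libraries: int = 20,
    coefficients: tuple[float, float, float, float] = (0.02, 0.5, 0.2, 0.02),
) -> float:
    """Empirical coverage of the +/- 3 sigma_res prediction intervals.

    Fits the interval model on ``n_libraries`` independently generated
    libraries and, for each, draws fresh cases from the same generating
    model.  Fresh-case AUC features are resampled from the library's own
    feature pairs, which reproduces the case-generator's feature
    distribution (including the OVH/OZH correlation) without
    re-voxelizing ten thousand phantoms; the fresh residuals are new
    Gaussian draws.  Returns the fraction of all ``n_test`` fresh cases
    whose true metric falls inside its interval; under Gaussian residuals
    this estimates 2*Phi(3) - 1 = 0.9973.
    """
    if spec is None:
        spec = LibraryGenSpec(
            metrics=(metric,), coefficients={metric.key: coefficients}, seed=seed
        )
    co = spec.coefficients[metric.key]
    if co[3] <= 0:
        raise ValueError("coverage experiment needs a positive residual sigma")
    if spec.mode != "fast":
        raise ValueError("coverage experiment requires fast mode")
    rng = np.random.default_rng(seed)
    lib_seeds = rng.integers(0, 2**31 - 1, size=n_libraries)
    n_per = n_test // n_libraries
    n_hit = 0
    n_tot = 0
    for r in range(n_libraries):
        kb = generate_library(replace(spec, seed=int(lib_seeds[r])))
        model = fit_interval_model(kb, metric)
        x = np.array([c.signature[metric.organ].auc_ovh for c in kb.cases])
        z = np.array([c.signature[metric.organ].auc_ozh for c in kb.cases])
        pick = rng.integers(0, x.size, size=n_per)
        xs, zs = x[pick], z[pick]
        truth = np.maximum(
            0.0, co[0] + co[1] * xs + co[2] * zs + rng.normal(0.0, co[3], size=n_per)
        )
        for j in range(n_per):
            lo, hi = predict_interval(model, xs[j], zs[j])
            n_hit += lo <= truth[j] <= hi
        n_tot += n_per
    return n_hit / n_tot
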
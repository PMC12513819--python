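"""Desk-scale beamlet dose engine and inner fluence optimizer.

This is the stand-in for a clinical optimizer: a parallel-beam influence
matrix (exponential pencil attenuation along exactly-traced rays in the
axial plane), a family of one-sided quadratic dose objectives, and a
projected-gradient solver with backtracking line search.  The planner
layer observes nothing but the returned dose, the per-objective values
F_obj and the total F_tot, so any smooth convex engine honoring the
:class:`EngineResult` contract would do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .dosimetry import DoseGrid
from .geometry import ROIMask, StructureSet, VoxelGrid

OBJECTIVE_KINDS = (
    "min_dose",
    "max_dose",
    "uniform_dose",
    "mean_below",
    "vdose_below",
    "dcc_below",
)


@dataclass(frozen=True)
class Objective:
    """One weighted dose objective.

    ``dose_level`` is in Gy.  ``volume_param`` is a volume fraction in
    [0, 1] for ``vdose_below`` and a volume in cc for ``dcc_below``.
    """

    roi: str
    kind: str
    dose_level: float
    weight: float
    volume_param: float | None = None

    def __post_init__(self):
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.dose_level <= 0:
            raise ValueError("dose_level must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.kind in ("vdose_below", "dcc_below") and (
            self.volume_param is None or self.volume_param < 0
        ):
            raise ValueError(f"{self.kind} needs a non-negative volume_param")


@dataclass(frozen=True)
class BeamConfig:
    """Parallel-beam geometry: equispaced coplanar angles, pencil beamlets."""

    n_angles: int = 36
    beamlet_width_mm: float = 4.0
    mu_per_mm: float = 0.005  # linear attenuation of the pencil deposition
    max_inner_iters: int = 500
    tol: float = 1e-6

    @property
    def angles_deg(self) -> np.ndarray:
        return 360.0 * np.arange(self.n_angles) / self.n_angles


@dataclass
class InfluenceMatrix:
    """Sparse (beamlet, voxel) dose per unit intensity, Gy."""

    matrix: sparse.csr_matrix  # (n_beamlets, n_voxels)
    grid: VoxelGrid
    beamlets: list[tuple[int, int, int]]  # (angle index, offset index, z index)
    config: BeamConfig

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EngineResult:
    """Outcome of one inner optimization.

    ``raw_values`` are the unweighted objective values f_i; ``f_obj`` are
    the weighted contributions w_i * f_i whose sum is ``f_tot``.
    """

    intensities: np.ndarray
    dose: DoseGrid
    raw_values: np.ndarray
    f_obj: np.ndarray
    f_tot: float
    converged: bool
    n_inner: int
    f_history: np.ndarray | None = None  # accepted F_tot per inner iteration


# ---------------------------------------------------------------------------
# Influence matrix
# ---------------------------------------------------------------------------

def _trace_ray_2d(
    shape_xy: tuple[int, int],
    spacing_xy: tuple[float, float],
    origin_xy: tuple[float, float],
    p0: np.ndarray,
    u: np.ndarray,
    length: float,
) -> tuple[list[tuple[int, int]], list[float]]:
    """Exact voxel traversal of one in-plane ray (Amanatides-Woo).

    Returns the visited (ix, iy) voxels in beam order and the intersection
    length (mm) of the ray with each.
    """
    lo = np.array([origin_xy[k] - spacing_xy[k] / 2.0 for k in range(2)])
    hi = lo + np.array([shape_xy[k] * spacing_xy[k] for k in range(2)])
    t0, t1 = 0.0, length
    for k in range(2):
        if abs(u[k]) < 1e-12:
            # half-open membership: a ray on the upper boundary belongs to
            # the next (non-existent) row, keeping opposed beams symmetric
            if not (lo[k] <= p0[k] < hi[k]):
                return [], []
        else:
            ta = (lo[k] - p0[k]) / u[k]
            tb = (hi[k] - p0[k]) / u[k]
            if ta > tb:
                ta, tb = tb, ta
            t0, t1 = max(t0, ta), min(t1, tb)
    if t1 <= t0 + 1e-12:
        return [], []

    p = p0 + (t0 + 1e-9) * u
    idx = [int(np.floor((p[k] - lo[k]) / spacing_xy[k])) for k in range(2)]
    idx = [min(max(idx[k], 0), shape_xy[k] - 1) for k in range(2)]
    step, t_max, t_delta = [0, 0], [math.inf, math.inf], [math.inf, math.inf]
    for k in range(2):
        if u[k] > 1e-12:
            step[k] = 1
            t_max[k] = (lo[k] + (idx[k] + 1) * spacing_xy[k] - p0[k]) / u[k]
            t_delta[k] = spacing_xy[k] / u[k]
        elif u[k] < -1e-12:
            step[k] = -1
            t_max[k] = (lo[k] + idx[k] * spacing_xy[k] - p0[k]) / u[k]
            t_delta[k] = -spacing_xy[k] / u[k]

    cells: list[tuple[int, int]] = []
    lengths: list[float] = []
    t = t0
    while t < t1 - 1e-12:
        k = 0 if t_max[0] <= t_max[1] else 1
        t_next = min(t_max[k], t1)
        seg = t_next - t
        if seg > 1e-12:
            cells.append((idx[0], idx[1]))
            lengths.append(seg)
        t = t_next
        if t_next == t_max[k]:
            idx[k] += step[k]
            t_max[k] += t_delta[k]
            if idx[k] < 0 or idx[k] >= shape_xy[k]:
                break
    return cells, lengths


def build_influence(phantom: StructureSet, config: BeamConfig | None = None) -> InfluenceMatrix:
    """Trace parallel pencil beamlets through the external contour.

    Per angle, beamlets are offset perpendicular to the beam direction in
    the axial plane and replicated on every z slice.  Deposition into a
    voxel is the intersection length times exp(-mu * radiological depth),
    where depth accumulates only inside the external contour (no dose and
    no attenuation outside the patient).  Beamlets that never intersect
    the external contour are dropped.
    """
    cfg = config or BeamConfig()
    if cfg.n_angles < 2:
        raise ValueError("at least 2 beam angles are required")
    if "external" not in phantom:
        raise ValueError("phantom needs an external contour to build beams")
    grid = phantom.grid
    ext = phantom["external"].voxels
    nx, ny, nz = grid.shape
    sx, sy, _ = grid.spacing
    ox, oy = grid.origin[0], grid.origin[1]

    center = np.array([ox + (nx - 1) * sx / 2.0, oy + (ny - 1) * sy / 2.0])
    half_diag = 0.5 * math.hypot(nx * sx, ny * sy)
    n_off = max(1, int(math.ceil(2.0 * half_diag / cfg.beamlet_width_mm)))
    offsets = (np.arange(n_off) - (n_off - 1) / 2.0) * cfg.beamlet_width_mm

    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    beamlets: list[tuple[int, int, int]] = []
    row = 0

    for ai, ang in enumerate(cfg.angles_deg):
        theta = math.radians(ang)
        u = np.array([math.cos(theta), math.sin(theta)])
        perp = np.array([-math.sin(theta), math.cos(theta)])
        for oi, off in enumerate(offsets):
            start = center + off * perp - (half_diag + 1.0) * u
            cells, lengths = _trace_ray_2d(
                (nx, ny), (sx, sy), (ox, oy), start, u, 2.0 * (half_diag + 1.0)
            )
            if not cells:
                continue
            ij = np.array(cells)
            seg = np.array(lengths)
            for iz in range(nz):
                inside = ext[ij[:, 0], ij[:, 1], iz]
                if not inside.any():
                    continue
                # radiological depth at segment midpoints, external-only
                path = seg * inside
                depth = np.cumsum(path) - 0.5 * path
                dep = seg * np.exp(-cfg.mu_per_mm * depth)
                dep = dep[inside]
                flat = np.ravel_multi_index(
                    (ij[inside, 0], ij[inside, 1], np.full(int(inside.sum()), iz)),
                    grid.shape,
                )
                rows.extend([row] * flat.size)
                cols.extend(flat.tolist())
                data.extend(dep.tolist())
                beamlets.append((ai, oi, iz))
                row += 1

    if row == 0:
        raise ValueError("no beamlet intersects the external contour")
    mat = sparse.csr_matrix(
        (data, (rows, cols)), shape=(row, grid.n_voxels), dtype=float
    )
    return InfluenceMatrix(mat, grid, beamlets, cfg)


# ---------------------------------------------------------------------------
# Objective evaluation
# ---------------------------------------------------------------------------

def _hottest_count(volume_cc: float, voxel_cc: float) -> int:
    return max(1, math.ceil(volume_cc / voxel_cc))


def _objective_value(d: np.ndarray, obj: Objective, voxel_cc: float) -> float:
    L = obj.dose_level
    if obj.kind == "min_dose":
        return float(np.mean(np.maximum(0.0, L - d) ** 2) / L**2)
    if obj.kind == "max_dose":
        return float(np.mean(np.maximum(0.0, d - L) ** 2) / L**2)
    if obj.kind == "uniform_dose":
        return float(np.mean((d - L) ** 2) / L**2)
    if obj.kind == "mean_below":
        return float(max(0.0, d.mean() - L) ** 2 / L**2)
    if obj.kind == "vdose_below":
        v = np.count_nonzero(d >= L) / d.size
        return float(max(0.0, v - obj.volume_param) ** 2)
    # dcc_below: max-dose form on the hottest volume_param cc
    n_hot = _hottest_count(obj.volume_param, voxel_cc)
    hot = np.sort(d)[::-1][: min(n_hot, d.size)]
    return float(np.mean(np.maximum(0.0, hot - L) ** 2) / L**2)


def _objective_grad(d: np.ndarray, obj: Objective, voxel_cc: float) -> np.ndarray:
    """Gradient (or descent subgradient) of the raw objective w.r.t. roi dose."""
    L = obj.dose_level
    n = d.size
    g = np.zeros(n)
    if obj.kind == "min_dose":
        g = -2.0 * np.maximum(0.0, L - d) / (n * L**2)
    elif obj.kind == "max_dose":
        g = 2.0 * np.maximum(0.0, d - L) / (n * L**2)
    elif obj.kind == "uniform_dose":
        g = 2.0 * (d - L) / (n * L**2)
    elif obj.kind == "mean_below":
        excess = max(0.0, d.mean() - L)
        g[:] = 2.0 * excess / (n * L**2)
    elif obj.kind == "vdose_below":
        v = np.count_nonzero(d >= L) / n
        excess = v - obj.volume_param
        if excess > 0:
            # push down the coolest voxels above the threshold: the
            # cheapest way to shrink the hot volume (step-function
            # surrogate; line search guards descent)
            above = np.nonzero(d >= L)[0]
            k = max(1, math.ceil(excess * n))
            coolest = above[np.argsort(d[above], kind="stable")[:k]]
            g[coolest] = 2.0 * excess / (n * L)
    else:  # dcc_below -- hottest subvolume recomputed at every step
        n_hot = min(_hottest_count(obj.volume_param, voxel_cc), n)
        hot = np.argsort(d, kind="stable")[::-1][:n_hot]
        g[hot] = 2.0 * np.maximum(0.0, d[hot] - L) / (n_hot * L**2)
    return g


def evaluate_objective(dose: DoseGrid, roi: ROIMask, objective: Objective) -> float:
    """Raw (unweighted) value of one objective; zero iff the objective is met."""
    if roi.is_empty():
        raise ValueError(f"ROI {roi.name!r} is empty")
    d = dose.dose[roi.voxels]
    return _objective_value(d, objective, roi.grid.voxel_volume_cc)


# ---------------------------------------------------------------------------
# Inner optimization
# ---------------------------------------------------------------------------

def inner_optimize(
    influence: InfluenceMatrix,
    objectives: list[Objective],
    rois: dict[str, ROIMask],
    init_intensities: np.ndarray | None = None,
    max_inner_iters: int | None = None,
    tol: float | None = None,
) -> EngineResult:
    """Projected-gradient descent on F_tot = sum_i w_i f_i(dose(x)).

    Non-negativity of the beamlet intensities is enforced by projection;
    the step size is found by backtracking (halving) under an Armijo
    decrease condition, which guarantees F_tot is non-increasing across
    iterations.  Deterministic for a fixed initial point.
    """
    max_iters = max_inner_iters if max_inner_iters is not None else influence.config.max_inner_iters
    rel_tol = tol if tol is not None else influence.config.tol
    A = influence.matrix
    grid = influence.grid
    voxel_cc = grid.voxel_volume_cc

    idx: dict[str, np.ndarray] = {}
    for obj in objectives:
        if obj.roi not in rois:
            raise KeyError(f"objective references unknown ROI {obj.roi!r}")
        if obj.roi not in idx:
            roi = rois[obj.roi]
            if roi.is_empty():
                raise ValueError(f"objective ROI {obj.roi!r} is empty")
            idx[obj.roi] = np.flatnonzero(roi.voxels.ravel())

    weights = np.array([o.weight for o in objectives], dtype=float)

    def split_eval(dose_flat: np.ndarray) -> np.ndarray:
        return np.array(
            [_objective_value(dose_flat[idx[o.roi]], o, voxel_cc) for o in objectives]
        )

    def total(raw: np.ndarray) -> float:
        return float(weights @ raw)

    x = (
        np.zeros(influence.n_beamlets)
        if init_intensities is None
        else np.array(init_intensities, dtype=float)
    )
    if x.shape != (influence.n_beamlets,):
        raise ValueError("init intensities have the wrong length")
    if (x < 0).any():
        raise ValueError("init intensities must be non-negative")

    dose_flat = A.T @ x
    raw = split_eval(dose_flat)
    f = total(raw)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite objective at the initial point")

    converged = False
    step = 1.0
    n_iter = 0
    x_prev = None
    g_prev = None
    history = [f]
    for n_iter in range(1, max_iters + 1):
        g_dose = np.zeros(grid.n_voxels)
        for o, w in zip(objectives, weights):
            if w == 0.0:
                continue
            ii = idx[o.roi]
            g_dose[ii] += w * _objective_grad(dose_flat[ii], o, voxel_cc)
        g = A @ g_dose
        if not np.any(g):
            converged = True
            break

        # Barzilai-Borwein initial step (robust to the huge weight spreads
        # the adaptation loop produces), then backtrack for monotonicity
        if x_prev is not None:
            s = x - x_prev
            y = g - g_prev
            sy = float(s @ y)
            yy = float(y @ y)
            if sy > 0 and yy > 0:
                step = sy / yy
            else:
                step *= 2.0
        else:
            step *= 2.0
        x_prev, g_prev = x, g
        accepted = False
        for _ in range(60):
            x_new = np.maximum(x - step * g, 0.0)
            dose_new = A.T @ x_new
            raw_new = split_eval(dose_new)
            f_new = total(raw_new)
            if not np.isfinite(f_new):
                raise FloatingPointError(
                    f"non-finite objective during line search at inner iteration {n_iter}"
                )
            if f_new <= f - 1e-4 * float(g @ (x - x_new)):
                accepted = True
                break
            step *= 0.5
        if not accepted or f_new > f:
            converged = True  # no descent direction left
            break
        x, dose_flat, raw = x_new, dose_new, raw_new
        f_prev, f = f, f_new
        history.append(f)
        if abs(f_prev - f) <= rel_tol * max(abs(f_prev), 1e-12):
            converged = True
            break

    dose = DoseGrid(grid, dose_flat.reshape(grid.shape))
    f_obj = weights * raw
    return EngineResult(
        intensities=x,
        dose=dose,
        raw_values=raw,
        f_obj=f_obj,
        f_tot=float(f_obj.sum()),
        converged=converged,
        n_inner=n_iter,
        f_history=np.array(history),
    )
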
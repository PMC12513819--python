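"""Voxel-grid structure handling and PTV--OAR geometry descriptors.

Everything downstream works on boolean voxel masks that share one
:class:`VoxelGrid`.  The two geometry descriptors computed here are the
overlap volume histogram (OVH) -- the fraction of an organ-at-risk within
signed Euclidean distance *t* of the target surface -- and its 1-D analog
along the cranio-caudal axis, the overlap-z-histogram (OZH).  Their areas
under the curve are the scalar features the prediction module regresses on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

# Canonical structure names every knowledge base and planner run agrees on.
CANONICAL_NAMES = frozenset(
    {
        "ptv",
        "total_lung",
        "heart",
        "spinal_cord",
        "esophagus",
        "skin",
        "breast_l",
        "breast_r",
        "external",
    }
)

# Shared OVH/OZH sampling window (mm).  AUC features are only comparable
# across cases when every case is sampled on the same window, so this is a
# global default recorded in the knowledge-base header and validated when a
# query signature is matched against it.
T_MIN_MM = -50.0
T_MAX_MM = 100.0
T_STEP_MM = 1.0
DEFAULT_WINDOW = (T_MIN_MM, T_MAX_MM, T_STEP_MM)


class GridMismatchError(ValueError):
    """Two masks that must share a voxel grid do not."""


class AmbiguousTargetError(ValueError):
    """More than one raw structure name resolved to the target role."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice; the third index is the cranio-caudal (z) axis.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    spacing : tuple of float
        Voxel edge lengths in mm.
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) of the voxels along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]


@dataclass
class ROIMask:
    """Boolean voxel occupancy of one structure on a shared grid."""

    grid: VoxelGrid
    voxels: np.ndarray
    name: str
    role: str = "oar"  # target | oar | auxiliary | external

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask {self.name!r}: occupancy shape {self.voxels.shape} "
                f"!= grid shape {self.grid.shape}"
            )
        if self.role not in ("target", "oar", "auxiliary", "external"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_cc

    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass
class StructureSet:
    """All ROIs of one case plus the prescription dose Dp (Gy)."""

    grid: VoxelGrid
    rois: dict[str, ROIMask] = field(default_factory=dict)
    prescription_dose: float = 50.4

    def __post_init__(self):
        for name, roi in self.rois.items():
            self._check(name, roi)

    def _check(self, name: str, roi: ROIMask) -> None:
        if roi.grid != self.grid:
            raise GridMismatchError(f"ROI {name!r} is not on the case grid")
        if name == "ptv" and roi.role != "target":
            raise ValueError("the ROI named 'ptv' must have role='target'")

    def add(self, roi: ROIMask) -> None:
        self._check(roi.name, roi)
        self.rois[roi.name] = roi

    def __contains__(self, name: str) -> bool:
        return name in self.rois

    def __getitem__(self, name: str) -> ROIMask:
        return self.rois[name]

    @property
    def ptv(self) -> ROIMask:
        try:
            return self.rois["ptv"]
        except KeyError:
            raise KeyError("structure set has no 'ptv'") from None


@dataclass(frozen=True)
class Curve:
    """Sampled curve: strictly increasing abscissa, values in [0, 1]."""

    abscissa: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.abscissa, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if a.ndim != 1 or a.shape != v.shape:
            raise ValueError("abscissa and values must be 1-D and equally long")
        if a.size >= 2 and not np.all(np.diff(a) > 0):
            raise ValueError("abscissa must be strictly increasing")
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("curve values must lie in [0, 1]")
        object.__setattr__(self, "abscissa", a)
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    def __len__(self) -> int:
        return self.abscissa.size


@dataclass(frozen=True)
class OrganGeometry:
    """OVH/OZH curves of one organ plus their normalized AUC features."""

    ovh: Curve
    ozh: Curve
    auc_ovh: float
    auc_ozh: float


@dataclass
class GeometrySignature:
    """Per-organ geometry descriptors of one case on a fixed window."""

    organs: dict[str, OrganGeometry]
    window: tuple[float, float, float] = DEFAULT_WINDOW

    def __contains__(self, organ: str) -> bool:
        return organ in self.organs

    def __getitem__(self, organ: str) -> OrganGeometry:
        return self.organs[organ]


# ---------------------------------------------------------------------------
# Structure-name resolution (preparation phase)
# ---------------------------------------------------------------------------

def resolve_roi_names(
    raw_names: list[str], dictionary: dict[str, str]
) -> tuple[dict[str, str], list[str]]:
    """Map raw structure-set names to canonical names via a synonym dictionary.

    Lookup is case-insensitive.  Raw names without a dictionary entry are
    returned in the ``unresolved`` list.  Two raw names resolving to the
    target structure is an error -- a case must have exactly one target.

    Returns
    -------
    (mapping, unresolved)
        ``mapping`` maps each resolved raw name to its canonical name.
    """
    lut = {}
    for syn, canon in dictionary.items():
        if canon not in CANONICAL_NAMES:
            raise ValueError(f"dictionary maps {syn!r} to unknown canonical name {canon!r}")
        lut[syn.strip().lower()] = canon

    mapping: dict[str, str] = {}
    unresolved: list[str] = []
    for raw in raw_names:
        canon = lut.get(raw.strip().lower())
        if canon is None:
            unresolved.append(raw)
        else:
            mapping[raw] = canon

    targets = [raw for raw, canon in mapping.items() if canon == "ptv"]
    if len(targets) > 1:
        raise AmbiguousTargetError(
            f"multiple structures resolve to the target 'ptv': {targets}"
        )
    return mapping, unresolved


# ---------------------------------------------------------------------------
# Signed distance and ROI algebra
# ---------------------------------------------------------------------------

def signed_distance_field(mask: ROIMask) -> np.ndarray:
    """Signed Euclidean distance (mm) of every voxel center to the mask.

    Negative inside the mask, positive outside; magnitudes are
    center-to-center distances under the physical grid spacing, computed
    with the exact Euclidean distance transform.
    """
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty; distance field undefined")
    m = mask.voxels
    spacing = mask.grid.spacing
    outside = ndimage.distance_transform_edt(~m, sampling=spacing)
    if m.all():
        return -ndimage.distance_transform_edt(m, sampling=spacing)
    inside = ndimage.distance_transform_edt(m, sampling=spacing)
    return np.where(m, -inside, outside)


def _same_grid(*masks: ROIMask) -> VoxelGrid:
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid != grid:
            raise GridMismatchError(
                f"masks {masks[0].name!r} and {m.name!r} are on different grids"
            )
    return grid


def union(*masks: ROIMask, name: str = "union", role: str = "auxiliary") -> ROIMask:
    grid = _same_grid(*masks)
    out = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        out |= m.voxels
    return ROIMask(grid, out, name, role)


def intersection(*masks: ROIMask, name: str = "intersection", role: str = "auxiliary") -> ROIMask:
    grid = _same_grid(*masks)
    out = np.ones(grid.shape, dtype=bool)
    for m in masks:
        out &= m.voxels
    return ROIMask(grid, out, name, role)


def difference(a: ROIMask, b: ROIMask, name: str | None = None, role: str = "auxiliary") -> ROIMask:
    grid = _same_grid(a, b)
    return ROIMask(grid, a.voxels & ~b.voxels, name or f"{a.name}-{b.name}", role)


def expand(mask: ROIMask, t_mm: float, name: str | None = None, role: str = "auxiliary") -> ROIMask:
    """Isotropic expansion: all voxels within signed distance ``t_mm``."""
    if t_mm < 0:
        raise ValueError("expansion margin must be >= 0")
    if t_mm == 0:
        return ROIMask(mask.grid, mask.voxels.copy(), name or mask.name, role)
    d = signed_distance_field(mask)
    return ROIMask(mask.grid, d <= t_mm, name or f"{mask.name}+{t_mm:g}mm", role)


def contract(mask: ROIMask, t_mm: float, name: str | None = None, role: str = "auxiliary") -> ROIMask:
    """Isotropic contraction: voxels strictly deeper than ``t_mm`` inside.

    Defined as the morphological dual of :func:`expand` (complement,
    expand, complement), so a 1-voxel rind peels exactly the boundary
    layer on a unit grid.
    """
    if t_mm < 0:
        raise ValueError("contraction margin must be >= 0")
    if t_mm == 0:
        return ROIMask(mask.grid, mask.voxels.copy(), name or mask.name, role)
    d = signed_distance_field(mask)
    return ROIMask(mask.grid, d < -t_mm, name or f"{mask.name}-{t_mm:g}mm", role)


def z_expand(mask: ROIMask, t_mm: float, name: str | None = None, role: str = "auxiliary") -> ROIMask:
    """Extend occupancy along the cranio-caudal axis only, by ``t_mm``."""
    if t_mm < 0:
        raise ValueError("z-expansion margin must be >= 0")
    n = int(round(t_mm / mask.grid.spacing[2]))
    if n == 0:
        return ROIMask(mask.grid, mask.voxels.copy(), name or mask.name, role)
    struct = np.ones((1, 1, 2 * n + 1), dtype=bool)
    out = ndimage.binary_dilation(mask.voxels, structure=struct)
    return ROIMask(mask.grid, out, name or f"{mask.name}+z{t_mm:g}mm", role)


_ALGEBRA_OPS = {
    "union": union,
    "intersection": intersection,
    "difference": difference,
    "expand": expand,
    "contract": contract,
    "z_expand": z_expand,
}


def roi_algebra(op: str, operands: list[ROIMask], t_mm: float | None = None, **kw) -> ROIMask:
    """Dispatcher over the ROI algebra used to build auxiliary structures."""
    try:
        fn = _ALGEBRA_OPS[op]
    except KeyError:
        raise ValueError(f"unknown ROI algebra op {op!r}") from None
    if op in ("expand", "contract", "z_expand"):
        (m,) = operands
        return fn(m, t_mm, **kw)
    return fn(*operands, **kw)


# ---------------------------------------------------------------------------
# Preparation-phase auxiliary structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AuxiliaryConfig:
    """Margins (mm) for the derived planning structures.

    skin_rind_mm
        Thickness of the skin shell peeled off the external contour.
    eso_z_mm
        Cranio-caudal extension of the esophagus.
    avoid_margin_mm
        Isotropic margin around the PTV excluded from the anterior
        avoidance structure.
    """

    skin_rind_mm: float = 5.0
    eso_z_mm: float = 10.0
    avoid_margin_mm: float = 20.0


def make_auxiliary_rois(structures: StructureSet, config: AuxiliaryConfig | None = None) -> StructureSet:
    """Add skin, extended esophagus and anterior-avoidance structures.

    Missing source structures are skipped with a logged warning rather than
    raising, so a partial structure set still yields a usable plan.  The
    anterior half-space is taken as the low-y half of the external contour
    (second grid axis, split at the external centroid).
    """
    cfg = config or AuxiliaryConfig()
    out = StructureSet(structures.grid, dict(structures.rois), structures.prescription_dose)

    external = structures.rois.get("external")
    esophagus = structures.rois.get("esophagus")
    ptv = structures.rois.get("ptv")

    if external is not None and not external.is_empty():
        rind = contract(external, cfg.skin_rind_mm, name="_core")
        skin = difference(external, rind, name="skin")
        skin.role = "auxiliary"
        out.add(skin)
    else:
        logger.warning("no external contour: skipping skin structure")

    if esophagus is not None and not esophagus.is_empty():
        eso_ext = z_expand(esophagus, cfg.eso_z_mm, name="esophagus_ext")
        out.add(eso_ext)
    else:
        logger.warning("no esophagus: skipping extended esophagus structure")

    if external is not None and ptv is not None and not external.is_empty() and not ptv.is_empty():
        ys = np.nonzero(external.voxels)[1]
        y_split = ys.mean()
        anterior = np.zeros(structures.grid.shape, dtype=bool)
        y_idx = np.arange(structures.grid.shape[1])
        anterior[:, y_idx < y_split, :] = True
        anterior &= external.voxels
        forbidden = expand(ptv, cfg.avoid_margin_mm)
        out.add(ROIMask(structures.grid, anterior & ~forbidden.voxels, "anterior_avoid", "auxiliary"))
    else:
        logger.warning("external or ptv missing: skipping anterior avoidance structure")

    return out


# ---------------------------------------------------------------------------
# OVH / OZH descriptors
# ---------------------------------------------------------------------------

def _window_samples(t_window: tuple[float, float], step: float) -> np.ndarray:
    t_min, t_max = t_window
    if t_max <= t_min or step <= 0:
        raise ValueError("window must satisfy t_max > t_min, step > 0")
    n = int(round((t_max - t_min) / step))
    return t_min + step * np.arange(n + 1)


def compute_ovh(
    oar: ROIMask,
    ptv: ROIMask,
    t_window: tuple[float, float] = (T_MIN_MM, T_MAX_MM),
    step: float = T_STEP_MM,
) -> Curve:
    """Overlap volume histogram of an organ with respect to the target.

    ``OVH(t)`` is the fraction of organ voxels whose signed Euclidean
    distance to the target is at most ``t`` mm (negative distances are
    inside the target, so negative ``t`` probes the penetrating part of
    the organ).  Non-decreasing in ``t`` by construction; equal to 1 once
    ``t`` exceeds the largest organ-to-target distance.
    """
    if oar.is_empty() or ptv.is_empty():
        raise ValueError("OVH requires non-empty OAR and PTV masks")
    _same_grid(oar, ptv)
    d = signed_distance_field(ptv)[oar.voxels]
    ts = _window_samples(t_window, step)
    # thresholds are inclusive for deterministic ties on integer fixtures
    vals = np.searchsorted(np.sort(d), ts, side="right") / d.size
    return Curve(ts, vals)


def compute_ozh(
    oar: ROIMask,
    ptv: ROIMask,
    t_window: tuple[float, float] = (T_MIN_MM, T_MAX_MM),
    step: float = T_STEP_MM,
) -> Curve:
    """Overlap-z-histogram: cranio-caudal analog of the OVH.

    ``OZH(t)`` is the fraction of organ voxels whose z coordinate falls in
    the target z-interval expanded by ``t`` mm on both ends (contracted for
    negative ``t``).
    """
    if oar.is_empty() or ptv.is_empty():
        raise ValueError("OZH requires non-empty OAR and PTV masks")
    grid = _same_grid(oar, ptv)
    zc = grid.axis_centers(2)
    z_ptv = zc[np.nonzero(ptv.voxels.any(axis=(0, 1)))[0]]
    z_lo, z_hi = z_ptv.min(), z_ptv.max()
    z_oar = zc[np.nonzero(oar.voxels)[2]]
    ts = _window_samples(t_window, step)
    n_oar = z_oar.size
    vals = np.empty(ts.size)
    for i, t in enumerate(ts):
        lo, hi = z_lo - t, z_hi + t
        vals[i] = 0.0 if lo > hi else np.count_nonzero((z_oar >= lo) & (z_oar <= hi)) / n_oar
    return Curve(ts, vals)


def curve_auc(curve: Curve) -> float:
    """Normalized area under a curve: trapezoid integral / window length."""
    if len(curve) < 2:
        raise ValueError("AUC needs at least 2 samples")
    a = curve.abscissa
    return float(np.trapezoid(curve.values, a) / (a[-1] - a[0]))


def compute_signature(
    structures: StructureSet,
    organs: list[str] | None = None,
    t_window: tuple[float, float] = (T_MIN_MM, T_MAX_MM),
    step: float = T_STEP_MM,
) -> GeometrySignature:
    """OVH/OZH curves and AUC features for every (present) requested organ."""
    ptv = structures.ptv
    if organs is None:
        organs = [
            n for n, r in structures.rois.items()
            if r.role == "oar" and not r.is_empty()
        ]
    result: dict[str, OrganGeometry] = {}
    for organ in organs:
        roi = structures.rois.get(organ)
        if roi is None or roi.is_empty():
            logger.warning("organ %r absent or empty: excluded from signature", organ)
            continue
        ovh = compute_ovh(roi, ptv, t_window, step)
        ozh = compute_ozh(roi, ptv, t_window, step)
        result[organ] = OrganGeometry(ovh, ozh, curve_auc(ovh), curve_auc(ozh))
    return GeometrySignature(result, (t_window[0], t_window[1], step))
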
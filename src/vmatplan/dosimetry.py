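"""Dose grids, cumulative DVHs, DVH-metric extraction and plan quality indices.

DVH metrics (mean, VxGy, Dxcc, Dx%) are computed from the raw sorted voxel
doses, never from binned curves, so they carry no bin-width sensitivity;
binned :func:`cumulative_dvh` curves exist for display and serialization.
The plan quality indices are

    coverage      C  = TV_RI / TV
    homogeneity   HI = (D2% - D98%) / Dp
    conformity    CI = (TV_RI / TV) * (TV_RI / V_RI)

with TV the target volume, V_RI the total volume covered by the reference
isodose (95% of the prescription dose Dp), and TV_RI their intersection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .geometry import Curve, ROIMask, VoxelGrid

logger = logging.getLogger(__name__)

REFERENCE_ISODOSE_FRACTION = 0.95


@dataclass
class DoseGrid:
    """Per-voxel absorbed dose (Gy) on a voxel grid."""

    grid: VoxelGrid
    dose: np.ndarray

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {self.dose.shape} != grid shape {self.grid.shape}"
            )
        if self.dose.size and self.dose.min() < 0:
            raise ValueError("dose values must be non-negative")


@dataclass(frozen=True)
class MetricSpec:
    """One DVH metric: organ, kind and (for Vx/Dxcc/Dx%) its parameter.

    kind is one of ``mean`` (Gy), ``v_dose`` (% of volume at >= parameter
    Gy), ``d_cc`` (Gy to the hottest parameter cc) or ``d_pct`` (Gy to the
    hottest parameter percent of the volume).
    """

    organ: str
    kind: str
    parameter: float | None = None

    def __post_init__(self):
        if self.kind not in ("mean", "v_dose", "d_cc", "d_pct"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.kind != "mean" and (self.parameter is None or self.parameter <= 0):
            raise ValueError(f"metric kind {self.kind!r} needs a positive parameter")

    @property
    def key(self) -> str:
        if self.kind == "mean":
            return f"{self.organ}.mean"
        return f"{self.organ}.{self.kind}.{self.parameter:g}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return {
            "mean": f"{self.organ} mean dose",
            "v_dose": f"{self.organ} V{self.parameter:g}Gy",
            "d_cc": f"{self.organ} D{self.parameter:g}cc",
            "d_pct": f"{self.organ} D{self.parameter:g}%",
        }[self.kind]


@dataclass(frozen=True)
class QualityIndices:
    """Target coverage / homogeneity / conformity summary of one plan."""

    coverage: float
    hi: float
    ci: float
    d2_pct: float
    d50_pct: float
    d98_pct: float
    tv_cc: float
    tvri_cc: float
    vri_cc: float


def _roi_doses(dose: DoseGrid, roi: ROIMask) -> np.ndarray:
    if roi.is_empty():
        raise ValueError(f"ROI {roi.name!r} is empty")
    if roi.grid != dose.grid:
        raise ValueError(f"ROI {roi.name!r} not on the dose grid")
    return dose.dose[roi.voxels]


def cumulative_dvh(dose: DoseGrid, roi: ROIMask, bin_width: float = 0.1) -> Curve:
    """Cumulative DVH: fraction of ROI volume receiving >= each dose level."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = np.sort(_roi_doses(dose, roi))
    n_bins = int(math.ceil(d[-1] / bin_width)) + 1 if d[-1] > 0 else 1
    edges = bin_width * np.arange(n_bins + 1)
    vals = 1.0 - np.searchsorted(d, edges, side="left") / d.size
    return Curve(edges, vals)


def dvh_metric(dose: DoseGrid, roi: ROIMask, spec: MetricSpec) -> float:
    """Evaluate one DVH metric from the raw voxel doses.

    ``d_cc``/``d_pct`` use the hottest-subvolume convention: the metric at
    volume x is the minimum dose of the hottest ceil(x / voxel volume)
    voxels (resp. ceil of the voxel-count fraction).  All dose thresholds
    are inclusive.
    """
    d = _roi_doses(dose, roi)
    if spec.kind == "mean":
        return float(d.mean())
    if spec.kind == "v_dose":
        return float(100.0 * np.count_nonzero(d >= spec.parameter) / d.size)
    if spec.kind == "d_cc":
        vol_cc = d.size * roi.grid.voxel_volume_cc
        if spec.parameter > vol_cc:
            raise ValueError(
                f"D{spec.parameter:g}cc of {roi.name!r}: parameter exceeds "
                f"ROI volume {vol_cc:.3f} cc"
            )
        n_hot = max(1, math.ceil(spec.parameter / roi.grid.voxel_volume_cc))
    else:  # d_pct
        if spec.parameter > 100:
            raise ValueError("Dx% parameter must be <= 100")
        n_hot = max(1, math.ceil(spec.parameter / 100.0 * d.size))
    hottest = np.sort(d)[::-1][:n_hot]
    return float(hottest[-1])


def coverage(dose: DoseGrid, ptv: ROIMask, prescription: float) -> float:
    """Fraction of the target receiving at least 95% of the prescription."""
    if prescription <= 0:
        raise ValueError("prescription dose must be positive")
    d = _roi_doses(dose, ptv)
    return float(np.count_nonzero(d >= REFERENCE_ISODOSE_FRACTION * prescription) / d.size)


def homogeneity_index(dose: DoseGrid, ptv: ROIMask, prescription: float) -> float:
    """(D2% - D98%) / Dp; 0 for a perfectly uniform target dose."""
    if prescription <= 0:
        raise ValueError("prescription dose must be positive")
    d2 = dvh_metric(dose, ptv, MetricSpec(ptv.name, "d_pct", 2.0))
    d98 = dvh_metric(dose, ptv, MetricSpec(ptv.name, "d_pct", 98.0))
    return float((d2 - d98) / prescription)


def conformity_index(dose: DoseGrid, ptv: ROIMask, prescription: float) -> float:
    """(TV_RI/TV) * (TV_RI/V_RI); 1 iff the isodose region equals the target.

    When no voxel reaches the reference isodose the index degenerates to 0
    (total non-conformity) with a logged warning.
    """
    if prescription <= 0:
        raise ValueError("prescription dose must be positive")
    if ptv.is_empty():
        raise ValueError("PTV is empty")
    ri = dose.dose >= REFERENCE_ISODOSE_FRACTION * prescription
    vri = int(ri.sum())
    if vri == 0:
        logger.warning("no voxel reaches the reference isodose; CI defined as 0")
        return 0.0
    tv = ptv.n_voxels
    tvri = int((ri & ptv.voxels).sum())
    return float((tvri / tv) * (tvri / vri))


def quality_indices(dose: DoseGrid, ptv: ROIMask, prescription: float) -> QualityIndices:
    """All target plan-quality indices of one dose distribution."""
    ri = dose.dose >= REFERENCE_ISODOSE_FRACTION * prescription
    vv = ptv.grid.voxel_volume_cc
    return QualityIndices(
        coverage=coverage(dose, ptv, prescription),
        hi=homogeneity_index(dose, ptv, prescription),
        ci=conformity_index(dose, ptv, prescription),
        d2_pct=dvh_metric(dose, ptv, MetricSpec(ptv.name, "d_pct", 2.0)),
        d50_pct=dvh_metric(dose, ptv, MetricSpec(ptv.name, "d_pct", 50.0)),
        d98_pct=dvh_metric(dose, ptv, MetricSpec(ptv.name, "d_pct", 98.0)),
        tv_cc=ptv.volume_cc,
        tvri_cc=float((ri & ptv.voxels).sum() * vv),
        vri_cc=float(ri.sum() * vv),
    )
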
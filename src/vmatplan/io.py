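"""On-disk formats: case directories, knowledge bases, exports.

A case is a directory holding ``grid.json`` (shape, spacing, origin,
prescription, per-ROI roles) plus one NIfTI volume per ROI mask and an
optional ``dose.nii``.  A knowledge base is a single JSON archive: one
header (window, metric list, case ids) and per-case curve samples and
achieved metrics.  DICOM-RT import is out of scope and the converter stub
says so.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dosimetry import DoseGrid
from .geometry import Curve, GeometrySignature, OrganGeometry, ROIMask, StructureSet, VoxelGrid
from .prediction import KBCase, KnowledgeBase

GRID_FILE = "grid.json"
DOSE_FILE = "dose.nii"


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def save_case(structures: StructureSet, directory: str | Path, dose: DoseGrid | None = None) -> Path:
    """Write a case directory: grid.json + one .nii per ROI (+ dose.nii)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    grid = structures.grid
    meta = {
        "shape": list(grid.shape),
        "spacing": list(grid.spacing),
        "origin": list(grid.origin),
        "prescription_dose": structures.prescription_dose,
        "rois": {name: roi.role for name, roi in structures.rois.items()},
    }
    (d / GRID_FILE).write_text(json.dumps(meta, indent=1))
    aff = _affine(grid)
    for name, roi in structures.rois.items():
        img = nib.Nifti1Image(roi.voxels.astype(np.uint8), aff)
        nib.save(img, d / f"{name}.nii")
    if dose is not None:
        nib.save(nib.Nifti1Image(dose.dose.astype(np.float32), aff), d / DOSE_FILE)
    return d


def load_case(directory: str | Path) -> tuple[StructureSet, DoseGrid | None]:
    """Read a case directory written by :func:`save_case`."""
    d = Path(directory)
    meta = json.loads((d / GRID_FILE).read_text())
    grid = VoxelGrid(tuple(meta["shape"]), tuple(meta["spacing"]), tuple(meta["origin"]))
    rois = {}
    for name, role in meta["rois"].items():
        arr = np.asarray(nib.load(d / f"{name}.nii").dataobj)
        rois[name] = ROIMask(grid, arr.astype(bool), name, role)
    structures = StructureSet(grid, rois, float(meta["prescription_dose"]))
    dose = None
    dose_path = d / DOSE_FILE
    if dose_path.exists():
        dose = DoseGrid(grid, np.asarray(nib.load(dose_path).dataobj, dtype=float))
    return structures, dose


def load_dicom_rt(path: str | Path):  # pragma: no cover - documented stub
    """DICOM-RT (RTSTRUCT/RTDOSE) import is unsupported; use case directories."""
    raise NotImplementedError(
        "DICOM-RT import is unsupported; convert to the case-directory format "
        "(grid.json + NIfTI masks) instead"
    )


# ---------------------------------------------------------------------------
# Knowledge-base archive
# ---------------------------------------------------------------------------

def save_kb(kb: KnowledgeBase, path: str | Path) -> Path:
    """Serialize a knowledge base as one JSON archive."""
    p = Path(path)
    doc = {
        "window": list(kb.window),
        "case_ids": [c.case_id for c in kb.cases],
        "cases": [
            {
                "case_id": c.case_id,
                "achieved": c.achieved,
                "organs": {
                    organ: {
                        "ovh": g.ovh.values.tolist(),
                        "ozh": g.ozh.values.tolist(),
                        "auc_ovh": g.auc_ovh,
                        "auc_ozh": g.auc_ozh,
                    }
                    for organ, g in c.signature.organs.items()
                },
            }
            for c in kb.cases
        ],
    }
    p.write_text(json.dumps(doc))
    return p


def load_kb(path: str | Path) -> KnowledgeBase:
    doc = json.loads(Path(path).read_text())
    window = tuple(doc["window"])
    t_min, t_max, step = window
    n = int(round((t_max - t_min) / step)) + 1
    ts = t_min + step * np.arange(n)
    cases = []
    for c in doc["cases"]:
        organs = {}
        for organ, g in c["organs"].items():
            organs[organ] = OrganGeometry(
                ovh=Curve(ts, np.asarray(g["ovh"])),
                ozh=Curve(ts, np.asarray(g["ozh"])),
                auc_ovh=float(g["auc_ovh"]),
                auc_ozh=float(g["auc_ozh"]),
            )
        cases.append(KBCase(c["case_id"], GeometrySignature(organs, window), dict(c["achieved"])))
    return KnowledgeBase(cases, window)


def kb_feature_table(kb: KnowledgeBase) -> pd.DataFrame:
    """Long-format AUC/metric table for external regression checks."""
    rows = []
    for c in kb.cases:
        for key, val in c.achieved.items():
            organ = key.split(".")[0]
            if organ not in c.signature:
                continue
            g = c.signature[organ]
            rows.append(
                {
                    "case_id": c.case_id,
                    "metric": key,
                    "auc_ovh": g.auc_ovh,
                    "auc_ozh": g.auc_ozh,
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def export_dvh_csv(curve: Curve, path: str | Path) -> Path:
    """Two-column CSV (dose Gy, volume fraction) of one DVH curve."""
    p = Path(path)
    pd.DataFrame({"dose_gy": curve.abscissa, "volume_fraction": curve.values}).to_csv(
        p, index=False
    )
    return p
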
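"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive quantities from first principles
(all-pairs distances, exhaustive voxel sorting) so that the package code
paths are checked against something that shares none of their machinery.
"""

from __future__ import annotations

import numpy as np
import pytest

from vmatplan.dosimetry import DoseGrid
from vmatplan.engine import BeamConfig, build_influence
from vmatplan.geometry import Curve, GeometrySignature, OrganGeometry, ROIMask, VoxelGrid
from vmatplan.synthetic import PhantomSpec, generate_phantom


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """All-pairs signed center-to-center distance to a boolean mask."""
    spacing = np.asarray(spacing, dtype=float)
    coords = np.argwhere(np.ones(mask.shape, dtype=bool)) * spacing
    inside_pts = np.argwhere(mask) * spacing
    outside_pts = np.argwhere(~mask) * spacing
    out = np.zeros(mask.shape)
    flat_inside = mask.ravel()
    for i, c in enumerate(coords):
        ij = np.unravel_index(i, mask.shape)
        if flat_inside[i]:
            if outside_pts.size == 0:
                # measure to the nearest point beyond the grid: unbounded
                # inside; mirror the implementation's all-true convention
                out[ij] = -np.min(
                    np.linalg.norm(inside_pts - c, axis=1)[
                        np.linalg.norm(inside_pts - c, axis=1) > 0
                    ],
                    initial=np.inf,
                )
            else:
                out[ij] = -np.min(np.linalg.norm(outside_pts - c, axis=1))
        else:
            out[ij] = np.min(np.linalg.norm(inside_pts - c, axis=1))
    return out


def brute_ovh(oar: np.ndarray, ptv: np.ndarray, spacing, ts) -> np.ndarray:
    d = brute_signed_distance(ptv, spacing)[oar]
    return np.array([(d <= t).mean() for t in ts])


def brute_ozh(oar: np.ndarray, ptv: np.ndarray, spacing, origin_z, ts) -> np.ndarray:
    z_centers = origin_z + np.arange(oar.shape[2]) * spacing[2]
    z_ptv = z_centers[ptv.any(axis=(0, 1))]
    z_oar = z_centers[np.argwhere(oar)[:, 2]]
    vals = []
    for t in ts:
        lo, hi = z_ptv.min() - t, z_ptv.max() + t
        vals.append(0.0 if lo > hi else ((z_oar >= lo) & (z_oar <= hi)).mean())
    return np.array(vals)


def oracle_d_at_volume(doses: np.ndarray, n_hot: int) -> float:
    """Minimum dose of the hottest n voxels, by explicit sorting."""
    return float(sorted(doses, reverse=True)[n_hot - 1])


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def planar_case():
    return generate_phantom(PhantomSpec.planar(seed=2))


@pytest.fixture(scope="session")
def planar_influence(planar_case):
    return build_influence(planar_case, BeamConfig(n_angles=12, max_inner_iters=500))


@pytest.fixture
def unit_grid():
    def make(shape, spacing=(1.0, 1.0, 1.0)):
        return VoxelGrid(shape, spacing)

    return make


@pytest.fixture
def mask_factory(unit_grid):
    def make(occupancy, spacing=(1.0, 1.0, 1.0), name="roi", role="oar"):
        occ = np.asarray(occupancy, dtype=bool)
        return ROIMask(unit_grid(occ.shape, spacing), occ, name, role)

    return make


@pytest.fixture
def dose_factory():
    def make(values, spacing=(1.0, 1.0, 1.0)):
        arr = np.asarray(values, dtype=float)
        return DoseGrid(VoxelGrid(arr.shape, spacing), arr)

    return make


@pytest.fixture
def sig_factory():
    """Synthetic geometry signatures with prescribed AUC features."""

    window = (-50.0, 100.0, 1.0)
    ts = np.array([-50.0, 100.0])

    def make(organ="total_lung", auc_ovh=0.5, auc_ozh=0.5, **extra_organs):
        organs = {organ: (auc_ovh, auc_ozh), **extra_organs}
        built = {
            name: OrganGeometry(
                ovh=Curve(ts, np.array([0.0, 1.0])),
                ozh=Curve(ts, np.array([0.0, 1.0])),
                auc_ovh=float(v[0]) if isinstance(v, tuple) else float(v),
                auc_ozh=float(v[1]) if isinstance(v, tuple) else float(v),
            )
            for name, v in organs.items()
        }
        return GeometrySignature(built, window)

    return make
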
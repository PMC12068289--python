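"""RPI-to-image co-registration.

Per-node RPI values are painted into the CTA voxel grid (each node maps to
the voxel whose center is nearest; painted intensity = offset + scale * RPI
with the offset strictly above the CTA background), optionally moved into PET
space by a known rigid transform with nearest-neighbor resampling (RPI
intensities are codes, not densities — interpolation would fabricate
intermediate RPI values), and finally aggregated per MAS quadrant using the
same sectoring labels as the uptake analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .biomech import RPIField, WallMesh
from .errors import DataError, UnsupportedFeatureError
from .imaging_io import ImageVolume
from .segmentation import QUADRANTS, AorticSegmentation

log = logging.getLogger("aaaquant")

__all__ = ["PaintedRPIVolume", "paint_rpi", "unpaint", "resample_to_pet",
           "quadrant_rpi", "nearest_voxel_index"]


@dataclass
class PaintedRPIVolume:
    """An ImageVolume whose nonzero voxels carry offset + scale * RPI."""

    volume: ImageVolume
    offset: float
    scale: float
    n_nodes_skipped: int = 0

    @property
    def painted_mask(self) -> np.ndarray:
        return self.volume.data != 0.0


def nearest_voxel_index(vol: ImageVolume, positions: np.ndarray) -> np.ndarray:
    """Index of the voxel center nearest each position (mm).

    Ties (a coordinate exactly halfway between two centers) resolve to the
    lower index on each axis, i.e. the lowest linear index in C order.
    """
    frac = vol.world_to_index(np.atleast_2d(positions))
    return np.ceil(frac - 0.5).astype(int)


def paint_rpi(field: RPIField, mesh: WallMesh, reference: ImageVolume,
              offset: float | None = None, scale: float | None = None
              ) -> PaintedRPIVolume:
    """Map mesh nodes to their nearest CTA voxel and paint RPI-coded intensity.

    Voxels receiving several nodes carry the mean of their RPI values.  The
    default offset is max(reference) + 3 * SD(reference) so every painted
    voxel is strictly distinct from the background CTA; the default scale
    equals the offset so the full RPI range stays well inside float range.
    Nodes outside the grid are skipped, counted and logged.
    """
    rpi = np.asarray(field.rpi, dtype=float)
    if len(rpi) != mesh.n_nodes:
        raise DataError("RPI field and mesh disagree on node count")
    if offset is None:
        offset = float(reference.data.max() + 3.0 * reference.data.std())
    if scale is None:
        scale = max(float(offset), 1.0)
    idx = nearest_voxel_index(reference, mesh.nodes)
    shape = np.array(reference.shape)
    ok = np.all((idx >= 0) & (idx < shape[None, :]), axis=1)
    n_skip = int((~ok).sum())
    if n_skip:
        log.warning("paint_rpi: %d nodes fall outside the reference grid; skipped",
                    n_skip)
    lin = np.ravel_multi_index(tuple(idx[ok].T), reference.shape)
    acc = np.zeros(reference.data.size)
    cnt = np.zeros(reference.data.size)
    np.add.at(acc, lin, rpi[ok])
    np.add.at(cnt, lin, 1.0)
    painted = np.zeros(reference.data.size)
    hit = cnt > 0
    painted[hit] = offset + scale * (acc[hit] / cnt[hit])
    vol = ImageVolume(painted.reshape(reference.shape), reference.spacing,
                      reference.origin)
    return PaintedRPIVolume(vol, float(offset), float(scale), n_skip)


def unpaint(painted: PaintedRPIVolume) -> np.ndarray:
    """Recover node-mean RPI values on the painted voxels: (v - offset)/scale."""
    data = painted.volume.data
    out = np.full(data.shape, np.nan)
    m = painted.painted_mask
    out[m] = (data[m] - painted.offset) / painted.scale
    return out


def _check_rigid(transform: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    T = np.asarray(transform, dtype=float)
    if T.shape != (4, 4) or not np.allclose(T[3], [0, 0, 0, 1]):
        raise DataError("transform must be a 4x4 homogeneous matrix")
    R = T[:3, :3]
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
        raise UnsupportedFeatureError(
            "only rigid transforms (proper rotation + translation) are supported")
    return R, T[:3, 3]


def resample_to_pet(painted: PaintedRPIVolume, transform: np.ndarray,
                    pet_grid: ImageVolume) -> PaintedRPIVolume:
    """Nearest-neighbor resampling of the painted volume onto the PET grid.

    ``transform`` maps CTA world coordinates into PET world coordinates.
    Nearest-neighbor keeps every output intensity exactly equal to some input
    intensity (no interpolation blending); voxels mapping outside the input
    grid become 0 (unpainted).
    """
    R, t = _check_rigid(transform)
    src = painted.volume
    S_in = np.diag(src.spacing)
    S_out = np.diag(pet_grid.spacing)
    Rinv = R.T
    M = np.linalg.solve(S_in, Rinv @ S_out)
    off = np.linalg.solve(S_in, Rinv @ (np.array(pet_grid.origin) - t)
                          - np.array(src.origin) + Rinv @ np.zeros(3))
    out = ndimage.affine_transform(src.data, M, offset=off,
                                   output_shape=pet_grid.shape, order=0,
                                   mode="constant", cval=0.0, prefilter=False)
    vol = ImageVolume(out, pet_grid.spacing, pet_grid.origin)
    return PaintedRPIVolume(vol, painted.offset, painted.scale,
                            painted.n_nodes_skipped)


def quadrant_rpi(painted: PaintedRPIVolume, seg: AorticSegmentation) -> pd.DataFrame:
    """Mean and peak RPI per MAS quadrant over painted voxels.

    Uses the identical quadrant labels as the SUV analysis so that the
    SUV-RPI correlation is computed over aligned sectors.
    """
    values = unpaint(painted)
    mas_z = seg.mas_region_mask()
    rows = []
    for qi, qname in enumerate(QUADRANTS):
        sel = painted.painted_mask & (seg.quadrant_labels == qi) & mas_z[None, None, :]
        v = values[sel]
        if v.size == 0:
            rows.append({"region": qname, "voxel_count": 0,
                         "mean_rpi": np.nan, "max_rpi": np.nan})
        else:
            rows.append({"region": qname, "voxel_count": int(v.size),
                         "mean_rpi": float(v.mean()), "max_rpi": float(v.max())})
    df = pd.DataFrame(rows, columns=["region", "voxel_count", "mean_rpi", "max_rpi"])
    if df["voxel_count"].sum() == 0:
        raise DataError("painted voxels do not intersect the MAS wall region; "
                        "check the co-registration transform")
    return df
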
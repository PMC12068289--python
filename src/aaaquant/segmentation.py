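"""Aortic segments, wall/blood-pool masks and four-quadrant sectoring.

Named axial landmarks (HRA = highest renal artery, LRA = lowest renal artery,
MIRA = mid infrarenal aorta, MAS = maximum aneurysm sac) define slabs
"Ab L" / "L" / "Be L" (above / at / below each landmark).  The wall mask is
sectored per slice into anterior / left / posterior / right quadrants around
the per-slice lumen centroid, with half-open 45-degree diagonal boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError
from .imaging_io import ImageVolume

log = logging.getLogger("aaaquant")

QUADRANTS = ("anterior", "left", "posterior", "right")
#: labels used for slabbed landmarks (LRA is a stored landmark but, like the
#: clinical protocol, the slab scheme runs over the HRA, MIRA and MAS triplets)
SLAB_LANDMARKS = ("HRA", "MIRA", "MAS")

BACKGROUND, LUMEN, WALL = 0, 1, 2


@dataclass
class AorticSegmentation:
    """Label volume plus everything derived from it for one subject."""

    labels: ImageVolume                       # 0 background / 1 lumen / 2 wall
    landmark_z: dict[str, float]              # axial world positions (mm)
    segment_slabs: dict[str, tuple[int, int]]  # half-open slice intervals
    wall_mask: np.ndarray
    blood_mask: np.ndarray
    quadrant_labels: np.ndarray               # int8; -1 outside wall
    lumen_centroids: np.ndarray               # (nz, 2) fractional indices, NaN if empty
    warnings: list[str] = field(default_factory=list)

    def slab_mask(self, name: str) -> np.ndarray:
        """Boolean z-selector for one named slab (length nz)."""
        k0, k1 = self.segment_slabs[name]
        m = np.zeros(self.labels.shape[2], dtype=bool)
        m[k0:k1] = True
        return m

    def mas_region_mask(self) -> np.ndarray:
        """z-selector for the MAS area = Ab MAS + MAS + Be MAS slabs."""
        m = np.zeros(self.labels.shape[2], dtype=bool)
        for name in ("Ab MAS", "MAS", "Be MAS"):
            if name in self.segment_slabs:
                m |= self.slab_mask(name)
        return m

    def to_frame(self) -> pd.DataFrame:
        rows = [{"landmark": k, "z_mm": v} for k, v in self.landmark_z.items()]
        for name, (k0, k1) in self.segment_slabs.items():
            rows.append({"segment": name, "slice_start": k0, "slice_stop": k1})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Segment slabs
# ---------------------------------------------------------------------------

def define_segments(landmark_z: dict[str, float], slab_halfwidth_mm: float,
                    spacing_z: float, n_slices: int, origin_z: float = 0.0,
                    landmarks: tuple[str, ...] = SLAB_LANDMARKS,
                    ) -> tuple[dict[str, tuple[int, int]], list[str]]:
    """Convert landmark positions into half-open slab slice intervals.

    For each landmark L at z_L with half-width h:
      "Ab L" = [z_L + h, z_L + 3h),  "L" = [z_L - h, z_L + h),
      "Be L" = [z_L - 3h, z_L - h).
    A slice belongs to a slab iff its center z falls in the interval.  Slabs
    extending beyond the grid are truncated with a logged warning (mirroring
    measurements that are anatomically unavailable in some subjects); fully
    empty slabs are kept with a zero-length interval so downstream tables can
    flag the cell missing rather than silently dropping it.
    """
    if slab_halfwidth_mm <= 0:
        raise DataError("slab half-width must be positive")
    h = slab_halfwidth_mm
    slabs: dict[str, tuple[int, int]] = {}
    warnings: list[str] = []

    def to_slices(z_lo: float, z_hi: float) -> tuple[int, int]:
        # slice k has center origin_z + k * spacing_z; half-open [z_lo, z_hi)
        eps = 1e-9
        k0 = int(np.ceil((z_lo - origin_z) / spacing_z - eps))
        k1 = int(np.ceil((z_hi - origin_z) / spacing_z - eps))
        return k0, k1

    for L in landmarks:
        if L not in landmark_z:
            raise DataError(f"landmark '{L}' missing from landmark_z {sorted(landmark_z)}")
        zL = landmark_z[L]
        for name, (lo, hi) in {
            f"Ab {L}": (zL + h, zL + 3 * h),
            f"{L}": (zL - h, zL + h),
            f"Be {L}": (zL - 3 * h, zL - h),
        }.items():
            k0, k1 = to_slices(lo, hi)
            t0, t1 = max(k0, 0), min(k1, n_slices)
            if t1 <= t0:
                warnings.append(f"segment '{name}' has no slices inside the grid; "
                                "cell will be reported missing")
                t0 = t1 = max(0, min(t0, n_slices))
            elif (t0, t1) != (k0, k1):
                warnings.append(f"segment '{name}' truncated to grid: "
                                f"[{k0},{k1}) -> [{t0},{t1})")
            slabs[name] = (t0, t1)
    for w in warnings:
        log.warning(w)
    return slabs, warnings


# ---------------------------------------------------------------------------
# Wall / blood-pool masks
# ---------------------------------------------------------------------------

def _ball_structuring_element(radius_mm: float, spacing) -> np.ndarray:
    """Spherical structuring element in voxel units, honoring anisotropy."""
    r = [max(0, int(np.floor(radius_mm / s))) for s in spacing]
    grids = np.meshgrid(*[np.arange(-ri, ri + 1) * s for ri, s in zip(r, spacing)],
                        indexing="ij")
    dist2 = sum(g * g for g in grids)
    return dist2 <= radius_mm**2 + 1e-9


def extract_wall_and_blood(labels: ImageVolume, erosion_radius_mm: float
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Wall mask = wall label; blood mask = lumen eroded by a spherical element.

    The erosion guarantees every blood-pool sample voxel sits at least the
    erosion radius away from the wall, keeping spill-over out of the blood
    reference.
    """
    if erosion_radius_mm < 0:
        raise DataError("erosion radius must be >= 0")
    lab = labels.data
    wall = lab == WALL
    lumen = lab == LUMEN
    if not wall.any() or not lumen.any():
        raise DataError("label volume must contain both lumen and wall voxels")
    if erosion_radius_mm == 0:
        blood = lumen.copy()
    else:
        se = _ball_structuring_element(erosion_radius_mm, labels.spacing)
        if any(s >= d for s, d in zip(se.shape, lumen.shape)):
            raise DataError(
                f"erosion radius {erosion_radius_mm} mm exceeds the grid extent; "
                "use a smaller erosion_radius_mm")
        blood = ndimage.binary_erosion(lumen, structure=se)
    if not blood.any():
        raise DataError(
            f"erosion radius {erosion_radius_mm} mm empties the lumen; "
            "use a smaller erosion_radius_mm")
    return wall, blood


def lumen_from_cta(cta: ImageVolume, threshold_hu: float = 150.0,
                   wall_band_mm: float = 6.0) -> ImageVolume:
    """Derive a lumen/wall label volume from a contrast CTA.

    Threshold at HU > threshold, keep the largest connected component as the
    lumen, and take a band of the given thickness outside it as the wall ROI.
    """
    bright = cta.data > threshold_hu
    if not bright.any():
        raise DataError(f"no voxels above {threshold_hu} HU; not a contrast CTA?")
    cc, n = ndimage.label(bright)
    sizes = ndimage.sum_labels(np.ones_like(cc), cc, index=np.arange(1, n + 1))
    lumen = cc == (1 + int(np.argmax(sizes)))
    se = _ball_structuring_element(wall_band_mm, cta.spacing)
    wall = ndimage.binary_dilation(lumen, structure=se) & ~lumen
    lab = np.zeros(cta.shape, dtype=np.int8)
    lab[lumen] = LUMEN
    lab[wall] = WALL
    return cta.copy_with(lab)


# ---------------------------------------------------------------------------
# Quadrant sectoring
# ---------------------------------------------------------------------------

def lumen_centroids(lumen_mask: np.ndarray) -> np.ndarray:
    """Per-slice lumen centroid in fractional (i, j) indices; NaN where empty."""
    nz = lumen_mask.shape[2]
    out = np.full((nz, 2), np.nan)
    counts = lumen_mask.sum(axis=(0, 1))
    ii, jj = np.meshgrid(np.arange(lumen_mask.shape[0]),
                         np.arange(lumen_mask.shape[1]), indexing="ij")
    for k in np.flatnonzero(counts):
        m = lumen_mask[:, :, k]
        out[k, 0] = ii[m].mean()
        out[k, 1] = jj[m].mean()
    return out


def quadrant_sectoring(wall_slice: np.ndarray, centroid_idx: tuple[float, float],
                       spacing) -> np.ndarray:
    """Assign each wall voxel of one axial slice to a quadrant.

    theta is the angle of (voxel - centroid) measured from +y (anterior)
    toward +x (subject-left); anterior = [-45, 45), left = [45, 135),
    posterior = [135, 225), right = [225, 315), half-open.  Returns an int8
    slice with 0..3 indexing :data:`QUADRANTS` and -1 outside the wall.
    """
    out = np.full(wall_slice.shape, -1, dtype=np.int8)
    if not wall_slice.any():
        log.warning("quadrant sectoring: empty wall slice")
        return out
    ii, jj = np.nonzero(wall_slice)
    dx = (ii - centroid_idx[0]) * spacing[0]   # +x subject-left
    dy = (jj - centroid_idx[1]) * spacing[1]   # +y anterior
    theta = np.degrees(np.arctan2(dx, dy))     # 0 at anterior, +90 at left
    out[ii, jj] = np.floor(((theta + 45.0) % 360.0) / 90.0).astype(np.int8)
    return out


def quadrant_volume(wall_mask: np.ndarray, centroids: np.ndarray, spacing) -> np.ndarray:
    """Quadrant labels for every wall voxel (slice-wise sectoring)."""
    out = np.full(wall_mask.shape, -1, dtype=np.int8)
    for k in range(wall_mask.shape[2]):
        if not wall_mask[:, :, k].any():
            continue
        c = centroids[k]
        if np.isnan(c).any():
            # fall back to wall centroid when the lumen vanished in this slice
            ii, jj = np.nonzero(wall_mask[:, :, k])
            c = (ii.mean(), jj.mean())
        out[:, :, k] = quadrant_sectoring(wall_mask[:, :, k], c, spacing)
    return out


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def segment(labels: ImageVolume, landmark_z: dict[str, float],
            slab_halfwidth_mm: float = 5.0, erosion_radius_mm: float = 2.0,
            landmarks: tuple[str, ...] = SLAB_LANDMARKS) -> AorticSegmentation:
    """Full segmentation: slabs, wall/blood masks, centroids, quadrants."""
    nz = labels.shape[2]
    slabs, warnings = define_segments(landmark_z, slab_halfwidth_mm,
                                      labels.spacing[2], nz, labels.origin[2],
                                      landmarks=landmarks)
    wall, blood = extract_wall_and_blood(labels, erosion_radius_mm)
    cent = lumen_centroids(labels.data == LUMEN)
    quad = quadrant_volume(wall, cent, labels.spacing)
    return AorticSegmentation(labels, dict(landmark_z), slabs, wall, blood,
                              quad, cent, warnings)
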
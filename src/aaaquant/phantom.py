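"""Synthetic CTA/PET phantoms of an aneurysmal aorta with known ground truth.

The phantom is an axisymmetric tube with a Gaussian fusiform bulge: the outer
radius profile is

    r(z) = r_neck + (r_sac - r_neck) * exp(-(z - z_bulge)^2 / (2 * sigma^2)),

so the slice of maximal outer radius (the MAS landmark) coincides with the
bulge center by construction and an analytic radius oracle exists for every
slice.  The wall compartment is the band of stated thickness inside the outer
surface; it models the peri-luminal ROI a reader contours on CTA (aneurysm
wall plus the mural thrombus region), which is why its default thickness
(8 mm) exceeds a bare arterial wall.  A thinner mechanical mid-surface mesh
(default 2 mm) is generated for the stress analysis.

World frame: axes in mm; +x subject-left, +y anterior, +z superior.  The
tube axis is x = y = 0.  PET simulation assigns blood-pool activity to the
lumen, quadrant-dependent activity to the wall, blurs with an isotropic
Gaussian point-spread function (the spill-over the analysis must tolerate)
and adds seeded Gaussian noise.  The pre-blur ground truth travels with the
simulated volume so every downstream recovery test can state absolute errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from . import segmentation
from .biomech import WallMesh, tube_mesh
from .errors import ConfigError, SizingError
from .imaging_io import ImageVolume

__all__ = ["SubjectCovariates", "PhantomSpec", "SimulatedPET",
           "generate_geometry", "simulate_pet", "simulate_cta", "outer_radius"]


@dataclass
class SubjectCovariates:
    """Covariates of the wall-strength model plus SUV normalization inputs.

    sex_code: +1/2 male, -1/2 female.  hist: 1 if family history of AAA,
    else 0.  nord: maximum aneurysm diameter / infrarenal neck diameter.
    """

    sex_code: float = 0.5
    hist: int = 0
    nord: float = 1.54
    body_weight_kg: float = 80.0
    injected_dose_MBq: float = 350.0

    def validate(self) -> "SubjectCovariates":
        if self.sex_code not in (0.5, -0.5):
            raise ConfigError(f"sex_code must be +0.5 or -0.5, got {self.sex_code}")
        if self.hist not in (0, 1):
            raise ConfigError(f"hist must be 0 or 1, got {self.hist}")
        if self.nord < 1:
            raise ConfigError(f"nord must be >= 1, got {self.nord}")
        if self.body_weight_kg <= 0 or self.injected_dose_MBq <= 0:
            raise ConfigError("body weight and injected dose must be positive")
        return self


@dataclass
class PhantomSpec:
    """Full description of one synthetic subject (geometry, uptake, noise)."""

    grid_shape: tuple[int, int, int] = (96, 96, 128)
    voxel_size_mm: float = 0.5
    neck_radius_mm: float = 13.0          # outer radius at the neck
    max_sac_radius_mm: float = 20.0       # outer radius at the bulge center
    wall_thickness_mm: float = 8.0        # imaging wall-ROI band
    mesh_thickness_mm: float = 2.0        # mechanical wall for the FEA
    bulge_center_z_mm: float = 16.0
    bulge_sigma_mm: float = 6.0
    landmark_z_mm: dict = field(default_factory=lambda: {
        "HRA": 54.0, "LRA": 48.0, "MIRA": 34.0, "MAS": 16.0})
    uptake_wall_by_quadrant: dict = field(default_factory=lambda: {
        "anterior": 2.1, "right": 2.4, "left": 2.7, "posterior": 3.0})  # kBq/mL
    uptake_blood: float = 0.9
    uptake_background: float = 0.15
    psf_sigma_mm: float = 0.5
    noise_sd: float = 0.3                 # 10% of peak wall activity
    rng_seed: int = 0
    pressure_mmHg: float = 120.0
    subject: SubjectCovariates = field(default_factory=SubjectCovariates)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.voxel_size_mm,) * 3

    @property
    def origin(self) -> tuple[float, float, float]:
        # x/y centered on the tube axis, z starting at 0
        nx, ny, _ = self.grid_shape
        return (-(nx - 1) / 2 * self.voxel_size_mm,
                -(ny - 1) / 2 * self.voxel_size_mm, 0.0)

    def validate(self) -> "PhantomSpec":
        if not (self.max_sac_radius_mm >= self.neck_radius_mm
                > self.wall_thickness_mm > 0):
            raise ConfigError("need max_sac_radius >= neck_radius > wall_thickness > 0")
        if self.wall_thickness_mm < self.voxel_size_mm:
            raise SizingError(
                f"wall band ({self.wall_thickness_mm} mm) thinner than one voxel "
                f"({self.voxel_size_mm} mm); enlarge the wall or refine the grid")
        if self.mesh_thickness_mm <= 0:
            raise ConfigError("mesh_thickness_mm must be positive")
        z_max = (self.grid_shape[2] - 1) * self.voxel_size_mm
        for name, z in self.landmark_z_mm.items():
            if not (0 <= z <= z_max):
                raise SizingError(f"landmark {name} at z={z} mm outside grid [0, {z_max}]")
        if "MAS" in self.landmark_z_mm and abs(
                self.landmark_z_mm["MAS"] - self.bulge_center_z_mm) > self.voxel_size_mm / 2:
            raise ConfigError("MAS landmark must coincide with the bulge center "
                              "(the slice of maximal outer radius)")
        if any(v < 0 for v in self.uptake_wall_by_quadrant.values()) \
                or self.uptake_blood < 0 or self.uptake_background < 0:
            raise ConfigError("uptake values must be >= 0")
        if set(self.uptake_wall_by_quadrant) != set(segmentation.QUADRANTS):
            raise ConfigError(f"uptake_wall_by_quadrant needs exactly the keys "
                              f"{segmentation.QUADRANTS}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.psf_sigma_mm < 0:
            raise ConfigError("psf_sigma_mm must be >= 0")
        if self.max_sac_radius_mm * 2 > min(self.grid_shape[0], self.grid_shape[1]) \
                * self.voxel_size_mm:
            raise SizingError("sac diameter exceeds the transverse grid extent")
        self.subject.validate()
        return self

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        import dataclasses
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown phantom spec keys: {sorted(unknown)}")
        if "subject" in raw and isinstance(raw["subject"], dict):
            raw["subject"] = SubjectCovariates(**raw["subject"])
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw).validate()


def outer_radius(spec: PhantomSpec, z: np.ndarray | float) -> np.ndarray:
    """Analytic outer-radius profile r(z) of the fusiform phantom."""
    z = np.asarray(z, dtype=float)
    return (spec.neck_radius_mm
            + (spec.max_sac_radius_mm - spec.neck_radius_mm)
            * np.exp(-((z - spec.bulge_center_z_mm) ** 2)
                     / (2.0 * spec.bulge_sigma_mm ** 2)))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def generate_geometry(spec: PhantomSpec, n_theta: int = 64, n_z: int = 96
                      ) -> tuple[ImageVolume, WallMesh]:
    """Voxel label volume (0 bg / 1 lumen / 2 wall) plus the mid-surface mesh.

    The mesh mid-surface sits at r_out(z) - mesh_thickness/2 (membrane-shell
    convention), spans the interior of the grid along z, carries the uniform
    mechanical thickness per node and flags both end rings as boundary.
    """
    spec.validate()
    nx, ny, nz = spec.grid_shape
    ox, oy, oz = spec.origin
    vs = spec.voxel_size_mm
    x = ox + np.arange(nx) * vs
    y = oy + np.arange(ny) * vs
    z = oz + np.arange(nz) * vs
    rho = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)       # (nx, ny)
    r_out = outer_radius(spec, z)                           # (nz,)
    lumen = rho[:, :, None] < (r_out - spec.wall_thickness_mm)[None, None, :]
    inside = rho[:, :, None] < r_out[None, None, :]
    lab = np.zeros(spec.grid_shape, dtype=np.int8)
    lab[inside] = segmentation.WALL
    lab[lumen] = segmentation.LUMEN
    labels = ImageVolume(lab, spec.spacing, spec.origin)

    z0, z1 = oz + 2 * vs, z[-1] - 2 * vs
    mesh = tube_mesh(
        lambda zz, th: float(outer_radius(spec, zz)) - spec.mesh_thickness_mm / 2.0,
        z0, z1, n_theta=n_theta, n_z=n_z, thickness=spec.mesh_thickness_mm,
        clamp="both", pressure_mmHg=spec.pressure_mmHg)
    return labels, mesh


# ---------------------------------------------------------------------------
# PET / CTA simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPET:
    """A simulated PET acquisition with its pre-blur ground truth."""

    volume: ImageVolume        # blurred + noisy activity (kBq/mL)
    ground_truth: ImageVolume  # piecewise-constant activity before PSF/noise


def _ground_truth_activity(labels: ImageVolume, spec: PhantomSpec) -> np.ndarray:
    lab = labels.data
    gt = np.full(lab.shape, spec.uptake_background, dtype=float)
    gt[lab == segmentation.LUMEN] = spec.uptake_blood
    wall = lab == segmentation.WALL
    cent = segmentation.lumen_centroids(lab == segmentation.LUMEN)
    quad = segmentation.quadrant_volume(wall, cent, labels.spacing)
    for qi, qname in enumerate(segmentation.QUADRANTS):
        gt[quad == qi] = spec.uptake_wall_by_quadrant[qname]
    return gt


def simulate_pet(labels: ImageVolume, spec: PhantomSpec) -> SimulatedPET:
    """Blur the piecewise-constant activity with the PSF and add seeded noise.

    Quadrant-dependent wall activity uses the same sectoring code as the
    analysis (single source of truth for the quadrant convention).
    """
    if spec.psf_sigma_mm < 0:
        raise ConfigError("psf_sigma_mm must be >= 0")
    gt = _ground_truth_activity(labels, spec)
    if spec.psf_sigma_mm > 0:
        sig = [spec.psf_sigma_mm / s for s in labels.spacing]
        blurred = ndimage.gaussian_filter(gt, sigma=sig, mode="nearest")
    else:
        blurred = gt.copy()
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        blurred = blurred + rng.normal(0.0, spec.noise_sd, size=blurred.shape)
    return SimulatedPET(ImageVolume(blurred, labels.spacing, labels.origin),
                        ImageVolume(gt, labels.spacing, labels.origin))


def simulate_cta(labels: ImageVolume, spec: PhantomSpec,
                 hu_lumen: float = 300.0, hu_wall: float = 50.0,
                 hu_background: float = -50.0, noise_sd_hu: float = 5.0
                 ) -> ImageVolume:
    """HU-like CTA: contrast-bright lumen >> wall >> background, mild noise."""
    lab = labels.data
    hu = np.full(lab.shape, hu_background, dtype=float)
    hu[lab == segmentation.WALL] = hu_wall
    hu[lab == segmentation.LUMEN] = hu_lumen
    if noise_sd_hu > 0:
        rng = np.random.default_rng(spec.rng_seed + 1)  # decouple from PET noise
        hu = hu + rng.normal(0.0, noise_sd_hu, size=hu.shape)
    return ImageVolume(hu, labels.spacing, labels.origin)
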
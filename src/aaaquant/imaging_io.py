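"""Volume, mesh, table and configuration I/O.

One internal axis convention is used everywhere: arrays are indexed
``data[i, j, k]`` with

* +x (axis 0): subject-left,
* +y (axis 1): anterior,
* +z (axis 2): superior (craniocaudal),

all in millimetres. NIfTI volumes are reoriented to the closest canonical
orientation on read so that downstream geometry code can assume this frame.
Meshes are stored as ASCII legacy-VTK POLYDATA with per-node scalar arrays.
"""

from __future__ import annotations

import csv
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, VolumeFormatError

log = logging.getLogger("aaaquant")


# ---------------------------------------------------------------------------
# ImageVolume
# ---------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """A 3D scalar grid with isotropic or anisotropic voxel spacing (mm).

    ``data[i, j, k]`` lives at world position ``origin + (i, j, k) * spacing``
    (voxel centers).  Carries HU-like (CTA), activity (kBq/mL) or SUV values.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError(f"ImageVolume requires a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise DataError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        A = np.diag(list(self.spacing) + [1.0])
        A[:3, 3] = self.origin
        return A

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Voxel index (possibly fractional) -> world mm."""
        return np.asarray(idx, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def world_to_index(self, pos: np.ndarray) -> np.ndarray:
        """World mm -> fractional voxel index."""
        return (np.asarray(pos, dtype=float) - np.array(self.origin)) / np.array(self.spacing)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        if data.shape != self.data.shape:
            raise DataError("replacement data must preserve the grid shape")
        return ImageVolume(data, self.spacing, self.origin)


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI volume, normalizing orientation to the internal frame."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise VolumeFormatError(f"{path}: expected NIfTI, got {type(img).__name__}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: header field dim declares {data.ndim}D data, need 3D")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: malformed header field pixdim = {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin)


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii or .nii.gz) with correct spacing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame | list[dict], path: str | Path,
                columns: list[str] | None = None) -> Path:
    """Write a CSV with a fixed column order and floats at 6 significant digits.

    Column order is taken from ``columns`` when given, otherwise from the
    DataFrame's columns sorted-stable as defined at construction; it never
    depends on record insertion order for list-of-dict input (keys are sorted).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, pd.DataFrame):
        df = records
        cols = columns if columns is not None else list(df.columns)
    else:
        keys = sorted({k for r in records for k in r})
        cols = columns if columns is not None else keys
        df = pd.DataFrame(records, columns=cols)
    try:
        df.to_csv(path, columns=cols, index=False, float_format="%.6g",
                  quoting=csv.QUOTE_MINIMAL)
    except OSError as exc:
        raise DataError(f"cannot write table to {path}: {exc}") from exc
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such table: {path}")
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# ASCII legacy-VTK POLYDATA meshes with per-node scalars
# ---------------------------------------------------------------------------

def write_mesh_vtk(path: str | Path, nodes: np.ndarray, faces: np.ndarray,
                   point_data: dict[str, np.ndarray] | None = None) -> Path:
    """Write a triangle mesh as ASCII legacy VTK with named per-node scalars."""
    nodes = np.asarray(nodes, dtype=float)
    faces = np.asarray(faces, dtype=int)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\naaaquant wall mesh\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for p in nodes:
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (len(nodes),):
                    raise DataError(f"point data '{name}' must be per-node scalar")
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    fh.write(f"{v:.10g}\n")
    return path


def read_mesh_vtk(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read an ASCII legacy-VTK POLYDATA triangle mesh written by this package."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such mesh: {path}")
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4 or "vtk" not in lines[0]:
        raise VolumeFormatError(f"{path}: not an ASCII legacy VTK file")
    for ln in lines[2:]:
        tokens.extend(ln.split())
    it = iter(range(len(tokens)))
    i = 0

    def expect(word: str) -> None:
        nonlocal i
        while i < len(tokens) and tokens[i].upper() != word:
            i += 1
        if i >= len(tokens):
            raise VolumeFormatError(f"{path}: missing {word} section")
        i += 1

    expect("POINTS")
    n = int(tokens[i]); i += 2  # skip dtype
    nodes = np.array(tokens[i:i + 3 * n], dtype=float).reshape(n, 3)
    i += 3 * n
    expect("POLYGONS")
    m = int(tokens[i]); total = int(tokens[i + 1]); i += 2
    raw = np.array(tokens[i:i + total], dtype=int)
    i += total
    faces = []
    j = 0
    while j < len(raw):
        cnt = raw[j]
        if cnt != 3:
            raise VolumeFormatError(f"{path}: non-triangular polygon of size {cnt}")
        faces.append(raw[j + 1:j + 4])
        j += cnt + 1
    point_data: dict[str, np.ndarray] = {}
    while i < len(tokens):
        if tokens[i].upper() == "SCALARS":
            name = tokens[i + 1]
            i += 4  # SCALARS name dtype [ncomp]
            while tokens[i].upper() in ("LOOKUP_TABLE", "DEFAULT", "1"):
                i += 1
            point_data[name] = np.array(tokens[i:i + n], dtype=float)
            i += n
        else:
            i += 1
    return nodes, np.array(faces, dtype=int), point_data


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ConfigError(f"config field '{name}' = {value} outside [{lo}, {hi}]")


@dataclass
class RunConfig:
    """Resolved configuration for one analysis run.

    Every run's output directory receives a copy of the resolved config plus
    a timestamped log, so each reported number is reproducible from disk.
    """

    # inputs (empty -> generate the default phantom in-run)
    cta_path: str = ""
    pet_path: str = ""
    labels_path: str = ""
    mesh_path: str = ""
    # segmentation
    slab_halfwidth_mm: float = 5.0
    erosion_radius_mm: float = 2.0
    # uptake
    suv_normalization: str = "body_weight"
    mas_threshold: float = 0.53
    # biomech
    pressure_mmHg: float = 120.0
    elastic_modulus_mpa: float = 2.7
    poisson_ratio: float = 0.49
    strength_coefficients: str = ""  # empty -> packaged defaults
    # stats
    alpha: float = 0.05
    correlation_method: str = "pearson"
    # run
    output_dir: str = "aaaquant_out"
    seed: int = 0

    def validate(self) -> "RunConfig":
        _check_range("slab_halfwidth_mm", self.slab_halfwidth_mm, 0.1, 50.0)
        _check_range("erosion_radius_mm", self.erosion_radius_mm, 0.0, 50.0)
        _check_range("pressure_mmHg", self.pressure_mmHg, 1.0, 400.0)
        _check_range("elastic_modulus_mpa", self.elastic_modulus_mpa, 0.01, 100.0)
        _check_range("poisson_ratio", self.poisson_ratio, 0.0, 0.4999)
        _check_range("alpha", self.alpha, 0.0001, 0.5)
        if self.suv_normalization != "body_weight":
            raise ConfigError("suv_normalization: only 'body_weight' is implemented")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ConfigError("correlation_method must be 'pearson' or 'spearman'")
        if int(self.seed) != self.seed or not (0 <= self.seed < 2**31):
            raise ConfigError("seed must be an integer in [0, 2^31)")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}")
    return RunConfig(**raw).validate()


def dump_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump({f.name: getattr(cfg, f.name) for f in fields(cfg)}, fh,
                       sort_keys=True)
    return path


def setup_run_logging(outdir: str | Path, level: int = logging.INFO) -> logging.Logger:
    """Attach a timestamped file handler under the run's output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("aaaquant")
    logger.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(fmt)
    logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler)
               for h in logger.handlers):
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    return logger
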
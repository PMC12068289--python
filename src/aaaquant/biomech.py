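"""Wall stress, wall strength and the rupture potential index (RPI).

The aneurysm wall is modelled as a thin membrane: because the loaded
configuration is observed directly on CTA, the wall can be treated as
statically determinate and a *linear* small-strain analysis suffices.  The
mid-surface triangulation is solved with constant-strain membrane triangles
(plane-stress constitutive law, thickness-scaled stiffness) under a uniform
intraluminal pressure applied along the outward facet normals.  Boundary-ring
nodes are clamped; closed surfaces with no flagged nodes receive a minimal
six-constraint rigid-body restraint chosen compatible with the uniform
breathing mode.

Wall strength comes from a covariate regression (see
``data/strength_coefficients.yaml``), and RPI = stress / strength per node.
An RPI around 1 indicates stress approaching strength, i.e. high rupture risk.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import yaml

from . import units
from .errors import ConfigError, DataError, NumericalError

__all__ = [
    "WallMesh", "RPIField", "StrengthCoefficients",
    "wall_stress_fea", "laplace_stress", "wall_strength", "compute_rpi",
    "tube_mesh", "cylinder_benchmark_mesh", "sphere_benchmark_mesh",
    "load_strength_coefficients",
]


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------

@dataclass
class WallMesh:
    """Triangulated wall mid-surface: the FEA domain.

    nodes        (n, 3) positions in mm
    faces        (m, 3) vertex indices, oriented so the right-hand normal
                 points outward (away from the lumen)
    thickness    (n,) per-node wall thickness in mm
    boundary     (n,) bool; True on clamped boundary rings
    """

    nodes: np.ndarray
    faces: np.ndarray
    thickness: np.ndarray
    boundary: np.ndarray
    elastic_modulus_mpa: float = 2.7
    poisson_ratio: float = 0.49
    pressure_mmHg: float = 120.0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.thickness = np.broadcast_to(
            np.asarray(self.thickness, dtype=float), (len(self.nodes),)).copy()
        self.boundary = np.asarray(self.boundary, dtype=bool)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def face_areas_normals(self) -> tuple[np.ndarray, np.ndarray]:
        p1, p2, p3 = (self.nodes[self.faces[:, k]] for k in range(3))
        nvec = np.cross(p2 - p1, p3 - p1)
        nrm = np.linalg.norm(nvec, axis=1)
        nhat = np.divide(nvec, nrm[:, None], out=np.zeros_like(nvec),
                         where=nrm[:, None] > 0)
        return 0.5 * nrm, nhat

    def validate(self) -> None:
        if self.faces.min() < 0 or self.faces.max() >= self.n_nodes:
            raise DataError("face indices out of range")
        if np.any(self.thickness <= 0):
            raise DataError("wall thickness must be positive everywhere")
        areas, _ = self.face_areas_normals()
        if np.any(areas <= 1e-12):
            raise DataError(f"{int(np.sum(areas <= 1e-12))} degenerate (zero-area) triangles")
        # watertight between boundary rings: every edge shared by exactly two
        # triangles unless both endpoints lie on a boundary ring
        edges = np.sort(np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                                        self.faces[:, [2, 0]]]), axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        bad = counts > 2
        if np.any(bad):
            raise DataError(f"non-manifold mesh: {int(bad.sum())} edges in >2 triangles")
        open_edges = uniq[counts == 1]
        if len(open_edges):
            # watertight between rings: open edges must form closed curves,
            # i.e. every node on an open edge touches exactly two of them
            node_ids, deg = np.unique(open_edges.ravel(), return_counts=True)
            if np.any(deg != 2):
                raise DataError(
                    f"mesh not watertight between boundary rings: "
                    f"{int((deg != 2).sum())} ragged boundary nodes")


@dataclass
class RPIField:
    """Per-node von Mises stress, strength and RPI (all on the WallMesh)."""

    stress_n_per_cm2: np.ndarray
    strength_n_per_cm2: np.ndarray
    rpi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        stress = np.asarray(self.stress_n_per_cm2, dtype=float)
        strength = np.asarray(self.strength_n_per_cm2, dtype=float)
        if np.any(strength <= 0):
            raise DataError("wall strength must be positive at every node; "
                            "check covariates / coefficient file")
        if np.any(stress < 0) or not np.all(np.isfinite(stress)):
            raise DataError("stress field must be finite and non-negative")
        self.stress_n_per_cm2 = stress
        self.strength_n_per_cm2 = strength
        self.rpi = stress / strength


# ---------------------------------------------------------------------------
# Closed-form oracle
# ---------------------------------------------------------------------------

def laplace_stress(radius_mm: float, thickness_mm: float, pressure_mmHg: float,
                   shape: str = "cylinder") -> float:
    """Thin-wall Laplace stress in N/cm^2: P*r/t (cylinder hoop), P*r/(2t) (sphere)."""
    if radius_mm <= 0 or thickness_mm <= 0 or pressure_mmHg <= 0:
        raise DataError("laplace_stress requires positive radius, thickness, pressure")
    p = units.mmhg_to_n_per_mm2(pressure_mmHg)
    if shape == "cylinder":
        s = p * radius_mm / thickness_mm
    elif shape == "sphere":
        s = p * radius_mm / (2.0 * thickness_mm)
    else:
        raise ConfigError(f"unknown shape '{shape}' (cylinder or sphere)")
    return units.n_per_mm2_to_n_per_cm2(s)


# ---------------------------------------------------------------------------
# Membrane FEA
# ---------------------------------------------------------------------------

def _rigid_body_restraints(nodes: np.ndarray) -> np.ndarray:
    """Minimal 6-DOF restraint for a closed surface, compatible with uniform
    radial breathing about the surface centroid: at the nodes closest to the
    +z, +x and +y extremes (relative to the centroid) the two *tangential*
    in-plane translations are fixed, leaving the radial direction free."""
    c = nodes.mean(axis=0)
    rel = nodes - c
    iA = int(np.argmax(rel[:, 2]))
    iB = int(np.argmax(rel[:, 0]))
    iC = int(np.argmax(rel[:, 1]))
    return np.array([3 * iA, 3 * iA + 1,        # node at +z: fix x, y
                     3 * iB + 1, 3 * iB + 2,    # node at +x: fix y, z
                     3 * iC, 3 * iC + 2])       # node at +y: fix x, z


def _assemble(mesh: WallMesh):
    """Vectorized CST membrane assembly.  Returns (K csr, F, element ops)."""
    nodes, faces = mesh.nodes, mesh.faces
    m = len(faces)
    p1, p2, p3 = nodes[faces[:, 0]], nodes[faces[:, 1]], nodes[faces[:, 2]]
    e1 = p2 - p1
    nvec = np.cross(e1, p3 - p1)
    nrm = np.linalg.norm(nvec, axis=1)
    if np.any(nrm <= 1e-12):
        raise DataError("degenerate triangle encountered during assembly")
    area = 0.5 * nrm
    nhat = nvec / nrm[:, None]
    e1 = e1 / np.linalg.norm(e1, axis=1)[:, None]
    e2 = np.cross(nhat, e1)

    # local planar coordinates of the three vertices
    x2 = np.einsum("ij,ij->i", p2 - p1, e1)
    y2 = np.einsum("ij,ij->i", p2 - p1, e2)
    x3 = np.einsum("ij,ij->i", p3 - p1, e1)
    y3 = np.einsum("ij,ij->i", p3 - p1, e2)
    x1 = np.zeros(m)
    y1 = np.zeros(m)

    b = np.stack([y2 - y3, y3 - y1, y1 - y2], axis=1)  # (m, 3)
    c = np.stack([x3 - x2, x1 - x3, x2 - x1], axis=1)

    B = np.zeros((m, 3, 6))
    B[:, 0, 0::2] = b
    B[:, 1, 1::2] = c
    B[:, 2, 0::2] = c
    B[:, 2, 1::2] = b
    B /= (2.0 * area)[:, None, None]

    E = mesh.elastic_modulus_mpa  # N/mm^2
    nu = mesh.poisson_ratio
    D = E / (1 - nu**2) * np.array([[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])

    T = np.zeros((m, 6, 9))
    for i in range(3):
        T[:, 2 * i, 3 * i:3 * i + 3] = e1
        T[:, 2 * i + 1, 3 * i:3 * i + 3] = e2

    t_elem = mesh.thickness[faces].mean(axis=1)
    BT = np.einsum("mab,mbc->mac", B, T)          # (m, 3, 9) strain operator
    DBT = np.einsum("ab,mbc->mac", D, BT)         # (m, 3, 9) stress operator
    Ke = np.einsum("mba,mbc->mac", BT, DBT) * (t_elem * area)[:, None, None]

    dofs = (3 * faces[:, :, None] + np.arange(3)[None, None, :]).reshape(m, 9)
    rows = np.repeat(dofs, 9, axis=1).ravel()
    cols = np.tile(dofs, (1, 9)).ravel()
    n_dof = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()

    # consistent pressure load along outward normals
    p = units.mmhg_to_n_per_mm2(mesh.pressure_mmHg)
    fe = (p * area / 3.0)[:, None] * nhat         # (m, 3) per-vertex force
    F = np.zeros(n_dof)
    for k in range(3):
        np.add.at(F, 3 * faces[:, k], fe[:, 0])
        np.add.at(F, 3 * faces[:, k] + 1, fe[:, 1])
        np.add.at(F, 3 * faces[:, k] + 2, fe[:, 2])
    return K, F, DBT, dofs, area


def wall_stress_fea(mesh: WallMesh, return_element_stress: bool = False):
    """Solve the membrane problem; return per-node von Mises stress in N/cm^2.

    Element stresses (constant per CST) are averaged onto nodes with
    area weights.  With ``return_element_stress`` the per-element von Mises
    values and areas are returned as well (used by convergence studies).
    """
    if mesh.pressure_mmHg < 0:
        raise DataError("pressure must be non-negative")
    mesh.validate()
    K, F, DBT, dofs, area = _assemble(mesh)
    n_dof = 3 * mesh.n_nodes
    fixed = np.zeros(n_dof, dtype=bool)
    if mesh.boundary.any():
        for d in range(3):
            fixed[3 * np.flatnonzero(mesh.boundary) + d] = True
    else:
        fixed[_rigid_body_restraints(mesh.nodes)] = True
    free = np.flatnonzero(~fixed)
    u = np.zeros(n_dof)
    Kff = K[np.ix_(free, free)]
    try:
        u[free] = spla.spsolve(Kff, F[free])
    except RuntimeError as exc:
        raise NumericalError(f"singular stiffness matrix: {exc}") from exc
    if not np.all(np.isfinite(u)):
        bad = np.flatnonzero(~np.isfinite(u))[:5] // 3
        raise NumericalError(
            f"singular system: unconstrained displacement components at nodes {bad}")

    s = np.einsum("mac,mc->ma", DBT, u[dofs])     # local (s11, s22, s12), N/mm^2
    vm_elem = np.sqrt(s[:, 0]**2 + s[:, 1]**2 - s[:, 0] * s[:, 1] + 3 * s[:, 2]**2)

    vm_node = np.zeros(mesh.n_nodes)
    wsum = np.zeros(mesh.n_nodes)
    for k in range(3):
        np.add.at(vm_node, mesh.faces[:, k], vm_elem * area)
        np.add.at(wsum, mesh.faces[:, k], area)
    vm_node = units.n_per_mm2_to_n_per_cm2(vm_node / wsum)
    if return_element_stress:
        return vm_node, units.n_per_mm2_to_n_per_cm2(vm_elem), area
    return vm_node


# ---------------------------------------------------------------------------
# Wall strength
# ---------------------------------------------------------------------------

@dataclass
class StrengthCoefficients:
    """Coefficients of the covariate wall-strength regression (N/cm^2)."""

    name: str
    intercept: float
    ilt_coef: float
    ilt_center: float
    nord_coef: float
    nord_center: float
    hist_coef: float
    sex_coef: float

    REQUIRED = ("intercept", "ilt", "nord", "hist", "sex")

    @classmethod
    def from_mapping(cls, raw: dict) -> "StrengthCoefficients":
        missing = [k for k in cls.REQUIRED if k not in raw]
        if missing:
            raise ConfigError(f"strength coefficient file missing entries: {missing}; "
                              f"required: {list(cls.REQUIRED)}")
        return cls(
            name=str(raw.get("name", "unnamed")),
            intercept=float(raw["intercept"]),
            ilt_coef=float(raw["ilt"]["coef"]),
            ilt_center=float(raw["ilt"]["center"]),
            nord_coef=float(raw["nord"]["coef"]),
            nord_center=float(raw["nord"].get("center", 0.0)),
            hist_coef=float(raw["hist"]["coef"]),
            sex_coef=float(raw["sex"]["coef"]),
        )


def load_strength_coefficients(path: str | None = None) -> StrengthCoefficients:
    """Load the versioned coefficient file (packaged default, or an override)."""
    if path:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    else:
        ref = importlib.resources.files("aaaquant").joinpath("data/strength_coefficients.yaml")
        raw = yaml.safe_load(ref.read_text())
    return StrengthCoefficients.from_mapping(raw)


def wall_strength(subject, coefficients: StrengthCoefficients | None = None,
                  n_nodes: int = 1, ilt_thickness_cm: float | np.ndarray = 0.0) -> np.ndarray:
    """Evaluate the covariate strength model per node (N/cm^2).

    Strength depends only on subject covariates (and optionally a per-node
    intraluminal thrombus thickness), so it is spatially constant for the
    no-thrombus default and invariant under mesh refinement.
    """
    if coefficients is None:
        coefficients = load_strength_coefficients()
    ilt = np.broadcast_to(np.asarray(ilt_thickness_cm, dtype=float), (n_nodes,))
    if np.any(ilt < 0):
        raise DataError("intraluminal thrombus thickness must be >= 0")
    c = coefficients
    s = (c.intercept
         + c.ilt_coef * (np.sqrt(ilt) - c.ilt_center)
         + c.nord_coef * (subject.nord - c.nord_center)
         + c.hist_coef * subject.hist
         + c.sex_coef * subject.sex_code)
    return np.asarray(s, dtype=float)


def compute_rpi(stress_n_per_cm2: np.ndarray, strength_n_per_cm2: np.ndarray) -> RPIField:
    """RPI_i = stress_i / strength_i (dimensionless)."""
    return RPIField(stress_n_per_cm2, strength_n_per_cm2)


# ---------------------------------------------------------------------------
# Mesh generators (analysis domain + analytic benchmarks)
# ---------------------------------------------------------------------------

def tube_mesh(radius_fn, z0: float, z1: float, n_theta: int = 64, n_z: int = 96,
              thickness: float = 2.0, clamp: str = "both",
              **mesh_kwargs) -> WallMesh:
    """Structured triangulated tube of mid-surface radius ``radius_fn(z, theta)``.

    ``clamp``: 'both' flags both end rings, 'one' only the z0 ring (the
    hoop-dominated benchmark configuration), 'none' leaves no flags.
    """
    if n_theta < 8 or n_z < 2:
        raise DataError("tube mesh needs n_theta >= 8 and n_z >= 2")
    th = np.arange(n_theta) * 2 * np.pi / n_theta
    zz = np.linspace(z0, z1, n_z + 1)
    Z, TH = np.meshgrid(zz, th, indexing="ij")
    R = np.vectorize(radius_fn)(Z, TH)
    nodes = np.stack([R * np.cos(TH), R * np.sin(TH), Z], axis=-1).reshape(-1, 3)
    faces = []
    for j in range(n_z):
        row, nxt = j * n_theta, (j + 1) * n_theta
        for i in range(n_theta):
            a, b = row + i, row + (i + 1) % n_theta
            c, d = nxt + i, nxt + (i + 1) % n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    faces = np.array(faces, dtype=int)
    # orient outward (away from the z axis)
    p1, p2, p3 = nodes[faces[:, 0]], nodes[faces[:, 1]], nodes[faces[:, 2]]
    ctr = (p1 + p2 + p3) / 3.0
    nrm = np.cross(p2 - p1, p3 - p1)
    flip = nrm[:, 0] * ctr[:, 0] + nrm[:, 1] * ctr[:, 1] < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    boundary = np.zeros(len(nodes), dtype=bool)
    if clamp in ("both", "one"):
        boundary[:n_theta] = True
    if clamp == "both":
        boundary[-n_theta:] = True
    elif clamp not in ("one", "none"):
        raise ConfigError(f"clamp must be 'both', 'one' or 'none', got '{clamp}'")
    return WallMesh(nodes, faces, thickness, boundary, **mesh_kwargs)


def cylinder_benchmark_mesh(radius: float = 10.0, length: float = 80.0,
                            n_theta: int = 64, n_z: int = 64, thickness: float = 1.5,
                            **mesh_kwargs) -> WallMesh:
    """Constant-radius tube clamped at one end: the Laplace hoop-stress benchmark.

    A single clamped ring leaves the other edge traction-free so the net
    axial force vanishes and the mid-span stress state is pure hoop,
    sigma = P*r/t (clamping both rings would add a Poisson-induced axial
    stress of nu*P*r/t and shift the von Mises value).
    """
    return tube_mesh(lambda z, th: radius, 0.0, length, n_theta, n_z, thickness,
                     clamp="one", **mesh_kwargs)


def sphere_benchmark_mesh(radius: float = 25.0, n_theta: int = 64, n_phi: int = 32,
                          thickness: float = 1.5, **mesh_kwargs) -> WallMesh:
    """Closed UV-sphere (no boundary rings; rigid modes pinned automatically)."""
    phis = np.linspace(0, np.pi, n_phi + 1)[1:-1]
    th = np.arange(n_theta) * 2 * np.pi / n_theta
    pts = [[0.0, 0.0, radius]]
    for p in phis:
        sp_, cp = np.sin(p), np.cos(p)
        for t in th:
            pts.append([radius * sp_ * np.cos(t), radius * sp_ * np.sin(t), radius * cp])
    pts.append([0.0, 0.0, -radius])
    nodes = np.array(pts)
    faces = []
    for i in range(n_theta):
        faces.append([0, 1 + i, 1 + (i + 1) % n_theta])
    for j in range(len(phis) - 1):
        row, nxt = 1 + j * n_theta, 1 + (j + 1) * n_theta
        for i in range(n_theta):
            a, b = row + i, row + (i + 1) % n_theta
            c, d = nxt + i, nxt + (i + 1) % n_theta
            faces.append([a, d, b])
            faces.append([a, c, d])
    south = len(nodes) - 1
    base = 1 + (len(phis) - 1) * n_theta
    for i in range(n_theta):
        faces.append([south, base + (i + 1) % n_theta, base + i])
    faces = np.array(faces, dtype=int)
    p1, p2, p3 = nodes[faces[:, 0]], nodes[faces[:, 1]], nodes[faces[:, 2]]
    ctr = (p1 + p2 + p3) / 3.0
    nrm = np.cross(p2 - p1, p3 - p1)
    flip = np.einsum("ij,ij->i", nrm, ctr) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return WallMesh(nodes, faces, thickness, np.zeros(len(nodes), dtype=bool),
                    **mesh_kwargs)
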
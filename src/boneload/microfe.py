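"""Voxel-based linear-elastic hexahedral micro-finite-element analysis.

Every bone voxel of a binary mask becomes one 8-node trilinear hexahedral
element (2x2x2 Gauss quadrature, isotropic elasticity).  Enclosed marrow
cavities are meshed with a soft tissue modulus so the structure stays
connected; everything outside the bone envelope is absent from the mesh.

Six canonical displacement-controlled load cases are supported: axial
compression C, transverse shears SX / SY, torsion MZ, and bending BX / BY.
Forces are applied as a 1% displacement of the axial length, moments as a
1-degree small-rotation displacement about the axis through the point of
reference (the centre of the minimal bounding box of the bone).  Both end
faces are bonded platens: the proximal face is fully fixed and the distal
face fully prescribed.  After solving, the per-element strain energy
density (SED, MPa, evaluated at the element centroid) is rescaled so the
reaction equals 1 N (forces) or 1 Nmm (moments); these unit-load SED fields
are the basis functions that the inverse load estimators superpose.

Units are mm / N / MPa throughout, moments in Nmm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from .images import BinaryMask

__all__ = [
    "DIRECTIONS",
    "FORCE_DIRECTIONS",
    "MOMENT_DIRECTIONS",
    "SCENARIOS",
    "MeshError",
    "SolverError",
    "VoxelMesh",
    "UnitLoadCase",
    "UnitLoadSet",
    "CompoundLoad",
    "build_mesh",
    "solve_case",
    "solve_unit_loads",
    "superpose",
    "scenario_load",
    "hex_stiffness",
    "elasticity_matrix",
]

#: Canonical load directions, in the fixed ordering used for every
#: coefficient vector in the package.
DIRECTIONS: tuple[str, ...] = ("C", "SX", "SY", "MZ", "BX", "BY")
FORCE_DIRECTIONS = ("C", "SX", "SY")  # reactions in N
MOMENT_DIRECTIONS = ("MZ", "BX", "BY")  # reactions in Nmm

#: Load scenarios: uniaxial one-hots plus the multiaxial mixtures
#: CS = 0.5 C + 0.25 SX + 0.25 SY, CB = 0.5 C + 0.25 BX + 0.25 BY and a
#: six-degree-of-freedom load with equal proportions in all directions.
SCENARIOS: dict[str, tuple[float, ...]] = {
    "C": (1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "SX": (0.0, 1.0, 0.0, 0.0, 0.0, 0.0),
    "SY": (0.0, 0.0, 1.0, 0.0, 0.0, 0.0),
    "MZ": (0.0, 0.0, 0.0, 1.0, 0.0, 0.0),
    "BX": (0.0, 0.0, 0.0, 0.0, 1.0, 0.0),
    "BY": (0.0, 0.0, 0.0, 0.0, 0.0, 1.0),
    "CS": (0.5, 0.25, 0.25, 0.0, 0.0, 0.0),
    "CB": (0.5, 0.0, 0.0, 0.0, 0.25, 0.25),
    "6DoF": (1 / 6,) * 6,
}

# Local corner offsets of a hexahedral element, binary (x fastest) order.
_CORNERS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
    dtype=np.int64,
)
_NAT = 2.0 * _CORNERS - 1.0  # natural coordinates of the corners, +-1


class MeshError(RuntimeError):
    """The mask cannot be meshed into a well-posed FE model."""


class SolverError(RuntimeError):
    """The linear system could not be solved to tolerance."""


def elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """Isotropic elasticity matrix in Voigt notation (engineering shear)."""
    if not -1.0 < nu < 0.5:
        raise ValueError(f"Poisson ratio out of range: {nu}")
    c = E / ((1 + nu) * (1 - 2 * nu))
    D = np.zeros((6, 6))
    D[:3, :3] = c * nu
    np.fill_diagonal(D[:3, :3], c * (1 - nu))
    np.fill_diagonal(D[3:, 3:], c * (1 - 2 * nu) / 2)
    return D


def _shape_gradients(xi: float, eta: float, zeta: float) -> np.ndarray:
    """d N_a / d(natural coords), shape (8, 3)."""
    g = np.empty((8, 3))
    for a, (cx, cy, cz) in enumerate(_NAT):
        g[a, 0] = 0.125 * cx * (1 + eta * cy) * (1 + zeta * cz)
        g[a, 1] = 0.125 * (1 + xi * cx) * cy * (1 + zeta * cz)
        g[a, 2] = 0.125 * (1 + xi * cx) * (1 + eta * cy) * cz
    return g


def _b_matrix(dndx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 24) from physical shape gradients."""
    B = np.zeros((6, 24))
    for a in range(8):
        bx, by, bz = dndx[a]
        c = 3 * a
        B[0, c] = bx
        B[1, c + 1] = by
        B[2, c + 2] = bz
        B[3, c] = by
        B[3, c + 1] = bx
        B[4, c + 1] = bz
        B[4, c + 2] = by
        B[5, c] = bz
        B[5, c + 2] = bx
    return B


@lru_cache(maxsize=8)
def hex_stiffness(nu: float, h: float) -> np.ndarray:
    """Element stiffness (24, 24) of a cubic hexahedron with E = 1.

    2x2x2 Gauss quadrature; for an affine cube of edge ``h`` the Jacobian
    is constant (h/2 on the diagonal).  Element matrices for any modulus E
    are E times this matrix, which is what makes voxel FE assembly a pure
    scatter operation.
    """
    D = elasticity_matrix(1.0, nu)
    detJ = (h / 2.0) ** 3
    K = np.zeros((24, 24))
    gp = (-1 / np.sqrt(3), 1 / np.sqrt(3))
    for xi in gp:
        for eta in gp:
            for zeta in gp:
                dndx = _shape_gradients(xi, eta, zeta) * (2.0 / h)
                B = _b_matrix(dndx)
                K += B.T @ D @ B * detJ
    return 0.5 * (K + K.T)


@lru_cache(maxsize=8)
def _centroid_b(h: float) -> np.ndarray:
    return _b_matrix(_shape_gradients(0.0, 0.0, 0.0) * (2.0 / h))


@dataclass
class VoxelMesh:
    """A voxel hexahedral mesh with per-element Young's modulus.

    ``elements`` are voxel indices on the (possibly disc-padded) grid;
    ``modulus`` is in MPa per element.  ``reference_point`` (mm) is the
    centre of the minimal bounding box of the bone elements, the point the
    torsion/bending rotations are taken about.
    """

    shape: tuple[int, int, int]
    elements: np.ndarray  # (ne, 3) int voxel indices
    modulus: np.ndarray  # (ne,) MPa
    poisson: float
    spacing: float
    is_bone: np.ndarray  # (ne,) bool; False for soft cavity elements
    reference_point: np.ndarray  # (3,) mm
    z_pad: int = 0  # disc layers added below/above the original mask grid
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_elements(self) -> int:
        return int(self.elements.shape[0])

    @property
    def axial_length(self) -> float:
        """End-to-end length of the meshed grid along z, mm."""
        return self.shape[2] * self.spacing

    def element_field(self, values: np.ndarray, crop: bool = True) -> np.ndarray:
        """Scatter per-element values into a dense volume (zeros elsewhere);
        with ``crop`` the disc padding is removed so the volume aligns with
        the original mask grid."""
        out = np.zeros(self.shape, dtype=np.float64)
        out[tuple(self.elements.T)] = values
        if crop and self.z_pad:
            out = out[:, :, self.z_pad : self.shape[2] - self.z_pad]
        return out


def build_mesh(
    mask: BinaryMask,
    tissue_modulus: float = 6800.0,
    soft_modulus: float = 2.0,
    poisson: float = 0.3,
    pad_discs: int = 0,
    modulus_map: np.ndarray | None = None,
) -> VoxelMesh:
    """Mesh a binary bone mask into voxel hexahedral elements.

    Bone voxels receive ``tissue_modulus`` (defaults to 6,800 MPa, the
    human distal radius value; use 14,800 MPa for mouse vertebrae) or, if
    ``modulus_map`` is given, the per-voxel modulus from that map (density
    derived moduli in remodelling simulations).  Marrow cavities fully
    enclosed by bone are meshed at ``soft_modulus`` (2 MPa); exterior
    voxels are absent.  ``pad_discs`` solid layers of tissue modulus may be
    added at both axial ends, mimicking embedding discs that distribute
    the platen load.

    Floating element groups touching neither end face cannot be restrained
    and are dropped; if no element group connects the two end faces the
    model is unsolvable and a :class:`MeshError` is raised.
    """
    if tissue_modulus <= 0 or soft_modulus <= 0:
        raise ValueError("moduli must be positive")
    bone = mask.values
    h = mask.spacing
    pad = int(pad_discs)
    if pad:
        nx, ny, nz = bone.shape
        padded = np.zeros((nx, ny, nz + 2 * pad), dtype=bool)
        padded[:, :, pad : pad + nz] = bone
        padded[:, :, :pad] = True
        padded[:, :, pad + nz :] = True
        bone = padded

    # Enclosed cavities: background not reachable from the grid boundary.
    bg = ~bone
    lbl, nlbl = ndi.label(bg, structure=ndi.generate_binary_structure(3, 1))
    edge_labels = np.unique(
        np.concatenate(
            [lbl[0].ravel(), lbl[-1].ravel(), lbl[:, 0].ravel(), lbl[:, -1].ravel(),
             lbl[:, :, 0].ravel(), lbl[:, :, -1].ravel()]
        )
    )
    exterior = np.isin(lbl, edge_labels[edge_labels > 0])
    cavity = bg & ~exterior

    solid = bone | cavity
    # Element groups share nodes under 26-connectivity; drop unrestrained ones.
    comp, ncomp = ndi.label(solid, structure=np.ones((3, 3, 3), dtype=bool))
    if ncomp == 0:
        raise MeshError("empty mask: nothing to mesh")
    lo = np.unique(comp[:, :, 0])
    hi = np.unique(comp[:, :, -1])
    lo, hi = set(lo[lo > 0]), set(hi[hi > 0])
    if not lo & hi:
        raise MeshError("no element group connects the proximal and distal end faces")
    keep = np.isin(comp, sorted(lo | hi))
    solid &= keep
    bone &= keep

    elements = np.argwhere(solid)
    is_bone = bone[tuple(elements.T)]
    modulus = np.where(is_bone, tissue_modulus, soft_modulus).astype(np.float64)
    if modulus_map is not None:
        mm = np.asarray(modulus_map, dtype=np.float64)
        if pad:
            full = np.full(bone.shape, tissue_modulus)
            full[:, :, pad : bone.shape[2] - pad] = mm
            mm = full
        if mm.shape != bone.shape:
            raise ValueError("modulus_map shape does not match the mask grid")
        vals = mm[tuple(elements.T)]
        if np.any(vals[is_bone] <= 0):
            raise ValueError("modulus_map must be positive on bone voxels")
        modulus[is_bone] = vals[is_bone]

    bone_idx = elements[is_bone]
    bb_lo = bone_idx.min(axis=0).astype(float) * h
    bb_hi = (bone_idx.max(axis=0) + 1.0) * h
    ref = 0.5 * (bb_lo + bb_hi)

    return VoxelMesh(
        shape=solid.shape,
        elements=elements,
        modulus=modulus,
        poisson=float(poisson),
        spacing=float(h),
        is_bone=is_bone,
        reference_point=ref,
        z_pad=pad,
    )


# ---------------------------------------------------------------------------
# assembly and solving

def _fe_system(mesh: VoxelMesh) -> dict:
    """Assemble (and cache on the mesh) the global stiffness and DOF maps."""
    cache = mesh._cache
    if "K" in cache:
        return cache

    nx, ny, nz = mesh.shape
    nyn, nzn = ny + 1, nz + 1
    elems = mesh.elements
    # Global grid node ids of the 8 corners of every element.
    corner = elems[:, None, :] + _CORNERS[None, :, :]
    gid = (corner[..., 0] * nyn + corner[..., 1]) * nzn + corner[..., 2]
    used, inv = np.unique(gid, return_inverse=True)
    enodes = inv.reshape(gid.shape)  # (ne, 8) local node ids
    nn = used.size

    edofs = (3 * enodes[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)

    K1 = hex_stiffness(mesh.poisson, mesh.spacing)
    edofs32 = edofs.astype(np.int32)
    rows = np.repeat(edofs32, 24, axis=1).ravel()
    cols = np.tile(edofs32, (1, 24)).ravel()
    vals = (mesh.modulus[:, None] * K1.ravel()[None, :]).ravel()
    ndof = 3 * nn
    K = sparse.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()

    # Node coordinates (mm) and end-face membership.
    kz = used % nzn
    rem = used // nzn
    jy = rem % nyn
    ix = rem // nyn
    coords = np.stack([ix, jy, kz], axis=1).astype(np.float64) * mesh.spacing

    cache.update(
        K=K,
        ndof=ndof,
        coords=coords,
        kz=kz,
        nz=nz,
        edofs=edofs,
    )
    return cache


def _node_dofs(nodes: np.ndarray) -> np.ndarray:
    return (3 * nodes[:, None] + np.arange(3)[None, :]).ravel()


def _solve_constrained(sys: dict, u_pres: np.ndarray, pres: np.ndarray,
                       solver: str, tol: float) -> np.ndarray:
    """Solve K u = 0 with prescribed DOFs ``pres`` set to ``u_pres``."""
    K = sys["K"]
    ndof = sys["ndof"]
    free = np.setdiff1d(np.arange(ndof), pres, assume_unique=False)
    u = np.zeros(ndof)
    u[pres] = u_pres
    rhs = -K[free][:, pres] @ u_pres
    Kff = K[free][:, free].tocsc()

    if solver == "auto":
        solver = "direct" if free.size <= 400_000 else "cg"
    if solver == "direct":
        # Mixed precision: factor in single precision (symmetric-mode
        # minimum-degree ordering, roughly half the fill and time), then
        # refine the solution against the double-precision matrix.  The
        # refinement converges to machine precision in a few sweeps; if it
        # stalls (extreme conditioning) a double factorisation takes over.
        key = ("lu", tuple(pres[:3]), pres.size)  # BC pattern is shared across cases
        lu = sys.get(key)
        if lu is None:
            try:
                lu = splu(Kff.astype(np.float32), permc_spec="MMD_AT_PLUS_A",
                          options={"SymmetricMode": True})
            except RuntimeError as err:  # exactly singular factor
                raise SolverError(f"singular FE system (floating region?): {err}") from err
            sys[key] = lu
        uf = lu.solve(rhs.astype(np.float32)).astype(np.float64)
        bnorm = max(float(np.linalg.norm(rhs)), 1e-300)
        converged = False
        for _ in range(6):
            r = rhs - Kff @ uf
            if np.linalg.norm(r) <= 1e-10 * bnorm:
                converged = True
                break
            uf += lu.solve(r.astype(np.float32)).astype(np.float64)
        if not converged:
            lu64 = sys.get(key + ("f64",))
            if lu64 is None:
                lu64 = splu(Kff, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})
                sys[key + ("f64",)] = lu64
            uf = lu64.solve(rhs)
    else:
        M = sparse.diags(1.0 / Kff.diagonal())
        uf, info = cg(Kff, rhs, rtol=tol, maxiter=20_000, M=M)
        if info != 0:
            res = np.linalg.norm(Kff @ uf - rhs) / max(np.linalg.norm(rhs), 1e-300)
            raise SolverError(f"CG did not converge (info={info}, relative residual {res:.2e})")
    u[free] = uf
    return u


@dataclass
class UnitLoadCase:
    """One solved canonical load case rescaled to a unit load.

    ``sed`` is the per-voxel strain energy density (MPa) on the original
    mask grid after rescaling the solution so the distal reaction equals
    1 N (C/SX/SY) or 1 Nmm (MZ/BX/BY).  ``reaction`` is the raw reaction
    magnitude before rescaling and ``lam`` = 1/reaction the displacement
    rescale factor (SED scales with lam^2).
    """

    direction: str
    sed: np.ndarray
    reaction: float
    lam: float
    force: np.ndarray  # raw distal reaction force, N
    moment: np.ndarray  # raw distal reaction moment about the reference point, Nmm
    spacing: float
    energy: float = 0.0  # total strain energy at unit load, N mm
    proximal_force: np.ndarray | None = None  # raw reaction on the fixed face, N

    @property
    def is_moment(self) -> bool:
        return self.direction in MOMENT_DIRECTIONS


def _prescribed_displacement(
    direction: str, coords: np.ndarray, ref: np.ndarray, L: float,
    strain: float, rotation_deg: float,
) -> np.ndarray:
    """Distal-face nodal displacement (n, 3) for one canonical case."""
    n = coords.shape[0]
    u = np.zeros((n, 3))
    if direction == "C":
        u[:, 2] = -strain * L
    elif direction == "SX":
        u[:, 0] = strain * L
    elif direction == "SY":
        u[:, 1] = strain * L
    elif direction in MOMENT_DIRECTIONS:
        axis = {"MZ": np.array([0.0, 0.0, 1.0]),
                "BX": np.array([1.0, 0.0, 0.0]),
                "BY": np.array([0.0, 1.0, 0.0])}[direction]
        theta = np.deg2rad(rotation_deg)
        u[:] = theta * np.cross(axis, coords - ref)
    else:
        raise ValueError(f"unknown load direction {direction!r}")
    return u


def solve_case(
    mesh: VoxelMesh,
    direction: str,
    strain: float = 0.01,
    rotation_deg: float = 1.0,
    solver: str = "auto",
    tol: float = 1e-8,
    platen_layers: int = 0,
) -> UnitLoadCase:
    """Solve one canonical displacement load case and rescale to unit load.

    The proximal face is fully fixed and the distal face fully prescribed
    (bonded platens): an axial/transverse translation of ``strain`` times
    the axial length for force cases, or a ``rotation_deg`` small-rotation
    displacement u = theta x (p - c) about the reference point c for
    moment cases.  Per-element SED is evaluated at the centroid; the
    distal reaction wrench sets the rescale factor lambda = 1/|reaction|
    (displacements scale with lambda, SED with lambda^2), so the returned
    field is per 1 N or per 1 Nmm.

    ``platen_layers`` > 0 extends each platen's rigid prescription to
    that many node layers, making the solid end plates of a phantom move
    rigidly with the platen; their DOFs then drop out of the system
    (they are load-transfer plumbing, not structure).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown load direction {direction!r}; expected one of {DIRECTIONS}")
    sys = _fe_system(mesh)
    coords = sys["coords"]
    ref = mesh.reference_point
    L = mesh.axial_length

    pl = int(platen_layers)
    kz, nz = sys["kz"], sys["nz"]
    prox = np.flatnonzero(kz <= pl)
    dist = np.flatnonzero(kz >= nz - pl)
    u_dist = _prescribed_displacement(direction, coords[dist], ref, L, strain, rotation_deg)
    pres = np.concatenate([_node_dofs(prox), _node_dofs(dist)])
    u_pres = np.concatenate([np.zeros(3 * prox.size), u_dist.ravel()])
    u = _solve_constrained(sys, u_pres, pres, solver, tol)

    # Reaction wrench on the distal face.
    R = (sys["K"] @ u).reshape(-1, 3)
    F = R[dist].sum(axis=0)
    Fp = R[prox].sum(axis=0)
    M = np.cross(coords[dist] - ref, R[dist]).sum(axis=0)
    mag = {
        "C": abs(F[2]), "SX": abs(F[0]), "SY": abs(F[1]),
        "MZ": abs(M[2]), "BX": abs(M[0]), "BY": abs(M[1]),
    }[direction]
    if mag <= 0:
        raise SolverError(f"zero reaction for case {direction}; system ill-posed")
    lam = 1.0 / mag

    # Centroid strains -> SED per element, rescaled to the unit load.
    B0 = _centroid_b(mesh.spacing)
    ue = u[sys["edofs"]]  # (ne, 24)
    eps = ue @ B0.T
    D1 = elasticity_matrix(1.0, mesh.poisson)
    sigma = (eps @ D1.T) * mesh.modulus[:, None]
    sed = 0.5 * np.einsum("ij,ij->i", eps, sigma)
    sed = np.maximum(sed, 0.0) * lam**2
    energy = 0.5 * float(u @ (sys["K"] @ u)) * lam**2

    return UnitLoadCase(
        direction=direction,
        sed=mesh.element_field(sed),
        reaction=float(mag),
        lam=float(lam),
        force=F,
        moment=M,
        spacing=mesh.spacing,
        energy=energy,
        proximal_force=Fp,
    )


@dataclass
class UnitLoadSet:
    """The six unit-load SED fields of one geometry, in canonical order."""

    cases: dict[str, UnitLoadCase]
    spacing: float
    reference_point: np.ndarray
    bounding_box: np.ndarray  # (3,) bone bounding-box extents, mm

    def __getitem__(self, direction: str) -> UnitLoadCase:
        return self.cases[direction]

    def __contains__(self, direction: str) -> bool:
        return direction in self.cases

    @property
    def directions(self) -> tuple[str, ...]:
        return tuple(d for d in DIRECTIONS if d in self.cases)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.cases.values())).sed.shape

    def fields(self) -> np.ndarray:
        """Stack of SED fields, shape (6, nx, ny, nz), canonical order.
        Missing directions are zero fields."""
        out = np.zeros((len(DIRECTIONS),) + self.grid_shape)
        for i, d in enumerate(DIRECTIONS):
            if d in self.cases:
                out[i] = self.cases[d].sed
        return out

    def sed_matrix(self, voxels: np.ndarray, dilated: bool = False) -> np.ndarray:
        """Per-voxel unit SEDs, shape (n, 6).

        With ``dilated`` each field is first passed through a one-voxel
        von Neumann maximum filter so that voxels just outside the bone
        (newly formed bone) pick up the signal of the adjacent surface.
        """
        idx = tuple(np.asarray(voxels).T)
        out = np.zeros((len(voxels), len(DIRECTIONS)))
        foot = ndi.generate_binary_structure(3, 1)
        for i, d in enumerate(DIRECTIONS):
            if d not in self.cases:
                continue
            f = self.cases[d].sed
            if dilated:
                f = ndi.maximum_filter(f, footprint=foot, mode="constant", cval=0.0)
            out[:, i] = f[idx]
        return out


def solve_unit_loads(
    mesh: VoxelMesh,
    directions: tuple[str, ...] = DIRECTIONS,
    strain: float = 0.01,
    rotation_deg: float = 1.0,
    solver: str = "auto",
    tol: float = 1e-8,
    platen_layers: int = 0,
) -> UnitLoadSet:
    """Solve the requested canonical cases on one mesh (shared factorisation)."""
    cases = {
        d: solve_case(mesh, d, strain, rotation_deg, solver, tol, platen_layers)
        for d in directions
    }
    bone_idx = mesh.elements[mesh.is_bone]
    extents = (bone_idx.max(axis=0) - bone_idx.min(axis=0) + 1).astype(float) * mesh.spacing
    return UnitLoadSet(
        cases=cases,
        spacing=mesh.spacing,
        reference_point=mesh.reference_point.copy(),
        bounding_box=extents,
    )


@dataclass
class CompoundLoad:
    """A voxelwise non-negative linear combination of unit SED fields.

    Superposing SED fields (rather than displacements) is the linear
    simplification used throughout the estimators: the compounded field is
    sum_i coefficient_i * U_i,unit(x)."""

    coefficients: np.ndarray  # (6,) in canonical DIRECTIONS order
    sed: np.ndarray

    @property
    def total(self) -> float:
        return float(self.coefficients.sum())


def superpose(unit_cases: UnitLoadSet, coefficients) -> CompoundLoad:
    """Form the compounded SED field sum_i c_i * U_i,unit.

    ``coefficients`` is a length-6 sequence in canonical order or a
    mapping from direction name to coefficient; all entries must be >= 0.
    """
    c = _as_coefficients(coefficients)
    if np.any(c < 0):
        raise ValueError("coefficients must be non-negative")
    fields = unit_cases.fields()
    sed = np.einsum("i,ixyz->xyz", c, fields)
    return CompoundLoad(coefficients=c, sed=sed)


def scenario_load(name: str) -> np.ndarray:
    """Coefficient vector of a named loading scenario (canonical order)."""
    try:
        return np.array(SCENARIOS[name], dtype=np.float64)
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}") from None


def _as_coefficients(c) -> np.ndarray:
    if isinstance(c, dict):
        unknown = set(c) - set(DIRECTIONS)
        if unknown:
            raise ValueError(f"unknown directions {sorted(unknown)}")
        return np.array([float(c.get(d, 0.0)) for d in DIRECTIONS])
    arr = np.asarray(c, dtype=np.float64)
    if arr.shape != (len(DIRECTIONS),):
        raise ValueError(f"expected {len(DIRECTIONS)} coefficients, got shape {arr.shape}")
    return arr
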
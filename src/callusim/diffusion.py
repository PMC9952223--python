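"""Trilinear hexahedral finite elements for Fick's second law, dc/dt = D lap(c).

The weak form on the voxel mesh gives, per element, a consistent mass matrix
Me and a diffusion (stiffness) matrix Ne, both integrated exactly by 2x2x2
Gauss quadrature (the integrands are at most quadratic per direction).  After
assembly the evolution M dc/dt = f - N c is advanced by a first-order implicit
scheme:

    (M/dt + N) c_{t+dt} = f + (M/dt) c_t

with essential (Dirichlet) conditions enforced by exact row/column elimination
and right-hand-side correction.  The remaining boundary is natural (zero
flux), so f = 0 and no surface terms appear.

Concentrations are used dimensionlessly: the growth law normalizes each
species by its maximum c_max (alpha = c_MSC/c_max, beta = c_cho/c_max).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import AssemblyError, SolverError
from .lattice import CORNER_OFFSETS, VoxelModel
from .units import convert_diffusivity  # noqa: F401  (re-exported; see __all__)

__all__ = [
    "ElementMatrices",
    "element_matrices",
    "BoundarySpec",
    "GlobalSystem",
    "assemble",
    "step",
    "ConcentrationFields",
    "convert_diffusivity",
]

_GAUSS_1D = (-1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0))
#: reference corner signs (+-1) in VTK order
_SIGNS = 2.0 * CORNER_OFFSETS.astype(float) - 1.0


def _shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear shape functions and reference gradients at a point xi in [-1,1]^3."""
    terms = 1.0 + _SIGNS * xi  # (8, 3)
    N = np.prod(terms, axis=1) / 8.0
    dN = np.empty((8, 3))
    for a in range(3):
        other = [b for b in range(3) if b != a]
        dN[:, a] = _SIGNS[:, a] * terms[:, other[0]] * terms[:, other[1]] / 8.0
    return N, dN


@lru_cache(maxsize=None)
def _unit_matrices(L: float) -> tuple[np.ndarray, np.ndarray]:
    """(Me, Ne/D) for a cube of side L, by full 2x2x2 Gauss quadrature."""
    Me = np.zeros((8, 8))
    Ke = np.zeros((8, 8))
    detJ = (L / 2.0) ** 3
    for gx in _GAUSS_1D:
        for gy in _GAUSS_1D:
            for gz in _GAUSS_1D:
                N, dN = _shape(np.array([gx, gy, gz]))
                grad = dN * (2.0 / L)  # physical gradients
                Me += np.outer(N, N) * detJ
                Ke += grad @ grad.T * detJ
    return Me, Ke


@dataclass(frozen=True)
class ElementMatrices:
    """Elemental mass/diffusion matrices and boundary-flux load (zero here)."""

    Me: np.ndarray
    Ne: np.ndarray
    fe: np.ndarray


def element_matrices(L: float, D: float) -> ElementMatrices:
    """Exact elemental matrices for a cubic trilinear hexahedron.

    Me entries integrate products of shape functions over the cube (so they sum
    to the element volume L^3); Ne is D times the gradient-product integrals
    and has zero row sums (a constant field diffuses nowhere).
    """
    if L <= 0:
        raise ValueError(f"element edge length must be > 0, got {L}")
    if D < 0:
        raise ValueError(f"diffusivity must be >= 0, got {D}")
    Me, Ke = _unit_matrices(float(L))
    return ElementMatrices(Me=Me.copy(), Ne=D * Ke, fe=np.zeros(8))


@dataclass
class BoundarySpec:
    """Essential (Dirichlet) conditions for both cell species.

    ``bone_regions`` mode prescribes dimensionless concentrations on every
    node of the live (non-inert) high-source elements — trabecular, marrow
    and periosteum, the cell reservoirs — at ``c_high``; a node touching both
    a high and a low region takes the high value.  Cortical bone is
    comparatively acellular: by default it stays a plain diffusive medium
    (its low diffusivity emerges from the material table), because clamping
    it at a fixed sub-threshold value would make the whole region an
    infinite sink that can starve thin gap regions forever.  Set
    ``prescribe_low=True`` to pin cortical nodes at ``c_low`` instead.
    Everything else — the outer callus surface in particular — is a natural
    zero-flux boundary.  ``end_faces`` mode restricts the material split to
    the two end cross-sections of the section.  ``scale`` multiplies the
    prescribed values: it is the single calibration constant of the model,
    the ratio of the prescribed boundary concentration to the normalizing
    maximum.
    """

    c_high: float = 1.0
    c_low: float = 0.3
    scale: float = 1.0
    mode: str = "bone_regions"
    prescribe_low: bool = False
    high_materials: tuple[str, ...] = ("trabecular", "marrow", "periosteum")
    low_materials: tuple[str, ...] = ("cortical",)

    def __post_init__(self) -> None:
        if not 0 <= self.c_low <= self.c_high:
            raise ValueError("require 0 <= c_low <= c_high")
        if self.scale <= 0:
            raise ValueError("boundary scale must be > 0")
        if self.mode not in ("bone_regions", "end_faces"):
            raise ValueError(f"unknown boundary mode {self.mode!r}")

    def dirichlet_map(self, model: VoxelModel) -> dict[int, float]:
        """node id -> prescribed dimensionless value for ``model``."""
        high = set(self.high_materials)
        low = set(self.low_materials) if (self.prescribe_low or self.mode == "end_faces") else set()
        if self.mode == "end_faces":
            ks = [s[2] for s in model.elem_sites]
            kmin, kmax = min(ks), max(ks)
        values: dict[int, float] = {}
        for eid in range(model.n_elements):
            mat = model.elem_material[eid]
            if model.elem_inert[eid] or (mat not in high and mat not in low):
                continue
            if self.mode == "end_faces" and model.elem_sites[eid][2] not in (kmin, kmax):
                continue
            v = self.c_high if mat in high else self.c_low
            nodes = model.conn[eid]
            if self.mode == "end_faces":
                k_edge = model.elem_sites[eid][2]
                k_node = kmin if k_edge == kmin else kmax + 1
                nodes = [n for n in nodes if model.node_sites[n][2] == k_node]
            for n in nodes:
                values[n] = max(values.get(n, 0.0), v)
        return {n: v * self.scale for n, v in values.items()}


@dataclass
class GlobalSystem:
    """Assembled global system with Dirichlet bookkeeping.

    M and N are indexed by equation number; ``node_ids`` maps equations back to
    mesh node ids (nail-only and inert-only nodes carry no equation).
    """

    M: sp.csr_matrix
    N: sp.csr_matrix
    f: np.ndarray
    node_ids: np.ndarray
    dof_of_node: dict[int, int]
    dirichlet_dofs: np.ndarray
    dirichlet_values: np.ndarray
    free_dofs: np.ndarray
    _reduced: dict = field(default_factory=dict, repr=False)

    @property
    def n_dofs(self) -> int:
        return len(self.node_ids)


def assemble(
    model: VoxelModel,
    materials: dict,
    bc: BoundarySpec | None = None,
    dirichlet: dict[int, float] | None = None,
    skip_fixed_elements: bool = True,
) -> GlobalSystem:
    """Assemble global M, N, f on the diffusive part of the voxel mesh.

    Nail and inert elements are excluded from the diffusive domain.  Dirichlet
    values come from ``bc`` (a BoundarySpec) and/or an explicit node -> value
    map (the explicit map wins on conflict).  Elements whose 8 nodes are all
    constrained contribute only to eliminated equations and are skipped by
    default; pass ``skip_fixed_elements=False`` to keep their entries.
    """
    unknown = [m for m in set(model.elem_material) if m not in materials]
    if unknown:
        raise AssemblyError(f"element materials not in table: {sorted(unknown)}")
    diffusive = np.fromiter(
        (
            materials[m].diffusive and not inert
            for m, inert in zip(model.elem_material, model.elem_inert)
        ),
        bool,
        count=model.n_elements,
    )
    if not diffusive.any():
        raise AssemblyError("no diffusive elements (empty diffusive domain)")

    conn = model.conn_arr[diffusive]
    node_ids = np.unique(conn)
    dof_of_node = {int(n): i for i, n in enumerate(node_ids)}
    values: dict[int, float] = {}
    if bc is not None:
        values.update(bc.dirichlet_map(model))
    if dirichlet:
        values.update({int(k): float(v) for k, v in dirichlet.items()})
    for n in values:
        if n not in dof_of_node:
            raise AssemblyError(
                f"Dirichlet requested on node {n} outside the diffusive domain"
            )

    D = np.fromiter(
        (materials[m].D for m in model.elem_material), float, count=model.n_elements
    )[diffusive]
    econn = np.vectorize(dof_of_node.__getitem__, otypes=[np.int64])(conn)

    if skip_fixed_elements and values:
        fixed = np.zeros(len(node_ids), dtype=bool)
        fixed[[dof_of_node[n] for n in values]] = True
        keep = ~fixed[econn].all(axis=1)
        econn_k, D_k = econn[keep], D[keep]
    else:
        econn_k, D_k = econn, D

    n = len(node_ids)
    Me, Ke = _unit_matrices(float(model.lattice.L))
    rows = np.repeat(econn_k, 8, axis=1).ravel()
    cols = np.tile(econn_k, (1, 8)).ravel()
    m_data = np.tile(Me.ravel(), len(econn_k))
    n_data = (D_k[:, None] * Ke.ravel()[None, :]).ravel()
    M = sp.coo_matrix((m_data, (rows, cols)), shape=(n, n)).tocsr()
    N = sp.coo_matrix((n_data, (rows, cols)), shape=(n, n)).tocsr()

    dir_dofs = np.array(sorted(dof_of_node[k] for k in values), dtype=np.int64)
    dir_nodes = node_ids[dir_dofs] if len(dir_dofs) else np.array([], dtype=np.int64)
    dir_vals = np.array([values[int(k)] for k in dir_nodes], dtype=float)
    free = np.setdiff1d(np.arange(n), dir_dofs, assume_unique=True)
    return GlobalSystem(
        M=M,
        N=N,
        f=np.zeros(n),
        node_ids=node_ids,
        dof_of_node=dof_of_node,
        dirichlet_dofs=dir_dofs,
        dirichlet_values=dir_vals,
        free_dofs=free,
    )


def _reduced_system(system: GlobalSystem, dt: float):
    """Cache the constrained operator (M/dt + N) restricted to free equations."""
    cached = system._reduced.get(dt)
    if cached is not None:
        return cached
    A = (system.M / dt + system.N).tocsr()
    free, cons = system.free_dofs, system.dirichlet_dofs
    A_free_rows = A[free]
    A_ff = A_free_rows[:, free].tocsr()
    A_fc = A_free_rows[:, cons].tocsr()
    diag = A_ff.diagonal()
    precond = spla.LinearOperator(A_ff.shape, matvec=lambda x: x / diag)
    lu = spla.splu(A_ff.tocsc()) if A_ff.shape[0] <= 4000 else None
    system._reduced[dt] = (A_ff, A_fc, precond, lu)
    return system._reduced[dt]


def step(
    system: GlobalSystem,
    c: np.ndarray,
    dt: float,
    rtol: float = 1e-10,
    maxiter: int = 2000,
) -> np.ndarray:
    """Advance one species by one implicit time step of length ``dt`` (days).

    ``c`` is the full per-node array (indexed by mesh node id); nodes outside
    the diffusive domain are untouched.  Dirichlet nodes carry exactly their
    prescribed values on return.  Small systems are solved by sparse LU,
    larger ones by preconditioned conjugate gradients warm-started from c_t;
    failure to reach the requested relative residual raises SolverError.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    ca = c[system.node_ids].astype(float)
    ca[system.dirichlet_dofs] = system.dirichlet_values
    free = system.free_dofs
    out = c.copy()
    if len(free) == 0:
        out[system.node_ids] = ca
        return out
    b = system.f + (system.M @ ca) / dt
    A_ff, A_fc, precond, lu = _reduced_system(system, dt)
    rhs = b[free]
    if len(system.dirichlet_dofs):
        rhs = rhs - A_fc @ system.dirichlet_values
    if lu is not None:
        x = lu.solve(rhs)
    else:
        x, info = spla.cg(
            A_ff, rhs, x0=ca[free], rtol=rtol, maxiter=maxiter, M=precond
        )
        if info != 0:
            raise SolverError(f"CG failed to converge (info={info})")
    resid = np.linalg.norm(A_ff @ x - rhs)
    if resid > max(rtol * np.linalg.norm(rhs), 1e2 * rtol):
        raise SolverError(f"linear solve residual {resid:.3e} above tolerance")
    ca[free] = x
    if not np.all(np.isfinite(ca)):
        raise SolverError("non-finite concentrations after implicit step")
    out[system.node_ids] = ca
    return out


class ConcentrationFields:
    """Per-species nodal concentration arrays with normalization maxima.

    Species keys are ``msc`` (alpha after normalization) and ``chondrocyte``
    (beta).  Arrays grow with the mesh; new nodes enter at zero until the
    spawning code initializes them.
    """

    SPECIES = ("msc", "chondrocyte")

    def __init__(self, n_nodes: int, c_max: dict[str, float] | None = None):
        self.c = {s: np.zeros(n_nodes) for s in self.SPECIES}
        self.c_max = dict(c_max) if c_max else {s: 1.0 for s in self.SPECIES}

    def ensure_size(self, n_nodes: int) -> None:
        for s, arr in self.c.items():
            if len(arr) < n_nodes:
                self.c[s] = np.concatenate([arr, np.zeros(n_nodes - len(arr))])

    def normalized(self, species: str) -> np.ndarray:
        return self.c[species] / self.c_max[species]

    def apply_dirichlet(self, values: dict[int, float]) -> None:
        if not values:
            return
        idx = np.fromiter(values.keys(), dtype=np.int64, count=len(values))
        val = np.fromiter(values.values(), dtype=float, count=len(values))
        for s in self.SPECIES:
            self.c[s][idx] = val

    def copy(self) -> "ConcentrationFields":
        other = ConcentrationFields(0, self.c_max)
        other.c = {s: a.copy() for s, a in self.c.items()}
        return other
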
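"""Voxel lattice data model and idealized fractured-diaphysis generators.

The growing mesh lives on an integer lattice of cubic voxels with edge length
``L``.  An element is identified by the integer triple of its minimum corner;
its 8 nodes are the corners of that unit cube in the standard VTK hexahedron
ordering.  All node identity is keyed by integer lattice triples, so node
deduplication during mesh growth is exact (no floating-point tolerance).

Idealized geometries (concentric cylinders along z: nail core, marrow annulus,
cortical annulus, one-voxel periosteal shell) stand in for patient-specific
voxelized bone; fracture cutters remove bone elements whose centroid falls
between two analytic surfaces, after which the remaining bone is relabelled
into fragments by 6-connected components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, IntegrityError
from .units import convert_diffusivity

__all__ = [
    "CORNER_OFFSETS",
    "DIRECTIONS",
    "FACE_CORNERS",
    "VoxelLattice",
    "Material",
    "default_materials",
    "VoxelModel",
    "CentroidIndex",
    "FractureSpec",
    "generate_diaphysis",
    "apply_fracture",
    "build_centroid_index",
]

#: VTK_HEXAHEDRON corner ordering relative to the element's minimum corner.
CORNER_OFFSETS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (1, 1, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (1, 1, 1),
        (0, 1, 1),
    ],
    dtype=np.int64,
)

#: The six axial growth directions, in canonical order.
DIRECTIONS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)


def _face_corners() -> dict[tuple[int, int, int], np.ndarray]:
    faces = {}
    for d in DIRECTIONS:
        axis = int(np.flatnonzero(d)[0])
        want = 1 if d[axis] > 0 else 0
        faces[tuple(int(x) for x in d)] = np.flatnonzero(
            CORNER_OFFSETS[:, axis] == want
        )
    return faces


#: direction triple -> local indices (into the 8-node connectivity) of the
#: 4 corners lying on that face.
FACE_CORNERS = _face_corners()


@dataclass(frozen=True)
class VoxelLattice:
    """Cubic voxel lattice: edge length ``L`` (mm), integer extents, origin (mm)."""

    extents: tuple[int, int, int]
    L: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise GeometryError(f"voxel edge length must be > 0, got {self.L}")
        if len(self.extents) != 3 or any(int(n) < 1 for n in self.extents):
            raise GeometryError(f"lattice extents must all be >= 1, got {self.extents}")
        object.__setattr__(self, "extents", tuple(int(n) for n in self.extents))

    @property
    def nx(self) -> int:
        return self.extents[0]

    @property
    def ny(self) -> int:
        return self.extents[1]

    @property
    def nz(self) -> int:
        return self.extents[2]

    def in_bounds(self, site) -> bool:
        i, j, k = site
        return 0 <= i < self.nx and 0 <= j < self.ny and 0 <= k < self.nz

    def node_coords(self, triples) -> np.ndarray:
        """Physical coordinates (mm) of node lattice triples."""
        return np.asarray(self.origin) + self.L * np.asarray(triples, dtype=float)

    def centroids(self, sites) -> np.ndarray:
        """Physical centroid coordinates (mm) of element sites."""
        return np.asarray(self.origin) + self.L * (
            np.asarray(sites, dtype=float) + 0.5
        )


@dataclass(frozen=True)
class Material:
    """A voxel material: diffusivity (mm^2/day) and growth/diffusion flags."""

    name: str
    D: float
    diffusive: bool = True
    growable: bool = True

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"material {self.name!r}: D must be >= 0")
        if not self.diffusive and self.D != 0:
            raise ValueError(f"material {self.name!r}: non-diffusive implies D = 0")


def default_materials() -> dict[str, Material]:
    """Default material table.

    Diffusion coefficients are the literature values for cell migration in the
    different bone regions (given in um^2/min and converted to mm^2/day):
    marrow and periosteum 100, callus 50, cortical bone 1.  Trabecular bone
    shares the high marrow/periosteal diffusivity.  The nail is impermeable
    and can never serve as a growth substrate.
    """
    c = convert_diffusivity
    return {
        "nail": Material("nail", 0.0, diffusive=False, growable=False),
        "cortical": Material("cortical", c(1.0)),
        "trabecular": Material("trabecular", c(100.0)),
        "marrow": Material("marrow", c(100.0)),
        "periosteum": Material("periosteum", c(100.0)),
        "callus": Material("callus", c(50.0)),
    }


class VoxelModel:
    """Growing hexahedral voxel mesh.

    Nodes are keyed by integer lattice triples; elements by their minimum-corner
    site.  Connectivity follows the VTK hexahedron corner order.  Appending an
    element reuses any node that already exists at a corner position, which
    keeps face-adjacent elements sharing exactly 4 node ids (watertightness).
    """

    def __init__(self, lattice: VoxelLattice):
        self.lattice = lattice
        self._node_id: dict[tuple[int, int, int], int] = {}
        self.node_sites: list[tuple[int, int, int]] = []
        self.elem_sites: list[tuple[int, int, int]] = []
        self.elem_material: list[str] = []
        self.elem_fragment: list[int] = []
        self.elem_inert: list[bool] = []
        self.conn: list[tuple[int, ...]] = []
        self._site_eid: dict[tuple[int, int, int], int] = {}
        self.metadata: dict = {}
        self._cache: dict[str, np.ndarray] = {}

    # -- bookkeeping ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_sites)

    @property
    def n_elements(self) -> int:
        return len(self.elem_sites)

    def node_at(self, triple) -> int | None:
        return self._node_id.get(tuple(int(x) for x in triple))

    def element_at(self, site) -> int | None:
        return self._site_eid.get(tuple(int(x) for x in site))

    def _array(self, key: str, source, dtype) -> np.ndarray:
        arr = self._cache.get(key)
        if arr is None or len(arr) != len(source):
            arr = np.asarray(source, dtype=dtype)
            self._cache[key] = arr
        return arr

    @property
    def sites_arr(self) -> np.ndarray:
        return self._array("sites", self.elem_sites, np.int64)

    @property
    def conn_arr(self) -> np.ndarray:
        return self._array("conn", self.conn, np.int64)

    @property
    def node_sites_arr(self) -> np.ndarray:
        return self._array("nodes", self.node_sites, np.int64)

    @property
    def fragment_arr(self) -> np.ndarray:
        return self._array("fragment", self.elem_fragment, np.int64)

    @property
    def inert_arr(self) -> np.ndarray:
        return self._array("inert", self.elem_inert, bool)

    def material_mask(self, names) -> np.ndarray:
        names = set(names)
        return np.fromiter(
            (m in names for m in self.elem_material), bool, count=self.n_elements
        )

    # -- mutation ------------------------------------------------------------

    def add_element(
        self,
        site,
        material: str,
        fragment_id: int = 0,
        inert: bool = False,
    ) -> tuple[int, list[int], list[int]]:
        """Append one element; returns (eid, created node ids, reused node ids)."""
        site = tuple(int(x) for x in site)
        if not self.lattice.in_bounds(site):
            raise GeometryError(f"element site {site} outside lattice {self.lattice.extents}")
        if site in self._site_eid:
            raise IntegrityError(f"duplicate element site {site}")
        created: list[int] = []
        reused: list[int] = []
        conn = []
        for off in CORNER_OFFSETS:
            triple = (site[0] + int(off[0]), site[1] + int(off[1]), site[2] + int(off[2]))
            nid = self._node_id.get(triple)
            if nid is None:
                nid = len(self.node_sites)
                self._node_id[triple] = nid
                self.node_sites.append(triple)
                created.append(nid)
            else:
                reused.append(nid)
            conn.append(nid)
        eid = len(self.elem_sites)
        self.elem_sites.append(site)
        self.elem_material.append(material)
        self.elem_fragment.append(int(fragment_id))
        self.elem_inert.append(bool(inert))
        self.conn.append(tuple(conn))
        self._site_eid[site] = eid
        self._cache.clear()
        return eid, created, reused

    def copy(self) -> "VoxelModel":
        other = VoxelModel(self.lattice)
        other._node_id = dict(self._node_id)
        other.node_sites = list(self.node_sites)
        other.elem_sites = list(self.elem_sites)
        other.elem_material = list(self.elem_material)
        other.elem_fragment = list(self.elem_fragment)
        other.elem_inert = list(self.elem_inert)
        other.conn = list(self.conn)
        other._site_eid = dict(self._site_eid)
        other.metadata = dict(self.metadata)
        return other

    # -- derived grids -------------------------------------------------------

    def occupancy_grid(self, include=None) -> np.ndarray:
        """Boolean occupancy over lattice sites; ``include`` filters by a mask."""
        grid = np.zeros(self.lattice.extents, dtype=bool)
        sites = self.sites_arr
        if sites.size == 0:
            return grid
        if include is not None:
            sites = sites[include]
        grid[sites[:, 0], sites[:, 1], sites[:, 2]] = True
        return grid

    def fragment_ids(self) -> list[int]:
        return sorted({f for f in self.elem_fragment if f > 0})


class CentroidIndex:
    """Occupancy map lattice site -> element id, bijective with the element table.

    Backed by a dense int32 grid (-1 marks unoccupied) so free-face detection
    and overlap checks vectorize over the whole element table.
    """

    UNOCCUPIED = -1

    def __init__(self, lattice: VoxelLattice):
        self.lattice = lattice
        self.grid = np.full(lattice.extents, self.UNOCCUPIED, dtype=np.int32)
        self._count = 0

    @classmethod
    def from_model(cls, model: VoxelModel) -> "CentroidIndex":
        index = cls(model.lattice)
        sites = model.sites_arr
        if sites.size:
            if len(np.unique(sites, axis=0)) != len(sites):
                raise IntegrityError("duplicate element sites in model")
            index.grid[sites[:, 0], sites[:, 1], sites[:, 2]] = np.arange(
                len(sites), dtype=np.int32
            )
            index._count = len(sites)
        return index

    def __len__(self) -> int:
        return self._count

    def get(self, site) -> int | None:
        """Element id at ``site``, or None if the site is unoccupied."""
        i, j, k = (int(x) for x in site)
        if not self.lattice.in_bounds((i, j, k)):
            raise IndexError(f"site {(i, j, k)} outside lattice")
        eid = int(self.grid[i, j, k])
        return None if eid == self.UNOCCUPIED else eid

    def add(self, site, eid: int) -> None:
        i, j, k = (int(x) for x in site)
        if self.grid[i, j, k] != self.UNOCCUPIED:
            raise IntegrityError(f"site {(i, j, k)} already occupied")
        self.grid[i, j, k] = eid
        self._count += 1

    @property
    def occupied(self) -> np.ndarray:
        return self.grid != self.UNOCCUPIED


def build_centroid_index(model: VoxelModel) -> CentroidIndex:
    """Build the site -> element occupancy index from the element table."""
    return CentroidIndex.from_model(model)


@dataclass(frozen=True)
class FractureSpec:
    """Analytic fracture cutter.

    kind:
        ``transverse`` (two horizontal planes ``gap`` apart), ``oblique``
        (planes tilted ``slope_deg`` about the y axis), ``comminuted``
        (a transverse cut plus an oblique cut leaving an inert intermediate
        wedge) or ``spiral`` (helicoidal band).
    gap:
        axial gap height in mm (0 = degenerate no-op cut).
    center_z:
        axial position of the cut centre; defaults to mid-section.
    comminuted_offset:
        half-distance (mm) between the transverse and oblique cut centres of a
        comminuted fracture.
    """

    kind: str
    gap: float
    slope_deg: float = 0.0
    center_z: float | None = None
    comminuted_offset: float = 3.5

    def __post_init__(self) -> None:
        if self.kind not in ("transverse", "oblique", "comminuted", "spiral"):
            raise GeometryError(f"unknown fracture kind {self.kind!r}")
        if self.gap < 0:
            raise GeometryError("fracture gap must be >= 0")
        if not 0 <= self.slope_deg < 90:
            raise GeometryError("slope_deg must lie in [0, 90)")


def _axis_center(model: VoxelModel) -> tuple[float, float]:
    meta = model.metadata.get("geometry", {})
    if "axis_center" in meta:
        return meta["axis_center"]
    lat = model.lattice
    return (
        lat.origin[0] + lat.nx * lat.L / 2.0,
        lat.origin[1] + lat.ny * lat.L / 2.0,
    )


def _axial_span(model: VoxelModel) -> tuple[float, float]:
    meta = model.metadata.get("geometry", {})
    if "length" in meta:
        return (model.lattice.origin[2], model.lattice.origin[2] + meta["length"])
    sites = model.sites_arr
    z = model.lattice.centroids(sites)[:, 2]
    return (float(z.min()) - model.lattice.L / 2, float(z.max()) + model.lattice.L / 2)


def removal_mask(model: VoxelModel, spec: FractureSpec) -> np.ndarray:
    """Brute-force evaluation of the cutting surfaces at every element centroid.

    Returns a boolean mask over the element table: True where a *bone* element
    (anything but the nail) lies between the fracture surfaces.  Cuts are
    half-open (lower surface inclusive) so a gap of n*L removes exactly n
    whole voxel layers in the transverse case.
    """
    lat = model.lattice
    cx, cy = _axis_center(model)
    cent = lat.centroids(model.sites_arr)
    x, y, z = cent[:, 0], cent[:, 1], cent[:, 2]
    z0, z1 = _axial_span(model)
    zc = spec.center_z if spec.center_z is not None else (z0 + z1) / 2.0
    g = spec.gap
    tan = math.tan(math.radians(spec.slope_deg))

    def band(surface_z):
        return (z >= surface_z - g / 2.0) & (z < surface_z + g / 2.0)

    if spec.kind == "transverse":
        cut = band(np.full_like(z, zc))
    elif spec.kind == "oblique":
        cut = band(zc + tan * (x - cx))
    elif spec.kind == "comminuted":
        cut = band(np.full_like(z, zc - spec.comminuted_offset)) | band(
            zc + spec.comminuted_offset + tan * (x - cx)
        )
    elif spec.kind == "spiral":
        theta = np.arctan2(y - cy, x - cx)
        rise = tan * np.hypot(x - cx, y - cy)
        cut = band(zc + rise * theta / math.pi)
    else:  # pragma: no cover - guarded by FractureSpec
        raise GeometryError(spec.kind)
    bone = ~model.material_mask(["nail"])
    return cut & bone


def _relabel_fragments(model: VoxelModel, inert_middle: bool) -> None:
    """Assign fragment ids to bone elements by 6-connected components.

    The component containing the lowest-z bone element becomes fragment 1, the
    one containing the highest-z element fragment 2; any remaining components
    are numbered 3+ in decreasing size and, for comminuted fractures, flagged
    inert.
    """
    bone_mask = ~model.material_mask(["nail", "callus"])
    grid = model.occupancy_grid(include=bone_mask)
    labels, n = ndimage.label(grid, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        raise GeometryError("fracture removed all bone")
    sites = model.sites_arr[bone_mask]
    eids = np.flatnonzero(bone_mask)
    lab = labels[sites[:, 0], sites[:, 1], sites[:, 2]]
    kmin = sites[np.argmin(sites[:, 2]), :]
    kmax = sites[np.argmax(sites[:, 2]), :]
    low_lab = int(labels[tuple(kmin)])
    high_lab = int(labels[tuple(kmax)])
    mapping = {low_lab: 1}
    if high_lab != low_lab:
        mapping[high_lab] = 2
    rest = [l for l in range(1, n + 1) if l not in mapping]
    rest.sort(key=lambda l: -int(np.sum(lab == l)))
    for i, l in enumerate(rest):
        mapping[l] = 3 + i if high_lab != low_lab else 2 + i
    for eid, l in zip(eids, lab):
        fid = mapping[int(l)]
        model.elem_fragment[eid] = fid
        if inert_middle and fid >= 3:
            model.elem_inert[eid] = True
    model._cache.clear()


def generate_diaphysis(
    lattice: VoxelLattice,
    outer_radius: float = 15.0,
    cortical_thickness: float = 5.0,
    periosteum_thickness: float | None = None,
    nail_diameter: float = 11.0,
    length: float = 43.0,
    growth_margin: float = 4.0,
) -> VoxelModel:
    """Generate an idealized nailed diaphyseal section as concentric cylinders.

    Along z (the bone axis): nail core, marrow annulus, cortical annulus and a
    periosteal shell (one voxel thick by default).  An element belongs to a
    region iff its centroid satisfies the region's radial inequality.  Free
    growth space of at least ``growth_margin`` mm must surround the bone.
    """
    L = lattice.L
    peri = L if periosteum_thickness is None else periosteum_thickness
    if outer_radius <= 0:
        raise GeometryError("outer_radius must be > 0 (empty bone)")
    if cortical_thickness <= 0 or peri <= 0:
        raise GeometryError("cortical and periosteal thickness must be > 0")
    canal_radius = outer_radius - peri - cortical_thickness
    nail_radius = nail_diameter / 2.0
    if nail_diameter > 0 and not nail_radius < canal_radius:
        raise GeometryError(
            f"nail radius {nail_radius} must be < inner cortical radius {canal_radius}"
        )
    if length > lattice.nz * L + 1e-9:
        raise GeometryError(f"length {length} exceeds lattice span {lattice.nz * L}")
    cx = lattice.origin[0] + lattice.nx * L / 2.0
    cy = lattice.origin[1] + lattice.ny * L / 2.0
    half_x = lattice.nx * L / 2.0
    half_y = lattice.ny * L / 2.0
    if outer_radius + growth_margin > min(half_x, half_y) + 1e-9:
        raise GeometryError(
            "lattice too small: outer_radius + growth_margin "
            f"({outer_radius + growth_margin} mm) exceeds the lateral half-extent "
            f"({min(half_x, half_y)} mm)"
        )

    model = VoxelModel(lattice)
    nk = int(round(length / L))
    ii, jj, kk = np.meshgrid(
        np.arange(lattice.nx), np.arange(lattice.ny), np.arange(nk), indexing="ij"
    )
    sites = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    cent = lattice.centroids(sites)
    r = np.hypot(cent[:, 0] - cx, cent[:, 1] - cy)
    material = np.full(len(sites), "", dtype=object)
    material[r <= outer_radius] = "periosteum"
    material[r <= outer_radius - peri] = "cortical"
    material[r <= canal_radius] = "marrow"
    if nail_diameter > 0:
        material[r <= nail_radius] = "nail"
    keep = material != ""
    order = np.lexsort((sites[keep, 0], sites[keep, 1], sites[keep, 2]))
    for idx in np.flatnonzero(keep)[order]:
        mat = material[idx]
        model.add_element(
            sites[idx], mat, fragment_id=0 if mat == "nail" else 1, inert=False
        )
    model.metadata["geometry"] = {
        "axis_center": (cx, cy),
        "outer_radius": outer_radius,
        "cortical_thickness": cortical_thickness,
        "periosteum_thickness": peri,
        "nail_diameter": nail_diameter,
        "length": length,
        "growth_margin": growth_margin,
    }
    return model


def apply_fracture(model: VoxelModel, spec: FractureSpec) -> VoxelModel:
    """Remove bone elements between the fracture surfaces and relabel fragments.

    The nail is never removed.  For comminuted fractures the intermediate
    wedge between the two cuts keeps its elements, receives its own fragment
    id and is flagged inert.  Metadata records the removed sites and the axial
    extent of the gap for the growth region of interest.
    """
    if spec.gap == 0:
        return model.copy()
    mask = removal_mask(model, spec)
    if not mask.any():
        raise GeometryError("fracture surfaces remove no bone elements")
    lat = model.lattice
    removed = model.sites_arr[mask]
    z = lat.centroids(removed)[:, 2]
    z0, z1 = _axial_span(model)
    if z.min() - lat.L / 2 <= z0 + 1e-9 or z.max() + lat.L / 2 >= z1 - 1e-9:
        raise GeometryError("fracture surfaces reach the ends of the model span")

    out = VoxelModel(lat)
    out.metadata = dict(model.metadata)
    for eid in np.flatnonzero(~mask):
        out.add_element(
            model.elem_sites[eid],
            model.elem_material[eid],
            model.elem_fragment[eid],
            model.elem_inert[eid],
        )
    _relabel_fragments(out, inert_middle=spec.kind == "comminuted")
    if spec.kind == "comminuted" and not any(
        f >= 3 for f in out.elem_fragment
    ):
        raise GeometryError("comminuted spec produced no intermediate fragment")
    out.metadata["fracture"] = spec
    out.metadata["removed_sites"] = [tuple(int(x) for x in s) for s in removed]
    out.metadata["gap_zrange"] = (
        float(z.min() - lat.L / 2),
        float(z.max() + lat.L / 2),
    )
    return out
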
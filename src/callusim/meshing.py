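"""Free mesh growth: creating callus elements on spawn requests.

A spawn request places a new element centroid at distance L from the parent's
centroid, in one of the six axial directions.  The path vectors — the fixed
centroid-to-corner offsets of the reference cube — locate the 8 corner
positions of the new element; a corner reuses an existing node when one sits
at that lattice position and creates one otherwise, which deduplicates nodes
exactly and keeps the growing mesh watertight.  Occupied target sites are
rejected (overlap check, covering both the parent fragment and the opposite
one), so element count and node count only ever increase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .lattice import CORNER_OFFSETS, FACE_CORNERS, CentroidIndex, VoxelModel

__all__ = ["SpawnRequest", "SpawnReport", "path_vectors", "spawn_element", "init_new_nodes"]


@dataclass(frozen=True)
class SpawnRequest:
    """Grow from ``parent`` through the face pointing along ``direction``."""

    parent: int
    direction: tuple[int, int, int]


@dataclass
class SpawnReport:
    """Outcome of one spawn request."""

    parent: int
    direction: tuple[int, int, int]
    target_site: tuple[int, int, int]
    element: int | None = None
    created_nodes: list[int] = field(default_factory=list)
    reused_nodes: list[int] = field(default_factory=list)
    parent_face_nodes: tuple[int, ...] = ()
    rejected: bool = False


def path_vectors(L: float = 1.0) -> np.ndarray:
    """Centroid-to-corner offset vectors of the reference cube, in canonical
    corner order; components are all +-L/2 and the offsets sum to zero."""
    return (CORNER_OFFSETS.astype(float) - 0.5) * L


def spawn_element(
    model: VoxelModel, index: CentroidIndex, req: SpawnRequest
) -> SpawnReport:
    """Create one callus element at the site adjacent to the parent face.

    If the target site is already occupied (bone, nail, callus or a fragment)
    the request is rejected and the model is unchanged.  Otherwise the new
    element's corners reuse existing node ids where lattice positions
    coincide and create nodes elsewhere; the centroid index is updated and
    the report lists reused vs created ids plus the parent face's node ids
    (used to seed concentrations).
    """
    psite = model.elem_sites[req.parent]
    d = req.direction
    target = (psite[0] + d[0], psite[1] + d[1], psite[2] + d[2])
    if not model.lattice.in_bounds(target):
        raise GeometryError(f"spawn target {target} outside lattice")
    face = tuple(int(model.conn[req.parent][i]) for i in FACE_CORNERS[d])
    report = SpawnReport(
        parent=req.parent, direction=d, target_site=target, parent_face_nodes=face
    )
    if index.get(target) is not None:
        report.rejected = True
        return report
    eid, created, reused = model.add_element(target, "callus", fragment_id=0, inert=False)
    index.add(target, eid)
    report.element = eid
    report.created_nodes = created
    report.reused_nodes = reused
    return report


def init_new_nodes(
    fields, report: SpawnReport, model: VoxelModel, mode: str = "parent_mean"
):
    """Initialize concentrations of nodes created by a successful spawn.

    ``parent_mean`` assigns each created node, per species, the mean of the
    parent face's 4 nodal values (smooth continuation); ``zero`` leaves the
    fresh tissue empty of cells so the growth front stays diffusion-limited.
    Reused nodes are untouched.  Returns the (mutated) fields.
    """
    if mode not in ("parent_mean", "zero"):
        raise ValueError(f"unknown init mode {mode!r}")
    if report.rejected or not report.created_nodes:
        return fields
    if max(report.parent_face_nodes) >= model.n_nodes:
        raise GeometryError("spawn report references unknown nodes")
    fields.ensure_size(model.n_nodes)
    idx = np.asarray(report.created_nodes)
    for s, arr in fields.c.items():
        arr[idx] = float(np.mean(arr[list(report.parent_face_nodes)])) if mode == "parent_mean" else 0.0
    return fields
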
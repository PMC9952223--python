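"""Growth triggering and the normalized sigmoid velocity law.

A face of the voxel mesh may sprout a new callus element when (i) it is free
(no element centroid at the neighbouring lattice site), (ii) it belongs to a
growable, non-inert, non-nail element inside the growth region of interest,
and (iii) the face-level dimensionless concentrations of both species reach
their trigger thresholds.  The face then accrues volume at

    v = v_max * phi(alpha, beta),
    phi(alpha, beta) = 4A / ([1 + e^{-a(alpha-alpha0)}][1 + e^{-b(beta-beta0)}]) + B

where phi is pinned to phi(alpha0, beta0) = 0 and phi(1, 1) = 1 by the
normalization constants

    k = 1 / ([1 + e^{-a(1-alpha0)}][1 + e^{-b(1-beta0)}]),
    A = 1 / (4k - 1),   B = -A.

The slope constants a and b summarize the levels of the chemical factors
(TNF-alpha, BMP-2) that modulate healing rate.  One new element represents
L^3 of tissue, so a face spawns once its accrued volume reaches L^3, keeping
the remainder; accruals persist if a face temporarily drops below threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import IntegrityError
from .lattice import DIRECTIONS, FACE_CORNERS, CentroidIndex, VoxelModel

__all__ = [
    "GrowthFunction",
    "normalize_sigmoid",
    "growth_velocity",
    "detect_free_faces",
    "eligible_candidates",
    "accrue_and_select",
    "GrowthCandidate",
]


@dataclass(frozen=True)
class GrowthFunction:
    """Normalized sigmoid growth-velocity law and its constants."""

    a: float
    b: float
    alpha0: float
    beta0: float
    v_max: float
    k: float
    A: float
    B: float

    def phi(self, alpha, beta):
        """Normalized sigmoid, with arguments above 1 clamped to 1."""
        al = np.minimum(np.asarray(alpha, dtype=float), 1.0)
        be = np.minimum(np.asarray(beta, dtype=float), 1.0)
        denom = (1.0 + np.exp(-self.a * (al - self.alpha0))) * (
            1.0 + np.exp(-self.b * (be - self.beta0))
        )
        out = 4.0 * self.A / denom + self.B
        return float(out) if np.isscalar(alpha) or np.ndim(alpha) == 0 else out


def normalize_sigmoid(
    a: float, b: float, alpha0: float, beta0: float, v_max: float = 5.0
) -> GrowthFunction:
    """Construct the growth function, fixing A and B so that the normalization
    contract phi(alpha0, beta0) = 0, phi(1, 1) = 1 holds exactly."""
    if a <= 0 or b <= 0:
        raise ValueError("slope constants a, b must be > 0")
    if not (0 < alpha0 < 1 and 0 < beta0 < 1):
        raise ValueError("thresholds alpha0, beta0 must lie in (0, 1)")
    if v_max <= 0:
        raise ValueError("v_max must be > 0")
    k = 1.0 / (
        (1.0 + math.exp(-a * (1.0 - alpha0))) * (1.0 + math.exp(-b * (1.0 - beta0)))
    )
    A = 1.0 / (4.0 * k - 1.0)
    return GrowthFunction(a=a, b=b, alpha0=alpha0, beta0=beta0, v_max=v_max, k=k, A=A, B=-A)


def growth_velocity(gf: GrowthFunction, alpha, beta):
    """Face growth velocity in mm^3/day.

    Zero below either trigger threshold, otherwise v_max * phi clipped to
    [0, v_max]; concentrations above 1 are clamped.  Negative concentrations
    are rejected.
    """
    al = np.asarray(alpha, dtype=float)
    be = np.asarray(beta, dtype=float)
    if np.any(al < 0) or np.any(be < 0):
        raise ValueError("concentrations must be >= 0")
    v = np.clip(gf.v_max * gf.phi(al, be), 0.0, gf.v_max)
    v = np.where((al < gf.alpha0) | (be < gf.beta0), 0.0, v)
    return float(v) if np.ndim(alpha) == 0 and np.ndim(beta) == 0 else v


@dataclass
class GrowthCandidate:
    """A free face above threshold, with its current growth velocity."""

    element: int
    direction: tuple[int, int, int]
    velocity: float


def detect_free_faces(
    model: VoxelModel,
    index: CentroidIndex,
    roi: tuple[float, float] | None = None,
) -> list[tuple[int, tuple[int, int, int]]]:
    """List (element, direction) pairs whose neighbouring lattice site is free.

    Checks the centroid index in each of the 6 axial directions; only
    growable, non-inert, non-nail elements whose centroid lies in the axial
    band ``roi`` (physical z range, inclusive) are examined, and directions
    leaving the lattice are never free.
    """
    if len(index) != model.n_elements:
        raise IntegrityError(
            f"stale centroid index: {len(index)} entries for "
            f"{model.n_elements} elements"
        )
    sites = model.sites_arr
    if sites.size == 0:
        return []
    eligible = ~model.inert_arr & model.material_mask(
        [m for m in set(model.elem_material) if m != "nail"]
    )
    if roi is not None:
        z = model.lattice.centroids(sites)[:, 2]
        eligible &= (z >= roi[0]) & (z <= roi[1])
    ext = np.array(model.lattice.extents)
    faces_e: list[np.ndarray] = []
    faces_d: list[np.ndarray] = []
    eids = np.flatnonzero(eligible)
    esites = sites[eids]
    for d_idx, d in enumerate(DIRECTIONS):
        nb = esites + d
        inside = np.all((nb >= 0) & (nb < ext), axis=1)
        free = np.zeros(len(eids), dtype=bool)
        ii = nb[inside]
        free[inside] = index.grid[ii[:, 0], ii[:, 1], ii[:, 2]] == CentroidIndex.UNOCCUPIED
        faces_e.append(eids[free])
        faces_d.append(np.full(free.sum(), d_idx))
    e = np.concatenate(faces_e)
    d = np.concatenate(faces_d)
    order = np.lexsort((d, e))
    return [(int(e[i]), tuple(int(x) for x in DIRECTIONS[d[i]])) for i in order]


def eligible_candidates(
    faces: list[tuple[int, tuple[int, int, int]]],
    fields,
    gf: GrowthFunction,
    model: VoxelModel,
    aggregation: str = "mean",
) -> list[GrowthCandidate]:
    """Filter free faces by the trigger thresholds and attach velocities.

    The face-level alpha and beta are the mean (or, optionally, the minimum)
    of the four face-node dimensionless concentrations per species; a face
    becomes a candidate iff alpha >= alpha0 and beta >= beta0.
    """
    if not faces:
        return []
    if aggregation not in ("mean", "min"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    conn = model.conn_arr
    eids = np.array([f[0] for f in faces])
    local = np.array([FACE_CORNERS[f[1]] for f in faces])
    nodes = conn[eids[:, None], local]
    for arr in fields.c.values():
        if nodes.max() >= len(arr):
            raise IntegrityError("concentration fields missing nodal values")
    agg = np.mean if aggregation == "mean" else np.min
    alpha = agg(fields.normalized("msc")[nodes], axis=1)
    beta = agg(fields.normalized("chondrocyte")[nodes], axis=1)
    ok = (alpha >= gf.alpha0) & (beta >= gf.beta0)
    vel = growth_velocity(gf, np.clip(alpha, 0.0, None), np.clip(beta, 0.0, None))
    return [
        GrowthCandidate(element=int(eids[i]), direction=faces[i][1], velocity=float(vel[i]))
        for i in np.flatnonzero(ok)
    ]


def accrue_and_select(
    candidates: list[GrowthCandidate],
    dt: float,
    accumulators: dict[tuple[int, tuple[int, int, int]], float],
    element_volume: float = 1.0,
) -> list[tuple[int, tuple[int, int, int]]]:
    """Advance per-face volume accrual and emit spawn requests.

    Each candidate's accumulator grows by velocity*dt (mm^3); a face that
    reaches the element volume emits one (element, direction) spawn request
    and keeps the remainder.  Accumulators of faces that are currently not
    candidates persist untouched (the concentration may come back).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    requests: list[tuple[int, tuple[int, int, int]]] = []
    for cand in candidates:
        key = (cand.element, cand.direction)
        acc = accumulators.get(key, 0.0) + cand.velocity * dt
        if acc >= element_volume:
            requests.append(key)
            acc -= element_volume
        accumulators[key] = acc
    return requests
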
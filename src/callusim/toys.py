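"""Deterministic toy models for tests and examples."""

from __future__ import annotations

from .lattice import VoxelLattice, VoxelModel


def bar_model(n: int, material: str = "cortical", L: float = 1.0) -> VoxelModel:
    """A 1 x 1 x n bar of one material along z (fragment 1)."""
    model = VoxelModel(VoxelLattice(extents=(1, 1, n), L=L))
    for k in range(n):
        model.add_element((0, 0, k), material, fragment_id=1)
    return model


def block_model(shape, material: str = "cortical", L: float = 1.0) -> VoxelModel:
    """A full nx x ny x nz block of one material (fragment 1)."""
    model = VoxelModel(VoxelLattice(extents=tuple(shape), L=L))
    for k in range(shape[2]):
        for j in range(shape[1]):
            for i in range(shape[0]):
                model.add_element((i, j, k), material, fragment_id=1)
    return model


def two_block_bar(
    block: int = 3, gap: int = 2, margin: int = 1, material: str = "trabecular"
) -> VoxelModel:
    """Two ``block``-cubed bone blocks separated by a ``gap``-voxel empty band.

    The blocks sit on the z axis with ``margin`` voxels of free growth space
    laterally; all bone carries the high-source material by default, so every
    fracture-facing node is a prescribed-concentration source.  Metadata marks
    the removed gap sites and axial range, mirroring a fractured model.
    """
    n_lat = block + 2 * margin
    nz = 2 * block + gap
    model = VoxelModel(VoxelLattice(extents=(n_lat, n_lat, nz)))
    lo = margin
    hi = margin + block
    removed = []
    for k in range(nz):
        frag = 1 if k < block else 2
        in_bone = k < block or k >= block + gap
        for j in range(lo, hi):
            for i in range(lo, hi):
                if in_bone:
                    model.add_element((i, j, k), material, fragment_id=frag)
                else:
                    removed.append((i, j, k))
    model.metadata["gap_zrange"] = (float(block), float(block + gap))
    model.metadata["removed_sites"] = removed
    model.metadata["geometry"] = {"length": float(nz)}
    return model
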
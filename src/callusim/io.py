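"""Readers, writers and configuration.

The single mesh interchange format is the legacy-ASCII VTK unstructured grid
(hexahedra with material / fragment / inert cell data and per-species point
data); labelled voxel volumes are imported from NIfTI or from a raw binary
array described by a small JSON header.  Configuration files are YAML or JSON
validated against a small schema with field-path error messages; diffusion
coefficients are accepted in um^2/min (the usual literature unit) and
converted to mm^2/day on load.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .diffusion import BoundarySpec, ConcentrationFields
from .errors import ConfigError, GeometryError, IntegrityError
from .growth import normalize_sigmoid
from .lattice import (
    FractureSpec,
    Material,
    VoxelLattice,
    VoxelModel,
    default_materials,
)
from .simulation import GeometrySpec, SimulationConfig, preset_config
from .units import convert_diffusivity

__all__ = [
    "export_vtk",
    "read_vtk",
    "import_labeled_volume",
    "load_config",
    "build_config",
    "dump_config",
    "write_manifest",
]

_VTK_HEX = 12


def export_vtk(
    model: VoxelModel, path, fields: ConcentrationFields | None = None
) -> Path:
    """Write the model (and optional nodal concentrations) as legacy-ASCII VTK.

    Cell data: integer material code (the code -> name map is embedded in the
    title line), fragment_id and inert flag.  Point data: one scalar array per
    species.  The encoding is lossless for a read-back round trip.
    """
    path = Path(path)
    mat_names = sorted(set(model.elem_material))
    code = {m: i for i, m in enumerate(mat_names)}
    pts = model.lattice.node_coords(model.node_sites_arr)
    if fields is not None and any(len(a) != model.n_nodes for a in fields.c.values()):
        raise ValueError("fields do not cover all model nodes")
    lines = [
        "# vtk DataFile Version 3.0",
        "callusim materials=" + json.dumps(mat_names),
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {model.n_nodes} double",
    ]
    lines += [" ".join(repr(float(v)) for v in p) for p in pts]
    lines.append(f"CELLS {model.n_elements} {model.n_elements * 9}")
    lines += ["8 " + " ".join(str(n) for n in c) for c in model.conn]
    lines.append(f"CELL_TYPES {model.n_elements}")
    lines += [str(_VTK_HEX)] * model.n_elements
    lines.append(f"CELL_DATA {model.n_elements}")
    for name, data in (
        ("material", [code[m] for m in model.elem_material]),
        ("fragment_id", model.elem_fragment),
        ("inert", [int(x) for x in model.elem_inert]),
    ):
        lines.append(f"SCALARS {name} int 1")
        lines.append("LOOKUP_TABLE default")
        lines += [str(int(v)) for v in data]
    if fields is not None:
        lines.append(f"POINT_DATA {model.n_nodes}")
        for s, arr in fields.c.items():
            lines.append(f"SCALARS {s} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [repr(float(v)) for v in arr]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk(path) -> dict:
    """Read back a file written by :func:`export_vtk`.

    Returns a dict with points (n,3), cells (ne,8), cell_types, cell_data and
    point_data arrays, plus the material code -> name list.
    """
    tokens_by_line = Path(path).read_text().splitlines()
    it = iter(tokens_by_line)
    out: dict = {"cell_data": {}, "point_data": {}}
    line = next(it)
    title = next(it)
    if "materials=" in title:
        out["materials"] = json.loads(title.split("materials=", 1)[1])
    for line in it:
        parts = line.split()
        if not parts:
            continue
        key = parts[0]
        if key == "POINTS":
            n = int(parts[1])
            out["points"] = np.array(
                [[float(x) for x in next(it).split()] for _ in range(n)]
            )
        elif key == "CELLS":
            ne = int(parts[1])
            out["cells"] = np.array(
                [[int(x) for x in next(it).split()[1:]] for _ in range(ne)]
            )
        elif key == "CELL_TYPES":
            ne = int(parts[1])
            out["cell_types"] = np.array([int(next(it)) for _ in range(ne)])
        elif key in ("CELL_DATA", "POINT_DATA"):
            section = "cell_data" if key == "CELL_DATA" else "point_data"
            count = int(parts[1])
            current = section, count
        elif key == "SCALARS":
            name, dtype = parts[1], parts[2]
            next(it)  # LOOKUP_TABLE
            section, count = current
            cast = int if dtype == "int" else float
            out[section][name] = np.array([cast(next(it)) for _ in range(count)])
    return out


def import_labeled_volume(
    path,
    label_map: dict[int, str],
    materials: dict[str, Material] | None = None,
    L: float | None = None,
    origin=(0.0, 0.0, 0.0),
) -> VoxelModel:
    """Build a voxel model from a labelled 3-D volume.

    Accepts a NIfTI file (``.nii`` / ``.nii.gz``; the voxel spacing must be
    cubic and supplies L) or a JSON header describing a raw binary array
    (keys: dtype, extents, L, raw, optional origin).  Every nonzero voxel
    becomes one element with the material mapped from its label; fragment ids
    are assigned by 6-connected components of the bone materials.
    """
    materials = materials or default_materials()
    path = Path(path)
    if path.suffix == ".json":
        header = json.loads(path.read_text())
        extents = tuple(int(n) for n in header["extents"])
        data = np.fromfile(
            path.parent / header["raw"], dtype=np.dtype(header["dtype"])
        ).reshape(extents)
        L = float(header.get("L", L or 1.0))
        origin = tuple(header.get("origin", origin))
    else:
        import nibabel as nib

        img = nib.load(str(path))
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        if not np.allclose(zooms, zooms[0], rtol=1e-6):
            raise GeometryError(
                f"anisotropic voxel spacing {tuple(zooms)}: only cubic voxels supported"
            )
        L = float(zooms[0])
        data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise GeometryError("label volume must be integer-valued")
        data = data.astype(np.int64)
    present = set(np.unique(data).tolist()) - {0}
    missing = sorted(present - set(label_map))
    if missing:
        raise GeometryError(f"labels without material mapping: {missing}")

    lattice = VoxelLattice(extents=data.shape, L=L, origin=tuple(origin))
    model = VoxelModel(lattice)
    nz = np.argwhere(data != 0)
    order = np.lexsort((nz[:, 0], nz[:, 1], nz[:, 2]))
    for site in nz[order]:
        model.add_element(site, label_map[int(data[tuple(site)])])
    bone_mask = ~model.material_mask(["nail", "callus"])
    if bone_mask.any():
        grid = model.occupancy_grid(include=bone_mask)
        labels, _ = ndimage.label(grid, structure=ndimage.generate_binary_structure(3, 1))
        for eid in np.flatnonzero(bone_mask):
            model.elem_fragment[eid] = int(labels[model.elem_sites[eid]])
        model._cache.clear()
    return model


# ---------------------------------------------------------------------------
# configuration

_SCHEMA = {
    "preset": None,
    "geometry": {
        "L",
        "outer_radius",
        "cortical_thickness",
        "periosteum_thickness",
        "nail_diameter",
        "length",
        "growth_margin",
    },
    "fracture": {"kind", "gap", "slope_deg", "center_z", "comminuted_offset"},
    "materials": None,  # free-form name -> {D_um2_min | D_mm2_day, diffusive, growable}
    "boundary": {"c_high", "c_low", "scale", "mode", "prescribe_low"},
    "growth": {"a", "b", "alpha0", "beta0", "v_max"},
    "simulation": {
        "dt",
        "horizon",
        "roi_halfwidth",
        "aggregation",
        "new_node_init",
        "stop_at_closure",
        "record_interval",
    },
}
_MATERIAL_KEYS = {"D_um2_min", "D_mm2_day", "diffusive", "growable"}


def _reject_unknown(data: dict, allowed, where: str) -> None:
    unknown = sorted(set(data) - set(allowed))
    if unknown:
        raise ConfigError(f"{where}: unknown keys {unknown}")


def build_config(data: dict, preset: str | None = None) -> SimulationConfig:
    """Validate a raw config mapping and build a SimulationConfig.

    Unspecified sections fall back to the preset (if given) or to the package
    defaults; unknown keys anywhere are rejected with the offending path.
    """
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root: expected a mapping")
    _reject_unknown(data, _SCHEMA, "config")
    preset = data.get("preset", preset)
    config = preset_config(preset) if preset else SimulationConfig(geometry=GeometrySpec())

    if "geometry" in data:
        _reject_unknown(data["geometry"], _SCHEMA["geometry"], "geometry")
        config.geometry = GeometrySpec(**{**asdict(config.geometry), **data["geometry"]})
    if "fracture" in data:
        _reject_unknown(data["fracture"], _SCHEMA["fracture"], "fracture")
        base = asdict(config.fracture) if config.fracture else {}
        try:
            config.fracture = FractureSpec(**{**base, **data["fracture"]})
        except (GeometryError, TypeError) as exc:
            raise ConfigError(f"fracture: {exc}") from exc
    if "materials" in data:
        table = dict(config.materials)
        for name, spec in data["materials"].items():
            _reject_unknown(spec, _MATERIAL_KEYS, f"materials.{name}")
            if "D_um2_min" in spec and "D_mm2_day" in spec:
                raise ConfigError(f"materials.{name}: give D in exactly one unit")
            base = table.get(name)
            D = (
                convert_diffusivity(spec["D_um2_min"])
                if "D_um2_min" in spec
                else spec.get("D_mm2_day", base.D if base else 0.0)
            )
            try:
                table[name] = Material(
                    name,
                    D,
                    diffusive=spec.get("diffusive", base.diffusive if base else True),
                    growable=spec.get("growable", base.growable if base else True),
                )
            except ValueError as exc:
                raise ConfigError(f"materials.{name}: {exc}") from exc
        config.materials = table
    if "boundary" in data:
        _reject_unknown(data["boundary"], _SCHEMA["boundary"], "boundary")
        base = {
            "c_high": config.boundary.c_high,
            "c_low": config.boundary.c_low,
            "scale": config.boundary.scale,
            "mode": config.boundary.mode,
            "prescribe_low": config.boundary.prescribe_low,
        }
        try:
            config.boundary = BoundarySpec(**{**base, **data["boundary"]})
        except ValueError as exc:
            raise ConfigError(f"boundary: {exc}") from exc
    if "growth" in data:
        _reject_unknown(data["growth"], _SCHEMA["growth"], "growth")
        g = config.growth
        params = {
            "a": g.a,
            "b": g.b,
            "alpha0": g.alpha0,
            "beta0": g.beta0,
            "v_max": g.v_max,
        }
        params.update(data["growth"])
        try:
            config.growth = normalize_sigmoid(**params)
        except ValueError as exc:
            raise ConfigError(f"growth: {exc}") from exc
    if "simulation" in data:
        _reject_unknown(data["simulation"], _SCHEMA["simulation"], "simulation")
        for key, value in data["simulation"].items():
            setattr(config, key, value)
    try:
        config.validate()
    except ValueError as exc:
        raise ConfigError(f"simulation: {exc}") from exc
    return config


def load_config(path, preset: str | None = None) -> SimulationConfig:
    """Load and validate a YAML or JSON configuration file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON ({exc})") from exc
    return build_config(data, preset=preset)


def dump_config(config: SimulationConfig) -> dict:
    """Plain-data echo of a config, suitable for YAML round-tripping."""
    g = config.growth
    out = {
        "geometry": asdict(config.geometry) if config.geometry else None,
        "fracture": asdict(config.fracture) if config.fracture else None,
        "materials": {
            name: {
                "D_mm2_day": m.D,
                "diffusive": m.diffusive,
                "growable": m.growable,
            }
            for name, m in sorted(config.materials.items())
        },
        "boundary": {
            "c_high": config.boundary.c_high,
            "c_low": config.boundary.c_low,
            "scale": config.boundary.scale,
            "mode": config.boundary.mode,
            "prescribe_low": config.boundary.prescribe_low,
        },
        "growth": {"a": g.a, "b": g.b, "alpha0": g.alpha0, "beta0": g.beta0, "v_max": g.v_max},
        "simulation": {
            "dt": config.dt,
            "horizon": config.horizon,
            "roi_halfwidth": config.roi_halfwidth,
            "aggregation": config.aggregation,
            "new_node_init": config.new_node_init,
            "stop_at_closure": config.stop_at_closure,
            "record_interval": config.record_interval,
        },
    }
    return out


def write_manifest(path, config: SimulationConfig, events: dict, files) -> Path:
    """JSON run manifest: config echo, version, events, file checksums."""
    from . import __version__

    path = Path(path)
    inventory = []
    for f in files:
        f = Path(f)
        if not f.exists():
            raise IntegrityError(f"manifest references missing file {f}")
        inventory.append(
            {
                "path": f.name,
                "bytes": f.stat().st_size,
                "sha256": hashlib.sha256(f.read_bytes()).hexdigest(),
            }
        )
    manifest = {
        "package": "callusim",
        "version": __version__,
        "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dump_config(config),
        "events": {k: v for k, v in events.items() if not k.endswith("sites")},
        "files": inventory,
    }
    path.write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    return path
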
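# callusim

Free-growth voxel finite-element simulation of **initial fracture-callus
formation** in long bones treated with an intramedullary nail.

After a femoral shaft fracture is stabilised with a nail, healing begins
with a soft primary callus that grows from the periosteal and endosteal
surfaces, surrounds the nail, bridges the fragments and finally seals the
interfragmentary gap.  `callusim` simulates that first stage on a mesh that
is *not* pre-defined: the callus domain is built element by element as the
simulation runs, so the final callus shape is an outcome, not an input, and
arbitrary fracture patterns (transverse, oblique, comminuted with isolated
fragments, spiral) can be handled by the same machinery.

Each time step couples three phases on the current voxel mesh:

1. **Cell diffusion** — mesenchymal stem cell and chondrocyte
   concentrations obey Fick's second law, `dc/dt = D lap(c)`, solved with
   trilinear hexahedral finite elements (consistent mass matrix) and an
   implicit scheme `(M/dt + N) c_{t+dt} = f + (M/dt) c_t`.  Bone regions
   act as prescribed-concentration reservoirs; all free surfaces are
   zero-flux.
2. **Growth triggering** — element faces bordering empty lattice sites
   (free faces, found via a centroid occupancy index) become growth
   candidates when both normalised concentrations exceed their thresholds
   (alpha >= alpha0, beta >= beta0); candidates accrue volume at
   `v = v_max * phi(alpha, beta)` where `phi` is a normalised sigmoid with
   `phi(alpha0, beta0) = 0` and `phi(1,1) = 1`, its slopes a, b standing in
   for the biochemical environment (TNF-alpha, BMP-2).
3. **Mesh growth** — a face that has accrued one element volume spawns a
   new callus cube at distance L, reusing coincident nodes exactly (lattice
   keyed, watertight by construction) and rejecting occupied targets.

Per-day records classify the gap as **open → bridged** (a 6-connected
path of non-nail tissue joins the fragments) **→ closed** (the removed
cavity is filled and no interior void remains).

See `docs/methods.md` for the full model description, parameter table,
boundary-condition rationale, calibration protocol and known limitations.

## Worked example

```python
import callusim as cs

config = cs.preset_config("transverse")   # 43 mm section, 6 mm gap, 11 mm nail
result = cs.run_simulation(config, progress=True)
df, events = cs.summarize(result)
print(events)
print(df.tail(3)[["day", "callus_volume_mm3", "bridged", "closed", "voids"]])
```

prints (abridged; the run takes about a minute):

```
day    1.0  callus   1416  voids     0  bridged=False closed=False
day    2.0  callus   1656  voids     0  bridged=False closed=False
...
day   13.0  callus   5976  voids     0  bridged=True closed=False
...
day   36.0  callus  11704  voids     0  bridged=True closed=True
{'first_bridging_day': 13.0, 'closure_day': 36.0}
     day  callus_volume_mm3  bridged  closed  voids
35  35.0            11528.0     True   False     16
36  36.0            11704.0     True    True      0
37  37.0            11880.0     True    True      0
```

Reading: callus growth becomes appreciable within the first days, the
fragments are first bridged (through the periosteal callus sleeve that
surrounds the nail) on day 13, and on day 36 the last interior voids of the
6 mm gap are filled — the fracture is closed.  `result.model` is the final
grown mesh and `result.fields` the nodal concentrations; both can be
written as VTK for inspection:

```python
from callusim.io import export_vtk
export_vtk(result.model, "final.vtk", result.fields)
```

The same is available from the shell:

```
callus-sim run --preset transverse --out out/ --vtk-every 5
callus-sim generate --preset comminuted --out comminuted.vtk
```

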
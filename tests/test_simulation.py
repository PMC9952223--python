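"""Three-phase loop, bridging/closure metrics and the toy-scenario oracle."""

import numpy as np
import pytest

from callusim import (
    ConcentrationFields,
    SimulationConfig,
    VoxelLattice,
    VoxelModel,
    bridged,
    closure_state,
    gap_roi_mask,
    normalize_sigmoid,
    run_simulation,
    summarize,
)
from callusim.toys import two_block_bar


def toy_config(**overrides) -> SimulationConfig:
    config = SimulationConfig(model=two_block_bar(), horizon=30.0, roi_halfwidth=5.0)
    for k, v in overrides.items():
        setattr(config, k, v)
    return config


class TestBridged:
    def test_initial_fracture_not_bridged(self):
        model = two_block_bar()
        assert not bridged(model, 1, 2)

    def test_single_callus_column_bridges(self):
        model = two_block_bar()
        for k in (3, 4):
            model.add_element((2, 2, k), "callus")
        assert bridged(model, 1, 2)

    def test_nail_does_not_bridge(self):
        model = two_block_bar()
        for k in (3, 4):
            model.add_element((2, 2, k), "nail")
        assert not bridged(model, 1, 2)

    def test_inert_fragment_is_substrate_but_needs_both_links(self):
        """Callus touching only fragment A and the inert middle piece does not
        bridge A to B; it does once callus also reaches B."""
        model = VoxelModel(VoxelLattice(extents=(3, 3, 9)))
        model.add_element((1, 1, 0), "cortical", fragment_id=1)
        model.add_element((1, 1, 4), "cortical", fragment_id=3, inert=True)
        model.add_element((1, 1, 8), "cortical", fragment_id=2)
        model.add_element((1, 1, 1), "callus")
        model.add_element((1, 1, 2), "callus")
        model.add_element((1, 1, 3), "callus")
        assert not bridged(model, 1, 2)
        model.add_element((1, 1, 5), "callus")
        model.add_element((1, 1, 6), "callus")
        model.add_element((1, 1, 7), "callus")
        assert bridged(model, 1, 2)

    def test_unknown_fragment_rejected(self):
        with pytest.raises(ValueError):
            bridged(two_block_bar(), 1, 9)


class TestClosureState:
    def test_empty_gap_is_open(self):
        model = two_block_bar()
        roi = gap_roi_mask(model, 2.0)
        state, voids = closure_state(model, roi)
        assert state == "open"
        assert voids == 0  # gap still connected to the exterior

    def test_filled_roi_is_closed(self):
        model = two_block_bar()
        for s in list(model.metadata["removed_sites"]):
            model.add_element(s, "callus")
        # fill the whole lateral band so no empty roi site remains enclosed
        roi = gap_roi_mask(model, 2.0)
        state, voids = closure_state(model, roi)
        assert state == "closed"
        assert voids == 0

    def test_hollow_shell_is_bridged_not_closed(self):
        """A hollow callus shell spanning the gap bridges the fragments but
        traps an interior void."""
        model = VoxelModel(VoxelLattice(extents=(7, 7, 7)))
        model.add_element((3, 3, 0), "cortical", fragment_id=1)
        model.add_element((3, 3, 6), "cortical", fragment_id=2)
        for i in range(2, 5):
            for j in range(2, 5):
                for k in range(2, 5):
                    if (i, j, k) != (3, 3, 3):
                        model.add_element((i, j, k), "callus")
        model.add_element((3, 3, 1), "callus")
        model.add_element((3, 3, 5), "callus")
        model.metadata["removed_sites"] = []
        roi = np.zeros((7, 7, 7), dtype=bool)
        roi[1:6, 1:6, 1:6] = True
        state, voids = closure_state(model, roi)
        assert state == "bridged"
        assert voids == 1

    def test_empty_roi_rejected(self):
        model = two_block_bar()
        with pytest.raises(Exception):
            closure_state(model, np.zeros(model.lattice.extents, dtype=bool))


class TestRunSimulation:
    def test_zero_horizon_only_day_zero_record(self):
        config = toy_config(horizon=0.0)
        result = run_simulation(config)
        assert list(result.records["day"]) == [0.0]
        assert result.model.n_elements == two_block_bar().n_elements

    def test_thresholds_above_sources_grow_nothing(self):
        from callusim import BoundarySpec

        config = toy_config(
            growth=normalize_sigmoid(5.0, 5.0, 0.99, 0.99, 5.0),
            boundary=BoundarySpec(scale=0.5),
            horizon=5.0,
        )
        result = run_simulation(config)
        assert (result.records["callus_volume_mm3"] == 0).all()

    def test_gap_fills_and_closes(self):
        result = run_simulation(toy_config())
        assert result.closure_day is not None
        assert result.bridging_day is not None
        assert result.bridging_day <= result.closure_day
        empty_removed = [
            s
            for s in result.model.metadata["removed_sites"]
            if result.model.element_at(s) is None
        ]
        assert empty_removed == []

    def test_determinism_bit_identical(self):
        a = run_simulation(toy_config())
        b = run_simulation(toy_config())
        assert a.records.equals(b.records)
        assert a.model.elem_sites == b.model.elem_sites
        for s in a.fields.SPECIES:
            assert np.array_equal(a.fields.c[s], b.fields.c[s])

    def test_monotone_volume_and_closure(self):
        result = run_simulation(toy_config(stop_at_closure=False, horizon=20.0))
        vol = result.records["callus_volume_mm3"].to_numpy()
        assert (np.diff(vol) >= 0).all()
        closed = result.records["closed"].to_numpy()
        if closed.any():
            first = int(np.argmax(closed))
            assert closed[first:].all()

    def test_dt_robustness_of_closure_day(self):
        """Halving the time step moves the toy closure day by < 2 days."""
        coarse = run_simulation(toy_config(dt=0.25)).closure_day
        fine = run_simulation(toy_config(dt=0.125)).closure_day
        assert coarse is not None and fine is not None
        assert abs(coarse - fine) < 2.0

    def test_summarize_consistency(self):
        result = run_simulation(toy_config())
        df, events = summarize(result)
        assert events["closure_day"] == result.closure_day
        n_initial = two_block_bar().n_elements
        expect = (result.model.n_elements - n_initial) * 1.0
        assert df["callus_volume_mm3"].iloc[-1] == pytest.approx(expect)
        assert events["first_bridging_day"] <= events["closure_day"]


# ---------------------------------------------------------------------------
# independent hand-stepped trace of the three-phase loop on the toy scenario


def hand_stepped_closure_day(dt=0.25, horizon=30.0, halfwidth=5.0):
    """Dense, dictionary-based re-implementation of the loop semantics for
    the two-block bar, written independently of the package internals."""
    from callusim import default_materials, element_matrices

    gf = normalize_sigmoid(5.0, 5.0, 1 / 32, 1 / 16, 5.0)
    mats = default_materials()
    nx = ny = 5
    nz = 8
    # element bookkeeping: site -> material
    elems: dict[tuple, str] = {}
    removed = []
    for k in range(nz):
        for j in range(1, 4):
            for i in range(1, 4):
                if k < 3 or k >= 5:
                    elems[(i, j, k)] = "trabecular"
                else:
                    removed.append((i, j, k))
    frag_of = {s: (1 if s[2] < 3 else 2) for s in elems}
    corners = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
    face_ids = {
        (1, 0, 0): [1, 2, 6, 5], (-1, 0, 0): [0, 3, 7, 4],
        (0, 1, 0): [2, 3, 6, 7], (0, -1, 0): [0, 1, 4, 5],
        (0, 0, 1): [4, 5, 6, 7], (0, 0, -1): [0, 1, 2, 3],
    }
    dirs = list(face_ids)

    def elem_nodes(site):
        return [tuple(np.add(site, c)) for c in corners]

    conc = {}  # node triple -> value (single field; both species identical here)
    dirichlet = set()
    for s, m in elems.items():
        for p in elem_nodes(s):
            dirichlet.add(p)
            conc[p] = 1.0

    def in_bounds(s):
        return 0 <= s[0] < nx and 0 <= s[1] < ny and 0 <= s[2] < nz

    em = element_matrices(1.0, mats["callus"].D)
    acc: dict[tuple, float] = {}

    def diffuse():
        callus = [s for s, m in elems.items() if m == "callus"]
        if not callus:
            return
        nodes = sorted({p for s in callus for p in elem_nodes(s)})
        idx = {p: i for i, p in enumerate(nodes)}
        n = len(nodes)
        M = np.zeros((n, n))
        N = np.zeros((n, n))
        for s in callus:
            ids = [idx[p] for p in elem_nodes(s)]
            for a in range(8):
                for b in range(8):
                    M[ids[a], ids[b]] += em.Me[a, b]
                    N[ids[a], ids[b]] += em.Ne[a, b]
        c0 = np.array([conc.get(p, 0.0) for p in nodes])
        A = M / dt + N
        bvec = (M / dt) @ c0
        free = [i for i, p in enumerate(nodes) if p not in dirichlet]
        cons = [i for i, p in enumerate(nodes) if p in dirichlet]
        rhs = bvec[free] - A[np.ix_(free, cons)] @ c0[cons]
        x = np.linalg.solve(A[np.ix_(free, free)], rhs)
        for i, f in enumerate(free):
            conc[nodes[f]] = x[i]

    def closure():
        # bridged: BFS over non-nail elements
        seeds = [s for s in elems if frag_of.get(s) == 1]
        seen = set(seeds)
        queue = list(seeds)
        hit2 = False
        while queue:
            cur = queue.pop()
            if frag_of.get(cur) == 2:
                hit2 = True
            for d in dirs:
                nb = tuple(np.add(cur, d))
                if nb in elems and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        if not hit2:
            return False
        if any(s not in elems for s in removed):
            return False
        # voids: flood the empty space from the lattice boundary
        empty = {
            (i, j, k)
            for i in range(nx)
            for j in range(ny)
            for k in range(nz)
            if (i, j, k) not in elems
        }
        boundary = [
            s
            for s in empty
            if 0 in s or s[0] == nx - 1 or s[1] == ny - 1 or s[2] == nz - 1
        ]
        seen = set(boundary)
        queue = list(boundary)
        while queue:
            cur = queue.pop()
            for d in dirs:
                nb = tuple(np.add(cur, d))
                if nb in empty and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        roi_lo, roi_hi = 3 - halfwidth, 5 + halfwidth
        voids = [
            s for s in empty - seen if roi_lo <= s[2] + 0.5 <= roi_hi
        ]
        return not voids

    steps_per_day = int(round(1.0 / dt))
    for day in range(1, int(horizon) + 1):
        for _ in range(steps_per_day):
            diffuse()
            # trigger + accrual on free faces in the roi band
            requests = []
            for s, m in sorted(elems.items()):
                if m == "nail" or not (3 - halfwidth <= s[2] + 0.5 <= 5 + halfwidth):
                    continue
                for d in dirs:
                    nb = tuple(np.add(s, d))
                    if not in_bounds(nb) or nb in elems:
                        continue
                    nodes = elem_nodes(s)
                    face = [nodes[i] for i in face_ids[d]]
                    val = np.mean([conc.get(p, 0.0) for p in face])
                    if val >= gf.alpha0 and val >= gf.beta0:
                        v = gf.v_max * gf.phi(val, val)
                        key = (s, d)
                        acc[key] = acc.get(key, 0.0) + v * dt
                        if acc[key] >= 1.0:
                            requests.append(nb)
                            acc[key] -= 1.0
            for target in requests:
                if target not in elems:
                    elems[target] = "callus"
                    for p in elem_nodes(target):
                        conc.setdefault(p, 0.0)
        if closure():
            return float(day)
    return None


class TestToyClosureOracle:
    def test_closure_day_matches_hand_stepped_trace(self):
        """The packaged loop and an independent dense trace of the same
        three-phase rules close the two-block gap on the same day."""
        result = run_simulation(toy_config())
        expect = hand_stepped_closure_day()
        assert expect is not None
        assert result.closure_day == expect
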
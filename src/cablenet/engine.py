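"""The fixed-step integration loop on the flattened network.

Each step executes, in order: (1) event-driven delivery of spikes due in
(t, t+dt], (2) assembly of the implicit-Euler membrane system, (3) tree
Gaussian elimination (Hines solve), (4) state-variable update at end-of-step
voltages, (5) threshold detection.  Spike exchange between cell groups
happens every minimum-NetCon-delay interval.

The membrane equation per node i (backward Euler, one step dt):

    (cm_i/dt + sum_mech g + sum_adj g_axial) v_i^new
        - sum_adj g_axial v_adj^new
        = (cm_i/dt + sum_mech g) v_i - sum_mech i + injected

so the matrix has diagonal ``d``, one off-diagonal ``b = -g_axial`` per
non-root node, and is eliminated leaf-to-root in node-index order: because
``parent[i] < i`` everywhere, a single reverse sweep triangularizes the tree
with exactly the operation count of an unbranched cable of the same size.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    IntegrityError,
    ParameterError,
    SingularSystemError,
)
from .mechanisms import (
    ARTIFICIAL,
    GAP_SNAPSHOT,
    MechanismPool,
    get_mechanism,
    mechanism_id,
    netstim_events,
)
from .model import Model
from .network import (
    TIME_TOL,
    EventQueue,
    NetCon,
    PreSyn,
    compute_mindelay,
    derive_key,
    deliver_until,
    index_netcons_by_source,
    spike_exchange,
)

DEFAULT_DT = 0.025  # ms
DEFAULT_V_INIT = -65.0  # mV


# --------------------------------------------------------------------------
# Hines solver
# --------------------------------------------------------------------------

def _hines_sweep_py(d, b, rhs, parent, v):
    """Tree Gaussian elimination + back substitution; returns op count or -1.

    Reverse sweep i = n-1..1: p = parent[i], factor = b_i/d_i,
    d_p -= factor*b_i, rhs_p -= factor*rhs_i.  Then roots solve directly and
    the forward sweep substitutes v_i = (rhs_i - b_i*v_parent)/d_i.  The
    multiply/divide count is 5 per non-root node plus 1 per root — a
    function of size only, never of branching pattern.
    """
    n = d.shape[0]
    nops = 0
    for i in range(n - 1, 0, -1):
        p = parent[i]
        if p < 0:
            continue
        if d[i] == 0.0:
            return -1
        factor = b[i] / d[i]
        d[p] -= factor * b[i]
        rhs[p] -= factor * rhs[i]
        nops += 3
    for i in range(n):
        p = parent[i]
        if p < 0:
            if d[i] == 0.0:
                return -1
            v[i] = rhs[i] / d[i]
            nops += 1
        else:
            v[i] = (rhs[i] - b[i] * v[p]) / d[i]
            nops += 2
    return nops


_hines_sweep = _hines_sweep_py
try:  # optional acceleration; identical arithmetic order either way
    from numba import njit as _njit

    _hines_sweep = _njit(cache=True)(_hines_sweep_py)
except ImportError:  # pragma: no cover
    pass


def hines_solve(d, b, rhs, parent):
    """Solve the tree system in place; returns (v, op_count).

    ``d``/``b``/``rhs`` are consumed (overwritten); ``parent`` must satisfy
    parent[i] < i with -1 at roots.  A forest (multiple roots) is solved as
    independent trees in one sweep.
    """
    d = np.ascontiguousarray(d, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    rhs = np.ascontiguousarray(rhs, dtype=np.float64)
    parent = np.ascontiguousarray(parent, dtype=np.int64)
    v = np.empty_like(d)
    nops = _hines_sweep(d, b, rhs, parent, v)
    if nops < 0:
        raise SingularSystemError("zero pivot during tree elimination")
    return v, int(nops)


# --------------------------------------------------------------------------
# Simulation state
# --------------------------------------------------------------------------

@dataclass
class SolverArrays:
    v: np.ndarray    # mV
    d: np.ndarray    # uS + nF/ms
    b: np.ndarray    # uS (off-diagonal to parent, -g_axial)
    rhs: np.ndarray  # nA


class SimState:
    """Flattened, ready-to-step instantiation of a :class:`Model`.

    Construction flattens all cells into global node arrays, groups
    mechanism instances into one SoA pool per (cell group, mechanism type),
    resolves NetCons and PreSyns to integer handles, and initializes
    voltages and states (v = v_init everywhere, gating states at their
    steady state for that voltage).
    """

    def __init__(self, model: Model, dt: float = DEFAULT_DT,
                 v_init: float = DEFAULT_V_INIT, seed: int = 0,
                 n_groups: int | None = None):
        if dt <= 0:
            raise ParameterError("dt must be positive")
        self.model = model
        self.dt = float(dt)
        self.v_init = float(v_init)
        self.seed = int(seed)
        net = model.net
        if n_groups is not None:
            net.assign_groups(n_groups)
        self.n_groups = max(net.group_of_cell, default=0) + 1

        # ---- flatten topology ----
        n = net.n_nodes_total
        self.n_nodes = n
        self.parent = np.empty(n, dtype=np.int64)
        self.area = np.empty(n, dtype=np.float64)
        self.g_axial = np.empty(n, dtype=np.float64)
        self.cm_node = np.empty(n, dtype=np.float64)
        node_of = []
        for c, cell in enumerate(net.cells):
            off = int(net.node_offset[c])
            sl = slice(off, off + cell.n_nodes)
            p = cell.parent.copy()
            self.parent[sl] = np.where(p < 0, -1, p + off)
            self.area[sl] = cell.area
            self.g_axial[sl] = cell.g_axial
            self.cm_node[sl] = cell.cm_node
            node_of.append(np.arange(off, off + cell.n_nodes, dtype=np.int64))
        #: node_of[c][j] = flattened index of cell c's local node j
        self.node_of = node_of

        self.solver = SolverArrays(
            v=np.full(n, self.v_init, dtype=np.float64),
            d=np.zeros(n), b=np.zeros(n), rhs=np.zeros(n),
        )

        # ---- pools: one per (group, mechanism type) ----
        staged: dict[tuple, list] = {}
        for k, ins in enumerate(model.insertions):
            group = net.group_of_cell[ins.cell]
            gnode = int(self.node_of[ins.cell][ins.node])
            peer = (int(self.node_of[ins.peer[0]][ins.peer[1]])
                    if ins.peer is not None else -1)
            staged.setdefault((group, ins.mech), []).append(
                (gnode, ins.params, peer, k)
            )
        gid_pool = {}
        for ns in model.netstims:
            group = ns.gid % self.n_groups
            staged.setdefault((group, "netstim"), []).append(
                (-1, dict(start=ns.start, interval=ns.interval,
                          number=float(ns.number), noise=ns.noise),
                 -1, ("netstim", ns.gid))
            )
        self.pools: dict[tuple, MechanismPool] = {}
        self.target_of_insertion: dict[int, tuple] = {}
        for key in sorted(staged, key=lambda k: (k[0], mechanism_id(k[1]))):
            group, mname = key
            entries = staged[key]
            entries.sort(key=lambda e: e[0])  # node_index ascending, stable
            spec = get_mechanism(mname)
            pool = MechanismPool(
                spec,
                node_index=[e[0] for e in entries],
                areas=[self.area[e[0]] if e[0] >= 0 else 0.0 for e in entries],
            )
            keys = []
            for pos, (gnode, params, peer, tag) in enumerate(entries):
                for pname, val in params.items():
                    if pname not in pool.params:
                        raise ConfigurationError(
                            f"{mname} has no parameter {pname!r}"
                        )
                    pool.params[pname][pos] = val
                if "peer_node" in pool.ints:
                    pool.ints["peer_node"][pos] = peer
                if isinstance(tag, tuple):  # netstim: tag = ("netstim", gid)
                    gid_pool[tag[1]] = (key, pos)
                    keys.append(derive_key(self.seed, tag[1], "netstim"))
                else:
                    self.target_of_insertion[tag] = (key, pos)
            if mname == "netstim":
                pool.rng_keys = np.asarray(keys, dtype=np.uint64)
                pool.gids = np.asarray(
                    [g for g, v in gid_pool.items() if v[0] == key],
                    dtype=np.int64,
                )
            self.pools[key] = pool
        self.pool_order = list(self.pools)

        # ---- events ----
        self.netcons: list[NetCon] = []
        for i, spec in enumerate(model.netcons):
            self.netcons.append(NetCon(
                index=i, src_gid=spec.src_gid,
                target=self.target_of_insertion[spec.target_insertion],
                weight=spec.weight, delay=spec.delay,
            ))
        self.netcons_by_src = index_netcons_by_source(self.netcons)
        self.known_gids = set(net.gids) | {ns.gid for ns in model.netstims}
        self.group_of_gid = {
            g: net.group_of_cell[c] for c, g in enumerate(net.gids)
        }
        for ns in model.netstims:
            self.group_of_gid[ns.gid] = ns.gid % self.n_groups

        self.presyns: list[PreSyn] = []
        for c, g in enumerate(net.gids):
            watch_local = model.watch_node.get(c, 0)
            self.presyns.append(PreSyn(
                gid=g, watch_node=int(self.node_of[c][watch_local]),
                threshold=model.threshold,
                armed=self.v_init < model.threshold,
            ))
        for ns in model.netstims:
            self.presyns.append(PreSyn(gid=ns.gid, watch_node=None))

        self.queue = EventQueue()
        self.fired_buffers: list[list] = [[] for _ in range(self.n_groups)]
        self.spikes: list[tuple[float, int]] = []
        self._netstim_times: dict[tuple, list[np.ndarray]] = {}

        self.t = 0.0
        self.step_index = 0
        self.op_counter = 0
        self.probes: list[int] = []
        self.probe_times: list[float] = []
        self.probe_data: list[np.ndarray] = []

        for pool in self.pools.values():
            if pool.mech.kind == ARTIFICIAL:
                continue
            pool.init(self.solver.v[pool.node_index])
            if pool.mech.name == "gap":
                GAP_SNAPSHOT(pool, self.solver.v)

    # -- helpers ---------------------------------------------------------

    def add_probe(self, cell: int, node: int = 0) -> int:
        """Record the voltage of one node at every step; returns its index."""
        g = int(self.node_of[cell][node])
        self.probes.append(g)
        return g

    def netstim_times(self, key) -> list[np.ndarray]:
        """Precomputed event schedule per instance of a netstim pool."""
        if key not in self._netstim_times:
            pool = self.pools[key]
            times = []
            for i in range(pool.count):
                times.append(netstim_events(
                    pool.params["start"][i], pool.params["interval"][i],
                    int(pool.params["number"][i]), pool.params["noise"][i],
                    tuple(int(w) for w in pool.rng_keys[i]),
                ))
            self._netstim_times[key] = times
        return self._netstim_times[key]

    def reseed_netstims(self, seed: int) -> None:
        """Re-key every netstim stream (alternative stimulus at restore)."""
        for key, pool in self.pools.items():
            if pool.mech.name != "netstim":
                continue
            pool.rng_keys = np.asarray(
                [derive_key(int(seed), int(g), "netstim") for g in pool.gids],
                dtype=np.uint64,
            )
            self._netstim_times.pop(key, None)

    def raster(self) -> list[tuple[float, int]]:
        """All spikes so far, sorted by (time, gid)."""
        return sorted(self.spikes)

    def structure_digest(self) -> str:
        """Digest of the structural arrays; guards checkpoint/model pairing."""
        h = hashlib.sha256()
        h.update(self.parent.tobytes())
        h.update(self.g_axial.tobytes())
        h.update(self.cm_node.tobytes())
        h.update(np.asarray(sorted(self.known_gids), dtype=np.int64).tobytes())
        for key in self.pool_order:
            pool = self.pools[key]
            h.update(repr(key).encode())
            h.update(pool.node_index.tobytes())
        for nc in self.netcons:
            h.update(f"{nc.src_gid}:{nc.target}:{nc.weight}:{nc.delay}".encode())
        return h.hexdigest()

    def _deliver(self, event):
        try:
            nc = self.netcons[event.netcon]
        except IndexError:
            raise IntegrityError(f"event references unknown netcon {event.netcon}")
        key, idx = nc.target
        if key not in self.pools:
            raise IntegrityError(f"event targets removed pool {key}")
        self.pools[key].net_receive(idx, nc.weight, event.delivery_time)

    def exchange(self) -> None:
        """Gather every group's spike buffer and fan out to all NetCons."""
        fired = []
        for buf in self.fired_buffers:
            fired.extend(buf)
            buf.clear()
        if fired:
            spike_exchange(fired, self.netcons_by_src, self.known_gids,
                           self.queue)


# --------------------------------------------------------------------------
# Per-step operations
# --------------------------------------------------------------------------

def assemble(state: SimState, dt: float | None = None) -> None:
    """Fill d, b, rhs for one backward-Euler step from current v and states."""
    dt = state.dt if dt is None else dt
    if dt <= 0:
        raise ParameterError("dt must be positive")
    sa = state.solver
    cm_dt = state.cm_node / dt
    sa.d[:] = cm_dt
    sa.rhs[:] = cm_dt * sa.v
    for key in state.pool_order:
        pool = state.pools[key]
        if pool.mech.kind == ARTIFICIAL:
            continue
        vg = sa.v[pool.node_index]
        g, i = pool.eval_current(vg, state.t, dt)
        np.add.at(sa.d, pool.node_index, g)
        np.add.at(sa.rhs, pool.node_index, g * vg - i)
    nonroot = state.parent >= 0
    sa.d += state.g_axial
    np.add.at(sa.d, state.parent[nonroot], state.g_axial[nonroot])
    sa.b[:] = -state.g_axial


def solve(state: SimState) -> None:
    """Hines solve of the assembled system; updates v and the op counter."""
    sa = state.solver
    v_new, nops = hines_solve(sa.d, sa.b, sa.rhs, state.parent)
    sa.v[:] = v_new
    state.op_counter += nops


def advance_states(state: SimState, dt: float | None = None) -> None:
    """Advance mechanism states using end-of-step voltages.

    Gating variables follow the exponential update
    x <- x_inf(v) + (x - x_inf(v)) e^(-dt/tau(v)); synaptic conductances
    decay; gap-junction peer voltages are snapshotted for the next step.
    """
    dt = state.dt if dt is None else dt
    v = state.solver.v
    for key in state.pool_order:
        pool = state.pools[key]
        if pool.mech.kind == ARTIFICIAL:
            continue
        pool.advance_state(v[pool.node_index], state.t, dt)
    for key in state.pool_order:
        pool = state.pools[key]
        if pool.mech.name == "gap":
            GAP_SNAPSHOT(pool, v)


def detect_spikes(state: SimState, t_end: float) -> None:
    """Scan threshold watchers; fire on upward crossings (>= rule).

    A watcher fires once per crossing: it must fall back below threshold
    before it can fire again.  Spike time is the end-of-step time.
    Artificial sources fire according to their precomputed schedules.
    """
    v = state.solver.v
    for ps in state.presyns:
        if ps.watch_node is None:
            continue
        vw = v[ps.watch_node]
        if ps.armed and vw >= ps.threshold:
            ps.armed = False
            state.spikes.append((t_end, ps.gid))
            state.fired_buffers[state.group_of_gid[ps.gid]].append(
                (ps.gid, t_end)
            )
        elif not ps.armed and vw < ps.threshold:
            ps.armed = True
    for key in state.pool_order:
        pool = state.pools[key]
        if pool.mech.name != "netstim":
            continue
        times = state.netstim_times(key)
        for i in range(pool.count):
            e = int(pool.ints["emitted"][i])
            ti = times[i]
            gid = int(pool.gids[i])
            while e < len(ti) and ti[e] <= t_end + TIME_TOL:
                state.spikes.append((float(ti[e]), gid))
                state.fired_buffers[state.group_of_gid[gid]].append(
                    (gid, float(ti[e]))
                )
                e += 1
            pool.ints["emitted"][i] = e


def step(state: SimState) -> None:
    """One integration step: deliver, assemble, solve, advance, detect."""
    t_end = (state.step_index + 1) * state.dt
    deliver_until(state.queue, t_end, state._deliver)
    assemble(state)
    solve(state)
    advance_states(state)
    detect_spikes(state, t_end)
    state.step_index += 1
    state.t = state.step_index * state.dt


def run(state: SimState, tstop: float) -> list[tuple[float, int]]:
    """Advance to tstop with spike exchange every mindelay; returns raster.

    The raster (sorted (time, gid) pairs) accumulates across successive
    calls, so splitting a run into segments yields identical output.
    """
    if tstop < state.t - TIME_TOL:
        raise ParameterError(f"tstop {tstop} < current t {state.t}")
    mindelay = compute_mindelay(state.netcons, tstop, state.dt)
    exchange_every = max(1, int(math.floor(mindelay / state.dt + TIME_TOL)))
    while state.t < tstop - TIME_TOL:
        step(state)
        if state.step_index % exchange_every == 0:
            state.exchange()
        if state.probes:
            state.probe_times.append(state.t)
            state.probe_data.append(state.solver.v[state.probes].copy())
    state.exchange()  # flush any spikes buffered since the last boundary
    return state.raster()
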
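"""Offline model archives and checkpoint-restart.

Model archive
-------------
A directory holding a JSON manifest plus one flat ``.npy`` dataset per
array, written group by group so a large model can be serialized one subset
at a time.  No dataset contains an absolute address: every cross-reference
is an integer offset whose meaning is declared by a *semantic tag* in the
manifest (``voltage_offset``, ``peer_voltage_offset``, ``netcon_target``,
``point_process_index``, ``presyn_index``, ``area_offset``).  Unknown tags
are fatal on read.  Output bytes are deterministic for a fixed model.

Checkpoint archive
------------------
The in-memory state at a step boundary: t, voltages, mechanism states, RNG
counters, watcher arm flags — and pending events.  Undelivered deliveries
are *collapsed* back into their originating source event, so each source
spike is stored once as (gid, spike_time) no matter how many NetCon
deliveries it still owes; restoring re-fans the stored source events out
and drops the deliveries that are already in the past (due time <= t).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .errors import ArchiveError, IntegrityError, StateError
from .mechanisms import get_mechanism, mechanism_id, registry_digest
from .model import Model, NetConSpec, NetStimSpec
from .morphology import CellTopology, NetworkModel
from .network import TIME_TOL

MODEL_FORMAT = "cablenet-model"
CHECKPOINT_FORMAT = "cablenet-checkpoint"
VERSION = 1

#: semantic tags an archive reader understands
KNOWN_TAGS = frozenset({
    "voltage_offset",        # index into the flattened voltage/node arrays
    "area_offset",           # index into the per-node area array
    "point_process_index",   # instance index within a mechanism pool
    "netcon_target",         # (group, mechanism id) pool handle of a NetCon
    "presyn_index",          # row in the threshold-watcher table
    "peer_voltage_offset",   # gap junction partner node
})

_UNITS = {"v": "mV", "t": "ms", "conductance": "uS", "current": "nA",
          "capacitance": "nF", "area": "um^2"}


def _save(path: Path, name: str, arr, dtype) -> str:
    np.save(path / f"{name}.npy", np.asarray(arr, dtype=dtype))
    return f"{name}.npy"


def _load(path: Path, entry) -> np.ndarray:
    tag = entry.get("tag")
    if tag is not None and tag not in KNOWN_TAGS:
        raise ArchiveError(f"unknown semantic tag {tag!r} in archive")
    try:
        return np.load(path / entry["file"])
    except (OSError, ValueError) as exc:
        raise ArchiveError(f"cannot read dataset {entry['file']}: {exc}") from exc


def _write_manifest(path: Path, manifest: dict, name: str) -> None:
    text = json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    (path / name).write_text(text)


def _read_manifest(path: Path, name: str, expected_format: str) -> dict:
    f = Path(path) / name
    if not f.exists():
        raise ArchiveError(f"no manifest at {f}")
    manifest = json.loads(f.read_text())
    if manifest.get("format") != expected_format:
        raise ArchiveError(f"not a {expected_format} archive: {f}")
    if manifest.get("version") != VERSION:
        raise ArchiveError(
            f"archive version {manifest.get('version')} != supported {VERSION}"
        )
    return manifest


# --------------------------------------------------------------------------
# Model archive
# --------------------------------------------------------------------------

def write_model(state, path) -> None:
    """Serialize a built simulation to a model archive directory.

    Node references are stored as offsets into the natural (unpermuted)
    flattened layout, so the archive is independent of any node permutation
    applied to ``state``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    model = state.model
    net = model.net

    # natural-layout inverse of state.node_of: global node -> natural offset
    natural = np.empty(state.n_nodes, dtype=np.int64)
    for c in range(net.n_cells):
        natural[state.node_of[c]] = np.arange(
            net.node_offset[c], net.node_offset[c] + net.cells[c].n_nodes
        )

    def to_natural(idx):
        idx = np.asarray(idx, dtype=np.int64)
        return np.where(idx < 0, -1, natural[np.maximum(idx, 0)])

    # per-pool natural row order: archive bytes are independent of any node
    # permutation applied to the live state
    row_order = {}
    for key in state.pool_order:
        if key[1] == "netstim":
            continue
        pool = state.pools[key]
        nat = to_natural(pool.node_index)
        order = np.argsort(nat, kind="stable")
        rows = np.empty(pool.count, dtype=np.int64)
        rows[order] = np.arange(pool.count)
        row_order[key] = (order, rows)

    groups_manifest = []
    n_groups = max(net.group_of_cell, default=0) + 1
    for g in range(n_groups):
        cells = [c for c in range(net.n_cells) if net.group_of_cell[c] == g]
        prefix = f"group{g}"
        datasets = {}
        parent = np.concatenate(
            [net.cells[c].parent for c in cells]
        ) if cells else np.empty(0, dtype=np.int64)
        datasets["parent"] = {
            "file": _save(path, f"{prefix}_parent", parent, np.int64),
            "tag": None,
        }
        for name, dtype in (("area", np.float64), ("g_axial", np.float64),
                            ("cm_node", np.float64),
                            ("section_of_node", np.int64)):
            arr = np.concatenate(
                [getattr(net.cells[c], name) for c in cells]
            ) if cells else np.empty(0)
            datasets[name] = {
                "file": _save(path, f"{prefix}_{name}", arr, dtype),
                "tag": None,
            }
        pools_manifest = []
        for key in state.pool_order:
            if key[0] != g or key[1] == "netstim":
                continue
            pool = state.pools[key]
            nat = to_natural(pool.node_index)
            order, _rows = row_order[key]
            pname = f"{prefix}_{key[1]}"
            pdatasets = {
                "node_index": {
                    "file": _save(path, f"{pname}_node_index",
                                  nat[order], np.int64),
                    "tag": "voltage_offset",
                },
                "area_index": {
                    "file": _save(path, f"{pname}_area_index",
                                  nat[order], np.int64),
                    "tag": "area_offset",
                },
            }
            for p in pool.params:
                pdatasets[f"param_{p}"] = {
                    "file": _save(path, f"{pname}_param_{p}",
                                  pool.params[p][order], np.float64),
                    "tag": None,
                }
            for s in pool.states:
                pdatasets[f"state_{s}"] = {
                    "file": _save(path, f"{pname}_state_{s}",
                                  pool.states[s][order], np.float64),
                    "tag": None,
                }
            if "peer_node" in pool.ints:
                pdatasets["peer_node"] = {
                    "file": _save(path, f"{pname}_peer_node",
                                  to_natural(pool.ints["peer_node"])[order],
                                  np.int64),
                    "tag": "peer_voltage_offset",
                }
            pools_manifest.append({"mech": key[1], "datasets": pdatasets})
        groups_manifest.append({
            "group": g,
            "cells": cells,
            "gids": [net.gids[c] for c in cells],
            "types": [net.type_of_cell[c] for c in cells],
            "cell_n_nodes": [net.cells[c].n_nodes for c in cells],
            "datasets": datasets,
            "pools": pools_manifest,
        })

    # global tables
    nc_datasets = {}
    netcons = state.netcons
    nc_datasets["src_gid"] = {
        "file": _save(path, "netcon_src_gid",
                      [nc.src_gid for nc in netcons], np.int64),
        "tag": None,
    }
    nc_datasets["target_group"] = {
        "file": _save(path, "netcon_target_group",
                      [nc.target[0][0] for nc in netcons], np.int64),
        "tag": "netcon_target",
    }
    nc_datasets["target_mech"] = {
        "file": _save(path, "netcon_target_mech",
                      [mechanism_id(nc.target[0][1]) for nc in netcons],
                      np.int64),
        "tag": "netcon_target",
    }
    nc_datasets["target_instance"] = {
        "file": _save(path, "netcon_target_instance",
                      [int(row_order[nc.target[0]][1][nc.target[1]])
                       for nc in netcons], np.int64),
        "tag": "point_process_index",
    }
    nc_datasets["weight"] = {
        "file": _save(path, "netcon_weight",
                      [nc.weight for nc in netcons], np.float64),
        "tag": None,
    }
    nc_datasets["delay"] = {
        "file": _save(path, "netcon_delay",
                      [nc.delay for nc in netcons], np.float64),
        "tag": None,
    }

    cell_presyns = [ps for ps in state.presyns if ps.watch_node is not None]
    ps_datasets = {
        "gid": {
            "file": _save(path, "presyn_gid",
                          [ps.gid for ps in cell_presyns], np.int64),
            "tag": "presyn_index",
        },
        "watch_node": {
            "file": _save(path, "presyn_watch_node",
                          to_natural([ps.watch_node for ps in cell_presyns]),
                          np.int64),
            "tag": "voltage_offset",
        },
    }

    manifest = {
        "format": MODEL_FORMAT,
        "version": VERSION,
        "units": _UNITS,
        "seed": state.seed,
        "threshold": model.threshold,
        "registry_digest": registry_digest(),
        "n_cells": net.n_cells,
        "n_nodes": state.n_nodes,
        "groups": groups_manifest,
        "netcon_table": nc_datasets,
        "presyn_table": ps_datasets,
        "netstims": [
            {"gid": ns.gid, "start": ns.start, "interval": ns.interval,
             "number": ns.number, "noise": ns.noise}
            for ns in model.netstims
        ],
    }
    _write_manifest(path, manifest, "manifest.json")


def read_model(path):
    """Decode a model archive; returns (Model, manifest).

    The reconstructed model instantiates to a simulation identical to the
    one the archive was written from.
    """
    path = Path(path)
    manifest = _read_manifest(path, "manifest.json", MODEL_FORMAT)
    if manifest["registry_digest"] != registry_digest():
        raise ArchiveError(
            "mechanism registry digest mismatch: archive was written with a "
            "different set of registered mechanisms"
        )

    n_cells = manifest["n_cells"]
    cells: list = [None] * n_cells
    gids = [0] * n_cells
    types = [0] * n_cells
    group_of_cell = [0] * n_cells
    for gm in manifest["groups"]:
        parent = _load(path, gm["datasets"]["parent"])
        area = _load(path, gm["datasets"]["area"])
        g_axial = _load(path, gm["datasets"]["g_axial"])
        cm_node = _load(path, gm["datasets"]["cm_node"])
        section = _load(path, gm["datasets"]["section_of_node"])
        expected = sum(gm["cell_n_nodes"])
        if len(parent) != expected:
            raise ArchiveError(
                f"group {gm['group']}: truncated dataset "
                f"(parent has {len(parent)} rows, expected {expected})"
            )
        off = 0
        for ci, c in enumerate(gm["cells"]):
            n = gm["cell_n_nodes"][ci]
            sl = slice(off, off + n)
            cells[c] = CellTopology(
                n_nodes=n, parent=parent[sl].copy(), area=area[sl].copy(),
                g_axial=g_axial[sl].copy(), cm_node=cm_node[sl].copy(),
                section_of_node=section[sl].copy(),
            )
            gids[c] = gm["gids"][ci]
            types[c] = gm["types"][ci]
            group_of_cell[c] = gm["group"]
            off += n
    net = NetworkModel(cells=cells, gids=gids, type_of_cell=types,
                       group_of_cell=group_of_cell)

    def cell_of_natural(idx):
        c = int(np.searchsorted(net.node_offset, idx, side="right")) - 1
        return c, int(idx - net.node_offset[c])

    model = Model(net=net, threshold=manifest["threshold"])
    # insertions, enumerated in (group, mechanism id, node) pool order:
    # stable re-sorting at build time reproduces the original pools exactly
    target_map = {}
    for gm in manifest["groups"]:
        for pm in gm["pools"]:
            mech = pm["mech"]
            spec = get_mechanism(mech)
            ds = pm["datasets"]
            node_index = _load(path, ds["node_index"])
            params = {p: _load(path, ds[f"param_{p}"]) for p in spec.param_defs}
            peers = (_load(path, ds["peer_node"])
                     if "peer_node" in ds else None)
            for i in range(len(node_index)):
                cell, local = cell_of_natural(node_index[i])
                peer = None
                if peers is not None and peers[i] >= 0:
                    peer = cell_of_natural(peers[i])
                k = model.insert(
                    mech, cell, local, peer=peer,
                    **{p: float(params[p][i]) for p in params},
                )
                target_map[(gm["group"], mech, i)] = k

    for nsm in manifest["netstims"]:
        model.netstims.append(NetStimSpec(
            gid=nsm["gid"], start=nsm["start"], interval=nsm["interval"],
            number=nsm["number"], noise=nsm["noise"],
        ))

    nct = manifest["netcon_table"]
    src = _load(path, nct["src_gid"])
    tgt_group = _load(path, nct["target_group"])
    tgt_mech = _load(path, nct["target_mech"])
    tgt_inst = _load(path, nct["target_instance"])
    weight = _load(path, nct["weight"])
    delay = _load(path, nct["delay"])
    from .mechanisms import registered_mechanisms

    mech_names = registered_mechanisms()
    for i in range(len(src)):
        key = (int(tgt_group[i]), mech_names[int(tgt_mech[i])], int(tgt_inst[i]))
        if key not in target_map:
            raise ArchiveError(f"netcon {i} targets unknown instance {key}")
        model.netcons.append(NetConSpec(
            src_gid=int(src[i]), target_insertion=target_map[key],
            weight=float(weight[i]), delay=float(delay[i]),
        ))

    pst = manifest["presyn_table"]
    ps_gid = _load(path, pst["gid"])
    ps_watch = _load(path, pst["watch_node"])
    gid_to_cell = {g: c for c, g in enumerate(net.gids)}
    for i in range(len(ps_gid)):
        cell, local = cell_of_natural(ps_watch[i])
        if gid_to_cell.get(int(ps_gid[i])) != cell:
            raise ArchiveError(f"presyn table row {i} is inconsistent")
        model.watch_node[cell] = local
    return model, manifest


# --------------------------------------------------------------------------
# Checkpoint archive
# --------------------------------------------------------------------------

def collapse_pending_events(state) -> list[tuple[int, float]]:
    """Pending deliveries and un-exchanged spikes as unique source events.

    Every undelivered message is collapsed back into the original event of
    the firing cell, so one (gid, spike_time) pair is stored regardless of
    how many NetCon deliveries it still owes.
    """
    sources = {(e.src_gid, e.spike_time) for e in state.queue.pending()}
    for buf in state.fired_buffers:
        for gid, t_spike in buf:
            sources.add((gid, t_spike))
    return sorted(sources)


def save_checkpoint(state, path) -> None:
    """Write the simulator state at the current step boundary."""
    if not math.isclose(state.t, state.step_index * state.dt, abs_tol=TIME_TOL):
        raise StateError("checkpoint must be taken on a step boundary")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    datasets = {
        "v": {"file": _save(path, "v", state.solver.v, np.float64),
              "tag": "voltage_offset"},
        "presyn_armed": {
            "file": _save(path, "presyn_armed",
                          [1 if ps.armed else 0 for ps in state.presyns],
                          np.int64),
            "tag": "presyn_index",
        },
    }
    pools_manifest = []
    for key in state.pool_order:
        pool = state.pools[key]
        pname = f"pool{key[0]}_{key[1]}"
        pdatasets = {}
        for s in pool.states:
            pdatasets[f"state_{s}"] = {
                "file": _save(path, f"{pname}_state_{s}",
                              pool.states[s], np.float64),
                "tag": None,
            }
        if "emitted" in pool.ints:  # RNG stream positions, not state blobs
            pdatasets["emitted"] = {
                "file": _save(path, f"{pname}_emitted",
                              pool.ints["emitted"], np.int64),
                "tag": None,
            }
        pools_manifest.append({"group": key[0], "mech": key[1],
                               "datasets": pdatasets})
    sources = collapse_pending_events(state)
    datasets["event_gid"] = {
        "file": _save(path, "event_gid", [s[0] for s in sources], np.int64),
        "tag": None,
    }
    datasets["event_time"] = {
        "file": _save(path, "event_time", [s[1] for s in sources], np.float64),
        "tag": None,
    }
    manifest = {
        "format": CHECKPOINT_FORMAT,
        "version": VERSION,
        "t": state.t,
        "step_index": state.step_index,
        "op_counter": state.op_counter,
        "seed": state.seed,
        "structure_digest": state.structure_digest(),
        "datasets": datasets,
        "pools": pools_manifest,
    }
    _write_manifest(path, manifest, "checkpoint.json")


def restore_checkpoint(path, state, netstim_seed=None):
    """Load a checkpoint into a freshly built matching simulation state.

    Stored source events are re-fanned out through the NetCons; regenerated
    deliveries already due (delivery time <= t) are dropped as delivered.
    Continuing to tstop reproduces the uninterrupted run bit-identically.
    ``netstim_seed`` optionally re-keys the stimulus streams, so alternative
    stimuli can be explored from the same checkpoint.  Returns the state.
    """
    path = Path(path)
    manifest = _read_manifest(path, "checkpoint.json", CHECKPOINT_FORMAT)
    if manifest["structure_digest"] != state.structure_digest():
        raise IntegrityError(
            "checkpoint does not match this model (structure digest differs)"
        )
    state.t = float(manifest["t"])
    state.step_index = int(manifest["step_index"])
    state.op_counter = int(manifest["op_counter"])
    ds = manifest["datasets"]
    state.solver.v[:] = _load(path, ds["v"])
    armed = _load(path, ds["presyn_armed"])
    for ps, a in zip(state.presyns, armed):
        ps.armed = bool(a)
    for pm in manifest["pools"]:
        key = (pm["group"], pm["mech"])
        if key not in state.pools:
            raise IntegrityError(f"checkpoint references unknown pool {key}")
        pool = state.pools[key]
        for s in pool.states:
            pool.states[s][:] = _load(path, pm["datasets"][f"state_{s}"])
        if "emitted" in pool.ints:
            pool.ints["emitted"][:] = _load(path, pm["datasets"]["emitted"])
    if netstim_seed is not None:
        state.reseed_netstims(netstim_seed)
    state.queue.clear()
    for buf in state.fired_buffers:
        buf.clear()
    ev_gid = _load(path, ds["event_gid"])
    ev_time = _load(path, ds["event_time"])
    for gid, t_spike in zip(ev_gid, ev_time):
        for nc in state.netcons_by_src.get(int(gid), ()):
            delivery = float(t_spike) + nc.delay
            if delivery <= state.t + TIME_TOL:
                continue  # already delivered before the checkpoint
            state.queue.push(delivery, int(gid), nc.index, float(t_spike))
    return state
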
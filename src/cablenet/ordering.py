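"""Node permutation schemes and a parent-access locality metric.

Tree elimination and matrix assembly read each node's parent; on SIMD-style
hardware those reads coalesce only when the parents of a contiguous group of
nodes (a *warp*) are themselves contiguous.  Two permutations improve this:

interleaved
    Within a block of N topologically identical cells, node j of cell c maps
    to ``block_offset + j*N + c`` — corresponding compartments of identical
    cells become adjacent, so a warp's parents are the previous node row.

constant depth
    All nodes at the same tree depth are adjacent; within a depth,
    corresponding nodes of identical cells are adjacent; within one cell,
    children of the same branch node are spread as far apart as possible.

Both preserve the parent-before-child ordering the solver requires, so a
permuted model simulates identically up to elimination-order roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, IntegrityError
from .morphology import NetworkModel


@dataclass
class Permutation:
    """Bijection old->new over flattened node indices."""

    forward: np.ndarray

    def __post_init__(self):
        self.forward = np.asarray(self.forward, dtype=np.int64)
        n = len(self.forward)
        if not np.array_equal(np.sort(self.forward), np.arange(n)):
            raise ConfigurationError("forward map is not a bijection")
        self.inverse = np.empty(n, dtype=np.int64)
        self.inverse[self.forward] = np.arange(n)

    def __len__(self) -> int:
        return len(self.forward)

    def inverted(self) -> "Permutation":
        return Permutation(self.inverse.copy())


def identity_order(model: NetworkModel) -> Permutation:
    return Permutation(np.arange(model.n_nodes_total))


def _cells_by_type(model: NetworkModel) -> dict[int, list[int]]:
    by_type: dict[int, list[int]] = {}
    for c, t in enumerate(model.type_of_cell):
        by_type.setdefault(t, []).append(c)
    return by_type


def interleaved_order(model: NetworkModel) -> Permutation:
    """One-cell-per-lane interleaving of identical cells.

    Cells are blocked by type (types in ascending order); within a type
    block of N cells, node j of the type's c-th cell maps to
    ``block_offset + j*N + c``.  Requires all cells of a type to be
    topologically identical.
    """
    forward = np.empty(model.n_nodes_total, dtype=np.int64)
    offset = 0
    by_type = _cells_by_type(model)
    for t in sorted(by_type):
        cells = by_type[t]
        ref = model.cells[cells[0]]
        for c in cells[1:]:
            if not model.cells[c].identical_to(ref):
                raise ConfigurationError(
                    f"cells of type {t} are not topologically identical"
                )
        n_cells = len(cells)
        n_nodes = ref.n_nodes
        for ci, c in enumerate(cells):
            base = int(model.node_offset[c])
            for j in range(n_nodes):
                forward[base + j] = offset + j * n_cells + ci
        offset += n_cells * n_nodes
    return Permutation(forward)


def _depth_row_ranks(cell) -> np.ndarray:
    """Within-cell rank of each node inside its depth row.

    Rows are ordered round-robin over branch parents sorted by descending
    child count, so the k-th children of all parents precede the (k+1)-th:
    siblings end up maximally separated (two siblings are at least
    floor(m/2) apart in a row of m whenever no sibling group exceeds half
    the row).
    """
    depth = cell.depth()
    rank = np.zeros(cell.n_nodes, dtype=np.int64)
    for d in range(int(depth.max()) + 1 if cell.n_nodes else 0):
        row = np.flatnonzero(depth == d)
        if d == 0:
            rank[row] = np.arange(len(row))
            continue
        children: dict[int, list[int]] = {}
        for i in row:
            children.setdefault(int(cell.parent[i]), []).append(int(i))
        parents = sorted(children, key=lambda p: (-len(children[p]), p))
        pos = 0
        k = 0
        while pos < len(row):
            for p in parents:
                if k < len(children[p]):
                    rank[children[p][k]] = pos
                    pos += 1
            k += 1
    return rank


def constant_depth_order(model: NetworkModel) -> Permutation:
    """Sort all nodes by (depth, type, within-cell row rank, cell).

    All nodes at the same depth from the root are adjacent; for a given
    depth, corresponding nodes of identical cells are adjacent; each type's
    roots come first within its depth row.
    """
    keys = []
    for c, cell in enumerate(model.cells):
        depth = cell.depth()
        rank = _depth_row_ranks(cell)
        t = model.type_of_cell[c]
        base = int(model.node_offset[c])
        for j in range(cell.n_nodes):
            keys.append((int(depth[j]), t, int(rank[j]), c, base + j))
    keys.sort()
    forward = np.empty(model.n_nodes_total, dtype=np.int64)
    for new, (_, _, _, _, old) in enumerate(keys):
        forward[old] = new
    return Permutation(forward)


def apply_permutation(state, perm: Permutation):
    """Relabel every node reference of a simulation state in place.

    Voltages, solver arrays, parent indices, pool node indices, gap peer
    nodes and threshold-watcher nodes are all remapped consistently; the
    permuted parent array is re-validated (parent-before-child must still
    hold).  Applying a permutation and then its inverse restores the state
    bit-identically.  Returns the state.
    """
    f = perm.forward
    if len(f) != state.n_nodes:
        raise IntegrityError(
            f"permutation size {len(f)} != node count {state.n_nodes}"
        )

    def scatter(arr):
        out = np.empty_like(arr)
        out[f] = arr
        return out

    new_parent = np.where(state.parent < 0, -1, f[state.parent])
    state.parent = scatter(new_parent)
    state.area = scatter(state.area)
    state.g_axial = scatter(state.g_axial)
    state.cm_node = scatter(state.cm_node)
    sa = state.solver
    sa.v = scatter(sa.v)
    sa.d = scatter(sa.d)
    sa.b = scatter(sa.b)
    sa.rhs = scatter(sa.rhs)
    state.node_of = [f[m] for m in state.node_of]

    pos_map: dict[tuple, np.ndarray] = {}
    for key, pool in state.pools.items():
        new_index = np.where(pool.node_index < 0, -1, f[pool.node_index])
        order = np.argsort(new_index, kind="stable")
        pos_map[key] = np.empty(pool.count, dtype=np.int64)
        pos_map[key][order] = np.arange(pool.count)
        pool.node_index = new_index[order]
        for store in (pool.params, pool.states, pool.ints):
            for name in store:
                store[name] = store[name][order]
        pool.area = pool.area[order]
        if "peer_node" in pool.ints:
            peers = pool.ints["peer_node"]
            pool.ints["peer_node"] = np.where(peers < 0, -1, f[peers])
        if pool.rng_keys is not None:
            pool.rng_keys = pool.rng_keys[order]
        if hasattr(pool, "gids"):
            pool.gids = pool.gids[order]
        if key in state._netstim_times:
            old_times = state._netstim_times[key]
            state._netstim_times[key] = [old_times[i] for i in order]

    for nc in state.netcons:
        key, idx = nc.target
        nc.target = (key, int(pos_map[key][idx]))
    state.target_of_insertion = {
        k: (key, int(pos_map[key][idx]))
        for k, (key, idx) in state.target_of_insertion.items()
    }
    for ps in state.presyns:
        if ps.watch_node is not None:
            ps.watch_node = int(f[ps.watch_node])

    diags = []
    for i in range(state.n_nodes):
        p = state.parent[i]
        if p >= i:
            diags.append(i)
    if diags:
        raise IntegrityError(
            f"permutation breaks parent-before-child at nodes {diags[:5]}"
        )
    return state


def order_by_name(name: str, model: NetworkModel) -> Permutation:
    """Look up a permutation scheme: none | interleaved | constant_depth."""
    if name in (None, "none", "identity"):
        return identity_order(model)
    if name == "interleaved":
        return interleaved_order(model)
    if name == "constant_depth":
        return constant_depth_order(model)
    raise ConfigurationError(f"unknown permutation scheme {name!r}")


def parent_contiguity(parent, warp_size: int = 32) -> float:
    """Fraction of warps whose parent reads are one contiguous run.

    Non-root nodes are partitioned, in index order, into consecutive groups
    of ``warp_size``; a group counts as contiguous iff its parents form a
    consecutive ascending run (each exactly one above the previous).  Models
    the contiguous-load vs strided-load distinction of warp execution.
    """
    if warp_size < 2:
        raise ConfigurationError("warp_size must be >= 2")
    parent = np.asarray(parent, dtype=np.int64)
    parents = parent[parent >= 0]
    if len(parents) == 0:
        return 1.0
    n_groups = 0
    n_contig = 0
    for start in range(0, len(parents), warp_size):
        grp = parents[start:start + warp_size]
        n_groups += 1
        if len(grp) == 1 or np.all(np.diff(grp) == 1):
            n_contig += 1
    return n_contig / n_groups
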
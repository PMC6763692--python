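"""Discretized neuron trees and synthetic network topologies.

A cell is a tree of unbranched cables (*sections*); each section is split
into ``nseg`` equal compartments (*nodes*), one membrane-potential unknown
per node.  Nodes are numbered so that ``parent[i] < i`` with the root at
index 0 — the ordering the tree Gaussian elimination relies on.

Unit system (fixed so that uS*mV = nA and nF*mV/ms = nA with no per-step
conversion factors):

===============  =========  =====================================
quantity         unit       from section parameters
===============  =========  =====================================
node area        um^2       pi * diam * dx
node capacitance nF         cm [uF/cm^2] * area [um^2] * 1e-5
axial conduct.   uS         1e2 * pi * diam^2 / (4 * Ra * dx)
===============  =========  =====================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidGeometryError, InvalidTopologyError
from .network import counter_rng, derive_key

ROOT = -1  # parent sentinel of a root node


@dataclass(frozen=True)
class SectionSpec:
    """One unbranched cable: geometry, passive constants, attachment.

    ``parent_section`` must reference a previously declared section id (or be
    None for the single root).  ``parent_x`` is the 0..1 normalized position
    on the parent where this section attaches; it is mapped to the nearest
    parent node, rounding down.
    """

    id: int
    length: float            # um
    diam: float              # um
    nseg: int = 1
    Ra: float = 150.0        # ohm*cm
    cm: float = 1.0          # uF/cm^2
    parent_section: int | None = None
    parent_x: float = 1.0


@dataclass(frozen=True)
class NodeGeom:
    """Geometry record of one compartment."""

    dx: float        # um
    area: float      # um^2
    cm_node: float   # nF
    g_axial: float   # uS, conductance to the previous node of the section


def discretize_section(spec: SectionSpec) -> list[NodeGeom]:
    """Split a section into ``nseg`` equal compartments.

    Each node gets dx = length/nseg, membrane area pi*diam*dx, capacitance
    cm*area*1e-5 nF, and axial conductance 1e2*pi*diam^2/(4*Ra*dx) uS to its
    neighbor.  The same conductance links the section's first node to its
    attachment node on the parent section.
    """
    if spec.nseg < 1:
        raise InvalidGeometryError(f"section {spec.id}: nseg must be >= 1")
    for name in ("length", "diam", "Ra", "cm"):
        if getattr(spec, name) <= 0:
            raise InvalidGeometryError(
                f"section {spec.id}: {name} must be positive"
            )
    dx = spec.length / spec.nseg
    area = math.pi * spec.diam * dx
    cm_node = spec.cm * area * 1e-5
    g_axial = 1e2 * math.pi * spec.diam ** 2 / (4.0 * spec.Ra * dx)
    return [NodeGeom(dx, area, cm_node, g_axial) for _ in range(spec.nseg)]


@dataclass
class CellTopology:
    """Flattened per-cell tree: parent indices and per-node passive data.

    Invariants: ``parent[i] < i`` for all non-root i, the root is index 0
    with ``parent[0] == -1`` and ``g_axial[0] == 0``.
    """

    n_nodes: int
    parent: np.ndarray          # int64, parent[0] == -1
    area: np.ndarray            # um^2
    g_axial: np.ndarray         # uS to parent, 0 at root
    cm_node: np.ndarray         # nF
    section_of_node: np.ndarray  # section id per node

    def depth(self) -> np.ndarray:
        """Distance (in nodes) from the root, root = 0."""
        d = np.zeros(self.n_nodes, dtype=np.int64)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + 1
        return d

    def identical_to(self, other: "CellTopology") -> bool:
        return (
            self.n_nodes == other.n_nodes
            and np.array_equal(self.parent, other.parent)
            and np.array_equal(self.area, other.area)
            and np.array_equal(self.g_axial, other.g_axial)
            and np.array_equal(self.cm_node, other.cm_node)
        )


def build_cell(sections: list[SectionSpec]) -> CellTopology:
    """Assemble sections, declared parent-first, into one cell tree.

    Node indices are assigned section by section in declaration order; a
    child section's first node attaches to the parent node nearest its
    ``parent_x`` (rounding down), which guarantees parent[i] < i.
    """
    if not sections:
        raise InvalidTopologyError("cell needs at least one section")
    roots = [s for s in sections if s.parent_section is None]
    if len(roots) != 1:
        raise InvalidTopologyError(
            f"cell must have exactly one root section, found {len(roots)}"
        )
    declared: dict[int, SectionSpec] = {}
    first_node: dict[int, int] = {}
    parent, area, g_axial, cm_node, sec_of = [], [], [], [], []
    for sec in sections:
        if sec.id in declared:
            raise InvalidTopologyError(f"duplicate section id {sec.id}")
        if sec.parent_section is not None:
            if sec.parent_section == sec.id:
                raise InvalidTopologyError(
                    f"section {sec.id} is its own parent"
                )
            if sec.parent_section not in declared:
                raise InvalidTopologyError(
                    f"section {sec.id}: parent {sec.parent_section} not "
                    "declared earlier (cycle or forward reference)"
                )
        geoms = discretize_section(sec)
        base = len(parent)
        first_node[sec.id] = base
        if sec.parent_section is None:
            attach = ROOT
        else:
            pspec = declared[sec.parent_section]
            if not (0.0 <= sec.parent_x <= 1.0):
                raise InvalidTopologyError(
                    f"section {sec.id}: parent_x must be in [0, 1]"
                )
            k = min(int(sec.parent_x * pspec.nseg), pspec.nseg - 1)
            attach = first_node[sec.parent_section] + k
        for j, g in enumerate(geoms):
            parent.append(base + j - 1 if j > 0 else attach)
            area.append(g.area)
            g_axial.append(0.0 if (j == 0 and attach == ROOT) else g.g_axial)
            cm_node.append(g.cm_node)
            sec_of.append(sec.id)
        declared[sec.id] = sec
    cell = CellTopology(
        n_nodes=len(parent),
        parent=np.asarray(parent, dtype=np.int64),
        area=np.asarray(area, dtype=np.float64),
        g_axial=np.asarray(g_axial, dtype=np.float64),
        cm_node=np.asarray(cm_node, dtype=np.float64),
        section_of_node=np.asarray(sec_of, dtype=np.int64),
    )
    diags = validate_tree(cell.parent)
    if diags:
        raise InvalidTopologyError("; ".join(diags))
    return cell


def validate_tree(parent) -> list[str]:
    """Diagnose a parent-index array; empty list iff a valid ordered tree.

    Reports the root count, any node whose parent index is not smaller than
    its own, and unreachable nodes.
    """
    parent = np.asarray(parent, dtype=np.int64)
    diags: list[str] = []
    roots = np.flatnonzero(parent == ROOT)
    if len(roots) != 1:
        diags.append(f"expected 1 root, found {len(roots)} at {roots.tolist()}")
    for i in range(len(parent)):
        p = parent[i]
        if p == ROOT:
            continue
        if p >= i:
            diags.append(f"node {i}: parent {p} >= {i} (ordering violation)")
        elif p < 0:
            diags.append(f"node {i}: invalid parent {p}")
    if not diags and len(parent) and parent[0] != ROOT:
        diags.append("node 0 is not the root")
    # with one root and parent[i] < i everywhere, all nodes reach the root
    return diags


# --------------------------------------------------------------------------
# Network container
# --------------------------------------------------------------------------

@dataclass
class NetworkModel:
    """A set of cells with globally unique gids and a cell-group partition.

    ``cells`` may hold shared CellTopology references for identical cells
    (the flattening step copies).  ``node_offset[c]`` is the index of cell
    c's root in the flattened node arrays.
    """

    cells: list[CellTopology]
    gids: list[int]
    type_of_cell: list[int]
    group_of_cell: list[int] = field(default_factory=list)
    node_offset: np.ndarray | None = None

    def __post_init__(self):
        if len(set(self.gids)) != len(self.gids):
            raise ConfigurationError("cell gids must be unique")
        if not self.group_of_cell:
            self.group_of_cell = [0] * len(self.cells)
        counts = np.asarray([c.n_nodes for c in self.cells], dtype=np.int64)
        self.node_offset = np.concatenate(([0], np.cumsum(counts)))[:-1]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_nodes_total(self) -> int:
        return int(sum(c.n_nodes for c in self.cells))

    def assign_groups(self, n_groups: int) -> None:
        """Partition cells round-robin into n_groups logical groups."""
        if n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        self.group_of_cell = [i % n_groups for i in range(self.n_cells)]


# --------------------------------------------------------------------------
# Synthetic generators
# --------------------------------------------------------------------------

def random_tree_sections(
    n_dend: int,
    nseg_per_dend: int,
    key,
    soma_nseg: int = 1,
    soma_diam: float = 20.0,
    soma_length: float = 20.0,
    dend_diam: float = 2.0,
    dend_length: float = 100.0,
    depth_cap: int = 5,
) -> list[SectionSpec]:
    """Soma plus ``n_dend`` dendrites with a random branching pattern.

    Each dendrite attaches uniformly at random to the distal end of an
    existing section (soma or dendrite) whose tree depth is below
    ``depth_cap``; draws come from the counter RNG stream ``key`` so a key
    determines the topology exactly.
    """
    if n_dend < 0 or nseg_per_dend < 1 or soma_nseg < 1:
        raise ConfigurationError("counts must be positive")
    sections = [SectionSpec(id=0, length=soma_length, diam=soma_diam,
                            nseg=soma_nseg)]
    sec_depth = {0: 0}
    for k in range(n_dend):
        candidates = [s for s in sec_depth if sec_depth[s] < depth_cap]
        u = counter_rng(key, k)
        pick = candidates[int(u * len(candidates))]
        sid = k + 1
        sections.append(SectionSpec(
            id=sid, length=dend_length, diam=dend_diam, nseg=nseg_per_dend,
            parent_section=pick, parent_x=1.0,
        ))
        sec_depth[sid] = sec_depth[pick] + 1
    return sections


def ring_network(
    n_types: int,
    cells_per_type: int,
    n_dend: int,
    nseg_per_dend: int,
    ring_size: int,
    seed: int,
    soma_nseg: int = 1,
    weight: float = 0.05,
    delay: float = 1.0,
    **tree_kwargs,
):
    """Multiple-ring benchmark network of randomly branching cells.

    Every cell type gets its own random dendritic branching pattern drawn
    from ``seed``; all cells of one type are topologically identical (they
    share one CellTopology object) and every cell has the same node count.
    Cells are wired into rings of ``ring_size``: within a ring, cell k
    excites cell k+1 (mod ring size) through an excitatory synapse with the
    fixed ``delay``.

    Returns (NetworkModel, connections) where each connection is a dict with
    src_gid, tgt_gid, weight (uS) and delay (ms).
    """
    for name, v in (("n_types", n_types), ("cells_per_type", cells_per_type),
                    ("n_dend", n_dend), ("nseg_per_dend", nseg_per_dend),
                    ("ring_size", ring_size)):
        if v < 1:
            raise ConfigurationError(f"{name} must be >= 1")
    total = n_types * cells_per_type
    if total % ring_size != 0:
        raise ConfigurationError(
            f"ring_size {ring_size} does not divide total cell count {total}"
        )
    type_cells = []
    for t in range(n_types):
        key = derive_key(seed, t, "ring-branching")
        secs = random_tree_sections(
            n_dend, nseg_per_dend, key, soma_nseg=soma_nseg, **tree_kwargs
        )
        type_cells.append(build_cell(secs))
    nodes_per_cell = type_cells[0].n_nodes
    cells, types = [], []
    for t in range(n_types):
        for _ in range(cells_per_type):
            cells.append(type_cells[t])  # shared reference: identical cells
            types.append(t)
    model = NetworkModel(cells=cells, gids=list(range(total)),
                         type_of_cell=types)
    connections = []
    for ring_start in range(0, total, ring_size):
        for k in range(ring_size):
            src = ring_start + k
            tgt = ring_start + (k + 1) % ring_size
            connections.append(dict(src_gid=src, tgt_gid=tgt,
                                    weight=weight, delay=delay))
    assert model.n_nodes_total == total * nodes_per_cell
    return model, connections
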
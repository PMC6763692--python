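"""Model assembly: mechanism placements, connections and ready-made fixtures.

A :class:`Model` couples a :class:`~cablenet.morphology.NetworkModel` (pure
topology) with mechanism insertions, synaptic connections, stimulus sources
and threshold watchers — everything the engine needs to instantiate a
simulation.  The builders at the bottom produce the standard test workloads:
single compartments, gap-coupled pairs, and the multiple-ring benchmark of
randomly branching cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .mechanisms import get_mechanism
from .morphology import NetworkModel, build_cell, ring_network, SectionSpec


@dataclass
class Insertion:
    """One mechanism instance on a node: (mech, cell index, local node).

    ``peer`` is (cell, node) of the partner compartment for gap junctions.
    """

    mech: str
    cell: int
    node: int
    params: dict = field(default_factory=dict)
    peer: tuple | None = None


@dataclass
class NetConSpec:
    """Connection from a source gid to the synapse made by one insertion."""

    src_gid: int
    target_insertion: int
    weight: float  # uS
    delay: float   # ms


@dataclass
class NetStimSpec:
    """Artificial spike source (regular or Poisson-like) with its own gid."""

    gid: int
    start: float = 0.0
    interval: float = 10.0
    number: int = 0
    noise: float = 0.0


@dataclass
class Model:
    net: NetworkModel
    insertions: list[Insertion] = field(default_factory=list)
    netcons: list[NetConSpec] = field(default_factory=list)
    netstims: list[NetStimSpec] = field(default_factory=list)
    threshold: float = -20.0       # mV, PreSyn firing condition
    watch_node: dict = field(default_factory=dict)  # cell -> local node (default 0)
    syn_of_gid: dict = field(default_factory=dict)  # gid -> synapse insertion

    def insert(self, mech: str, cell: int, node: int, peer=None, **params) -> int:
        """Place one mechanism instance; returns the insertion index."""
        get_mechanism(mech)  # validates the name
        self.insertions.append(Insertion(mech, cell, node, params, peer))
        return len(self.insertions) - 1

    def connect(self, src_gid: int, target_insertion: int,
                weight: float, delay: float) -> int:
        if not (0 <= target_insertion < len(self.insertions)):
            raise ConfigurationError("netcon target insertion out of range")
        tgt = self.insertions[target_insertion]
        if not get_mechanism(tgt.mech).has_net_receive:
            raise ConfigurationError(
                f"netcon target mechanism {tgt.mech!r} has no net_receive"
            )
        self.netcons.append(NetConSpec(src_gid, target_insertion, weight, delay))
        return len(self.netcons) - 1

    def add_netstim(self, start=0.0, interval=10.0, number=0,
                    noise=0.0, gid=None) -> NetStimSpec:
        if gid is None:
            used = set(self.net.gids) | {ns.gid for ns in self.netstims}
            gid = max(used, default=-1) + 1
        ns = NetStimSpec(gid, start, interval, int(number), noise)
        self.netstims.append(ns)
        return ns


# --------------------------------------------------------------------------
# Fixture builders
# --------------------------------------------------------------------------

def soma_only_cell(diam=20.0, length=20.0, nseg=1, Ra=150.0, cm=1.0):
    return build_cell([SectionSpec(id=0, length=length, diam=diam,
                                   nseg=nseg, Ra=Ra, cm=cm)])


def single_compartment(mechs=(), gid=0, **cell_kwargs) -> Model:
    """One isolated soma; ``mechs`` is a list of (name, params) to insert."""
    cell = soma_only_cell(**cell_kwargs)
    net = NetworkModel(cells=[cell], gids=[gid], type_of_cell=[0])
    model = Model(net=net)
    for name, params in mechs:
        model.insert(name, 0, 0, **params)
    return model


def gap_pair(g_gap=0.01, g_pas=0.001, e_pas=-65.0, v_kick=None) -> Model:
    """Two passive somas coupled by a symmetric gap junction."""
    cells = [soma_only_cell(), soma_only_cell()]
    net = NetworkModel(cells=cells, gids=[0, 1], type_of_cell=[0, 0])
    model = Model(net=net)
    for c in (0, 1):
        model.insert("pas", c, 0, g=g_pas, e=e_pas)
    model.insert("gap", 0, 0, peer=(1, 0), g=g_gap)
    model.insert("gap", 1, 0, peer=(0, 0), g=g_gap)
    if v_kick is not None:  # transient depolarizing pulse on cell 0
        model.insert("iclamp", 0, 0, amp=v_kick, start=0.0, dur=1.0)
    return model


def ring_model(
    n_types: int = 2,
    cells_per_type: int = 8,
    n_dend: int = 4,
    nseg_per_dend: int = 2,
    ring_size: int | None = None,
    seed: int = 0,
    soma_nseg: int = 1,
    weight: float = 0.05,
    delay: float = 1.0,
    tau_syn: float = 2.0,
    e_syn: float = 0.0,
    stim_amp: float = 1.0,
    stim_start: float = 1.0,
    stim_dur: float = 1.0,
    g_pas: float = 0.001,
    e_pas: float = -65.0,
    **tree_kwargs,
) -> Model:
    """The multiple-ring benchmark: active somas, passive random dendrites.

    Each cell type has its own random branching pattern; cells are wired into
    rings (cell k excites cell k+1 mod ring size through an ExpSyn on the
    soma) and the first cell of every ring gets a current-clamp kick that
    starts a spike wave circulating the ring indefinitely.
    """
    total = n_types * cells_per_type
    if ring_size is None:
        ring_size = total
    net, connections = ring_network(
        n_types, cells_per_type, n_dend, nseg_per_dend, ring_size, seed,
        soma_nseg=soma_nseg, weight=weight, delay=delay, **tree_kwargs,
    )
    model = Model(net=net)
    syn_of_cell = {}
    for c, cell in enumerate(net.cells):
        soma_nodes = np.flatnonzero(cell.section_of_node == 0)
        dend_nodes = np.flatnonzero(cell.section_of_node != 0)
        for j in soma_nodes:
            model.insert("hh", c, int(j))
        for j in dend_nodes:
            model.insert("pas", c, int(j), g=g_pas, e=e_pas)
        syn_of_cell[net.gids[c]] = model.insert(
            "expsyn", c, int(soma_nodes[0]), tau=tau_syn, e=e_syn
        )
    model.syn_of_gid = dict(syn_of_cell)
    cell_of_gid = {g: c for c, g in enumerate(net.gids)}
    for conn in connections:
        model.connect(conn["src_gid"], syn_of_cell[conn["tgt_gid"]],
                      conn["weight"], conn["delay"])
    for ring_start in range(0, total, ring_size):
        c0 = cell_of_gid[ring_start]
        model.insert("iclamp", c0, 0, amp=stim_amp,
                     start=stim_start, dur=stim_dur)
    return model
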
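# cablenet

A desk-scale compute engine for networks of morphologically detailed
neurons: implicit cable-equation integration on branched cell trees,
event-driven synaptic communication, Structure-of-Arrays mechanism kernels,
node-permutation memory layouts, an offline model-archive format and
checkpoint–restart with undelivered-event collapsing.

It is aimed at people who study *simulator engineering* for compartmental
network models — the numerical core, data layout and event machinery that
large parallel neural simulators are built around — and who want a small,
fully testable implementation whose correctness contracts (solver
equivalence, operation-count identity, partition and permutation
invariance, checkpoint bit-reproducibility) can be exercised on a laptop.

## The model

Each neuron is a tree of unbranched cables (*sections*) discretized into
compartments. The membrane potential `v(x, t)` obeys the cable equation

    (d / 4·Ra) ∂²v/∂x² = cm ∂v/∂t + I_pas + I_ion + I_syn

with diameter `d` (µm), axial resistivity `Ra` (Ω·cm), specific capacitance
`cm` (µF/cm²), and passive, active (Hodgkin–Huxley) and synaptic current
densities on the right. Spatial discretization yields one unknown per
compartment and a tree-structured linear system per cell. Integration is
backward Euler with a fixed step (default `dt = 0.025 ms`); each step runs,
in order:

1. **Event delivery** — synaptic callbacks for every spike due in `(t, t+dt]`;
2. **Matrix assembly** — mechanism conductances/currents enter diagonal and
   right-hand side;
3. **Matrix resolution** — Gaussian elimination on the tree in
   parent-before-child node order (Hines ordering), which costs exactly the
   same number of multiply/divides as an unbranched cable of equal size;
4. **State update** — gating variables advance by the exponential rule
   `x ← x∞(v) + (x − x∞(v))·exp(−dt/τₓ(v))`;
5. **Threshold detection** — per-cell watchers convert upward crossings into
   spike events.

Spikes are exchanged between logical cell groups every *minimum NetCon
delay* interval; since no delivery can be due earlier than one mindelay
after its source spike, this is exactly equivalent to exchanging every
step, and simulations are bit-identical for any partition of cells into
groups. All randomness flows through a counter-based generator (a pure
function of a 4-word key and an integer counter), so results are
independent of call order and survive checkpointing as plain counters.

Built-in mechanisms: `pas`, `hh` (density), `expsyn`, `iclamp`, `gap`
(point), `netstim` (artificial spike source). All instances of one type
live in one Structure-of-Arrays pool — one contiguous array per parameter
and state — so kernels are plain vectorized expressions.

## Worked example

```python
import cablenet as cn

model = cn.ring_model(n_types=2, cells_per_type=8, ring_size=16,
                      n_dend=2, nseg_per_dend=2, seed=42)
state = cn.SimState(model, seed=42)
raster = cn.run(state, 50.0)
print(f"{len(raster)} spikes from {model.net.n_cells} cells "
      f"({state.n_nodes} compartments)")
for t, gid in raster[:5]:
    print(f"{t:8.3f} ms  gid {gid}")
print("solver multiply/divide count:", state.op_counter)
```

prints

```
36 spikes from 16 cells (80 compartments)
   1.650 ms  gid 0
   3.025 ms  gid 1
   4.400 ms  gid 2
   5.775 ms  gid 3
   7.150 ms  gid 4
solver multiply/divide count: 672000
```

Sixteen cells with random dendritic trees are wired into a ring; a current
kick makes cell 0 spike at 1.650 ms and the wave then circulates — each
successive gid fires ≈1.375 ms later (1 ms synaptic delay plus integration
time to threshold). The operation counter confirms the solver's cost:
`5·(n − c) + c = 336` multiply/divides per step for n = 80 nodes in c = 16
independent trees, times 2000 steps.

The same workflow is available from the shell:

```sh
cablenet run config.yaml            # simulate, write raster + probes
cablenet make-model config.yaml m/  # write a model archive, no simulation
cablenet run-archive m/ --tstop 50  # simulate from the archive
cablenet inspect m/                 # counts + manifest summary
cablenet resume config.yaml ck/ --tstop 100   # continue from a checkpoint
```

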
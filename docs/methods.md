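# Methods

## Scope and model

cablenet simulates networks of compartmental neurons under the standard
cable-equation formalism: each cell is a rooted tree of unbranched cables
split into `nseg` equal compartments, one membrane-potential unknown per
compartment, with membrane mechanisms (channels, synapses, stimuli)
contributing conductance and current at their node. Cells interact only
through delayed spike events (and, optionally, gap junctions); there is no
extracellular coupling, reaction–diffusion, or variable-step integration.

## Units

A single consistent unit system removes all per-step conversion factors:
voltage mV, time ms, conductance µS, current nA, capacitance nF (so
µS·mV = nA and nF·mV/ms = nA). Section parameters keep their conventional
units and are converted once at discretization:

- node area `π·diam·Δx` µm², with `Δx = length/nseg`;
- node capacitance `cm[µF/cm²]·area[µm²]·1e−5` nF;
- axial conductance to the neighboring node
  `1e2·π·diam²/(4·Ra·Δx)` µS;
- density-mechanism outputs convert as `S/cm² → µS` and `mA/cm² → nA`
  via `· area[µm²] · 1e−2`.

Nodes sit at segment centers; a child section attaches to the parent node
nearest its normalized attachment position, rounding down. Indexing is
0-based with parent sentinel −1; every cell satisfies `parent[i] < i`.

## Integration

Backward Euler with fixed `dt` (default 0.025 ms). For one step the
per-node equations give diagonal `d_i = cm_i/dt + Σ g_mech + Σ g_axial`,
off-diagonal `−g_axial` to the parent, and right-hand side
`(cm_i/dt + Σ g_mech)·v_i − Σ i_mech + injected`, where each mechanism
reports `(g, i)` such that its current at voltage `w` is `i + g·(w − v)`.
The tree system is solved by Gaussian elimination in node-index order
(parent-before-child): one reverse sweep eliminates every non-root node
into its parent, then roots solve directly and a forward sweep
back-substitutes. The multiply/divide count is `5` per non-root node plus
`1` per root — a function of size only, never of branching — and is
tallied in `op_counter`. A zero pivot raises a singular-system error.

Gating states advance *after* the voltage solve using end-of-step
voltages, by the unconditionally stable exponential rule
`x ← x∞ + (x − x∞)·e^(−dt/τ)`; there is no half-step staggering, a
deliberate simplification that keeps checkpoint state minimal and trades
second-order accuracy in time for a plainly analyzable first-order scheme.
Synaptic conductances decay exponentially between events; deliveries add
their weight at delivery time, before assembly, so an event due at `t+dt`
affects that same step's matrix. Gap junctions couple explicitly: the
self-conductance enters the matrix, the peer voltage is a snapshot from
the end of the previous step, refreshed after each solve. Voltage
initializes to −65 mV everywhere and gating states to their steady state
at that voltage.

Hodgkin–Huxley rate functions are the classic squid-axon forms
(α_m = 0.1(v+40)/(1−e^(−(v+40)/10)) etc., defaults g_Na = 0.12,
g_K = 0.036, g_L = 0.0003 S/cm², e_Na = 50, e_K = −77, e_L = −54.3 mV).
Removable singularities (α_m at −40 mV, α_n at −55 mV) switch to a 2-term
Taylor expansion when the exponential argument is below 1e−6.

## Events, groups and spike exchange

Cells are partitioned into logical *groups* — the unit a rank or thread
would own in a distributed run. Threshold watchers fire on upward
crossings (`v ≥ threshold`, rearming only after falling below), with the
spike timestamped at the end of the crossing step (no interpolation).
Spikes buffer per group and are fanned out to all matching NetCons every
*mindelay* (minimum NetCon delay) interval; with no NetCons the whole run
is one interval. Because every delivery is due at least one mindelay after
its source spike, exchange cadence cannot change results, and because
deliveries pop in the total order (time, source gid, NetCon id),
simulations are bit-identical for any group count — the partition
invariance contract that stands in for multi-rank execution.

Delays are not quantized to dt; due-time comparisons use a 1e−9 ms
tolerance to absorb floating accumulation of t. NetCon delays below dt are
rejected (they would require mid-interval exchange).

## Random numbers

All stochastic features draw from a counter-based generator: a pure
function of a 4-word 64-bit key and an integer counter, built from four
rounds of keyed splitmix64-style avalanche mixing (add key word and Weyl
increment, xor-shift-multiply finalizer; constants are frozen by golden
tests). Streams are keyed per (seed, gid, purpose), so draws are
independent of cell-group partitioning, call order and checkpointing — a
stream position is just an integer, stored and restored as such. Mapping
to [0,1) uses the top 53 bits. The netstim source blends regular and
Poisson firing: inter-event gaps are
`interval·((1−noise) + noise·Exp(1))`, with the first gap scaled by
`noise` so that `noise = 0` fires exactly at `start`.

## Node orderings and the locality metric

Two permutations of the flattened node array model SIMD-friendly layouts:
*interleaved* (node j of the c-th of N identical cells maps to
`j·N + c` within the type's block) and *constant depth* (sort by tree
depth, then type, then within-cell row rank, then cell — corresponding
nodes of identical cells adjacent, each type's roots first). Within one
cell's depth row, children are ordered round-robin over parents sorted by
descending child count, which separates two siblings by at least
⌊row/2⌋ whenever no sibling group exceeds half the row. Both schemes
preserve parent-before-child, so the solver runs unchanged; only the
elimination order (and hence the last-bit roundoff) differs.

Since SIMD runtimes cannot be measured meaningfully on one core, the
observable stand-in is `parent_contiguity`: partition non-root nodes into
consecutive warps (default 32) and report the fraction of warps whose
parents form a consecutive ascending run — the contiguous-load vs
strided-load distinction made precise. Interleaving ≥32 identical cells
per type yields 1.0 by construction; fewer cells per type degrade it
monotonically, and constant-depth ordering dominates interleaving when
every cell is unique.

## Archives and checkpointing

A model archive is a directory: a JSON manifest plus one `.npy` dataset
per array, written group by group (so a large model can be serialized one
subset at a time) and byte-deterministic for a fixed model. No dataset
stores an absolute address: every cross-reference is an integer offset
whose meaning a *semantic tag* in the manifest declares (`voltage_offset`,
`area_offset`, `point_process_index`, `netcon_target`, `presyn_index`,
`peer_voltage_offset`); unknown tags are fatal on read, as are version or
mechanism-registry digest mismatches. Pool rows are stored in natural
(unpermuted) node order, so archives are independent of the in-memory
layout. Truncated datasets are detected against the manifest's counts.

A checkpoint stores t, step index, voltages, per-pool states, RNG stream
positions, watcher arm flags — and pending events in *collapsed* form:
every undelivered delivery is folded back into its originating source
event, so one (gid, spike time) pair is kept regardless of fan-out.
Restore re-fans stored source events through the NetCons and drops
regenerated deliveries already due (`delivery_time ≤ t`, so events exactly
at the checkpoint time count as delivered and are never duplicated).
Because delivery times are recomputed by the same expression that
produced them originally, a split run continues bit-identically; a
checkpoint taken immediately after a restore is byte-identical to the one
restored. Alternative stimuli can be explored from one checkpoint by
re-keying the netstim streams at restore; trajectories then diverge only
after the restore time.

## Synthetic workloads

The generators are the package's only data source; there are no external
datasets. The multiple-ring benchmark builds `n_types` random dendritic
branching patterns (each dendrite attaches uniformly at random to an
existing section below a depth cap of 5, drawn from the counter RNG), with
all cells of a type sharing one topology and every cell the same node
count. Cells are wired into rings (cell k excites cell k+1 mod ring size
through a soma ExpSyn, weight 0.05 µS, delay 1.0 ms, τ 2 ms, reversal
0 mV) and the first cell of each ring gets a 1 nA, 1 ms current kick — the
wave then circulates indefinitely. Somas (20×20 µm) carry HH channels;
dendrites (2 µm diameter) are passive (g = 0.001 S/cm², e = −65 mV).
Test networks use 16–64 cells over 30–100 ms and 8-node cells; the
bookkeeping configuration (4096 types × 32 cells, 40 dendrites of 2
segments, 3-segment soma = 83 nodes/cell, 10,878,976 nodes total) is
instantiated for counting only. These sizes keep the full suite and the
acceptance script to tens of seconds while still exercising every
invariant at network scale.

What the workloads do **not** emulate: realistic reconstructed
morphologies, heterogeneous channel repertoires, conductance
distributions fit to data, or biologically calibrated connectivity.
Passing tests therefore demonstrate the *engine contracts* — numerical
equivalence, determinism, layout/partition invariance, serialization
fidelity — not the biological validity of any particular network.

## Known limitations

- First-order accuracy in dt (no staggered half-step states, no
  Crank–Nicolson); stiff mechanism ODEs requiring implicit per-mechanism
  solves are out of scope — all built-in states admit the exponential
  update.
- Spike times are quantized to step boundaries (no threshold
  interpolation).
- Gap junctions are explicit in the peer voltage, which is stable for the
  small coupling conductances used here but not for arbitrarily stiff
  coupling with large dt.
- Single-process execution only: groups are a correctness contract, not a
  parallelization; the locality metric stands in for SIMD runtime effects.
- Mechanisms are built-in Python/numpy kernels behind a registry; there is
  no model-description-language compiler, and user extensions register
  kernels obeying the same SoA contract.
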
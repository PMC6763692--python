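"""Event machinery: counter-based random streams, NetCon fan-out, the delivery
priority queue, and minimum-delay spike exchange between cell groups.

The design mirrors the message-passing structure of large parallel network
simulators, recast for a single process: cells are partitioned into logical
*groups* (the unit a rank/thread would own), spikes generated inside a group
are buffered, and every minimum-NetCon-delay interval all buffers are gathered
and fanned out to the NetCons of every group.  Because a delivery can never be
due earlier than one mindelay after its source spike, exchanging at mindelay
granularity is exactly equivalent to exchanging every step.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, WiringError

# --------------------------------------------------------------------------
# Counter-based random number generation
# --------------------------------------------------------------------------
# A pure function of (key, counter): no hidden state, so random streams are
# reproducible regardless of call order, cell-group partitioning, or
# checkpoint/restart (a stream position is just an integer counter).
#
# Mixing: four rounds, each injecting one 64-bit key word plus a Weyl
# increment and applying a splitmix64-style xor-shift-multiply avalanche.
# The constants below are fixed by golden-value tests.

_MULT1 = np.uint64(0xBF58476D1CE4E5B9)
_MULT2 = np.uint64(0x94D049BB133111EB)
_WEYL = np.uint64(0x9E3779B97F4A7C15)  # 2^64 / golden ratio
_SEED0 = np.uint64(0x243F6A8885A308D3)  # pi fraction, key-derivation start

_INV53 = float(2.0 ** -53)


def _mix64(x: np.uint64) -> np.uint64:
    """splitmix64 finalizer: full-avalanche bijection on 64-bit words."""
    x = x ^ (x >> np.uint64(30))
    x = x * _MULT1
    x = x ^ (x >> np.uint64(27))
    x = x * _MULT2
    x = x ^ (x >> np.uint64(31))
    return x


def counter_rng(key, counter):
    """Uniform variate(s) in [0, 1) from a 4-word key and an integer counter.

    Parameters
    ----------
    key : sequence of 4 ints
        Stream identity (derive with :func:`derive_key`).
    counter : int or array of ints
        Position in the stream.

    Returns
    -------
    float or ndarray of float64 in [0, 1).  Pure: identical inputs give
    bit-identical outputs.
    """
    key = tuple(key)
    if len(key) != 4:
        raise ConfigurationError("counter_rng key must have exactly 4 words")
    scalar = np.isscalar(counter)
    with np.errstate(over="ignore"):  # modular 64-bit arithmetic is intended
        x = np.asarray(counter, dtype=np.uint64)
        for i, k in enumerate(key):
            x = x + np.uint64(k & 0xFFFFFFFFFFFFFFFF) + np.uint64(i + 1) * _WEYL
            x = _mix64(x)
        u = (x >> np.uint64(11)).astype(np.float64) * _INV53
    return float(u) if scalar else u


def derive_key(*parts) -> tuple:
    """Derive a 4-word RNG key from a mixture of ints and strings.

    Streams are conventionally keyed per (seed, gid, purpose) so that results
    do not depend on cell-group partitioning or call order.
    """
    acc = _SEED0
    with np.errstate(over="ignore"):
        for p in parts:
            if isinstance(p, str):
                data = p.encode("utf-8")
                w = np.uint64(0)
                for b in data:
                    w = _mix64(w + np.uint64(b) + _WEYL)
                acc = _mix64(acc ^ w)
            else:
                acc = _mix64(acc ^ np.uint64(int(p) & 0xFFFFFFFFFFFFFFFF))
        return tuple(
            int(_mix64(acc + np.uint64(i + 1) * _WEYL)) for i in range(4)
        )


def uniform_stream(key, start: int, n: int) -> np.ndarray:
    """n consecutive uniforms from counters start .. start+n-1."""
    return counter_rng(key, np.arange(start, start + n, dtype=np.uint64))


# --------------------------------------------------------------------------
# Connection and spike-source records
# --------------------------------------------------------------------------

#: due-time comparison tolerance (ms), absorbs floating accumulation of t
TIME_TOL = 1e-9


@dataclass
class NetCon:
    """Delayed, weighted connection from a spike source to a synapse instance.

    ``target`` resolves to an instance of a mechanism pool that has a
    net_receive kernel; ``index`` is the global creation index used as the
    final tie-break of simultaneous deliveries.
    """

    index: int
    src_gid: int
    target: tuple  # (pool key, instance index)
    weight: float  # uS
    delay: float   # ms, >= dt


@dataclass
class PreSyn:
    """Per-cell threshold watcher turning a voltage crossing into a spike.

    Artificial cells carry a PreSyn with ``watch_node=None``; their spikes are
    produced by their own event schedule rather than a crossing.
    """

    gid: int
    watch_node: int | None
    threshold: float = -20.0  # mV
    armed: bool = True


@dataclass(frozen=True)
class SpikeEvent:
    """A delivery event, still carrying its originating source spike time.

    ``spike_time`` lets a checkpoint collapse pending deliveries back into
    the single source event they came from, without any float roundtrip.
    """

    delivery_time: float
    src_gid: int
    netcon: int
    spike_time: float


class EventQueue:
    """Time-ordered multiset of deliveries; ties broken (time, src_gid, netcon)."""

    def __init__(self):
        self._heap: list[tuple[float, int, int, float]] = []

    def __len__(self) -> int:
        return len(self._heap)

    def push(self, delivery_time: float, src_gid: int, netcon: int,
             spike_time: float) -> None:
        heapq.heappush(self._heap, (delivery_time, src_gid, netcon, spike_time))

    def peek_time(self) -> float:
        return self._heap[0][0]

    def pop(self) -> SpikeEvent:
        t, gid, nc, ts = heapq.heappop(self._heap)
        return SpikeEvent(t, gid, nc, ts)

    def pending(self) -> list[SpikeEvent]:
        """Snapshot of all queued events in pop order (non-destructive)."""
        return [SpikeEvent(*e) for e in sorted(self._heap)]

    def clear(self) -> None:
        self._heap.clear()


# --------------------------------------------------------------------------
# Exchange operations
# --------------------------------------------------------------------------

def compute_mindelay(netcons, tstop: float, dt: float) -> float:
    """Minimum NetCon delay: the global spike-exchange interval.

    With no NetCons the whole run is one exchange interval (returns tstop).
    A delay below dt would require mid-interval exchange and is rejected.
    """
    if not netcons:
        return tstop
    delays = [nc.delay for nc in netcons]
    mind = min(delays)
    if mind < dt - TIME_TOL:
        raise ConfigurationError(
            f"NetCon delay {mind} ms is smaller than dt={dt} ms"
        )
    return mind


def index_netcons_by_source(netcons) -> dict:
    """src_gid -> list of NetCons in creation order."""
    table: dict[int, list[NetCon]] = {}
    for nc in netcons:
        table.setdefault(nc.src_gid, []).append(nc)
    return table


def spike_exchange(fired, netcons_by_src, known_gids, queue: EventQueue) -> int:
    """Fan fired source events out to all matching NetCons.

    Parameters
    ----------
    fired : iterable of (gid, spike_time)
        Source events gathered from all cell-group buffers.
    netcons_by_src : dict gid -> [NetCon]
    known_gids : container of all valid source gids
    queue : EventQueue receiving the delivery events

    Returns the number of deliveries enqueued.  Every source spike with k
    matching NetCons produces exactly k deliveries.
    """
    n = 0
    for gid, t_spike in fired:
        if gid not in known_gids:
            raise WiringError(f"spike from unknown source gid {gid}")
        for nc in netcons_by_src.get(gid, ()):
            queue.push(t_spike + nc.delay, gid, nc.index, t_spike)
            n += 1
    return n


def deliver_until(queue: EventQueue, t_limit: float, deliver) -> int:
    """Pop and deliver every event due at or before t_limit (+tolerance).

    ``deliver(event)`` invokes the target's net_receive.  Pop order is the
    total (time, src_gid, netcon) order, so simultaneous deliveries to one
    synapse always arrive in a fixed sequence.
    """
    n = 0
    while len(queue) and queue.peek_time() <= t_limit + TIME_TOL:
        deliver(queue.pop())
        n += 1
    return n
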
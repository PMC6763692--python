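"""Structure-of-Arrays mechanism framework and built-in membrane mechanisms.

Every mechanism type stores the data of all its instances in one
:class:`MechanismPool`: each parameter and each state variable is a separate
contiguous array of length ``count`` (SoA), never interleaved per instance,
so kernels are plain vectorized array expressions.

Kernel contracts
----------------
current(pool, v, t, dt) -> (g, i)
    Per-instance conductance g [uS] and current i [nA] evaluated at the
    per-instance voltages v [mV]; the current at a nearby voltage w is
    approximated by ``i + g * (w - v)``.  Density mechanisms compute a
    current density [mA/cm^2] and convert to nA with ``* area[um^2] * 1e-2``
    (and conductance S/cm^2 -> uS likewise).
state(pool, v, t, dt)
    Advance internal states one step, given end-of-step voltages.
net_receive(pool, idx, weight, t)
    Event callback on one instance (synapses and artificial cells).
init(pool, v)
    Set states to their steady state at the initial voltage.

Built-ins: ``pas`` and ``hh`` (density), ``expsyn``, ``iclamp`` and ``gap``
(point), ``netstim`` (artificial).  Further types can be added through
:func:`register_mechanism`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import (
    NumericalStateError,
    ParameterError,
    RegistrationError,
    WiringError,
)
from .network import counter_rng

DENSITY, POINT, ARTIFICIAL = "density", "point", "artificial"

#: S/cm^2 * um^2 -> uS, and mA/cm^2 * um^2 -> nA
DENSITY_TO_ABS = 1e-2


@dataclass(frozen=True)
class MechanismSpec:
    """Declaration of one mechanism type.

    ``param_defs`` / ``state_defs`` are ordered name -> (unit, default) and
    name -> initial-value maps; their order fixes the array layout in pools
    and archives.  Density mechanisms cannot have net_receive; artificial
    mechanisms have no voltage kernels.
    """

    name: str
    kind: str
    param_defs: dict = field(default_factory=dict)   # name -> (unit, default)
    state_defs: dict = field(default_factory=dict)   # name -> initial value
    has_net_receive: bool = False
    current_kernel: Callable | None = None
    state_kernel: Callable | None = None
    net_receive_kernel: Callable | None = None
    init_kernel: Callable | None = None
    int_defs: tuple = ()  # names of per-instance integer fields

    def __post_init__(self):
        if self.kind not in (DENSITY, POINT, ARTIFICIAL):
            raise RegistrationError(f"unknown mechanism kind {self.kind!r}")
        if self.kind == DENSITY and self.has_net_receive:
            raise RegistrationError(
                f"density mechanism {self.name!r} cannot have net_receive"
            )
        if self.kind == ARTIFICIAL and (self.current_kernel or self.state_kernel):
            raise RegistrationError(
                f"artificial mechanism {self.name!r} cannot have voltage kernels"
            )


class MechanismPool:
    """SoA storage for all instances of one mechanism type in one cell group.

    ``node_index`` maps instances to flattened node indices (ascending);
    artificial mechanisms use -1.  ``params``/``states`` hold one contiguous
    float64 array per variable, ``ints`` one int64/uint64 array per integer
    field (e.g. gap-junction peer nodes, RNG counters).
    """

    def __init__(self, mech: MechanismSpec, node_index, areas=None):
        self.mech = mech
        self.node_index = np.asarray(node_index, dtype=np.int64)
        if len(self.node_index) > 1 and np.any(np.diff(self.node_index) < 0):
            raise WiringError(
                f"pool {mech.name}: node_index must be ascending"
            )
        self.count = len(self.node_index)
        self.params = {
            name: np.full(self.count, default, dtype=np.float64)
            for name, (_unit, default) in mech.param_defs.items()
        }
        self.states = {
            name: np.full(self.count, init, dtype=np.float64)
            for name, init in mech.state_defs.items()
        }
        self.ints = {
            name: np.zeros(self.count, dtype=np.int64)
            for name in mech.int_defs
        }
        self.area = (
            np.asarray(areas, dtype=np.float64)
            if areas is not None
            else np.zeros(self.count)
        )
        self.rng_keys = None  # artificial sources: (count, 4) uint64 array

    def eval_current(self, v, t, dt):
        if not np.all(np.isfinite(v)):
            raise NumericalStateError(
                f"pool {self.mech.name}: non-finite voltage"
            )
        return self.mech.current_kernel(self, v, t, dt)

    def advance_state(self, v, t, dt):
        if self.mech.state_kernel is not None:
            self.mech.state_kernel(self, v, t, dt)

    def net_receive(self, idx, weight, t):
        if self.mech.net_receive_kernel is None:
            raise WiringError(
                f"mechanism {self.mech.name} has no net_receive"
            )
        self.mech.net_receive_kernel(self, idx, weight, t)

    def init(self, v):
        if self.mech.init_kernel is not None:
            self.mech.init_kernel(self, v)


# --------------------------------------------------------------------------
# Registry
# --------------------------------------------------------------------------

_REGISTRY: dict[str, tuple[int, MechanismSpec]] = {}


def register_mechanism(spec: MechanismSpec) -> int:
    """Register a mechanism type; returns its dense integer type id."""
    if spec.name in _REGISTRY:
        raise RegistrationError(f"mechanism {spec.name!r} already registered")
    type_id = len(_REGISTRY)
    _REGISTRY[spec.name] = (type_id, spec)
    return type_id


def get_mechanism(name: str) -> MechanismSpec:
    try:
        return _REGISTRY[name][1]
    except KeyError:
        raise RegistrationError(f"unknown mechanism {name!r}") from None


def mechanism_id(name: str) -> int:
    return _REGISTRY[name][0]


def registered_mechanisms() -> list[str]:
    """Names in registration (id) order."""
    return sorted(_REGISTRY, key=lambda n: _REGISTRY[n][0])


def registry_digest() -> str:
    """Stable digest of the registry layout, stored in archives."""
    import hashlib

    h = hashlib.sha256()
    for name in registered_mechanisms():
        spec = _REGISTRY[name][1]
        h.update(name.encode())
        h.update(spec.kind.encode())
        for p, (unit, default) in spec.param_defs.items():
            h.update(f"{p}:{unit}:{default!r}".encode())
        for s, init in spec.state_defs.items():
            h.update(f"{s}:{init!r}".encode())
        for s in spec.int_defs:
            h.update(s.encode())
    return h.hexdigest()


# --------------------------------------------------------------------------
# Hodgkin-Huxley rate functions
# --------------------------------------------------------------------------
# Classic squid-axon forms (voltages in mV, rates in 1/ms).  The removable
# singularities of alpha_m (v = -40) and alpha_n (v = -55) are evaluated by a
# 2-term Taylor expansion when the exponential argument is below 1e-6.

_SINGULAR_TOL = 1e-6


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with its limit y * (1 + x/(2y)) near x = 0."""
    x = np.asarray(x, dtype=np.float64)
    small = np.abs(x / y) < _SINGULAR_TOL
    safe = np.where(small, 1.0, x)
    out = np.where(
        small,
        y * (1.0 + x / (2.0 * y)),
        safe / (1.0 - np.exp(-safe / y)),
    )
    return out


def hh_rates(v):
    """Six voltage-dependent rate constants (1/ms) of the HH channel gates.

    Returns (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n); accepts a
    scalar or an array, strictly positive on the physiological range.
    """
    v = np.asarray(v, dtype=np.float64)
    a_m = 0.1 * _vtrap(v + 40.0, 10.0)
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    a_n = 0.01 * _vtrap(v + 55.0, 10.0)
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def _exp_gate_update(x, alpha, beta, dt):
    """Exponential-integrator gate update x <- x_inf + (x - x_inf)e^(-dt/tau).

    Unconditionally stable: x stays in [0, 1] for any dt > 0.
    """
    tau = 1.0 / (alpha + beta)
    inf = alpha * tau
    return inf + (x - inf) * np.exp(-dt / tau)


# --------------------------------------------------------------------------
# Built-in mechanisms
# --------------------------------------------------------------------------

def _pas_current(pool, v, t, dt):
    g = pool.params["g"] * pool.area * DENSITY_TO_ABS  # S/cm^2 -> uS
    i = g * (v - pool.params["e"])
    return g, i


def _hh_current(pool, v, t, dt):
    m, h, n = pool.states["m"], pool.states["h"], pool.states["n"]
    p = pool.params
    conv = pool.area * DENSITY_TO_ABS
    g_na = p["gnabar"] * m ** 3 * h * conv
    g_k = p["gkbar"] * n ** 4 * conv
    g_l = p["gl"] * conv
    g = g_na + g_k + g_l
    i = g_na * (v - p["ena"]) + g_k * (v - p["ek"]) + g_l * (v - p["el"])
    return g, i


def _hh_state(pool, v, t, dt):
    a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(v)
    s = pool.states
    s["m"][:] = _exp_gate_update(s["m"], a_m, b_m, dt)
    s["h"][:] = _exp_gate_update(s["h"], a_h, b_h, dt)
    s["n"][:] = _exp_gate_update(s["n"], a_n, b_n, dt)


def _hh_init(pool, v):
    a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(v)
    s = pool.states
    s["m"][:] = a_m / (a_m + b_m)
    s["h"][:] = a_h / (a_h + b_h)
    s["n"][:] = a_n / (a_n + b_n)


def _expsyn_current(pool, v, t, dt):
    g = pool.states["g"]
    return g.copy(), g * (v - pool.params["e"])


def _expsyn_state(pool, v, t, dt):
    tau = pool.params["tau"]
    if np.any(tau <= 0):
        raise ParameterError("expsyn: tau must be positive")
    pool.states["g"] *= np.exp(-dt / tau)


def _expsyn_receive(pool, idx, weight, t):
    pool.states["g"][idx] += weight


def _iclamp_current(pool, v, t, dt):
    p = pool.params
    active = (t >= p["start"] - 1e-9) & (t < p["start"] + p["dur"] - 1e-9)
    g = np.zeros(pool.count)
    i = np.where(active, -p["amp"], 0.0)  # inward (depolarizing) injection
    return g, i


def _gap_current(pool, v, t, dt):
    if np.any(pool.ints["peer_node"] < 0):
        raise WiringError("gap: unpaired instance (peer_node unset)")
    g = pool.params["g"]
    i = g * (v - pool.states["v_peer"])
    return g.copy(), i


def _gap_snapshot(pool, v_global):
    """End-of-step peer-voltage refresh (explicit gap coupling)."""
    pool.states["v_peer"][:] = v_global[pool.ints["peer_node"]]


def netstim_events(start, interval, number, noise, rng_key) -> np.ndarray:
    """Event times of one stochastic/regular stimulus source.

    noise = 0 gives regular times ``start + k * interval``; noise = 1 draws
    exponential inter-event intervals of mean ``interval`` from the counter
    RNG stream ``rng_key`` (intermediate noise blends the two).  The first
    interval (start -> first event) is scaled by noise so that noise = 0
    fires exactly at ``start``.
    """
    if interval <= 0:
        raise ParameterError("netstim: interval must be positive")
    if number < 0:
        raise ParameterError("netstim: number must be >= 0")
    if not (0.0 <= noise <= 1.0):
        raise ParameterError("netstim: noise must be in [0, 1]")
    if number == 0:
        return np.empty(0, dtype=np.float64)
    if noise == 0.0:
        return start + interval * np.arange(number, dtype=np.float64)
    u = counter_rng(rng_key, np.arange(number, dtype=np.uint64))
    exp_draw = -np.log1p(-u)  # Exp(1)
    gaps = interval * ((1.0 - noise) + noise * exp_draw)
    gaps[0] = noise * interval * exp_draw[0]
    return start + np.cumsum(gaps)


def _netstim_receive(pool, idx, weight, t):  # pragma: no cover - extension hook
    pass


PAS = MechanismSpec(
    name="pas", kind=DENSITY,
    param_defs={"g": ("S/cm2", 0.001), "e": ("mV", -65.0)},
    current_kernel=_pas_current,
)

HH = MechanismSpec(
    name="hh", kind=DENSITY,
    param_defs={
        "gnabar": ("S/cm2", 0.12), "gkbar": ("S/cm2", 0.036),
        "gl": ("S/cm2", 0.0003), "ena": ("mV", 50.0),
        "ek": ("mV", -77.0), "el": ("mV", -54.3),
    },
    state_defs={"m": 0.0, "h": 0.0, "n": 0.0},
    current_kernel=_hh_current, state_kernel=_hh_state, init_kernel=_hh_init,
)

EXPSYN = MechanismSpec(
    name="expsyn", kind=POINT,
    param_defs={"tau": ("ms", 2.0), "e": ("mV", 0.0)},
    state_defs={"g": 0.0},
    has_net_receive=True,
    current_kernel=_expsyn_current, state_kernel=_expsyn_state,
    net_receive_kernel=_expsyn_receive,
)

ICLAMP = MechanismSpec(
    name="iclamp", kind=POINT,
    param_defs={"amp": ("nA", 0.0), "start": ("ms", 0.0), "dur": ("ms", 0.0)},
    current_kernel=_iclamp_current,
)

GAP = MechanismSpec(
    name="gap", kind=POINT,
    param_defs={"g": ("uS", 0.0)},
    state_defs={"v_peer": -65.0},
    current_kernel=_gap_current,
    int_defs=("peer_node",),
)

NETSTIM = MechanismSpec(
    name="netstim", kind=ARTIFICIAL,
    param_defs={
        "start": ("ms", 0.0), "interval": ("ms", 10.0),
        "number": ("1", 0.0), "noise": ("1", 0.0),
    },
    has_net_receive=True,
    net_receive_kernel=_netstim_receive,
    int_defs=("emitted",),
)

for _spec in (PAS, HH, EXPSYN, ICLAMP, GAP, NETSTIM):
    register_mechanism(_spec)

GAP_SNAPSHOT = _gap_snapshot  # post-solve hook used by the engine
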
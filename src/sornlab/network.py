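"""Core SORN dynamics: state container, update equation and plasticity rules.

The excitatory state evolves as

    x(t+1) = Theta( W_ee x(t) - W_ei y(t) + W_eu u(t) - T_e(t) )
    y(t+1) = Theta( W_ie x(t+1) - T_i )

with Theta the elementwise Heaviside function mapping strictly positive
activations to 1.  Three plasticity rules shape the excitatory population:

* STDP:  dW_ee = eta_stdp * (x(t+1) x(t)' - x(t) x(t+1)') on existing
  synapses, clipped at zero.
* Synaptic normalization (SN):  every nonzero weight is pulled towards unit
  incoming *and* outgoing sums,
  W_ij <- 0.9 W_ij + 0.1 W_ij / (0.5 sum_k W_ik + 0.5 sum_k W_kj).
* Intrinsic plasticity (IP):  T_e <- T_e + eta_ip (x - H), with per-neuron
  targets H drawn around ``h_ip``.

``run_phase`` advances the network for a whole phase through a compiled
kernel; the single-step functions in this module are the readable reference
implementation of the same arithmetic and are interchangeable with it.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .params import SornParams

__all__ = [
    "SornState",
    "SpikeRecording",
    "PhaseProtocol",
    "init_network",
    "step",
    "apply_stdp",
    "apply_synaptic_normalization",
    "apply_ip",
    "run_phase",
    "spawn_rngs",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SornState:
    """Full mutable network state.

    ``w_ee`` is stored densely with an explicit boolean synapse mask ``conn``
    (``w_ee[i, j] > 0`` only where ``conn[i, j]``); at the network sizes this
    model targets a dense array with a mask is the faster sparse
    representation.  ``w_eu`` maps input letters to their excitatory target
    pools with constant weight ``w_in``.
    """

    params: SornParams
    x: np.ndarray
    y: np.ndarray
    t_e: np.ndarray
    t_i: np.ndarray
    h_targets: np.ndarray
    w_ee: np.ndarray
    conn: np.ndarray
    w_ei: np.ndarray
    w_ie: np.ndarray
    w_eu: Optional[np.ndarray] = None

    @property
    def n_exc(self) -> int:
        return self.x.shape[0]

    @property
    def n_inh(self) -> int:
        return self.y.shape[0]

    def copy(self) -> "SornState":
        return SornState(
            params=copy.deepcopy(self.params),
            x=self.x.copy(),
            y=self.y.copy(),
            t_e=self.t_e.copy(),
            t_i=self.t_i.copy(),
            h_targets=self.h_targets.copy(),
            w_ee=self.w_ee.copy(),
            conn=self.conn.copy(),
            w_ei=self.w_ei.copy(),
            w_ie=self.w_ie.copy(),
            w_eu=None if self.w_eu is None else self.w_eu.copy(),
        )

    def check(self) -> None:
        """Raise if the state violates its invariants."""
        for v, name in ((self.x, "x"), (self.y, "y")):
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValueError(f"{name} must be strictly binary")
        if np.diagonal(self.w_ee).any():
            raise ValueError("autapses are not allowed")
        if (self.w_ee < 0).any() or (self.w_ei < 0).any() or (self.w_ie < 0).any():
            raise ValueError("synaptic weights must be non-negative")
        if ((self.w_ee > 0) & ~self.conn).any():
            raise ValueError("nonzero weight outside the synapse mask")


@dataclass
class SpikeRecording:
    """Binary raster of one phase, annotated with the input letter per step.

    Row ``t`` holds the state x(t+1) produced by the input presented at step
    ``t``; ``letters[t]`` is that input's symbol (``"_"`` for blanks), so the
    evoked state of a letter is the state recorded against it.
    """

    spikes: np.ndarray                    # (T, n_exc) uint8
    letters: np.ndarray                   # (T,) unicode
    phase: str = ""
    inhibitory_spikes: Optional[np.ndarray] = None
    connection_fraction: Optional[np.ndarray] = None
    connection_sample_every: int = 0
    noise_flips: int = 0

    def __post_init__(self) -> None:
        if self.spikes.shape[0] != self.letters.shape[0]:
            raise ValueError("letters must annotate every recorded step")

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[0]

    def rates(self) -> np.ndarray:
        """Per-neuron mean firing rate over the recording."""
        return self.spikes.mean(axis=0)


@dataclass
class PhaseProtocol:
    """Symbol stream plus plasticity flags for one simulation phase.

    ``drive`` holds one pre-computed feed-forward input vector per distinct
    symbol (row 0 is conventionally the blank), and ``sym`` indexes into it
    per step; ``letters`` carries the human-readable annotation.
    """

    sym: np.ndarray                       # (T,) int64 row index into drive
    drive: np.ndarray                     # (n_rows, n_exc) float64
    letters: np.ndarray                   # (T,) unicode
    stdp: bool = False
    sn: bool = False
    ip: bool = True
    structural: bool = False
    name: str = ""
    shuffle_after: bool = True
    record_inhibitory: bool = False
    connection_sample_every: int = 0

    def __post_init__(self) -> None:
        if self.sym.shape[0] != self.letters.shape[0]:
            raise ValueError("sym and letters must have equal length")
        if self.sym.size and (self.sym.min() < 0 or self.sym.max() >= self.drive.shape[0]):
            raise ValueError("sym indexes outside the drive table")

    @property
    def n_steps(self) -> int:
        return self.sym.shape[0]


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def spawn_rngs(seed, names: Sequence[str]) -> dict:
    """Independent child generators for the named random sources."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _evenly_spaced(n: int, upper: float) -> np.ndarray:
    """n values evenly spaced strictly inside (0, upper)."""
    return upper * np.arange(1, n + 1) / (n + 1)


def init_network(
    params: SornParams,
    rng: Optional[np.random.Generator] = None,
    w_eu: Optional[np.ndarray] = None,
    sn_tol: float = 1e-4,
    sn_max_iter: int = 10_000,
) -> SornState:
    """Create and normalize a fresh network state.

    The sparse E->E topology is drawn with density ``p_ee`` (no autapses),
    weights uniform on [0, 1] and then iterated through synaptic
    normalization until incoming and outgoing sums are within ``sn_tol`` of
    one.  Inhibitory weight rows are scaled to unit sum.  Thresholds are
    evenly spaced in their intervals and assigned to neurons in randomly
    permuted order; the initial excitatory state is Bernoulli with
    per-neuron probability T_e(0).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, ni = params.n_exc, params.n_inh

    conn = rng.random((n, n)) < params.p_ee
    np.fill_diagonal(conn, False)
    w_ee = np.where(conn, rng.random((n, n)), 0.0)

    w_ei = rng.random((n, ni))
    w_ei /= w_ei.sum(axis=1, keepdims=True)
    w_ie = rng.random((ni, n))
    w_ie /= w_ie.sum(axis=1, keepdims=True)

    t_e = rng.permutation(_evenly_spaced(n, params.t_e_max))
    t_i = rng.permutation(_evenly_spaced(ni, params.t_i_max))
    h_targets = rng.uniform(params.h_ip - params.eps_ip, params.h_ip + params.eps_ip, size=n)

    x0 = (rng.random(n) < t_e).astype(float)
    y0 = np.zeros(ni)

    state = SornState(
        params=params, x=x0, y=y0, t_e=t_e, t_i=t_i, h_targets=h_targets,
        w_ee=w_ee, conn=conn, w_ei=w_ei, w_ie=w_ie, w_eu=w_eu,
    )
    for _ in range(sn_max_iter):
        apply_synaptic_normalization(state)
        rs = state.w_ee.sum(axis=1)
        cs = state.w_ee.sum(axis=0)
        dev = max(
            np.abs(rs[rs > 0] - 1.0).max(initial=0.0),
            np.abs(cs[cs > 0] - 1.0).max(initial=0.0),
        )
        if dev < sn_tol:
            break
    return state


# ---------------------------------------------------------------------------
# single-step operations (reference path)
# ---------------------------------------------------------------------------

def step(
    state: SornState,
    input_drive: Optional[np.ndarray] = None,
    noise: Optional[np.ndarray] = None,
) -> SornState:
    """Advance the network by one deterministic update (Eqs. of the model).

    ``input_drive`` is the feed-forward drive vector W_eu u(t) (zeros or
    ``None`` for a blank).  Returns the same state object, mutated.
    """
    act = state.w_ee @ state.x - state.w_ei @ state.y - state.t_e
    if input_drive is not None:
        act = act + input_drive
    if noise is not None:
        act = act + noise
    x_new = (act > 0.0).astype(float)
    y_new = ((state.w_ie @ x_new - state.t_i) > 0.0).astype(float)
    state.x = x_new
    state.y = y_new
    return state


def apply_stdp(state: SornState, x_prev: np.ndarray, x_now: np.ndarray) -> SornState:
    """Additive STDP on existing synapses, clipped at zero.

    Potentiates W_ij when a spike in i (``x_now``) follows a spike in j
    (``x_prev``); depresses the reverse order.  If ``prune_zero_weights`` is
    set, synapses reaching zero are removed from the structure.
    """
    dw = np.outer(x_now, x_prev) - np.outer(x_prev, x_now)
    upd = state.conn & (dw != 0)
    if upd.any():
        state.w_ee[upd] = np.maximum(
            state.w_ee[upd] + state.params.eta_stdp * dw[upd], 0.0
        )
        if state.params.prune_zero_weights:
            dead = upd & (state.w_ee == 0.0)
            state.conn[dead] = False
    return state


def apply_synaptic_normalization(state: SornState) -> SornState:
    """One iterative SN update towards unit incoming and outgoing sums."""
    w = state.w_ee
    if (w < 0).any():
        raise ValueError("synaptic normalization requires non-negative weights")
    rs = w.sum(axis=1)
    cs = w.sum(axis=0)
    denom = 0.5 * rs[:, None] + 0.5 * cs[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        upd = 0.9 * w + 0.1 * w / denom
    state.w_ee = np.where((w > 0) & (denom > 0), upd, w)
    return state


def apply_ip(state: SornState, x_now: np.ndarray) -> SornState:
    """Intrinsic plasticity: thresholds track per-neuron target rates."""
    state.t_e = state.t_e + state.params.eta_ip * (x_now - state.h_targets)
    return state


def structural_plasticity(state: SornState, rng: np.random.Generator) -> SornState:
    """With probability ``structural_rate``, create one new random synapse."""
    p = state.params
    if rng.random() < p.structural_rate:
        i = int(rng.integers(p.n_exc))
        j = int(rng.integers(p.n_exc))
        if i != j and not state.conn[i, j]:
            state.conn[i, j] = True
            state.w_ee[i, j] = p.structural_weight
    return state


# ---------------------------------------------------------------------------
# phase execution
# ---------------------------------------------------------------------------

def _adjacency(conn: np.ndarray):
    n = conn.shape[0]
    adj = np.zeros((n, n), dtype=np.int64)
    deg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        js = np.flatnonzero(conn[i])
        deg[i] = js.size
        adj[i, : js.size] = js
    return adj, deg


def run_phase(
    state: SornState,
    protocol: PhaseProtocol,
    rng: np.random.Generator,
    _python_reference: bool = False,
) -> tuple[SornState, SpikeRecording]:
    """Simulate one phase in place and return the spike recording.

    During self-organization phases STDP, SN and (optionally) structural
    plasticity are active; during training/testing phases only IP remains on
    to keep the average activity stable.  At the end of the phase the
    excitatory state vector is shuffled (uniform random permutation across
    neurons) unless ``protocol.shuffle_after`` is false.
    """
    p = state.params
    T = protocol.n_steps
    n, ni = p.n_exc, p.n_inh
    struct_on = bool(protocol.structural and p.structural_rate > 0.0)

    # pre-generate all randomness so the inner loop is deterministic
    if struct_on:
        struct_u = rng.random(T)
        struct_i = rng.integers(0, n, size=T)
        struct_j = rng.integers(0, n, size=T)
    else:
        struct_u = np.ones(0)
        struct_i = np.zeros(0, dtype=np.int64)
        struct_j = np.zeros(0, dtype=np.int64)
    noise_on = p.noise_sd > 0.0
    noise = rng.normal(0.0, p.noise_sd, size=(T, n)) if noise_on else np.zeros((0, n))

    spikes = np.zeros((T, n), dtype=np.uint8)
    inh = np.zeros((T if protocol.record_inhibitory else 0, ni), dtype=np.uint8)
    every = protocol.connection_sample_every
    conn_frac = np.zeros(-(-T // every) if every > 0 else 0)

    if _python_reference:
        flips = _phase_loop_python(
            state, protocol, struct_u, struct_i, struct_j, noise, noise_on,
            spikes, inh, conn_frac, every,
        )
    else:
        adj, deg = _adjacency(state.conn)
        if not struct_on and T:
            struct_u = np.ones(T)
            struct_i = np.zeros(T, dtype=np.int64)
            struct_j = np.zeros(T, dtype=np.int64)
        flips = _kernel.phase_loop(
            state.w_ee, state.conn, adj, deg, state.w_ei, state.w_ie,
            state.t_e, state.t_i, state.h_targets, state.x, state.y,
            protocol.sym, protocol.drive,
            p.eta_stdp, p.eta_ip,
            protocol.stdp, protocol.sn, protocol.ip, struct_on,
            p.prune_zero_weights,
            struct_u, struct_i, struct_j, p.structural_rate, p.structural_weight,
            noise, noise_on,
            spikes, inh, protocol.record_inhibitory,
            conn_frac, every,
        )

    if protocol.shuffle_after and T:
        state.x = state.x[rng.permutation(n)]

    rec = SpikeRecording(
        spikes=spikes,
        letters=protocol.letters.copy(),
        phase=protocol.name,
        inhibitory_spikes=inh if protocol.record_inhibitory else None,
        connection_fraction=conn_frac if every > 0 else None,
        connection_sample_every=every,
        noise_flips=int(flips),
    )
    return state, rec


def _phase_loop_python(
    state, protocol, struct_u, struct_i, struct_j, noise, noise_on,
    spikes, inh, conn_frac, every,
):
    """Reference phase loop composed from the public single-step operations."""
    p = state.params
    n = p.n_exc
    n_edges = int(state.conn.sum())
    flips = 0
    for t in range(protocol.n_steps):
        drive = protocol.drive[protocol.sym[t]]
        x_prev = state.x
        if noise_on:
            act = state.w_ee @ x_prev - state.w_ei @ state.y + drive - state.t_e
            det = act > 0.0
            step(state, drive, noise=noise[t])
            flips += int((det != (state.x > 0)).sum())
        else:
            step(state, drive)
        if protocol.stdp:
            apply_stdp(state, x_prev, state.x)
            n_edges = int(state.conn.sum())
        if protocol.structural and struct_u.size and struct_u[t] < p.structural_rate:
            i, j = int(struct_i[t]), int(struct_j[t])
            if i != j and not state.conn[i, j]:
                state.conn[i, j] = True
                state.w_ee[i, j] = p.structural_weight
                n_edges += 1
        if protocol.sn:
            apply_synaptic_normalization(state)
        if protocol.ip:
            apply_ip(state, state.x)
        spikes[t] = state.x
        if protocol.record_inhibitory:
            inh[t] = state.y
        if every > 0 and t % every == 0:
            conn_frac[t // every] = n_edges / (n * (n - 1))
    return flips
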
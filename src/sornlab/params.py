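"""Parameter set for the self-organizing recurrent network (SORN).

The SORN is a discrete-time network of binary (McCulloch & Pitts) threshold
units: ``n_exc`` excitatory neurons recurrently coupled through a sparse,
plastic weight matrix, and ``n_inh = 0.2 * n_exc`` inhibitory neurons that
provide dense, static feedback inhibition.  Three plasticity rules act on the
excitatory population: spike-timing dependent plasticity (STDP), synaptic
normalization (SN) of incoming *and* outgoing weights, and intrinsic
plasticity (IP) of the firing thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

__all__ = ["SornParams", "load_params", "dump_params"]


@dataclass
class SornParams:
    """Configuration of a SORN instance.

    Parameters
    ----------
    n_exc : int
        Number of excitatory units (``N^E``).
    n_inh : int, optional
        Number of inhibitory units.  Defaults to ``round(0.2 * n_exc)``.
    p_ee : float
        Directed connection probability of the sparse excitatory-to-excitatory
        matrix.  No autapses are created.
    n_input : int
        Number of excitatory targets per input letter (``N^U``).
    w_in : float
        Input weight; every input projection has this constant strength.
    eta_stdp : float
        STDP learning rate.
    eta_ip : float
        Intrinsic-plasticity learning rate.
    h_ip : float
        Mean target firing rate for IP (spikes per step).
    eps_ip : float
        Half-width of the per-neuron target-rate interval
        ``(h_ip - eps_ip, h_ip + eps_ip)``.
    t_e_max : float
        Upper end of the interval of initial excitatory thresholds.
    t_i_max : float
        Upper end of the (fixed) inhibitory threshold interval.  ``0.35``
        yields fine-grained inhibition for continuous stimulation; ``1.0``
        balances excitation and inhibition and is used for trial-structured
        tasks with strong onset transients.
    prune_zero_weights : bool
        Remove synapses that STDP drives to zero from the sparse structure.
    structural_rate : float
        Probability per plastic step of creating one new random E->E synapse
        (initial weight ``structural_weight``).  Set to 0 to disable
        structural plasticity.
    structural_weight : float
        Initial weight of structurally created synapses.
    noise_sd : float
        Standard deviation of an optional Gaussian perturbation added to the
        excitatory pre-threshold activation.  The model is fully
        deterministic for ``noise_sd = 0`` (the default).
    seed : int, optional
        Master seed; child streams are spawned for topology, thresholds,
        stimulus order, cue draws and state shuffles.
    """

    n_exc: int = 200
    n_inh: Optional[int] = None
    p_ee: float = 0.1
    n_input: int = 10
    w_in: float = 0.5
    eta_stdp: float = 0.001
    eta_ip: float = 0.001
    h_ip: float = 0.1
    eps_ip: float = 0.01
    t_e_max: float = 0.5
    t_i_max: float = 0.35
    prune_zero_weights: bool = True
    structural_rate: float = 0.1
    structural_weight: float = 0.001
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_inh is None:
            self.n_inh = int(round(0.2 * self.n_exc))
        self.validate()

    def validate(self) -> None:
        if self.n_exc <= 0 or self.n_inh <= 0:
            raise ValueError("population sizes must be positive")
        for name in ("p_ee", "h_ip", "eps_ip", "structural_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.h_ip - self.eps_ip <= 0.0:
            raise ValueError("h_ip - eps_ip must be positive")
        if self.n_input > self.n_exc:
            raise ValueError("n_input cannot exceed n_exc")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SornParams":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown parameter(s): {sorted(extra)}")
        return cls(**d)


def load_params(path) -> SornParams:
    """Read a :class:`SornParams` from a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SornParams.from_dict(data)


def dump_params(params: SornParams, path) -> None:
    """Write a fully resolved config to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)
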
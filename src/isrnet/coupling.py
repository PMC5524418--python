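"""Synaptic coupling: linear gap junctions and exponential chemical synapses.

Gap junctions inject I_i = g_e * sum_j (V_j - V_i) over neighbors j.
Chemical synapses are conductance based, I_i = g_c (E_rev - V_i) * sum_j s_j,
where each presynaptic open-receptor fraction s_j decays exponentially
with time constant tau_syn = 3 ms and jumps by 1 when neuron j fires
(an upward crossing of the 20 mV spike threshold, detected with a
per-neuron latch so a sustained suprathreshold excursion counts once).
E_rev = 70 mV gives an excitatory synapse, E_rev = -10 mV an inhibitory
one.  Conductances are in mS/cm^2 so currents land in uA/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import Topology

__all__ = [
    "CouplingConfig",
    "SynapseState",
    "gap_junction_current",
    "decay_and_jump",
    "chemical_current",
    "E_REV_EXCITATORY",
    "E_REV_INHIBITORY",
    "TAU_SYN",
]

E_REV_EXCITATORY = 70.0   # mV
E_REV_INHIBITORY = -10.0  # mV
TAU_SYN = 3.0             # ms

_MODES = ("gap", "excitatory", "inhibitory", "none")


@dataclass(frozen=True)
class CouplingConfig:
    """Coupling mode and strength.

    ``mode='none'`` (or g = 0 in any mode) leaves the neurons isolated.
    """

    mode: str = "none"
    g: float = 0.0               # mS/cm^2
    E_rev: float | None = None   # mV; ignored for gap junctions
    tau_syn: float = TAU_SYN     # ms

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.g < 0:
            raise ValueError("conductance must be non-negative")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.E_rev is None and self.mode in ("excitatory", "inhibitory"):
            object.__setattr__(
                self, "E_rev",
                E_REV_EXCITATORY if self.mode == "excitatory" else E_REV_INHIBITORY,
            )

    @property
    def is_chemical(self) -> bool:
        return self.mode in ("excitatory", "inhibitory")

    @classmethod
    def gap(cls, g_e: float) -> "CouplingConfig":
        return cls(mode="gap", g=g_e)

    @classmethod
    def excitatory(cls, g_c: float) -> "CouplingConfig":
        return cls(mode="excitatory", g=g_c)

    @classmethod
    def inhibitory(cls, g_c: float) -> "CouplingConfig":
        return cls(mode="inhibitory", g=g_c)


@dataclass
class SynapseState:
    """Per-neuron open-receptor fraction and spike-edge latch."""

    s: np.ndarray
    above_threshold: np.ndarray

    @classmethod
    def zeros(cls, N: int) -> "SynapseState":
        return cls(s=np.zeros(N), above_threshold=np.zeros(N, dtype=bool))


def gap_junction_current(
    V: np.ndarray, topology: Topology, g_e: float
) -> np.ndarray:
    """Electrical coupling current g_e * sum_j (V_j - V_i) per neuron.

    Pairwise antisymmetry makes the currents sum to zero over the
    network on every call.
    """
    V = np.asarray(V, dtype=float)
    deg = topology.degrees
    rows = np.repeat(np.arange(topology.N), deg)
    neighbor_sum = np.bincount(rows, weights=V[topology.indices], minlength=topology.N)
    return g_e * (neighbor_sum - deg * V)


def decay_and_jump(
    state: SynapseState, spikes_this_step: np.ndarray, dt: float,
    tau_syn: float = TAU_SYN,
) -> SynapseState:
    """Advance s by exact exponential decay over ``dt``, then apply the
    unit jump for every neuron that fired this step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = state.s * np.exp(-dt / tau_syn)
    s = s + np.asarray(spikes_this_step, dtype=float)
    return SynapseState(s=s, above_threshold=state.above_threshold.copy())


def chemical_current(
    V: np.ndarray, s: np.ndarray, topology: Topology, g_c: float, E_rev: float
) -> np.ndarray:
    """Conductance-based synaptic current g_c (E_rev - V_i) sum_j s_j."""
    V = np.asarray(V, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("open-receptor fractions must be non-negative")
    rows = np.repeat(np.arange(topology.N), topology.degrees)
    neighbor_s = np.bincount(rows, weights=s[topology.indices], minlength=topology.N)
    return g_c * neighbor_s * (E_rev - V)
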
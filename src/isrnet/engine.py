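"""Network integrator: initial conditions, RK4 stepping, and the
transient/measurement protocol.

A simulation draws each neuron's initial condition uniformly from the
box V in [-10, 80] mV, m, h, n in [0, 1], integrates the coupled
stochastic system with fixed-step RK4 at dt = 10 us through a 1 s
transient, and then records spike times (upward crossings of 20 mV)
for a 5 s measurement window.

Randomness is organized as one master seed -> per-realization seeds ->
per-neuron substreams (``numpy.random.SeedSequence`` spawning with
Philox counters).  Each neuron's substream supplies first its initial
condition and then its gating-noise draws, so an uncoupled (g = 0)
network factorizes exactly into single-neuron simulations run on the
same substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernel
from .channel_noise import ChannelPopulation
from .coupling import CouplingConfig
from .hh_neuron import HHParams, NeuronState
from .observables import SpikeRaster
from .topology import Topology

__all__ = [
    "SimulationProtocol",
    "SimResult",
    "sample_initial_conditions",
    "neuron_generators",
    "simulate",
    "deterministic_orbit",
]

# target in-memory size of one pregenerated noise block, in draws
_NOISE_BLOCK_DRAWS = 18_000_000


@dataclass(frozen=True)
class SimulationProtocol:
    """Integration and measurement protocol."""

    dt: float = 0.01                 # ms (10 us)
    T_transient: float = 1000.0      # ms, discarded
    tau_measure: float = 5000.0      # ms, spike-counting window
    spike_threshold: float = 20.0    # mV
    n_realizations: int = 50
    trace_dt: float = 0.1            # ms, voltage-trace subsampling grid

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T_transient < 0 or self.tau_measure < 0:
            raise ValueError("T_transient and tau_measure must be non-negative")


@dataclass
class SimResult:
    raster: SpikeRaster
    final_state: NeuronState
    traces: np.ndarray | None = None      # (n_samples, N) float32, measurement window
    trace_times: np.ndarray | None = None  # ms, relative to measurement start


def neuron_generators(
    seed: int | np.random.SeedSequence, N: int,
    neuron_seeds: Sequence[np.random.SeedSequence] | None = None,
) -> list[np.random.Generator]:
    """Per-neuron Philox generators spawned from one seed.

    Passing an explicit subset of previously spawned ``neuron_seeds``
    reproduces individual neurons of a larger network exactly.
    """
    if neuron_seeds is None:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        # stateless spawn: reusing the same SeedSequence must reproduce
        # the same substreams (SeedSequence.spawn advances a counter)
        neuron_seeds = [
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (i,))
            for i in range(N)
        ]
    if len(neuron_seeds) != N:
        raise ValueError("need one seed sequence per neuron")
    return [np.random.Generator(np.random.Philox(s)) for s in neuron_seeds]


def sample_initial_conditions(
    N: int, rng: np.random.Generator | Sequence[np.random.Generator]
) -> NeuronState:
    """Uniform initial conditions: V ~ U(-10, 80) mV; m, h, n ~ U(0, 1).

    ``rng`` may be a single generator or one generator per neuron (the
    engine's per-neuron substreams)."""
    if isinstance(rng, np.random.Generator):
        u = rng.random((N, 4))
    else:
        if len(rng) != N:
            raise ValueError("need one generator per neuron")
        u = np.stack([g.random(4) for g in rng])
    return NeuronState(
        V=-10.0 + 90.0 * u[:, 0], m=u[:, 1], h=u[:, 2], n=u[:, 3]
    )


def _mode_code(coupling: CouplingConfig) -> int:
    if coupling.g == 0.0 or coupling.mode == "none":
        return _kernel.MODE_NONE
    if coupling.mode == "gap":
        return _kernel.MODE_GAP
    return _kernel.MODE_CHEM


def simulate(
    topology: Topology,
    coupling: CouplingConfig,
    A: float,
    protocol: SimulationProtocol | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    params: HHParams | None = None,
    init_state: NeuronState | None = None,
    neuron_seeds: Sequence[np.random.SeedSequence] | None = None,
    record_traces: bool = False,
) -> SimResult:
    """Run the full protocol on one network realization.

    ``A`` is the membrane patch area in um^2 (``math.inf`` switches the
    channel noise off).  Initial conditions are drawn from the standard
    box unless ``init_state`` is given; per-neuron noise substreams are
    consumed either way so trajectories with and without custom initial
    conditions remain comparable.
    """
    protocol = protocol or SimulationProtocol()
    params = params or HHParams()
    if params != HHParams():
        raise NotImplementedError(
            "the compiled integrator is specialized to the default membrane "
            "parameters"
        )
    N = topology.N
    pop = ChannelPopulation(A)
    inv_NNa = 0.0 if math.isinf(pop.N_Na) else 1.0 / pop.N_Na
    inv_NK = 0.0 if math.isinf(pop.N_K) else 1.0 / pop.N_K
    has_noise = inv_NNa > 0.0 or inv_NK > 0.0

    gens = neuron_generators(seed, N, neuron_seeds)
    drawn = sample_initial_conditions(N, gens)
    state = (init_state.copy() if init_state is not None else drawn)
    if state.V.size != N:
        raise ValueError("init_state size does not match topology")
    state.clip_gates()

    V = state.V.astype(float).ravel().copy()
    m = state.m.astype(float).ravel().copy()
    h = state.h.astype(float).ravel().copy()
    n = state.n.astype(float).ravel().copy()
    s = np.zeros(N)
    above = (V >= protocol.spike_threshold).astype(np.uint8)

    dt = protocol.dt
    n_trans = int(round(protocol.T_transient / dt))
    n_meas = int(round(protocol.tau_measure / dt))
    trace_every = max(1, int(round(protocol.trace_dt / dt)))

    mode = _mode_code(coupling)
    E_rev = coupling.E_rev if coupling.E_rev is not None else 0.0

    n_trace_rows = (n_meas // trace_every) if record_traces else 0
    traces = np.zeros((n_trace_rows, N), dtype=np.float32)

    block = max(1, _NOISE_BLOCK_DRAWS // (3 * N))
    spike_cap = int(N * block * dt) + 64
    spike_i = np.empty(spike_cap, dtype=np.int64)
    spike_t = np.empty(spike_cap, dtype=np.float64)
    all_i: list[np.ndarray] = []
    all_t: list[np.ndarray] = []

    def run_phase(n_steps: int, t0: float, recording: bool, meas_done: int) -> int:
        done = 0
        while done < n_steps:
            nb = min(block, n_steps - done)
            if has_noise:
                noise = np.empty((nb, N, 3), dtype=np.float32)
                for i, g in enumerate(gens):
                    noise[:, i, :] = g.standard_normal((nb, 3), dtype=np.float32)
            else:
                noise = np.zeros((1, 1, 3), dtype=np.float32)
            nsp, ntr, ok = _kernel.run_chunk(
                V, m, h, n, s, above,
                topology.indptr, topology.indices,
                mode, coupling.g, E_rev, coupling.tau_syn,
                inv_NNa, inv_NK, dt, nb,
                noise, has_noise,
                protocol.spike_threshold,
                0 if recording else nb,
                t0 + done * dt,
                spike_i, spike_t,
                traces if recording else np.zeros((0, 0), dtype=np.float32),
                trace_every,
                meas_done + done if recording else 0,
                (meas_done + done) // trace_every if recording else 0,
            )
            if not ok:
                if not np.all(np.isfinite(V)):
                    raise FloatingPointError(
                        f"non-finite membrane potential at t ~ {t0 + done * dt:.2f} ms"
                    )
                raise RuntimeError("spike buffer overflow")  # pragma: no cover
            if recording and nsp:
                all_i.append(spike_i[:nsp].copy())
                all_t.append(spike_t[:nsp].copy())
            done += nb
        return done

    run_phase(n_trans, -protocol.T_transient, False, 0)
    run_phase(n_meas, 0.0, True, 0)

    ids = np.concatenate(all_i) if all_i else np.empty(0, dtype=np.int64)
    ts = np.concatenate(all_t) if all_t else np.empty(0, dtype=np.float64)
    raster = SpikeRaster.from_events(N, protocol.tau_measure, ids, ts)
    result = SimResult(
        raster=raster,
        final_state=NeuronState(V.copy(), m.copy(), h.copy(), n.copy()),
    )
    if record_traces:
        result.traces = traces
        result.trace_times = (np.arange(n_trace_rows) + 1.0) * trace_every * dt
    return result


def save_result(result: SimResult, path, config: dict | None = None) -> None:
    """Write the spike raster as two-column text (neuron id, time ms)
    with a JSON sidecar holding the full run configuration."""
    import json
    from pathlib import Path

    from .observables import save_raster

    path = Path(path)
    save_raster(result.raster, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(config or {}, sort_keys=True, default=str))


def deterministic_orbit(
    state0: NeuronState, t_total: float, dt: float = 0.01,
    record_traces: bool = False,
) -> SimResult:
    """Noise-free single/multi-neuron reference run (no transient, the
    whole interval is the measurement window)."""
    N = state0.V.size
    proto = SimulationProtocol(dt=dt, T_transient=0.0, tau_measure=t_total)
    return simulate(
        Topology.empty(N), CouplingConfig(), math.inf, proto,
        seed=0, init_state=state0, record_traces=record_traces,
    )
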
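"""Population observables: spike detection, mean firing rate, synchrony,
and the spiking/resting census.

The mean firing rate over a window of length tau is

    nu = (1 / (N tau)) * sum_i N_i^spikes        [Hz, tau in seconds]

and the synchrony measure is the variance of the population-mean
voltage normalized by the mean single-neuron voltage variance,

    sync = Var_t[ Vbar(t) ] / ( (1/N) sum_i Var_t[ V_i(t) ] ),

a dimensionless number in [0, 1] (up to estimator fluctuations), equal
to 1 for identical traces and ~1/N for independent ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SpikeRaster",
    "detect_spikes",
    "mean_firing_rate",
    "synchrony",
    "classify_states",
    "save_raster",
    "load_raster",
]


@dataclass
class SpikeRaster:
    """Per-neuron ordered spike times (ms) within a measurement window."""

    N: int
    tau: float  # window length, ms
    spike_times: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.spike_times) != self.N:
            raise ValueError("need one spike-time array per neuron")
        for st in self.spike_times:
            if st.size and (st.min() < 0 or st.max() > self.tau):
                raise ValueError("spike times must lie within [0, tau]")
            if st.size > 1 and np.any(np.diff(st) <= 0):
                raise ValueError("spike times must be strictly increasing")

    @classmethod
    def from_events(
        cls, N: int, tau: float, neuron_ids: np.ndarray, times: np.ndarray
    ) -> "SpikeRaster":
        neuron_ids = np.asarray(neuron_ids, dtype=np.int64)
        times = np.asarray(times, dtype=float)
        order = np.lexsort((times, neuron_ids))
        neuron_ids, times = neuron_ids[order], times[order]
        spike_times = [times[neuron_ids == i] for i in range(N)]
        return cls(N=N, tau=tau, spike_times=spike_times)

    def counts(self) -> np.ndarray:
        return np.array([st.size for st in self.spike_times], dtype=np.int64)

    @property
    def n_spikes(self) -> int:
        return int(self.counts().sum())


def detect_spikes(
    trace: np.ndarray, times: np.ndarray | None = None, threshold: float = 20.0
) -> np.ndarray:
    """Spike times of one uniformly sampled voltage trace.

    A spike is an upward crossing of ``threshold``: the sample time of
    the first above-threshold point after a below-threshold one.  A
    trace that starts above threshold does not count an initial event.
    """
    trace = np.asarray(trace, dtype=float)
    above = trace >= threshold
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if times is None:
        return up.astype(float)
    return np.asarray(times, dtype=float)[up]


def mean_firing_rate(raster: SpikeRaster) -> float:
    """Population mean firing rate nu in Hz (tau converted ms -> s)."""
    if raster.tau <= 0:
        raise ValueError("window length must be positive")
    return raster.n_spikes / (raster.N * raster.tau * 1e-3)


def synchrony(traces: np.ndarray) -> float:
    """Voltage-coherence measure in [0, 1] from traces of shape (T, N).

    Returns NaN (with a warning) when every trace is constant, which
    leaves the normalization undefined.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[1] < 2:
        raise ValueError("need a (T, N) array with at least 2 neurons")
    if not np.all(np.isfinite(traces)):
        raise ValueError("traces must be finite")
    per_neuron_var = traces.var(axis=0)
    denom = per_neuron_var.mean()
    # relative floor: constant traces leave only rounding residue in var
    if denom <= 1e-12 * max(1.0, float(np.mean(traces**2))):
        warnings.warn("all traces constant: synchrony undefined", RuntimeWarning)
        return float("nan")
    pop_var = traces.mean(axis=1).var()
    return float(pop_var / denom)


def classify_states(raster: SpikeRaster) -> tuple[float, float]:
    """(spiking fraction N_s/N, resting fraction N_r/N).

    A neuron is in the spiking state iff it fired at least once during
    the measurement window; the two fractions sum to 1 exactly.
    """
    counts = raster.counts()
    ns = int(np.count_nonzero(counts))
    return ns / raster.N, (raster.N - ns) / raster.N


def save_raster(raster: SpikeRaster, path: str | Path) -> None:
    """Two-column text: neuron id, spike time (ms)."""
    ids = np.concatenate([
        np.full(st.size, i, dtype=np.int64)
        for i, st in enumerate(raster.spike_times)
    ]) if raster.n_spikes else np.empty(0, dtype=np.int64)
    ts = np.concatenate([st for st in raster.spike_times]) if raster.n_spikes \
        else np.empty(0)
    header = f"N={raster.N} tau_ms={raster.tau}"
    np.savetxt(path, np.column_stack([ids, ts]), fmt=["%d", "%.6f"], header=header)


def load_raster(path: str | Path) -> SpikeRaster:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    meta = dict(kv.split("=") for kv in header)
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        data = np.empty((0, 2))
    return SpikeRaster.from_events(
        int(meta["N"]), float(meta["tau_ms"]),
        data[:, 0].astype(np.int64), data[:, 1],
    )
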
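"""Random scale-free graph generation with prescribed degree exponent and mean.

Degrees are drawn from a continuous power law p(k) ~ k^-gamma truncated
to (k0, k_max) and rounded to integers; the graph is then wired in the
configurational ensemble, accepting candidate edges (i, j) with
probability p_ij = k_i k_j / (N <k>) until every node has exactly its
drawn degree.  The truncation bounds are tied together:

    k_max = sqrt(N <k>)     (the unique cap making p_ij <= 1)
    k0    : solved numerically so the truncated law's mean equals <k>.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Topology",
    "truncation_bounds",
    "draw_degree_sequence",
    "wire_network",
    "random_scale_free",
    "network_stats",
    "save_edge_list",
    "load_edge_list",
]


class WiringError(RuntimeError):
    """Raised when the configurational wiring cannot complete; the caller
    should redraw the degree sequence."""


@dataclass
class Topology:
    """Undirected simple graph with its generating parameters.

    ``indptr``/``indices`` hold the adjacency in CSR form (symmetric,
    zero diagonal); ``degrees`` is the realized = requested degree
    sequence.
    """

    N: int
    gamma: float
    k_mean: float
    degrees: np.ndarray
    indptr: np.ndarray
    indices: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.indices.size // 2

    def edge_array(self) -> np.ndarray:
        """(n_edges, 2) array of undirected edges with i < j."""
        rows = np.repeat(np.arange(self.N), np.diff(self.indptr))
        mask = rows < self.indices
        return np.column_stack([rows[mask], self.indices[mask]])

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]: self.indptr[i + 1]]

    @classmethod
    def from_edges(
        cls, N: int, edges: np.ndarray, gamma: float = float("nan"),
        k_mean: float = float("nan"),
    ) -> "Topology":
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            if edges.min() < 0 or edges.max() >= N:
                raise ValueError("edge endpoints out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            und = np.vstack([edges, edges[:, ::-1]])
            key = und[:, 0] * N + und[:, 1]
            if np.unique(key).size != key.size:
                raise ValueError("duplicate edges are not allowed")
            order = np.lexsort((und[:, 1], und[:, 0]))
            und = und[order]
        else:
            und = np.empty((0, 2), dtype=np.int64)
        degrees = np.bincount(und[:, 0], minlength=N).astype(np.int64)
        indptr = np.concatenate([[0], np.cumsum(degrees)]).astype(np.int64)
        return cls(N=N, gamma=gamma, k_mean=k_mean, degrees=degrees,
                   indptr=indptr, indices=und[:, 1].copy())

    @classmethod
    def empty(cls, N: int) -> "Topology":
        """N isolated nodes (used for uncoupled / single-neuron runs)."""
        return cls.from_edges(N, np.empty((0, 2), dtype=np.int64))


def _truncated_mean(k0: float, k_max: float, gamma: float) -> float:
    """Mean of the continuous power law ~ k^-gamma on (k0, k_max)."""
    if gamma == 2.0:
        num = np.log(k_max / k0)
    else:
        num = (k_max ** (2.0 - gamma) - k0 ** (2.0 - gamma)) / (2.0 - gamma)
    den = (k_max ** (1.0 - gamma) - k0 ** (1.0 - gamma)) / (1.0 - gamma)
    return num / den


def truncation_bounds(N: int, gamma: float, k_mean: float) -> tuple[float, float]:
    """(k0, k_max) for the truncated power-law degree distribution.

    Raises ``ValueError`` when the required k0 would fall below 1
    (degrees of at least 1 could then not carry the requested mean).
    """
    if N < 2 or k_mean < 1 or k_mean >= N:
        raise ValueError("need N >= 2 and 1 <= k_mean < N")
    if gamma <= 2.0:
        raise ValueError("degree exponent must exceed 2")
    k_max = float(np.sqrt(N * k_mean))
    if k_max <= 1.0:
        raise ValueError("k_max <= 1: network too small for the requested mean degree")
    lo, hi = 1e-9, k_max * (1.0 - 1e-12)
    f = lambda k0: _truncated_mean(k0, k_max, gamma) - k_mean
    # the truncated mean increases monotonically with k0, from ~0 to k_max
    if f(hi) < 0:
        raise ValueError("requested mean degree not reachable below k_max")
    if f(lo) > 0:
        raise ValueError("requested mean degree below the distribution floor")
    k0 = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    if k0 < 1.0:
        raise ValueError(
            f"infeasible degree distribution: solving the truncated power-law "
            f"mean identity gives k0 = {k0:.4f} < 1 for N={N}, gamma={gamma}, "
            f"k_mean={k_mean}; increase k_mean or gamma"
        )
    return k0, k_max


def sample_truncated_power_law(
    n: int, k0: float, k_max: float, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """Continuous inverse-CDF samples from p(k) ~ k^-gamma on (k0, k_max)."""
    u = rng.random(n)
    a = 1.0 - gamma
    return (k0 ** a + u * (k_max ** a - k0 ** a)) ** (1.0 / a)


def draw_degree_sequence(
    N: int, gamma: float, k_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Integer degree sequence of length N with power-law tail.

    Continuous draws are rounded to the nearest integer (floor 1, cap
    floor(k_max)); if the resulting stub count is odd, one uniformly
    chosen node gets an extra stub so that configurational wiring is
    possible.
    """
    k0, k_max = truncation_bounds(N, gamma, k_mean)
    ks = sample_truncated_power_law(N, k0, k_max, gamma, rng)
    cap = int(np.floor(k_max))
    degrees = np.clip(np.rint(ks).astype(np.int64), 1, cap)
    if degrees.sum() % 2 == 1:
        # add the balancing stub to a node that stays under the p_ij cap
        candidates = np.flatnonzero(degrees < cap)
        degrees[rng.choice(candidates)] += 1
    return degrees


def wire_network(
    degrees: np.ndarray,
    rng: np.random.Generator,
    gamma: float = float("nan"),
    k_mean: float | None = None,
    max_passes: int = 1000,
) -> Topology:
    """Configurational wiring of a drawn degree sequence.

    Candidate edges between distinct, unconnected nodes with residual
    stubs are accepted with probability p_ij = k_i k_j / (N <k>);
    sweeps repeat until every node's realized degree equals its drawn
    degree.  Raises :class:`WiringError` when the pass budget is
    exhausted (the caller should redraw the sequence).
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    N = degrees.size
    if degrees.sum() % 2 == 1:
        raise ValueError("degree sum must be even")
    if k_mean is None:
        k_mean = degrees.mean()
    norm = N * k_mean
    if degrees.max() ** 2 > norm * (1.0 + 1e-9):
        raise ValueError("max degree exceeds sqrt(N <k>); p_ij would exceed 1")

    residual = degrees.copy()
    connected: list[set[int]] = [set() for _ in range(N)]
    edges: list[tuple[int, int]] = []

    def add_edge(i: int, j: int) -> None:
        connected[i].add(j)
        connected[j].add(i)
        edges.append((int(i), int(j)))
        residual[i] -= 1
        residual[j] -= 1

    def drop_edge(idx: int) -> tuple[int, int]:
        u, v = edges[idx]
        edges[idx] = edges[-1]
        edges.pop()
        connected[u].discard(v)
        connected[v].discard(u)
        return u, v

    def repair_step(open_nodes: np.ndarray) -> bool:
        """Degree-preserving double-edge swap for a structurally stalled
        end-game (all remaining open pairs already connected)."""
        i = int(open_nodes[0])
        j = int(open_nodes[1]) if open_nodes.size > 1 else i
        for _ in range(500):
            idx = int(rng.integers(len(edges)))
            u, v = edges[idx]
            if rng.random() < 0.5:
                u, v = v, u
            if u in (i, j) or v in (i, j):
                continue
            if u in connected[i] or v in connected[j]:
                continue
            if i == j and u in connected[i]:  # single node needs 2 stubs
                continue
            drop_edge(idx)
            add_edge(i, u)
            add_edge(j, v)
            return True
        return False

    for _ in range(max_passes):
        open_nodes = np.flatnonzero(residual > 0)
        if open_nodes.size == 0:
            break
        # random sweep over candidate pairs among nodes with open stubs
        nodes = open_nodes[rng.permutation(open_nodes.size)]
        progress = False
        for ai in range(nodes.size):
            i = nodes[ai]
            if residual[i] == 0:
                continue
            for bi in range(ai + 1, nodes.size):
                j = nodes[bi]
                if residual[i] == 0:
                    break
                if residual[j] == 0 or j in connected[i]:
                    continue
                if rng.random() < degrees[i] * degrees[j] / norm:
                    add_edge(i, j)
                    progress = True
        if not progress:
            open_nodes = np.flatnonzero(residual > 0)
            stalled = all(
                j in connected[i] or residual[j] == 0
                for ai, i in enumerate(open_nodes)
                for j in open_nodes[ai + 1:]
            )
            if stalled and not repair_step(open_nodes):
                raise WiringError(
                    "stalled configurational wiring could not be repaired; "
                    "redraw the degree sequence"
                )
    else:
        raise WiringError(
            "configurational wiring did not converge within the pass budget; "
            "redraw the degree sequence"
        )
    topo = Topology.from_edges(N, np.array(edges, dtype=np.int64).reshape(-1, 2),
                               gamma=gamma, k_mean=float(k_mean))
    assert np.array_equal(topo.degrees, degrees)
    return topo


def random_scale_free(
    N: int, gamma: float, k_mean: float, rng: np.random.Generator,
    max_redraws: int = 20,
) -> Topology:
    """Draw a degree sequence and wire it, redrawing on wiring failure."""
    last: WiringError | None = None
    for _ in range(max_redraws):
        degrees = draw_degree_sequence(N, gamma, k_mean, rng)
        try:
            return wire_network(degrees, rng, gamma=gamma, k_mean=k_mean)
        except WiringError as err:  # pragma: no cover - rare
            last = err
    raise last  # pragma: no cover


def network_stats(topology: Topology) -> dict:
    """Mean/max degree and a maximum-likelihood (Hill) exponent estimate.

    The exponent is fitted on degrees >= ceil(k0); it is undefined (NaN)
    when all retained degrees are equal.
    """
    degrees = topology.degrees
    out = {
        "n_nodes": topology.N,
        "n_edges": topology.n_edges,
        "mean_degree": float(degrees.mean()),
        "max_degree": int(degrees.max()),
        "gamma_hat": float("nan"),
    }
    try:
        k0, _ = truncation_bounds(topology.N, topology.gamma, topology.k_mean)
    except (ValueError, TypeError):
        k0 = float(degrees.min())
    tail = degrees[degrees >= np.ceil(k0)].astype(float)
    kmin = tail.min() if tail.size else float("nan")
    if tail.size >= 2 and np.any(tail > kmin):
        # continuous MLE with the standard -1/2 discreteness correction
        out["gamma_hat"] = 1.0 + tail.size / np.sum(np.log(tail / (kmin - 0.5)))
    return out


def save_edge_list(topology: Topology, path: str | Path) -> None:
    """Write edges as two 0-based integer columns plus a JSON sidecar
    with the degree sequence and generation parameters."""
    path = Path(path)
    np.savetxt(path, topology.edge_array(), fmt="%d")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "N": topology.N,
        "gamma": topology.gamma,
        "k_mean": topology.k_mean,
        "degrees": topology.degrees.tolist(),
    }))


def load_edge_list(path: str | Path) -> Topology:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    edges = np.loadtxt(path, dtype=np.int64, ndmin=2)
    if edges.size == 0:
        edges = np.empty((0, 2), dtype=np.int64)
    topo = Topology.from_edges(meta["N"], edges, gamma=meta["gamma"],
                               k_mean=meta["k_mean"])
    if not np.array_equal(topo.degrees, np.asarray(meta["degrees"])):
        raise ValueError("edge list inconsistent with stored degree sequence")
    return topo
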
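"""Deterministic Hodgkin-Huxley single-compartment dynamics.

Classic squid-axon kinetics in the rest-near-0 mV convention
(E_Na = 115 mV, E_K = -12 mV, E_L = 10.6 mV), with a constant bias
current I0 that places the neuron in the bistable regime where a stable
resting equilibrium coexists with a stable spiking limit cycle.  All
voltages are in mV, times in ms, currents in uA/cm^2 and conductances
in mS/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "HHParams",
    "NeuronState",
    "GatingRates",
    "rate_constants",
    "steady_state_gates",
    "ionic_currents",
    "membrane_rhs",
    "gating_rhs",
    "find_resting_equilibrium",
]

# half-width of the series window around the removable singularities of
# the alpha_m / alpha_n expressions, in mV
_SINGULAR_EPS = 1e-6


@dataclass(frozen=True)
class HHParams:
    """Membrane parameters (per unit area).

    Defaults are the classic squid-axon values with a bias current of
    6.8 uA/cm^2, for which the neuron is bistable between rest and
    periodic spiking.
    """

    C_m: float = 1.0          # uF/cm^2
    g_Na_max: float = 120.0   # mS/cm^2
    g_K_max: float = 36.0     # mS/cm^2
    g_L: float = 0.3          # mS/cm^2
    E_Na: float = 115.0       # mV
    E_K: float = -12.0        # mV
    E_L: float = 10.6         # mV
    I0: float = 6.8           # uA/cm^2

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        for name in ("g_Na_max", "g_K_max", "g_L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class NeuronState:
    """Per-neuron continuous state: membrane potential and gates.

    Arrays of equal shape; a single neuron is simply shape ``()`` or
    ``(1,)``.  Gating variables are expected to lie in [0, 1]; the
    integrator enforces this by clipping after each committed step.
    """

    V: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if not (self.V.shape == self.m.shape == self.h.shape == self.n.shape):
            raise ValueError("V, m, h, n must have identical shapes")

    @property
    def size(self) -> int:
        return self.V.size

    def copy(self) -> "NeuronState":
        return NeuronState(self.V.copy(), self.m.copy(), self.h.copy(), self.n.copy())

    def clip_gates(self) -> None:
        np.clip(self.m, 0.0, 1.0, out=self.m)
        np.clip(self.h, 0.0, 1.0, out=self.h)
        np.clip(self.n, 0.0, 1.0, out=self.n)


class GatingRates(NamedTuple):
    """Voltage-dependent opening/closing rates (1/ms) of the m, h, n gates."""

    alpha_m: np.ndarray
    beta_m: np.ndarray
    alpha_h: np.ndarray
    beta_h: np.ndarray
    alpha_n: np.ndarray
    beta_n: np.ndarray


def _alpha_ratio(u: np.ndarray) -> np.ndarray:
    """u / (e^u - 1), with the removable singularity at u = 0 evaluated
    by its series 1 - u/2 + u^2/12 within |u| < _SINGULAR_EPS/10 (u is
    the voltage offset divided by 10 mV)."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < _SINGULAR_EPS / 10.0
    out = np.empty_like(u)
    us = u[small]
    out[small] = 1.0 - us / 2.0 + us * us / 12.0
    ub = u[~small]
    out[~small] = ub / np.expm1(ub)
    return out


def rate_constants(V: float | np.ndarray) -> GatingRates:
    """Gating rate functions alpha_x(V), beta_x(V) in 1/ms.

    Classic Hodgkin-Huxley forms in the rest-near-0 convention:

        alpha_m = 0.1 (25 - V) / (e^{(25-V)/10} - 1)   beta_m = 4 e^{-V/18}
        alpha_h = 0.07 e^{-V/20}                       beta_h = 1 / (e^{(30-V)/10} + 1)
        alpha_n = 0.01 (10 - V) / (e^{(10-V)/10} - 1)  beta_n = 0.125 e^{-V/80}

    The removable singularities at V = 25 (alpha_m) and V = 10 (alpha_n)
    are evaluated by their analytic limits.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    alpha_m = _alpha_ratio((25.0 - V) / 10.0)            # = 0.1(25-V)/expm1((25-V)/10)
    beta_m = 4.0 * np.exp(-V / 18.0)
    alpha_h = 0.07 * np.exp(-V / 20.0)
    beta_h = 1.0 / (np.exp((30.0 - V) / 10.0) + 1.0)
    alpha_n = 0.1 * _alpha_ratio((10.0 - V) / 10.0)      # = 0.01(10-V)/expm1((10-V)/10)
    beta_n = 0.125 * np.exp(-V / 80.0)
    return GatingRates(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)


def steady_state_gates(V: float | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voltage-clamped stationary gate values x_inf = alpha/(alpha+beta)."""
    r = rate_constants(V)
    m_inf = r.alpha_m / (r.alpha_m + r.beta_m)
    h_inf = r.alpha_h / (r.alpha_h + r.beta_h)
    n_inf = r.alpha_n / (r.alpha_n + r.beta_n)
    return m_inf, h_inf, n_inf


class IonicCurrents(NamedTuple):
    G_Na: np.ndarray  # instantaneous sodium conductance g_Na_max m^3 h
    G_K: np.ndarray   # instantaneous potassium conductance g_K_max n^4
    I_Na: np.ndarray  # G_Na (V - E_Na), the term subtracted in the membrane equation
    I_K: np.ndarray
    I_L: np.ndarray


def ionic_currents(state: NeuronState, params: HHParams) -> IonicCurrents:
    """Per-channel conductances and (subtracted) driving-force currents."""
    G_Na = params.g_Na_max * state.m ** 3 * state.h
    G_K = params.g_K_max * state.n ** 4
    return IonicCurrents(
        G_Na=G_Na,
        G_K=G_K,
        I_Na=G_Na * (state.V - params.E_Na),
        I_K=G_K * (state.V - params.E_K),
        I_L=params.g_L * (state.V - params.E_L),
    )


def membrane_rhs(
    state: NeuronState, params: HHParams, I_syn: float | np.ndarray = 0.0
) -> np.ndarray:
    """dV/dt (mV/ms): ionic currents, bias current and synaptic input."""
    cur = ionic_currents(state, params)
    return (-cur.I_Na - cur.I_K - cur.I_L + params.I0 + I_syn) / params.C_m


def gating_rhs(state: NeuronState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic gate kinetics dx/dt = alpha(1-x) - beta x."""
    r = rate_constants(state.V)
    dm = r.alpha_m * (1.0 - state.m) - r.beta_m * state.m
    dh = r.alpha_h * (1.0 - state.h) - r.beta_h * state.h
    dn = r.alpha_n * (1.0 - state.n) - r.beta_n * state.n
    return dm, dh, dn


def find_resting_equilibrium(params: HHParams | None = None) -> NeuronState:
    """Locate the stable resting equilibrium of the deterministic system.

    With gates at their voltage-clamped steady state, the 4-D fixed-point
    problem reduces to a scalar root of dV/dt in V; the root is bracketed
    and refined with Brent's method.
    """
    from scipy.optimize import brentq

    params = params or HHParams()

    def residual(V: float) -> float:
        m_inf, h_inf, n_inf = steady_state_gates(V)
        st = NeuronState(np.asarray(V), m_inf, h_inf, n_inf)
        return float(membrane_rhs(st, params))

    # the resting branch sits a few mV above 0 for the default bias current
    grid = np.linspace(-20.0, 30.0, 201)
    vals = [residual(v) for v in grid]
    for lo, hi, flo, fhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if flo == 0.0:
            V_eq = float(lo)
            break
        if flo * fhi < 0:
            V_eq = brentq(residual, lo, hi, xtol=1e-12)
            break
    else:  # pragma: no cover - bias currents far outside the bistable range
        raise RuntimeError("no resting equilibrium found in [-20, 30] mV")
    m_inf, h_inf, n_inf = steady_state_gates(V_eq)
    return NeuronState(np.asarray(float(V_eq)), m_inf, h_inf, n_inf)
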
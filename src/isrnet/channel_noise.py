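"""Fox's Langevin approximation of ion-channel noise.

Finite numbers of sodium and potassium channels in a membrane patch of
area A make the gating variables fluctuate.  In the diffusion limit the
fluctuation enters each gate equation as an additive zero-mean Gaussian
white noise xi_x(t) with

    <xi_x(t) xi_x(t')> = 2 D_x delta(t - t'),
    D_m = alpha_m beta_m / [N_Na (alpha_m + beta_m)]   (h analogous, N_Na)
    D_n = alpha_n beta_n / [N_K  (alpha_n + beta_n)]

where N_Na = rho_Na * A and N_K = rho_K * A are the channel counts.
Membrane area is therefore the (inverse) noise control parameter: the
larger the patch, the closer the dynamics to the deterministic limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hh_neuron import GatingRates

__all__ = [
    "RHO_NA",
    "RHO_K",
    "ChannelPopulation",
    "channel_counts",
    "noise_intensity",
    "sample_gating_noise",
]

RHO_NA = 60.0  # sodium channel density, um^-2
RHO_K = 18.0   # potassium channel density, um^-2


def channel_counts(A: float) -> tuple[float, float]:
    """Channel numbers (N_Na, N_K) for a patch of area ``A`` (um^2).

    Counts are kept real-valued: they only enter the noise variances,
    and the Langevin description is continuous anyway.  ``A = inf`` is
    the deterministic (noise-free) sentinel.
    """
    if not A > 0:
        raise ValueError(f"membrane area must be positive, got {A!r}")
    return RHO_NA * A, RHO_K * A


@dataclass(frozen=True)
class ChannelPopulation:
    """Sodium/potassium channel population of one membrane patch."""

    A: float                      # um^2; may be inf (noise off)
    rho_Na: float = RHO_NA
    rho_K: float = RHO_K
    N_Na: float = field(init=False)
    N_K: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"membrane area must be positive, got {self.A!r}")
        object.__setattr__(self, "N_Na", self.rho_Na * self.A)
        object.__setattr__(self, "N_K", self.rho_K * self.A)


def noise_intensity(x: str, rates: GatingRates, pop: ChannelPopulation) -> np.ndarray:
    """Spectral intensity D_x (1/ms) of the channel noise on gate ``x``.

    ``x`` is one of ``'m'``, ``'h'`` (sodium) or ``'n'`` (potassium).
    Where alpha + beta == 0 the gate is degenerate and D is set to 0.
    """
    if x in ("m", "h"):
        N = pop.N_Na
    elif x == "n":
        N = pop.N_K
    else:
        raise ValueError(f"unknown gate label {x!r}")
    alpha = np.asarray(getattr(rates, f"alpha_{x}"), dtype=float)
    beta = np.asarray(getattr(rates, f"beta_{x}"), dtype=float)
    if np.any(alpha < 0) or np.any(beta < 0):
        raise ValueError("gating rates must be non-negative")
    denom = N * (alpha + beta)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(denom > 0, alpha * beta / np.where(denom > 0, denom, 1.0), 0.0)
    if not np.isfinite(N):  # deterministic limit
        D = np.zeros_like(D)
    return D


def sample_gating_noise(
    D_x: float | np.ndarray, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """One white-noise value per gate for a time step of length ``dt``.

    Discretized as xi = z * sqrt(2 D / dt) with z standard normal, so
    that the sample variance over many steps matches the delta-correlated
    contract 2 D / dt.  The engine draws z once per gate/neuron/step and
    holds it fixed across the Runge-Kutta stages.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    D_x = np.asarray(D_x, dtype=float)
    if np.any(D_x < 0):
        raise ValueError("noise intensity must be non-negative")
    z = rng.standard_normal(D_x.shape)
    return z * np.sqrt(2.0 * D_x / dt)
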
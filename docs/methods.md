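# Methods

## Model

Each of the N neurons is a single-compartment Hodgkin-Huxley membrane in
the classic squid-axon parameterization, written in the rest-near-0 mV
convention:

    C_m dV_i/dt = - g_Na m_i^3 h_i (V_i - E_Na) - g_K n_i^4 (V_i - E_K)
                  - g_L (V_i - E_L) + I0 + I_i^syn

with C_m = 1 uF/cm^2, g_Na = 120, g_K = 36, g_L = 0.3 mS/cm^2,
E_Na = 115, E_K = -12, E_L = 10.6 mV.  The gating rates are the classic
forms (alpha_m = 0.1(25-V)/(e^{(25-V)/10}-1), beta_m = 4 e^{-V/18},
alpha_h = 0.07 e^{-V/20}, beta_h = 1/(e^{(30-V)/10}+1),
alpha_n = 0.01(10-V)/(e^{(10-V)/10}-1), beta_n = 0.125 e^{-V/80});
this is the only convention compatible with the reversal potentials
above.  No temperature factor is applied.  At the bias current
I0 = 6.8 uA/cm^2 the deterministic neuron is bistable: a stable resting
equilibrium (V = 4.128 mV) coexists with a stable limit cycle
(57.0 Hz at dt = 0.01 ms); the basin boundary (an unstable periodic
orbit) lies much closer to the cycle than to the equilibrium, which is
the dynamical structure behind all the noise effects measured here.

## Channel noise

Channel-count fluctuations are modeled in the Langevin (diffusion)
approximation: each gate obeys

    dx/dt = alpha_x (1 - x) - beta_x x + xi_x(t),
    <xi_x(t) xi_x(t')> = 2 D_x delta(t - t'),
    D_m = alpha_m beta_m / [N_Na (alpha_m + beta_m)]    (h: same, N_Na)
    D_n = alpha_n beta_n / [N_K  (alpha_n + beta_n)]

with channel counts N_Na = 60/um^2 x A and N_K = 18/um^2 x A for a
membrane patch of area A.  A is the noise control parameter: noise
variance scales exactly as 1/A, and A = inf is the deterministic
sentinel.  Counts are kept real-valued — they enter only through the
variances and the diffusion approximation is continuous anyway.

## Coupling

Gap junctions: I_i = g_e sum_{j in neigh(i)} (V_j - V_i); currents sum
to zero over the network by antisymmetry.  Chemical synapses:
I_i = g_c (E_rev - V_i) sum_j s_j with E_rev = 70 mV (excitatory) or
-10 mV (inhibitory); each presynaptic open fraction s_j decays as
exp(-t/3 ms) and jumps by 1 at every presynaptic spike.  Edges are
undirected and chemical conduction is bidirectional (both endpoints are
presynaptic to each other), consistent with the symmetric adjacency.
Conductances are in mS/cm^2, making currents uA/cm^2 with V in mV.

## Topology

Degrees k_i are drawn from a continuous power law p(k) ~ k^-gamma
truncated to (k0, k_max), rounded to integers (floor 1).  The cap
k_max = sqrt(N <k>) is the unique choice that keeps the configurational
acceptance probabilities p_ij = k_i k_j / (N <k>) at or below 1; k0 is
then solved numerically (Brent) from the truncated-law mean identity so
that the distribution mean equals <k>.  If the drawn stub count is odd,
one node below the cap receives an extra stub.  Wiring proposes edges
between unconnected stub-holding pairs, accepting with p_ij, and sweeps
until every realized degree equals its drawn value (a hard
postcondition).  Dense sequences can stall structurally — the remaining
stub-holders are already pairwise connected — in which case a
degree-preserving double-edge swap frees compatible stubs and the
sweeps resume; the swap leaves the degree sequence exact and perturbs
the ensemble only in these rare end-games.  If the swap search also
fails, the sequence is redrawn.

## Integration

Fixed-step RK4 at dt = 0.01 ms (10 us).  The stochastic scheme draws
one standard normal z per gate, neuron and step, and adds
z sqrt(2 D_x / dt) to the gating derivative at all four stages; D_x is
re-evaluated at each stage's voltage (the intensities are
state-dependent) while z stays frozen.  This realizes "RK4 on the
Langevin equations" in a well-defined way; its strong convergence order
in the noise is that of Euler-Maruyama, which is adequate for additive
noise statistics at this step size (halving dt changes deterministic
5 s spike counts by at most 1, tested).  Gates are clipped to [0, 1]
after each committed step, since the Langevin scheme can overshoot the
unit interval.  The open fraction s is held constant within a step when
evaluating synaptic currents and advanced between steps by exact
exponential decay plus the unit jump of every neuron whose voltage
crossed 20 mV upward that step (edge detection by a per-neuron latch,
so one count per excursion; sub-step spike timing is below the 10 us
resolution and not interpolated).

Spikes are upward crossings of 20 mV.  Each run integrates a 1 s
transient (latch carried across the boundary, so a straddling spike is
not double-counted) and then records spikes for the measurement window
(5 s by default).  The population rate is nu = sum_i N_i^spikes/(N tau);
the synchrony measure is Var_t[Vbar]/mean_i Var_t[V_i] on voltage
traces subsampled to a 0.1 ms grid (the measure is grid-insensitive
well below spike timescales).

## Randomness

One master seed spawns per-realization seeds, which spawn one Philox
counter-based substream per neuron; the substream supplies the neuron's
initial condition (V ~ U(-10, 80) mV, gates ~ U(0, 1)) and then its
noise.  Consequences, both tested: identical seeds give bit-identical
rasters, and a g = 0 network factorizes exactly into single-neuron runs
on the same substreams.  Topology generation uses a separate
per-realization stream; every sweep realization gets a fresh topology
and fresh initial conditions.

## Study conditions and desk-scale choices

The full-scale study conditions are N = 200, gamma and <k> as per
experiment, A on [1, 1e5] um^2, 1 s transient + 5 s window, and
50 realizations per point.  Those defaults are what `SweepSpec` and
`SimulationProtocol` expose (`n_realizations=50` is the protocol
default; the sweep default of 10 is the desk-scale profile).  This
package's own test and reproduction runs scale the averaging down, not
the physics:

- Uncoupled (g = 0) checks use ensembles of 40-100 independent neurons;
  by the exact factorization above this is the same estimator as a
  g = 0 network with proportionally fewer realizations.
- Coupled checks keep <k>, gamma, g and A (per-neuron synaptic input
  statistics depend on these, not on N) and use N = 40-100 networks
  with 2-3 realizations; the size study confirms N-insensitivity.
- The termination census uses a 2.5 s measurement window: its
  classifier only asks whether fewer than N/10 neurons spike after the
  window's first 500 ms, and the immediate-termination/sustained
  distinction is settled well within 2.5 s.

The ISR detector is a fixed, documented criterion — "ISR observed" is
otherwise a visual judgement on rate curves: ISR is declared when the smallest
interior point of nu(A) is at most half the smaller endpoint rate and
the global minimum is interior.  The 0.5 depth ratio is reported with
every result; conclusions about where ISR disappears are made on a
conductance grid and quoted to within one grid step.

## What the generators emulate — and what they do not

The topology generator reproduces the power-law degree distribution,
the p_ij wiring rule and exact degree sequences; it does not model
degree correlations, clustering, directedness, spatial embedding or
autapses.  The initial-condition generator is the stated uniform box,
uncorrelated across neurons.  Neurons are point compartments with
homogeneous channel densities; synapses are single-exponential without
delays or plasticity, and each network is purely electrical, purely
excitatory or purely inhibitory.  Passing tests therefore support
claims about this model class, not about biological tissue: in real
networks mixed coupling, correlated inputs and dendritic filtering can
shift or suppress the ISR dip.

## Numerical choices and degenerate inputs

- Removable singularities of alpha_m (V = 25) and alpha_n (V = 10) are
  evaluated by series within 1e-7 of the singular point (in V/10
  units); agreement with the analytic limits is tested to 1e-6
  relative.
- alpha + beta = 0 would make a noise intensity 0/0; it is defined as
  D = 0 (noise-free gate).  It cannot occur for these rate functions.
- Constant voltage traces leave the synchrony denominator at rounding
  residue; anything below 1e-12 of the mean-square trace is treated as
  degenerate and reported as NaN with a warning.
- All-equal degree sequences make the power-law exponent estimate
  undefined; reported as NaN.
- Non-finite membrane potentials abort a run with a diagnostic rather
  than propagating.
- The compiled integrator is specialized to the default membrane
  parameters; constructing a run with any other `HHParams` raises
  rather than silently ignoring them.

## Known limitations

The Langevin channel-noise approximation degrades for very small
patches (A ~ 1 um^2, tens of channels) where discrete-state effects
matter; results at the small-A end describe the diffusion model, not
exact Markov channel gating.  Clipping gates to [0, 1] slightly biases
gate statistics at high noise.  The conductance units (mS/cm^2) are a
dimensional-consistency convention; only the printed dimensionless
magnitudes of g_e and g_c are meaningful for comparison.  The wiring
repair step departs from pure acceptance sampling in rare stalled
end-games of dense sequences.
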
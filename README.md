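# isrnet — inverse stochastic resonance in spiking networks

`isrnet` simulates populations of Hodgkin-Huxley neurons with ion-channel
noise, coupled through gap junctions or chemical synapses on random
scale-free graphs, and measures how the population firing rate depends
on the noise level.  It is built for studying **inverse stochastic
resonance (ISR)**: the counterintuitive *minimum* of the average spiking
rate at intermediate noise, the mirror image of stochastic resonance.
The intended users are computational neuroscientists studying
noise-driven switching in bistable neurons and its interaction with
network structure.

## Model

Each neuron follows the classic squid-axon Hodgkin-Huxley equations
(rest-near-0 convention) with a bias current I0 = 6.8 uA/cm^2 that makes
the cell bistable — a stable resting equilibrium coexists with a stable
~57 Hz limit cycle:

    C_m dV_i/dt = − g_Na m_i³h_i (V_i − E_Na) − g_K n_i⁴ (V_i − E_K)
                  − g_L (V_i − E_L) + I0 + I_i^syn

Channel noise enters through the Langevin (diffusion) approximation:
each gate x ∈ {m, h, n} receives Gaussian white noise of intensity
D_x = α_x β_x / [N(α_x + β_x)], with channel counts N set by the
membrane area A (ρ_Na = 60 /µm², ρ_K = 18 /µm²).  Area is therefore the
inverse noise dial: the ISR curve is the realization-averaged rate
ν(A) = Σᵢ Nᵢ^spikes/(N τ) over A ∈ [1, 10⁵] µm².

Networks are scale-free: degrees drawn from p(k) ∝ k^−γ truncated to
(k₀, √(N⟨k⟩)) and wired configurationally with acceptance probability
p_ij = k_i k_j/(N⟨k⟩) until every degree matches exactly.  Coupling is
electrical (I = g_e Σ (V_j − V_i)), excitatory (E_rev = 70 mV) or
inhibitory (E_rev = −10 mV) with single-exponential synapses
(τ_syn = 3 ms).  Integration is fixed-step RK4 at 10 µs with frozen
per-step noise draws; see `docs/methods.md` for the scheme and all
numerical conventions.

## Worked example

```python
import numpy as np
from isrnet import SweepSpec, SimulationProtocol, isr_curve, detect_isr

spec = SweepSpec(N=60, gamma=3.0, k_mean=3.0, mode="gap",
                 n_realizations=2, master_seed=7,
                 protocol=SimulationProtocol())
curve = isr_curve(spec, g=0.0)          # uncoupled: pure channel-noise ISR
print(np.round(curve.nu_mean, 2))
print(detect_isr(curve))
```

With g = 0 the neurons are independent, so this measures the
single-neuron ISR curve averaged over 120 neurons (runtime ~5 min).
Output:

    [67.66 60.25 55.79 51.21 44.19 31.18  8.04  0.    0.06 24.58 47.58]
    (True, 3162.2776601683795)

Read left (A = 1 µm², strong noise) to right (A = 10⁵ µm², weak noise):
at strong noise every neuron fires rapidly but randomly (~68 Hz); at
intermediate areas moderate noise traps neurons in the resting state
and the rate collapses to zero near A ≈ 3×10³ µm² — the ISR dip; as
noise vanishes the rate recovers toward (fraction of initial conditions
in the spiking basin) × 57 Hz.  `detect_isr` confirms an interior
minimum at least 50% below both endpoints and returns its location.

The numbered scripts under `analysis/` run the full campaigns (each
accepts `--seed`, `--out`, and `--quick`): `01_single_neuron.py`
(bistability + uncoupled ISR), `02_gap_junction_sweep.py` (ISR
destruction with increasing g_e), `03_excitatory_termination.py`
(synchronization-induced termination), `04_inhibitory_robustness.py`
(g_c-insensitive ISR and the dense-network onset), `05_size_study.py`
(N-invariance).  Each writes CSV tables under `results/`.

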
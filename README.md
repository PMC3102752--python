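# ordsim — the undiseased human ventricular action potential, in silico

`ordsim` is a simulator for the ORd dynamic model of the undiseased human
ventricular myocyte: 41 coupled ODEs for membrane voltage, Hodgkin–Huxley
channel gating (fast/late I_Na, I_to, I_CaL with separate Ca²⁺- and
voltage-dependent inactivation, I_Kr, I_Ks, I_K1), Na⁺/Ca²⁺ exchange and
Na⁺/K⁺-pump cycles, CaMKII signalling, and four-compartment Ca²⁺ cycling
with SR release/uptake.  It is aimed at cardiac electrophysiologists and
modellers who need the cell-level arrhythmia phenotypes of the human
ventricle — APD rate dependence and restitution, early
afterdepolarizations, APD/Ca²⁺ alternans — together with the wet-lab
protocols that validate them.

The package provides, as library functions and CLI subcommands:

* the single-cell model (`ordsim.model`) with endo/epi/M transmural
  variants, drug block as fractional conductance scaling, and optional
  CaMK removal (31-variable system);
* a deterministic hybrid-step integrator (`ordsim.integrator`) with
  Rush–Larsen gate updates and declarative interventions (ion clamps,
  per-beat gate resets, recovery freezes, waveform clamps);
* the experimental protocol suite (`ordsim.protocols`): steady-state rate
  dependence, S1S2 and dynamic restitution, accommodation, EAD and
  alternans induction, Na⁺/Ca²⁺ rate dependence, mechanistic clamp/reset
  experiments;
* a virtual voltage-clamp workbench (`ordsim.clamp`): step families, FRC
  analysis (CDI vs VDI), steady-state activation/inactivation curves,
  tail-current I–V, double-pulse recovery, AP-clamp difference currents;
* a 1D monodomain fiber (`ordsim.fiber`) for conduction velocity and the
  transmural-wedge pseudo-ECG.

## Worked example

Pace an endocardial cell to steady state at a 1000 ms cycle length and
report the classic AP metrics:

```python
from ordsim import make_params, steady_state_pace

params = make_params("endo")
res = steady_state_pace(params, cl=1000.0, max_beats=1000)
beat = res.beats.iloc[-1]
print(f"APD90     = {beat.apd90:.1f} ms")
print(f"dV/dt max = {beat.dvdt_max:.0f} mV/ms")
print(f"[Na+]i    = {res.state['nai']:.2f} mM")
```

prints

```
APD90     = 272.0 ms
dV/dt max = 255 mV/ms
[Na+]i    = 7.25 mM
```

i.e. an action potential duration of 272 ms (undiseased human endocardial
preparations: ~275 ms), a fast-Na⁺-driven upstroke of ~255 mV/ms
(nonfailing human myocytes: 234 ± 28 mV/ms), and a diastolic intracellular
sodium of 7.25 mM.  From the same state, fast pacing exposes the
arrhythmia phenotypes:

```python
from ordsim.protocols import alternans_metrics
fast = steady_state_pace(params, cl=250.0, start_state=res.state,
                         max_beats=1000)
print(alternans_metrics(fast))
# {'delta_apd90': 10.849..., 'delta_ca_peak': 0.000878..., 'block_2to1': False}
```

— a stable period-2 rhythm alternating by ~11 ms in APD90, driven by the
Ca²⁺ subsystem (it disappears with CaMK disabled or SERCA uptake raised
20%).  The same protocols are available from the shell:

```bash
ordsim simulate --cl 1000 --beats 10 --out results/
ordsim alternans --cl 250
ordsim ead --cl 4000 --ikr-block 0.85
ordsim ecg --beats 3
```

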
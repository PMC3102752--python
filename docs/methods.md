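# Methods

## The model

`ordsim` implements the ORd dynamic model of the undiseased
human ventricular myocyte: a deterministic system of 41 ordinary
differential equations (31 with CaMK signalling disabled) describing
membrane voltage, Hodgkin–Huxley gating for nine reformulated currents
(fast and late I_Na, I_to, I_CaL with its Ca²⁺- vs voltage-dependent
inactivation partition, I_Kr, I_Ks, I_K1, I_NaCa, I_NaK), background and
pump currents, and Ca²⁺ cycling across four compartments (bulk myoplasm,
subspace, network and junctional SR) with CMDN/TRPN/BSR/BSL/CSQN buffering.

Key structural choices of the formulation, preserved here:

* **CDI n-gate.** The fraction of L-type channels operating in
  calcium-dependent-inactivation mode is a state variable (`nca`), driven
  by subspace Ca²⁺/calmodulin binding; CDI behaves as a faster VDI.
  Forcing `nca = 0` is the in-silico analogue of Ba²⁺ as charge carrier.
* **Two-time-constant gates.** Where inactivation/deactivation is
  bi-exponential (I_to, I_CaL VDI, I_Kr), fast and slow gates are combined
  by a voltage-dependent *weighted sum*, never a product.
* **CaMK population mixing.** Every CaMK-sensitive quantity is computed
  twice — fully phosphorylated and non-phosphorylated — and mixed with the
  weight CaMKa/(CaMKa + K_mCaMK).  Disabling CaMK removes the ten
  phosphorylated-pathway states, leaving the 31-variable system.
* **Transmural cell types.** Epi and M parameters are derived from the
  endo baseline by fixed expression-ratio scalings (late I_Na, I_to,
  I_CaL, I_Kr, I_Ks, I_K1, NCX, NaK, I_Kb, J_rel, J_up, calmodulin), plus
  an epi-specific speed-up of I_to inactivation at hyperpolarized
  voltages.
* **Smoothness.** GHK-type flux expressions use a series expansion near
  Vm = 0 so the right-hand side is free of singularities on the whole
  physiological voltage range.

All constants and initial conditions live in `ordsim.constants`, the
single authoritative table used by both the implementation and the test
oracle (an independently transcribed copy of the complete equation set,
compared to 1e-10 relative in the test suite).

## Numerics

Gates advance by the exponential (Rush–Larsen) update, which is exact for
frozen voltage and unconditionally stable; voltage, concentrations and the
CaMK trap advance by forward Euler.  The time step is hybrid, keyed to
|dVm/dt|:

| phase | dt (ms) | criterion |
|---|---|---|
| stimulus & upstroke | 0.005 | during stimulus or \|dV/dt\| > 0.2 mV/ms |
| plateau / repolarization | 0.02 | \|dV/dt\| > 0.02 mV/ms |
| diastole | 0.1 | otherwise |

Halving all three steps changes steady-state APD90 at CL = 1000 ms by
< 0.05 ms, and the APD error shrinks roughly linearly with dt (first-order
scheme), so the default grid is well inside the 0.5 ms acceptance
tolerance.  The alternans amplitude at CL = 250 ms is the quantity most
sensitive to dt (10.9 ms at the default grid, 10.5 ms at half steps).
Per-beat APDs are measured *inside* the integrator at full resolution:
AP onset is the time of maximum dVm/dt, and APD_X ends where Vm falls
below X% of the pre-stimulus resting voltage (linear interpolation between
steps).  Any non-finite state aborts the run with the step index.

The default stimulus is −80 µA/µF for 0.5 ms (charge carried by K⁺).
The documented initial conditions start at Vm = −87 mV (a rounded value);
the quiescent model relaxes by ~1 mV to its true rest near −88.1 mV and
is then stationary.

Steady-state pacing stops when the relative L∞ change of the pre-stimulus
state between consecutive beats (or beats n and n−2 for a period-2 orbit)
falls below 1e-6, with per-variable absolute floors of 1e-3 of a
characteristic magnitude so that physically meaningless diastolic tails
(e.g. the release-flux state, ~1e-7 mM/ms between beats) cannot dominate;
the cap is 1000 beats, the published count for true steady state.  The Na⁺
pool is the slowest mode, so headline quantities (APD90, [Na⁺]i) are
stationary well before the formal criterion is met.

## Protocols and their problem sizes

* **Rate dependence / restitution** pace each cycle length to steady state
  (descending order, carrying the previous state).  S1S2 delivers the S2
  at DI measured from APD90 completion; DI < 0 is outside the protocol's
  domain and rejected.
* **Dynamic restitution** paces 30 s per CL from 1000 down to 230 ms and
  plots APD95 against DI = CL − APD95 of the preceding beat, keeping both
  alternans phases; bifurcation is flagged where consecutive-beat APD95
  differ by > 1 ms (1 ms cleanly separates alternans from numerical
  noise, which is < 0.1 ms).
* **Alternans / 2:1 block.** Each test rate is paced from the 1 Hz steady
  state.  This matters: a slowly descending CL sweep that carries the
  adapted state across rates sustains a metastable alternating 1:1 rhythm
  down to ~205 ms, whereas from the 1 Hz baseline the model blocks 2:1 for
  every CL ≤ 225 ms (within the first handful of beats) and captures 1:1
  with ~11 ms alternans at 230–250 ms.
* **EADs** follow the slow-pacing protocol (CL = 4000 ms, 85% I_Kr block,
  300 conditioning beats — the state at slow rate is essentially settled
  long before the formal 1000-beat criterion).  Detection: dVm/dt turning
  positive above −40 mV after the AP peak followed by a rise ≥ 1 mV.  The
  mechanistic control prevents I_CaL recovery by letting the VDI/CDI
  inactivation gates move only downward during the measured beat.
* **Accommodation** (Franz protocol): steady state at the first CL, abrupt
  switch, 600–900 s at the new CL (the course is settled well within
  either window); a single exponential with offset is fit
  to APD90 versus wall time from the *first post-switch beat* (the switch
  beat itself carries the instantaneous restitution step, which is not
  accommodation; the early "notching" overshoot is retained in the fit
  window and in the reported course).
* **Voltage clamp** isolates channel kinetics: concentrations are pinned
  at pipette/bath-like values; only for the L-type current is subspace
  Ca²⁺ dynamic (CDI requires Ca²⁺ entry).  Step families use a 3–5 s
  holding equilibration in place of the wet interpulse interval.  CaMK is
  off in clamp mode unless requested.  AP-clamp "difference currents"
  default to full subtraction since simulated channels are noiseless.
* **Fiber**: monodomain cable, one node per cell (dx = 0.01 cm = cell
  length), no-flux ends, operator splitting (reaction then explicit
  diffusion), global hybrid dt capped by the diffusion stability limit.
  The diffusion coefficient D = 1.4127e-3 cm²/ms was tuned once so a
  homogeneous endo strand paced at 1 Hz (from per-cell single-cell steady
  states) conducts at 45.0 cm/s between interior cells, then frozen.
  Cable end-stimulation uses a 2 ms, −80 µA/µF pulse (the single-cell
  0.5 ms pulse cannot charge the cable end past threshold against the
  electrotonic load).  The transmural wedge is 60 endo / 45 M / 60 epi
  cells stimulated at the endo end; the pseudo-ECG is the
  distance-weighted integral of the spatial voltage gradient at an axial
  electrode 2 cm past the epi end, excluding 15 cells at each end.
  CV and wedge runs use 1–3 beats from per-cell steady-state initial
  conditions (the strand re-equilibrates within a beat or two, since each
  cell starts on its own limit cycle).

## Known limitations and open discrepancies

These are properties of this implementation measured honestly against the
published headline values; everything below is reproduced by
`scripts/acceptance.py` at run time.

* **Reproduced quantitatively**: APD90 = 272.0 ms and [Na⁺]i = 7.25 mM at
  CL = 1000 ms; max dVm/dt = 255 mV/ms; [Na⁺]i = 6.2 mM at CL = 2000 ms;
  APD alternans ~10.9 ms at CL = 250 ms, eliminated by CaMK suppression or
  a 20% J_up increase; 2:1 block below CL = 230 ms; dynamic-restitution
  bifurcation confined to DI < 90 ms; exactly one EAD under 85% I_Kr
  block at CL = 4000 ms and none without block or without I_CaL recovery;
  CV = 45 cm/s at 1 Hz; upright, rate-dependent T wave; transmural APD
  ordering epi (231) < endo (272) < M (333 ms).
* **Late Na⁺ current scale.** The canonical released conductance
  (G_NaL = 0.0075 mS/µF) yields −0.27 pA/pF for the Maltsev-protocol mean
  (published scaling target −0.356) and 0.13 µA/µF for the free-running
  late peak (published ~0.15).  The internal ratio — AP peak ≈ half the
  I–V maximum — holds exactly, so the discrepancy is a single overall
  scale whose origin we could not reconstruct; we keep the canonical
  conductance rather than rescale to the printed number.
* **Quiescent conduction velocity.** With coupling frozen at the 45 cm/s
  anchor, a single beat from quiescence conducts at ~55 cm/s, not the
  published 70 cm/s; the availability gain of the quiescent state
  (h·j ≈ 1.0 vs ≈ 0.5) is eroded during the upstroke foot and supports a
  CV ratio of ~1.2, not 1.56.
* **Accommodation kinetics.** The bulk-Na⁺ relaxation time constant of
  these equations is ~90 s at CL = 480 ms, so fitted APD-accommodation
  time constants come out near 105 s for all four Franz protocol legs,
  versus the published 165–300 s, even though every Na⁺ *equilibrium*
  value verifies.  The fitted tau is insensitive to fit-window choices we
  tried (300–1800 s, with or without the first beats).
* **I_Ks block margin.** 90% I_Ks block prolongs APD90 by 15.4 ms at
  CL = 1000 ms against the published "< 15 ms" — a ~1 ms margin that is
  within plausible measurement-convention differences but fails the bound
  as stated.
* The AP-clamp experiments use the model's own steady-state AP as the
  command waveform (the experimental waveforms are not tabulated), so
  AP-clamp comparisons are morphological, not quantitative.
* No β-adrenergic signalling, no H⁺/CO₂/HCO₃⁻ fluxes, no Markov channel
  variants, 37 °C only, 1D tissue only.
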
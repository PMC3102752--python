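"""Authoritative constant tables for the ORd human ventricular myocyte model.

Everything numerical that defines the model lives here: physical constants,
cell geometry, the 41-variable state layout, resting initial conditions,
baseline (endocardial) maximal conductances/permeabilities, buffer and CaMK
constants, and the transmural (epi / M) scaling table.  Both the simulation
kernel and the public parameter objects read from this module, so there is a
single place where a constant can be right or wrong.

Units follow the cardiac-modelling convention: time in ms, voltage in mV,
concentrations in mM, currents in uA/uF, fluxes in mM/ms, volumes in uL.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# Physical constants and cell geometry (37 C only)
# ---------------------------------------------------------------------------

R_GAS = 8314.0       # J / (kmol K)
TEMP = 310.0         # K
FARADAY = 96485.0    # C / mol

CELL_LENGTH = 0.01   # cm
CELL_RADIUS = 0.0011  # cm

VCELL = 1000.0 * math.pi * CELL_RADIUS ** 2 * CELL_LENGTH          # uL
AGEO = 2.0 * math.pi * CELL_RADIUS ** 2 + 2.0 * math.pi * CELL_RADIUS * CELL_LENGTH
ACAP = 2.0 * AGEO    # cm^2, capacitive area (membrane folding factor 2)
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

# Extracellular (bath) concentrations, mM
NAO = 140.0
CAO = 1.8
KO = 5.4

# ---------------------------------------------------------------------------
# State vector layout: 41 variables (31 with CaMK disabled)
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "v",                                            # membrane potential, mV
    "nai", "nass", "ki", "kss",                     # Na+/K+ concentrations
    "cai", "cass", "cansr", "cajsr",                # Ca2+ concentrations
    "m", "hf", "hs", "j", "hsp", "jp",              # fast INa gates
    "mL", "hL", "hLp",                              # late INa gates
    "a", "iF", "iS", "ap", "iFp", "iSp",            # Ito gates
    "d", "ff", "fs", "fcaf", "fcas", "jca",         # ICaL VDI/CDI gates
    "nca", "ffp", "fcafp",                          # ICaL CDI fraction + CaMK gates
    "xrf", "xrs",                                   # IKr gates
    "xs1", "xs2",                                   # IKs gates
    "xk1",                                          # IK1 gate
    "Jrelnp", "Jrelp",                              # RyR release flux states
    "CaMKt",                                        # trapped CaMK fraction
)
N_STATE = len(STATE_NAMES)
assert N_STATE == 41

STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}

# States that exist only because of CaMK signalling.  Without CaMK the model
# is the 31-variable system of the same equations with all phosphorylated
# pathways removed.
CAMK_STATE_NAMES = ("hsp", "jp", "hLp", "ap", "iFp", "iSp",
                    "ffp", "fcafp", "Jrelp", "CaMKt")
assert len(STATE_NAMES) - len(CAMK_STATE_NAMES) == 31

# Gating-type variables advanced by the exponential (Rush-Larsen) update:
# everything from "m" through "Jrelp" (indices 9..39 inclusive).
GATE_SLICE = slice(STATE_INDEX["m"], STATE_INDEX["Jrelp"] + 1)
N_GATE = GATE_SLICE.stop - GATE_SLICE.start  # 31

# Documented resting initial conditions (identical for all cell types).
_INITIAL = {
    "v": -87.0,
    "nai": 7.0, "nass": 7.0, "ki": 145.0, "kss": 145.0,
    "cai": 1.0e-4, "cass": 1.0e-4, "cansr": 1.2, "cajsr": 1.2,
    "m": 0.0, "hf": 1.0, "hs": 1.0, "j": 1.0, "hsp": 1.0, "jp": 1.0,
    "mL": 0.0, "hL": 1.0, "hLp": 1.0,
    "a": 0.0, "iF": 1.0, "iS": 1.0, "ap": 0.0, "iFp": 1.0, "iSp": 1.0,
    "d": 0.0, "ff": 1.0, "fs": 1.0, "fcaf": 1.0, "fcas": 1.0, "jca": 1.0,
    "nca": 0.0, "ffp": 1.0, "fcafp": 1.0,
    "xrf": 0.0, "xrs": 0.0, "xs1": 0.0, "xs2": 0.0, "xk1": 1.0,
    "Jrelnp": 0.0, "Jrelp": 0.0, "CaMKt": 0.0,
}

INITIAL_STATE = np.array([_INITIAL[n] for n in STATE_NAMES])

# ---------------------------------------------------------------------------
# Baseline (endocardial) parameter vector
# ---------------------------------------------------------------------------
# The kernel receives parameters as a flat float64 array; the P_* indices name
# its slots.  Cell-type and drug scalings multiply entries of this array.

P_GNA = 0      # fast INa conductance, mS/uF
P_GNAL = 1     # late INa conductance
P_GTO = 2      # Ito conductance
P_PCA = 3      # ICaL permeability
P_GKR = 4      # IKr conductance
P_GKS = 5      # IKs conductance
P_GK1 = 6      # IK1 conductance
P_GNCX = 7     # Na/Ca exchanger scale
P_PNAK = 8     # Na/K pump scale
P_GKB = 9      # background K conductance
P_PNAB = 10    # background Na permeability
P_PCAB = 11    # background Ca permeability
P_GPCA = 12    # sarcolemmal Ca pump scale
P_JREL = 13    # RyR release flux scale
P_JUP = 14     # SERCA uptake scale
P_CMDN = 15    # calmodulin buffer capacity, mM
P_NAO = 16     # extracellular Na, mM
P_CAO = 17     # extracellular Ca, mM
P_KO = 18      # extracellular K, mM
N_PARAM = 19

BASE_PARAMS = np.zeros(N_PARAM)
BASE_PARAMS[P_GNA] = 75.0
BASE_PARAMS[P_GNAL] = 0.0075
BASE_PARAMS[P_GTO] = 0.02
BASE_PARAMS[P_PCA] = 0.0001
BASE_PARAMS[P_GKR] = 0.046
BASE_PARAMS[P_GKS] = 0.0034
BASE_PARAMS[P_GK1] = 0.1908
BASE_PARAMS[P_GNCX] = 0.0008
BASE_PARAMS[P_PNAK] = 30.0
BASE_PARAMS[P_GKB] = 0.003
BASE_PARAMS[P_PNAB] = 3.75e-10
BASE_PARAMS[P_PCAB] = 2.5e-8
BASE_PARAMS[P_GPCA] = 0.0005
BASE_PARAMS[P_JREL] = 1.0
BASE_PARAMS[P_JUP] = 1.0
BASE_PARAMS[P_CMDN] = 0.05
BASE_PARAMS[P_NAO] = NAO
BASE_PARAMS[P_CAO] = CAO
BASE_PARAMS[P_KO] = KO

# Transmural expression scaling (relative to the validated endo baseline).
# Targets: late INa, Ito, ICaL, IKr, IKs, IK1, NCX, NaK, IKb, Jrel, Jup, CMDN.
CELLTYPE_ENDO = 0
CELLTYPE_EPI = 1
CELLTYPE_M = 2

CELLTYPE_SCALING = {
    CELLTYPE_EPI: {
        P_GNAL: 0.6, P_GTO: 4.0, P_PCA: 1.2, P_GKR: 1.3, P_GKS: 1.4,
        P_GK1: 1.2, P_GNCX: 1.1, P_PNAK: 0.9, P_GKB: 0.6,
        P_JUP: 1.3, P_CMDN: 1.3,
    },
    CELLTYPE_M: {
        P_GTO: 4.0, P_PCA: 2.5, P_GKR: 0.8, P_GK1: 1.3,
        P_GNCX: 1.4, P_PNAK: 0.7, P_JREL: 1.7,
    },
}

# ---------------------------------------------------------------------------
# Fixed kinetic constants used inside the kernel
# ---------------------------------------------------------------------------

# CaMK signalling
CAMK_A = 0.05        # phosphorylation (trapping) rate, 1/ms
CAMK_B = 0.00068     # dephosphorylation rate, 1/ms
CAMK_O = 0.05        # fraction of active binding sites at saturating Ca
KM_CAM = 0.0015      # CaM/Ca half saturation, mM
KM_CAMK = 0.15       # phosphorylation half saturation on CaMKa

PKNA = 0.01833       # IKs Na+/K+ permeability ratio

# Ca2+ buffers (myoplasm / subspace / JSR), mM
KM_CMDN = 0.00238
TRPN_MAX = 0.07
KM_TRPN = 0.0005
BSR_MAX = 0.047
KM_BSR = 0.00087
BSL_MAX = 1.124
KM_BSL = 0.0087
CSQN_MAX = 10.0
KM_CSQN = 0.8

# Default stimulus (charge carried by K+)
STIM_AMP = -80.0     # uA/uF (carried by K+)
STIM_DUR = 0.5       # ms

# Default hybrid time-step scheme (see docs/methods.md)
DT_FAST = 0.005      # ms, during stimulus and upstroke (|dV/dt| > THR_FAST)
DT_MID = 0.02        # ms, plateau / repolarization
DT_SLOW = 0.1        # ms, diastole (|dV/dt| < THR_MID)
THR_FAST = 0.2       # mV/ms
THR_MID = 0.02       # mV/ms

# Monodomain fiber: one node per cell, dx = cell length.  The diffusion
# coefficient was tuned once so a homogeneous endo strand conducts at
# 45 cm/s during steady 1 Hz pacing, then frozen (see docs/methods.md).
FIBER_DX = CELL_LENGTH                  # cm
FIBER_DIFF = 1.4127e-3                  # cm^2/ms  (frozen; see docs/methods.md)
FIBER_STIM_DUR = 2.0                    # ms; cable end-stimulation needs a
                                        # longer pulse than the single cell
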
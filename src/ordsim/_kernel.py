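"""Numba-compiled numerical core: right-hand side and time steppers.

The single-cell right-hand side (`compute_rhs`) evaluates every membrane
current, intracellular flux, gate steady state / time constant, and state
derivative at one instant.  Three integration drivers share it:

* `run_cell`    -- paced free-running cell with intervention hooks,
* `run_vclamp`  -- voltage-clamp mode (imposed Vm, frozen bath/pipette
                   concentrations, optionally dynamic subspace Ca2+),
* `run_fiber`   -- 1D monodomain strand with operator splitting.

Gates advance with the exponential (Rush-Larsen) update; voltage,
concentrations and the CaMK trap advance with forward Euler on a hybrid
time step keyed to |dVm/dt|.  Everything here is deterministic.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .constants import (
    ACAP, BSL_MAX, BSR_MAX, CAMK_A, CAMK_B, CAMK_O, CSQN_MAX, FARADAY,
    KM_BSL, KM_BSR, KM_CAM, KM_CAMK, KM_CMDN, KM_CSQN, KM_TRPN, PKNA,
    P_CAO, P_CMDN, P_GK1, P_GKB, P_GKR, P_GKS, P_GNA, P_GNAL, P_GNCX,
    P_GPCA, P_GTO, P_JREL, P_JUP, P_KO, P_NAO, P_PCA, P_PCAB, P_PNAB,
    P_PNAK, R_GAS, TEMP, TRPN_MAX, VJSR, VMYO, VNSR, VSS,
)

RTF = R_GAS * TEMP / FARADAY
FRT = 1.0 / RTF

# current / flux snapshot layout
C_INA = 0
C_INAL = 1
C_ITO = 2
C_ICAL = 3
C_ICANA = 4
C_ICAK = 5
C_IKR = 6
C_IKS = 7
C_IK1 = 8
C_INACA_I = 9
C_INACA_SS = 10
C_INAK = 11
C_INAB = 12
C_ICAB = 13
C_IKB = 14
C_IPCA = 15
C_ISTIM = 16
C_JREL = 17
C_JUP = 18
C_JTR = 19
C_JDIFFNA = 20
C_JDIFFCA = 21
C_JDIFFK = 22
C_JLEAK = 23
C_CAMKA = 24
N_CUR = 25

_BIG_TAU = 1.0e12


@njit(cache=True, fastmath=False)
def _ghk_flux(z, vfrt, vffrt, a_in, a_out):
    """Constant-field flux z^2*vffrt*(a_in*e^{z vfrt}-a_out)/(e^{z vfrt}-1).

    Series expansion near Vm = 0 keeps the expression smooth.
    """
    x = z * vfrt
    if abs(x) < 1.0e-5:
        # vffrt = x*F/z; flux -> z*F*((a_in-a_out) + x*(a_in+a_out)/2)
        return z * FARADAY * ((a_in - a_out) + 0.5 * x * (a_in + a_out))
    e = math.exp(x)
    return z * z * vffrt * (a_in * e - a_out) / (e - 1.0)


@njit(cache=True, fastmath=False)
def _ncx(v, na, ca, nao, cao):
    """Na/Ca exchanger turnover (per unit scale) for one compartment."""
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = math.exp(qca * v * FRT)
    hna = math.exp(qna * v * FRT)
    h1 = 1.0 + na / kna3 * (1.0 + hna)
    h2 = (na * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + na / kna1 * (1.0 + na / kna2)
    h5 = na * na / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * ca * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    s = x1 + x2 + x3 + x4
    e1 = x1 / s
    e2 = x2 / s
    e3 = x3 / s
    e4 = x4 / s
    allo = 1.0 / (1.0 + (150.0e-6 / ca) ** 2.0)
    jna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
    jca = e2 * k2 - e1 * k1
    return allo * (jna + 2.0 * jca)


@njit(cache=True, fastmath=False)
def compute_rhs(y, p, celltype, camk_on, ist, cur, ginf, gtau, dy):
    """Evaluate currents, fluxes, gate kinetics and state derivatives.

    Fills `cur[N_CUR]`, `ginf[31]`/`gtau[31]` (states 9..39) and `dy[41]`.
    Gate entries of `dy` are (ginf-g)/gtau so that `dy` is the complete
    time derivative of the state vector.
    """
    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]

    nao = p[P_NAO]
    cao = p[P_CAO]
    ko = p[P_KO]

    vfrt = v * FRT
    vffrt = v * FARADAY * FRT

    ena = RTF * math.log(nao / nai)
    ek = RTF * math.log(ko / ki)
    eks = RTF * math.log((ko + PKNA * nao) / (ki + PKNA * nai))

    # ---- CaMK ----------------------------------------------------------
    if camk_on:
        camkb = CAMK_O * (1.0 - y[40]) / (1.0 + KM_CAM / cass)
        camka = camkb + y[40]
        dy[40] = CAMK_A * camkb * (camkb + y[40]) - CAMK_B * y[40]
        fp = 1.0 / (1.0 + KM_CAMK / camka)
    else:
        camka = 0.0
        dy[40] = 0.0
        fp = 0.0
    cur[C_CAMKA] = camka

    # ---- fast INa ------------------------------------------------------
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77)
                + 8.552 * math.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                 + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * math.exp((v + 5.730) / 56.66))
    ahf = 0.99
    ahs = 1.0 - ahf
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * math.exp((v + 0.9941) / 38.45))
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))  # CaMK: -6.2 mV shift
    thsp = 3.0 * ths
    tjp = 1.46 * tj
    ginf[0] = mss
    gtau[0] = tm
    ginf[1] = hss
    gtau[1] = thf
    ginf[2] = hss
    gtau[2] = ths
    ginf[3] = jss
    gtau[3] = tj
    ginf[4] = hssp
    gtau[4] = thsp
    ginf[5] = jss
    gtau[5] = tjp
    h = ahf * y[1 + 9] + ahs * y[2 + 9]
    hp = ahf * y[1 + 9] + ahs * y[4 + 9]
    m = y[9]
    ina = (p[P_GNA] * (v - ena) * m ** 3
           * ((1.0 - fp) * h * y[12] + fp * hp * y[14]))

    # ---- late INa ------------------------------------------------------
    mlss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    hlss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    hlssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    thl = 200.0
    ginf[6] = mlss
    gtau[6] = tm
    ginf[7] = hlss
    gtau[7] = thl
    ginf[8] = hlssp
    gtau[8] = 3.0 * thl
    inal = (p[P_GNAL] * (v - ena) * y[15]
            * ((1.0 - fp) * y[16] + fp * y[17]))

    # ---- Ito -----------------------------------------------------------
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    if celltype == 1:  # epi: faster inactivation at hyperpolarized Vm
        delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tif = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * math.exp((v + 50.0) / 16.59))
    tis = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    tif *= delta_epi
    tis *= delta_epi
    aif = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    ais = 1.0 - aif
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))  # CaMK: +10 mV shift
    dti_dev = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89)
                                + math.exp(-(v - 12.23) / 0.2154))
    dti_rec = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    ginf[9] = ass
    gtau[9] = ta
    ginf[10] = iss
    gtau[10] = tif
    ginf[11] = iss
    gtau[11] = tis
    ginf[12] = assp
    gtau[12] = ta
    ginf[13] = iss
    gtau[13] = dti_dev * dti_rec * tif
    ginf[14] = iss
    gtau[14] = dti_dev * dti_rec * tis
    i_gate = aif * y[19] + ais * y[20]
    ip_gate = aif * y[22] + ais * y[23]
    ito = (p[P_GTO] * (v - ek)
           * ((1.0 - fp) * y[18] * i_gate + fp * y[21] * ip_gate))

    # ---- ICaL (with CDI n-gate) ---------------------------------------
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * math.exp((v + 5.0) / 6.0))
    aff = 0.6
    afs = 1.0 - aff
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0)
                         + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0)
                           + 0.00012 * math.exp(v / 7.0))
    afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    afcas = 1.0 - afcaf
    tjca = 75.0
    ginf[15] = dss
    gtau[15] = td
    ginf[16] = fss
    gtau[16] = tff
    ginf[17] = fss
    gtau[17] = tfs
    ginf[18] = fss
    gtau[18] = tfcaf
    ginf[19] = fss
    gtau[19] = tfcas
    ginf[20] = fss
    gtau[20] = tjca
    ginf[22] = fss
    gtau[22] = 2.5 * tff      # ffp: CaMK 2.5-fold faster fast VDI
    ginf[23] = fss
    gtau[23] = 2.5 * tfcaf    # fcafp
    f = aff * y[25] + afs * y[26]
    fca = afcaf * y[27] + afcas * y[28]
    fp_gate = aff * y[31] + afs * y[26]
    fcap = afcaf * y[32] + afcas * y[28]
    jca = y[29]
    nca = y[30]
    # n-gate: CDI-mode fraction, driven by subspace Ca2+/CaM binding
    kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / max(km2n, 1.0e-12) + (1.0 + kmn / cass) ** 4.0)
    ginf[21] = anca * k2n / max(km2n, 1.0e-12)
    gtau[21] = 1.0 / max(km2n, 1.0e-12)
    phical = _ghk_flux(2.0, vfrt, vffrt, cass, 0.341 * cao)
    phicana = _ghk_flux(1.0, vfrt, vffrt, 0.75 * nass, 0.75 * nao)
    phicak = _ghk_flux(1.0, vfrt, vffrt, 0.75 * kss, 0.75 * ko)
    pca = p[P_PCA]
    pcap = 1.1 * pca
    pcana = 0.00125 * pca
    pcak = 3.574e-4 * pca
    pcanap = 0.00125 * pcap
    pcakp = 3.574e-4 * pcap
    d = y[24]
    gate_np = f * (1.0 - nca) + jca * fca * nca
    gate_p = fp_gate * (1.0 - nca) + jca * fcap * nca
    ical = d * ((1.0 - fp) * pca * phical * gate_np
                + fp * pcap * phical * gate_p)
    icana = d * ((1.0 - fp) * pcana * phicana * gate_np
                 + fp * pcanap * phicana * gate_p)
    icak = d * ((1.0 - fp) * pcak * phicak * gate_np
                + fp * pcakp * phicak * gate_p)

    # ---- IKr -----------------------------------------------------------
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    axrs = 1.0 - axrf
    ginf[24] = xrss
    gtau[24] = txrf
    ginf[25] = xrss
    gtau[25] = txrs
    xr = axrf * y[33] + axrs * y[34]
    rkr = (1.0 / (1.0 + math.exp((v + 55.0) / 75.0))
           / (1.0 + math.exp((v - 10.0) / 30.0)))
    ikr = p[P_GKR] * math.sqrt(ko / 5.4) * xr * rkr * (v - ek)

    # ---- IKs -----------------------------------------------------------
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                          + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    ginf[26] = xs1ss
    gtau[26] = txs1
    ginf[27] = xs1ss
    gtau[27] = txs2
    ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    iks = p[P_GKS] * ksca * y[35] * y[36] * (v - eks)

    # ---- IK1 -----------------------------------------------------------
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * ko + 144.59)
                                  / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36)
                    + math.exp((v + 236.8) / 69.33))
    ginf[28] = xk1ss
    gtau[28] = txk1
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * ko) / 9.493))
    ik1 = p[P_GK1] * math.sqrt(ko) * rk1 * y[37] * (v - ek)

    # ---- INaCa (80% myoplasm, 20% subspace) ----------------------------
    inaca_i = 0.8 * p[P_GNCX] * _ncx(v, nai, cai, nao, cao)
    inaca_ss = 0.2 * p[P_GNCX] * _ncx(v, nass, cass, nao, cao)

    # ---- INaK (Smith-Crampin scheme) -----------------------------------
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p = 1899.0
    k3m = 79300.0
    k4p = 639.0
    k4m = 40.0
    knai0 = 9.073
    knao0 = 27.78
    delta = -0.1550
    knai = knai0 * math.exp(delta * vfrt / 3.0)
    knao = knao0 * math.exp((1.0 - delta) * vfrt / 3.0)
    kki = 0.5
    kko = 0.3582
    mgadp = 0.05
    mgatp = 9.8
    kmgatp = 1.698e-7
    hconc = 1.0e-7
    ep = 4.2
    khp = 1.698e-7
    knap = 224.0
    kxkur = 292.0
    pconc = ep / (1.0 + hconc / khp + nai / knap + ki / kxkur)
    a1 = (k1p * (nai / knai) ** 3.0
          / ((1.0 + nai / knai) ** 3.0 + (1.0 + ki / kki) ** 2.0 - 1.0))
    b1 = k1m * mgadp
    a2 = k2p
    b2 = (k2m * (nao / knao) ** 3.0
          / ((1.0 + nao / knao) ** 3.0 + (1.0 + ko / kko) ** 2.0 - 1.0))
    a3 = (k3p * (ko / kko) ** 2.0
          / ((1.0 + nao / knao) ** 3.0 + (1.0 + ko / kko) ** 2.0 - 1.0))
    b3 = k3m * pconc * hconc / (1.0 + mgatp / kmgatp)
    a4 = k4p * mgatp / kmgatp / (1.0 + mgatp / kmgatp)
    b4 = (k4m * (ki / kki) ** 2.0
          / ((1.0 + nai / knai) ** 3.0 + (1.0 + ki / kki) ** 2.0 - 1.0))
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b1 * a1
    s = x1 + x2 + x3 + x4
    e1 = x1 / s
    e2 = x2 / s
    e3 = x3 / s
    e4 = x4 / s
    jnak_na = 3.0 * (e1 * a3 - e2 * b3)
    jnak_k = 2.0 * (e4 * b1 - e3 * a1)
    inak = p[P_PNAK] * (jnak_na + jnak_k)

    # ---- background and pump currents ----------------------------------
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    ikb = p[P_GKB] * xkb * (v - ek)
    inab = p[P_PNAB] * _ghk_flux(1.0, vfrt, vffrt, nai, nao)
    icab = p[P_PCAB] * _ghk_flux(2.0, vfrt, vffrt, cai, 0.341 * cao)
    ipca = p[P_GPCA] * cai / (0.0005 + cai)

    # ---- SR fluxes ------------------------------------------------------
    bt = 4.75
    a_rel = 0.5 * bt
    jrel_inf = a_rel * (-ical) / (1.0 + (1.5 / cajsr) ** 8.0)
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    jrel_infp = a_relp * (-ical) / (1.0 + (1.5 / cajsr) ** 8.0)
    # transmural (M-cell) release scaling arrives via P_JREL
    jrel_inf *= p[P_JREL]
    jrel_infp *= p[P_JREL]
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    ginf[29] = jrel_inf
    gtau[29] = tau_rel
    ginf[30] = jrel_infp
    gtau[30] = tau_relp
    jrel = (1.0 - fp) * y[38] + fp * y[39]

    jupnp = 0.004375 * cai / (cai + 0.00092)
    jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    jleak = 0.0039375 * cansr / 15.0
    jup = p[P_JUP] * ((1.0 - fp) * jupnp + fp * jupp) - jleak
    jtr = (cansr - cajsr) / 100.0

    jdiff_na = (nass - nai) / 2.0
    jdiff_k = (kss - ki) / 2.0
    jdiff_ca = (cass - cai) / 0.2

    # ---- assemble -------------------------------------------------------
    cur[C_INA] = ina
    cur[C_INAL] = inal
    cur[C_ITO] = ito
    cur[C_ICAL] = ical
    cur[C_ICANA] = icana
    cur[C_ICAK] = icak
    cur[C_IKR] = ikr
    cur[C_IKS] = iks
    cur[C_IK1] = ik1
    cur[C_INACA_I] = inaca_i
    cur[C_INACA_SS] = inaca_ss
    cur[C_INAK] = inak
    cur[C_INAB] = inab
    cur[C_ICAB] = icab
    cur[C_IKB] = ikb
    cur[C_IPCA] = ipca
    cur[C_ISTIM] = ist
    cur[C_JREL] = jrel
    cur[C_JUP] = jup
    cur[C_JTR] = jtr
    cur[C_JDIFFNA] = jdiff_na
    cur[C_JDIFFCA] = jdiff_ca
    cur[C_JDIFFK] = jdiff_k
    cur[C_JLEAK] = jleak

    dy[0] = -(ina + inal + ito + ical + icana + icak + ikr + iks + ik1
              + inaca_i + inaca_ss + inak + inab + ikb + ipca + icab + ist)

    dy[1] = (-(ina + inal + 3.0 * inaca_i + 3.0 * inak + inab)
             * ACAP / (FARADAY * VMYO) + jdiff_na * VSS / VMYO)
    dy[2] = -(icana + 3.0 * inaca_ss) * ACAP / (FARADAY * VSS) - jdiff_na
    dy[3] = (-(ito + ikr + iks + ik1 + ikb + ist - 2.0 * inak)
             * ACAP / (FARADAY * VMYO) + jdiff_k * VSS / VMYO)
    dy[4] = -icak * ACAP / (FARADAY * VSS) - jdiff_k
    bcai = 1.0 / (1.0 + p[P_CMDN] * KM_CMDN / (KM_CMDN + cai) ** 2.0
                  + TRPN_MAX * KM_TRPN / (KM_TRPN + cai) ** 2.0)
    dy[5] = bcai * (-(ipca + icab - 2.0 * inaca_i) * ACAP / (2.0 * FARADAY * VMYO)
                    - jup * VNSR / VMYO + jdiff_ca * VSS / VMYO)
    bcass = 1.0 / (1.0 + BSR_MAX * KM_BSR / (KM_BSR + cass) ** 2.0
                   + BSL_MAX * KM_BSL / (KM_BSL + cass) ** 2.0)
    dy[6] = bcass * (-(ical - 2.0 * inaca_ss) * ACAP / (2.0 * FARADAY * VSS)
                     + jrel * VJSR / VSS - jdiff_ca)
    dy[7] = jup - jtr * VJSR / VNSR
    bcajsr = 1.0 / (1.0 + CSQN_MAX * KM_CSQN / (KM_CSQN + cajsr) ** 2.0)
    dy[8] = bcajsr * (jtr - jrel)

    for g in range(31):
        dy[9 + g] = (ginf[g] - y[9 + g]) / gtau[g]


@njit(cache=True)
def _rl_step(y, dt, ginf, gtau, dy):
    """Advance one step: Euler for v/concentrations/CaMKt, RL for gates."""
    y[0] += dt * dy[0]
    for k in range(1, 9):
        y[k] += dt * dy[k]
    y[40] += dt * dy[40]
    for g in range(31):
        tau = gtau[g]
        if tau > _BIG_TAU:
            y[9 + g] += dt * dy[9 + g]
        else:
            y[9 + g] = ginf[g] + (y[9 + g] - ginf[g]) * math.exp(-dt / tau)


@njit(cache=True)
def run_cell(y, p, celltype, camk_on,
             stim_times, stim_amp, stim_dur, t_end,
             dt_fast, dt_mid, dt_slow, thr_fast, thr_mid,
             clamp_idx, clamp_val,
             wave_idx, wave_t, wave_y,
             reset_idx, reset_val, reset_from_beat,
             mono_idx,
             rec_start, rec_dt, rec_currents, rec_states,
             apd_levels):
    """Paced single-cell run with intervention hooks.

    Returns per-beat summaries computed at full integrator resolution plus an
    optional recorded trace over [rec_start, t_end].

    status: 0 = ok, 1 = non-finite state (step index in `fail_step`).
    """
    nb = stim_times.shape[0]
    nlev = apd_levels.shape[0]
    prestate = np.zeros((nb, 41))
    vrest = np.zeros(nb)
    vmax = np.full(nb, -1.0e30)
    dvdtmax = np.full(nb, -1.0e30)
    t_dvdtmax = np.zeros(nb)
    apd = np.full((nb, nlev), np.nan)
    cai_max = np.full(nb, -1.0e30)
    cai_min = np.full(nb, 1.0e30)
    inal_min = np.zeros(nb)
    camka_sum = np.zeros(nb)
    camka_wt = np.zeros(nb)

    do_rec = rec_start <= t_end
    if do_rec:
        nrec = int((t_end - rec_start) / rec_dt) + 1
    else:
        nrec = 0
    rec_t = np.zeros(nrec)
    rec_v = np.zeros(nrec)
    rec_cur = np.zeros((nrec if rec_currents else 0, N_CUR))
    rec_y = np.zeros((nrec if rec_states else 0, 41))

    cur = np.zeros(N_CUR)
    ginf = np.zeros(31)
    gtau = np.zeros(31)
    dy = np.zeros(41)
    yold = np.zeros(41)

    nclamp = clamp_idx.shape[0]
    nwave = wave_t.shape[0]
    nreset = reset_idx.shape[0]
    nmono = mono_idx.shape[0]

    # apply constant clamps to the starting state too
    for k in range(nclamp):
        y[clamp_idx[k]] = clamp_val[k]

    t = 0.0
    ib = 0          # next stimulus index
    cb = -1         # current beat index
    dvdt = 0.0
    irec = 0
    next_rec = rec_start if do_rec else 1.0e30
    step = 0
    status = 0
    fail_step = -1
    iw = 0          # waveform search hint

    while t < t_end - 1.0e-9:
        # ---- beat onset ----
        if ib < nb and t >= stim_times[ib] - 1.0e-9:
            for k in range(41):
                prestate[ib, k] = y[k]
            vrest[ib] = y[0]
            if ib >= reset_from_beat:
                for k in range(nreset):
                    y[reset_idx[k]] = reset_val[k]
            cb = ib
            ib += 1

        in_stim = cb >= 0 and (t - stim_times[cb]) < stim_dur - 1.0e-12
        ist = stim_amp if in_stim else 0.0

        # ---- hybrid dt ----
        if in_stim or abs(dvdt) > thr_fast:
            dt = dt_fast
        elif abs(dvdt) > thr_mid:
            dt = dt_mid
        else:
            dt = dt_slow
        if ib < nb and stim_times[ib] - t < dt:
            dt = stim_times[ib] - t
        if in_stim:
            rem = stim_times[cb] + stim_dur - t
            if rem < dt:
                dt = rem
        if next_rec - t < dt:
            dt = next_rec - t
        if t_end - t < dt:
            dt = t_end - t
        if dt < 1.0e-9:
            dt = 1.0e-9

        compute_rhs(y, p, celltype, camk_on, ist, cur, ginf, gtau, dy)

        # ---- record sample (state at time t) ----
        if do_rec and t >= next_rec - 1.0e-9 and irec < nrec:
            rec_t[irec] = t
            rec_v[irec] = y[0]
            if rec_currents:
                for k in range(N_CUR):
                    rec_cur[irec, k] = cur[k]
            if rec_states:
                for k in range(41):
                    rec_y[irec, k] = y[k]
            irec += 1
            next_rec += rec_dt

        for k in range(41):
            yold[k] = y[k]
        _rl_step(y, dt, ginf, gtau, dy)

        for k in range(nmono):
            g = mono_idx[k]
            if y[g] > yold[g]:
                y[g] = yold[g]
        for k in range(nclamp):
            y[clamp_idx[k]] = clamp_val[k]
        if nwave > 0:
            tq = t + dt
            while iw < nwave - 2 and wave_t[iw + 1] < tq:
                iw += 1
            w0 = wave_t[iw]
            w1 = wave_t[iw + 1]
            frac = (tq - w0) / (w1 - w0)
            if frac < 0.0:
                frac = 0.0
            if frac > 1.0:
                frac = 1.0
            y[wave_idx] = wave_y[iw] + frac * (wave_y[iw + 1] - wave_y[iw])

        dvdt = (y[0] - yold[0]) / dt
        t += dt
        step += 1

        if not math.isfinite(y[0]):
            status = 1
            fail_step = step
            break

        # ---- per-beat metrics ----
        if cb >= 0:
            if camk_on:
                camka_sum[cb] += cur[C_CAMKA] * dt
                camka_wt[cb] += dt
            if dvdt > dvdtmax[cb]:
                dvdtmax[cb] = dvdt
                t_dvdtmax[cb] = t - 0.5 * dt
            if y[0] > vmax[cb]:
                vmax[cb] = y[0]
            if y[5] > cai_max[cb]:
                cai_max[cb] = y[5]
            if y[5] < cai_min[cb]:
                cai_min[cb] = y[5]
            if cur[C_INAL] < inal_min[cb]:
                inal_min[cb] = cur[C_INAL]
            # APD crossings: downward crossing of level% of resting Vm,
            # searched after the upstroke of a captured beat
            if vmax[cb] > 0.0 and t - 0.5 * dt > t_dvdtmax[cb]:
                for k in range(nlev):
                    if math.isnan(apd[cb, k]):
                        thr = apd_levels[k] * 0.01 * vrest[cb]
                        if yold[0] > thr and y[0] <= thr:
                            tc = (t - dt) + dt * (yold[0] - thr) / (yold[0] - y[0])
                            apd[cb, k] = tc - t_dvdtmax[cb]

    camka_avg = np.zeros(nb)
    for b in range(nb):
        if camka_wt[b] > 0.0:
            camka_avg[b] = camka_sum[b] / camka_wt[b]

    return (status, fail_step, prestate, vrest, vmax, dvdtmax, t_dvdtmax,
            apd, cai_max, cai_min, inal_min, camka_avg,
            rec_t[:irec], rec_v[:irec], rec_cur[:irec if rec_currents else 0],
            rec_y[:irec if rec_states else 0])


@njit(cache=True)
def run_vclamp(y, p, celltype, camk_on,
               seg_dur, seg_v, wave_t, wave_v,
               dt, rec_dt, cass_dynamic, freeze_nca):
    """Voltage-clamp run: Vm imposed, concentrations held fixed.

    Either piecewise-constant segments (seg_dur/seg_v) or a sampled waveform
    (wave_t/wave_v; linear interpolation) define Vm(t).  With `cass_dynamic`
    the subspace Ca2+ (and SR release state) evolve so that Ca2+ entry can
    drive calcium-dependent inactivation; all other concentrations stay at
    their configured pipette/bath values.  `freeze_nca` pins the CDI-mode
    fraction at 0 (Ba2+ surrogate).
    """
    use_wave = wave_t.shape[0] > 0
    if use_wave:
        t_end = wave_t[wave_t.shape[0] - 1]
    else:
        t_end = 0.0
        for k in range(seg_dur.shape[0]):
            t_end += seg_dur[k]
    nrec = int(t_end / rec_dt) + 1
    rec_t = np.zeros(nrec)
    rec_v = np.zeros(nrec)
    rec_cur = np.zeros((nrec, N_CUR))

    cur = np.zeros(N_CUR)
    ginf = np.zeros(31)
    gtau = np.zeros(31)
    dy = np.zeros(41)

    t = 0.0
    irec = 0
    next_rec = 0.0
    iseg = 0
    seg_end = seg_dur[0] if not use_wave else 0.0
    iw = 0

    while t < t_end - 1.0e-9:
        if use_wave:
            while iw < wave_t.shape[0] - 2 and wave_t[iw + 1] < t:
                iw += 1
            frac = (t - wave_t[iw]) / (wave_t[iw + 1] - wave_t[iw])
            if frac < 0.0:
                frac = 0.0
            if frac > 1.0:
                frac = 1.0
            y[0] = wave_v[iw] + frac * (wave_v[iw + 1] - wave_v[iw])
        else:
            while t >= seg_end - 1.0e-9 and iseg < seg_dur.shape[0] - 1:
                iseg += 1
                seg_end += seg_dur[iseg]
            y[0] = seg_v[iseg]
        if freeze_nca:
            y[30] = 0.0

        h = dt
        if next_rec - t < h:
            h = next_rec - t
        if not use_wave and seg_end - t < h:
            h = seg_end - t
        if t_end - t < h:
            h = t_end - t
        if h < 1.0e-9:
            h = 1.0e-9

        compute_rhs(y, p, celltype, camk_on, 0.0, cur, ginf, gtau, dy)

        if t >= next_rec - 1.0e-9 and irec < nrec:
            rec_t[irec] = t
            rec_v[irec] = y[0]
            for k in range(N_CUR):
                rec_cur[irec, k] = cur[k]
            irec += 1
            next_rec += rec_dt

        # gates only (plus optional subspace Ca2+); Vm and other
        # concentrations are clamped
        for g in range(31):
            tau = gtau[g]
            if tau > _BIG_TAU:
                y[9 + g] += h * dy[9 + g]
            else:
                y[9 + g] = ginf[g] + (y[9 + g] - ginf[g]) * math.exp(-h / tau)
        if cass_dynamic:
            y[6] += h * dy[6]
        if camk_on:
            y[40] += h * dy[40]
        if freeze_nca:
            y[30] = 0.0
        t += h

    return rec_t[:irec], rec_v[:irec], rec_cur[:irec]


@njit(cache=True)
def run_fiber(Y, P3, ctypes, camk_on, diff, dx,
              stim_cells, stim_times, stim_amp, stim_dur, t_end,
              dt_fast, dt_mid, dt_slow, thr_fast,
              rec_dt, act_t0, act_t1):
    """1D monodomain strand, operator splitting (reaction then diffusion).

    `Y` is (ncell, 41); `P3` holds one parameter vector per transmural cell
    type, `ctypes[i]` selects it.  No-flux boundaries.  Per-cell activation
    (max dVm/dt and its time, within [act_t0, act_t1]) is tracked at full
    resolution for conduction-velocity measurement.

    Returns (status, rec_t, rec_V, act_dvdt, act_time).
    """
    n = Y.shape[0]
    nrec = int(t_end / rec_dt) + 1
    rec_t = np.zeros(nrec)
    rec_V = np.zeros((nrec, n))

    cur = np.zeros(N_CUR)
    ginf = np.zeros(31)
    gtau = np.zeros(31)
    dy = np.zeros(41)
    vold = np.zeros(n)
    vnew = np.zeros(n)

    act_dvdt = np.full(n, -1.0e30)
    act_time = np.zeros(n)

    dt_cap = 0.8 * dx * dx / (2.0 * diff)
    if dt_mid > dt_cap:
        dt_mid = dt_cap
    if dt_slow > dt_cap:
        dt_slow = dt_cap

    nb = stim_times.shape[0]
    t = 0.0
    ib = 0
    tstim = -1.0e30
    maxdv = 0.0
    irec = 0
    next_rec = 0.0
    status = 0

    while t < t_end - 1.0e-9:
        if ib < nb and t >= stim_times[ib] - 1.0e-9:
            tstim = stim_times[ib]
            ib += 1
        in_stim = (t - tstim) < stim_dur - 1.0e-12 and t >= tstim

        if in_stim or maxdv > thr_fast:
            dt = dt_fast
        elif maxdv > 0.02:
            dt = dt_mid
        else:
            dt = dt_slow
        if ib < nb and stim_times[ib] - t < dt:
            dt = stim_times[ib] - t
        if in_stim:
            rem = tstim + stim_dur - t
            if rem < dt:
                dt = rem
        if next_rec - t < dt:
            dt = next_rec - t
        if t_end - t < dt:
            dt = t_end - t
        if dt < 1.0e-9:
            dt = 1.0e-9

        if t >= next_rec - 1.0e-9 and irec < nrec:
            rec_t[irec] = t
            for i in range(n):
                rec_V[irec, i] = Y[i, 0]
            irec += 1
            next_rec += rec_dt

        # reaction step
        for i in range(n):
            vold[i] = Y[i, 0]
            ist = 0.0
            if in_stim:
                for k in range(stim_cells.shape[0]):
                    if stim_cells[k] == i:
                        ist = stim_amp
            yi = Y[i]
            compute_rhs(yi, P3[ctypes[i]], ctypes[i], camk_on, ist,
                        cur, ginf, gtau, dy)
            _rl_step(yi, dt, ginf, gtau, dy)

        # diffusion step (no-flux boundaries)
        r = dt * diff / (dx * dx)
        for i in range(n):
            vm = Y[i, 0]
            vl = Y[i - 1, 0] if i > 0 else Y[i + 1, 0]
            vr = Y[i + 1, 0] if i < n - 1 else Y[i - 1, 0]
            vnew[i] = vm + r * (vl - 2.0 * vm + vr)
        maxdv = 0.0
        tm = t + 0.5 * dt
        for i in range(n):
            Y[i, 0] = vnew[i]
            dv = (vnew[i] - vold[i]) / dt
            if abs(dv) > maxdv:
                maxdv = abs(dv)
            if act_t0 <= tm and tm <= act_t1 and dv > act_dvdt[i]:
                act_dvdt[i] = dv
                act_time[i] = tm
        if not math.isfinite(Y[n // 2, 0]):
            status = 1
            break
        t += dt

    return status, rec_t[:irec], rec_V[:irec], act_dvdt, act_time
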
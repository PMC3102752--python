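"""Independent transcription of the complete current/flux equation set.

This module re-derives every membrane current, intracellular flux and
concentration derivative of the ventricular cell model in plain numpy,
organised current-by-current and written separately from the simulation
kernel.  The test suite demands agreement with the package implementation
to 1e-10 relative; any transcription slip in either copy shows up there.
"""

from __future__ import annotations

import math

import numpy as np

R = 8314.0
T = 310.0
F = 96485.0
RTF = R * T / F

L_CELL = 0.01
R_CELL = 0.0011
V_CELL = 1000.0 * math.pi * R_CELL * R_CELL * L_CELL
A_GEO = 2.0 * math.pi * R_CELL * R_CELL + 2.0 * math.pi * R_CELL * L_CELL
A_CAP = 2.0 * A_GEO
V_MYO = 0.68 * V_CELL
V_NSR = 0.0552 * V_CELL
V_JSR = 0.0048 * V_CELL
V_SS = 0.02 * V_CELL


def _safe_exp_flux(z, v, a_in, a_out):
    """z^2 (vF^2/RT) (a_in e^{zvF/RT} - a_out)/(e^{zvF/RT} - 1), smooth at 0."""
    x = z * v * F / (R * T)
    if abs(x) < 1e-5:
        return z * F * ((a_in - a_out) + 0.5 * x * (a_in + a_out))
    return (z * z * (v * F * F / (R * T))
            * (a_in * math.exp(x) - a_out) / (math.exp(x) - 1.0))


def oracle_rhs(sd: dict, cond: dict, celltype: str = "endo",
               camk_on: bool = True, i_stim: float = 0.0) -> dict:
    """Evaluate all currents/fluxes and concentration derivatives.

    ``sd`` maps state names to values, ``cond`` holds conductances
    (``GNa``..``ko`` symbols).  Returns a dict of currents, fluxes and the
    time derivatives of Vm, concentrations and CaMKt, plus each gate's
    (inf, tau).
    """
    v = sd["v"]
    nai, nass = sd["nai"], sd["nass"]
    ki, kss = sd["ki"], sd["kss"]
    cai, cass = sd["cai"], sd["cass"]
    cansr, cajsr = sd["cansr"], sd["cajsr"]
    nao, cao, ko = cond["nao"], cond["cao"], cond["ko"]
    epi = celltype == "epi"
    mcell = celltype == "M"

    ena = RTF * math.log(nao / nai)
    ek = RTF * math.log(ko / ki)
    pkna = 0.01833
    eks = RTF * math.log((ko + pkna * nao) / (ki + pkna * nai))

    gates = {}

    # CaMK
    if camk_on:
        camk_bound = 0.05 * (1.0 - sd["CaMKt"]) / (1.0 + 0.0015 / cass)
        camka = camk_bound + sd["CaMKt"]
        d_camkt = 0.05 * camk_bound * camka - 0.00068 * sd["CaMKt"]
        phi = camka / (camka + 0.15)
    else:
        camka, d_camkt, phi = 0.0, 0.0, 0.0

    def sig(x):
        return 1.0 / (1.0 + math.exp(x))

    # fast Na+
    m_inf = sig(-(v + 39.57) / 9.871)
    m_tau = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77)
                   + 8.552 * math.exp(-(v + 77.42) / 5.955))
    h_inf = sig((v + 82.90) / 6.086)
    hf_tau = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                    + 6.149 * math.exp((v + 0.5096) / 20.27))
    hs_tau = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                    + 0.3343 * math.exp((v + 5.730) / 56.66))
    j_tau = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                           + 0.3052 * math.exp((v + 0.9941) / 38.45))
    hp_inf = sig((v + 89.1) / 6.086)
    gates.update(m=(m_inf, m_tau), hf=(h_inf, hf_tau), hs=(h_inf, hs_tau),
                 j=(h_inf, j_tau), hsp=(hp_inf, 3.0 * hs_tau),
                 jp=(h_inf, 1.46 * j_tau))
    h_mix = 0.99 * sd["hf"] + 0.01 * sd["hs"]
    hp_mix = 0.99 * sd["hf"] + 0.01 * sd["hsp"]
    i_na = (cond["GNa"] * (v - ena) * sd["m"] ** 3
            * ((1.0 - phi) * h_mix * sd["j"] + phi * hp_mix * sd["jp"]))

    # late Na+
    ml_inf = sig(-(v + 42.85) / 5.264)
    hl_inf = sig((v + 87.61) / 7.488)
    hlp_inf = sig((v + 93.81) / 7.488)
    gates.update(mL=(ml_inf, m_tau), hL=(hl_inf, 200.0),
                 hLp=(hlp_inf, 600.0))
    gnal = cond["GNaL"] * (0.6 if epi else 1.0)
    i_nal = gnal * (v - ena) * sd["mL"] * ((1.0 - phi) * sd["hL"]
                                           + phi * sd["hLp"])

    # Ito
    a_inf = sig(-(v - 14.34) / 14.82)
    a_tau = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099)
                                                      / 29.3814)))
                      + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    i_inf = sig((v + 43.94) / 5.711)
    depi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0)) if epi else 1.0
    tif = (4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                          + 0.08004 * math.exp((v + 50.0) / 16.59))) * depi
    tis = (23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                          + 1.780e-8 * math.exp((v + 114.1) / 8.079))) * depi
    w_fast = sig((v - 213.6) / 151.2)
    ap_inf = sig(-(v - 24.34) / 14.82)
    dd = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89)
                           + math.exp(-(v - 12.23) / 0.2154))
    dr = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    gates.update(a=(a_inf, a_tau), iF=(i_inf, tif), iS=(i_inf, tis),
                 ap=(ap_inf, a_tau), iFp=(i_inf, dd * dr * tif),
                 iSp=(i_inf, dd * dr * tis))
    gto = cond["Gto"] * (4.0 if (epi or mcell) else 1.0)
    i_to = gto * (v - ek) * (
        (1.0 - phi) * sd["a"] * (w_fast * sd["iF"] + (1 - w_fast) * sd["iS"])
        + phi * sd["ap"] * (w_fast * sd["iFp"] + (1 - w_fast) * sd["iSp"]))

    # ICaL / ICaNa / ICaK
    d_inf = sig(-(v + 3.940) / 4.230)
    d_tau = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0))
                         + math.exp(0.09 * (v + 14.0)))
    f_inf = sig((v + 19.58) / 3.696)
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (3.5e-5 * math.exp(-(v + 5.0) / 4.0)
                          + 3.5e-5 * math.exp((v + 5.0) / 6.0))
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0)
                         + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (1.2e-4 * math.exp(-v / 3.0)
                           + 1.2e-4 * math.exp(v / 7.0))
    wca_f = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    gates.update(d=(d_inf, d_tau), ff=(f_inf, tff), fs=(f_inf, tfs),
                 fcaf=(f_inf, tfcaf), fcas=(f_inf, tfcas),
                 jca=(f_inf, 75.0), ffp=(f_inf, 2.5 * tff),
                 fcafp=(f_inf, 2.5 * tfcaf))
    km2n = sd["jca"] if sd["jca"] > 1e-12 else 1e-12
    alpha_n = 1.0 / (1000.0 / km2n + (1.0 + 0.002 / cass) ** 4)
    gates["nca"] = (alpha_n * 1000.0 / km2n, 1.0 / km2n)
    f_mix = 0.6 * sd["ff"] + 0.4 * sd["fs"]
    fca_mix = wca_f * sd["fcaf"] + (1 - wca_f) * sd["fcas"]
    fp_mix = 0.6 * sd["ffp"] + 0.4 * sd["fs"]
    fcap_mix = wca_f * sd["fcafp"] + (1 - wca_f) * sd["fcas"]
    open_np = f_mix * (1 - sd["nca"]) + sd["jca"] * fca_mix * sd["nca"]
    open_p = fp_mix * (1 - sd["nca"]) + sd["jca"] * fcap_mix * sd["nca"]
    pca = cond["PCa"] * (1.2 if epi else 2.5 if mcell else 1.0)
    psi_ca = _safe_exp_flux(2.0, v, cass, 0.341 * cao)
    psi_na = _safe_exp_flux(1.0, v, 0.75 * nass, 0.75 * nao)
    psi_k = _safe_exp_flux(1.0, v, 0.75 * kss, 0.75 * ko)
    d_g = sd["d"]
    i_cal = d_g * psi_ca * ((1 - phi) * pca * open_np
                            + phi * 1.1 * pca * open_p)
    i_cana = d_g * psi_na * 0.00125 * ((1 - phi) * pca * open_np
                                       + phi * 1.1 * pca * open_p)
    i_cak = d_g * psi_k * 3.574e-4 * ((1 - phi) * pca * open_np
                                      + phi * 1.1 * pca * open_p)

    # IKr
    xr_inf = sig(-(v + 8.337) / 6.789)
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    wxr = sig((v + 54.81) / 38.21)
    gates.update(xrf=(xr_inf, txrf), xrs=(xr_inf, txrs))
    rect = sig((v + 55.0) / 75.0) * sig((v - 10.0) / 30.0)
    gkr = cond["GKr"] * (1.3 if epi else 0.8 if mcell else 1.0)
    i_kr = (gkr * math.sqrt(ko / 5.4)
            * (wxr * sd["xrf"] + (1 - wxr) * sd["xrs"]) * rect * (v - ek))

    # IKs
    xs1_inf = sig(-(v + 11.60) / 8.932)
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                          + 1.292e-3 * math.exp(-(v + 210.0) / 230.0))
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    gates.update(xs1=(xs1_inf, txs1), xs2=(xs1_inf, txs2))
    gks = cond["GKs"] * (1.4 if epi else 1.0)
    i_ks = (gks * (1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4))
            * sd["xs1"] * sd["xs2"] * (v - eks))

    # IK1
    xk1_inf = sig(-(v + 2.5538 * ko + 144.59) / (1.5692 * ko + 3.8115))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36)
                    + math.exp((v + 236.8) / 69.33))
    gates["xk1"] = (xk1_inf, txk1)
    rk1 = sig((v + 105.8 - 2.6 * ko) / 9.493)
    gk1 = cond["GK1"] * (1.2 if epi else 1.3 if mcell else 1.0)
    i_k1 = gk1 * math.sqrt(ko) * rk1 * sd["xk1"] * (v - ek)

    # INaCa (fraction 0.8 myoplasmic, 0.2 subspace)
    def ncx(na_c, ca_c):
        kna1, kna2, kna3 = 15.0, 5.0, 88.12
        hca = math.exp(0.1670 * v * F / (R * T))
        hna = math.exp(0.5224 * v * F / (R * T))
        h1 = 1.0 + na_c / kna3 * (1.0 + hna)
        h2 = na_c * hna / (kna3 * h1)
        h3 = 1.0 / h1
        h4 = 1.0 + na_c / kna1 * (1.0 + na_c / kna2)
        h5 = na_c * na_c / (h4 * kna1 * kna2)
        h6 = 1.0 / h4
        h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
        h8 = nao / (kna3 * hna * h7)
        h9 = 1.0 / h7
        h10 = 12.5 + 1.0 + nao / kna1 * (1.0 + nao / kna2)
        h11 = nao * nao / (h10 * kna1 * kna2)
        h12 = 1.0 / h10
        k1 = h12 * cao * 1.5e6
        k2 = 5.0e3
        k3p = h9 * 6.0e4
        k3pp = h8 * 5.0e3
        k4p = h3 * 6.0e4 / hca
        k4pp = h2 * 5.0e3
        k5 = 5.0e3
        k6 = h6 * ca_c * 1.5e6
        k7 = h5 * h2 * 6.0e4
        k8 = h8 * h11 * 6.0e4
        k3 = k3p + k3pp
        k4 = k4p + k4pp
        x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
        x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
        x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
        x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
        tot = x1 + x2 + x3 + x4
        e1, e2, e3, e4 = x1 / tot, x2 / tot, x3 / tot, x4 / tot
        act = 1.0 / (1.0 + (1.5e-4 / ca_c) ** 2)
        jna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
        jca_f = e2 * k2 - e1 * k1
        return act * (jna + 2.0 * jca_f)

    gncx = cond["Gncx"] * (1.1 if epi else 1.4 if mcell else 1.0)
    i_ncx_i = 0.8 * gncx * ncx(nai, cai)
    i_ncx_ss = 0.2 * gncx * ncx(nass, cass)

    # INaK
    knai = 9.073 * math.exp(-0.1550 * v * F / (3.0 * R * T))
    knao = 27.78 * math.exp(1.1550 * v * F / (3.0 * R * T))
    den_i = (1.0 + nai / knai) ** 3 + (1.0 + ki / 0.5) ** 2 - 1.0
    den_o = (1.0 + nao / knao) ** 3 + (1.0 + ko / 0.3582) ** 2 - 1.0
    pfrac = 4.2 / (1.0 + 1e-7 / 1.698e-7 + nai / 224.0 + ki / 292.0)
    a1 = 949.5 * (nai / knai) ** 3 / den_i
    b1 = 182.4 * 0.05
    a2 = 687.2
    b2 = 39.4 * (nao / knao) ** 3 / den_o
    a3 = 1899.0 * (ko / 0.3582) ** 2 / den_o
    b3 = 79300.0 * pfrac * 1e-7 / (1.0 + 9.8 / 1.698e-7)
    a4 = 639.0 * (9.8 / 1.698e-7) / (1.0 + 9.8 / 1.698e-7)
    b4 = 40.0 * (ki / 0.5) ** 2 / den_i
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b1 * a1
    tot = x1 + x2 + x3 + x4
    e1, e2, e3, e4 = x1 / tot, x2 / tot, x3 / tot, x4 / tot
    pnak = cond["Pnak"] * (0.9 if epi else 0.7 if mcell else 1.0)
    i_nak = pnak * (3.0 * (e1 * a3 - e2 * b3) + 2.0 * (e4 * b1 - e3 * a1))

    # background / pump
    gkb = cond["GKb"] * (0.6 if epi else 1.0)
    i_kb = gkb * (v - ek) / (1.0 + math.exp(-(v - 14.48) / 18.34))
    i_nab = cond["PNab"] * _safe_exp_flux(1.0, v, nai, nao)
    i_cab = cond["PCab"] * _safe_exp_flux(2.0, v, cai, 0.341 * cao)
    i_pca = cond["GpCa"] * cai / (0.0005 + cai)

    # SR release / uptake / translocation
    rel_scale = (1.7 if mcell else 1.0) * cond.get("Jrel", 1.0)
    rel_inf = rel_scale * 0.5 * 4.75 * (-i_cal) / (1.0 + (1.5 / cajsr) ** 8)
    rel_infp = rel_scale * 0.5 * (1.25 * 4.75) * (-i_cal) \
        / (1.0 + (1.5 / cajsr) ** 8)
    rel_tau = max(4.75 / (1.0 + 0.0123 / cajsr), 0.001)
    rel_taup = max(1.25 * 4.75 / (1.0 + 0.0123 / cajsr), 0.001)
    gates.update(Jrelnp=(rel_inf, rel_tau), Jrelp=(rel_infp, rel_taup))
    j_rel = (1.0 - phi) * sd["Jrelnp"] + phi * sd["Jrelp"]

    up_scale = (1.3 if epi else 1.0) * cond.get("Jup", 1.0)
    j_up_np = 0.004375 * cai / (cai + 0.00092)
    j_up_p = 2.75 * 0.004375 * cai / (cai + 0.00075)
    j_leak = 0.0039375 * cansr / 15.0
    j_up = up_scale * ((1.0 - phi) * j_up_np + phi * j_up_p) - j_leak
    j_tr = (cansr - cajsr) / 100.0
    j_diff_na = (nass - nai) / 2.0
    j_diff_k = (kss - ki) / 2.0
    j_diff_ca = (cass - cai) / 0.2

    i_total = (i_na + i_nal + i_to + i_cal + i_cana + i_cak + i_kr + i_ks
               + i_k1 + i_ncx_i + i_ncx_ss + i_nak + i_nab + i_cab + i_kb
               + i_pca + i_stim)

    cmdn = cond["cmdnmax"] * (1.3 if epi else 1.0)
    beta_cai = 1.0 / (1.0 + cmdn * 0.00238 / (0.00238 + cai) ** 2
                      + 0.07 * 0.0005 / (0.0005 + cai) ** 2)
    beta_cass = 1.0 / (1.0 + 0.047 * 0.00087 / (0.00087 + cass) ** 2
                       + 1.124 * 0.0087 / (0.0087 + cass) ** 2)
    beta_cajsr = 1.0 / (1.0 + 10.0 * 0.8 / (0.8 + cajsr) ** 2)

    return {
        "INa": i_na, "INaL": i_nal, "Ito": i_to, "ICaL": i_cal,
        "ICaNa": i_cana, "ICaK": i_cak, "IKr": i_kr, "IKs": i_ks,
        "IK1": i_k1, "INaCa_i": i_ncx_i, "INaCa_ss": i_ncx_ss,
        "INaK": i_nak, "INab": i_nab, "ICab": i_cab, "IKb": i_kb,
        "IpCa": i_pca, "Istim": i_stim, "Jrel": j_rel, "Jup": j_up,
        "Jtr": j_tr, "Jdiff_Na": j_diff_na, "Jdiff_Ca": j_diff_ca,
        "Jdiff_K": j_diff_k, "Jleak": j_leak, "CaMKa": camka,
        "gates": gates,
        "dv": -i_total,
        "dnai": (-(i_na + i_nal + 3 * i_ncx_i + 3 * i_nak + i_nab)
                 * A_CAP / (F * V_MYO) + j_diff_na * V_SS / V_MYO),
        "dnass": (-(i_cana + 3 * i_ncx_ss) * A_CAP / (F * V_SS)
                  - j_diff_na),
        "dki": (-(i_to + i_kr + i_ks + i_k1 + i_kb + i_stim - 2 * i_nak)
                * A_CAP / (F * V_MYO) + j_diff_k * V_SS / V_MYO),
        "dkss": -i_cak * A_CAP / (F * V_SS) - j_diff_k,
        "dcai": beta_cai * (-(i_pca + i_cab - 2 * i_ncx_i)
                            * A_CAP / (2 * F * V_MYO)
                            - j_up * V_NSR / V_MYO
                            + j_diff_ca * V_SS / V_MYO),
        "dcass": beta_cass * (-(i_cal - 2 * i_ncx_ss)
                              * A_CAP / (2 * F * V_SS)
                              + j_rel * V_JSR / V_SS - j_diff_ca),
        "dcansr": j_up - j_tr * V_JSR / V_NSR,
        "dcajsr": beta_cajsr * (j_tr - j_rel),
        "dCaMKt": d_camkt,
    }


def oracle_conductances(overrides: dict | None = None) -> dict:
    cond = {"GNa": 75.0, "GNaL": 0.0075, "Gto": 0.02, "PCa": 1e-4,
            "GKr": 0.046, "GKs": 0.0034, "GK1": 0.1908, "Gncx": 8e-4,
            "Pnak": 30.0, "GKb": 0.003, "PNab": 3.75e-10, "PCab": 2.5e-8,
            "GpCa": 5e-4, "cmdnmax": 0.05, "nao": 140.0, "cao": 1.8,
            "ko": 5.4, "Jrel": 1.0, "Jup": 1.0}
    if overrides:
        cond.update(overrides)
    return cond
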
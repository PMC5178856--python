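"""Compiled core of the myocyte model.

Single source of truth for the right-hand side of the cell ODE system:
the full O'Hara--Rudy (ORd) human ventricular formulation with the
regulatory hooks used elsewhere in the package --

* CaMKII activation with up to two activity tracks (control /
  overexpressed CaMK_0), routed per phosphorylation target;
* PKA (saturated-ISO) effects on I_CaL (availability factor, activation
  shift, Ca permeability, slowed activation), I_Ks (conductance and
  XS1 steady-state shift) and PLB/SERCA (fPKA_PLB in the uptake fraction);
* maximal-conductance scaling of I_Kr by a blockage fraction.

Everything here is plain scalar float math so that numba can compile it;
the public modules (`ionic_base`, `camkii_pathway`, ...) wrap these
arrays in typed containers.  The integrator is an adaptive-step
Rush--Larsen / forward-Euler splitting: Hodgkin--Huxley gates (and other
linear relaxation states) advance by their exact exponential update,
voltage and concentrations by forward Euler, with the step refined on
|dV/dt| and on relative Ca-compartment change and capped at the
protocol's maximum step (2 ms by default).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# state vector layout (42 states: 41 ORd states + a second CaMKtrap track)

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp",
    "camkt", "camkt_ox",
)
NSTATE = len(STATE_NAMES)

(IV, INAI, INASS, IKI, IKSS, ICAI, ICASS, ICANSR, ICAJSR,
 IM, IHF, IHS, IJ, IHSP, IJP, IML, IHL, IHLP,
 IA, IIF, IIS, IAP, IIFP, IISP,
 ID, IFF, IFS, IFCAF, IFCAS, IJCA, INCA, IFFP, IFCAFP,
 IXRF, IXRS, IXS1, IXS2, IXK1, IJRELNP, IJRELP,
 ICAMKT, ICAMKT2) = range(NSTATE)

# ---------------------------------------------------------------------------
# parameter vector layout

PARAM_NAMES = (
    "celltype", "ikr_block", "stim_amp", "stim_dur",
    "vshift", "perm_scale", "td_scale", "favail", "frac_iks", "fpka_plb",
    "camk0_trap0", "camk0_trap1",
    "camk0_ina", "trk_ina", "camk0_inal", "trk_inal",
    "camk0_ical", "trk_ical", "camk0_icak", "trk_icak",
    "camk0_icana", "trk_icana", "camk0_ito", "trk_ito",
    "camk0_jrel", "trk_jrel", "camk0_serca", "trk_serca",
    "km_camk", "km_cam", "a_camk", "b_camk",
)
NPARAM = len(PARAM_NAMES)

(P_CELLTYPE, P_IKR_BLOCK, P_STIM_AMP, P_STIM_DUR,
 P_VSHIFT, P_PERM, P_TD, P_FAVAIL, P_FRACIKS, P_FPKAPLB,
 P_CAMK0_T0, P_CAMK0_T1,
 P_CAMK0_INA, P_TRK_INA, P_CAMK0_INAL, P_TRK_INAL,
 P_CAMK0_ICAL, P_TRK_ICAL, P_CAMK0_ICAK, P_TRK_ICAK,
 P_CAMK0_ICANA, P_TRK_ICANA, P_CAMK0_ITO, P_TRK_ITO,
 P_CAMK0_JREL, P_TRK_JREL, P_CAMK0_SERCA, P_TRK_SERCA,
 P_KM_CAMK, P_KM_CAM, P_A_CAMK, P_B_CAMK) = range(NPARAM)

# ---------------------------------------------------------------------------
# current/flux output layout

CURRENT_NAMES = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "INab", "IKb", "IpCa", "ICab", "Istim",
    "Jrel", "Jup", "Jleak", "Jdiff", "CaMKa", "CaMKa_ox", "Jupnp", "Jupp",
)
NCUR = len(CURRENT_NAMES)

(C_INA, C_INAL, C_ITO, C_ICAL, C_ICANA, C_ICAK, C_IKR, C_IKS, C_IK1,
 C_INACA_I, C_INACA_SS, C_INAK, C_INAB, C_IKB, C_IPCA, C_ICAB, C_ISTIM,
 C_JREL, C_JUP, C_JLEAK, C_JDIFF, C_CAMKA, C_CAMKA_OX,
 C_JUPNP, C_JUPP) = range(NCUR)

# physical constants and cell geometry (ORd)
_R = 8314.0
_T = 310.0
_F = 96485.0
_NAO = 140.0
_CAO = 1.8
_KO = 5.4
_L = 0.01
_RAD = 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL

# ORd published resting state (endocardial); pre-pacing equilibrates it
INITIAL_STATE = np.zeros(NSTATE)
INITIAL_STATE[IV] = -87.0
INITIAL_STATE[INAI] = 7.0
INITIAL_STATE[INASS] = 7.0
INITIAL_STATE[IKI] = 145.0
INITIAL_STATE[IKSS] = 145.0
INITIAL_STATE[ICAI] = 1.0e-4
INITIAL_STATE[ICASS] = 1.0e-4
INITIAL_STATE[ICANSR] = 1.2
INITIAL_STATE[ICAJSR] = 1.2
for _i, _nm in enumerate(STATE_NAMES):
    if _nm in ("hf", "hs", "j", "hsp", "jp", "hL", "hLp", "iF", "iS",
               "iFp", "iSp", "ff", "fs", "fcaf", "fcas", "jca", "ffp",
               "fcafp", "xk1"):
        INITIAL_STATE[_i] = 1.0


@njit(cache=True)
def _camk_active(camk0, camkt, cass, km_cam):
    """CaMKbound + CaMKtrap for one activity track."""
    bound = camk0 * (1.0 - camkt) / (1.0 + km_cam / cass)
    return bound + camkt


@njit(cache=True)
def derivatives(t, y, p, dy, yinf, ytau, cur):
    """Fill dy (full derivative), yinf/ytau (relaxation form; ytau<0 marks
    a non-relaxation state) and cur (currents/fluxes) at state y.

    ``t`` is time within the beat; the stimulus is on for t < stim_dur.
    """
    v = y[IV]
    nai = y[INAI]
    nass = y[INASS]
    ki = y[IKI]
    kss = y[IKSS]
    cai = y[ICAI]
    cass = y[ICASS]
    cansr = y[ICANSR]
    cajsr = y[ICAJSR]

    celltype = int(p[P_CELLTYPE])
    km_camk = p[P_KM_CAMK]
    km_cam = p[P_KM_CAM]

    # --- CaMKII tracks -----------------------------------------------------
    camkt0 = y[ICAMKT]
    camkt1 = y[ICAMKT2]
    camkb0 = p[P_CAMK0_T0] * (1.0 - camkt0) / (1.0 + km_cam / cass)
    camkb1 = p[P_CAMK0_T1] * (1.0 - camkt1) / (1.0 + km_cam / cass)
    camka0 = camkb0 + camkt0
    camka1 = camkb1 + camkt1
    dy[ICAMKT] = p[P_A_CAMK] * camkb0 * camka0 - p[P_B_CAMK] * camkt0
    dy[ICAMKT2] = p[P_A_CAMK] * camkb1 * camka1 - p[P_B_CAMK] * camkt1
    ytau[ICAMKT] = -1.0
    ytau[ICAMKT2] = -1.0
    cur[C_CAMKA] = camka0
    cur[C_CAMKA_OX] = camka1

    # per-target active CaMKII (bound on the target's own CaMK_0, trap from
    # its assigned track)
    def _target_camka(camk0_t, trk):
        trap = camkt1 if trk >= 0.5 else camkt0
        return camk0_t * (1.0 - trap) / (1.0 + km_cam / cass) + trap

    camka_ina = _target_camka(p[P_CAMK0_INA], p[P_TRK_INA])
    camka_inal = _target_camka(p[P_CAMK0_INAL], p[P_TRK_INAL])
    camka_ical = _target_camka(p[P_CAMK0_ICAL], p[P_TRK_ICAL])
    camka_icak = _target_camka(p[P_CAMK0_ICAK], p[P_TRK_ICAK])
    camka_icana = _target_camka(p[P_CAMK0_ICANA], p[P_TRK_ICANA])
    camka_ito = _target_camka(p[P_CAMK0_ITO], p[P_TRK_ITO])
    camka_jrel = _target_camka(p[P_CAMK0_JREL], p[P_TRK_JREL])
    camka_serca = _target_camka(p[P_CAMK0_SERCA], p[P_TRK_SERCA])

    # reversal potentials
    ENa = (_R * _T / _F) * math.log(_NAO / nai)
    EK = (_R * _T / _F) * math.log(_KO / ki)
    PKNa = 0.01833
    EKs = (_R * _T / _F) * math.log((_KO + PKNa * _NAO) / (ki + PKNa * nai))
    vv = v
    if -1.0e-6 < vv < 1.0e-6:
        vv = 1.0e-6  # GHK flux singularities at v = 0
    vffrt = vv * _F * _F / (_R * _T)
    vfrt = vv * _F / (_R * _T)

    # --- fast Na current ---------------------------------------------------
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77)
                + 8.552 * math.exp(-(v + 77.42) / 5.955))
    yinf[IM] = mss
    ytau[IM] = tm
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                 + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * math.exp((v + 5.730) / 56.66))
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    yinf[IHF] = hss
    ytau[IHF] = thf
    yinf[IHS] = hss
    ytau[IHS] = ths
    h = Ahf * y[IHF] + Ahs * y[IHS]
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * math.exp((v + 0.9941) / 38.45))
    yinf[IJ] = jss
    ytau[IJ] = tj
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    yinf[IHSP] = hssp
    ytau[IHSP] = 3.0 * ths
    hp = Ahf * y[IHF] + Ahs * y[IHSP]
    yinf[IJP] = jss
    ytau[IJP] = 1.46 * tj
    GNa = 75.0
    fINap = 1.0 / (1.0 + km_camk / camka_ina)
    INa = (GNa * (v - ENa) * y[IM] ** 3
           * ((1.0 - fINap) * h * y[IJ] + fINap * hp * y[IJP]))

    # --- late Na current ---------------------------------------------------
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    yinf[IML] = mLss
    ytau[IML] = tm
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thL = 200.0
    yinf[IHL] = hLss
    ytau[IHL] = thL
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    yinf[IHLP] = hLssp
    ytau[IHLP] = 3.0 * thL
    GNaL = 0.0075
    if celltype == 1:
        GNaL *= 0.6
    fINaLp = 1.0 / (1.0 + km_camk / camka_inal)
    INaL = (GNaL * (v - ENa) * y[IML]
            * ((1.0 - fINaLp) * y[IHL] + fINaLp * y[IHLP]))

    # --- transient outward K -----------------------------------------------
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    yinf[IA] = ass
    ytau[IA] = ta
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    if celltype == 1:
        delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    tiF *= delta_epi
    tiS *= delta_epi
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    yinf[IIF] = iss
    ytau[IIF] = tiF
    yinf[IIS] = iss
    ytau[IIS] = tiS
    i_gate = AiF * y[IIF] + AiS * y[IIS]
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    yinf[IAP] = assp
    ytau[IAP] = ta
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89)
                                    + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    yinf[IIFP] = iss
    ytau[IIFP] = dti_develop * dti_recover * tiF
    yinf[IISP] = iss
    ytau[IISP] = dti_develop * dti_recover * tiS
    ip = AiF * y[IIFP] + AiS * y[IISP]
    Gto = 0.02
    if celltype == 1 or celltype == 2:
        Gto *= 4.0
    fItop = 1.0 / (1.0 + km_camk / camka_ito)
    Ito = Gto * (v - EK) * ((1.0 - fItop) * y[IA] * i_gate
                            + fItop * y[IAP] * ip)

    # --- L-type Ca channel (ICaL, ICaNa, ICaK) ------------------------------
    # PKA: activation midpoint shifted by vshift (3.94 without ISO = ORd),
    # activation time constant scaled by td_scale, Ca permeability by
    # perm_scale, total current by favail.
    dss = 1.0 / (1.0 + math.exp(-(v + p[P_VSHIFT]) / 4.230))
    td = p[P_TD] * (0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0))
                                 + math.exp(0.09 * (v + 14.0))))
    yinf[ID] = dss
    ytau[ID] = td
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * math.exp((v + 5.0) / 6.0))
    Aff = 0.6
    Afs = 1.0 - Aff
    yinf[IFF] = fss
    ytau[IFF] = tff
    yinf[IFS] = fss
    ytau[IFS] = tfs
    f = Aff * y[IFF] + Afs * y[IFS]
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0)
                         + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0)
                           + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    yinf[IFCAF] = fcass
    ytau[IFCAF] = tfcaf
    yinf[IFCAS] = fcass
    ytau[IFCAS] = tfcas
    fca = Afcaf * y[IFCAF] + Afcas * y[IFCAS]
    yinf[IJCA] = fcass
    ytau[IJCA] = 75.0
    yinf[IFFP] = fss
    ytau[IFFP] = 2.5 * tff
    fp = Aff * y[IFFP] + Afs * y[IFS]
    yinf[IFCAFP] = fcass
    ytau[IFCAFP] = 2.5 * tfcaf
    fcap = Afcaf * y[IFCAFP] + Afcas * y[IFCAS]

    Kmn = 0.002
    k2n = 1000.0
    km2n = y[IJCA] * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    # nca relaxes linearly: dnca = anca*k2n - nca*km2n
    if km2n > 1.0e-12:
        yinf[INCA] = anca * k2n / km2n
        ytau[INCA] = 1.0 / km2n
    else:
        ytau[INCA] = -1.0
    dy[INCA] = anca * k2n - y[INCA] * km2n

    e2v = math.exp(2.0 * vfrt)
    e1v = math.exp(1.0 * vfrt)
    PhiCaL = 4.0 * vffrt * (cass * e2v - 0.341 * _CAO) / (e2v - 1.0)
    PhiCaNa = 1.0 * vffrt * (0.75 * nass * e1v - 0.75 * _NAO) / (e1v - 1.0)
    PhiCaK = 1.0 * vffrt * (0.75 * kss * e1v - 0.75 * _KO) / (e1v - 1.0)
    PCa = 0.0001 * p[P_PERM]
    if celltype == 1:
        PCa *= 1.2
    elif celltype == 2:
        PCa *= 2.5
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap

    d_gate = y[ID]
    nca = y[INCA]
    gate_np = f * (1.0 - nca) + y[IJCA] * fca * nca
    gate_p = fp * (1.0 - nca) + y[IJCA] * fcap * nca
    favail = p[P_FAVAIL]

    phi_ical = 1.0 / (1.0 + km_camk / camka_ical)
    phi_icak = 1.0 / (1.0 + km_camk / camka_icak)
    phi_icana = 1.0 / (1.0 + km_camk / camka_icana)
    ICaL = ((1.0 - phi_ical) * PCa * PhiCaL * d_gate * gate_np
            + phi_ical * PCap * PhiCaL * d_gate * gate_p) * favail
    ICaNa = ((1.0 - phi_icana) * PCaNa * PhiCaNa * d_gate * gate_np
             + phi_icana * PCaNap * PhiCaNa * d_gate * gate_p) * favail
    ICaK = ((1.0 - phi_icak) * PCaK * PhiCaK * d_gate * gate_np
            + phi_icak * PCaKp * PhiCaK * d_gate * gate_p) * favail

    # --- rapid delayed rectifier K -----------------------------------------
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    yinf[IXRF] = xrss
    ytau[IXRF] = txrf
    yinf[IXRS] = xrss
    ytau[IXRS] = txrs
    xr = Axrf * y[IXRF] + Axrs * y[IXRS]
    rkr = (1.0 / (1.0 + math.exp((v + 55.0) / 75.0))
           * 1.0 / (1.0 + math.exp((v - 10.0) / 30.0)))
    GKr = 0.046
    if celltype == 1:
        GKr *= 1.3
    elif celltype == 2:
        GKr *= 0.8
    GKr *= (1.0 - p[P_IKR_BLOCK])
    IKr = GKr * math.sqrt(_KO / 5.4) * xr * rkr * (v - EK)

    # --- slow delayed rectifier K ------------------------------------------
    # PKA: GKs scaled by frac_iks; XS1 steady state midpoint Xs05 =
    # 11.60*frac_iks (11.60 = unmodified ORd midpoint at frac_iks = 1).
    frac_iks = p[P_FRACIKS]
    xs05 = 11.60 * frac_iks
    xs1ss = 1.0 / (1.0 + math.exp(-(v + xs05) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                          + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    yinf[IXS1] = xs1ss
    ytau[IXS1] = txs1
    xs2ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    yinf[IXS2] = xs2ss
    ytau[IXS2] = txs2
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034
    if celltype == 1:
        GKs *= 1.4
    GKs *= frac_iks
    IKs = GKs * KsCa * y[IXS1] * y[IXS2] * (v - EKs)

    # --- inward rectifier K ------------------------------------------------
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * _KO + 144.59)
                                  / (1.5692 * _KO + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36)
                    + math.exp((v + 236.8) / 69.33))
    yinf[IXK1] = xk1ss
    ytau[IXK1] = txk1
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * _KO) / 9.493))
    GK1 = 0.1908
    if celltype == 1:
        GK1 *= 1.2
    elif celltype == 2:
        GK1 *= 1.3
    IK1 = GK1 * math.sqrt(_KO) * rk1 * y[IXK1] * (v - EK)

    # --- Na/Ca exchanger ----------------------------------------------------
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
    hca = math.exp(qca * v * _F / (_R * _T))
    hna = math.exp(qna * v * _F / (_R * _T))
    Gncx = 0.0008
    if celltype == 1:
        Gncx *= 1.1
    elif celltype == 2:
        Gncx *= 1.4
    KmCaAct = 150.0e-6
    zca = 2.0
    zna = 1.0

    # myoplasmic component
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + _NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = _NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + _NAO / kna1 * (1.0 + _NAO / kna2)
    h11 = _NAO * _NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * _CAO * kcaon
    k2 = kcaoff
    k3p_ = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p_ + k3pp
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # subspace component
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # --- Na/K pump ----------------------------------------------------------
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p_ = 1899.0
    k3m = 79300.0
    k4p_ = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * math.exp(delta * v * _F / (3.0 * _R * _T))
    Knao = Knao0 * math.exp((1.0 - delta) * v * _F / (3.0 * _R * _T))
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H_ = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P_ = eP / (1.0 + H_ / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (_NAO / Knao) ** 3
          / ((1.0 + _NAO / Knao) ** 3 + (1.0 + _KO / Kko) ** 2 - 1.0))
    a3 = (k3p_ * (_KO / Kko) ** 2
          / ((1.0 + _NAO / Knao) ** 3 + (1.0 + _KO / Kko) ** 2 - 1.0))
    b3 = k3m * P_ * H_ / (1.0 + MgATP / Kmgatp)
    a4 = k4p_ * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * ki * ki / (Kki * Kki)
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0
    if celltype == 1:
        Pnak *= 0.9
    elif celltype == 2:
        Pnak *= 0.7
    INaK = Pnak * (zna * JnakNa + zk * JnakK)

    # --- background and pump currents ---------------------------------------
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    if celltype == 1:
        GKb *= 0.6
    IKb = GKb * xkb * (v - EK)
    PNab = 3.75e-10
    INab = PNab * vffrt * (nai * e1v - _NAO) / (e1v - 1.0)
    PCab = 2.5e-8
    ICab = PCab * 4.0 * vffrt * (cai * e2v - 0.341 * _CAO) / (e2v - 1.0)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)

    # --- stimulus -----------------------------------------------------------
    Istim = p[P_STIM_AMP] if t < p[P_STIM_DUR] else 0.0

    # --- diffusion fluxes ---------------------------------------------------
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # --- SR release ---------------------------------------------------------
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    if celltype == 2:
        Jrel_inf *= 1.7
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    yinf[IJRELNP] = Jrel_inf
    ytau[IJRELNP] = tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    if celltype == 2:
        Jrel_infp *= 1.7
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    yinf[IJRELP] = Jrel_infp
    ytau[IJRELP] = tau_relp
    fJrelp = 1.0 / (1.0 + km_camk / camka_jrel)
    Jrel = (1.0 - fJrelp) * y[IJRELNP] + fJrelp * y[IJRELP]

    # --- SR uptake (SERCA): combined CaMKII + PKA regulation ----------------
    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    if celltype == 1:
        Jupnp *= 1.3
        Jupp *= 1.3
    fJupp = 1.0 / (1.0 + km_camk * p[P_FPKAPLB] / camka_serca)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fJupp) * Jupnp + fJupp * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # --- membrane potential and concentration derivatives -------------------
    Isum = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + Istim)
    dy[IV] = -Isum
    ytau[IV] = -1.0

    cmdnmax = 0.05
    if celltype == 1:
        cmdnmax *= 1.3
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    dy[INAI] = (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab)
                * _ACAP / (_F * _VMYO) + JdiffNa * _VSS / _VMYO)
    dy[INASS] = -(ICaNa + 3.0 * INaCa_ss) * _ACAP / (_F * _VSS) - JdiffNa
    dy[IKI] = (-(Ito + IKr + IKs + IK1 + IKb + Istim - 2.0 * INaK)
               * _ACAP / (_F * _VMYO) + JdiffK * _VSS / _VMYO)
    dy[IKSS] = -ICaK * _ACAP / (_F * _VSS) - JdiffK
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dy[ICAI] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i)
                       * _ACAP / (2.0 * _F * _VMYO)
                       - Jup * _VNSR / _VMYO + Jdiff * _VSS / _VMYO)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dy[ICASS] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * _ACAP / (2.0 * _F * _VSS)
                         + Jrel * _VJSR / _VSS - Jdiff)
    dy[ICANSR] = Jup - Jtr * _VJSR / _VNSR
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dy[ICAJSR] = Bcajsr * (Jtr - Jrel)
    for k in (INAI, INASS, IKI, IKSS, ICAI, ICASS, ICANSR, ICAJSR):
        ytau[k] = -1.0

    # relaxation-form states also get a plain derivative (for LSODA and
    # derivative-based checks)
    for k in range(NSTATE):
        if ytau[k] > 0.0:
            dy[k] = (yinf[k] - y[k]) / ytau[k]

    cur[C_INA] = INa
    cur[C_INAL] = INaL
    cur[C_ITO] = Ito
    cur[C_ICAL] = ICaL
    cur[C_ICANA] = ICaNa
    cur[C_ICAK] = ICaK
    cur[C_IKR] = IKr
    cur[C_IKS] = IKs
    cur[C_IK1] = IK1
    cur[C_INACA_I] = INaCa_i
    cur[C_INACA_SS] = INaCa_ss
    cur[C_INAK] = INaK
    cur[C_INAB] = INab
    cur[C_IKB] = IKb
    cur[C_IPCA] = IpCa
    cur[C_ICAB] = ICab
    cur[C_ISTIM] = Istim
    cur[C_JREL] = Jrel
    cur[C_JUP] = Jup
    cur[C_JLEAK] = Jleak
    cur[C_JDIFF] = Jdiff
    cur[C_JUPNP] = Jupnp
    cur[C_JUPP] = Jupp


@njit(cache=True)
def rhs(t, y, p):
    """Plain derivative vector (used by the LSODA cross-check path)."""
    dy = np.zeros(NSTATE)
    yinf = np.zeros(NSTATE)
    ytau = np.zeros(NSTATE)
    cur = np.zeros(NCUR)
    derivatives(t, y, p, dy, yinf, ytau, cur)
    return dy


@njit(cache=True)
def integrate_beat(y, p, cl, max_step, dt_min, dv_max, plateau_cap,
                   sample_dt, rec_t, rec_sig, rec_sigidx):
    """Advance the state through one paced beat of length ``cl`` (ms).

    When ``rec_t.size > 0`` the beat is sampled on the uniform grid
    t = 0, sample_dt, 2*sample_dt, ... (steps are forced to land on the
    grid points, where state and currents are recorded).  Returns the
    number of recorded samples.
    """
    dy = np.zeros(NSTATE)
    yinf = np.zeros(NSTATE)
    ytau = np.zeros(NSTATE)
    cur = np.zeros(NCUR)
    t = 0.0
    nrec = 0
    recording = rec_t.size > 0
    next_sample = 0.0
    stim_dur = p[P_STIM_DUR]
    eps = 1.0e-9
    while t < cl - eps:
        derivatives(t, y, p, dy, yinf, ytau, cur)

        if recording and t >= next_sample - eps and nrec < rec_t.size:
            rec_t[nrec] = t
            for s in range(rec_sigidx.size):
                idx = rec_sigidx[s]
                if idx >= 0:
                    rec_sig[nrec, s] = cur[idx]
                else:
                    rec_sig[nrec, s] = y[-idx - 1]  # state channel
            nrec += 1
            next_sample = nrec * sample_dt

        # --- step selection -------------------------------------------------
        dt = max_step
        if y[IV] > -70.0 and plateau_cap < dt:
            dt = plateau_cap
        advdt = abs(dy[IV])
        if advdt > 1.0e-12 and dv_max / advdt < dt:
            dt = dv_max / advdt
        # limit relative change of the fast Ca compartments
        dca = abs(dy[ICASS])
        if dca > 1.0e-12:
            cap = 0.05 * (y[ICASS] + 1.0e-6) / dca
            if cap < dt:
                dt = cap
        dcj = abs(dy[ICAJSR])
        if dcj > 1.0e-12:
            cap = 0.05 * (y[ICAJSR] + 1.0e-3) / dcj
            if cap < dt:
                dt = cap
        if dt < dt_min:
            dt = dt_min
        # land exactly on stimulus edge, sampling grid and beat end
        if t < stim_dur - eps and t + dt > stim_dur:
            dt = stim_dur - t
        if recording and next_sample < cl and t + dt > next_sample + eps:
            dt = next_sample - t
        if t + dt > cl:
            dt = cl - t

        # --- update ---------------------------------------------------------
        for k in range(NSTATE):
            tau = ytau[k]
            if tau > 0.0:
                y[k] = yinf[k] + (y[k] - yinf[k]) * math.exp(-dt / tau)
            else:
                y[k] = y[k] + dt * dy[k]
        t += dt

        if not math.isfinite(y[IV]):
            return -1

    if recording and nrec < rec_t.size and next_sample <= cl + eps:
        # final sample at t = cl (end of beat)
        derivatives(cl - eps, y, p, dy, yinf, ytau, cur)
        rec_t[nrec] = cl
        for s in range(rec_sigidx.size):
            idx = rec_sigidx[s]
            if idx >= 0:
                rec_sig[nrec, s] = cur[idx]
            else:
                rec_sig[nrec, s] = y[-idx - 1]
        nrec += 1
    return nrec


@njit(cache=True)
def pace(y, p, n_beats, cl, max_step, dt_min, dv_max, plateau_cap,
         beat_states):
    """Pace ``n_beats`` beats without trace recording; store the end-of-beat
    state of each beat in ``beat_states``.  Returns the index of the last
    completed beat, or -1 on a non-finite state."""
    dummy_t = np.zeros(0)
    dummy_s = np.zeros((0, 0))
    dummy_i = np.zeros(0, dtype=np.int64)
    for b in range(n_beats):
        ok = integrate_beat(y, p, cl, max_step, dt_min, dv_max,
                            plateau_cap, 1.0, dummy_t, dummy_s, dummy_i)
        if ok < 0:
            return -1
        beat_states[b, :] = y
    return n_beats - 1
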
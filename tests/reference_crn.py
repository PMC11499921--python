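"""Naive reference integrator for the atrial cell model.

Written straight from the published model equations with plain Python
floats and loops: no lookup tables, no vectorization, no cached Nernst
potentials.  Gating variables use their exact exponential (Rush-Larsen)
solution computed from the closed-form rate expressions each step;
voltage and concentrations use forward Euler.  Deliberately independent
of the package's optimized kernel; used only as an oracle in equivalence
tests.
"""

import math

R = 8.3143
T = 310.0
F = 96.4867
RTF = R * T / F
Cm = 100.0
Ko, Nao, Cao = 5.4, 140.0, 1.8
Vi, Vup, Vrel = 13668.0, 1109.52, 96.48

REST = [
    -81.18,
    2.908e-3, 9.649e-1, 9.775e-1, 3.043e-2, 9.992e-1, 4.966e-3, 9.986e-1,
    3.296e-5, 1.869e-2, 1.367e-4, 9.996e-1, 7.755e-1, 2.35e-112, 1.0, 0.9992,
    11.17, 139.0, 1.013e-4, 1.488, 1.488,
]


def _safe_ratio(num, den, limit):
    return limit if abs(den) < 1e-12 else num / den


def derivatives(y, scal, i_stim=0.0):
    """Time derivatives (per ms) of the 21 state variables.

    ``scal`` maps channel name -> conductance factor; ``i_stim`` is a
    depolarizing current density (pA/pF).
    """
    (v, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, vv, w,
     nai, ki, cai, caup, carel) = y

    ena = RTF * math.log(Nao / nai)
    ek = RTF * math.log(Ko / ki)
    eca = 0.5 * RTF * math.log(Cao / cai)

    ina = scal.get("INa", 1.0) * 7.8 * m ** 3 * h * j * (v - ena)
    ik1 = scal.get("IK1", 1.0) * 0.09 * (v - ek) / (1 + math.exp(0.07 * (v + 80)))
    ito = scal.get("Ito", 1.0) * 0.1652 * oa ** 3 * oi * (v - ek)
    gkur = 0.005 + 0.05 / (1 + math.exp(-(v - 15) / 13))
    ikur = scal.get("IKur", 1.0) * gkur * ua ** 3 * ui * (v - ek)
    ikr = scal.get("IKr", 1.0) * 0.029411765 * xr * (v - ek) / (1 + math.exp((v + 15) / 22.4))
    iks = scal.get("IKs", 1.0) * 0.12941176 * xs ** 2 * (v - ek)
    ical = scal.get("ICaL", 1.0) * 0.12375 * d * f * fca * (v - 65)
    sigma = (math.exp(Nao / 67.3) - 1) / 7
    fnak = 1.0 / (1 + 0.1245 * math.exp(-0.1 * v / RTF) + 0.0365 * sigma * math.exp(-v / RTF))
    inak = scal.get("INaK", 1.0) * 0.59933874 * fnak / (1 + (10.0 / nai) ** 1.5) * Ko / (Ko + 1.5)
    eg = math.exp(0.35 * v / RTF)
    eg1 = math.exp(-0.65 * v / RTF)
    inaca = (scal.get("INaCa", 1.0) * 1600.0
             * (eg * nai ** 3 * Cao - eg1 * Nao ** 3 * cai)
             / ((87.5 ** 3 + Nao ** 3) * (1.38 + Cao) * (1 + 0.1 * eg1)))
    ibna = scal.get("IbNa", 1.0) * 0.0006744375 * (v - ena)
    ibca = scal.get("IbCa", 1.0) * 0.001131 * (v - eca)
    ipca = scal.get("IpCa", 1.0) * 0.275 * cai / (0.0005 + cai)

    iion = (ina + ical + ito + ikur + ikr + iks + ik1 + inaca + inak
            + ibna + ibca + ipca)

    # gate kinetics
    am = _safe_ratio(0.32 * (v + 47.13), 1 - math.exp(-0.1 * (v + 47.13)), 3.2)
    bm = 0.08 * math.exp(-v / 11)
    if v < -40:
        ah = 0.135 * math.exp(-(v + 80) / 6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = ((-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
              * (v + 37.78) / (1 + math.exp(0.311 * (v + 79.23))))
        bj = 0.1212 * math.exp(-0.01052 * v) / (1 + math.exp(-0.1378 * (v + 40.14)))
    else:
        ah = 0.0
        bh = 1.0 / (0.13 * (1 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1 + math.exp(-0.1 * (v + 32)))

    aoa = 0.65 / (math.exp(-(v + 10) / 8.5) + math.exp(-(v - 30) / 59))
    boa = 0.65 / (2.5 + math.exp((v + 82) / 17))
    oainf = 1 / (1 + math.exp(-(v + 20.47) / 17.54))
    aoi = 1 / (18.53 + math.exp((v + 113.7) / 10.95))
    boi = 1 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    oiinf = 1 / (1 + math.exp((v + 43.1) / 5.3))
    uainf = 1 / (1 + math.exp(-(v + 30.3) / 9.6))
    aui = 1 / (21 + math.exp(-(v - 185) / 28))
    bui = math.exp((v - 158) / 16)
    uiinf = 1 / (1 + math.exp((v - 99.45) / 27.48))
    axr = _safe_ratio(0.0003 * (v + 14.1), 1 - math.exp(-(v + 14.1) / 5), 0.0015)
    bxr = _safe_ratio(7.3898e-5 * (v - 3.3328),
                      math.exp((v - 3.3328) / 5.1237) - 1, 3.7836118e-4)
    xrinf = 1 / (1 + math.exp(-(v + 14.1) / 6.5))
    axs = _safe_ratio(4e-5 * (v - 19.9), 1 - math.exp(-(v - 19.9) / 17), 6.8e-4)
    bxs = _safe_ratio(3.5e-5 * (v - 19.9), math.exp((v - 19.9) / 9) - 1, 3.15e-4)
    xsinf = 1 / math.sqrt(1 + math.exp(-(v - 19.9) / 12.7))
    e_d = math.exp(-(v + 10) / 6.24)
    taud = _safe_ratio(1 - e_d, 0.035 * (v + 10) * (1 + e_d), 1 / (0.035 * 6.24 * 2))
    dinf = 1 / (1 + math.exp(-(v + 10) / 8))
    tauf = 9 / (0.0197 * math.exp(-(0.0337 ** 2) * (v + 10) ** 2) + 0.02)
    finf = 1 / (1 + math.exp((v + 28) / 6.9))
    e_w = math.exp(-(v - 7.9) / 5)
    tauw = _safe_ratio(6 * (1 - e_w), (1 + 0.3 * e_w) * (v - 7.9), 6 * 0.2 / 1.3)
    winf = 1 - 1 / (1 + math.exp(-(v - 40) / 17))

    irel = 30.0 * u ** 2 * vv * w * (carel - cai)
    itr = (caup - carel) / 180.0
    iup = 0.005 / (1 + 0.00092 / cai)
    iupleak = 0.005 * caup / 15.0
    fn = 1e-12 * Vrel * irel - (5e-13 / F) * (0.5 * ical * Cm - 0.2 * inaca * Cm)
    arg = max(min((fn - 3.4175e-13) / 1.367e-15, 80.0), -80.0)
    uinf = 1 / (1 + math.exp(-arg))
    tauv = 1.91 + 2.09 / (1 + math.exp(-arg))
    arg2 = max(min((fn - 6.835e-14) / 1.367e-15, 80.0), -80.0)
    vinf = 1 - 1 / (1 + math.exp(-arg2))

    cf = Cm / (F * Vi)
    b1 = (cf * 0.5 * (2 * inaca - ipca - ical - ibca)
          + (Vup * (iupleak - iup) + irel * Vrel) / Vi)
    b2 = (1 + 0.07 * 0.0005 / (cai + 0.0005) ** 2
          + 0.05 * 0.00238 / (cai + 0.00238) ** 2)

    return [
        -(iion - i_stim),
        am * (1 - m) - bm * m,
        ah * (1 - h) - bh * h,
        aj * (1 - j) - bj * j,
        ((aoa + boa) * 3) * (oainf - oa),
        ((aoi + boi) * 3) * (oiinf - oi),
        ((aoa + boa) * 3) * (uainf - ua),
        ((aui + bui) * 3) * (uiinf - ui),
        (axr + bxr) * (xrinf - xr),
        ((axs + bxs) / 0.5) * (xsinf - xs),
        (dinf - d) / taud,
        (finf - f) / tauf,
        (1 / (1 + cai / 0.00035) - fca) / 2.0,
        (uinf - u) / 8.0,
        (vinf - vv) / tauv,
        (winf - w) / tauw,
        cf * (-3 * inak - 3 * inaca - ibna - ina),
        cf * (2 * inak - ik1 - ito - ikur - ikr - iks),
        b1 / b2,
        iup - iupleak - itr * Vrel / Vup,
        (itr - irel) / (1 + 10 * 0.8 / (carel + 0.8) ** 2),
    ]


def gate_kinetics(y):
    """Per-gate (inf, tau) pairs from the closed-form rate expressions.

    Order matches the state vector gates: m h j oa oi ua ui xr xs d f
    fca u v w (fca/u/v depend on Ca and the SR release flux).
    """
    (v, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, vv, w,
     nai, ki, cai, caup, carel) = y

    am = _safe_ratio(0.32 * (v + 47.13), 1 - math.exp(-0.1 * (v + 47.13)), 3.2)
    bm = 0.08 * math.exp(-v / 11)
    if v < -40:
        ah = 0.135 * math.exp(-(v + 80) / 6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = ((-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
              * (v + 37.78) / (1 + math.exp(0.311 * (v + 79.23))))
        bj = 0.1212 * math.exp(-0.01052 * v) / (1 + math.exp(-0.1378 * (v + 40.14)))
    else:
        ah = 0.0
        bh = 1.0 / (0.13 * (1 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1 + math.exp(-0.1 * (v + 32)))

    aoa = 0.65 / (math.exp(-(v + 10) / 8.5) + math.exp(-(v - 30) / 59))
    boa = 0.65 / (2.5 + math.exp((v + 82) / 17))
    aoi = 1 / (18.53 + math.exp((v + 113.7) / 10.95))
    boi = 1 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    aui = 1 / (21 + math.exp(-(v - 185) / 28))
    bui = math.exp((v - 158) / 16)
    axr = _safe_ratio(0.0003 * (v + 14.1), 1 - math.exp(-(v + 14.1) / 5), 0.0015)
    bxr = _safe_ratio(7.3898e-5 * (v - 3.3328),
                      math.exp((v - 3.3328) / 5.1237) - 1, 3.7836118e-4)
    axs = _safe_ratio(4e-5 * (v - 19.9), 1 - math.exp(-(v - 19.9) / 17), 6.8e-4)
    bxs = _safe_ratio(3.5e-5 * (v - 19.9), math.exp((v - 19.9) / 9) - 1, 3.15e-4)
    e_d = math.exp(-(v + 10) / 6.24)
    taud = _safe_ratio(1 - e_d, 0.035 * (v + 10) * (1 + e_d), 1 / (0.035 * 6.24 * 2))
    tauf = 9 / (0.0197 * math.exp(-(0.0337 ** 2) * (v + 10) ** 2) + 0.02)
    e_w = math.exp(-(v - 7.9) / 5)
    tauw = _safe_ratio(6 * (1 - e_w), (1 + 0.3 * e_w) * (v - 7.9), 6 * 0.2 / 1.3)

    # Fn-gated SR release gates need the fluxes
    ena = RTF * math.log(Nao / nai)
    ical = 0.12375 * d * f * fca * (v - 65)
    eg = math.exp(0.35 * v / RTF)
    eg1 = math.exp(-0.65 * v / RTF)
    inaca = (1600.0 * (eg * nai ** 3 * Cao - eg1 * Nao ** 3 * cai)
             / ((87.5 ** 3 + Nao ** 3) * (1.38 + Cao) * (1 + 0.1 * eg1)))
    irel = 30.0 * u ** 2 * vv * w * (carel - cai)
    fn = 1e-12 * Vrel * irel - (5e-13 / F) * (0.5 * ical * Cm - 0.2 * inaca * Cm)
    arg = max(min((fn - 3.4175e-13) / 1.367e-15, 80.0), -80.0)
    uinf = 1 / (1 + math.exp(-arg))
    tauv = 1.91 + 2.09 / (1 + math.exp(-arg))
    arg2 = max(min((fn - 6.835e-14) / 1.367e-15, 80.0), -80.0)
    vinf = 1 - 1 / (1 + math.exp(-arg2))
    del ena

    return [
        (am / (am + bm), 1 / (am + bm)),
        (ah / (ah + bh), 1 / (ah + bh)),
        (aj / (aj + bj), 1 / (aj + bj)),
        (1 / (1 + math.exp(-(v + 20.47) / 17.54)), 1 / ((aoa + boa) * 3)),
        (1 / (1 + math.exp((v + 43.1) / 5.3)), 1 / ((aoi + boi) * 3)),
        (1 / (1 + math.exp(-(v + 30.3) / 9.6)), 1 / ((aoa + boa) * 3)),
        (1 / (1 + math.exp((v - 99.45) / 27.48)), 1 / ((aui + bui) * 3)),
        (1 / (1 + math.exp(-(v + 14.1) / 6.5)), 1 / (axr + bxr)),
        (1 / math.sqrt(1 + math.exp(-(v - 19.9) / 12.7)), 0.5 / (axs + bxs)),
        (1 / (1 + math.exp(-(v + 10) / 8)), taud),
        (1 / (1 + math.exp((v + 28) / 6.9)), tauf),
        (1 / (1 + cai / 0.00035), 2.0),
        (uinf, 8.0),
        (vinf, tauv),
        (1 - 1 / (1 + math.exp(-(v - 40) / 17)), tauw),
    ]


def step(y, dt, scal=None, i_stim=0.0):
    """One time step: exact-exponential gates, Euler Vm/concentrations."""
    scal = scal or {}
    dy = derivatives(y, scal, i_stim)
    kin = gate_kinetics(y)
    out = list(y)
    out[0] = y[0] + dt * dy[0]
    for g, (inf, tau) in enumerate(kin):
        out[1 + g] = inf + (y[1 + g] - inf) * math.exp(-dt / tau)
    for i in range(16, 21):
        out[i] = y[i] + dt * dy[i]
    return out


def integrate_cell(y0, dt, n_steps, scal=None, stim=None):
    """Loop integration; ``stim(t_ms)`` returns pA/pF (depolarizing).

    Returns the list of Vm samples (one per step, pre-step values).
    """
    scal = scal or {}
    y = list(y0)
    vms = []
    for s in range(n_steps):
        t = s * dt
        vms.append(y[0])
        i_stim = stim(t) if stim else 0.0
        y = step(y, dt, scal, i_stim)
    return vms, y


def integrate_cable(n_nodes, d_coeff, h, dt, n_steps, stim_nodes, stim_t0,
                    stim_t1, stim_amp, scal=None):
    """1D monodomain cable, dense loops: Euler reaction + 3-point diffusion.

    Lie splitting (reaction step, then an explicit diffusion step on the
    reacted voltage), matching the splitting the tissue solver documents.
    ``d_coeff`` in mm^2/ms, ``h`` in mm.  No-flux ends.  Returns the final
    per-node Vm list and a per-step trace of node ``n_nodes // 2``.
    """
    scal = scal or {}
    ys = [list(REST) for _ in range(n_nodes)]
    mid_trace = []
    r = d_coeff / (h * h)
    for s in range(n_steps):
        t = s * dt
        mid_trace.append(ys[n_nodes // 2][0])
        ys = [step(y, dt, scal,
                   stim_amp if (k in stim_nodes and stim_t0 <= t < stim_t1) else 0.0)
              for k, y in enumerate(ys)]
        vmid = [y[0] for y in ys]
        for k in range(n_nodes):
            left = vmid[k - 1] if k > 0 else vmid[k]
            right = vmid[k + 1] if k < n_nodes - 1 else vmid[k]
            ys[k][0] += dt * r * (left - 2 * vmid[k] + right)
    return [y[0] for y in ys], mid_trace
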
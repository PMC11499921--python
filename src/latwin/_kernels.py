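"""Numba kernels for the atrial myocyte model and monodomain tissue stepping.

The ionic model is the Courtemanche–Ramirez–Nattel (CRN) human atrial
action-potential model with an added acetylcholine-dependent potassium
current (I_KACh, Kneller-style formulation, inactive at zero ACh).  All
voltage-dependent gate kinetics and current factors are pre-tabulated on a
uniform Vm grid per time step (Rush–Larsen factors exp(-dt/tau) are baked
into the table), so the per-node per-step cost is dominated by table
interpolation rather than transcendental calls.

Units: time ms, voltage mV, currents pA/pF, concentrations mM,
conductances nS/pF.  dVm/dt = -(I_ion + I_stim)/1 since Cm = 100 pF and
currents are expressed per pF.

State vector layout (N_STATE = 21 rows, one column per node):
  0 Vm, 1 m, 2 h, 3 j, 4 oa, 5 oi, 6 ua, 7 ui, 8 xr, 9 xs,
  10 d, 11 f, 12 fca, 13 u, 14 v, 15 w,
  16 Na_i, 17 K_i, 18 Ca_i, 19 Ca_up, 20 Ca_rel

Channel-scaling vector layout (N_CHAN = 13 rows):
  0 INa, 1 ICaL, 2 Ito, 3 IKur, 4 IKr, 5 IKs, 6 IK1, 7 IKACh,
  8 INaCa, 9 INaK, 10 IbNa, 11 IbCa, 12 IpCa
"""

import numpy as np
from numba import njit

N_STATE = 21
N_CHAN = 13

# physical constants (CRN unit system)
R_GAS = 8.3143
TEMP = 310.0
FARADAY = 96.4867
FRT = FARADAY / (R_GAS * TEMP)  # 1/mV
CM_PF = 100.0

# extracellular concentrations (mM)
KO = 5.4
NAO = 140.0
CAO = 1.8

# cell volumes (um^3)
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

KQ10 = 3.0
SIGMA_NAK = (np.exp(NAO / 67.3) - 1.0) / 7.0

# maximal conductances / rates
G_NA = 7.8
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375
I_NAK_MAX = 0.59933874
I_NACA_MAX = 1600.0
I_PCA_MAX = 0.275
I_UP_MAX = 0.005
K_UP = 0.00092
CA_UP_MAX = 15.0
K_REL = 30.0
TAU_TR = 180.0
TAU_FCA = 2.0
TAU_U = 8.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

# voltage table grid
V_MIN = -110.0
V_MAX = 70.0
DV_TAB = 0.05
N_TAB = int(round((V_MAX - V_MIN) / DV_TAB)) + 1
N_COL = 31

# table column indices: 12 tabulated gates x (inf, rush-larsen factor)
# gates in table order: m h j oa oi ua ui xr xs d f w
COL_K1F = 24
COL_GKUR = 25
COL_KRF = 26
COL_FNAK = 27
COL_EXPG = 28
COL_EXPG1 = 29
COL_KACHF = 30


@njit(cache=True)
def fill_rate_table(table, dt):
    """Fill the (N_TAB, N_COL) voltage lookup table for a given time step."""
    for i in range(N_TAB):
        v = V_MIN + i * DV_TAB

        # --- I_Na gates ---------------------------------------------------
        dvm = v + 47.13
        if abs(dvm) < 1e-10:
            a_m = 3.2
        else:
            a_m = 0.32 * dvm / (1.0 - np.exp(-0.1 * dvm))
        b_m = 0.08 * np.exp(-v / 11.0)

        if v < -40.0:
            a_h = 0.135 * np.exp(-(v + 80.0) / 6.8)
            b_h = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
            a_j = (
                (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
                * (v + 37.78)
                / (1.0 + np.exp(0.311 * (v + 79.23)))
            )
            b_j = 0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
        else:
            a_h = 0.0
            b_h = 1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
            a_j = 0.0
            b_j = 0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))

        # --- I_to gates ---------------------------------------------------
        a_oa = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
        b_oa = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
        tau_oa = 1.0 / ((a_oa + b_oa) * KQ10)
        oa_inf = 1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54))

        a_oi = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
        b_oi = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
        tau_oi = 1.0 / ((a_oi + b_oi) * KQ10)
        oi_inf = 1.0 / (1.0 + np.exp((v + 43.1) / 5.3))

        # --- I_Kur gates (ua kinetics identical to oa) ---------------------
        tau_ua = tau_oa
        ua_inf = 1.0 / (1.0 + np.exp(-(v + 30.3) / 9.6))

        a_ui = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
        b_ui = np.exp((v - 158.0) / 16.0)
        tau_ui = 1.0 / ((a_ui + b_ui) * KQ10)
        ui_inf = 1.0 / (1.0 + np.exp((v - 99.45) / 27.48))

        # --- I_Kr / I_Ks gates ---------------------------------------------
        dvx = v + 14.1
        if abs(dvx) < 1e-10:
            a_xr = 0.0015
        else:
            a_xr = 0.0003 * dvx / (1.0 - np.exp(-dvx / 5.0))
        dvx = v - 3.3328
        if abs(dvx) < 1e-10:
            b_xr = 3.7836118e-4
        else:
            b_xr = 7.3898e-5 * dvx / (np.exp(dvx / 5.1237) - 1.0)
        tau_xr = 1.0 / (a_xr + b_xr)
        xr_inf = 1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5))

        dvx = v - 19.9
        if abs(dvx) < 1e-10:
            a_xs = 6.8e-4
            b_xs = 3.15e-4
        else:
            a_xs = 4e-5 * dvx / (1.0 - np.exp(-dvx / 17.0))
            b_xs = 3.5e-5 * dvx / (np.exp(dvx / 9.0) - 1.0)
        tau_xs = 0.5 / (a_xs + b_xs)
        xs_inf = 1.0 / np.sqrt(1.0 + np.exp(-(v - 19.9) / 12.7))

        # --- I_CaL gates ----------------------------------------------------
        dvx = v + 10.0
        e1 = np.exp(-dvx / 6.24)
        if abs(dvx) < 1e-10:
            tau_d = 1.0 / (0.035 * 6.24 * 2.0)
        else:
            tau_d = (1.0 - e1) / (0.035 * dvx * (1.0 + e1))
        d_inf = 1.0 / (1.0 + np.exp(-dvx / 8.0))

        tau_f = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * dvx * dvx) + 0.02)
        f_inf = 1.0 / (1.0 + np.exp((v + 28.0) / 6.9))

        # --- SR release w gate ----------------------------------------------
        dvx = v - 7.9
        if abs(dvx) < 1e-10:
            tau_w = 6.0 * 0.2 / 1.3
        else:
            tau_w = 6.0 * (1.0 - np.exp(-dvx / 5.0)) / ((1.0 + 0.3 * np.exp(-dvx / 5.0)) * dvx)
        w_inf = 1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0))

        # gate columns: inf, exp(-dt/tau)
        infs = (
            a_m / (a_m + b_m), a_h / (a_h + b_h), a_j / (a_j + b_j),
            oa_inf, oi_inf, ua_inf, ui_inf, xr_inf, xs_inf, d_inf, f_inf, w_inf,
        )
        taus = (
            1.0 / (a_m + b_m), 1.0 / (a_h + b_h), 1.0 / (a_j + b_j),
            tau_oa, tau_oi, tau_ua, tau_ui, tau_xr, tau_xs, tau_d, tau_f, tau_w,
        )
        for g in range(12):
            table[i, 2 * g] = infs[g]
            table[i, 2 * g + 1] = np.exp(-dt / taus[g])

        # --- current factors -------------------------------------------------
        table[i, COL_K1F] = 1.0 / (1.0 + np.exp(0.07 * (v + 80.0)))
        table[i, COL_GKUR] = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
        table[i, COL_KRF] = 1.0 / (1.0 + np.exp((v + 15.0) / 22.4))
        table[i, COL_FNAK] = 1.0 / (
            1.0
            + 0.1245 * np.exp(-0.1 * FRT * v)
            + 0.0365 * SIGMA_NAK * np.exp(-FRT * v)
        )
        table[i, COL_EXPG] = np.exp(0.35 * FRT * v)
        table[i, COL_EXPG1] = np.exp(-0.65 * FRT * v)
        table[i, COL_KACHF] = 0.0517 + 0.4516 / (1.0 + np.exp((v + 59.53) / 17.18))


def make_rate_table(dt):
    table = np.empty((N_TAB, N_COL), dtype=np.float64)
    fill_rate_table(table, dt)
    return table


@njit(cache=True, fastmath=True)
def step_reaction(states, scal, cach, table, dt, rl_fca, rl_u,
                  ena, ek, eca, active, iion_out):
    """Advance the ionic model of every active node by one step of size dt.

    `states` has one contiguous row of 21 state variables per node;
    `ena/ek/eca` are cached Nernst potentials (refreshed by the caller),
    `cach` the constant ACh-dependent I_KACh prefactor, `iion_out`
    receives the total ionic current (pA/pF) used for the Vm update.
    """
    n = states.shape[0]
    denom_naca = (87.5 ** 3 + NAO ** 3) * (1.38 + CAO)
    conc_fac = CM_PF / (FARADAY * V_I)

    for k in range(n):
        if not active[k]:
            continue
        row = states[k]
        v = row[0]
        # table lookup with linear interpolation
        x = (v - V_MIN) / DV_TAB
        if x < 0.0:
            x = 0.0
        elif x > N_TAB - 1.001:
            x = N_TAB - 1.001
        i0 = int(x)
        w1 = x - i0
        w0 = 1.0 - w1
        t0 = table[i0]
        t1 = table[i0 + 1]

        m = row[1]
        h = row[2]
        j = row[3]
        oa = row[4]
        oi = row[5]
        ua = row[6]
        ui = row[7]
        xr = row[8]
        xs = row[9]
        d = row[10]
        f = row[11]
        fca = row[12]
        u = row[13]
        vg = row[14]
        w = row[15]
        nai = row[16]
        ki = row[17]
        cai = row[18]
        caup = row[19]
        carel = row[20]

        k1f = w0 * t0[COL_K1F] + w1 * t1[COL_K1F]
        gkur = w0 * t0[COL_GKUR] + w1 * t1[COL_GKUR]
        krf = w0 * t0[COL_KRF] + w1 * t1[COL_KRF]
        fnak = w0 * t0[COL_FNAK] + w1 * t1[COL_FNAK]
        expg = w0 * t0[COL_EXPG] + w1 * t1[COL_EXPG]
        expg1 = w0 * t0[COL_EXPG1] + w1 * t1[COL_EXPG1]
        kachf = w0 * t0[COL_KACHF] + w1 * t1[COL_KACHF]

        sk = scal[k]
        # --- membrane currents (pA/pF) ---
        ina = sk[0] * G_NA * m * m * m * h * j * (v - ena[k])
        ical = sk[1] * G_CAL * d * f * fca * (v - 65.0)
        ito = sk[2] * G_TO * oa * oa * oa * oi * (v - ek[k])
        ikur = sk[3] * gkur * ua * ua * ua * ui * (v - ek[k])
        ikr = sk[4] * G_KR * xr * krf * (v - ek[k])
        iks = sk[5] * G_KS * xs * xs * (v - ek[k])
        ik1 = sk[6] * G_K1 * k1f * (v - ek[k])
        ikach = sk[7] * cach * kachf * (v - ek[k])
        inaca = (
            sk[8] * I_NACA_MAX
            * (expg * nai * nai * nai * CAO - expg1 * NAO * NAO * NAO * cai)
            / (denom_naca * (1.0 + 0.1 * expg1))
        )
        rn = 10.0 / nai
        inak = (
            sk[9] * I_NAK_MAX * fnak
            / (1.0 + rn * np.sqrt(rn))
            * (KO / (KO + 1.5))
        )
        ibna = sk[10] * G_B_NA * (v - ena[k])
        ibca = sk[11] * G_B_CA * (v - eca[k])
        ipca = sk[12] * I_PCA_MAX * cai / (0.0005 + cai)

        iion = (ina + ical + ito + ikur + ikr + iks + ik1 + ikach
                + inaca + inak + ibna + ibca + ipca)
        iion_out[k] = iion

        # --- SR calcium fluxes (mM/ms) ---
        irel = K_REL * u * u * vg * w * (carel - cai)
        itr = (caup - carel) / TAU_TR
        iup = I_UP_MAX / (1.0 + K_UP / cai)
        iupleak = I_UP_MAX * caup / CA_UP_MAX

        # --- Fn-gated SR release gates ---
        fn = (1e-12 * V_REL * irel
              - (5e-13 / FARADAY) * (0.5 * ical * CM_PF - 0.2 * inaca * CM_PF))
        arg = (fn - 3.4175e-13) / 1.367e-15
        if arg > 80.0:
            arg = 80.0
        elif arg < -80.0:
            arg = -80.0
        e1 = np.exp(-arg)
        u_inf = 1.0 / (1.0 + e1)
        tau_v = 1.91 + 2.09 / (1.0 + e1)
        arg2 = (fn - 6.835e-14) / 1.367e-15
        if arg2 > 80.0:
            arg2 = 80.0
        elif arg2 < -80.0:
            arg2 = -80.0
        v_inf = 1.0 - 1.0 / (1.0 + np.exp(-arg2))

        # --- gate updates (Rush-Larsen; table holds inf and exp(-dt/tau)) ---
        # table gate order m h j oa oi ua ui xr xs d f -> state rows 1..11
        for g in range(11):
            inf = w0 * t0[2 * g] + w1 * t1[2 * g]
            rl = w0 * t0[2 * g + 1] + w1 * t1[2 * g + 1]
            row[1 + g] = inf + (row[1 + g] - inf) * rl
        inf = w0 * t0[22] + w1 * t1[22]  # w gate (state row 15)
        rl = w0 * t0[23] + w1 * t1[23]
        row[15] = inf + (w - inf) * rl
        fca_inf = 1.0 / (1.0 + cai / 0.00035)
        row[12] = fca_inf + (fca - fca_inf) * rl_fca
        row[13] = u_inf + (u - u_inf) * rl_u
        row[14] = v_inf + (vg - v_inf) * np.exp(-dt / tau_v)

        # --- concentration updates (forward Euler) ---
        row[16] = nai + dt * conc_fac * (-3.0 * inak - 3.0 * inaca - ibna - ina)
        row[17] = ki + dt * conc_fac * (2.0 * inak - ik1 - ito - ikur - ikr
                                        - iks - ikach)
        b1 = (
            conc_fac * 0.5 * (2.0 * inaca - ipca - ical - ibca)
            + (V_UP * (iupleak - iup) + irel * V_REL) / V_I
        )
        b2 = (
            1.0
            + TRPN_MAX * KM_TRPN / ((cai + KM_TRPN) * (cai + KM_TRPN))
            + CMDN_MAX * KM_CMDN / ((cai + KM_CMDN) * (cai + KM_CMDN))
        )
        row[18] = cai + dt * b1 / b2
        row[19] = caup + dt * (iup - iupleak - itr * V_REL / V_UP)
        row[20] = carel + dt * (itr - irel) / (
            1.0 + CSQN_MAX * KM_CSQN / ((carel + KM_CSQN) * (carel + KM_CSQN))
        )
    return 0


@njit(cache=True, fastmath=True)
def refresh_nernst(states, active, ena, ek, eca):
    n = states.shape[0]
    rtf = 1.0 / FRT
    for k in range(n):
        if not active[k]:
            continue
        ena[k] = rtf * np.log(NAO / states[k, 16])
        ek[k] = rtf * np.log(KO / states[k, 17])
        eca[k] = 0.5 * rtf * np.log(CAO / states[k, 18])


@njit(cache=True, fastmath=True)
def integrate(states, scal, cach, table, dt, n_steps, t0,
              nernst_every,
              Lp, Lj, Lx,
              stim_start, stim_stop, stim_amp, stim_indptr, stim_nodes,
              act_thr, act_times, act_counts,
              frames, rec_every,
              active, quiet_stop_ms):
    """Main monodomain integration loop (operator splitting, shared dt).

    Returns (status, step, node): status 0 = completed, 1 = Vm out of
    bounds, 2 = NaN detected; step/node identify the failure site.
    Records up-crossings of `act_thr` into act_times/act_counts and Vm
    frames (float32) every `rec_every` steps.

    If `quiet_stop_ms` > 0 the loop stops once no activation has occurred
    for that long after the last stimulus has ended (the tissue is then
    at rest and, absent stimuli, stays there); remaining frames are
    filled with the final state so trace shapes are unchanged.
    """
    n = states.shape[0]
    iion = np.empty(n, dtype=np.float64)
    ena = np.empty(n, dtype=np.float64)
    ek = np.empty(n, dtype=np.float64)
    eca = np.empty(n, dtype=np.float64)
    vprev = np.empty(n, dtype=np.float64)
    refresh_nernst(states, active, ena, ek, eca)
    rl_fca = np.exp(-dt / TAU_FCA)
    rl_u = np.exp(-dt / TAU_U)
    n_stim = stim_start.shape[0]
    max_act = act_times.shape[1]
    n_frames = frames.shape[0]
    frame_i = 0
    has_diff = Lx.shape[0] > 0
    stim_all_end = 0.0
    for si in range(n_stim):
        if stim_stop[si] > stim_all_end:
            stim_all_end = stim_stop[si]
    last_act_t = t0

    for s in range(n_steps):
        if rec_every > 0 and s % rec_every == 0 and frame_i < n_frames:
            for k in range(n):
                frames[frame_i, k] = states[k, 0]
            frame_i += 1
        if s % nernst_every == 0:
            refresh_nernst(states, active, ena, ek, eca)

        for k in range(n):
            vprev[k] = states[k, 0]

        step_reaction(states, scal, cach, table, dt, rl_fca, rl_u,
                      ena, ek, eca, active, iion)

        t = t0 + s * dt
        for k in range(n):
            if active[k]:
                states[k, 0] = vprev[k] - dt * iion[k]

        # stimuli (depolarizing current of given pA/pF amplitude)
        for si in range(n_stim):
            if stim_start[si] <= t < stim_stop[si]:
                a = dt * stim_amp[si]
                for p in range(stim_indptr[si], stim_indptr[si + 1]):
                    node = stim_nodes[p]
                    if active[node]:
                        states[node, 0] += a

        # diffusion (explicit, CSR Laplacian in 1/ms); increments buffered
        # in iion so the update stays synchronous
        if has_diff:
            for k in range(n):
                acc = 0.0
                for p in range(Lp[k], Lp[k + 1]):
                    acc += Lx[p] * states[Lj[p], 0]
                iion[k] = dt * acc
            for k in range(n):
                if active[k]:
                    states[k, 0] += iion[k]

        # activation detection + stability guard
        for k in range(n):
            if not active[k]:
                continue
            vnew = states[k, 0]
            if vnew != vnew or vnew > 200.0 or vnew < -200.0:
                status = 2 if vnew != vnew else 1
                return status, s, k
            if vprev[k] < act_thr and vnew >= act_thr:
                last_act_t = t + dt
                c = act_counts[k]
                if c < max_act:
                    act_times[k, c] = t + dt
                    act_counts[k] = c + 1

        if (quiet_stop_ms > 0.0 and t > stim_all_end
                and t - last_act_t > quiet_stop_ms):
            # tissue quiescent with no pending stimuli: fill remaining
            # frames with the final Vm and finish
            while frame_i < n_frames:
                for k in range(n):
                    frames[frame_i, k] = states[k, 0]
                frame_i += 1
            return 0, n_steps, -1
    return 0, n_steps, -1
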
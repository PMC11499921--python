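"""Single-cell human atrial action-potential model.

The ionic model is the Courtemanche–Ramirez–Nattel (CRN) formulation of the
human atrial myocyte, extended with an acetylcholine-activated potassium
current I_KACh (inactive at the default ACh level of 0).  Total membrane
current is

    I_ion = I_Na + I_CaL + I_to + I_Kur + I_Kr + I_Ks + I_K1 + I_KACh
          + I_NaCa + I_NaK + I_b,Na + I_b,Ca + I_p,Ca

Chronic-AF electrical remodeling, fibrosis, and drug blockade all act as
multiplicative per-channel conductance factors (:class:`ConductanceScaling`);
they compose by elementwise product.

Integration uses Rush–Larsen exponential updates for the 15 gating
variables and forward Euler for Vm and the 5 concentrations, with
voltage-dependent rates tabulated per time step (see ``_kernels``).
The declared stability bound is dt <= 0.1 ms; the single-cell default is
dt = 0.02 ms.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels as K

#: Channel order used throughout the package (scaling vectors, drug tables).
CHANNELS = (
    "INa", "ICaL", "Ito", "IKur", "IKr", "IKs", "IK1", "IKACh",
    "INaCa", "INaK", "IbNa", "IbCa", "IpCa",
)
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

GATE_NAMES = (
    "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "fca",
    "u", "v", "w",
)
CONC_NAMES = ("Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel")

#: Declared stability bound for the reaction step (ms).
DT_MAX = 0.1
#: Single-cell default time step (ms).
DT_CELL = 0.02

# CRN published resting initial conditions.
_REST_STATE = np.array([
    -81.18,        # Vm
    2.908e-3, 9.649e-1, 9.775e-1,          # m h j
    3.043e-2, 9.992e-1,                    # oa oi
    4.966e-3, 9.986e-1,                    # ua ui
    3.296e-5, 1.869e-2,                    # xr xs
    1.367e-4, 9.996e-1, 7.755e-1,          # d f fca
    2.35e-112, 1.0, 0.9992,                # u v w
    11.17, 139.0, 1.013e-4, 1.488, 1.488,  # Na_i K_i Ca_i Ca_up Ca_rel
])


class ModelError(ValueError):
    """Invalid state, scaling, or integration setting."""


@dataclasses.dataclass
class MyocyteState:
    """Full state of one myocyte node.

    Attributes
    ----------
    vm : float
        Membrane potential (mV).
    gates : numpy.ndarray
        The 15 gating variables in :data:`GATE_NAMES` order, each in [0, 1].
    concentrations : numpy.ndarray
        Na_i, K_i, Ca_i, Ca_up, Ca_rel (mM), all positive.
    """

    vm: float
    gates: np.ndarray
    concentrations: np.ndarray

    @classmethod
    def resting(cls) -> "MyocyteState":
        v = _REST_STATE
        return cls(vm=float(v[0]), gates=v[1:16].copy(), concentrations=v[16:].copy())

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "MyocyteState":
        vec = np.asarray(vec, dtype=float)
        return cls(vm=float(vec[0]), gates=vec[1:16].copy(), concentrations=vec[16:21].copy())

    def to_vector(self) -> np.ndarray:
        return np.concatenate(([self.vm], self.gates, self.concentrations))

    def validate(self) -> None:
        if not math.isfinite(self.vm):
            raise ModelError(f"membrane potential is not finite: vm={self.vm!r}")
        for name, g in zip(GATE_NAMES, self.gates):
            if not math.isfinite(g) or not (0.0 <= g <= 1.0):
                raise ModelError(f"gating variable {name!r} out of [0,1]: {g!r}")
        for name, c in zip(CONC_NAMES, self.concentrations):
            if not math.isfinite(c) or c <= 0.0:
                raise ModelError(f"concentration {name!r} must be positive: {c!r}")


@dataclasses.dataclass
class ConductanceScaling:
    """Multiplicative per-channel conductance factors.

    Factor 1.0 leaves a channel unmodified; factors compose by elementwise
    product, so remodeling, fibrosis, and drug block can be stacked in any
    order.
    """

    factors: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.factors, dtype=float)
        if f.shape != (len(CHANNELS),):
            raise ModelError(f"scaling must have {len(CHANNELS)} factors, got shape {f.shape}")
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise ModelError("scaling factors must be finite and >= 0")
        self.factors = f

    @classmethod
    def unit(cls) -> "ConductanceScaling":
        return cls(np.ones(len(CHANNELS)))

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ConductanceScaling":
        f = np.ones(len(CHANNELS))
        for name, val in d.items():
            if name not in CHANNEL_INDEX:
                raise ModelError(f"unknown channel {name!r}")
            f[CHANNEL_INDEX[name]] = val
        return cls(f)

    @classmethod
    def af_remodeling(cls, profile: Mapping[str, float] | None = None) -> "ConductanceScaling":
        """Chronic-AF electrical remodeling profile (substitutable default)."""
        if profile is None:
            profile = {"ICaL": 0.3, "Ito": 0.5, "IKur": 0.5, "IK1": 2.0}
        return cls.from_dict(profile)

    @classmethod
    def fibrotic(cls) -> "ConductanceScaling":
        """Fibrotic-myocyte profile: I_K1 and I_CaL reduced by 50%, I_Na by 40%."""
        return cls.from_dict({"IK1": 0.5, "ICaL": 0.5, "INa": 0.6})

    def compose(self, other: "ConductanceScaling") -> "ConductanceScaling":
        return ConductanceScaling(self.factors * other.factors)

    def __mul__(self, other: "ConductanceScaling") -> "ConductanceScaling":
        return self.compose(other)

    def __getitem__(self, channel: str) -> float:
        return float(self.factors[CHANNEL_INDEX[channel]])


@dataclasses.dataclass
class APMetrics:
    """Action-potential measurements on the last paced beat."""

    captured: bool
    apd90_ms: float = float("nan")
    dvdt_max_Vps: float = float("nan")
    amplitude_mV: float = float("nan")
    resting_mV: float = float("nan")

    @classmethod
    def no_ap(cls) -> "APMetrics":
        return cls(captured=False)


def ach_prefactor(ach_uM: float) -> float:
    """Constant dose factor of I_KACh; zero at zero acetylcholine."""
    if ach_uM <= 0.0:
        return 0.0
    return 10.0 / (1.0 + 9.13652 / ach_uM ** 0.477811)


def ionic_currents(state: MyocyteState, scaling: ConductanceScaling | None = None,
                   ach_uM: float = 0.0) -> dict:
    """All 13 membrane currents (pA/pF) at a fixed state, plus their sum.

    Each current is exactly proportional to its composed scaling factor.
    Returns a dict keyed by :data:`CHANNELS` plus ``"I_ion"``.
    """
    state.validate()
    s = scaling.factors if scaling is not None else np.ones(len(CHANNELS))
    v = state.vm
    m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, vg, w = state.gates
    nai, ki, cai, caup, carel = state.concentrations

    rtf = 1.0 / K.FRT
    ena = rtf * math.log(K.NAO / nai)
    ek = rtf * math.log(K.KO / ki)
    eca = 0.5 * rtf * math.log(K.CAO / cai)

    out = {}
    out["INa"] = s[0] * K.G_NA * m ** 3 * h * j * (v - ena)
    out["ICaL"] = s[1] * K.G_CAL * d * f * fca * (v - 65.0)
    out["Ito"] = s[2] * K.G_TO * oa ** 3 * oi * (v - ek)
    gkur = 0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0))
    out["IKur"] = s[3] * gkur * ua ** 3 * ui * (v - ek)
    out["IKr"] = s[4] * K.G_KR * xr * (v - ek) / (1.0 + math.exp((v + 15.0) / 22.4))
    out["IKs"] = s[5] * K.G_KS * xs ** 2 * (v - ek)
    out["IK1"] = s[6] * K.G_K1 * (v - ek) / (1.0 + math.exp(0.07 * (v + 80.0)))
    kachf = 0.0517 + 0.4516 / (1.0 + math.exp((v + 59.53) / 17.18))
    out["IKACh"] = s[7] * ach_prefactor(ach_uM) * kachf * (v - ek)
    expg = math.exp(0.35 * K.FRT * v)
    expg1 = math.exp(-0.65 * K.FRT * v)
    out["INaCa"] = (
        s[8] * K.I_NACA_MAX
        * (expg * nai ** 3 * K.CAO - expg1 * K.NAO ** 3 * cai)
        / ((87.5 ** 3 + K.NAO ** 3) * (1.38 + K.CAO) * (1.0 + 0.1 * expg1))
    )
    fnak = 1.0 / (
        1.0 + 0.1245 * math.exp(-0.1 * K.FRT * v)
        + 0.0365 * K.SIGMA_NAK * math.exp(-K.FRT * v)
    )
    out["INaK"] = s[9] * K.I_NAK_MAX * fnak / (1.0 + (10.0 / nai) ** 1.5) * (K.KO / (K.KO + 1.5))
    out["IbNa"] = s[10] * K.G_B_NA * (v - ena)
    out["IbCa"] = s[11] * K.G_B_CA * (v - eca)
    out["IpCa"] = s[12] * K.I_PCA_MAX * cai / (0.0005 + cai)
    out["I_ion"] = sum(out[c] for c in CHANNELS)
    return out


# ---------------------------------------------------------------------------
# integration helpers
# ---------------------------------------------------------------------------

_TABLE_CACHE: dict[float, np.ndarray] = {}


def rate_table(dt: float) -> np.ndarray:
    """dt-specific voltage lookup table (cached)."""
    tab = _TABLE_CACHE.get(dt)
    if tab is None:
        tab = K.make_rate_table(dt)
        _TABLE_CACHE[dt] = tab
    return tab


def _check_dt(dt: float) -> None:
    if not (0.0 < dt <= DT_MAX):
        raise ModelError(f"dt={dt} ms outside stability bound (0, {DT_MAX}] ms")


def step_cell(state: MyocyteState, scaling: ConductanceScaling | None = None,
              i_stim: float = 0.0, dt: float = DT_CELL,
              ach_uM: float = 0.0) -> MyocyteState:
    """Advance one cell a single time step.

    ``i_stim`` is a depolarizing stimulus current density in pA/pF
    (positive values depolarize).  Raises :class:`ModelError` for a dt
    outside the declared stability bound or a non-finite state.
    """
    _check_dt(dt)
    state.validate()
    if scaling is None:
        scaling = ConductanceScaling.unit()
    states = state.to_vector().reshape(1, -1).copy()
    scal = scaling.factors.reshape(1, -1).copy()
    active = np.ones(1, dtype=np.bool_)
    iion = np.empty(1)
    ena = np.empty(1)
    ek = np.empty(1)
    eca = np.empty(1)
    K.refresh_nernst(states, active, ena, ek, eca)
    tab = rate_table(dt)
    vprev = states[0, 0]
    K.step_reaction(states, scal, ach_prefactor(ach_uM), tab, dt,
                    math.exp(-dt / K.TAU_FCA), math.exp(-dt / K.TAU_U),
                    ena, ek, eca, active, iion)
    states[0, 0] = vprev - dt * (iion[0] - i_stim)
    if not np.isfinite(states[0, 0]):
        raise ModelError("NaN/Inf emerged during step (step index 0)")
    return MyocyteState.from_vector(states[0])


def simulate_cell(scaling: ConductanceScaling | None = None,
                  t_end_ms: float = 1000.0,
                  dt: float = DT_CELL,
                  stim_times_ms: Sequence[float] = (),
                  stim_duration_ms: float = 2.0,
                  stim_amplitude: float = 20.0,
                  ach_uM: float = 0.0,
                  record_dt_ms: float = 0.1,
                  initial: MyocyteState | None = None) -> tuple[np.ndarray, np.ndarray, MyocyteState]:
    """Run a single cell, returning (times_ms, vm_mV, final_state).

    Stimuli are rectangular depolarizing pulses (pA/pF).  The recorded
    trace is sampled every ``record_dt_ms``.
    """
    _check_dt(dt)
    if scaling is None:
        scaling = ConductanceScaling.unit()
    state = initial if initial is not None else MyocyteState.resting()
    state.validate()
    states = state.to_vector().reshape(1, -1).copy()
    scal = scaling.factors.reshape(1, -1).copy()
    active = np.ones(1, dtype=np.bool_)
    n_steps = int(round(t_end_ms / dt))
    rec_every = max(1, int(round(record_dt_ms / dt)))
    n_frames = (n_steps + rec_every - 1) // rec_every
    frames = np.empty((n_frames, 1), dtype=np.float32)
    stim_times = np.asarray(stim_times_ms, dtype=float)
    n_stim = stim_times.shape[0]
    stim_start = stim_times.copy()
    stim_stop = stim_times + stim_duration_ms
    stim_amp = np.full(n_stim, float(stim_amplitude))
    stim_indptr = np.arange(n_stim + 1, dtype=np.int64)
    stim_nodes = np.zeros(n_stim, dtype=np.int64)
    act_times = np.full((1, 512), np.nan)
    act_counts = np.zeros(1, dtype=np.int64)
    empty_i = np.zeros(0, dtype=np.int64)
    empty_f = np.zeros(0, dtype=np.float64)
    lp = np.zeros(2, dtype=np.int64)

    status, step, node = K.integrate(
        states, scal, ach_prefactor(ach_uM), rate_table(dt), dt, n_steps, 0.0,
        1, lp, empty_i, empty_f,
        stim_start, stim_stop, stim_amp, stim_indptr, stim_nodes,
        -40.0, act_times, act_counts,
        frames, rec_every, active, 0.0)
    if status != 0:
        kind = "NaN" if status == 2 else "Vm out of bounds"
        raise ModelError(f"integration aborted ({kind}) at step {step}")
    times = np.arange(n_frames) * rec_every * dt
    return times, frames[:, 0].astype(float), MyocyteState.from_vector(states[0])


# ---------------------------------------------------------------------------
# AP measurement
# ---------------------------------------------------------------------------

def measure_ap(times_ms: np.ndarray, vm_mV: np.ndarray,
               cl_ms: float | None = None,
               threshold_mV: float = -40.0) -> APMetrics:
    """APD90, peak upstroke velocity, amplitude, and resting Vm of the last beat.

    Activation time is the instant of maximal dV/dt on the upstroke; the
    amplitude is peak Vm minus take-off Vm of that beat; APD90 ends where
    Vm first falls below peak − 0.9·amplitude.  Returns an
    :class:`APMetrics` with ``captured=False`` when no beat is detected.
    """
    t = np.asarray(times_ms, dtype=float)
    v = np.asarray(vm_mV, dtype=float)
    if t.shape != v.shape or t.size < 3:
        raise ModelError("trace must contain matching time/vm arrays with >= 3 samples")
    up = np.flatnonzero((v[:-1] < threshold_mV) & (v[1:] >= threshold_mV))
    if up.size == 0:
        return APMetrics.no_ap()
    k = up[-1]  # last beat
    dt = np.diff(t)
    dvdt = np.diff(v) / dt

    # search window for the upstroke around the crossing
    w0 = np.searchsorted(t, t[k] - 5.0)
    w1 = min(v.size - 1, np.searchsorted(t, t[k] + 5.0))
    i_act = w0 + int(np.argmax(dvdt[w0:w1]))
    dvdt_max = float(dvdt[i_act])

    # take-off: minimum Vm over the 50 ms preceding activation (or trace start)
    p0 = np.searchsorted(t, t[i_act] - 50.0)
    v_takeoff = float(np.min(v[p0:i_act + 1])) if i_act > p0 else float(v[i_act])

    seg_end = v.size if cl_ms is None else min(v.size, np.searchsorted(t, t[k] + cl_ms))
    seg = v[i_act:seg_end]
    v_peak = float(np.max(seg))
    amplitude = v_peak - v_takeoff
    if amplitude <= 0:
        return APMetrics.no_ap()
    level = v_peak - 0.9 * amplitude
    i_peak = i_act + int(np.argmax(seg))
    below = np.flatnonzero(v[i_peak:seg_end] <= level)
    if below.size == 0:
        return APMetrics.no_ap()
    i_r = i_peak + below[0]
    # linear interpolation of the crossing time
    if i_r > 0 and v[i_r - 1] > level:
        frac = (v[i_r - 1] - level) / (v[i_r - 1] - v[i_r])
        t_repol = t[i_r - 1] + frac * (t[i_r] - t[i_r - 1])
    else:
        t_repol = t[i_r]
    apd90 = float(t_repol - t[i_act])
    return APMetrics(captured=True, apd90_ms=apd90, dvdt_max_Vps=dvdt_max,
                     amplitude_mV=amplitude, resting_mV=v_takeoff)


def pace_to_steady_state(scaling: ConductanceScaling | None = None,
                         cl_ms: float = 500.0,
                         n_prebeats: int = 20,
                         n_measure_beats: int = 1,
                         dt: float = DT_CELL,
                         ach_uM: float = 0.0,
                         stim_amplitude: float = 20.0,
                         record_dt_ms: float = 0.1):
    """Pace a cell at fixed cycle length and return the measurement-beat trace.

    Runs ``n_prebeats`` conditioning beats followed by ``n_measure_beats``
    recorded beats; returns (times_ms, vm_mV) of the measurement window
    (time restarts at the first measured stimulus).
    """
    n_total = n_prebeats + n_measure_beats
    stim_times = np.arange(n_total) * cl_ms
    t_end = n_total * cl_ms
    t, v, _ = simulate_cell(scaling=scaling, t_end_ms=t_end, dt=dt,
                            stim_times_ms=stim_times,
                            stim_amplitude=stim_amplitude,
                            ach_uM=ach_uM, record_dt_ms=record_dt_ms)
    t0 = n_prebeats * cl_ms
    sel = t >= t0 - 1e-9
    return t[sel] - t0, v[sel]


def dose_response_cell(drug, concentrations_uM: Sequence[float],
                       cl_ms: float = 500.0,
                       base_scaling: ConductanceScaling | None = None,
                       n_prebeats: int = 20,
                       dt: float = DT_CELL) -> pd.DataFrame:
    """Steady-state AP metrics per drug concentration.

    ``drug`` is a :class:`latwin.pharmacology.DrugSpec`.  Concentrations
    must be sorted ascending.  Rows where the cell loses capture are
    flagged (``captured=False``), never dropped.
    """
    from .pharmacology import hill_blockade, apply_drug

    conc = [float(c) for c in concentrations_uM]
    if sorted(conc) != conc:
        raise ModelError("concentrations must be sorted ascending")
    if base_scaling is None:
        base_scaling = ConductanceScaling.unit()
    rows = []
    for c in conc:
        scal = apply_drug(hill_blockade(drug, c), base_scaling)
        t, v = pace_to_steady_state(scal, cl_ms=cl_ms, n_prebeats=n_prebeats, dt=dt)
        m = measure_ap(t, v, cl_ms=cl_ms)
        rows.append({
            "concentration_uM": c,
            "captured": m.captured,
            "apd90_ms": m.apd90_ms,
            "dvdtmax_Vps": m.dvdt_max_Vps,
            "amplitude_mV": m.amplitude_mV,
            "resting_mV": m.resting_mV,
        })
    return pd.DataFrame(rows)
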
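"""Pacing protocols, virtual AF induction, and rhythm-outcome classification.

Two protocols drive the virtual experiments: constant pacing at a 500 ms
cycle length at the earliest activation site (EAS) for action-potential
measurements, and ramp pacing for AF induction — cycle length stepping
200, 190, ..., 120 ms with a fixed number of beats per cycle length
(8 beats/CL spans exactly 11.52 s, since the nine CLs sum to 1440 ms).

After the observation window, the rhythm is classified:

  - ``termination`` — no activation signal in the final detection window
    (default 500 ms) of the observation;
  - ``AT`` — sustained activation whose pooled cycle lengths are regular
    (coefficient of variation below threshold) with a dominant CL above
    120 ms;
  - ``AF`` — sustained irregular activation otherwise.

A virtual drug test runs induction at each dose preset; *Effective* means
AF termination at at least one therapeutic dose (low or high), otherwise
*Ineffective*.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .myocyte import ModelError
from .tissue import (DT_TISSUE, SimulationTrace, StimulusEvent, TissueGrid,
                     build_scaling_field, run)

RAMP_CLS_MS = tuple(range(200, 110, -10))  # 200, 190, ..., 120
RAMP_BEATS_PER_CL = 8
CONSTANT_CL_MS = 500.0


@dataclasses.dataclass(frozen=True)
class PacingProtocol:
    """A pacing schedule on a site node set.

    ``kind='constant'`` paces at ``cl_ms`` for ``n_beats``; ``kind='ramp'``
    delivers ``beats_per_cl`` beats at each CL of ``ramp_cls_ms``.
    """

    kind: str
    site: np.ndarray
    cl_ms: float = CONSTANT_CL_MS
    n_beats: int = 10
    ramp_cls_ms: Sequence[float] = RAMP_CLS_MS
    beats_per_cl: int = RAMP_BEATS_PER_CL
    stim_duration_ms: float = 2.0
    stim_amplitude: float = 40.0

    def __post_init__(self):
        if self.kind not in ("constant", "ramp"):
            raise ModelError(f"unknown protocol kind {self.kind!r}")
        object.__setattr__(self, "site",
                           np.asarray(self.site, dtype=np.int64).ravel())
        if self.site.size == 0:
            raise ModelError("protocol needs a pacing site")

    def stimulus_times_ms(self) -> np.ndarray:
        if self.kind == "constant":
            return np.arange(self.n_beats) * self.cl_ms
        times = []
        t = 0.0
        for cl in self.ramp_cls_ms:
            for _ in range(self.beats_per_cl):
                times.append(t)
                t += cl
        return np.asarray(times)

    @property
    def span_ms(self) -> float:
        if self.kind == "constant":
            return self.n_beats * self.cl_ms
        return float(self.beats_per_cl * sum(self.ramp_cls_ms))

    def events(self) -> list[StimulusEvent]:
        return [StimulusEvent(self.site, t, self.stim_duration_ms,
                              self.stim_amplitude)
                for t in self.stimulus_times_ms()]


@dataclasses.dataclass(frozen=True)
class RhythmOutcome:
    """Classified rhythm at the end of the observation window."""

    label: str  # "AF" | "AT" | "termination"
    t_termination_ms: float | None = None
    mean_cl_ms: float | None = None
    cl_cv: float | None = None

    @property
    def terminated(self) -> bool:
        return self.label == "termination"


@dataclasses.dataclass(frozen=True)
class VirtualDrugVerdict:
    """Per-dose outcomes and the Effective/Ineffective grouping."""

    outcomes: Mapping[str, RhythmOutcome]
    group: str  # "Effective" | "Ineffective"
    calibration_ok: bool = True


def find_eas(trace: SimulationTrace) -> int:
    """Earliest activation site: node with the earliest recorded activation.

    Ties are broken toward the lowest node index.
    """
    first = np.where(trace.act_counts > 0, trace.act_times[:, 0], np.inf)
    if not np.isfinite(first).any():
        raise ModelError("no activation in trace; cannot locate EAS")
    return int(np.argmin(first))  # argmin takes the lowest index on ties


def diastolic_threshold(grid: TissueGrid, site: np.ndarray,
                        scaling_field: np.ndarray | None = None,
                        dt: float = DT_TISSUE,
                        lo: float = 0.5, hi: float = 128.0) -> float:
    """Minimal 2-ms stimulus amplitude (pA/pF) that captures the tissue.

    Bisection over amplitude; capture means some node outside the
    stimulated set activates within 50 ms.  Used to set protocol stimuli
    at twice diastolic threshold.
    """
    site = np.asarray(site, dtype=np.int64)
    outside = np.ones(grid.n_nodes, dtype=bool)
    outside[site] = False
    outside &= grid.active

    def captures(amp: float) -> bool:
        tr = run(grid, scaling_field, [StimulusEvent(site, 2.0, 2.0, amp)],
                 t_end_ms=52.0, dt=dt, record_dt_ms=1e9, max_act=4)
        return bool(np.any(tr.act_counts[outside] > 0))

    if not captures(hi):
        raise ModelError(f"no capture even at {hi} pA/pF")
    if captures(lo):
        return lo
    for _ in range(10):
        mid = np.sqrt(lo * hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def run_protocol(grid: TissueGrid, scaling_field: np.ndarray | None,
                 protocol: PacingProtocol, observe_until_ms: float,
                 dt: float = DT_TISSUE, record_dt_ms: float = 2.0,
                 max_act: int = 256, ach_uM: float = 0.0,
                 quiet_stop_ms: float = 1000.0) -> SimulationTrace:
    """Deliver a pacing protocol and record until ``observe_until_ms``.

    Once pacing has ended and the tissue has been quiescent for
    ``quiet_stop_ms`` the solver finishes the window at rest (exact for
    the autonomous system; terminated runs cost only their active span).
    """
    if observe_until_ms < protocol.span_ms:
        raise ModelError(
            f"observe_until ({observe_until_ms} ms) shorter than the pacing "
            f"span ({protocol.span_ms} ms)")
    return run(grid, scaling_field, protocol.events(),
               t_end_ms=observe_until_ms, dt=dt, record_dt_ms=record_dt_ms,
               max_act=max_act, ach_uM=ach_uM, quiet_stop_ms=quiet_stop_ms)


def classify_rhythm(trace: SimulationTrace, window_end_ms: float | None = None,
                    detection_window_ms: float = 500.0,
                    analysis_window_ms: float = 3000.0,
                    at_cv_threshold: float = 0.1,
                    at_min_cl_ms: float = 120.0) -> RhythmOutcome:
    """Classify the rhythm at the end of the observation window.

    Termination: no node crosses the activation threshold during the final
    ``detection_window_ms``.  Otherwise, cycle lengths pooled over the
    final ``analysis_window_ms`` decide AT (regular: CV below threshold
    and dominant CL above ``at_min_cl_ms``) versus AF.
    """
    end = trace.t_end_ms if window_end_ms is None else float(window_end_ms)
    if end > trace.t_end_ms + 1e-9:
        raise ModelError(
            f"trace ends at {trace.t_end_ms} ms, before the requested "
            f"window end {end} ms")
    all_acts = trace.act_times[np.isfinite(trace.act_times)]
    final = all_acts[(all_acts >= end - detection_window_ms) & (all_acts < end)]
    if final.size == 0:
        before = all_acts[all_acts < end - detection_window_ms]
        t_term = float(before.max()) if before.size else 0.0
        return RhythmOutcome("termination", t_termination_ms=t_term)

    t0 = end - analysis_window_ms
    cls = []
    for k in range(trace.n_nodes):
        a = trace.node_activations(k)
        a = a[(a >= t0) & (a < end)]
        if a.size >= 2:
            cls.append(np.diff(a))
    if not cls:
        return RhythmOutcome("AF")
    pooled = np.concatenate(cls)
    mean_cl = float(np.mean(pooled))
    cv = float(np.std(pooled) / mean_cl) if mean_cl > 0 else np.inf
    if cv < at_cv_threshold and np.median(pooled) > at_min_cl_ms:
        return RhythmOutcome("AT", mean_cl_ms=mean_cl, cl_cv=cv)
    return RhythmOutcome("AF", mean_cl_ms=mean_cl, cl_cv=cv)


def virtual_drug_test(grid: TissueGrid, drug, eas_node: int,
                      remodeling=None,
                      dose_presets: Mapping[str, float] | None = None,
                      observe_until_ms: float = 10_000.0,
                      beats_per_cl: int = RAMP_BEATS_PER_CL,
                      site_radius_mm: float = 1.0,
                      stim_amplitude: float = 40.0,
                      dt: float = DT_TISSUE,
                      record_dt_ms: float = 2.0,
                      ach_uM: float = 0.0,
                      baseline_trace: SimulationTrace | None = None,
                      classify_kwargs: Mapping | None = None) -> VirtualDrugVerdict:
    """Run ramp-pacing induction at each dose and apply the grouping rule.

    The baseline (zero-dose) model must sustain AF — a terminating
    baseline is flagged as a calibration failure and yields no verdict
    group.  *Effective* means termination at >= 1 therapeutic dose.
    A pre-computed drug-free trace (e.g. from calibration) can be passed
    to avoid re-running the baseline.
    """
    from .myocyte import ConductanceScaling
    from .pharmacology import DOSE_PRESETS, THERAPEUTIC_DOSES, hill_blockade

    if remodeling is None:
        remodeling = ConductanceScaling.af_remodeling()
    doses = dict(dose_presets if dose_presets is not None else DOSE_PRESETS)
    mesh = grid.substrate.mesh
    pts = mesh.points
    cx, cy = pts[eas_node, 0], pts[eas_node, 1]
    site = grid.disc_nodes(cx, cy, site_radius_mm)
    protocol = PacingProtocol("ramp", site, beats_per_cl=beats_per_cl,
                              stim_amplitude=stim_amplitude)
    ckw = dict(classify_kwargs or {})

    outcomes: dict[str, RhythmOutcome] = {}
    for label in sorted(doses, key=lambda k: doses[k]):
        conc = doses[label]
        if conc == 0.0 and baseline_trace is not None:
            trace = baseline_trace
        else:
            blockade = hill_blockade(drug, conc)
            field = build_scaling_field(grid.substrate, remodeling, blockade)
            trace = run_protocol(grid, field, protocol, observe_until_ms,
                                 dt=dt, record_dt_ms=record_dt_ms,
                                 ach_uM=ach_uM)
        outcomes[label] = classify_rhythm(trace, observe_until_ms, **ckw)

    calibration_ok = not outcomes.get("none", RhythmOutcome("AF")).terminated
    if not calibration_ok:
        return VirtualDrugVerdict(outcomes, group="calibration_failure",
                                  calibration_ok=False)
    effective = any(outcomes[d].terminated for d in THERAPEUTIC_DOSES
                    if d in outcomes)
    return VirtualDrugVerdict(
        outcomes, group="Effective" if effective else "Ineffective")


def grouping_rule(outcome_low: RhythmOutcome, outcome_high: RhythmOutcome) -> str:
    """Pure grouping rule on the two therapeutic-dose outcomes."""
    return ("Effective"
            if outcome_low.terminated or outcome_high.terminated
            else "Ineffective")
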
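"""Stimulation protocols, trace simulation, and trace-level measurements.

A :class:`Protocol` is an ordered list of piecewise-constant ligand segments
(solution exchange is treated as instantaneous).  :func:`simulate` propagates
the kinetic scheme across the segments and returns a :class:`Trace`; the
measurement helpers implement the peak / steady-state / inhibition-fraction /
recovery-from-desensitization readouts used on the experimental recordings,
including their exclusion rules (85% recovery from block; normalized peaks
capped at 1.2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import (CurrentParams, KineticScheme, LigandContext, RateSet,
                         _occupancies_from_generator, rate_matrix,
                         steady_state)

__all__ = [
    "Segment", "Protocol", "Trace", "InhibitionTable", "TraceRejected",
    "make_ic50_protocol", "make_rfd_protocol", "make_agonist_step_protocol",
    "simulate", "measure_peak", "measure_steady_state", "measure_baseline",
    "inhibition_table", "iss_over_ipeak", "rfd_peak_series",
    "normalize_to_steady_state", "write_trace", "read_trace",
]

DEFAULT_RFD_INTERVALS_S = (200.0, 100.0, 50.0, 20.0, 10.0, 5.0, 2.0, 1.0)


class TraceRejected(ValueError):
    """Raised when a trace fails one of the published exclusion criteria."""


@dataclass(frozen=True)
class Segment:
    duration_s: float
    ligands: LigandContext
    role: str = ""   # optional tag: baseline/agonist/blocker/interval/application/recovery

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("segment duration must be > 0")


@dataclass
class Protocol:
    segments: list[Segment]
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol must contain at least one segment")
        ca = {s.ligands.ca_i_uM for s in self.segments}
        if len(ca) != 1:
            raise ValueError("ca_i_uM must be identical across all segments "
                             "(pipette-clamped)")

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    @property
    def ca_i_uM(self) -> float:
        return self.segments[0].ligands.ca_i_uM

    def segment_bounds_s(self) -> np.ndarray:
        """Cumulative segment edges: [0, t1, t2, ..., T]."""
        return np.concatenate(([0.0], np.cumsum([s.duration_s for s in self.segments])))

    def to_json_dict(self) -> dict:
        return {
            "label": self.label,
            "meta": self.meta,
            "segments": [
                {"duration_s": s.duration_s, "glu_uM": s.ligands.glu_uM,
                 "mem_uM": s.ligands.mem_uM, "ca_i_uM": s.ligands.ca_i_uM,
                 "role": s.role}
                for s in self.segments
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "Protocol":
        segs = [Segment(s["duration_s"],
                        LigandContext(s["glu_uM"], s["mem_uM"], s["ca_i_uM"]),
                        s.get("role", ""))
                for s in d["segments"]]
        return cls(segments=segs, label=d.get("label", ""), meta=dict(d.get("meta", {})))


@dataclass
class Trace:
    time_s: np.ndarray
    current_pA: np.ndarray
    protocol: Protocol
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.time_s.shape != self.current_pA.shape:
            raise ValueError("time and current must have the same length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def segment_mask(self, index: int) -> np.ndarray:
        bounds = self.protocol.segment_bounds_s()
        t0, t1 = bounds[index], bounds[index + 1]
        last = index == len(self.protocol.segments) - 1
        return (self.time_s >= t0 - 1e-12) & (
            self.time_s <= t1 + 1e-12 if last else self.time_s < t1 - 1e-12)


@dataclass
class InhibitionTable:
    """Concentration-inhibition rows: fractional steady-state current
    I_Blocker / I_Glu at each blocker concentration."""

    blocker_uM: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.blocker_uM = np.asarray(self.blocker_uM, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if np.any(np.diff(self.blocker_uM) <= 0):
            raise ValueError("blocker concentrations must be strictly increasing")
        if np.any(self.fraction <= 0) or np.any(self.fraction > 1.2):
            raise ValueError("fractional currents must lie in (0, 1.2]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"blocker_uM": self.blocker_uM, "fraction": self.fraction})


def make_agonist_step_protocol(glu_uM: float = 1000.0, app_s: float = 15.0,
                               ca_i_uM: float = 0.0, baseline_s: float = 2.0,
                               wash_s: float = 5.0, mem_uM: float = 0.0) -> Protocol:
    """Baseline, single agonist application, wash — the desensitization-
    measurement stimulus."""
    segs = [
        Segment(baseline_s, LigandContext(0.0, mem_uM, ca_i_uM), "baseline"),
        Segment(app_s, LigandContext(glu_uM, mem_uM, ca_i_uM), "agonist"),
        Segment(wash_s, LigandContext(0.0, mem_uM, ca_i_uM), "wash"),
    ]
    return Protocol(segs, label="agonist_step",
                    meta={"glu_uM": glu_uM, "app_s": app_s})


def make_ic50_protocol(glu_uM: float = 1000.0,
                       blocker_concs_uM: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0, 50.0),
                       app_s: float = 15.0, ca_i_uM: float = 0.0,
                       baseline_s: float = 2.0) -> Protocol:
    """Concentration-inhibition stimulus: agonist to steady state, then
    sequentially increasing blocker concentrations in constant agonist,
    then agonist alone to allow recovery from block."""
    concs = tuple(float(c) for c in blocker_concs_uM)
    if not concs:
        raise ValueError("blocker_concs_uM must be non-empty")
    if any(np.diff(concs) <= 0):
        raise ValueError("blocker concentrations must be strictly increasing")
    segs = [
        Segment(baseline_s, LigandContext(0.0, 0.0, ca_i_uM), "baseline"),
        Segment(app_s, LigandContext(glu_uM, 0.0, ca_i_uM), "agonist"),
    ]
    for c in concs:
        segs.append(Segment(app_s, LigandContext(glu_uM, c, ca_i_uM), "blocker"))
    segs.append(Segment(app_s, LigandContext(glu_uM, 0.0, ca_i_uM), "recovery"))
    return Protocol(segs, label="ic50",
                    meta={"blocker_concs_uM": list(concs), "app_s": app_s})


def make_rfd_protocol(intervals_s: tuple[float, ...] = DEFAULT_RFD_INTERVALS_S,
                      app_s: float = 15.0, glu_uM: float = 1000.0,
                      mem_uM: float = 0.0, ca_i_uM: float = 0.0,
                      baseline_s: float = 2.0) -> Protocol:
    """Recovery-from-desensitization stimulus: a conditioning agonist
    application, then agonist-free intervals of varying duration each followed
    by a test application.  Blocker, when present, is co-applied throughout."""
    intervals = tuple(float(x) for x in intervals_s)
    if not intervals:
        raise ValueError("intervals_s must be non-empty")
    rest = LigandContext(0.0, mem_uM, ca_i_uM)
    stim = LigandContext(glu_uM, mem_uM, ca_i_uM)
    segs = [Segment(baseline_s, rest, "baseline"),
            Segment(app_s, stim, "conditioning")]
    for iv in intervals:
        segs.append(Segment(iv, rest, "interval"))
        segs.append(Segment(app_s, stim, "application"))
    return Protocol(segs, label="rfd",
                    meta={"intervals_s": list(intervals), "app_s": app_s,
                          "mem_uM": mem_uM})


def simulate(scheme: KineticScheme, rates: RateSet, protocol: Protocol,
             current_params: CurrentParams = CurrentParams(),
             dt_s: float = 1e-3) -> Trace:
    """Simulate a protocol by piecewise matrix-exponential propagation.

    Initial occupancy is the steady state of the first segment's ligand
    context (receptors pre-equilibrate with the pipette solution before the
    first application).  Returns the current trace on a uniform ``dt_s`` grid.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    bounds = protocol.segment_bounds_s()
    total = bounds[-1]
    n = int(round(total / dt_s))
    times = np.arange(n + 1) * dt_s

    p = steady_state(scheme, rates, protocol.segments[0].ligands)
    u = np.zeros(scheme.n_states)
    u[scheme.conducting_indices] = 1.0  # project onto conducting occupancy
    po = np.empty(times.size)
    for k, seg in enumerate(protocol.segments):
        t0, t1 = bounds[k], bounds[k + 1]
        last = k == len(protocol.segments) - 1
        if last:
            mask = (times >= t0 - 1e-12)
        else:
            mask = (times >= t0 - 1e-12) & (times < t1 - dt_s * 1e-6)
        seg_times = times[mask] - t0
        Q = rate_matrix(scheme, rates, seg.ligands)
        if seg_times.size:
            if seg_times[0] < dt_s * 1e-6:
                rest = _occupancies_from_generator(Q, p, seg_times[1:], project=u) \
                    if seg_times.size > 1 else np.empty(0)
                po[mask] = np.concatenate(([p @ u], rest))
            else:
                po[mask] = _occupancies_from_generator(Q, p, seg_times, project=u)
        # advance exactly to the segment end
        p = p @ _segment_propagator(Q, seg.duration_s)
        p[p < 0] = 0.0

    cp = current_params
    cur = cp.N * po * cp.gamma_pS * (cp.Vm_mV - cp.Vrev_mV) * 1e-3
    return Trace(times, cur, protocol, meta={"dt_s": dt_s})


def _segment_propagator(Q: np.ndarray, duration: float) -> np.ndarray:
    import scipy.linalg
    return scipy.linalg.expm(Q * duration)


def _segment_indices(trace: Trace, segment: int) -> np.ndarray:
    idx = np.nonzero(trace.segment_mask(segment))[0]
    if idx.size == 0:
        raise ValueError(f"segment {segment} contains no samples")
    return idx


def measure_baseline(trace: Trace, last_s: float = 1.0) -> float:
    """Mean current over the final ``last_s`` of the first agonist-free,
    blocker-free segment; 0.0 if the protocol has no such segment."""
    for i, seg in enumerate(trace.protocol.segments):
        if seg.ligands.glu_uM == 0 and seg.ligands.mem_uM == 0:
            idx = _segment_indices(trace, i)
            n = max(1, min(idx.size, int(round(last_s / trace.dt_s))))
            return float(trace.current_pA[idx[-n:]].mean())
    return 0.0


def measure_peak(trace: Trace, segment: int, window_ms: float = 30.0,
                 search_s: float = 2.0, baseline: float | None = None,
                 center_s: float | None = None) -> float:
    """Mean current over a ``window_ms`` window centered on the extremum
    (most negative, inward current) within the first ``search_s`` of the
    segment; window truncated to the segment when it would overrun.
    ``center_s`` (relative to segment start) pins the window instead of
    searching — useful when the peak time is known independently."""
    if baseline is None:
        baseline = measure_baseline(trace)
    idx = _segment_indices(trace, segment)
    dt = trace.dt_s
    if center_s is not None:
        k_peak = min(idx.size - 1, max(0, int(round(center_s / dt))))
    else:
        n_search = max(1, min(idx.size, int(round(search_s / dt))))
        seg_cur = trace.current_pA[idx[:n_search]] - baseline
        # extremum by magnitude: most negative for raw inward currents, most
        # positive for normalized (sign-flipped) traces
        k_peak = int(np.argmax(np.abs(seg_cur)))
    half = max(0, int(round(window_ms * 1e-3 / dt / 2)))
    lo = max(0, k_peak - half)
    hi = min(idx.size, k_peak + half + 1)
    window = trace.current_pA[idx[lo:hi]] - baseline
    return float(window.mean())


def measure_steady_state(trace: Trace, segment: int, last_s: float = 1.0,
                         baseline: float | None = None) -> float:
    """Baseline-subtracted mean current over the final ``last_s`` of the
    segment."""
    seg = trace.protocol.segments[segment]
    if seg.duration_s < last_s:
        raise ValueError(f"segment {segment} shorter than {last_s} s")
    if baseline is None:
        baseline = measure_baseline(trace)
    idx = _segment_indices(trace, segment)
    n = max(1, int(round(last_s / trace.dt_s)))
    return float(trace.current_pA[idx[-n:]].mean() - baseline)


def inhibition_table(trace: Trace, min_recovery: float = 0.85) -> InhibitionTable:
    """Fractional steady-state currents from a concentration-inhibition trace.

    I_Glu is the average of the steady states of the pre-blocker agonist
    application and the post-blocker recovery application.  Traces whose
    recovery falls below ``min_recovery`` of the pre-blocker steady state are
    rejected.
    """
    proto = trace.protocol
    roles = [s.role for s in proto.segments]
    try:
        i_ag = roles.index("agonist")
        i_rec = len(roles) - 1 - roles[::-1].index("recovery")
    except ValueError:
        raise ValueError("inhibition_table requires an ic50-style protocol "
                         "(agonist and recovery segments)") from None
    baseline = measure_baseline(trace)
    ss_pre = measure_steady_state(trace, i_ag, baseline=baseline)
    ss_rec = measure_steady_state(trace, i_rec, baseline=baseline)
    if abs(ss_rec) < min_recovery * abs(ss_pre):
        raise TraceRejected(
            f"recovery {abs(ss_rec):.3g} pA is below {min_recovery:.0%} of the "
            f"pre-blocker steady state {abs(ss_pre):.3g} pA")
    i_glu = 0.5 * (ss_pre + ss_rec)
    concs, fracs = [], []
    for i, seg in enumerate(proto.segments):
        if seg.role == "blocker":
            concs.append(seg.ligands.mem_uM)
            fracs.append(measure_steady_state(trace, i, baseline=baseline) / i_glu)
    return InhibitionTable(np.array(concs), np.array(fracs))


def iss_over_ipeak(trace: Trace, segment: int | None = None) -> float:
    """Desensitization extent: steady-state over peak current of one agonist
    application."""
    if segment is None:
        segment = next(i for i, s in enumerate(trace.protocol.segments)
                       if s.ligands.glu_uM > 0)
    baseline = measure_baseline(trace)
    peak = measure_peak(trace, segment, baseline=baseline)
    if peak == 0:
        raise ZeroDivisionError("zero peak current")
    return measure_steady_state(trace, segment, baseline=baseline) / peak


def rfd_peak_series(trace: Trace, reference_interval_s: float = 200.0,
                    max_normalized: float = 1.2) -> pd.DataFrame:
    """Normalized test-application peaks of a recovery-from-desensitization
    trace, one row per interapplication interval.

    Peaks are normalized to the peak following the reference (200-s) interval;
    the trace is excluded when any normalized peak exceeds ``max_normalized``.
    """
    proto = trace.protocol
    baseline = measure_baseline(trace)
    rows = []
    for i, seg in enumerate(proto.segments):
        if seg.role == "application" and i > 0 and proto.segments[i - 1].role == "interval":
            interval = proto.segments[i - 1].duration_s
            rows.append((interval, measure_peak(trace, i, baseline=baseline)))
    if not rows:
        raise ValueError("rfd_peak_series requires an RfD-style protocol")
    intervals = np.array([r[0] for r in rows])
    peaks = np.array([r[1] for r in rows])
    ref = np.isclose(intervals, reference_interval_s)
    if not ref.any():
        raise ValueError(f"missing {reference_interval_s:g}-s reference interval")
    norm = peaks / peaks[ref][0]
    if np.any(norm > max_normalized):
        raise TraceRejected(
            f"normalized peak {norm.max():.3g} exceeds {max_normalized:g}")
    return pd.DataFrame({"interval_s": intervals, "normalized_peak": norm})


def normalize_to_steady_state(trace: Trace, segment: int | None = None,
                              last_s: float = 1.0) -> Trace:
    """Divide the current by the trace's own reference steady state.

    The reference is the first agonist-only (blocker-free) application, so a
    normalized trace has steady-state value 1 there and positive sign.
    """
    proto = trace.protocol
    if segment is None:
        segment = next(i for i, s in enumerate(proto.segments)
                       if s.ligands.glu_uM > 0 and s.ligands.mem_uM == 0)
    baseline = measure_baseline(trace)
    ss = measure_steady_state(trace, segment, last_s=last_s, baseline=baseline)
    if ss == 0:
        raise ZeroDivisionError("zero reference steady state")
    meta = dict(trace.meta)
    meta["normalized"] = True
    return Trace(trace.time_s.copy(), (trace.current_pA - baseline) / ss,
                 proto, meta)


def write_trace(trace: Trace, csv_path: str | Path) -> None:
    """Write a trace as time/current CSV plus a JSON protocol sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.time_s, "current_pA": trace.current_pA}) \
        .to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    payload = {"protocol": trace.protocol.to_json_dict(), "meta": trace.meta}
    sidecar.write_text(json.dumps(payload, indent=1))


def read_trace(csv_path: str | Path) -> Trace:
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing protocol sidecar {sidecar}")
    df = pd.read_csv(csv_path)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ValueError(f"{csv_path}: missing required column {col!r}")
    payload = json.loads(sidecar.read_text())
    proto = Protocol.from_json_dict(payload["protocol"])
    return Trace(df["time_s"].to_numpy(), df["current_pA"].to_numpy(),
                 proto, dict(payload.get("meta", {})))
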
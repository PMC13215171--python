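"""Synthetic whole-cell data emulating the recorded datasets.

Generates every input the analysis pipeline consumes without any external
recordings: noisy per-cell current traces simulated from a ground-truth rate
set (lognormal cell-to-cell amplitude spread, additive Gaussian current noise,
optional linear baseline drift), the per-trace normalization and
per-condition averaging applied before model fitting, and potentiometric
calibration series for the Ca2+-buffer electrode model.  All generators are
pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import CurrentParams, RateSet, build_scheme
from .protocols import (Protocol, Trace, make_agonist_step_protocol,
                        make_ic50_protocol, normalize_to_steady_state,
                        read_trace, simulate, write_trace)
from .lom import (BufferModel, CalibrationSeries, ElectrodeModel,
                  potential_from_free, total_from_free)

__all__ = [
    "SyntheticSpec", "generate_traces", "normalize_and_average",
    "generate_electrode_series", "generate_fit_datasets",
    "read_trace", "write_trace",
]


@dataclass
class SyntheticSpec:
    """Ground truth and noise structure for a batch of synthetic cells.

    ``noise_sd_frac`` scales additive Gaussian noise by the absolute peak of
    the clean trace (the recordings were low-pass filtered and densely
    sampled, so iid Gaussian noise on the working grid is an adequate model
    for sum-of-squares fitting of second-scale kinetics).
    """

    rates: RateSet
    protocol: Protocol
    n_cells: int = 5
    noise_sd_frac: float = 0.02
    amplitude_sigma: float = 0.3      # lognormal sd of per-cell scale
    baseline_drift_pA_per_s: float = 0.0
    N: float = 100.0                  # mean receptor-count scale
    dt_s: float = 1e-3
    seed: int = 0
    statistical_factors: bool = True

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")


def generate_traces(spec: SyntheticSpec) -> list[Trace]:
    """Simulate one clean trace from the ground truth, then emit per-cell
    noisy copies: clean * lognormal amplitude + Gaussian noise + drift."""
    rng = np.random.default_rng(spec.seed)
    scheme = build_scheme(spec.rates, statistical_factors=spec.statistical_factors)
    clean = simulate(scheme, spec.rates, spec.protocol,
                     CurrentParams(N=spec.N), dt_s=spec.dt_s)
    peak = np.abs(clean.current_pA).max()
    traces = []
    for cell in range(spec.n_cells):
        amp = np.exp(rng.normal(0.0, spec.amplitude_sigma)) if spec.amplitude_sigma > 0 else 1.0
        noise = rng.normal(0.0, spec.noise_sd_frac * peak * amp,
                           size=clean.current_pA.size) if spec.noise_sd_frac > 0 else 0.0
        drift = spec.baseline_drift_pA_per_s * clean.time_s
        cur = clean.current_pA * amp + noise + drift
        traces.append(Trace(clean.time_s.copy(), cur, spec.protocol,
                            meta={"cell": cell, "seed": spec.seed,
                                  "amplitude": float(amp)}))
    return traces


def normalize_and_average(traces: list[Trace]) -> Trace:
    """Normalize each trace to its own reference steady state, then average
    pointwise across cells (the pre-fitting treatment of the recordings)."""
    if not traces:
        raise ValueError("need at least one trace")
    ref = traces[0]
    for t in traces[1:]:
        if t.time_s.shape != ref.time_s.shape or \
                not np.allclose(t.time_s, ref.time_s, atol=1e-9):
            raise ValueError("traces must share a common protocol/time grid")
        if t.protocol.to_json_dict() != ref.protocol.to_json_dict():
            raise ValueError("traces must share a common protocol")
    normed = np.vstack([normalize_to_steady_state(t).current_pA for t in traces])
    return Trace(ref.time_s.copy(), normed.mean(axis=0), ref.protocol,
                 meta={"normalized": True, "n_cells": len(traces)})


def generate_electrode_series(electrode: ElectrodeModel, buffer: BufferModel,
                              noise_mV: float = 0.1, seed: int = 0,
                              n_calibration: int = 7, n_buffered: int = 10,
                              calibration_range_M: tuple[float, float] = (0.5e-3, 10e-3),
                              buffered_free_decades: float = 1.5) -> CalibrationSeries:
    """Synthetic potentiometric series matching the published solution
    design: buffer-free calibration solutions spanning 0.5-10 mM total Ca,
    and buffered solutions whose free Ca spans ``buffered_free_decades``
    decades around the buffer Kd."""
    rng = np.random.default_rng(seed)
    cal_T = np.geomspace(*calibration_range_M, n_calibration)
    cal_dE = potential_from_free(cal_T, electrode) \
        + rng.normal(0.0, noise_mV, n_calibration)
    free = np.geomspace(buffer.Kd_M * 10 ** (-buffered_free_decades),
                        buffer.Kd_M * 10 ** buffered_free_decades, n_buffered)
    buf_T = total_from_free(free, buffer)
    buf_dE = potential_from_free(free, electrode) \
        + rng.normal(0.0, noise_mV, n_buffered)
    return CalibrationSeries(cal_T, cal_dE, buf_T, buf_dE)


def generate_fit_datasets(rates: RateSet | None = None,
                          noise_sd_frac: float = 0.0, n_cells: int = 1,
                          seed: int = 0, dt_s: float = 1e-3,
                          app_s: float = 15.0,
                          blocker_concs_uM: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0, 50.0),
                          ca_high_uM: float = 10.0) -> dict[int, Trace]:
    """The four averaged, normalized datasets the staged fit consumes:
    agonist step and concentration-inhibition protocol, each at nominally
    Ca-free and at 10 uM [Ca2+]i."""
    if rates is None:
        rates = RateSet()
    protos = {
        1: make_agonist_step_protocol(ca_i_uM=0.0, app_s=app_s),
        2: make_ic50_protocol(ca_i_uM=0.0, app_s=app_s,
                              blocker_concs_uM=blocker_concs_uM),
        3: make_agonist_step_protocol(ca_i_uM=ca_high_uM, app_s=app_s),
        4: make_ic50_protocol(ca_i_uM=ca_high_uM, app_s=app_s,
                              blocker_concs_uM=blocker_concs_uM),
    }
    out = {}
    for step_id, proto in protos.items():
        spec = SyntheticSpec(rates=rates, protocol=proto, n_cells=n_cells,
                             noise_sd_frac=noise_sd_frac,
                             amplitude_sigma=0.3 if n_cells > 1 else 0.0,
                             dt_s=dt_s, seed=seed * 10 + step_id)
        out[step_id] = normalize_and_average(generate_traces(spec))
    return out
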
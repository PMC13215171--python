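"""Ligand-optimization-method (LOM) calibration of Ca2+ buffers.

Free Ca2+ in a high-capacity buffered solution is read out with a
Ca2+-selective electrode whose response follows a Nikolsky-Eisenman form,

    dE = E0 + s * log10([Ca2+]_F + Sigma),

where ``s`` is the electrode slope (mV per decade), ``Sigma`` a lumped
interference constant describing the low-[Ca2+] floor, and potentials are
referenced to the 10-uM calibration solution.  Single-site buffer binding
links total and free Ca2+,

    [Ca2+]_T = [Ca2+]_F * ([B]_T + [Ca2+]_F + Kd) / ([Ca2+]_F + Kd).

The LOM jointly optimizes (E0, s, Sigma, [B]_T, Kd) against potentials
measured on buffer-free calibration solutions and buffered solutions,
correcting for misreported buffer Kd and hydration-driven overestimates of
[B]_T.  This module works in molar units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = [
    "ElectrodeModel", "BufferModel", "CalibrationSeries", "BufferRecipe",
    "STANDARD_BUFFERS", "free_from_potential", "potential_from_free",
    "total_from_free", "free_from_total", "fit_lom", "recipe",
    "uM_to_M", "M_to_uM",
]


def uM_to_M(x_uM: float) -> float:
    return x_uM * 1e-6


def M_to_uM(x_M: float) -> float:
    return x_M * 1e6


@dataclass(frozen=True)
class ElectrodeModel:
    E0_mV: float
    s_mV_per_decade: float
    sigma_M: float = 0.0
    reference_Ca_T_M: float = 1e-5   # calibration point where dE is zeroed

    def __post_init__(self) -> None:
        if self.s_mV_per_decade <= 0:
            raise ValueError("electrode slope must be > 0")
        if self.sigma_M < 0:
            raise ValueError("interference constant must be >= 0")


@dataclass(frozen=True)
class BufferModel:
    name: str
    Kd_M: float
    BT_M: float

    def __post_init__(self) -> None:
        if self.Kd_M <= 0 or self.BT_M <= 0:
            raise ValueError("Kd and [B]_T must be > 0")


# published Kd values for the three chelators, at 10 mM nominal weight
STANDARD_BUFFERS: dict[str, BufferModel] = {
    "BAPTA": BufferModel("BAPTA", Kd_M=144e-9, BT_M=10e-3),
    "HEDTA": BufferModel("HEDTA", Kd_M=2.24e-6, BT_M=10e-3),
    "NTA": BufferModel("NTA", Kd_M=81.5e-6, BT_M=10e-3),
}


@dataclass
class CalibrationSeries:
    """Potentiometric series: buffer-free calibration rows (constrain E0, s)
    and buffered rows (constrain Sigma, [B]_T, Kd)."""

    calibration_Ca_T_M: np.ndarray
    calibration_dE_mV: np.ndarray
    buffered_Ca_T_M: np.ndarray
    buffered_dE_mV: np.ndarray

    def __post_init__(self) -> None:
        for attr in ("calibration_Ca_T_M", "calibration_dE_mV",
                     "buffered_Ca_T_M", "buffered_dE_mV"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if np.any(self.calibration_Ca_T_M <= 0) or np.any(self.buffered_Ca_T_M <= 0):
            raise ValueError("total Ca concentrations must be > 0")

    def to_frame(self) -> pd.DataFrame:
        cal = pd.DataFrame({"Ca_total_M": self.calibration_Ca_T_M,
                            "delta_E_mV": self.calibration_dE_mV,
                            "buffered": False})
        buf = pd.DataFrame({"Ca_total_M": self.buffered_Ca_T_M,
                            "delta_E_mV": self.buffered_dE_mV,
                            "buffered": True})
        return pd.concat([cal, buf], ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CalibrationSeries":
        cal = df[~df["buffered"].astype(bool)]
        buf = df[df["buffered"].astype(bool)]
        return cls(cal["Ca_total_M"].to_numpy(), cal["delta_E_mV"].to_numpy(),
                   buf["Ca_total_M"].to_numpy(), buf["delta_E_mV"].to_numpy())


@dataclass(frozen=True)
class BufferRecipe:
    buffer: BufferModel
    target_free_M: float
    Ca_total_M: float


def potential_from_free(Ca_free_M, model: ElectrodeModel):
    """Electrode response dE = E0 + s log10([Ca]_F + Sigma), in mV."""
    ca = np.asarray(Ca_free_M, dtype=float)
    if np.any(ca < 0):
        raise ValueError("free Ca must be >= 0")
    arg = ca + model.sigma_M
    if np.any(arg <= 0):
        raise ValueError("Ca_free + Sigma must be > 0")
    out = model.E0_mV + model.s_mV_per_decade * np.log10(arg)
    return float(out) if np.isscalar(Ca_free_M) else out


def free_from_potential(delta_E_mV, model: ElectrodeModel):
    """Invert the electrode response: [Ca]_F = 10^((dE - E0)/s) - Sigma,
    clamped at 0 (a clamp indicates a potential at/below the interference
    floor)."""
    dE = np.asarray(delta_E_mV, dtype=float)
    ca = 10.0 ** ((dE - model.E0_mV) / model.s_mV_per_decade) - model.sigma_M
    ca = np.maximum(ca, 0.0)
    return float(ca) if np.isscalar(delta_E_mV) else ca


def total_from_free(Ca_free_M, buffer: BufferModel):
    """[Ca]_T = [Ca]_F ([B]_T + [Ca]_F + Kd) / ([Ca]_F + Kd)."""
    f = np.asarray(Ca_free_M, dtype=float)
    out = f * (buffer.BT_M + f + buffer.Kd_M) / (f + buffer.Kd_M)
    return float(out) if np.isscalar(Ca_free_M) else out


def free_from_total(Ca_total_M, buffer: BufferModel):
    """Positive root of the single-site binding quadratic (inverse of
    :func:`total_from_free`)."""
    T = np.asarray(Ca_total_M, dtype=float)
    if np.any(T < 0):
        raise ValueError("total Ca must be >= 0")
    b = buffer.BT_M + buffer.Kd_M - T
    # f^2 + b f - Kd T = 0; numerically stable positive root
    disc = np.sqrt(b * b + 4.0 * buffer.Kd_M * T)
    f = np.where(b >= 0, 2.0 * buffer.Kd_M * T / (b + disc), (disc - b) / 2.0)
    return float(f) if np.isscalar(Ca_total_M) else f


def fit_lom(series: CalibrationSeries, init: BufferModel,
            init_sigma_M: float = 1e-8) -> tuple[ElectrodeModel, BufferModel]:
    """Joint least-squares fit of the electrode + buffer model.

    Buffer-free rows (free Ca = total Ca) constrain E0 and s; buffered rows,
    through the binding quadratic composed with the electrode response,
    constrain Sigma, [B]_T and Kd.  Sigma and Kd are optimized on a log scale.
    """
    if series.calibration_Ca_T_M.size == 0 or series.buffered_Ca_T_M.size == 0:
        raise ValueError("need both buffer-free and buffered rows "
                         "(otherwise the design is unidentifiable)")
    # initialize E0, s from the buffer-free rows (linear in log10 Ca_T)
    A = np.vstack([np.ones_like(series.calibration_Ca_T_M),
                   np.log10(series.calibration_Ca_T_M)]).T
    (e0_init, s_init), *_ = np.linalg.lstsq(A, series.calibration_dE_mV, rcond=None)

    def residuals(x):
        e0, s, log_sigma, bt, log_kd = x
        model = ElectrodeModel(e0, s, 10.0 ** log_sigma)
        buf = BufferModel(init.name, 10.0 ** log_kd, bt)
        r_cal = potential_from_free(series.calibration_Ca_T_M, model) \
            - series.calibration_dE_mV
        free = free_from_total(series.buffered_Ca_T_M, buf)
        r_buf = potential_from_free(free, model) - series.buffered_dE_mV
        return np.concatenate([r_cal, r_buf])

    x0 = np.array([e0_init, max(s_init, 1.0), np.log10(init_sigma_M),
                   init.BT_M, np.log10(init.Kd_M)])
    lb = [-np.inf, 1.0, -12.0, init.BT_M * 1e-2, np.log10(init.Kd_M) - 3]
    ub = [np.inf, 100.0, -3.0, init.BT_M * 1e2, np.log10(init.Kd_M) + 3]
    res = scipy.optimize.least_squares(residuals, x0, bounds=(lb, ub),
                                       xtol=1e-14, ftol=1e-14, gtol=1e-14)
    e0, s, log_sigma, bt, log_kd = res.x
    return (ElectrodeModel(float(e0), float(s), float(10.0 ** log_sigma)),
            BufferModel(init.name, float(10.0 ** log_kd), float(bt)))


def recipe(target_Ca_free_M: float,
           buffers: dict[str, BufferModel] | None = None) -> BufferRecipe:
    """Choose the buffer whose Kd brackets the target free Ca and compute the
    total Ca to add: BAPTA below 1 uM, HEDTA for 1-10 uM, NTA above 10 uM."""
    if target_Ca_free_M <= 0:
        raise ValueError("target free Ca must be > 0")
    if buffers is None:
        buffers = STANDARD_BUFFERS
    if target_Ca_free_M < 1e-6:
        buf = buffers["BAPTA"]
    elif target_Ca_free_M <= 1e-5:
        buf = buffers["HEDTA"]
    else:
        buf = buffers["NTA"]
    return BufferRecipe(buffer=buf, target_free_M=float(target_Ca_free_M),
                        Ca_total_M=total_from_free(target_Ca_free_M, buf))
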
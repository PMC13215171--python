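"""Concentration-response curve fitting.

Four empirical fits used on the trace-level measurements:

* Hill concentration-inhibition, ``I_Blocker/I_Glu = 1/(1+([B]/IC50)^nH)``;
* [Ca2+]i dependence of a readout Y (blocker IC50 or Iss/Ipeak),
  ``Y = min + (max-min)/(1+([Ca]/CaEC50)^nH)``;
* recovery from desensitization as single/double exponential, with the
  amplitude-weighted time constant for double fits;
* normalized LDH neuroprotection,
  ``LDH = min + (1-min)/(1+([B]/IC50)^nH)``.

All fits are unweighted least squares via lmfit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit

from .protocols import InhibitionTable

__all__ = [
    "HillFit", "CaDependenceFit", "RfDFit", "LdhFit",
    "fit_hill", "fit_ca_dependence", "fit_rfd", "normalize_ldh", "fit_ldh",
    "hill_fraction", "ca_dependence_curve", "ldh_curve", "weighted_tau",
    "DEFAULT_LDH_GRID_UM",
]

DEFAULT_LDH_GRID_UM = (0.3, 1.0, 3.0, 10.0, 30.0, 100.0)

_NH_MAX = 6.0


def hill_fraction(blocker_uM, ic50_uM: float, n_H: float):
    """Fractional current remaining at a blocker concentration."""
    b = np.asarray(blocker_uM, dtype=float)
    return 1.0 / (1.0 + (b / ic50_uM) ** n_H)


def ca_dependence_curve(ca_uM, y_min: float, y_max: float,
                        ca_ec50_uM: float, n_H: float):
    ca = np.asarray(ca_uM, dtype=float)
    return y_min + (y_max - y_min) / (1.0 + (ca / ca_ec50_uM) ** n_H)


def ldh_curve(blocker_uM, min_ldh_norm: float, ic50_uM: float, n_H: float):
    b = np.asarray(blocker_uM, dtype=float)
    return min_ldh_norm + (1.0 - min_ldh_norm) / (1.0 + (b / ic50_uM) ** n_H)


def weighted_tau(tau_fast: float, a_fast: float,
                 tau_slow: float, a_slow: float) -> float:
    """Amplitude-weighted time constant of a double-exponential fit."""
    return (tau_fast * a_fast + tau_slow * a_slow) / (a_fast + a_slow)


@dataclass(frozen=True)
class HillFit:
    ic50_uM: float
    n_H: float

    def predict(self, blocker_uM):
        return hill_fraction(blocker_uM, self.ic50_uM, self.n_H)


@dataclass(frozen=True)
class CaDependenceFit:
    y_min: float
    y_max: float
    ca_ec50_uM: float
    n_H: float
    flagged: bool = False

    @property
    def midpoint(self) -> float:
        """Y at the half-maximal [Ca2+]i: (min + max)/2."""
        return 0.5 * (self.y_min + self.y_max)

    def predict(self, ca_uM):
        return ca_dependence_curve(ca_uM, self.y_min, self.y_max,
                                   self.ca_ec50_uM, self.n_H)


@dataclass(frozen=True)
class RfDFit:
    kind: str                       # "single" | "double"
    tau_w_s: float
    tau_s: float | None = None      # single-exponential tau
    tau_fast_s: float | None = None
    a_fast: float | None = None
    tau_slow_s: float | None = None
    a_slow: float | None = None

    def predict(self, interval_s):
        t = np.asarray(interval_s, dtype=float)
        if self.kind == "single":
            a = self.a_fast if self.a_fast is not None else 1.0
            return 1.0 - a * np.exp(-t / self.tau_s)
        return 1.0 - (self.a_fast * np.exp(-t / self.tau_fast_s)
                      + self.a_slow * np.exp(-t / self.tau_slow_s))


@dataclass(frozen=True)
class LdhFit:
    min_ldh_norm: float
    ic50_uM: float
    n_H: float

    def predict(self, blocker_uM):
        return ldh_curve(blocker_uM, self.min_ldh_norm, self.ic50_uM, self.n_H)


def _ic50_bounds(concs: np.ndarray) -> tuple[float, float]:
    lo, hi = concs[concs > 0].min(), concs.max()
    return lo * 0.01, hi * 100.0


def fit_hill(table: InhibitionTable) -> HillFit:
    """Least-squares Hill fit of a concentration-inhibition table; IC50 and
    nH free."""
    b = np.asarray(table.blocker_uM, dtype=float)
    y = np.asarray(table.fraction, dtype=float)
    pos = b > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 nonzero blocker concentrations")
    if np.all(y > 0.9) or np.all(y < 0.1):
        raise ValueError("degenerate concentration-inhibition data "
                         "(no inflection within the tested range)")
    lo, hi = _ic50_bounds(b)
    model = lmfit.Model(hill_fraction)
    params = model.make_params(
        ic50_uM=dict(value=float(np.sqrt(lo * hi)), min=lo, max=hi),
        n_H=dict(value=1.0, min=1e-3, max=_NH_MAX))
    res = model.fit(y[pos], params, blocker_uM=b[pos])
    return HillFit(ic50_uM=float(res.params["ic50_uM"]),
                   n_H=float(res.params["n_H"]))


def fit_ca_dependence(ca_uM, y, anchor_max: bool = True,
                      anchor_min: bool = True) -> CaDependenceFit:
    """Fit the [Ca2+]i dependence of a readout.

    The default follows the convention used on the recordings, where only
    CaEC50 and nH were free: the maximum plateau is fixed at the
    lowest-[Ca2+]i observation and the minimum plateau at the smallest
    observed value.  Either anchor can be released.  Data that are
    non-monotone beyond their spread are fit anyway but flagged.
    """
    ca = np.asarray(ca_uM, dtype=float)
    y = np.asarray(y, dtype=float)
    if ca.size < 4:
        raise ValueError("need at least 4 [Ca2+]i points")
    order = np.argsort(ca)
    ca, y = ca[order], y[order]
    y_at_low = float(y[0])
    pos = ca[ca > 0]
    ec50_lo, ec50_hi = pos.min() * 1e-3, pos.max() * 1e3
    model = lmfit.Model(ca_dependence_curve, independent_vars=["ca_uM"])
    params = model.make_params(
        y_min=dict(value=float(y.min()), vary=not anchor_min,
                   min=0.0, max=float(y.max())),
        y_max=dict(value=y_at_low, vary=not anchor_max,
                   min=float(y.min()), max=float(2 * y.max())),
        ca_ec50_uM=dict(value=float(np.median(pos)), min=ec50_lo, max=ec50_hi),
        n_H=dict(value=1.0, min=1e-3, max=_NH_MAX))
    res = model.fit(y, params, ca_uM=ca)
    resid_scale = float(np.std(res.residual)) if res.residual.size else 0.0
    flagged = bool(np.any(np.diff(y) > 3 * resid_scale + 1e-12)
                   and np.any(np.diff(y) < -(3 * resid_scale + 1e-12)))
    return CaDependenceFit(y_min=float(res.params["y_min"]),
                           y_max=float(res.params["y_max"]),
                           ca_ec50_uM=float(res.params["ca_ec50_uM"]),
                           n_H=float(res.params["n_H"]),
                           flagged=flagged)


def _fit_exponential_deficit(t: np.ndarray, deficit: np.ndarray,
                             double: bool) -> lmfit.model.ModelResult:
    if double:
        def f(t, a_fast, tau_fast, a_slow, tau_slow):
            return a_fast * np.exp(-t / tau_fast) + a_slow * np.exp(-t / tau_slow)
        model = lmfit.Model(f)
        a0 = max(float(deficit.max()), 1e-3)
        tspan = t.max()
        params = model.make_params(
            a_fast=dict(value=a0 / 2, min=0.0, max=2.0),
            tau_fast=dict(value=tspan / 20, min=1e-4, max=tspan * 10),
            a_slow=dict(value=a0 / 2, min=0.0, max=2.0),
            tau_slow=dict(value=tspan / 2, min=1e-4, max=tspan * 100))
    else:
        def f(t, a, tau):
            return a * np.exp(-t / tau)
        model = lmfit.Model(f)
        params = model.make_params(
            a=dict(value=max(float(deficit.max()), 1e-3), min=0.0, max=2.0),
            tau=dict(value=t.max() / 5, min=1e-4, max=t.max() * 100))
    return model.fit(deficit, params, t=t)


def fit_rfd(interval_s, normalized_peak, aicc_margin: float = 0.0) -> RfDFit:
    """Fit the recovery-from-desensitization time course.

    The recovery deficit ``1 - normalized_peak`` is fit with one or two
    exponential components; the double-exponential model is kept only when it
    improves the corrected AIC.  Double fits are summarized by the
    amplitude-weighted tau.
    """
    t = np.asarray(interval_s, dtype=float)
    y = np.asarray(normalized_peak, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 interapplication intervals")
    order = np.argsort(t)
    t, y = t[order], y[order]
    deficit = 1.0 - y
    if deficit[-1] > 0.5:
        raise ValueError("non-recovering data: peak after the longest "
                         "interval is below half of full recovery")
    single = _fit_exponential_deficit(t, deficit, double=False)
    result = RfDFit(kind="single", tau_s=float(single.params["tau"]),
                    a_fast=float(single.params["a"]),
                    tau_w_s=float(single.params["tau"]))
    if t.size >= 6:
        double = _fit_exponential_deficit(t, deficit, double=True)
        n = t.size

        def aicc(res, k):
            rss = max(float(np.sum(res.residual ** 2)), 1e-300)
            a = n * np.log(rss / n) + 2 * k
            return a + (2 * k * (k + 1) / (n - k - 1)) if n - k - 1 > 0 else a

        if aicc(double, 4) + aicc_margin < aicc(single, 2):
            tf, af = float(double.params["tau_fast"]), float(double.params["a_fast"])
            ts, as_ = float(double.params["tau_slow"]), float(double.params["a_slow"])
            if tf > ts:  # order the components
                tf, af, ts, as_ = ts, as_, tf, af
            result = RfDFit(kind="double", tau_fast_s=tf, a_fast=af,
                            tau_slow_s=ts, a_slow=as_,
                            tau_w_s=weighted_tau(tf, af, ts, as_))
    return result


def normalize_ldh(treatment: float, vehicle: float, nmda_only: float) -> float:
    """Baseline-adjusted, NMDA-normalized LDH release:
    (treatment - vehicle) / (nmda_only - vehicle)."""
    if nmda_only <= vehicle:
        raise ValueError("nmda_only must exceed vehicle LDH")
    return (treatment - vehicle) / (nmda_only - vehicle)


def fit_ldh(blocker_uM, ldh_normalized) -> LdhFit:
    """Fit the neuroprotection curve; min plateau, IC50 and nH free."""
    b = np.asarray(blocker_uM, dtype=float)
    y = np.asarray(ldh_normalized, dtype=float)
    if b.size < 4:
        raise ValueError("need at least 4 blocker concentrations")
    if float(np.ptp(y)) < 1e-12:
        raise ValueError("degenerate (flat) neuroprotection data")
    lo, hi = _ic50_bounds(b)
    model = lmfit.Model(ldh_curve)
    params = model.make_params(
        min_ldh_norm=dict(value=float(max(y.min(), 0.0)), min=0.0, max=1.0 - 1e-9),
        ic50_uM=dict(value=float(np.sqrt(lo * hi)), min=lo, max=hi),
        n_H=dict(value=1.0, min=1e-3, max=_NH_MAX))
    res = model.fit(y, params, blocker_uM=b)
    return LdhFit(min_ldh_norm=float(res.params["min_ldh_norm"]),
                  ic50_uM=float(res.params["ic50_uM"]),
                  n_H=float(res.params["n_H"]))
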
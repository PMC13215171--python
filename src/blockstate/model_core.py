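"""Two-plane Markov kinetic model of NMDA receptor gating, open-channel block
and Ca2+-dependent desensitization.

The receptor scheme has two "planes" (intracellular Ca2+ unbound / bound) and,
within each plane, two "arms" (channel blocker unbound / bound).  Each arm
carries the core activation states ``R -> RA -> RA2 -> RA2*`` (two sequential
glutamate bindings followed by a single gating step) plus a Ca2+-independent
desensitized state ``dRA2``.  The Ca2+-bound plane additionally carries a
Ca2+-dependent desensitized state ``cddRA2`` reachable only from the fully
agonist-bound closed state.  The blocker (memantine) binds exclusively to open
channels and is trapped: blocked receptors traverse the same closed states as
unblocked receptors but cannot release the blocker until the channel reopens.

Occupancy evolves as a continuous-time Markov chain, ``dp/dt = p Q`` with the
row-vector convention.  Propagation over piecewise-constant ligand segments
uses the spectral expansion of the generator (the classic Q-matrix method),
cross-checked against the matrix exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

__all__ = [
    "RateSet",
    "LigandContext",
    "CurrentParams",
    "StateLabel",
    "Edge",
    "KineticScheme",
    "build_scheme",
    "rate_matrix",
    "propagate",
    "steady_state",
    "current",
    "p_open",
    "TABLE_RATE_NAMES",
]

# Canonical rate-constant names.  Units: second-order constants are per-uM-per-s
# (glutamate, memantine, Ca2+ binding); all others are per-s.
TABLE_RATE_NAMES = (
    "k_Ca_plus", "k_Ca_minus",
    "k_M_plus", "k_M_minus",
    "k_a_plus", "k_a_minus", "k_aM_plus", "k_aM_minus",
    "k_g_plus", "k_g_minus", "k_gM_plus", "k_gM_minus",
    "k_d_plus", "k_d_minus", "k_dM_plus", "k_dM_minus",
    "k_cdd_plus", "k_cdd_minus", "k_cddM_plus", "k_cddM_minus",
)


@dataclass
class RateSet:
    """Named rate constants of the full model.

    Defaults are the optimized/fixed values of the published parameter table:
    Ca2+ binding rates arbitrarily fast with K_D = k_Ca_minus/k_Ca_plus =
    0.082 uM; agonist-binding and gating rates fixed from prior work; the four
    desensitization-related pairs from the staged fit.
    """

    k_Ca_plus: float = 1e6      # uM^-1 s^-1
    k_Ca_minus: float = 8.2e4   # s^-1
    k_M_plus: float = 30.0      # uM^-1 s^-1
    k_M_minus: float = 143.0    # s^-1
    k_a_plus: float = 5.0       # uM^-1 s^-1
    k_a_minus: float = 25.0     # s^-1
    k_aM_plus: float = 5.0
    k_aM_minus: float = 25.0
    k_g_plus: float = 71.0      # s^-1
    k_g_minus: float = 305.0
    k_gM_plus: float = 71.0
    k_gM_minus: float = 305.0
    k_d_plus: float = 0.135
    k_d_minus: float = 0.243
    k_dM_plus: float = 0.520
    k_dM_minus: float = 0.243
    k_cdd_plus: float = 0.737
    k_cdd_minus: float = 0.692
    k_cddM_plus: float = 1.75
    k_cddM_minus: float = 0.304

    def __post_init__(self) -> None:
        for name in TABLE_RATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in TABLE_RATE_NAMES}

    def updated(self, **changes: float) -> "RateSet":
        return replace(self, **changes)

    def to_json_dict(self, statistical_factors: bool = True) -> dict:
        return {"rates": self.as_dict(),
                "options": {"statistical_factors": bool(statistical_factors)}}

    @classmethod
    def from_json_dict(cls, d: dict) -> tuple["RateSet", dict]:
        return cls(**d["rates"]), dict(d.get("options", {}))


@dataclass(frozen=True)
class LigandContext:
    """Free ligand concentrations (uM): glutamate, memantine, intracellular Ca2+.

    [Ca2+]i is pipette-clamped in the experiments being modeled, so it is held
    fixed for the duration of a recording.
    """

    glu_uM: float = 0.0
    mem_uM: float = 0.0
    ca_i_uM: float = 0.0

    def __post_init__(self) -> None:
        for name in ("glu_uM", "mem_uM", "ca_i_uM"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class CurrentParams:
    """Whole-cell current scaling: I = N * P_open * gamma * (Vm - Vrev).

    gamma in pS and voltages in mV give current in 1e-3 pA units, hence the
    1e-3 factor applied in :func:`current`.  With Vm < Vrev the current is
    inward (negative).
    """

    N: float = 1.0
    gamma_pS: float = 50.0
    Vm_mV: float = -65.0
    Vrev_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_pS <= 0:
            raise ValueError("gamma_pS must be > 0")


@dataclass(frozen=True)
class StateLabel:
    plane: str   # "Ca-free" | "Ca-bound"
    arm: str     # "unblocked" | "blocked"
    core: str    # "R" | "RA" | "RA2" | "RA2open" | "dRA2" | "cddRA2"

    def __post_init__(self) -> None:
        if self.core == "cddRA2" and self.plane != "Ca-bound":
            raise ValueError("cddRA2 exists only in the Ca-bound plane")

    @property
    def conducting(self) -> bool:
        return self.core == "RA2open" and self.arm == "unblocked"

    def __str__(self) -> str:
        prefix = ("M" if self.arm == "blocked" else "")
        ca = ("Ca" if self.plane == "Ca-bound" else "")
        core = {"R": "R", "RA": "RA", "RA2": "RA2", "RA2open": "RA2*",
                "dRA2": "dRA2", "cddRA2": "cddRA2"}[self.core]
        if self.core in ("dRA2", "cddRA2"):
            kind = "cdd" if self.core == "cddRA2" else "d"
            return f"{prefix}{kind}{ca}RA2"
        return f"{prefix}{ca}{core}"


@dataclass(frozen=True)
class Edge:
    """Directed transition: rate = rate_constant * ligand_conc * stat_factor."""

    src: int
    dst: int
    rate_name: str
    ligand: str = "none"      # "glu" | "mem" | "ca_i" | "none"
    stat_factor: float = 1.0


_CORES_PLAIN = ("R", "RA", "RA2", "RA2open", "dRA2")
_CORES_LOWER = ("R", "RA", "RA2", "RA2open", "dRA2", "cddRA2")


@dataclass
class KineticScheme:
    states: list[StateLabel]
    edges: list[Edge]
    statistical_factors: bool = True

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def conducting_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.states) if s.conducting])

    def index(self, plane: str, arm: str, core: str) -> int:
        target = StateLabel(plane, arm, core)
        return self.states.index(target)


def build_scheme(rates: RateSet | None = None, statistical_factors: bool = True) -> KineticScheme:
    """Construct the 22-state scheme.

    State order: Ca-free unblocked, Ca-free blocked, Ca-bound unblocked,
    Ca-bound blocked; each arm ordered R, RA, RA2, RA2open, dRA2(, cddRA2).
    ``rates`` is accepted for interface symmetry and validation only — the
    topology does not depend on the rate values.
    """
    if rates is not None and not isinstance(rates, RateSet):
        raise TypeError("rates must be a RateSet or None")

    states: list[StateLabel] = []
    for plane, cores in (("Ca-free", _CORES_PLAIN), ("Ca-bound", _CORES_LOWER)):
        for arm in ("unblocked", "blocked"):
            for core in cores:
                states.append(StateLabel(plane, arm, core))
    # reorder: spec order is built above already as upper-unblocked,
    # upper-blocked, lower-unblocked, lower-blocked
    idx = {s: i for i, s in enumerate(states)}

    f2 = 2.0 if statistical_factors else 1.0
    edges: list[Edge] = []

    def add_pair(a: StateLabel, b: StateLabel, fwd: str, rev: str,
                 ligand: str = "none", f_fwd: float = 1.0, f_rev: float = 1.0) -> None:
        edges.append(Edge(idx[a], idx[b], fwd, ligand, f_fwd))
        edges.append(Edge(idx[b], idx[a], rev, "none", f_rev))

    for plane in ("Ca-free", "Ca-bound"):
        for arm, suff in (("unblocked", ""), ("blocked", "M")):
            S = lambda core: StateLabel(plane, arm, core)
            ka_p, ka_m = f"k_a{suff}_plus", f"k_a{suff}_minus"
            # two sequential identical agonist sites with statistical factors
            add_pair(S("R"), S("RA"), ka_p, ka_m, "glu", f_fwd=f2, f_rev=1.0)
            add_pair(S("RA"), S("RA2"), ka_p, ka_m, "glu", f_fwd=1.0, f_rev=f2)
            add_pair(S("RA2"), S("RA2open"), f"k_g{suff}_plus", f"k_g{suff}_minus")
            add_pair(S("RA2"), S("dRA2"), f"k_d{suff}_plus", f"k_d{suff}_minus")
            if plane == "Ca-bound":
                add_pair(S("RA2"), S("cddRA2"), f"k_cdd{suff}_plus", f"k_cdd{suff}_minus")

    # memantine binds open channels only (trapping block)
    for plane in ("Ca-free", "Ca-bound"):
        a = StateLabel(plane, "unblocked", "RA2open")
        b = StateLabel(plane, "blocked", "RA2open")
        add_pair(a, b, "k_M_plus", "k_M_minus", "mem")

    # Ca2+ binding couples every Ca-free state to its Ca-bound counterpart
    for arm in ("unblocked", "blocked"):
        for core in _CORES_PLAIN:
            a = StateLabel("Ca-free", arm, core)
            b = StateLabel("Ca-bound", arm, core)
            add_pair(a, b, "k_Ca_plus", "k_Ca_minus", "ca_i")

    return KineticScheme(states=states, edges=edges,
                         statistical_factors=statistical_factors)


def _ligand_value(ligands: LigandContext, name: str) -> float:
    if name == "none":
        return 1.0
    if name == "glu":
        return ligands.glu_uM
    if name == "mem":
        return ligands.mem_uM
    if name == "ca_i":
        return ligands.ca_i_uM
    raise ValueError(f"unknown ligand multiplier {name!r}")


def rate_matrix(scheme: KineticScheme, rates: RateSet,
                ligands: LigandContext) -> np.ndarray:
    """Generator (Q) matrix in s^-1: off-diagonal (i, j) holds the i->j rate,
    diagonal entries make each row sum to zero."""
    n = scheme.n_states
    Q = np.zeros((n, n))
    rd = rates.as_dict()
    for e in scheme.edges:
        try:
            k = rd[e.rate_name]
        except KeyError:
            raise KeyError(f"unknown rate constant {e.rate_name!r} in scheme") from None
        Q[e.src, e.dst] += k * _ligand_value(ligands, e.ligand) * e.stat_factor
    if not np.all(np.isfinite(Q)):
        raise ValueError("non-finite entries in rate matrix")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


_SPECTRAL_TOL = 1e-7      # spectral-vs-expm agreement required at segment end
_MODE_DROP_LOG = -69.0    # modes decayed below e^-69 (~1e-30) by the first sample


def _occupancies_from_generator(Q: np.ndarray, p0: np.ndarray,
                                times: np.ndarray,
                                project: np.ndarray | None = None) -> np.ndarray:
    """p(t) = p0 expm(Q t) at each requested (positive) time via spectral
    expansion of the generator.

    The expansion is validated against scipy's expm at the last time point;
    if the generator is (numerically) defective -- possible, e.g., when the
    blocked and unblocked arms carry identical rates -- the routine falls back
    to uniform-step matrix-exponential propagation.  Modes that have decayed
    below double precision by the first sample time (the stiff Ca2+-binding
    modes, on ms-scale grids) are dropped.  With ``project`` given, returns
    the scalar series p(t) @ project instead of full occupancy rows.
    """
    times = np.asarray(times, dtype=float)
    n = Q.shape[0]
    if times.size == 0:
        return np.empty(0) if project is not None else np.empty((0, n))
    t_end = times[-1]
    p_end_ref = p0 @ scipy.linalg.expm(Q * t_end)

    ok = False
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        c = p0.astype(complex) @ V
        # clamp tiny positive real parts (eigenvalues of a generator are <= 0)
        w = np.where(w.real > 0, 1j * w.imag, w)
        end_exp = np.exp(np.clip(w.real * t_end, -700.0, None)
                         + 1j * w.imag * t_end)
        end = ((end_exp * c) @ Vinv).real
        ok = np.max(np.abs(end - p_end_ref)) < _SPECTRAL_TOL
    except np.linalg.LinAlgError:
        pass

    if ok:
        keep = w.real * times[0] > _MODE_DROP_LOG
        wk, ck, Vik = w[keep], c[keep], Vinv[keep]
        A = np.outer(times, wk.real)
        np.clip(A, -700.0, None, out=A)  # avoid subnormal exp stalls
        if np.all(np.abs(wk.imag) < 1e-300):
            E = np.exp(A) * ck.real
            right = Vik.real if project is None else Vik.real @ project
            occ = E @ right
        else:
            E = np.exp(A + 1j * np.outer(times, wk.imag)) * ck
            right = Vik if project is None else Vik @ project
            occ = (E @ right).real
        if project is not None:
            return occ
    else:
        # defective or ill-conditioned generator: step with the exact
        # propagator on the (uniform) grid
        dts = np.diff(np.concatenate(([0.0], times)))
        dt0 = dts[dts > 0].min() if np.any(dts > 0) else 0.0
        occ = np.empty((times.size, n))
        p = p0.copy()
        uniform = dt0 > 0 and np.allclose(dts[dts > 0], dt0, rtol=1e-9)
        P = scipy.linalg.expm(Q * dt0) if uniform else None
        for i, dt in enumerate(dts):
            if dt > 0:
                p = p @ (P if uniform else scipy.linalg.expm(Q * dt))
            occ[i] = p
        if project is not None:
            return occ @ project

    occ[occ < 0] = 0.0
    # the zero eigenvalue of a conservative generator is only resolved to
    # ~1e-10 numerically; renormalizing removes the resulting slow drift
    occ /= occ.sum(axis=1, keepdims=True)
    return occ


def propagate(scheme: KineticScheme, rates: RateSet, ligands: LigandContext,
              occ0: np.ndarray, duration_s: float, dt_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Evolve occupancies under constant ligand concentrations.

    Returns ``(times, occupancies)`` with ``times = 0, dt, ..., <= duration``
    and one occupancy row per time (row 0 is ``occ0``).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    occ0 = np.asarray(occ0, dtype=float)
    _check_occupancy(occ0, scheme.n_states)
    Q = rate_matrix(scheme, rates, ligands)
    # states unreachable from the initial support stay at exactly zero
    # (e.g. the Ca-bound plane at ca_i = 0, the blocked arms at mem = 0)
    mask = np.zeros(scheme.n_states, dtype=bool)
    for i in np.nonzero(occ0 > 0)[0]:
        mask |= _reachable(Q, i)
    n_steps = int(np.floor(duration_s / dt_s + 1e-9))
    times = np.arange(1, n_steps + 1) * dt_s
    occ_r = _occupancies_from_generator(Q[np.ix_(mask, mask)], occ0[mask], times)
    occ = np.zeros((times.size, scheme.n_states))
    occ[:, mask] = occ_r
    return np.concatenate(([0.0], times)), np.vstack([occ0, occ])


def _check_occupancy(p: np.ndarray, n: int) -> None:
    if p.shape != (n,):
        raise ValueError(f"occupancy vector must have shape ({n},)")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("invalid occupancy vector (negative entries or sum != 1)")


def _reachable(Q: np.ndarray, start: int) -> np.ndarray:
    n = Q.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [start]
    seen[start] = True
    while stack:
        i = stack.pop()
        for j in np.nonzero(Q[i] > 0)[0]:
            if j != i and not seen[j]:
                seen[j] = True
                stack.append(j)
    return seen


def steady_state(scheme: KineticScheme, rates: RateSet, ligands: LigandContext,
                 start: int = 0) -> np.ndarray:
    """Stationary occupancy: p with p Q = 0, sum(p) = 1.

    When some states are unreachable under the given ligand context (e.g. the
    blocked arms at [mem] = 0 from a resting receptor), the stationary
    distribution is resolved on the component reachable from ``start``
    (default: the Ca-free, unblocked resting state R).
    """
    Q = rate_matrix(scheme, rates, ligands)
    mask = _reachable(Q, start)
    Qr = Q[np.ix_(mask, mask)]
    ns = scipy.linalg.null_space(Qr.T)
    if ns.shape[1] != 1:
        raise ValueError(
            f"stationary distribution is not unique on the reachable component "
            f"(null space dimension {ns.shape[1]})")
    p_r = ns[:, 0]
    p_r = p_r / p_r.sum()
    if np.any(p_r < -1e-9):
        raise ValueError("stationary solve produced negative occupancies")
    p_r[p_r < 0] = 0.0
    p = np.zeros(scheme.n_states)
    p[mask] = p_r
    return p


def p_open(occ: np.ndarray, scheme: KineticScheme) -> np.ndarray | float:
    """Summed occupancy of the conducting states (open probability)."""
    occ = np.asarray(occ, dtype=float)
    cond = scheme.conducting_indices
    return occ[..., cond].sum(axis=-1)


def current(occ: np.ndarray, scheme: KineticScheme,
            params: CurrentParams = CurrentParams()) -> np.ndarray | float:
    """Membrane current in pA: I = N * P_open * gamma * (Vm - Vrev) * 1e-3."""
    po = p_open(occ, scheme)
    return params.N * po * params.gamma_pS * (params.Vm_mV - params.Vrev_mV) * 1e-3
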
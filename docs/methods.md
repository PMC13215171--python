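# Methods

## The kinetic model

`blockstate` models the interaction of an NMDA receptor (NMDAR) with
glutamate, intracellular Ca²⁺, and the open-channel blocker memantine as a
continuous-time Markov chain on 22 states. The state space is the product of
three coordinates:

* **plane** — intracellular Ca²⁺ unbound (upper) or bound (lower). A single
  Ca²⁺ association site is assumed; every Ca²⁺-free state connects to its
  Ca²⁺-bound counterpart with shared rates `k_Ca+·[Ca²⁺]ᵢ` / `k_Ca−`, i.e.
  all receptor states bind Ca²⁺ with equal affinity.
* **arm** — blocker unbound or bound. Memantine binds **only** to open
  channels (`RA₂* ⇌ M·RA₂*`, rates `k_M+·[mem]` / `k_M−`) and is trapped:
  blocked receptors traverse the same closed/desensitized states as
  unblocked receptors (with their own `k_*M` rate constants) but cannot
  release the blocker until the channel pore is open.
* **core** — `R ⇌ RA ⇌ RA₂ ⇌ RA₂*` (two sequential glutamate bindings, one
  gating step) plus a Ca²⁺-independent desensitized state `dRA₂` reachable
  from `RA₂`. The Ca²⁺-bound plane carries one additional state per arm, the
  Ca²⁺-dependent desensitized (CDD) state `cddRA₂`, attached to the fully
  agonist-bound closed state `RA₂` of that plane. Only the two unblocked
  open states conduct.

Agonist binding uses the standard two-identical-site statistical factors
(`2k_a+`, `k_a−` for the first site; `k_a+`, `2k_a−` for the second);
`build_scheme(..., statistical_factors=False)` disables them. At the
saturating 1 mM glutamate used throughout, this choice is kinetically minor.

Default rate constants are the published values for GluN1/2A receptors at
−65 mV (units µM⁻¹s⁻¹ for second-order steps, s⁻¹ otherwise): Ca²⁺ binding
made arbitrarily fast (`k_Ca+ = 10⁶`, `k_Ca− = 8.2·10⁴`, so that only the
ratio — the 82 nM Ca²⁺ K_D — matters), `k_M+ = 30`, `k_M− = 143`,
`k_a± = 5/25`, `k_g± = 71/305` (equal in blocked and unblocked arms),
`k_d± = 0.135/0.243`, `k_dM+ = 0.520` with `k_dM−` tied to `k_d−`,
`k_cdd± = 0.737/0.692`, and `k_cddM± = 1.75/0.304`. Voltage dependence of
block is not modeled; the blocker rates are −65 mV effective values.

Simulated current is `I = N·P_open·γ·(V_m − V_rev)` with γ = 50 pS,
V_m = −65 mV, V_rev = 0 (inward, negative). `N` is an arbitrary amplitude
scale because all fitting is done on normalized currents.

## Numerics

Occupancy evolves as `dp/dt = pQ` (row-vector convention) with a generator
`Q` that is constant within each protocol segment; solution exchange is
treated as instantaneous, and the segment-1 ligand context supplies the
initial condition (receptors pre-equilibrate with the pipette solution).
Because `k_Ca−` makes the system stiff (rates spanning 10⁻¹–10⁷ s⁻¹),
propagation uses the spectral expansion of `Q` — the classical Q-matrix
method — which is unconditionally stable and exact for a linear
time-invariant generator. Three safeguards apply:

* each segment's expansion is checked against `scipy.linalg.expm` at the
  segment end (tolerance 10⁻⁷); if the generator is numerically defective
  (possible when blocked and unblocked arms carry identical rates, making
  `Q` block-triangular with repeated blocks), propagation falls back to
  stepping with the exact matrix exponential of one grid interval;
* modes that decay below ~10⁻³⁰ before the first sample (the stiff Ca²⁺
  binding modes on ms-scale grids) are dropped, and exponents are clamped at
  −700 to avoid subnormal-arithmetic stalls;
* occupancy rows are renormalized to sum 1: LAPACK resolves the zero
  eigenvalue of a conservative generator only to ~10⁻¹⁰, which otherwise
  accumulates visible mass drift over minute-long protocols. States
  unreachable from the initial support (the Ca²⁺-bound plane at
  [Ca²⁺]ᵢ = 0, the blocked arms at [mem] = 0) are held at exactly zero.

Steady states solve `pQ = 0` by SVD null space on the component reachable
from the resting state, which handles ligand contexts that disconnect parts
of the graph (e.g. agonist-free conditions).

The default simulation grid is dt = 1 ms. The experimental 20-kHz sampling
is unnecessary for the second-scale kinetics of interest; measurements that
need finer grids (the 30-ms peak window) accept any dt.

## Protocols and measurements

* **Concentration-inhibition**: baseline, agonist to steady state,
  sequentially increasing blocker concentrations in constant agonist
  (default 0.1–50 µM, 15 s each, within the 10–30 s range used
  experimentally), agonist-only recovery. Fractional currents are
  steady-state means over the final 1 s, baseline-subtracted, divided by the
  average of pre-blocker and post-recovery agonist steady states. Traces
  recovering to < 85% of the pre-blocker steady state are rejected.
* **Recovery from desensitization (RfD)**: conditioning agonist application,
  then agonist-free intervals (default 200, 100, 50, 20, 10, 5, 2, 1 s —
  decreasing, as in the published example traces) each followed by a 15-s
  test application; blocker, when present, is co-applied throughout. Peaks
  are 30-ms window means centered on the within-application extremum
  (search restricted to the first 2 s to avoid locking onto plateau noise),
  normalized to the 200-s-interval peak; traces with any normalized peak
  > 1.2 are excluded.
* **Desensitization extent**: I_ss/I_peak of a single application.

## Staged multistart fitting

The pipeline reproduces the four-step procedure used to constrain the model,
freeing at most two kinetic rate constants per step:

1. `k_d+`, `k_d−` — agonist step, Ca²⁺-free internal;
2. `k_M−`, `k_dM+` — concentration-inhibition protocol, Ca²⁺-free;
3. `k_cdd+`, `k_cdd−` — agonist step, 10 µM [Ca²⁺]ᵢ;
4. `k_cddM+`, `k_cddM−` — concentration-inhibition protocol, 10 µM [Ca²⁺]ᵢ.

Each step's ensemble means are frozen before the next step; `k_dM−` stays
tied to `k_d−`, and the Ca²⁺ rates stay at their fixed large values. Every
trial multiplies the starting rates by independent lognormal jitter
(σ = 1.2, median ×1, spread ≈ e^±1.2), then chains five runs of a
derivative-free local minimizer, each warm-started from the previous best.
The minimizer is adaptive Nelder-Mead on log-transformed rates (enforcing
positivity without constraints); it fills the role of the principal-axis
(PRAXIS) optimizer used originally — the contract is only "derivative-free
local minimizer of the SSE". Per-trial seeds are `seed + trial_index`.

The objective is the sum of squared differences between the simulated and
observed traces after each is normalized to its own reference steady state
(the first blocker-free agonist application). The amplitude scale `N` is
free in every fit; since it enters linearly, its SSE-optimal value has the
closed form ⟨s,d⟩/⟨s,s⟩ and is profiled out analytically — exactly the
optimum a numerical search over `N` would reach — and is excluded from
ensemble statistics.

Ensembles report the arithmetic mean across trials and two-sided 95%
t-based intervals (mean ± t₀.₉₇₅,ₙ₋₁·SE). These intervals quantify
*optimization* spread across jittered restarts on one averaged dataset, not
sampling uncertainty across cells; they are not expected to cover a
generating value in the frequentist sense.

### Thermodynamics

Entry into the CDD state is summarized by equilibrium constants
`K_cddM = k_cddM+/k_cddM−` and `K_cdd = k_cdd+/k_cdd−` and free energies
`ΔG = −RT ln K` (R = 1.9872·10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K — room
temperature, matching the 25 °C used for solution calibration). With the
default rates, K_cddM ≈ 5.76, K_cdd ≈ 1.06, ΔG(blocker-bound) ≈ −1.04
kcal/mol, and the blocker stabilizes the CDD state by
ΔΔG = −RT ln(K_cddM/K_cdd) ≈ 1.0 kcal/mol. Note that averaging ΔG per trial
(the published convention) and taking ΔG of the mean K differ slightly for
the near-unity K_cdd; both are available (`FitEnsemble` + `free_energy`).

## Empirical curve fits

Unweighted least squares (lmfit) throughout; bounds n_H ∈ (0, 6] and IC₅₀
within the data span × [0.01, 100] prevent runaway fits.

* Hill inhibition: `I_B/I_Glu = 1/(1+([B]/IC₅₀)^n_H)`, IC₅₀ and n_H free.
* [Ca²⁺]ᵢ dependence: `Y = min + (max−min)/(1+([Ca²⁺]ᵢ/CaEC₅₀)^n_H)`. The
  default follows the published convention in which only CaEC₅₀ and n_H are
  free: the max plateau is anchored at the lowest-[Ca²⁺]ᵢ observation (the
  value recorded at < 1 nM, a condition entered as [Ca²⁺]ᵢ = 0, where the
  curve is finite) and the min plateau at the smallest observed value.
  Either anchor can be released. The half-effect readout is the midpoint
  (min+max)/2.
* RfD: the deficit `1 − normalized peak` is fit with one or two exponential
  components; the double model is kept only when it improves the corrected
  AIC (the original analysis chose "single or double" without a stated
  criterion). Double fits report the amplitude-weighted
  τ_w = (τ_f·A_f + τ_s·A_s)/(A_f + A_s).
* Neuroprotection: LDH release normalized as (treatment − vehicle)/(NMDA −
  vehicle), fit with `min + (1−min)/(1+([B]/IC₅₀)^n_H)`, all three
  parameters free.

## Ca²⁺-buffer calibration (LOM)

The ligand-optimization method treats the Ca²⁺-selective electrode as a
Nikolsky-Eisenman device, `ΔE = E⁰ + s·log₁₀([Ca²⁺]_F + Σ)`, with
potentials referenced to the 10 µM calibration solution, and single-site
buffer binding `[Ca²⁺]_T = [Ca²⁺]_F([B]_T + [Ca²⁺]_F + K_d)/([Ca²⁺]_F +
K_d)` (inverted via the numerically stable quadratic root). `fit_lom`
jointly optimizes (E⁰, s, Σ, [B]_T, K_d) — Σ and K_d on a log scale — using
buffer-free calibration rows (which constrain E⁰, s) and buffered rows
(which constrain the rest). Joint optimization is the default; the original
staged/iterative alternation is a special case of the same residual and was
not needed for convergence. This module works in molar units, matching the
calibration literature; helpers convert to the µM convention of the kinetic
model. Buffer choice follows the published rule: BAPTA (K_d = 144 nM) below
1 µM free Ca²⁺, HEDTA (2.24 µM) for 1–10 µM, NTA (81.5 µM) above.

## Synthetic data

The generator emulates the recorded datasets: per-cell traces are one clean
simulation scaled by a lognormal cell amplitude (sd 0.3 — the published
work does not state the spread; this is a configurable assumption), plus
iid additive Gaussian noise scaled to a fraction of peak current (default
2%) and optional linear baseline drift. Traces are normalized to their own
steady state and averaged per condition before fitting, as the recordings
were. The noise is not spectrally shaped (the experimental 5-kHz filtering
is not modeled) because sum-of-squares fitting of second-scale features is
insensitive to noise color. Cell-to-cell variability is limited to
amplitude; rate constants are shared across cells, matching the use of a
single averaged trace per condition. Electrode series use the published
design: 7 buffer-free solutions spanning 0.5–10 mM total Ca²⁺ and 10
buffered solutions spanning ±1.5 decades of free Ca²⁺ around the buffer
K_d, with 0.1 mV Gaussian potential noise.

Passing recovery tests on these data demonstrate correctness of the
machinery — identifiability of the freed rates under the stated protocols
and noise — not that the model captures every feature of real recordings
(notably, single-gating-step activation underestimates peak currents and
slows simulated block onset, limitations inherited from the published
scheme).

## Problem sizes and determinism

Fitting-oriented tests and the acceptance script use 15-s applications,
six blocker concentrations (0.1–50 µM), a 1-ms grid, and 3 trials × 3
chained restarts — the package's reduced-but-faithful default for parameter
recovery studies; the full published configuration (10 × 5) is a `FitConfig`
away. All stochastic components (jitter, synthetic noise, cell amplitudes)
are driven by explicit seeds; identical seeds reproduce results exactly.

## Known limitations

* Single gating step; no additional agonist-bound closed states, so fast
  activation/deactivation kinetics are approximate.
* No Mg²⁺ competition, no voltage-dependent block, no GluN2B/C/D-specific
  schemes.
* Instantaneous solution exchange (experimental exchange is ~ms).
* The across-trial intervals quantify optimizer spread, not biological or
  sampling variability.
* LOM ignores temperature/ionic-strength corrections of K_d by design —
  avoiding them is the method's purpose.
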
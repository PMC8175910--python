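# Methods

## Scope and data flow

socekit analyses single-cell [Ca²⁺]ᵢ time series recorded under a
solution-exchange protocol for store-operated Ca²⁺ entry (SOCE): a
Ca²⁺-free baseline, Ca²⁺-free store depletion with thapsigargin (Tg),
Ca²⁺ re-addition, and Ca²⁺ removal. It works directly in nM; conversion of
ratiometric Fura-2 signals to nM (calibration chemistry) is upstream of
the package and out of scope — every in-scope computation is unit-agnostic.
Traces travel as long-format CSV (cell_id, population, t_s, ca_nM) bound
to a YAML protocol; all downstream tables are tidy CSVs.

## The trace model

Each simulated cell integrates

    dC/dt = g·ca_o(t)·d(t) + r(t) + L − V·m(t)
    dm/dt = (H(C) − m)/τ_m,   H(C) = Cʰ/(Kʰ + Cʰ)

* `g` (`influx_gain`, nM/s per mM): store-operated influx per unit
  extracellular Ca²⁺. Default 10 — with 1 mM re-addition this yields peaks
  near 300–450 nM and plateaus near 150–300 nM, typical Fura-2 magnitudes
  for T cells.
* `d(t)`: store-depletion state, 0 before Tg and `1 − e^{−Δt/τ_rel}`
  after Tg onset (`store_release_tau`, default 30 s). Tg blocks SERCA, so
  stores never refill and SOCE stays on.
* `r(t)`: store-release flux pulse `(A/τ_rel)·e^{−Δt/τ_rel}` carrying a
  total of `A = store_release_amp` nM (default 150) — the familiar
  Ca²⁺-free Tg transient.
* `L` (`leak`, default 1.5 nM/s): constant background influx, chosen so
  the pump balances it near the default 80 nM baseline.
* Pump: maximal rate `V` (`v_max`), half-activation `K` (`k_half`,
  default 400 nM), Hill slope `h` (default 2). Defaults `V = 40` nM/s
  describe a naïve-like cell; memory-like cells use `V ≈ 80`.
  `pump_scale` multiplies each cell's drawn `V` and emulates
  pharmacological block or siRNA knockdown (e.g. 0.2 for a strong block).

**Why the pump activation lags.** PMCA activity is modulated by Ca²⁺ on a
timescale of tens of seconds rather than instantaneously. With an
instantaneous Hill pump, re-addition would drive `C` monotonically to its
steady state — no influx peak would exist, and the peak→plateau decay that
defines the in-Ca²⁺ efflux estimate would vanish. The first-order
activation lag (`pump_tau`, default 40 s) reproduces the canonical
overshoot-then-plateau shape. Deactivation uses a faster constant
(`pump_tau_down`, default 10 s): without it, a fully activated pump keeps
extruding after Ca²⁺ removal and drives [Ca²⁺]ᵢ unphysiologically to
zero. Because the lag vanishes at steady state (`m = H(C)`), the plateau
still satisfies the algebraic balance

    g·ca_o + L = V·C*ʰ/(Kʰ + C*ʰ)

which serves as the independent fixed-point oracle in the tests (the
simulated noiseless plateau matches the root of this equation to well
under 1%). A side effect of the lag is a mildly underdamped approach to
the plateau; residual ringing at the default protocol durations is < 1%
of the plateau by the time the plateau window opens.

**Integration and sampling.** Fixed-step explicit Euler with 0.1 s
substeps (the fastest relaxation rate in the default parameter range is
~0.1 s⁻¹, so the scheme is comfortably stable); emitted traces are
sampled at 2 s, the typical frame interval of ratiometric imaging. `C` is
clamped at 0 during integration. Non-finite states abort with the
offending parameter set named.

**Variability and noise.** Cell-to-cell variability is log-normal
(median-preserving) on `v_max`, `influx_gain` and `baseline_ca`, default
CV 25% each — matching the visible spread of single-cell SOCE data while
keeping all parameters positive. Measurement noise is i.i.d. Gaussian
(default sd 8 nM) added to emitted samples after integration. A master
seed is expanded via `SeedSequence.spawn` into one substream per cell
from which that cell's parameter draws and noise are taken in a fixed
order, so populations are bit-reproducible independent of iteration
order, and noisy/noiseless "twin" populations share identical parameter
draws.

**What the generator does not emulate.** No ER/mitochondrial compartment
dynamics beyond the phenomenological release pulse, no NCX/SERCA terms,
no near-membrane gradients, no photobleaching or baseline drift, no
Ca²⁺-dependent channel inactivation. Passing recovery tests therefore
demonstrates correctness of the estimators under these idealised
conditions, not robustness to every artefact of real recordings.

## Per-cell metrics

* **Baseline**: mean over the pre-Tg Ca²⁺-free segment (≥ 3 samples).
* **Peak**: maximum restricted to the re-addition segment, so the Tg
  store-release transient is never mistaken for SOCE; ties break to the
  earliest time.
* **Plateau**: mean over samples in `[t_removal − 25 s, t_removal)` —
  closed left, open right, no interpolation, so results are reproducible
  at coarse sampling.
* **Retained fraction**: Plateau/Peak per cell. Population summaries
  average per-cell fractions; a ratio of population means is a different
  (and biased) quantity, and the test suite pins the distinction on a
  constructed counterexample.
* Peaks are reported raw by default; `subtract_baseline=True` reports
  both quantities (and their ratio) relative to baseline.
* **QC**: cells with `peak − baseline` below 3× a noise-sd estimate
  (median over cells of `std(diff(baseline))/√2`, or a user-supplied
  value) are flagged `non_responder` and excluded from population
  statistics; a zero peak leaves the retained fraction undefined.

## Efflux kinetics

Lab conventions for "efflux rate" vary (initial slope, fitted amplitude
over τ, maximal derivative), so both estimators are implemented and every
estimate records which method produced it:

* **In the presence of Ca²⁺ₒ** (`rate_with_cao`): magnitude of the
  steepest negative slope between peak and removal, after a 3-sample
  moving average (derivative-noise control at 2-s sampling; window
  configurable). 0 if the trace never decreases; windows with < 5 samples
  are flagged and skipped.
* **After removal** (`rate_post_removal`, τ): least-squares fit of
  `C(t) = C_∞ + (C₀ − C_∞)e^{−(t−t₀)/τ}` with `C_∞ ≥ 0` constrained,
  initial guesses from first/last samples, tolerances 1e−8. The rate is
  the initial-slope magnitude `(C₀ − C_∞)/τ`. Fitted amplitudes below 3×
  the residual RMSE are treated as flat (τ undefined, flagged);
  non-convergence falls back to the steepest-slope estimator with τ
  absent. The underlying Hill decay is not exactly exponential, so R²
  degrades for very fast decays; τ remains a useful comparative summary
  because noisy fits track their noiseless twins to a few percent.

**Iso-cell binning.** Extrusion depends steeply on [Ca²⁺]ᵢ, so rates are
compared only between cells at matched concentration: cells are assigned
to left-closed 50-nM bins (0–1000 nM by default, configurable) of their
peak (paired with `rate_with_cao`) or plateau (paired with
`rate_post_removal`). Out-of-range cells are counted, never silently
dropped. Per bin and population the table reports n, mean and SEM; the
two-group decision scheme runs per bin only when both populations have
≥ 10 cells there — sparse bins are reported `untested` rather than
over-interpreted.

## Statistics

* Two groups: Shapiro–Wilk on each group at α = 0.05; Student t-test
  (unpaired, two-tailed, pooled variance) only when both groups pass
  *and* both have n ≥ 8 — below that the normality test is uninformative
  and the Mann–Whitney U branch is forced. The result records which
  branch fired.
* ≥ 3 groups: classical one-way ANOVA when all groups pass Shapiro–Wilk
  and Levene's test at α = 0.05, else Kruskal–Wallis (tie-corrected H,
  chi-square p with k−1 df; a Monte-Carlo permutation p is available for
  tiny samples). Totally tied data is flagged degenerate instead of
  erroring. No post-hoc correction is applied by default; pairwise Dunn
  tests with Holm adjustment are available explicitly.
* Stars use strict thresholds: `*** p<0.001, ** p<0.01, * p<0.05`.
* Pooled single cells are not independent replicates; for SOCE parameters
  the pipeline therefore tests per-experiment means (each experiment is
  one dot). Per-cell testing remains available through the same functions
  — iso-bin comparisons use cells, as bins subsample experiments.
* qPCR: `2^−ΔCq` relative expression and `2^−ΔΔCq` fold changes, with
  gene/reference identity enforced.
* Dual-luciferase: per-well firefly/renilla ratio → divide by the mean
  control ratio → per-condition mean ± SEM over normalised replicate
  ratios. This order is fixed and documented because alternatives
  (normalising condition means) propagate error differently.

## Cytometry

Rectangular threshold gates with strict positivity (`intensity >
threshold`) replace hand-drawn polygons, making gating deterministic and
testable. Compartments follow the standard two-marker definitions
(N: CD62L⁺CD45RO⁻, CM: CD62L⁺CD45RO⁺, EM: CD62L⁻CD45RO⁺,
EMRA: CD62L⁻CD45RO⁻; CCR7 may replace CD62L). The synthetic generator
draws compartments multinomially at target frequencies and intensities
from well-separated log-normal negative/positive modes (medians 100 and
2000 a.u., log-sd 0.5, threshold 500), i.e. post-compensation bimodal
distributions; no spillover or biexponential transform is modelled, and
FCS parsing is out of scope (events travel as CSV). Condition comparisons
run the two-group scheme per compartment on replicate-level frequency
tables (≥ 3 experiments per condition); an omnibus across compartments is
deliberately not the default, since the scientific question is
per-compartment.

## Problem sizes and determinism

Default study conditions: 100–250 cells per experiment (pipeline default
150 × 6 experiments × 2 populations), protocol 60/240/300/120 s with 1 mM
re-addition. Recovery and discrimination checks use 200–500 cells per
population; null calibration of the decision scheme uses 1000 replicates.
The acceptance script scales the pipeline-reproducibility run to 3 × 40
cells per population, which exercises every stage while keeping the
double run brief. Every stochastic step is seeded; pipeline outputs are
bit-identical across runs with the same seed (fixed CSV float format,
`%.10g`).

## Known limitations

* The exponential τ is a phenomenological summary of a non-exponential
  (Hill) decay; comparisons across populations are meaningful, absolute τ
  values depend on the window.
* The steepest-slope estimator is max-biased under noise (the maximum of
  a noisy derivative); the bias is common to all populations compared
  under equal noise, so directional comparisons are unaffected.
* Euler integration with 0.1-s substeps is accurate to ~0.2% at the
  plateau for default parameters; stiff parameter regimes (very large
  `v_max` with small `pump_tau_down`) would need smaller substeps.
* The statistics module implements the decision scheme as specified
  rather than a modern hierarchical treatment of cells-within-donors;
  pooled-cell p-values should be read accordingly.
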
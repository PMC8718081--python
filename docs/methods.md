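# Methods

## Kinetic model and its assumptions

A protein (or nucleic-acid) pool is modelled with zero-order synthesis and
first-order degradation, dP/dt = k_syn − k_deg·P, solved in closed form as
P(t) = P0·e^(−k_deg·t) + P_eq·(1 − e^(−k_deg·t)) with P_eq = k_syn/k_deg.
Assumptions, in decreasing order of consequence:

- **Step label.** The precursor is treated as fully enriched at E\* from
  t = 0 (bolus + enriched drinking water is designed to reach the body-water
  plateau within hours of a multi-day study). Whether new protein tracks the
  instantaneous or averaged body water during the first hours is not
  identifiable from a single terminal sample; the step assumption is the
  package's modelling choice, and `plateau_body_water` offers a
  time-weighted-mean alternative when a body-water series exists.
- **Single well-mixed pool.** No precursor–product delay compartments, no
  amino-acid recycling correction. Recycling makes the apparent E\* too low
  and thus inflates f; with ~5 % body water and 7 days this is a
  second-order effect but is not modelled.
- **Constant rates over the interval.** k_syn and k_deg are the *average*
  rates over the labelling window; the single-terminal-point design cannot
  resolve time variation within it.
- **Old protein decays first-order**, so unlabelled survivors are
  P_t(1 − f) = P0·e^(−k_deg·t). This is what makes the inversion exact:
  k_deg = −(1/t)·ln[(1 − f)·(P_t/P0)], then P_eq from the trajectory closed
  form and k_syn = k_deg·P_eq. The non-steady FSR, (100/t)(1/P0)[P0 −
  P_t(1−f)], equals (100/t)(1 − e^(−k_deg·t)) for model-consistent inputs.

Time is in days throughout; rates are %/day (FSR, FBR) or mass/day (k_syn).

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `t` | days | 7 | the labelling window of the emulated design |
| `body_water_plateau` | mole fraction | 0.05 | 5 %-of-body-water bolus + 8 % drinking water plateau |
| `n_sites` (alanine/ribose/deoxyribose) | count | 4 / 5 / 7 | common exchangeable-H counts for D₂O work; configurable because labs differ |
| `plateau_method` | — | `last` | terminal plasma distillation is the usual single sample |
| `p0_policy` | — | `paired_sham` | in a unilateral design the contralateral sham terminal mass is the least-bad P0 proxy; `nonsurgical_mean` and `table` are switches |
| pool `mode` | — | nonsteady (myofibrillar, collagen), steady (RNA, DNA) | nucleic-acid content is typically unchanged; overridable per pool |
| ROUT `q`, `rout_pools` | % | 1.0, collagen | outliers in collagen rates usually trace to assay failures on small tissue remnants |

## Degenerate inputs and numerical choices

- **k_deg = 0** is an explicit branch (P grows linearly, M = k_syn·t), not a
  limit: fully inhibited degradation occurs (denervated collagen). In the
  inverse direction, a log argument (1−f)(P_t/P0) ≥ 1 − 1e-12 selects this
  branch; the estimate is clamped to 0 and flagged `kdeg_clamped_zero`
  unless the observation is trivially static (f = 0, P_t = P0). In the
  branch, k_syn is estimated from labelled accrual f·P_t/t — exact when the
  true k_deg is 0 — and P_eq is NaN (no finite equilibrium).
- **f ≥ 1** (product more enriched than precursor) is physically impossible
  under the model: rates become NaN with flag `fraction_exceeds_one`; the
  value is never silently clipped.
- **Steady mode** substitutes P_t := P0, flags `steady_assumed`, and takes
  the steady reduction FSR_nss = FSR_ss as an explicit branch so the
  identity is exact in floating point (the general expression differs by
  ~1e-16 relative).
- `KineticParams` enforces P_eq = k_syn/k_deg to 1e-12 relative; the closed
  forms are verified against a DOP853 integration of the ODE at rtol 1e-11
  to 1e-8 relative over t ∈ [0, 28] days.
- Paired t tests on identical samples return (t = 0, p = 1) with a warning;
  a constant non-zero difference returns (±inf, 0) with a warning — batch
  runs proceed rather than abort.

## ROUT specialisation

ROUT is defined for robust nonlinear regression. Applied to scalar rate
values the fitted "model" is a constant, so the robust fit degenerates to
the median, with scale from the RSDR (68.27th percentile of absolute
residuals × n/(n−1), one parameter consumed). Each point's |residual|/RSDR
is converted to a two-tailed t(n−1) p-value and outliers are declared by
Benjamini–Hochberg FDR control at rate Q. On outlier-free normal data at
Q = 1 % the procedure removes more than ⌈Q·n⌉+1 points in <1 % of seeds
(test-pinned). In paired comparisons, removing an animal removes its pair.

No multiple-testing correction is applied across metrics by default (the
emulated analysis reported none); the comparisons table carries raw p-values.

The normality screen uses the Lilliefors-corrected KS test (KS against a
normal with sample mean/sd, with the p-value calibrated for the estimated
parameters); it is advisory only.

## What the simulator emulates — and what it does not

`simulate_study` draws per-animal truths log-normally around group means
(rates are positive and right-skewed): denervated k_deg 0.050/day and k_syn
2.44 mg/day; sham and non-surgical limbs at steady state (k_syn tied to
k_deg·P0) with k_deg 0.019 and 0.023/day; animal masses 174 mg (surgical
pairs, shared by both limbs) and 162 mg (controls). Between-animal CVs
(rates 0.20, pair mass 0.30, control mass 0.07) are calibrated so simulated
SEMs match the reported SEMs' order of magnitude (e.g. k_deg 0.050 ± 0.003
at n = 14); the true between-animal CVs are not recoverable from published
summaries. Measurement noise is multiplicative Gaussian — 2 % CV on
enrichments (GC-MS-like) and masses — which keeps values positive at
realistic levels. The sham limb's *measured* terminal mass serves as the
denervated limb's P0 proxy, so sham noise propagates into denervated
estimates exactly as in a real unilateral analysis.

`simulate_collagen_arm` sets denervated collagen k_deg = 0 with positive
synthesis (content rises); `simulate_crossover_effect` rebuilds the sham
group from the non-surgical truth with turnover suppressed by a given
fraction — a crossover effect of unilateral surgery on the contralateral
limb — which makes the denervation deficit comparator-dependent.

Not emulated: body-water pharmacokinetics beyond a plateau, raw mass
spectra and natural-abundance correction (inputs are excess enrichments),
histology, multi-timepoint designs. Passing tests therefore demonstrate
correct inversion and calibrated statistics *under the model's own
assumptions*, not robustness to precursor delay, recycling, or assay
systematics in real data.

Randomness uses NumPy's PCG64 (`default_rng`), so a seed reproduces tables
bit-for-bit across platforms.

## Problem sizes used in checks

The deterministic worked example is three mean-level observations. The
zero-noise recovery check uses 25 surgical pairs + 5 controls (55
observations); the stochastic calibration uses the emulated design (14
pairs + 5 controls) across 100 seeds, where group-mean k_deg and k_syn bias
stays under 5 % and mean ± 2·SEM covers the realized truth in ≥ 90 % of
seeds.

## Known limitations and open choices

- The myofibrillar pool proxy is whole-muscle wet mass; the collagen proxy
  is hydroxyproline-based, with both concentration-only and mass-scaled
  modes implemented because the right choice depends on the question
  (collagen density vs whole-muscle collagen).
- FBR is defined strictly as 100·k_deg. Mean-level arithmetic on group
  means differs slightly from averaging per-animal estimates (e.g. 2.42 vs
  2.44 mg/day for denervated k_syn); summaries are therefore always
  computed per animal and the mean-level path is kept only as a worked
  example.
- Whether denervated-vs-non-surgical contrasts should be paired is
  design-dependent (different n); the pipeline pairs only the sham
  comparator and uses unpaired t for non-surgical.
- The contralateral sham limb is itself affected by unilateral surgery
  (crossover); both comparators are reported and the run report carries the
  caveat.
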
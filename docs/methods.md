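# Methods

## Model structure

A cohort of metastatic NSCLC patients enters progression-free (PF) on
first-line therapy and moves through a three-state discrete-time Markov
model (PF → progressive disease (PD) → death) in 6-week cycles. The cycle
length matches the dosing grid shared by the regimens (ipilimumab every 6
weeks, platinum doublets every 3 weeks). No death is allowed without prior
progression and no background (other-cause) mortality is modeled; both are
deliberate structural simplifications, and the second is known to omit
roughly the ~6% of deaths attributable to comorbidity in this population.
Cohort math is fractional (expectations), so results are invariant to the
nominal cohort size used for reporting.

The simulation runs to cohort extinction — the first cycle where
PF + PD < 1e−4 — or a hard cap of 40 years, whichever comes first. These
two constants define "lifetime horizon" here; both are settings fields.

## Survival inputs

Trial survival enters as digitized Kaplan-Meier step curves: survival
probabilities read at grid times (weeks) with numbers-at-risk tables.
Within the digitized range, per-cycle transition probabilities use the
step curve directly; beyond it, a Weibull S(t) = exp(−(t/λ)^γ) fitted to
the curve extrapolates to lifetime. The composite curve rescales the
Weibull tail to be continuous at the switch time (the last digitized
point, configurable); a raw unrescaled tail can jump at the seam, which
would inject a spurious one-cycle transition probability.

**Fitting.** With an at-risk table, per-interval event counts are
reconstructed as d_k = n_k (1 − S_{k+1}/S_k) and the remainder of the
at-risk decline treated as censoring at the interval midpoint; the Weibull
maximizes the resulting interval-censored likelihood (Nelder-Mead on log
parameters, initialized from weighted least squares on the
log(−log S) / log t linearization). Without an at-risk table the WLS
linearization is the fit. Counts may be fractional; intervals with nobody
at risk are excluded. On noiselessly digitized 1000-patient curves over a
one-year window the fit recovers generating parameters to ~1e−3 in shape;
accuracy degrades if the digitization grid extends deep into the tail
where rounded at-risk counts hit zero.

**Hazard ratios.** The combination arm has no digitized curves of its own;
it is the proportional-hazards transform S'(t) = S(t)^HR of the
chemotherapy reference (PFS HR 0.68, OS HR 0.66), applied to whichever
representation — step curve or Weibull tail — is active at t. For a pure
Weibull this is exactly a scale change λ' = λ·HR^(−1/γ).

## Calibration

PF→PD probabilities come from the PFS curve; PD→death probabilities are
back-solved per cycle: p_death(k) = (OS_model(k) − OS_target(k+1)) / m_PD(k),
with PD membership m_PD evolved by forward simulation. Patients progressing
in cycle k become eligible for death from cycle k+1. Numerical policy:

- If m_PD ≤ 1e−9 while the target demands a drop (typically the very first
  cycles, where the target OS declines before anyone has progressed — a
  structural impossibility under the no-death-in-PF assumption), the drop
  is deferred; because the next requirement is measured from *modeled*
  survival, the deficit carries forward and is absorbed as soon as the PD
  pool exists. Deferred cycles are recorded on the schedule.
- Requirements outside [0, 1] are clamped and recorded rather than raised:
  digitization noise can transiently demand impossible drops.

The calibration report states both the overall maximum |OS_model −
OS_target| and the maximum excluding boundaries immediately downstream of
a clamped/deferred cycle. On clean synthetic inputs the latter is at
machine precision; the former is dominated by the first-cycle deferral
(≈ the target's first-cycle OS drop, a few percent for Weibull targets
with shape near 1).

## Valuation

Accruals per cycle use start-of-cycle occupancy: ΔLY = (PF+PD)·Δt,
ΔQALY = (PF·u_PF + PD·u_PD)·Δt, Δcost = PF·c_PF(k) + PD·c_PD(k). Utilities:
0.79 (PF, chemotherapy), 0.88 (PF, both N+I-containing arms — including the
chemotherapy-co-administration cycle), 0.72 (PD). Death accrues nothing.

- **Half-cycle correction**: weight ½ on the first and last accrual cycle
  (classic correction; a single-cycle run gets total weight ½). Applied to
  costs and effects alike; a settings flag disables it.
- **Discounting**: (1+r)^(−t/52.18) at cycle start times, r = 3%/year,
  weeks-per-year = 365.25/7 ≈ 52.18 (also used for LY conversion).
- **One-time entry cost**: the expected grade 3/4 adverse-event management
  cost (Σ incidence × cost over the arm's AE profile) is charged once at
  t = 0, undiscounted and outside the half-cycle weighting — it is an event
  cost, not an occupancy cost.

## Costing

All costs are 2020 USD per-6-week inputs. PF: first-line drug cost while
within the duration cap (chemotherapy 2 cycles = 12 weeks; N+I 17 cycles
≈ 2 years, from ⌊2·52.18/6⌋; the combination arm's two 3-week chemotherapy
cycles fall inside model cycle 0) plus one administration fee per cycle
containing an infusion. First-line chemotherapy is histology-weighted
(28% squamous): pemetrexed+carboplatin for non-squamous in all arms;
gemcitabine+carboplatin (chemotherapy arm) or paclitaxel+carboplatin
(combination arm) for squamous. PD: expected second-line drug +
administration cost weighted by the arm's observed second-line mix
(docetaxel after chemotherapy; platinum doublet by histology after the
immunotherapy arms; nivolumab for second-line immunotherapy; oral
erlotinib, no administration fee, for targeted therapy), plus best
supportive care for all PD occupancy. Second-line therapy is modeled as
continuing through PD occupancy; a cap flag exists. BSC is PD-only by
default (flag to extend to PF). Drug wastage is ignored. The Calvert
formula and body-metric dosing helpers document how per-cycle prices arise
from unit prices; per-cycle prices themselves are configuration inputs.

## Economics

ICER = Δcost/ΔQALY on unrounded model outputs (published tables round
LY/QALY to 2 decimals, so ratios recomputed from printed values will not
reproduce printed ICERs exactly). QALY differences below 1e−9 are treated
as equal effectiveness ("undefined" ICER marker, not an exception).
Frontier construction: sort by cost, drop strictly dominated strategies
(≥ cost, ≤ QALY, one strict), then repeatedly drop extendedly dominated
ones (segment ICER not below the following segment's) until frontier
ICERs strictly increase. The frontier equals the set of strategies that
uniquely maximize net monetary benefit for some willingness-to-pay
(property-tested against an NMB-sweep oracle).

## Sensitivity analysis

Each uncertain parameter carries its published distribution: Beta for
probabilities/utilities, Gamma for costs (all with shape 100, i.e. 10%
CV), a two-count Dirichlet (≡ Beta) for histology. PSA redraws every
parameter independently each iteration; parameters shared between arms
(the N+I PF utility) occupy one configuration slot and are drawn once,
keeping arms correlated. Iteration i uses substream (seed, i) of the
PCG64 generator, making runs reproducible and order-independent.
Transition probabilities stay at base during PSA — they are
curve-derived, time-dependent quantities published without a sampling
distribution; survival-parameter uncertainty (e.g. multivariate normal on
Weibull parameters) is a possible extension, off by default. CEAC
probabilities split ties equally, so they sum to one at every threshold.
One-way DSA reruns the base case at each parameter's published range ends
and ranks by ICER swing.

Internal consistency of the published parameter table is validated: each
baseline should match its family's analytic mean to 0.5% relative or to
its printed precision. Six combination-arm rows (standardized
adverse-event incidences and second-line proportions) fail both by up to
~7% relative; the validator reports them and the base case uses the
printed baselines as given.

## Synthetic data

The generator emulates what curve digitization yields: per-arm Weibull
ground truth for PFS and OS evaluated on a 6-week grid out to 204 weeks
(the ~4-year follow-up typical of these trials), with at-risk tables, in
two modes — "exact" (grid evaluation with at_risk = round(N·S); an
arbitrarily precise digitization) and "sampled" (event/censor times
simulated per patient, Kaplan-Meier estimated via lifelines, digitized at
the grid). Optional digitization error adds truncated Gaussian noise
(default SD 0.005, ±3σ) to survival values, re-monotonized by cumulative
minimum; OS is kept at or above PFS pointwise by construction. Default
scenario shapes put median OS around 14–17 months and median PFS around
5 months with a flatter late hazard on the immunotherapy arm (shape < 1),
qualitatively echoing checkpoint-inhibitor trial curves; enrollment
defaults to 583 per arm. Scenario presets exist for PD-L1 ≥ 1% / < 1%
subgroups and for an alternative chemotherapy reference with slightly
better OS.

What the synthetic data does *not* emulate: correlated PFS/OS within
patients, non-proportional hazards between arms, delayed separation of
immunotherapy curves, informative censoring, or real digitization
artifacts (pixel quantization, risk-table misalignment). Passing tests
therefore demonstrate correctness of the machinery — fitting,
calibration, accounting, comparison — under the model's own assumptions,
not fidelity of any particular published ICER, which depends on curves
that exist only as figures.

## Problem sizes and numerics

Default runs use 347 cycles (40 years), 500 PSA iterations, and
1000-patient synthetic digitizations; the engine-validation
microsimulation uses 100,000 patients. Optimizer: Nelder-Mead,
xatol 1e−10. Calibration tolerance for "well calibrated" defaults to
1e−6 on the unclamped maximum deviation. Interval probabilities at
exhausted support (S(t) ≤ 1e−300) return 1 by convention; the absorbing
death state makes the choice immaterial downstream.

## Known limitations

- The structural no-death-without-progression assumption makes the first
  cycles of any real OS target unreachable exactly (deferred, as above).
- Extended-dominance removal assumes strategies are comparable on QALYs
  alone; ties beyond the 1e−9 tolerance break by name for determinism.
- The unit-price derivation behind per-6-week drug costs (fee schedules,
  CPI inflation) is out of scope; costs are inputs.
- Subgroup scenarios are qualitative presets, not re-digitized subgroup
  curves.
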
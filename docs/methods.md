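# Methods

This note documents the statistical procedures implemented in `licksupp`,
the assumptions behind them, the synthetic-data model used to exercise
them, and the numerical choices made where the design was genuinely open.

## From lick events to percent time drinking

The raw input is a timestamped event stream per subject-session: lick
contacts (onset + duration, duration 0 for point events such as single
beam breaks) and stimulus markers (`tone_on`/`tone_off`,
`shock_on`/`shock_off`).  The canonical file format is a plain CSV with
header `subject,session,time_s,event,value`, times in seconds on the
session clock; `session_start`/`session_end` rows delimit the session.
Hardware vendors' proprietary formats should be converted to this dialect
upstream.

**Bout rule.**  Optical lickometers emit individual contacts, not
"drinking time", so a lick→time rule is required and is *not* dictated by
the paradigm itself.  We adopt the standard licking-microstructure
convention: a point contact occupies `point_dwell = 0.1 s`, and successive
contacts separated by at most `bout_gap = 1.0 s` (next onset minus
previous end) merge into one drinking bout.  Both constants are
configurable; analyses of real data should check sensitivity to them.
Rodents lick at 6–7 Hz within bouts, so any gap threshold between ~0.5 s
and ~2 s yields near-identical bout sets.

**Windows.**  All intervals are half-open `[a, b)` in seconds, so any
partition of a window adds exactly (the suite verifies duration-weighted
additivity to 1e-9).  Per tone trial *i*:

* `cs` = `[tone_on, tone_off)` (20 s by default),
* `pre_cs` = the 20 s before `tone_on` (clipped at session start and
  flagged if the first tone comes early),
* `iti` = from the previous `tone_off` (session start for trial 1, so the
  pre-tone context period is represented) to `tone_on`.

Percent time drinking in a window is `100 × |bouts ∩ window| / |window|`.
Percentages are kept on the 0–100 scale throughout.

## Behavioral measures

The **Kamin suppression ratio** `cs / (cs + pre_cs)` is computed and
exported for completeness but is not used by the ANOVA stages: with
unrestricted ("pleasure") drinking, many trials have no drinking in either
window, where the ratio is undefined (the implementation returns an
explicit undefined sentinel, never a division-by-zero fault).  All
inference runs on percent-time units, which also keeps drinking and
freezing on the same scale.

**Drink trajectories.**  Each subject's ITI drinking is concatenated
across tone-alone sessions in chronological order; the maximum of the
series and the 1-based index of its *first* attainment ("latency to reach
its personal maximum", in cumulative tone presentations) summarise
recovery of drinking.  Ties resolve to the first attainment, matching the
meaning of a latency.

**Group assignment.**  Cage mates must share a group (they share a home
cage and a test schedule), and the groups should be matched on baseline
drinking motivation.  The matching objective is stated by the paradigm but
the algorithm is not; we sort cages by mean baseline drinking percent,
pair neighbours, and randomly allocate each pair's two cages to the two
groups.  On sorted means, adjacent pairing minimises the within-pair gap
over all perfect matchings (verified against exhaustive enumeration in the
tests), and the random within-pair flip leaves the expected group
difference at zero.

## Split-plot ANOVA with two-stage permutation p-values

**Model.**  Designs have one between-subjects factor (Group) and 1–3
fully-crossed within-subjects factors with exactly one observation per
subject per within-cell.  The classical univariate split-plot
decomposition is used:

* Group is tested against the Subject-within-Group stratum,
  `df = (g−1, g(s−1))`;
* each within effect U (and Group × U) is tested against
  U × Subject-within-Group, `df = (∏(ℓ−1), g(s−1)∏(ℓ−1))`.

Balanced complete data are required and validated (no imputation); with
balance, Type I/II/III sums of squares coincide and everything is computed
from cell means via Möbius inclusion–exclusion over margins, which makes
one full ANOVA cheap enough to recompute thousands of times.  The engine
is verified against (a) a from-scratch loop implementation of the textbook
formulas, (b) R's `aov` with `Error(subject/(w1*w2))` strata, and
(c) statsmodels `AnovaRM` for purely within designs.  No sphericity
correction is applied: the reported df are the uncorrected products above,
and robustness is delegated to the permutation p-values.

**Why permutation.**  Suppression data are mostly exact zeros with long
right tails, grossly violating the normality behind the theoretical F
distribution.  Each ANOVA therefore also reports an empirical p-value per
effect, built from a two-stage permutation of the data:

1. *within subjects*: each subject's observations are uniformly reshuffled
   across all of that subject's within-cells (unrestricted within-subject
   permutation — no finer exchangeability restriction is imposed);
2. *between subjects*: group labels are reshuffled across subjects,
   preserving group sizes.

This maintains the within/between variance partition: each subject's
multiset of values survives intact into every permuted dataset.  One
shared stream of `n` permuted datasets (default `n = 5000`) feeds the null
F distributions of *all* effects of one ANOVA simultaneously, exactly as
one reshuffled dataset would be re-analysed in full.  The empirical
p-value is `(r + 1)/(n + 1)`, `r` = permutations with `F* ≥ F` (ties count
toward `r`), so p is never 0 and its floor is `1/(n + 1)`.  The whole
resampling is driven by one recorded seed; reruns are bit-identical.

Caveat: stage 1 treats a subject's observations as exchangeable across all
within-cells, which is exact under the global null but only approximate
for a given effect when other within effects are large.  The type-I
simulations in the suite (exchangeable Gaussian nulls) confirm nominal
calibration in that regime; with strong nuisance within effects the
empirical p for a specific effect should be read as a robustness check
alongside the theoretical one, not a guaranteed exact test.

**Simple effects.**  When an interaction involving Group reaches empirical
`p ≤ 0.05` (configurable), group differences are tested within each level
combination of the interacting within factors: pooled-variance two-sample
t with its two-sided theoretical p, plus an empirical p from group-label
permutations using `|t|` and the same `(r+1)/(n+1)` rule.  Pooled variance
(not Welch) is used here because the simple effects accompany an ANOVA
whose stratum already assumes homogeneous within-cell variance; Welch's
test is used for the stand-alone baseline group comparisons, and paired t
for within-subject baseline contrasts (infinite-t sentinel with a warning
if the paired differences are constant).

**Exact enumeration.**  For tiny designs the full two-stage permutation
group (all per-subject cell orderings × all group splits) can be
enumerated; `exact_permutation_p` does so and is used to validate the
sampler.  Mathematically tied F values can differ by float roundoff across
enumerated configurations, so ties are counted with a 1e-9 relative
tolerance.

## LOESS extinction curves and bootstrap bands

Extinction curves are LOESS smooths of percent time drinking against trial
number within each Group × Session × window cell, evaluated on the integer
trial grid 1..18.  The smoother is the canonical formulation: at each grid
point, a weighted polynomial of degree 2 is fitted to the nearest
`span = 0.75` fraction of observations under tricube weights (bandwidth =
distance to the q-th nearest observation, `q = ⌈span·n⌉`).  Both
parameters are configurable; the implementation agrees with R's
`stats::loess` (`surface="direct"`) to 4+ digits and reproduces constants
and straight lines exactly.

Uncertainty is a pointwise percentile bootstrap: the cell's observation
triples are resampled with replacement (same size), the curve refitted on
each of `n_boot = 5000` resamples, and the 2.5–97.5 percentile envelope
forms the 95% band.  Resampling with replacement is implemented as
multinomial frequency weights, which makes a refit a cheap reweighted
smooth; the tests verify the weighted fast path equals literal refitting
on the expanded resample.  A resample can concentrate on too few distinct
trials to smooth; such refits are skipped and the effective count is
reported (`n_boot_effective`).  Observation-level resampling treats
trials × subjects within a cell as exchangeable draws; a subject-level
(cluster) bootstrap is available via `resample="subject"` for data with
strong within-subject dependence, but the observation bootstrap is the
default.  Percentile bands are envelopes of refits: the point fit is not
guaranteed to lie inside them, but `lower ≤ upper` always holds.
Mid-grid pointwise coverage of a known truth measures ~92–94% at the 95%
nominal level in the suite's simulations — the usual mild undercoverage of
percentile bootstrap bands.

## The synthetic cohort generator

The generator exists so every stage is testable end-to-end with known
ground truth; it is not fitted to any dataset.

**Drinking** is an alternating renewal process: exponential waits to bout
onset at rate `λ_on` (default 0.04 /s), exponential bout lengths with mean
`μ_b` (default 8 s).  The stationary drinking fraction is
`λμ/(1 + λμ) ≈ 24%` — a realistic unrestricted baseline.  Conditioned
fear multiplies the *initiation* rate (not bout length — the simplest
mechanism that yields window-specific percent-time suppression):

| factor | default | role |
|---|---|---|
| `phi_cs` | 0.1 | during the tone CS |
| `phi_post` | 0.05 | contextual suppression after acquisition |
| `phi_session` | 4.0 | per-later-extinction-session recovery |
| `phi_trial` | 1.15 | per-trial within-session recovery |
| `phi_reinstate` | 0.1 | context at the post-reinstatement test |
| `phi_group` | 1.0 | RetExt multiplier (1 = no drinking group effect) |
| `restrict_boost` | 2.0 | first habituation session (24-h water deprivation) |
| `recovery_cap` | 2.5 | ceiling on the context multiplier |

`recovery_cap > 1` lets well-habituated rats exceed their unrestricted
baseline late in extinction, so the subject's maximum ITI drinking
typically surpasses even the water-restricted rate — the pattern such
experiments report.  Per-subject lognormal random effects on `λ_on`
(sd 0.5 on the log scale) create individual differences; cage-wise
matching then operates on simulated baseline sessions exactly as it would
on real ones.  Short windows over this process give exact zeros with long
tails — in a default cohort ~85–90% of first-session CS windows are 0 —
which is precisely the distributional pathology the permutation machinery
exists for.  The schedule mirrors the standard paradigm: 3 baseline
sessions (10 min), 2 extinction sessions of 18 tone-alone trials (20-s CS,
ITI uniform 1–5 min, 4-min lead-in), and three 3-tone memory sessions
(post-acquisition, post-extinction, post-reinstatement).  A within-session
satiety decline is representable by setting `phi_trial < 1`; it is off by
default.

**Freezing** is generated directly as percent time: `100·expit(z)` with
`z ~ Normal(m(session, window), s)` on the logit scale (`s = 1.5` gives the
wide individual spread typical of conditioned freezing), quantised at the
scoring resolution (default 0.1%) so floor-level values collapse to exact
zeros.  A `freeze_group_shift` subtracts from the RetExt group's logit
mean for tone freezing at the post-reinstatement test — the
retrieval+extinction effect — and is 0 unless requested.

**What passing tests do and do not show.**  The generator reproduces the
zero inflation, floor effects, bout structure, schedule and design of real
cohorts, so green tests demonstrate that the pipeline is correct and
calibrated *under these mechanisms*.  Real data add features the generator
omits — serial dependence between neighbouring trials beyond the smooth
recovery trend, lick-rate drift, circadian effects, occasional equipment
dropouts — so calibration on synthetic cohorts is evidence of, not proof
of, calibration on any particular real dataset.

## Pipeline and problem sizes

`run_full_analysis` is a pure function of (input data, config, seed): one
master seed spawns independent child seeds for simulation, each ANOVA's
permutation stream, simple effects, and each bootstrap band, so reruns are
byte-identical and stages are insensitive to each other's draw counts.
The three ANOVA designs are fixed in config: extinction CS analysis uses
the `pre_cs` and `cs` windows (2 × 2 × 18 × 2), the contextual analysis
uses the `iti` window (2 × 2 × 18), and the memory analyses use only the
first trial of each memory session (2 × 3 × 2) — the first trial is the
only pure read-out of the preceding training phase.  Trial is categorical
(17 numerator df), not a continuous covariate.

Default resample sizes follow the paradigm's convention (`n_perms = 5000`,
`n_boot = 5000`).  The verification suite and `scripts/acceptance.py` use
smaller, stated sizes chosen to keep each check's Monte Carlo error well
inside its tolerance: 10,000 permutations against exact enumeration
(tolerance 0.02), 500 null simulations at 199 permutations for type-I
calibration (binomial 99% CI), 100–200 cohorts at 199 permutations for
power, and 100–200 simulations at 300–500 bootstrap refits for band
coverage (tolerance ±4 points).

## Known limitations

* Balanced complete designs only; no mixed-model (REML) fallback for
  missing cells, by design — incomplete cells raise immediately.
* No formal between-curve tests; the bands support visual comparison and
  the ANOVAs carry the inference.
* No explicit zero-inflation model (hurdle/two-part); the permutation
  p-values are the robustness device.
* Stage-1 exchangeability is approximate per-effect when other within
  effects are large (see above).
* The event dialect assumes one clock per session; cross-session clock
  drift is out of scope.
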
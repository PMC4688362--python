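# licksupp

Analysis toolkit for **conditioned suppression of reward seeking** — measuring
fear in rodents not by how much they freeze, but by how much a fear cue
disrupts voluntary ("pleasure") drinking of a sweet solution.

In this paradigm a rat with free access to a 10% sucrose bottle is fear
conditioned to a 20-s tone (CS).  Fear then shows up as a *reduction in
percent time drinking* during the tone relative to matched context windows.
`licksupp` provides the full analysis chain for such experiments:

1. **Lickometer event processing** — parse timestamped lick/stimulus event
   logs, merge licks into drinking bouts, intersect them with per-trial
   windows (CS = tone period; pre-CS = the 20 s before tone onset; ITI = the
   whole inter-tone interval), and report percent time drinking per window.
2. **Behavioral measures** — the Kamin suppression ratio
   `CS / (CS + pre-CS)` (0.5 = no suppression, 0 = total suppression,
   undefined when both are 0), per-subject maximum ITI drinking and the
   latency (in cumulative tone presentations) to reach it, and cage-wise
   matched assignment of subjects to groups balanced on baseline drinking.
3. **Balanced split-plot ANOVA with permutation p-values** — the univariate
   mixed repeated-measures decomposition (between factor Group; within
   factors Session, Trial, CS window), each within effect tested against its
   interaction with Subject-within-Group.  Because suppression data are
   heavily zero-inflated, every theoretical F-based p-value is paired with an
   **empirical p-value** from a two-stage permutation scheme: observations
   are reshuffled within each subject, then group labels between subjects,
   the full ANOVA is recomputed for each of the `n` permuted datasets, and
   `p = (r + 1)/(n + 1)` where `r` counts permutations with `F* ≥ F`.
   Permutation simple effects of group, paired and Welch t-tests round out
   the inference toolbox.
4. **LOESS extinction curves with bootstrap bands** — degree-2 local
   polynomial smooths of drinking vs. trial per Group × Session × window
   cell, with pointwise 2.5–97.5 percentile bands over bootstrap refits.
5. **Synthetic cohorts** — drinking as an alternating renewal process
   (exponential bout initiation modulated multiplicatively by fear factors,
   exponential bout lengths), which reproduces the field's signature data
   pathologies: exact zeros in short windows, long right tails, and floor
   effects.  Freezing is logit-normal per condition.  Every pipeline stage
   is testable end-to-end with known ground truth and no external data.

## Worked example

Simulate a full cohort (2 groups × 16 rats, cage-paired; 2 extinction
sessions × 18 tone trials; 3 memory-test sessions) and run the complete
analysis:

```python
from licksupp import RunConfig, run_full_analysis

bundle = run_full_analysis(RunConfig(seed=42, n_perms=999, n_boot=500))
print(bundle.anova_ltm_drink.summary())
```

```
Mixed repeated-measures ANOVA: value
Between: group ('Ext', 'RetExt')
Within: session (3 levels), window (2 levels)
Permutations: 999 (two-stage), seed=1129302213

              Effect    df        F Theoretical p Empirical p
               Group 1, 30   0.8131         0.374       0.351
             Session 2, 60    71.57      1.29e-16       0.001
                  CS 1, 30     21.9      5.74e-05       0.001
     Group × Session 2, 60    1.074         0.348        0.37
          Group × CS 1, 30 0.006954         0.934        0.93
        Session × CS 2, 60    18.51      5.49e-07       0.001
Group × Session × CS 2, 60   0.1088         0.897       0.914
```

This is the long-term-memory drinking analysis (first trial of each memory
session, Group × Session × CS).  The strong Session and CS main effects and
the Session × CS interaction say that drinking is suppressed by the tone,
that suppression changes across post-acquisition / post-extinction /
post-reinstatement tests, and that tone and context recover differently —
while the null Group effects say the two experimental groups do not differ
in drinking.  Note the theoretical and empirical p-values agree closely
even though the underlying drinking data are mostly zeros with long tails;
the permutation p-values are the ones to trust when that skew is extreme.
The df column carries the design structure: with 32 subjects in 2 groups,
between-stratum tests have (1, 30) df, and a 3-level within factor gives
(2, 60).

The same bundle carries the extinction ANOVAs (2 × 2 × 18 × 2 CS-vs-pre-CS
and 2 × 2 × 18 ITI), baseline drinking-motivation t-tests, permutation
simple effects of group (triggered when a Group interaction reaches
empirical p ≤ 0.05), and the LOESS band table:

```
window session group  trial      fit    lower    upper
   iti    EXT1   Ext    1.0 1.603728 0.478970 3.008363
   iti    EXT1   Ext    2.0 2.227190 1.407549 3.307340
   ...
```

— the fitted extinction curve for ITI drinking in session 1 of the Ext
group, rising from near-complete suppression, with its 95% bootstrap band.

A command-line interface wraps the same stages:

```bash
licksupp simulate --seed 1 --out-dir runs/sim      # event logs + freezing + truth
licksupp process runs/sim/events.csv --out measures.csv
licksupp analyze --seed 1 --n-perms 999 --out-dir runs/tables
licksupp report  --seed 1 --out-dir runs/report    # tables + curve figure
```

## Layout

| module | contents |
|---|---|
| `licksupp.events` | event-log CSV dialect, `SessionLog`, trial windows, bout merging, percent time |
| `licksupp.metrics` | tidy behavior table, Kamin ratio, drink trajectories, cage-wise matching |
| `licksupp.anova` | `MixedAnova` model → `MixedAnovaResults`, two-stage permutation, simple effects, t-tests |
| `licksupp.loess` | `ExtinctionCurve` model → `LoessBand`, degree-2 LOESS, bootstrap bands |
| `licksupp.simulate` | `SimParams`, `CohortSpec`, renewal-process drinking, logit-normal freezing, null data |
| `licksupp.pipeline` | `RunConfig`, `run_full_analysis` → `ReportBundle` |
| `licksupp.cli` | `licksupp` command-line entry point |

See `docs/methods.md` for the statistical model, the simulator's
assumptions, and the numerical choices.
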
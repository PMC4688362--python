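"""Synthetic cohorts with the statistical structure of conditioned
suppression experiments.

Nothing here is fitted to data; the generator exists so that every pipeline
stage (event parsing, windowing, ANOVA, curves) can be exercised end-to-end
with known ground truth.

Drinking is an alternating renewal process: a rat in the chamber starts a
drinking bout after an exponential wait (rate ``lambda_on`` per second,
modulated by the current suppression state) and drinks for an exponential
bout length (mean ``mu_bout`` seconds).  Conditioned fear acts
multiplicatively on the bout *initiation* rate: a tone CS multiplies it by
``phi_cs``, contextual fear right after acquisition by ``phi_post``, with
recovery across sessions (``phi_session`` per later session) and across
trials within a session (``phi_trial`` per trial).  Short windows over such
a process give exactly the zero-inflated, long-tailed percent-time
distributions these experiments produce: a window with no bout is an exact
zero, and bout structure creates occasional large values.

Freezing is generated directly as percent time from a logit-normal model
per condition (large between-subject variance emulates the wide individual
differences typical of conditioned freezing), quantised at the scoring
resolution so that floor values collapse to exact zeros.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from licksupp.events import (
    SessionLog,
    ValidationError,
    drink_intervals,
    percent_time,
)
from licksupp.metrics import cagewise_group_assignment

__all__ = [
    "SimParams",
    "SessionSchedule",
    "CohortSpec",
    "simulate_session_log",
    "simulate_cohort",
    "simulate_freezing",
    "null_dataset",
]

#: Memory-test sessions and the contextual suppression state they probe.
LTM_SESSIONS = ("LTM_POST_ACQ", "LTM_POST_EXT", "LTM_POST_REINST")


@dataclass(frozen=True)
class SimParams:
    """Generating parameters of the drinking/freezing processes.

    Drinking (alternating renewal):

    lambda_on
        Baseline bout-initiation rate in a safe context, bouts/s.  The
        stationary drinking fraction is ``lambda_on * mu_bout /
        (1 + lambda_on * mu_bout)``; the defaults give ~24% baseline
        drinking, a realistic unrestricted ("pleasure drinking") level.
    mu_bout
        Mean drinking-bout length, seconds.
    phi_cs
        Multiplier on the initiation rate while the tone CS is on.
    phi_post
        Contextual suppression right after fear acquisition (start of the
        first extinction session).
    phi_session
        Between-session contextual recovery: the context multiplier gains
        this factor per later extinction session.
    phi_trial
        Within-session recovery: per-trial multiplier on the context rate.
    recovery_cap
        Upper bound on the context multiplier.  Values above 1 let
        well-habituated rats drink at higher-than-baseline rates late in
        extinction, as seen in unrestricted drinking after extensive
        chamber exposure.
    phi_group
        Multiplier applied to the RetExt group in the sessions named by
        ``group_affects`` (1 = no group effect, the usual outcome for
        drinking).
    phi_reinstate
        Contextual suppression at the post-reinstatement memory test.
    subject_sd
        SD of the lognormal subject random effect on ``lambda_on``.
    restrict_boost
        Multiplier on the initiation rate in the first baseline session,
        emulating the 24-h water deprivation that precedes it (later
        baseline sessions are unrestricted).

    Freezing (logit-normal percent time):

    freeze_logit_means
        ``(session_id, window) -> mean`` on the logit scale; missing keys
        fall back to ``freeze_default_logit``.
    freeze_logit_sd
        SD on the logit scale (shared), controlling individual differences.
    freeze_resolution
        Scoring resolution in percent; values are quantised to it, so very
        low freezing collapses to exact 0 (the floor effect).  ``None``
        keeps the continuous values.
    """

    lambda_on: float = 0.04
    mu_bout: float = 8.0
    phi_cs: float = 0.1
    phi_post: float = 0.05
    phi_session: float = 4.0
    phi_trial: float = 1.15
    recovery_cap: float = 2.5
    phi_group: float = 1.0
    phi_reinstate: float = 0.1
    subject_sd: float = 0.5
    restrict_boost: float = 2.0
    group_affects: tuple[str, ...] = ()
    freeze_logit_means: Mapping[tuple[str, str], float] = field(default_factory=dict)
    freeze_default_logit: float = 0.0
    freeze_logit_sd: float = 1.5
    freeze_resolution: float | None = 0.1

    def __post_init__(self):
        for name in ("lambda_on", "phi_cs", "phi_post", "phi_session",
                     "phi_trial", "phi_group", "phi_reinstate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.mu_bout <= 0:
            raise ValidationError("mu_bout must be > 0")

    def context_rate_factor(self, session_id: str, session_ordinal: int,
                            trial_index: int, group: str) -> float:
        """Multiplier on lambda_on for the context (no tone) in the given
        session/trial; suppression never recovers above baseline (capped
        at 1)."""
        if session_id.startswith("BASE") or session_id == "COND":
            # water restriction only precedes the first habituation session
            return self.restrict_boost if session_id == "BASE1" else 1.0
        elif session_id.startswith("EXT"):
            f = (self.phi_post * self.phi_session ** session_ordinal
                 * self.phi_trial ** (trial_index - 1))
        elif session_id == "LTM_POST_ACQ":
            f = self.phi_post
        elif session_id == "LTM_POST_EXT":
            # contextual fear has extinguished to the level reached at the
            # end of the standard 2-session x 18-trial schedule
            f = self.phi_post * self.phi_session ** 2 * self.phi_trial ** 17
        elif session_id == "LTM_POST_REINST":
            f = self.phi_reinstate
        else:
            f = 1.0
        if group == "RetExt" and session_id in self.group_affects:
            f *= self.phi_group
        return min(f, self.recovery_cap)


@dataclass(frozen=True)
class SessionSchedule:
    """Tone schedule of one session: id, length, and tone-on times."""

    session_id: str
    duration: float
    tone_onsets: tuple[float, ...] = ()
    cs_duration: float = 20.0

    def __post_init__(self):
        times = self.tone_onsets
        if any(b - a < self.cs_duration for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"{self.session_id}: overlapping tones in schedule")
        if times and (times[0] < 0 or times[-1] + self.cs_duration > self.duration):
            raise ValidationError(f"{self.session_id}: tone outside session")


def _extinction_schedule(session_id: str, n_tones: int, rng: np.random.Generator,
                         cs_duration: float = 20.0, lead_in: float = 240.0,
                         iti_range: tuple[float, float] = (60.0, 300.0)
                         ) -> SessionSchedule:
    """Tone-alone schedule: a pre-tone context period, then ``n_tones``
    tones separated by ITIs drawn uniformly from ``iti_range``."""
    onsets = []
    t = lead_in
    for i in range(n_tones):
        onsets.append(t)
        t += cs_duration + float(rng.uniform(*iti_range))
    return SessionSchedule(session_id, duration=t + 60.0,
                           tone_onsets=tuple(onsets), cs_duration=cs_duration)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout and experimental schedule.

    Defaults mirror the standard paradigm: 2 groups x 16 subjects housed 2
    per cage (cage mates share a group), 3 baseline (habituation) sessions,
    2 extinction sessions of 18 tone-alone trials (20-s CS, ITI uniform
    1-5 min), and 3 memory-test sessions of 3 tones each (post-acquisition,
    post-extinction, post-reinstatement).
    """

    n_per_group: int = 16
    subjects_per_cage: int = 2
    n_baseline_sessions: int = 3
    baseline_duration: float = 600.0
    n_ext_sessions: int = 2
    tones_per_ext_session: int = 18
    tones_per_ltm_session: int = 3
    cs_duration: float = 20.0
    iti_range: tuple[float, float] = (60.0, 300.0)
    lead_in: float = 240.0
    groups: tuple[str, str] = ("Ext", "RetExt")

    def __post_init__(self):
        n_subj = 2 * self.n_per_group
        if n_subj % self.subjects_per_cage:
            raise ValidationError("cohort size must fill cages exactly")
        if (n_subj // self.subjects_per_cage) % 2:
            raise ValidationError("need an even number of cages for matching")

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_per_group

    @property
    def ext_sessions(self) -> list[str]:
        return [f"EXT{i + 1}" for i in range(self.n_ext_sessions)]

    def subject_ids(self) -> list[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_subjects)]

    def cages(self) -> dict[str, list[str]]:
        ids = self.subject_ids()
        k = self.subjects_per_cage
        return {f"C{i // k + 1:02d}": ids[i:i + k] for i in range(0, len(ids), k)}


# ---------------------------------------------------------------------------
# Renewal-process session simulation
# ---------------------------------------------------------------------------

def _piecewise_rates(params: SimParams, schedule: SessionSchedule,
                     session_ordinal: int, group: str, lam0: float):
    """Breakpoints and bout-initiation rates across the session.

    The context factor is per-trial (a tone's trial governs the ITI that
    precedes the next tone); the CS factor multiplies during tones.
    """
    times = [0.0]
    rates = []
    onsets = schedule.tone_onsets
    for i, on in enumerate(onsets, start=1):
        ctx = params.context_rate_factor(schedule.session_id, session_ordinal,
                                         i, group)
        rates.append(lam0 * ctx)          # context before tone i
        times.append(on)
        rates.append(lam0 * ctx * params.phi_cs)  # during tone i
        times.append(on + schedule.cs_duration)
    n_tr = max(len(onsets), 1)
    ctx = params.context_rate_factor(schedule.session_id, session_ordinal,
                                     n_tr, group)
    rates.append(lam0 * ctx)              # tail after last tone
    times.append(schedule.duration)
    return np.asarray(times), np.asarray(rates)


def _sample_onset(t: float, times: np.ndarray, rates: np.ndarray,
                  rng: np.random.Generator) -> float:
    """Next bout onset after t for a piecewise-constant rate; inf if none
    occurs before the session ends (inversion of the cumulative hazard)."""
    target = rng.exponential()
    acc = 0.0
    for i in range(len(rates)):
        a, b = max(times[i], t), times[i + 1]
        if b <= a:
            continue
        lam = rates[i]
        seg = lam * (b - a)
        if acc + seg >= target and lam > 0:
            return a + (target - acc) / lam
        acc += seg
    return math.inf


def simulate_session_log(params: SimParams, schedule: SessionSchedule,
                         rng: np.random.Generator,
                         subject_id: str = "R01", group: str = "Ext",
                         session_ordinal: int = 0,
                         lambda_on: float | None = None) -> SessionLog:
    """Simulate one subject-session as a lick event log.

    Drinking alternates exponential waits (rate = ``lambda_on`` x active
    suppression factors, piecewise-constant over the session) with
    exponential bouts (mean ``mu_bout``); each bout is emitted as a single
    contact interval.  Stimulus events come from the schedule.
    """
    lam0 = params.lambda_on if lambda_on is None else lambda_on
    times, rates = _piecewise_rates(params, schedule, session_ordinal, group,
                                    lam0)
    licks: list[tuple[float, float]] = []
    t = 0.0
    while True:
        onset = _sample_onset(t, times, rates, rng)
        if onset >= schedule.duration:
            break
        dur = rng.exponential(params.mu_bout)
        dur = min(dur, schedule.duration - onset)
        if dur > 0:
            licks.append((onset, dur))
        t = onset + dur
    stimulus = []
    for on in schedule.tone_onsets:
        stimulus.append((on, "tone_on"))
        stimulus.append((on + schedule.cs_duration, "tone_off"))
    log = SessionLog(subject_id=subject_id, session_id=schedule.session_id,
                     session_start=0.0, session_end=schedule.duration,
                     lick_events=licks, stimulus_events=stimulus)
    return log.validate()


# ---------------------------------------------------------------------------
# Freezing and null-data generators
# ---------------------------------------------------------------------------

def simulate_freezing(params: SimParams, design: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Percent-time-freezing draws for each row of ``design``.

    ``design`` needs columns ``subject, session, trial, window``.  Each
    value is ``100 * expit(z)`` with ``z ~ Normal(mean(session, window),
    sd)`` on the logit scale, then quantised at ``freeze_resolution`` so
    that floor-level freezing becomes an exact 0.
    """
    need = ["subject", "session", "trial", "window"]
    missing = [c for c in need if c not in design.columns]
    if missing:
        raise ValidationError(f"design missing column(s) {missing}")
    out = design[need].copy()
    means = np.array([
        params.freeze_logit_means.get((s, w), params.freeze_default_logit)
        for s, w in zip(out["session"], out["window"])
    ])
    z = rng.normal(means, params.freeze_logit_sd)
    vals = 100.0 * expit(z)
    if params.freeze_resolution:
        vals = np.round(vals / params.freeze_resolution) * params.freeze_resolution
    out["value"] = np.clip(vals, 0.0, 100.0)
    return out


def null_dataset(design: pd.DataFrame, rng: np.random.Generator,
                 mean: float = 0.0, sd: float = 1.0) -> pd.DataFrame:
    """I.i.d. Gaussian responses with no effect of any factor; for type-I
    error and theoretical/empirical agreement studies."""
    out = design.copy()
    out["value"] = rng.normal(mean, sd, size=len(design))
    return out


def balanced_design(subjects: Sequence[str], groups: Mapping[str, str],
                    within: Mapping[str, Sequence]) -> pd.DataFrame:
    """Long skeleton with one row per subject x within-cell."""
    import itertools as it
    rows = []
    names = list(within.keys())
    for subj in subjects:
        for combo in it.product(*within.values()):
            rows.append((subj, groups[subj], *combo))
    return pd.DataFrame(rows, columns=["subject", "group", *names])


# ---------------------------------------------------------------------------
# Full-cohort simulation
# ---------------------------------------------------------------------------

def _default_freeze_means() -> dict[tuple[str, str], float]:
    """Logit means emulating memory-test freezing: high tone freezing after
    acquisition with wide individual spread, partial extinction, and
    reinstatement that the RetExt group resists (the group effect is added
    in simulate_cohort via a logit shift)."""
    return {
        ("LTM_POST_ACQ", "cs"): 1.5,
        ("LTM_POST_ACQ", "pre_cs"): 0.0,
        ("LTM_POST_EXT", "cs"): 0.5,
        ("LTM_POST_EXT", "pre_cs"): -2.0,
        ("LTM_POST_REINST", "cs"): 1.0,
        ("LTM_POST_REINST", "pre_cs"): -0.5,
    }


def simulate_cohort(spec: CohortSpec, params: SimParams,
                    rng: np.random.Generator,
                    freeze_group_shift: float = 0.0
                    ) -> tuple[list[SessionLog], pd.DataFrame, dict]:
    """Simulate a full cohort: session logs, freezing table, and the truth.

    Per-subject lognormal random effects on ``lambda_on`` create individual
    differences in drinking motivation.  Baseline sessions are simulated
    first; cage-wise matching on the observed baseline drinking then assigns
    groups (so the assignment sees the same data a real experiment would),
    and the remaining sessions are simulated with group-dependent factors.

    ``freeze_group_shift`` is subtracted from the RetExt group's freezing
    logit mean at the post-reinstatement test (the retrieval + extinction
    effect on freezing; 0 = no group effect).

    Returns ``(logs, freezing, truth)`` where ``truth`` records every
    generating parameter and the assignment.
    """
    subjects = spec.subject_ids()
    cages = spec.cages()
    lam = params.lambda_on * np.exp(
        rng.normal(0.0, params.subject_sd, size=len(subjects)))
    lam_by_subj = dict(zip(subjects, lam))

    logs: list[SessionLog] = []
    # baseline sessions (no tones) drive the cage matching
    base_pct: dict[str, list[float]] = {s: [] for s in subjects}
    for b in range(spec.n_baseline_sessions):
        sched = SessionSchedule(f"BASE{b + 1}", duration=spec.baseline_duration)
        for subj in subjects:
            log = simulate_session_log(params, sched, rng, subject_id=subj,
                                       lambda_on=lam_by_subj[subj])
            logs.append(log)
            # no tones -> no trial windows; measure over the whole session
            iv = drink_intervals(log.lick_events)
            base_pct[subj].append(percent_time(iv, (0.0, spec.baseline_duration)))
    subj_base = {s: float(np.mean(v)) for s, v in base_pct.items()}
    cage_means = {c: float(np.mean([subj_base[s] for s in members]))
                  for c, members in cages.items()}
    assignment = cagewise_group_assignment(cage_means, cages, rng,
                                           groups=spec.groups)

    # extinction + memory sessions
    for k, sid in enumerate(spec.ext_sessions):
        sched = _extinction_schedule(sid, spec.tones_per_ext_session, rng,
                                     spec.cs_duration, spec.lead_in,
                                     spec.iti_range)
        for subj in subjects:
            logs.append(simulate_session_log(
                params, sched, rng, subject_id=subj, group=assignment[subj],
                session_ordinal=k, lambda_on=lam_by_subj[subj]))
    for sid in LTM_SESSIONS:
        sched = _extinction_schedule(sid, spec.tones_per_ltm_session, rng,
                                     spec.cs_duration, spec.lead_in,
                                     spec.iti_range)
        for subj in subjects:
            logs.append(simulate_session_log(
                params, sched, rng, subject_id=subj, group=assignment[subj],
                lambda_on=lam_by_subj[subj]))

    # freezing at the memory tests
    design = balanced_design(
        subjects, assignment,
        {"session": LTM_SESSIONS,
         "trial": list(range(1, spec.tones_per_ltm_session + 1)),
         "window": ("pre_cs", "cs")})
    means = dict(params.freeze_logit_means) or _default_freeze_means()
    fparams = SimParams(**{**asdict(params), "freeze_logit_means": means})
    freezing = simulate_freezing(fparams, design, rng)
    if freeze_group_shift:
        # tone-CS-specific retrieval + extinction effect at reinstatement
        mask = ((design["group"] == spec.groups[1])
                & (design["session"] == "LTM_POST_REINST")
                & (design["window"] == "cs"))
        shifted = simulate_freezing(
            SimParams(**{**asdict(fparams), "freeze_logit_means": {
                k: v - freeze_group_shift for k, v in means.items()}}),
            design[mask], rng)
        freezing.loc[mask, "value"] = shifted["value"].to_numpy()

    truth = {
        "params": {k: (dict([(f"{a}|{b}", v) for (a, b), v in val.items()])
                       if isinstance(val, dict) else val)
                   for k, val in asdict(params).items()},
        "assignment": assignment,
        "lambda_by_subject": {s: float(l) for s, l in lam_by_subj.items()},
        "baseline_pct": subj_base,
        "freeze_group_shift": freeze_group_shift,
    }
    return logs, freezing, truth
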
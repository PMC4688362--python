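"""Behavioral summary measures and group assignment.

Builds the tidy subject x session x trial x window measurement table that
drives the ANOVAs and curves, and implements the classic conditioned
suppression measures:

* the Kamin suppression ratio ``cs / (cs + pre_cs)`` (0.5 = no suppression,
  0 = total suppression; undefined when there was no responding in either
  window),
* each subject's maximum ITI drinking rate across extinction and the
  latency (in cumulative tone-alone presentations) to first reach it, and
* cage-wise matched assignment of subjects to the two experimental groups,
  balancing baseline drinking motivation while keeping cage mates together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from licksupp.events import (
    SessionLog,
    ValidationError,
    derive_trial_windows,
    drink_intervals,
    percent_time,
)

__all__ = [
    "SuppressionRatio",
    "DrinkTrajectory",
    "BEHAVIOR_COLUMNS",
    "session_drink_rows",
    "build_behavior_table",
    "kamin_ratio",
    "max_iti_drinking",
    "drink_trajectories",
    "cagewise_group_assignment",
    "validate_behavior_table",
]

#: Canonical column order of the tidy measurement table.
BEHAVIOR_COLUMNS = ["subject", "group", "session", "trial", "window",
                    "measure", "value"]

WINDOWS = ("cs", "pre_cs", "iti")


@dataclass(frozen=True)
class SuppressionRatio:
    """Kamin conditioned suppression ratio for one trial.

    ``ratio`` is ``cs / (cs + pre_cs)`` in ``[0, 1]``, or ``None`` when both
    inputs are zero (no responding in either window: the ratio is undefined,
    never a division-by-zero fault).
    """

    cs_responding: float
    pre_cs_responding: float
    ratio: float | None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def kamin_ratio(cs_pct: float, pre_cs_pct: float) -> SuppressionRatio:
    """Conditioned suppression ratio ``cs / (cs + pre_cs)``.

    Inputs are percent-time values in [0, 100].  Scale-invariant: only the
    ratio of CS to pre-CS responding matters.
    """
    for name, v in (("cs_pct", cs_pct), ("pre_cs_pct", pre_cs_pct)):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"{name}={v} outside [0, 100]")
    total = cs_pct + pre_cs_pct
    if total == 0.0:
        return SuppressionRatio(cs_pct, pre_cs_pct, None)
    return SuppressionRatio(cs_pct, pre_cs_pct, cs_pct / total)


def max_iti_drinking(series: Sequence[float]) -> tuple[float, int]:
    """Maximum of a per-trial ITI drinking series and the 1-based index of
    its first attainment (the latency in cumulative tone presentations)."""
    if len(series) == 0:
        raise ValidationError("empty drinking series")
    arr = np.asarray(series, dtype=float)
    idx = int(np.argmax(arr))  # first attainment: argmax takes the first max
    return float(arr[idx]), idx + 1


@dataclass(frozen=True)
class DrinkTrajectory:
    """A subject's per-trial ITI drinking in cumulative tone-presentation
    order, with its maximum and the latency (tones) to first reach it."""

    subject_id: str
    series: tuple[float, ...]
    max_iti_pct: float
    latency_tones: int


def drink_trajectories(table: pd.DataFrame,
                       session_order: Sequence[str]) -> list[DrinkTrajectory]:
    """Per-subject ITI drinking trajectories across tone-alone sessions.

    ``table`` is the tidy measurement table; ``session_order`` gives the
    chronological order of the sessions whose ITI values form the series
    (trials are indexed by cumulative tone presentations across them).
    """
    sub = table[(table["measure"] == "drink_pct")
                & (table["window"] == "iti")
                & (table["session"].isin(session_order))].copy()
    sub["session"] = pd.Categorical(sub["session"], categories=session_order,
                                    ordered=True)
    out = []
    for subj, rows in sub.groupby("subject", sort=True):
        rows = rows.sort_values(["session", "trial"])
        series = tuple(rows["value"].tolist())
        mx, lat = max_iti_drinking(series)
        out.append(DrinkTrajectory(subject_id=str(subj), series=series,
                                   max_iti_pct=mx, latency_tones=lat))
    return out


def cagewise_group_assignment(
    cage_means: Mapping[str, float],
    cage_members: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
    groups: tuple[str, str] = ("Ext", "RetExt"),
) -> dict[str, str]:
    """Assign subjects to two groups by cage-wise matching on baseline drinking.

    Cages are sorted by mean baseline drinking and consecutive cages paired;
    within each matched pair, one cage (chosen at random) goes to the first
    group and the other to the second.  Cage mates therefore always share a
    group, and the groups end up matched on baseline drinking motivation.

    Parameters
    ----------
    cage_means
        Per-cage mean baseline drink percent.
    cage_members
        Cage id -> subject ids (2 subjects per cage).
    rng
        Seeded generator deciding the within-pair allocation.

    Returns
    -------
    dict mapping subject id -> group label.
    """
    cages = sorted(cage_means)
    if len(cages) % 2 != 0:
        raise ValidationError(f"need an even number of cages, got {len(cages)}")
    if set(cages) != set(cage_members):
        raise ValidationError("cage_means and cage_members disagree on cage ids")
    order = sorted(cages, key=lambda c: (cage_means[c], c))
    assignment: dict[str, str] = {}
    for i in range(0, len(order), 2):
        pair = [order[i], order[i + 1]]
        flip = bool(rng.integers(0, 2))
        labels = (groups[1], groups[0]) if flip else groups
        for cage, label in zip(pair, labels):
            for subject in cage_members[cage]:
                assignment[subject] = label
    return assignment


# ---------------------------------------------------------------------------
# Tidy table construction
# ---------------------------------------------------------------------------

def session_drink_rows(log: SessionLog,
                       pre_cs_len: float = 20.0,
                       bout_gap: float = 1.0,
                       point_dwell: float = 0.1) -> pd.DataFrame:
    """Per-trial percent-time-drinking rows (cs / pre_cs / iti) for one log."""
    log.validate()
    intervals = drink_intervals(log.lick_events, bout_gap=bout_gap,
                                point_dwell=point_dwell)
    rows = []
    windows = derive_trial_windows(log, pre_cs_len=pre_cs_len)
    for tw in windows:
        for window in WINDOWS:
            rows.append((log.subject_id, log.session_id, tw.trial_index, window,
                         "drink_pct", percent_time(intervals, tw.window(window))))
    if not windows:
        # tone-less session (e.g. baseline habituation): the whole session
        # is one context-only interval, reported as trial 1's ITI
        rows.append((log.subject_id, log.session_id, 1, "iti", "drink_pct",
                     percent_time(intervals, (log.session_start,
                                              log.session_end))))
    return pd.DataFrame(rows, columns=["subject", "session", "trial", "window",
                                       "measure", "value"])


def validate_behavior_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check tidy-table invariants: columns, value range, key uniqueness."""
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"behavior table missing column(s) {missing}")
    vals = table["value"].to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 100):
        bad = vals[(vals < 0) | (vals > 100)][0]
        raise ValidationError(f"percent value {bad} outside [0, 100]")
    key = ["subject", "session", "trial", "window", "measure"]
    dup = table.duplicated(subset=key)
    if dup.any():
        first = table.loc[dup.idxmax(), key].tolist()
        raise ValidationError(f"duplicate measurement key {first}")
    return table


def build_behavior_table(
    logs: Iterable[SessionLog],
    freezing: pd.DataFrame | None = None,
    group_map: Mapping[str, str] | None = None,
    pre_cs_len: float = 20.0,
    bout_gap: float = 1.0,
    point_dwell: float = 0.1,
    strict: bool = False,
    expected: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge session logs (drinking) and pre-scored freezing into one tidy table.

    Parameters
    ----------
    logs
        Session logs; each contributes one ``drink_pct`` row per trial-window.
    freezing
        Optional tidy table with columns ``subject, session, trial, window,
        value`` (percent time freezing); it is keyed and range-checked like
        the drinking rows and merged in as ``measure == 'freeze_pct'``.
    group_map
        Subject -> group label; subjects without an entry get ``'unassigned'``.
    strict
        If True, require every key in ``expected`` (columns subject, session,
        trial, window, measure) to be present.
    """
    frames = [session_drink_rows(log, pre_cs_len, bout_gap, point_dwell)
              for log in logs]
    if freezing is not None and len(freezing):
        fz = freezing.copy()
        need = ["subject", "session", "trial", "window", "value"]
        missing = [c for c in need if c not in fz.columns]
        if missing:
            raise ValidationError(f"freezing table missing column(s) {missing}")
        fz = fz[need].copy()
        fz["measure"] = "freeze_pct"
        frames.append(fz)
    frames = [f for f in frames if len(f)]
    if not frames:
        table = pd.DataFrame(columns=BEHAVIOR_COLUMNS)
    else:
        table = pd.concat(frames, ignore_index=True)
    gm = dict(group_map or {})
    table["group"] = table["subject"].map(lambda s: gm.get(s, "unassigned"))
    table = table[BEHAVIOR_COLUMNS]
    validate_behavior_table(table)
    if expected is not None:
        key = ["subject", "session", "trial", "window", "measure"]
        have = set(map(tuple, table[key].itertuples(index=False)))
        want = set(map(tuple, expected[key].itertuples(index=False)))
        absent = sorted(want - have)
        if absent and strict:
            raise ValidationError(
                f"{len(absent)} expected cell(s) missing, first: {absent[0]}"
            )
    return table.sort_values(["measure", "subject", "session", "trial",
                              "window"]).reset_index(drop=True)
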
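"""Lickometer event processing.

This module turns a raw behavioral event stream (lick contacts plus
stimulus on/off markers for one subject-session) into trial-aligned
percent-time-drinking measures.  The conditioning-chamber software exports
timestamped events; here they are read from a documented CSV dialect, licks
are merged into drinking bouts, and each bout set is intersected with the
trial windows that matter for conditioned suppression:

* ``cs``     — the tone period ``[tone_on, tone_off)``,
* ``pre_cs`` — the 20 s immediately preceding tone onset (the contextual
  comparator matched to the CS in duration), and
* ``iti``    — the whole inter-tone interval preceding the tone (for trial 1,
  everything from session start to the first tone).

All intervals are half-open ``[a, b)`` in seconds measured on the session
clock, so partitions of a window add exactly with no double counting.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventLogDialect",
    "IntervalSet",
    "SessionLog",
    "TrialWindows",
    "EventLogError",
    "ParseError",
    "StructuralError",
    "ValidationError",
    "read_session_log",
    "read_session_logs",
    "write_session_logs",
    "derive_trial_windows",
    "drink_intervals",
    "percent_time",
]


class EventLogError(ValueError):
    """Base class for event-log problems."""


class ParseError(EventLogError):
    """A row of the event-log CSV could not be interpreted."""


class StructuralError(EventLogError):
    """Events are individually valid but structurally inconsistent
    (e.g. a tone_off with no preceding tone_on)."""


class ValidationError(EventLogError):
    """A domain invariant is violated (e.g. an event outside session bounds)."""


STIMULUS_KINDS = ("tone_on", "tone_off", "shock_on", "shock_off")
MARKER_KINDS = ("session_start", "session_end")
LICK_KIND = "lick"


@dataclass(frozen=True)
class EventLogDialect:
    """Column and event-name mapping for the event-log CSV.

    The canonical file is UTF-8 CSV with header
    ``subject,session,time_s,event,value``: one row per event, times in
    seconds as decimals on the session clock.  ``event`` is one of
    ``session_start``, ``session_end``, ``lick``, ``tone_on``, ``tone_off``,
    ``shock_on``, ``shock_off``.  For ``lick`` rows, ``value`` is the contact
    duration in seconds (0 or empty for a point event, e.g. a beam-break
    count source); for all other rows ``value`` is ignored and may be empty.
    """

    subject_col: str = "subject"
    session_col: str = "session"
    time_col: str = "time_s"
    event_col: str = "event"
    value_col: str = "value"


@dataclass(frozen=True)
class IntervalSet:
    """Disjoint, sorted, half-open intervals ``[a, b)`` in seconds.

    Used to represent the union of time spent drinking.  Construction via
    :meth:`from_intervals` normalises (sorts and merges touching/overlapping
    pieces) so the invariants always hold.
    """

    starts: np.ndarray
    ends: np.ndarray

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(np.empty(0), np.empty(0))

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[float, float]]) -> "IntervalSet":
        """Build from arbitrary (possibly overlapping) intervals; zero-length
        pieces are dropped."""
        ivs = [(float(a), float(b)) for a, b in intervals if b > a]
        if not ivs:
            return cls.empty()
        ivs.sort()
        merged: list[list[float]] = [list(ivs[0])]
        for a, b in ivs[1:]:
            if a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        arr = np.asarray(merged, dtype=float)
        return cls(arr[:, 0].copy(), arr[:, 1].copy())

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        return iter(zip(self.starts.tolist(), self.ends.tolist()))

    @property
    def total_length(self) -> float:
        return float(np.sum(self.ends - self.starts))

    def intersect_length(self, window: tuple[float, float]) -> float:
        """Total overlap (seconds) of this set with ``[window[0], window[1])``."""
        a, b = float(window[0]), float(window[1])
        if b <= a or len(self) == 0:
            return 0.0
        lo = np.maximum(self.starts, a)
        hi = np.minimum(self.ends, b)
        return float(np.sum(np.clip(hi - lo, 0.0, None)))

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet.from_intervals(list(self) + list(other))


@dataclass
class SessionLog:
    """All timestamped events of one subject-session.

    ``lick_events`` are ``(onset, duration)`` pairs with duration ``>= 0``
    (0 marks a point event such as a single beam break).  ``stimulus_events``
    are ``(time, kind)`` with kind in ``{tone_on, tone_off, shock_on,
    shock_off}``.  :meth:`validate` enforces the session invariants.
    """

    subject_id: str
    session_id: str
    session_start: float
    session_end: float
    lick_events: list[tuple[float, float]] = field(default_factory=list)
    stimulus_events: list[tuple[float, str]] = field(default_factory=list)

    def validate(self) -> "SessionLog":
        if not self.session_end > self.session_start:
            raise ValidationError(
                f"{self.subject_id}/{self.session_id}: session_end "
                f"({self.session_end}) must exceed session_start ({self.session_start})"
            )
        # sub-microsecond slack: serialised timestamps may round by 1 ulp
        eps = 1e-6
        last_onset = -np.inf
        for onset, dur in self.lick_events:
            if dur < 0:
                raise ValidationError(
                    f"{self.subject_id}/{self.session_id}: negative lick duration {dur}"
                )
            if onset < last_onset:
                raise ValidationError(
                    f"{self.subject_id}/{self.session_id}: lick onsets not sorted"
                )
            if (onset < self.session_start - eps
                    or onset + dur > self.session_end + eps):
                raise ValidationError(
                    f"{self.subject_id}/{self.session_id}: lick at {onset} "
                    f"(duration {dur}) outside session bounds"
                )
            last_onset = onset
        tone_state = "off"
        for time, kind in self.stimulus_events:
            if kind not in STIMULUS_KINDS:
                raise ValidationError(
                    f"{self.subject_id}/{self.session_id}: unknown stimulus kind {kind!r}"
                )
            if not (self.session_start - eps <= time <= self.session_end + eps):
                raise ValidationError(
                    f"{self.subject_id}/{self.session_id}: stimulus {kind} at {time} "
                    "outside session bounds"
                )
            if kind == "tone_on":
                if tone_state == "on":
                    raise StructuralError(
                        f"{self.subject_id}/{self.session_id}: tone_on at {time} "
                        "while tone already on"
                    )
                tone_state = "on"
            elif kind == "tone_off":
                if tone_state == "off":
                    raise StructuralError(
                        f"{self.subject_id}/{self.session_id}: tone_off at {time} "
                        "with no preceding tone_on"
                    )
                tone_state = "off"
        if tone_state == "on":
            raise StructuralError(
                f"{self.subject_id}/{self.session_id}: unclosed tone_on at session end"
            )
        return self

    def tone_pairs(self) -> list[tuple[float, float]]:
        """Ordered ``(tone_on, tone_off)`` pairs; one per trial."""
        ons = [t for t, k in self.stimulus_events if k == "tone_on"]
        offs = [t for t, k in self.stimulus_events if k == "tone_off"]
        return list(zip(ons, offs))


@dataclass(frozen=True)
class TrialWindows:
    """The three analysis windows of one trial (half-open, seconds)."""

    trial_index: int  # 1-based
    cs: tuple[float, float]
    pre_cs: tuple[float, float]
    iti: tuple[float, float]
    pre_cs_clipped: bool = False

    def window(self, name: str) -> tuple[float, float]:
        try:
            return {"cs": self.cs, "pre_cs": self.pre_cs, "iti": self.iti}[name]
        except KeyError:
            raise KeyError(f"unknown window {name!r}; expected cs, pre_cs or iti")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _events_frame(path, dialect: EventLogDialect) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    needed = [dialect.subject_col, dialect.session_col, dialect.time_col,
              dialect.event_col, dialect.value_col]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; header is {list(df.columns)}")
    out = df[needed].copy()
    out.columns = ["subject", "session", "time_s", "event", "value"]
    times = pd.to_numeric(out["time_s"], errors="coerce")
    bad = times.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: line {line}: non-numeric time {out['time_s'][bad.idxmax()]!r}")
    out["time_s"] = times
    known = set(STIMULUS_KINDS) | set(MARKER_KINDS) | {LICK_KIND}
    bad = ~out["event"].isin(known)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: line {idx + 2}: unknown event {out['event'].iloc[idx]!r}"
        )
    vals = pd.to_numeric(out["value"].replace("", "0"), errors="coerce")
    bad = vals.isna() & (out["event"] == LICK_KIND)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: line {idx + 2}: non-numeric lick duration "
            f"{out['value'].iloc[idx]!r}"
        )
    out["value"] = vals.fillna(0.0)
    return out


def _log_from_frame(sub: pd.DataFrame, subject: str, session: str,
                    source: str) -> SessionLog:
    starts = sub.loc[sub["event"] == "session_start", "time_s"]
    ends = sub.loc[sub["event"] == "session_end", "time_s"]
    if len(starts) != 1 or len(ends) != 1:
        raise StructuralError(
            f"{source}: {subject}/{session}: expected exactly one session_start "
            f"and one session_end (got {len(starts)} and {len(ends)})"
        )
    licks = sub[sub["event"] == LICK_KIND].sort_values("time_s")
    stims = sub[sub["event"].isin(STIMULUS_KINDS)].sort_values(
        "time_s", kind="stable")
    log = SessionLog(
        subject_id=subject,
        session_id=session,
        session_start=float(starts.iloc[0]),
        session_end=float(ends.iloc[0]),
        lick_events=[(float(t), float(v)) for t, v in
                     zip(licks["time_s"], licks["value"])],
        stimulus_events=[(float(t), str(k)) for t, k in
                         zip(stims["time_s"], stims["event"])],
    )
    return log.validate()


def read_session_log(path, dialect: EventLogDialect | None = None) -> SessionLog:
    """Read one subject-session from an event-log CSV.

    The file must contain exactly one ``(subject, session)`` pair; use
    :func:`read_session_logs` for multi-session files.

    Raises :class:`ParseError` for malformed rows (with the line number),
    :class:`StructuralError` for unpaired tone events, and
    :class:`ValidationError` for events outside session bounds.
    """
    dialect = dialect or EventLogDialect()
    df = _events_frame(path, dialect)
    keys = df[["subject", "session"]].drop_duplicates()
    if len(keys) == 0:
        raise StructuralError(f"{path}: no event rows")
    if len(keys) > 1:
        raise StructuralError(
            f"{path}: expected a single subject-session, found {len(keys)}; "
            "use read_session_logs()"
        )
    subject, session = keys.iloc[0]
    return _log_from_frame(df, str(subject), str(session), str(path))


def read_session_logs(path, dialect: EventLogDialect | None = None) -> list[SessionLog]:
    """Read every subject-session from an event-log CSV (any number of
    ``(subject, session)`` blocks; rows need not be contiguous)."""
    dialect = dialect or EventLogDialect()
    df = _events_frame(path, dialect)
    logs = []
    for (subject, session), sub in df.groupby(["subject", "session"], sort=True):
        logs.append(_log_from_frame(sub, str(subject), str(session), str(path)))
    return logs


def write_session_logs(logs: Sequence[SessionLog], path,
                       dialect: EventLogDialect | None = None) -> None:
    """Write session logs to the canonical event-log CSV dialect."""
    dialect = dialect or EventLogDialect()
    rows = []
    for log in logs:
        rows.append((log.subject_id, log.session_id, log.session_start,
                     "session_start", ""))
        for onset, dur in log.lick_events:
            rows.append((log.subject_id, log.session_id, onset, LICK_KIND, dur))
        for time, kind in log.stimulus_events:
            rows.append((log.subject_id, log.session_id, time, kind, ""))
        rows.append((log.subject_id, log.session_id, log.session_end,
                     "session_end", ""))
    df = pd.DataFrame(rows, columns=[dialect.subject_col, dialect.session_col,
                                     dialect.time_col, dialect.event_col,
                                     dialect.value_col])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Windowing and percent time
# ---------------------------------------------------------------------------

def derive_trial_windows(log: SessionLog,
                         pre_cs_len: float = 20.0) -> list[TrialWindows]:
    """One :class:`TrialWindows` per tone pair, in presentation order.

    The ITI of trial 1 starts at ``session_start`` (so the pre-tone context
    period is represented); later ITIs start at the previous ``tone_off``.
    A pre-CS window that would extend before ``session_start`` is clipped
    and flagged.  A session with no tones yields an empty list.
    """
    pairs = log.tone_pairs()
    windows: list[TrialWindows] = []
    prev_off = log.session_start
    for i, (on, off) in enumerate(pairs, start=1):
        pre_start = on - pre_cs_len
        clipped = pre_start < log.session_start
        if clipped:
            pre_start = log.session_start
        windows.append(TrialWindows(
            trial_index=i,
            cs=(on, off),
            pre_cs=(pre_start, on),
            iti=(prev_off, on),
            pre_cs_clipped=clipped,
        ))
        prev_off = off
    return windows


def drink_intervals(lick_events: Sequence[tuple[float, float]],
                    bout_gap: float = 1.0,
                    point_dwell: float = 0.1) -> IntervalSet:
    """Convert lick events into drinking-bout intervals.

    Point events (duration 0) are expanded to ``[onset, onset + point_dwell)``;
    successive events separated by a gap of at most ``bout_gap`` seconds
    (next onset minus previous end) are merged into a single bout.  This is
    the usual licking-microstructure convention: licks within a second of
    each other belong to one drinking bout.
    """
    if bout_gap <= 0:
        raise ValidationError(f"bout_gap must be > 0, got {bout_gap}")
    ivs = []
    last = -np.inf
    for onset, dur in lick_events:
        if dur < 0:
            raise ValidationError(f"negative lick duration {dur} at {onset}")
        if onset < last:
            raise ValidationError("lick events must be sorted by onset")
        last = onset
        ivs.append((onset, onset + (dur if dur > 0 else point_dwell)))
    if not ivs:
        return IntervalSet.empty()
    merged: list[list[float]] = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a - merged[-1][1] <= bout_gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return IntervalSet.from_intervals(merged)


def percent_time(intervals: IntervalSet, window: tuple[float, float]) -> float:
    """Percent of ``[window[0], window[1])`` covered by ``intervals`` (0-100)."""
    a, b = float(window[0]), float(window[1])
    if not b > a:
        raise ValidationError(f"window [{a}, {b}) has non-positive length")
    return 100.0 * intervals.intersect_length((a, b)) / (b - a)
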
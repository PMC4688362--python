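"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results from first principles
(brute force, explicit textbook formulas, exhaustive enumeration) so they
stay independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20151223)


def brute_force_union_length(intervals, window=None):
    """O(n * grid) union length by fine-grained scanning of interval
    endpoints: sums lengths of elementary segments covered by >= 1 interval."""
    if not intervals:
        return 0.0
    pts = sorted({p for a, b in intervals for p in (a, b)}
                 | ({window[0], window[1]} if window else set()))
    total = 0.0
    for lo, hi in zip(pts, pts[1:]):
        if window is not None:
            lo2, hi2 = max(lo, window[0]), min(hi, window[1])
            if hi2 <= lo2:
                continue
            lo, hi = lo2, hi2
        mid = (lo + hi) / 2
        if any(a <= mid < b for a, b in intervals):
            total += hi - lo
    return total


def naive_split_plot(df, subject="subject", between="group", within=(),
                     dv="value"):
    """Split-plot ANOVA straight from the defining cell-mean formulas.

    Returns ``{effect_cols_tuple: (ss, df_num, df_den, F)}`` keyed by the
    tuple of factor columns in the effect (between first).  Written with
    plain loops over marginal means; no code shared with the library.
    """
    factors = [between, *within]
    grand = df[dv].mean()
    N = len(df)

    def raw_ss(cols):
        if not cols:
            return 0.0
        means = df.groupby(list(cols), observed=True)[dv].mean()
        counts = df.groupby(list(cols), observed=True)[dv].size()
        return float((counts * (means - grand) ** 2).sum())

    def effect_ss(cols):
        cols = list(cols)
        total = 0.0
        for r in range(len(cols) + 1):
            for sub in itertools.combinations(cols, r):
                total += (-1) ** (len(cols) - len(sub)) * raw_ss(sub)
        return total

    levels = {f: df[f].nunique() for f in factors}
    n_subj = df[subject].nunique()
    g = levels[between]
    s = n_subj // g

    # error strata
    ss_subj = raw_ss([subject]) - raw_ss([between])
    df_subj = g * (s - 1)
    err = {(): (ss_subj, df_subj)}
    for r in range(1, len(within) + 1):
        for cols in itertools.combinations(within, r):
            ss_int = 0.0
            for r2 in range(len(cols) + 1):
                for sub in itertools.combinations(cols, r2):
                    sign = (-1) ** (len(cols) - len(sub))
                    ss_int += sign * (raw_ss([subject, *sub])
                                      - raw_ss([between, *sub]))
            dfe = df_subj * int(np.prod([levels[c] - 1 for c in cols]))
            err[cols] = (ss_int, dfe)

    out = {}
    for r in range(1, len(factors) + 1):
        for cols in itertools.combinations(factors, r):
            wset = tuple(c for c in cols if c != between)
            ss = effect_ss(cols)
            dfn = int(np.prod([levels[c] - 1 for c in cols]))
            ss_e, dfe = err[wset]
            F = (ss / dfn) / (ss_e / dfe)
            out[cols] = (ss, dfn, dfe, F)
    return out


def make_balanced(subjects_per_group, within_levels, rng, groups=("A", "B"),
                  values=None):
    """Small balanced long-format dataset for ANOVA tests."""
    subs = []
    gmap = {}
    for gi, gname in enumerate(groups):
        for i in range(subjects_per_group):
            sid = f"{gname}{i}"
            subs.append(sid)
            gmap[sid] = gname
    names = list(within_levels.keys())
    rows = []
    for sid in subs:
        for combo in itertools.product(*within_levels.values()):
            rows.append((sid, gmap[sid], *combo))
    df = pd.DataFrame(rows, columns=["subject", "group", *names])
    df["value"] = (values if values is not None
                   else rng.normal(size=len(df)))
    return df
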
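"""LOESS extinction curves with bootstrap confidence bands.

Extinction of conditioned suppression is visualised by smoothing drinking
(or freezing) percent-time against trial number within each
Group x Session x window cell.  The smoother is classic LOESS: at each
evaluation point a weighted polynomial (degree 2 by default) is fitted to
the nearest ``span`` fraction of the data under tricube weights, and the
local fit's value at that point is the smoothed estimate.

Uncertainty is expressed as a pointwise percentile bootstrap band: the
cell's observations are resampled with replacement (same size), the curve
is refitted on each resample, and the 2.5-97.5 percentile envelope over the
refits forms the 95% band.  A subject-level (cluster) bootstrap is offered
as an option for data with strong within-subject dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from licksupp.events import ValidationError

__all__ = ["LoessBand", "ExtinctionCurve", "loess_fit", "bootstrap_band"]


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w ** 3


def _local_fit(x: np.ndarray, y: np.ndarray, x0: float, h: float,
               degree: int, counts: np.ndarray | None = None) -> float:
    """Weighted polynomial fit around x0 with bandwidth h; returns the
    fitted value at x0.  ``counts`` are optional frequency weights."""
    d = np.abs(x - x0)
    if h <= 0:  # all in-window points coincide with x0
        sel = d == 0
        w = np.ones(int(sel.sum()))
        if counts is not None:
            w = counts[sel]
        return float(np.average(y[sel], weights=w))
    w = _tricube(d / h)
    if counts is not None:
        w = w * counts
    sel = w > 0
    xs, ys, ws = x[sel] - x0, y[sel], w[sel]
    deg = min(degree, len(np.unique(xs)) - 1)
    # weighted least squares on the local polynomial basis
    X = np.vander(xs, deg + 1, increasing=True)
    sw = np.sqrt(ws)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], ys * sw, rcond=None)
    return float(beta[0])


def loess_fit(x: Sequence[float], y: Sequence[float],
              grid: Sequence[float], span: float = 0.75,
              degree: int = 2,
              counts: Sequence[float] | None = None) -> np.ndarray:
    """LOESS smooth of ``y`` on ``x`` evaluated at ``grid``.

    ``span`` is the fraction of observations entering each local fit
    (tricube-weighted by distance, bandwidth = distance to the q-th nearest
    point, q = ceil(span * n)); ``degree`` is the local polynomial degree.
    Deterministic given inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if counts is not None:
        counts = np.asarray(counts, dtype=float)
        keep = counts > 0
        n_eff = int(counts.sum())
        distinct = len(np.unique(x[keep]))
    else:
        n_eff = len(x)
        distinct = len(np.unique(x))
    if not 0 < span:
        raise ValidationError(f"span must be positive, got {span}")
    if distinct < max(4, degree + 2):
        raise ValidationError(
            f"need at least {max(4, degree + 2)} distinct x positions, "
            f"have {distinct}")
    q = min(n_eff, max(int(math.ceil(span * n_eff)), degree + 1))
    out = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        if counts is None:
            h = float(np.partition(d, q - 1)[q - 1])
        else:
            # q-th nearest observation counting multiplicities
            order = np.argsort(d)
            cum = np.cumsum(counts[order])
            h = float(d[order][int(np.searchsorted(cum, q))])
        out[i] = _local_fit(x, y, float(x0), h, degree, counts)
    return out


@dataclass
class LoessBand:
    """A fitted extinction curve with its pointwise bootstrap band.

    ``lower <= upper`` everywhere; the point fit need not lie inside the
    band (percentile bands are envelopes of refits, not of the fit).
    ``n_boot_effective`` counts the refits that succeeded (a resample can
    lack enough distinct trials to smooth and is then skipped).
    """

    grid: np.ndarray
    fit: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int
    n_boot_effective: int
    span: float
    degree: int
    seed: int | None = None
    labels: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"trial": self.grid, "fit": self.fit,
                           "lower": self.lower, "upper": self.upper})
        for k, v in self.labels.items():
            df.insert(0, k, v)
        return df


class ExtinctionCurve:
    """LOESS extinction-curve model for one Group x Session x window cell.

    Parameters
    ----------
    observations
        ``(subject, trial_index, value)`` triples (DataFrame with columns
        ``subject, trial, value`` or an iterable of triples).
    span, degree
        LOESS smoothing parameters.
    grid
        Evaluation grid; defaults to the integer trials present.
    """

    def __init__(self, observations, span: float = 0.75, degree: int = 2,
                 grid: Sequence[float] | None = None, labels: dict | None = None):
        if isinstance(observations, pd.DataFrame):
            df = observations
            need = ["subject", "trial", "value"]
            missing = [c for c in need if c not in df.columns]
            if missing:
                raise ValidationError(f"observations missing column(s) {missing}")
            self.subject = df["subject"].to_numpy()
            self.x = df["trial"].to_numpy(dtype=float)
            self.y = df["value"].to_numpy(dtype=float)
        else:
            triples = list(observations)
            if not triples:
                raise ValidationError("no observations")
            self.subject = np.array([t[0] for t in triples])
            self.x = np.array([t[1] for t in triples], dtype=float)
            self.y = np.array([t[2] for t in triples], dtype=float)
        if len(self.x) == 0:
            raise ValidationError("no observations")
        self.span = float(span)
        self.degree = int(degree)
        self.grid = (np.asarray(grid, dtype=float) if grid is not None
                     else np.unique(self.x))
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        self.labels = dict(labels or {})

    def fit(self, n_boot: int = 5000, seed: int | None = None,
            resample: str = "observation") -> LoessBand:
        """Smooth the cell and bootstrap its 95% band.

        ``resample='observation'`` resamples the observation triples with
        replacement (the default); ``'subject'`` resamples whole subjects
        (cluster bootstrap).  Reproducible from ``seed``.
        """
        point = loess_fit(self.x, self.y, self.grid, self.span, self.degree)
        rng = np.random.default_rng(seed)
        n = len(self.x)
        min_distinct = max(4, self.degree + 2)
        fits = np.empty((n_boot, len(self.grid)))
        ok = 0
        if resample == "observation":
            # resampling with replacement == multinomial frequency weights,
            # which keeps the refit a cheap weighted smooth
            counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
            for b in range(n_boot):
                c = counts[b].astype(float)
                if len(np.unique(self.x[c > 0])) < min_distinct:
                    continue
                fits[ok] = loess_fit(self.x, self.y, self.grid, self.span,
                                     self.degree, counts=c)
                ok += 1
        elif resample == "subject":
            subjects = np.unique(self.subject)
            by_subj = {s: np.flatnonzero(self.subject == s) for s in subjects}
            for b in range(n_boot):
                draw = rng.choice(subjects, size=len(subjects), replace=True)
                idx = np.concatenate([by_subj[s] for s in draw])
                if len(np.unique(self.x[idx])) < min_distinct:
                    continue
                fits[ok] = loess_fit(self.x[idx], self.y[idx], self.grid,
                                     self.span, self.degree)
                ok += 1
        else:
            raise ValidationError(f"unknown resample mode {resample!r}")
        if ok == 0:
            raise ValidationError("no bootstrap refit succeeded")
        lower = np.percentile(fits[:ok], 2.5, axis=0)
        upper = np.percentile(fits[:ok], 97.5, axis=0)
        return LoessBand(grid=self.grid.copy(), fit=point, lower=lower,
                         upper=upper, n_boot=n_boot, n_boot_effective=ok,
                         span=self.span, degree=self.degree, seed=seed,
                         labels=dict(self.labels))


def bootstrap_band(observations, n_boot: int = 5000, seed: int | None = None,
                   span: float = 0.75, degree: int = 2,
                   grid: Sequence[float] | None = None,
                   resample: str = "observation",
                   labels: dict | None = None) -> LoessBand:
    """Convenience wrapper: build an :class:`ExtinctionCurve` and fit it."""
    return ExtinctionCurve(observations, span=span, degree=degree, grid=grid,
                           labels=labels).fit(n_boot=n_boot, seed=seed,
                                              resample=resample)
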
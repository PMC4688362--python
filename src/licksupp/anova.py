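"""Balanced split-plot (mixed repeated-measures) ANOVA with permutation p-values.

The design has one between-subjects factor (experimental group) and one or
more fully-crossed within-subjects factors (session, trial, CS window ...),
with exactly one observation per subject per within-cell.  The univariate
split-plot decomposition is used:

* the between effect is tested against the Subject-within-Group stratum,
* each within effect (and its interaction with Group) is tested against its
  own interaction with Subject-within-Group,

with degrees of freedom given by the usual products of (levels - 1).  With
balanced data the Type I/II/III sums of squares coincide and everything can
be computed from cell means, which is what makes recomputing the ANOVA for
thousands of permuted datasets cheap.

Behavioral suppression data are heavily zero-inflated, so the theoretical
F-based p-values are complemented by empirical p-values from a two-stage
permutation scheme that respects the within/between variance partition:
first each subject's observations are reshuffled across that subject's
within-cells, then group labels are reshuffled between subjects.  For each
effect the empirical p-value is ``(r + 1) / (n + 1)`` where ``r`` counts
permutations whose F statistic is greater than or equal to the observed one
(so a p-value is never reported as 0; the floor is ``1 / (n + 1)``).

The main entry point is the :class:`MixedAnova` model::

    model = MixedAnova.from_dataframe(df, dv="value", subject="subject",
                                      between="group",
                                      within=("session", "trial", "window"))
    res = model.fit(n_perms=5000, seed=42)
    print(res.summary())
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from licksupp.events import ValidationError

__all__ = [
    "DesignSpec",
    "EffectResult",
    "PermutationPlan",
    "MixedAnova",
    "MixedAnovaResults",
    "rm_anova",
    "run_permutation_anova",
    "two_stage_permutation",
    "empirical_p",
    "exact_permutation_p",
    "simple_effect_test",
    "paired_t",
    "welch_t",
]


@dataclass(frozen=True)
class DesignSpec:
    """Factorial layout of one mixed repeated-measures analysis.

    Parameters
    ----------
    between
        Name of the between-subjects factor column (e.g. ``"group"``).
    between_levels
        Its levels in display order, e.g. ``("Ext", "RetExt")``.
    within
        Ordered mapping of within-factor column name -> tuple of levels,
        e.g. ``{"session": ("EXT1", "EXT2"), "trial": (1, ..., 18),
        "window": ("pre_cs", "cs")}``.
    subject
        Name of the subject identifier column.
    response
        Name of the response (measure value) column.
    display
        Optional column -> display-name mapping used in effect labels
        (e.g. ``{"window": "CS"}``); default capitalises the column name.
    """

    between: str
    between_levels: tuple
    within: Mapping[str, tuple]
    subject: str = "subject"
    response: str = "value"
    display: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "within",
                           {k: tuple(v) for k, v in dict(self.within).items()})
        object.__setattr__(self, "between_levels", tuple(self.between_levels))
        if len(self.between_levels) < 1:
            raise ValidationError("between factor needs >= 1 level; use a "
                                  "single level for a purely within design")
        for name, levels in self.within.items():
            if len(levels) < 2:
                raise ValidationError(f"within factor {name!r} needs >= 2 levels")

    @property
    def factor_names(self) -> list[str]:
        return [self.between, *self.within.keys()]

    def label(self, cols: Sequence[str]) -> str:
        parts = [self.display.get(c, c.capitalize()) for c in cols]
        return " × ".join(parts)

    @property
    def n_cells(self) -> int:
        return int(np.prod([len(v) for v in self.within.values()]))


@dataclass
class EffectResult:
    """One row of an ANOVA summary: effect, df pair, F, theoretical and
    (optionally) permutation-empirical p."""

    effect: str
    df_num: int
    df_den: int
    F: float
    p_theoretical: float
    p_empirical: float | None = None
    ss: float = math.nan
    ss_error: float = math.nan
    n_ge: int | None = None  # permutations with F >= observed


@dataclass
class PermutationPlan:
    """Two-stage permutation settings: number of resamples and seed."""

    n_perms: int = 5000
    seed: int | None = None
    strategy: str = "two_stage"

    def __post_init__(self):
        if self.n_perms < 1:
            raise ValidationError("n_perms must be >= 1")
        if self.strategy != "two_stage":
            raise ValidationError(f"unknown permutation strategy {self.strategy!r}")


# ---------------------------------------------------------------------------
# Core balanced cell-means engine
# ---------------------------------------------------------------------------

def _effect_subsets(n_within: int) -> list[tuple[int, ...]]:
    """All effects as index tuples over factors (0 = between, 1.. = within),
    ordered by interaction order then lexicographically -- the order the
    field's summary tables use (Group, Session, ..., Group × Session, ...)."""
    idx = range(n_within + 1)
    out: list[tuple[int, ...]] = []
    for size in range(1, n_within + 2):
        out.extend(itertools.combinations(idx, size))
    return out


class _Engine:
    """Vectorised split-plot SS/F computation for arrays of shape
    ``(P, g, s, l1, ..., lk)`` (P = batch of permuted datasets)."""

    def __init__(self, g: int, s: int, levels: Sequence[int]):
        self.g, self.s = g, s
        self.levels = tuple(int(l) for l in levels)
        self.k = len(self.levels)
        self.N = g * s * int(np.prod(self.levels))
        self.within_subsets = [tuple(c) for r in range(1, self.k + 1)
                               for c in itertools.combinations(range(self.k), r)]
        self.effects = _effect_subsets(self.k)
        if g == 1:  # purely within-subjects: no between stratum effects
            self.effects = [e for e in self.effects if 0 not in e]

    # axis index of within factor i in the (P, g, s, ...) array
    def _waxis(self, i: int) -> int:
        return 3 + i

    def _raw_ss(self, Y: np.ndarray, grand: np.ndarray, keep: tuple[int, ...]):
        """Raw between-margin-cells SS for the margin keeping ``keep`` axes
        (axis 0, the batch, is always kept)."""
        drop = tuple(a for a in range(1, Y.ndim) if a not in keep)
        m = Y.mean(axis=drop) if drop else Y
        cells = int(np.prod([Y.shape[a] for a in keep if a != 0])) or 1
        count = self.N / cells
        diff = m - grand.reshape((-1,) + (1,) * (m.ndim - 1))
        return count * np.sum(diff * diff, axis=tuple(range(1, m.ndim)))

    def sums_of_squares(self, Y: np.ndarray):
        """Effect and error-stratum SS for each dataset in the batch."""
        grand = Y.mean(axis=tuple(range(1, Y.ndim)))
        raw: dict[tuple, np.ndarray] = {}

        def get_raw(keep_g: bool, keep_s: bool, wset: tuple[int, ...]):
            key = (keep_g, keep_s, wset)
            if key not in raw:
                keep = (0,)
                if keep_g or keep_s:
                    keep += (1,)
                if keep_s:
                    keep += (2,)
                keep += tuple(self._waxis(i) for i in wset)
                raw[key] = self._raw_ss(Y, grand, keep)
            return raw[key]

        effects: dict[tuple, np.ndarray] = {}
        # effects among {G} U within, by inclusion-exclusion over margins;
        # for effects containing G, each term is the G-margin minus the
        # plain within-margin so the nesting chain (grand < G < Subj) holds
        # and raw(emptyset) = 0
        for eff in self.effects:
            keep_g = 0 in eff
            wset = tuple(i - 1 for i in eff if i != 0)
            total = np.zeros(Y.shape[0])
            for r in range(len(wset) + 1):
                for sub in itertools.combinations(wset, r):
                    sign = (-1) ** (len(wset) - len(sub))
                    if keep_g:
                        a = get_raw(True, False, sub)
                        b = get_raw(False, False, sub) if sub else 0.0
                        total = total + sign * (a - b)
                    else:
                        total = total + sign * (get_raw(False, False, sub)
                                                if sub else 0.0)
            effects[eff] = total

        errors: dict[tuple, np.ndarray] = {}
        # Subject-within-Group stratum
        errors[()] = get_raw(True, True, ()) - get_raw(True, False, ())
        # U × Subject-within-Group strata
        for wset in self.within_subsets:
            total = np.zeros(Y.shape[0])
            for r in range(len(wset) + 1):
                for sub in itertools.combinations(wset, r):
                    sign = (-1) ** (len(wset) - len(sub))
                    a = get_raw(True, True, sub)
                    b = get_raw(True, False, sub)
                    total = total + sign * (a - b)
            errors[wset] = total
        return effects, errors

    def effect_df(self, eff: tuple[int, ...]) -> int:
        df = 1
        if 0 in eff:
            df *= self.g - 1
        for i in (i - 1 for i in eff if i != 0):
            df *= self.levels[i] - 1
        return df

    def error_df(self, wset: tuple[int, ...]) -> int:
        df = self.g * (self.s - 1)
        for i in wset:
            df *= self.levels[i] - 1
        return df

    def f_stats(self, Y: np.ndarray):
        """F statistic per effect for each dataset in the batch (shape (P,))."""
        effects, errors = self.sums_of_squares(Y)
        out: dict[tuple, np.ndarray] = {}
        for eff in self.effects:
            wset = tuple(i - 1 for i in eff if i != 0)
            ss_err = errors[wset]
            ms = effects[eff] / self.effect_df(eff)
            mse = ss_err / self.error_df(wset)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = ms / mse
            out[eff] = np.where(mse > 0, f, np.where(ms > 0, np.inf, 0.0))
        return out


# ---------------------------------------------------------------------------
# Long-table <-> array plumbing
# ---------------------------------------------------------------------------

def _to_array(table: pd.DataFrame, design: DesignSpec):
    """Pivot a tidy table into shape ``(g, s, l1, ..., lk)``.

    Validates completeness and balance: every subject must contribute
    exactly one observation per within-cell, and each group must contain
    the same number of subjects.
    """
    cols = [design.subject, design.between, *design.within.keys(), design.response]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"table missing column(s) {missing}")
    df = table[cols].copy()

    subj_group = df[[design.subject, design.between]].drop_duplicates()
    if subj_group[design.subject].duplicated().any():
        bad = subj_group.loc[subj_group[design.subject].duplicated(),
                             design.subject].iloc[0]
        raise ValidationError(f"subject {bad!r} appears in more than one group")
    glv = list(design.between_levels)
    unknown = set(subj_group[design.between]) - set(glv)
    if unknown:
        raise ValidationError(f"unexpected {design.between} level(s) {sorted(unknown)}")
    subjects_by_group = {
        g: sorted(subj_group.loc[subj_group[design.between] == g, design.subject])
        for g in glv
    }
    sizes = {g: len(v) for g, v in subjects_by_group.items()}
    if len(set(sizes.values())) != 1 or min(sizes.values()) < 2:
        raise ValidationError(
            f"groups must have equal sizes >= 2, got {sizes}")
    s = sizes[glv[0]]
    g = len(glv)
    levels = [len(v) for v in design.within.values()]
    n_cells = int(np.prod(levels))

    subj_order = [subj for grp in glv for subj in subjects_by_group[grp]]
    subj_codes = {subj: i for i, subj in enumerate(subj_order)}
    cell_index = {}
    for i, combo in enumerate(itertools.product(*design.within.values())):
        cell_index[combo] = i

    codes = df[design.subject].map(subj_codes).to_numpy()
    try:
        cells = np.array([
            cell_index[tuple(t)]
            for t in df[list(design.within.keys())].itertuples(index=False)
        ])
    except KeyError as exc:
        raise ValidationError(
            f"within-level combination {exc.args[0]!r} not declared in design"
        ) from exc
    flat = codes * n_cells + cells
    counts = np.bincount(flat, minlength=len(subj_order) * n_cells)
    if np.any(counts != 1):
        i = int(np.flatnonzero(counts != 1)[0])
        subj = subj_order[i // n_cells]
        combo = list(itertools.product(*design.within.values()))[i % n_cells]
        what = "missing" if counts[i] == 0 else "duplicated"
        raise ValidationError(
            f"unbalanced design: observation for subject {subj!r}, cell "
            f"{combo} is {what}")
    Y = np.empty(len(subj_order) * n_cells)
    Y[flat] = df[design.response].to_numpy(dtype=float)
    Y = Y.reshape(g, s, *levels)
    return Y, subj_order


def _from_array(Y: np.ndarray, subj_order: list, design: DesignSpec) -> pd.DataFrame:
    g = len(design.between_levels)
    s = len(subj_order) // g
    cells = list(itertools.product(*design.within.values()))
    rows = []
    flat = Y.reshape(len(subj_order), len(cells))
    for j, subj in enumerate(subj_order):
        grp = design.between_levels[j // s]
        for c, combo in enumerate(cells):
            rows.append((subj, grp, *combo, flat[j, c]))
    return pd.DataFrame(rows, columns=[design.subject, design.between,
                                       *design.within.keys(), design.response])


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class MixedAnova:
    """Balanced mixed (split-plot) repeated-measures ANOVA model.

    Parameters
    ----------
    table
        Tidy long table with one row per subject x within-cell.
    design
        The :class:`DesignSpec`; the table is validated against it at
        construction (completeness, balance, no duplicate cells).
    """

    def __init__(self, table: pd.DataFrame, design: DesignSpec):
        self.design = design
        self.Y, self.subjects = _to_array(table, design)
        g = len(design.between_levels)
        self._engine = _Engine(g, self.Y.shape[1],
                               [len(v) for v in design.within.values()])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dv: str = "value",
                       subject: str = "subject", between: str = "group",
                       within: Sequence[str] = ("session", "trial"),
                       between_levels: Sequence | None = None,
                       within_levels: Mapping[str, Sequence] | None = None,
                       display: Mapping[str, str] | None = None) -> "MixedAnova":
        """Build the model straight from a tidy DataFrame, inferring factor
        levels (sorted order) unless given explicitly."""
        blv = tuple(between_levels) if between_levels is not None else \
            tuple(sorted(df[between].dropna().unique()))
        wl = {}
        for w in within:
            if within_levels and w in within_levels:
                wl[w] = tuple(within_levels[w])
            else:
                wl[w] = tuple(sorted(df[w].dropna().unique()))
        design = DesignSpec(between=between, between_levels=blv, within=wl,
                            subject=subject, response=dv,
                            display=dict(display or {}))
        return cls(df, design)

    # -- fitting ------------------------------------------------------------

    def _observed(self) -> list[EffectResult]:
        eng = self._engine
        Y = self.Y[None]  # batch of 1
        effects_ss, errors_ss = eng.sums_of_squares(Y)
        fs = eng.f_stats(Y)
        out = []
        names = self.design.factor_names
        for eff in eng.effects:
            wset = tuple(i - 1 for i in eff if i != 0)
            df1 = eng.effect_df(eff)
            df2 = eng.error_df(wset)
            F = float(fs[eff][0])
            out.append(EffectResult(
                effect=self.design.label([names[i] for i in eff]),
                df_num=df1, df_den=df2, F=F,
                p_theoretical=float(stats.f.sf(F, df1, df2)),
                ss=float(effects_ss[eff][0]),
                ss_error=float(errors_ss[wset][0]),
            ))
        return out

    def fit(self, n_perms: int | None = None, seed: int | None = None,
            plan: PermutationPlan | None = None,
            batch_size: int = 512) -> "MixedAnovaResults":
        """Fit the ANOVA; with ``n_perms`` (or ``plan``) also compute
        two-stage permutation empirical p-values.

        One shared stream of permuted datasets feeds the null F
        distributions of all effects simultaneously, exactly as a single
        reshuffled dataset would be re-analysed in full.
        """
        if plan is None and n_perms is not None:
            plan = PermutationPlan(n_perms=n_perms, seed=seed)
        results = self._observed()
        if plan is not None:
            eng = self._engine
            rng = np.random.default_rng(plan.seed)
            f_obs = {eff: res.F for eff, res in zip(eng.effects, results)}
            counts = {eff: 0 for eff in eng.effects}
            done = 0
            while done < plan.n_perms:
                nb = min(batch_size, plan.n_perms - done)
                Yp = _permute_batch(self.Y, rng, nb)
                fs = eng.f_stats(Yp)
                for eff in eng.effects:
                    counts[eff] += int(np.sum(fs[eff] >= f_obs[eff]))
                done += nb
            for eff, res in zip(eng.effects, results):
                res.n_ge = counts[eff]
                res.p_empirical = empirical_p_from_counts(counts[eff], plan.n_perms)
        return MixedAnovaResults(self, results, plan)


class MixedAnovaResults:
    """Fitted split-plot ANOVA: effect table, permutation metadata,
    ``summary()`` in the field's standard layout."""

    def __init__(self, model: MixedAnova, effects: list[EffectResult],
                 plan: PermutationPlan | None):
        self.model = model
        self.design = model.design
        self.effects = effects
        self.plan = plan

    def __getitem__(self, effect: str) -> EffectResult:
        for res in self.effects:
            if res.effect == effect:
                return res
        raise KeyError(f"no effect {effect!r}; have "
                       f"{[r.effect for r in self.effects]}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.effects:
            rows.append({
                "Effect": r.effect,
                "df": f"{r.df_num}, {r.df_den}",
                "F": r.F,
                "Theoretical p": r.p_theoretical,
                "Empirical p": r.p_empirical,
            })
        df = pd.DataFrame(rows)
        if self.plan is None:
            df = df.drop(columns=["Empirical p"])
        return df

    @property
    def ss_total(self) -> float:
        Y = self.model.Y
        return float(np.sum((Y - Y.mean()) ** 2))

    def summary(self) -> str:
        df = self.to_frame().copy()
        df["F"] = df["F"].map(lambda v: f"{v:.4g}")
        df["Theoretical p"] = df["Theoretical p"].map(lambda v: f"{v:.3g}")
        if "Empirical p" in df:
            df["Empirical p"] = df["Empirical p"].map(lambda v: f"{v:.3g}")
        head = [f"Mixed repeated-measures ANOVA: {self.design.response}",
                f"Between: {self.design.between} {self.design.between_levels}",
                "Within: " + ", ".join(f"{k} ({len(v)} levels)"
                                       for k, v in self.design.within.items())]
        if self.plan is not None:
            head.append(f"Permutations: {self.plan.n_perms} (two-stage), "
                        f"seed={self.plan.seed}")
        return "\n".join(head) + "\n\n" + df.to_string(index=False)


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def _permute_batch(Y: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    """``n`` independent two-stage permutations of ``Y`` (shape (g, s, *L)).

    Stage 1: each subject's observations are uniformly reshuffled across
    all of that subject's within-cells.  Stage 2: group assignments are
    uniformly reshuffled between subjects (group sizes preserved; with the
    group/subject axes this is a random reordering of subjects).  Each
    subject's multiset of values is preserved exactly.
    """
    g, s = Y.shape[0], Y.shape[1]
    n_subj = g * s
    cells = int(np.prod(Y.shape[2:]))
    flat = np.broadcast_to(Y.reshape(n_subj, cells), (n, n_subj, cells)).copy()
    rng.permuted(flat, axis=2, out=flat)  # stage 1
    order = rng.permuted(np.broadcast_to(np.arange(n_subj),
                                         (n, n_subj)).copy(), axis=1)  # stage 2
    flat = np.take_along_axis(flat, order[:, :, None], axis=1)
    return flat.reshape(n, g, s, *Y.shape[2:])


def two_stage_permutation(table: pd.DataFrame, design: DesignSpec,
                          rng: np.random.Generator) -> pd.DataFrame:
    """One two-stage permutation of a tidy table (observations reshuffled
    within each subject, then group labels reshuffled between subjects)."""
    model = MixedAnova(table, design)
    Yp = _permute_batch(model.Y, rng, 1)[0]
    return _from_array(Yp, model.subjects, design)


def empirical_p_from_counts(r: int, n: int) -> float:
    """The ``(r + 1) / (n + 1)`` rule; r = permutations with statistic >=
    observed (ties count), n = number of permutations."""
    if n < 1:
        raise ValidationError("need at least one permutation")
    if not 0 <= r <= n:
        raise ValidationError(f"r={r} outside [0, {n}]")
    return (r + 1) / (n + 1)


def empirical_p(F_obs: float, F_null: Sequence[float]) -> float:
    """Permutation p-value of an observed statistic against a null sample."""
    null = np.asarray(F_null, dtype=float)
    if null.size == 0:
        raise ValidationError("empty null distribution")
    r = int(np.sum(null >= F_obs))
    return empirical_p_from_counts(r, null.size)


def rm_anova(table: pd.DataFrame, design: DesignSpec) -> list[EffectResult]:
    """Split-plot ANOVA with theoretical p-values only."""
    return MixedAnova(table, design).fit().effects


def run_permutation_anova(table: pd.DataFrame, design: DesignSpec,
                          plan: PermutationPlan) -> list[EffectResult]:
    """Split-plot ANOVA with both theoretical and permutation p-values."""
    return MixedAnova(table, design).fit(plan=plan).effects


def exact_permutation_p(table: pd.DataFrame, design: DesignSpec,
                        max_configs: int = 2_000_000) -> dict[str, float]:
    """Exact permutation p-values by full enumeration of the two-stage
    permutation group (all within-subject orderings x all group
    assignments).  Only feasible for very small designs; raises if the
    group has more than ``max_configs`` elements.

    The exact p of an effect is the proportion of configurations whose F is
    greater than or equal to the observed F (the identity configuration is
    a member of the group, so the p-value is never 0).
    """
    model = MixedAnova(table, design)
    eng = model._engine
    Y = model.Y
    g, s = Y.shape[0], Y.shape[1]
    n_subj = g * s
    cells = int(np.prod(Y.shape[2:]))
    n_orders = math.factorial(cells) ** n_subj
    group_assignments = list(
        itertools.combinations(range(n_subj), s))  # positions of group 1
    if g != 2:
        raise ValidationError("exact enumeration implemented for 2 groups")
    total = n_orders * len(group_assignments)
    if total > max_configs:
        raise ValidationError(
            f"permutation group has {total} elements > max_configs={max_configs}")

    f_obs = {eff: float(eng.f_stats(Y[None])[eff][0]) for eff in eng.effects}
    # many configurations are mathematically tied with the observed F
    # (symmetries of the group); count ties robustly to float roundoff
    tol = {eff: 1e-9 * max(1.0, abs(f)) for eff, f in f_obs.items()}
    counts = {eff: 0 for eff in eng.effects}
    flat = Y.reshape(n_subj, cells)
    cell_orders = list(itertools.permutations(range(cells)))
    # enumerate stage 1 as a mixed-radix counter over per-subject orderings
    batch = []
    for combo in itertools.product(range(len(cell_orders)), repeat=n_subj):
        perm = np.array([flat[j, list(cell_orders[combo[j]])]
                         for j in range(n_subj)])
        for first in group_assignments:
            rest = [j for j in range(n_subj) if j not in first]
            batch.append(perm[list(first) + rest])
    Yp = np.array(batch).reshape(-1, g, s, *Y.shape[2:])
    fs = eng.f_stats(Yp)
    out = {}
    names = design.factor_names
    for eff in eng.effects:
        r = int(np.sum(fs[eff] >= f_obs[eff] - tol[eff]))
        out[design.label([names[i] for i in eff])] = r / total
    return out


# ---------------------------------------------------------------------------
# t statistics: simple effects and baseline comparisons
# ---------------------------------------------------------------------------

def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    diff = x.mean() - y.mean()
    sp2 = (np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)) / (n1 + n2 - 2)
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / se


def simple_effect_test(x: Sequence[float], y: Sequence[float],
                       plan: PermutationPlan | None = None,
                       exhaustive: bool = False,
                       rng: np.random.Generator | None = None
                       ) -> tuple[float, int, float, float]:
    """Permutation simple-effect test of a group difference within one cell.

    Computes the pooled-variance two-sample t statistic with its two-sided
    theoretical p, and an empirical p from group-label permutations using
    ``|t|`` and the ``(r + 1)/(n + 1)`` rule.  With ``exhaustive=True`` all
    label assignments are enumerated instead of sampled.

    Returns ``(t, df, p_theoretical, p_empirical)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 values")
    t_obs = _pooled_t(x, y)
    df = len(x) + len(y) - 2
    p_theo = float(2 * stats.t.sf(abs(t_obs), df)) if math.isfinite(t_obs) else 0.0
    pooled = np.concatenate([x, y])
    n1 = len(x)
    if exhaustive:
        r = 0
        n = 0
        for first in itertools.combinations(range(len(pooled)), n1):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(first)] = True
            t = _pooled_t(pooled[mask], pooled[~mask])
            r += abs(t) >= abs(t_obs)
            n += 1
    else:
        if plan is None:
            plan = PermutationPlan()
        if rng is None:
            rng = np.random.default_rng(plan.seed)
        n = plan.n_perms
        r = 0
        for _ in range(n):
            perm = rng.permutation(len(pooled))
            t = _pooled_t(pooled[perm[:n1]], pooled[perm[n1:]])
            r += abs(t) >= abs(t_obs)
    return float(t_obs), df, p_theo, empirical_p_from_counts(int(r), int(n))


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Paired t-test; returns ``(t, df, p)`` with ``df = n - 1``.

    Zero variance of the paired differences yields an infinite-t sentinel
    (p = 0 for a nonzero mean difference) with a warning, or ``t = 0, p = 1``
    when the samples are identical.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValidationError("paired samples must have equal length >= 2")
    d = x - y
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 0.0, len(d) - 1, 1.0
        warnings.warn("paired differences have zero variance; t is infinite")
        return math.copysign(math.inf, d[0]), len(d) - 1, 0.0
    t, p = stats.ttest_rel(x, y)
    return float(t), len(d) - 1, float(p)


def welch_t(x1: Sequence[float], x2: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test; returns ``(t, df, p)`` with Satterthwaite df."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValidationError("each sample needs >= 2 values")
    res = stats.ttest_ind(x1, x2, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
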
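"""End-to-end orchestration: events -> measures -> ANOVA tables -> curves.

``run_full_analysis`` executes the whole analysis on either real event logs
(plus a pre-scored freezing table) or a synthetic cohort, and returns a
:class:`ReportBundle` holding the five numeric tables the analysis is
contracted to produce:

1. extinction CS-vs-preCS drinking ANOVA (Group x Session x Trial x CS),
2. extinction ITI drinking ANOVA (Group x Session x Trial),
3. long-term-memory (LTM) drinking ANOVA (Group x Session x CS, first
   trial of each memory session only),
4. the parallel LTM freezing ANOVA, and
5. permutation simple effects of group, computed within each level of the
   interacting within-factors whenever an LTM ANOVA shows a significant
   (empirical p <= alpha) interaction involving Group,

plus the baseline drinking-motivation t-tests and the LOESS bootstrap
extinction-curve bands.  The run is a pure function of (input data, config,
seed): rerunning with the same inputs reproduces every number bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from licksupp.anova import (
    DesignSpec,
    MixedAnova,
    MixedAnovaResults,
    PermutationPlan,
    paired_t,
    simple_effect_test,
    welch_t,
)
from licksupp.events import ValidationError, read_session_logs
from licksupp.loess import ExtinctionCurve
from licksupp.metrics import build_behavior_table, drink_trajectories
from licksupp.simulate import (
    LTM_SESSIONS,
    CohortSpec,
    SimParams,
    simulate_cohort,
)

logger = logging.getLogger("licksupp")

__all__ = ["RunConfig", "ReportBundle", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    ``mode`` is ``"synthetic"`` (simulate a cohort) or ``"logs"`` (read
    ``events_path``/``freezing_path``/``assignment_path``).  Seeds drive
    every source of randomness; ``n_perms``/``n_boot`` size the permutation
    and bootstrap resamples; ``alpha`` is the empirical-p threshold that
    triggers simple-effects tests on Group interactions.
    """

    mode: str = "synthetic"
    events_path: str | None = None
    freezing_path: str | None = None
    assignment_path: str | None = None
    out_dir: str | None = None
    seed: int = 0
    n_perms: int = 5000
    n_boot: int = 5000
    alpha: float = 0.05
    span: float = 0.75
    degree: int = 2
    resample: str = "observation"
    pre_cs_len: float = 20.0
    bout_gap: float = 1.0
    point_dwell: float = 0.1
    ext_sessions: tuple[str, ...] = ("EXT1", "EXT2")
    ltm_sessions: tuple[str, ...] = LTM_SESSIONS
    n_trials: int = 18
    sim_params: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    freeze_group_shift: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValidationError(f"unknown config key(s) {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.mode not in ("synthetic", "logs"):
            raise ValidationError(f"mode must be 'synthetic' or 'logs', "
                                  f"got {cfg.mode!r}")
        if cfg.mode == "logs":
            for name in ("events_path",):
                p = getattr(cfg, name)
                if not p or not os.path.exists(p):
                    raise ValidationError(f"{name} {p!r} does not exist")
        return cfg


@dataclass
class ReportBundle:
    """All numeric outputs of one run, with seed/n_perms provenance."""

    measurements: pd.DataFrame
    anova_ext_cs: MixedAnovaResults
    anova_ext_iti: MixedAnovaResults
    anova_ltm_drink: MixedAnovaResults
    anova_ltm_freeze: MixedAnovaResults
    simple_effects: pd.DataFrame
    baseline_tests: pd.DataFrame
    curve_bands: pd.DataFrame
    metadata: dict

    def anova_tables(self) -> dict[str, pd.DataFrame]:
        return {
            "extinction_cs": self.anova_ext_cs.to_frame(),
            "extinction_iti": self.anova_ext_iti.to_frame(),
            "ltm_drinking": self.anova_ltm_drink.to_frame(),
            "ltm_freezing": self.anova_ltm_freeze.to_frame(),
        }

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = "".join(f"# {k}: {v}\n" for k, v in self.metadata.items())

        def write(df: pd.DataFrame, name: str) -> None:
            path = out / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)

        write(self.measurements, "measurements")
        for name, df in self.anova_tables().items():
            write(df, f"anova_{name}")
        write(self.simple_effects, "simple_effects")
        write(self.baseline_tests, "baseline_tests")
        write(self.curve_bands, "curve_bands")
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)

    def plot_extinction_curves(self, path=None):
        """Panel plot of the LOESS bands (one panel per session x window);
        optional artifact, the numeric tables are the contract."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        bands = self.curve_bands
        windows = ["iti", "pre_cs", "cs"]
        sessions = sorted(bands["session"].unique())
        fig, axes = plt.subplots(len(windows), len(sessions),
                                 figsize=(4 * len(sessions), 3 * len(windows)),
                                 sharex=True, sharey=True, squeeze=False)
        colors = {"Ext": "tab:blue", "RetExt": "tab:orange"}
        for i, win in enumerate(windows):
            for j, sess in enumerate(sessions):
                ax = axes[i][j]
                for grp, sub in bands[(bands["window"] == win)
                                      & (bands["session"] == sess)
                                      ].groupby("group"):
                    c = colors.get(grp, None)
                    ax.plot(sub["trial"], sub["fit"], label=grp, color=c)
                    ax.fill_between(sub["trial"], sub["lower"], sub["upper"],
                                    alpha=0.25, color=c)
                ax.set_title(f"{sess} — {win}")
                if i == len(windows) - 1:
                    ax.set_xlabel("Trial")
                if j == 0:
                    ax.set_ylabel("% time drinking")
        axes[0][0].legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _load_inputs(config: RunConfig, rng: np.random.Generator):
    if config.mode == "synthetic":
        params = SimParams(**config.sim_params)
        spec = CohortSpec(**config.cohort)
        logs, freezing, truth = simulate_cohort(
            spec, params, rng, freeze_group_shift=config.freeze_group_shift)
        return logs, freezing, truth["assignment"], truth
    logs = read_session_logs(config.events_path)
    freezing = (pd.read_csv(config.freezing_path)
                if config.freezing_path else None)
    if config.assignment_path:
        adf = pd.read_csv(config.assignment_path)
        assignment = dict(zip(adf["subject"].astype(str), adf["group"]))
    else:
        assignment = {}
    return logs, freezing, assignment, {}


def _anova(table: pd.DataFrame, measure: str, sessions, windows, trials,
           n_perms: int, seed: int) -> MixedAnovaResults:
    sub = table[(table["measure"] == measure)
                & (table["session"].isin(sessions))
                & (table["window"].isin(windows))
                & (table["trial"].isin(trials))]
    within: dict[str, tuple] = {}
    if len(sessions) > 1:
        within["session"] = tuple(sessions)
    if len(trials) > 1:
        within["trial"] = tuple(trials)
    if len(windows) > 1:
        within["window"] = tuple(windows)
    design = DesignSpec(between="group",
                        between_levels=tuple(sorted(sub["group"].unique())),
                        within=within, display={"window": "CS"})
    model = MixedAnova(sub, design)
    return model.fit(plan=PermutationPlan(n_perms=n_perms, seed=seed))


def _simple_effects(table: pd.DataFrame, measure: str, sessions,
                    res: MixedAnovaResults, config: RunConfig,
                    seed: int) -> pd.DataFrame:
    """Group simple effects within each level of the within-factors that
    interact significantly with Group (empirical p <= alpha)."""
    within_cols: set[str] = set()
    inv_display = {v: k for k, v in res.design.display.items()}
    for eff in res.effects:
        parts = eff.effect.split(" × ")
        if len(parts) < 2 or "Group" not in parts:
            continue
        if eff.p_empirical is not None and eff.p_empirical <= config.alpha:
            for p in parts:
                if p != "Group":
                    col = inv_display.get(p, p.lower())
                    within_cols.add(col)
    rows = []
    if within_cols:
        cols = [c for c in ("session", "trial", "window") if c in within_cols]
        sub = table[(table["measure"] == measure)
                    & (table["session"].isin(sessions))
                    & (table["window"].isin(["pre_cs", "cs"]))
                    & (table["trial"] == 1)]
        rng = np.random.default_rng(seed)
        groups = sorted(sub["group"].unique())
        for keys, cell in sub.groupby(cols, sort=True):
            keys = keys if isinstance(keys, tuple) else (keys,)
            # one value per subject in the cell (mean over any within
            # factor not part of the interaction)
            cell = cell.groupby("subject", as_index=False).agg(
                value=("value", "mean"), group=("group", "first"))
            x = cell.loc[cell["group"] == groups[0], "value"].to_numpy()
            y = cell.loc[cell["group"] == groups[1], "value"].to_numpy()
            t, df, p_t, p_e = simple_effect_test(
                x, y, plan=PermutationPlan(n_perms=config.n_perms), rng=rng)
            row = dict(zip(cols, keys))
            row.update({"measure": measure, "t": t, "df": df,
                        "Theoretical p": p_t, "Empirical p": p_e})
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["session", "window", "measure", "t",
                                     "df", "Theoretical p", "Empirical p"])
    return pd.DataFrame(rows)


def _baseline_tests(table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Drinking-motivation summary: restricted vs unrestricted baseline,
    subsequent max ITI drinking vs restricted baseline, and group
    differences in the max and the latency to reach it."""
    rows = []
    base = table[(table["measure"] == "drink_pct")
                 & table["session"].astype(str).str.startswith("BASE")]
    if len(base):
        wide = base.pivot_table(index="subject", columns="session",
                                values="value", aggfunc="mean")
        restricted = wide.iloc[:, 0]
        if wide.shape[1] > 1:
            unrestricted = wide.iloc[:, 1:].mean(axis=1)
            t, df, p = paired_t(restricted, unrestricted)
            rows.append({"test": "baseline restricted vs unrestricted (paired)",
                         "t": t, "df": df, "p": p})
        session_order = [s for s in
                         ("LTM_POST_ACQ", *config.ext_sessions,
                          "LTM_POST_EXT", "LTM_POST_REINST")
                         if s in set(table["session"])]
        trajs = drink_trajectories(table, session_order)
        if trajs:
            tr = pd.DataFrame({
                "subject": [t_.subject_id for t_ in trajs],
                "max_iti": [t_.max_iti_pct for t_ in trajs],
                "latency": [t_.latency_tones for t_ in trajs],
            }).set_index("subject")
            common = restricted.index.intersection(tr.index)
            t, df, p = paired_t(tr.loc[common, "max_iti"],
                                restricted.loc[common])
            rows.append({"test": "max ITI drinking vs restricted baseline "
                                 "(paired)", "t": t, "df": df, "p": p})
            gm = table[["subject", "group"]].drop_duplicates().set_index(
                "subject")["group"]
            tr["group"] = gm.reindex(tr.index)
            grps = sorted(tr["group"].dropna().unique())
            if len(grps) == 2:
                for col, label in (("max_iti", "group difference in max ITI "
                                               "drinking (Welch)"),
                                   ("latency", "group difference in latency "
                                               "to max (Welch)")):
                    a = tr.loc[tr["group"] == grps[0], col]
                    b = tr.loc[tr["group"] == grps[1], col]
                    t, df, p = welch_t(a, b)
                    rows.append({"test": label, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows, columns=["test", "t", "df", "p"])


def _curve_bands(table: pd.DataFrame, config: RunConfig,
                 seed: int) -> pd.DataFrame:
    frames = []
    sub = table[(table["measure"] == "drink_pct")
                & (table["session"].isin(config.ext_sessions))]
    trials = list(range(1, config.n_trials + 1))
    child = np.random.SeedSequence(seed).spawn(
        len(config.ext_sessions) * 6)
    i = 0
    for session in config.ext_sessions:
        for group in sorted(sub["group"].unique()):
            for window in ("iti", "pre_cs", "cs"):
                cell = sub[(sub["session"] == session)
                           & (sub["group"] == group)
                           & (sub["window"] == window)]
                curve = ExtinctionCurve(
                    cell, span=config.span, degree=config.degree, grid=trials,
                    labels={"group": group, "session": session,
                            "window": window})
                band = curve.fit(n_boot=config.n_boot,
                                 seed=int(child[i].generate_state(1)[0]
                                          % (2 ** 31)),
                                 resample=config.resample)
                frames.append(band.to_frame())
                i += 1
    return pd.concat(frames, ignore_index=True)


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute the whole pipeline and return (and optionally write) the
    report bundle.  Stage failures raise with a stage-tagged message."""
    master = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in master.spawn(8)]
    rng = np.random.default_rng(seeds[0])

    def stage(name, fn, *args, **kw):
        try:
            logger.info("stage %s", name)
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    logs, freezing, assignment, truth = stage("input", _load_inputs, config, rng)
    table = stage("measures", build_behavior_table, logs, freezing, assignment,
                  config.pre_cs_len, config.bout_gap, config.point_dwell)

    trials = list(range(1, config.n_trials + 1))
    ext_cs = stage("anova_ext_cs", _anova, table, "drink_pct",
                   list(config.ext_sessions), ["pre_cs", "cs"], trials,
                   config.n_perms, seeds[1])
    ext_iti = stage("anova_ext_iti", _anova, table, "drink_pct",
                    list(config.ext_sessions), ["iti"], trials,
                    config.n_perms, seeds[2])
    ltm_drink = stage("anova_ltm_drink", _anova, table, "drink_pct",
                      list(config.ltm_sessions), ["pre_cs", "cs"], [1],
                      config.n_perms, seeds[3])
    ltm_freeze = stage("anova_ltm_freeze", _anova, table, "freeze_pct",
                       list(config.ltm_sessions), ["pre_cs", "cs"], [1],
                       config.n_perms, seeds[4])

    def _all_simple_effects():
        parts = [
            _simple_effects(table, "drink_pct", list(config.ltm_sessions),
                            ltm_drink, config, seeds[5]),
            _simple_effects(table, "freeze_pct", list(config.ltm_sessions),
                            ltm_freeze, config, seeds[5] + 1),
        ]
        kept = [p for p in parts if len(p)]
        return pd.concat(kept, ignore_index=True) if kept else parts[0]

    simple = stage("simple_effects", _all_simple_effects)
    baseline = stage("baseline_tests", _baseline_tests, table, config)
    bands = stage("curves", _curve_bands, table, config, seeds[6])

    metadata = {
        "mode": config.mode,
        "seed": config.seed,
        "n_perms": config.n_perms,
        "n_boot": config.n_boot,
        "alpha": config.alpha,
        "span": config.span,
        "degree": config.degree,
        "resample": config.resample,
        "n_subjects": int(table["subject"].nunique()),
    }
    bundle = ReportBundle(
        measurements=table, anova_ext_cs=ext_cs, anova_ext_iti=ext_iti,
        anova_ltm_drink=ltm_drink, anova_ltm_freeze=ltm_freeze,
        simple_effects=simple, baseline_tests=baseline, curve_bands=bands,
        metadata=metadata)
    if config.out_dir:
        bundle.save(config.out_dir)
    return bundle
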
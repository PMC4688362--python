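"""Synthetic-cohort generator: renewal process, freezing model, null data."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import expit

from licksupp.events import drink_intervals, percent_time
from licksupp.metrics import build_behavior_table
from licksupp.simulate import (
    CohortSpec,
    SessionSchedule,
    SimParams,
    balanced_design,
    null_dataset,
    simulate_cohort,
    simulate_freezing,
    simulate_session_log,
)


def _schedule(n_tones=3, duration=None):
    onsets = tuple(240.0 + i * 220.0 for i in range(n_tones))
    dur = duration or (onsets[-1] + 300.0 if onsets else 600.0)
    return SessionSchedule("EXT1", duration=dur, tone_onsets=onsets)


class TestSimulateSessionLog:
    def test_phi_cs_zero_silences_cs_windows(self, rng):
        params = SimParams(phi_cs=0.0, phi_post=1.0, phi_session=1.0,
                           phi_trial=1.0, mu_bout=0.5)
        sched = _schedule(5)
        for _ in range(3):
            log = simulate_session_log(params, sched, rng)
            iv = drink_intervals(log.lick_events)
            for on in sched.tone_onsets:
                # bouts can run into the tone but never start during it
                for a, b in iv:
                    assert not (on < a < on + sched.cs_duration)

    def test_stationary_drink_fraction(self, rng):
        """All factors 1, long session: observed drink fraction matches the
        alternating-renewal closed form lam*mu/(1 + lam*mu) within 3 SE."""
        lam, mu = 0.05, 6.0
        params = SimParams(lambda_on=lam, mu_bout=mu, phi_post=1.0,
                           phi_session=1.0, phi_trial=1.0, phi_cs=1.0)
        sched = SessionSchedule("BASE2", duration=40000.0)
        log = simulate_session_log(params, sched, rng)
        iv = drink_intervals(log.lick_events, bout_gap=1e-9)
        frac = iv.total_length / sched.duration
        expect = lam * mu / (1 + lam * mu)
        # cycle count ~ duration / E[cycle]; SE of the fraction estimate
        n_cycles = sched.duration / (1 / lam + mu)
        se = np.sqrt(expect * (1 - expect) / n_cycles)
        assert abs(frac - expect) < 3 * se + 0.01

    def test_same_seed_identical_logs(self):
        params = SimParams()
        sched = _schedule(4)
        a = simulate_session_log(params, sched, np.random.default_rng(42))
        b = simulate_session_log(params, sched, np.random.default_rng(42))
        assert a.lick_events == b.lick_events
        assert a.stimulus_events == b.stimulus_events

    def test_cs_suppression_orders_window_means(self):
        """phi_cs < 1 makes expected CS drinking below context drinking."""
        params = SimParams(phi_cs=0.1, phi_post=1.0, phi_session=1.0,
                           phi_trial=1.0)
        cs_tot, pre_tot = 0.0, 0.0
        rng = np.random.default_rng(8)
        sched = _schedule(10)
        for _ in range(20):
            log = simulate_session_log(params, sched, rng)
            iv = drink_intervals(log.lick_events)
            for on in sched.tone_onsets:
                cs_tot += percent_time(iv, (on, on + 20.0))
                pre_tot += percent_time(iv, (on - 20.0, on))
        assert cs_tot < pre_tot


class TestSimulateFreezing:
    def _design(self, n=40):
        subs = [f"S{i}" for i in range(n)]
        groups = {s: "Ext" for s in subs}
        return balanced_design(subs, groups,
                               {"session": ["LTM_POST_ACQ"], "trial": [1],
                                "window": ["cs"]})

    def test_zero_sd_hits_condition_mean(self, rng):
        params = SimParams(freeze_logit_sd=0.0, freeze_default_logit=1.0,
                           freeze_resolution=None)
        out = simulate_freezing(params, self._design(), rng)
        assert np.allclose(out["value"], 100 * expit(1.0))

    def test_very_negative_mean_floors_at_zero(self, rng):
        params = SimParams(freeze_default_logit=-12.0, freeze_logit_sd=0.5)
        out = simulate_freezing(params, self._design(200), rng)
        assert (out["value"] == 0.0).mean() > 0.95

    def test_mean_matches_quadrature_oracle(self):
        """Empirical mean of the logit-normal freezing within 3 SE of the
        distribution mean computed by numeric integration."""
        m, s = 0.8, 1.2
        params = SimParams(freeze_default_logit=m, freeze_logit_sd=s,
                           freeze_resolution=None)
        rng = np.random.default_rng(99)
        out = simulate_freezing(params, self._design(4000), rng)
        mean_th, _ = integrate.quad(
            lambda z: 100 * expit(z) * stats.norm.pdf(z, m, s), -12, 12)
        var_th, _ = integrate.quad(
            lambda z: (100 * expit(z) - mean_th) ** 2 * stats.norm.pdf(z, m, s),
            -12, 12)
        se = np.sqrt(var_th / len(out))
        assert abs(out["value"].mean() - mean_th) < 3 * se


class TestNullDataset:
    def test_no_effects_and_deterministic(self, rng):
        des = balanced_design([f"S{i}" for i in range(8)],
                              {f"S{i}": ("A" if i < 4 else "B")
                               for i in range(8)}, {"w": [1, 2, 3]})
        a = null_dataset(des, np.random.default_rng(5))
        b = null_dataset(des, np.random.default_rng(5))
        assert a.equals(b)
        grand = a["value"].mean()
        assert abs(grand) < 4 / np.sqrt(len(a))

    def test_theoretical_p_uniform_under_null(self):
        """rm_anova theoretical p-values are uniform under the Gaussian
        null (KS test over simulations)."""
        from licksupp.anova import DesignSpec, rm_anova
        des = balanced_design([f"S{i}" for i in range(8)],
                              {f"S{i}": ("A" if i < 4 else "B")
                               for i in range(8)}, {"w": [1, 2]})
        design = DesignSpec(between="group", between_levels=("A", "B"),
                            within={"w": (1, 2)})
        ps = {"Group": [], "W": [], "Group × W": []}
        for sim in range(300):
            df = null_dataset(des, np.random.default_rng(50_000 + sim))
            for r in rm_anova(df, design):
                ps[r.effect].append(r.p_theoretical)
        for effect, vals in ps.items():
            assert stats.kstest(vals, "uniform").pvalue > 0.005, effect


class TestSimulateCohort:
    def test_structure_and_balance(self):
        spec = CohortSpec(n_per_group=4, n_baseline_sessions=2,
                          tones_per_ext_session=6)
        logs, freezing, truth = simulate_cohort(
            spec, SimParams(), np.random.default_rng(0))
        table = build_behavior_table(logs, freezing, truth["assignment"])
        # every subject has all sessions
        per_subj = table.groupby("subject")["session"].nunique()
        assert (per_subj == 2 + 2 + 3).all()
        # groups are equal-sized and cage mates concordant
        amap = truth["assignment"]
        sizes = pd.Series(amap).value_counts()
        assert sizes.tolist() == [4, 4]
        cages = spec.cages()
        for members in cages.values():
            assert len({amap[m] for m in members}) == 1
        # ANOVA-ready: extinction CS design pivots without error
        from licksupp.anova import DesignSpec, MixedAnova
        sub = table[(table.measure == "drink_pct")
                    & (table.session.isin(["EXT1", "EXT2"]))
                    & (table.window.isin(["pre_cs", "cs"]))]
        design = DesignSpec(
            between="group", between_levels=tuple(sorted(set(amap.values()))),
            within={"session": ("EXT1", "EXT2"),
                    "trial": tuple(range(1, 7)),
                    "window": ("pre_cs", "cs")})
        MixedAnova(sub, design)  # raises if unbalanced

    def test_same_seed_reproducible(self):
        spec = CohortSpec(n_per_group=2, n_baseline_sessions=1,
                          tones_per_ext_session=3)
        out1 = simulate_cohort(spec, SimParams(), np.random.default_rng(3))
        out2 = simulate_cohort(spec, SimParams(), np.random.default_rng(3))
        assert out1[1].equals(out2[1])
        assert out1[2]["assignment"] == out2[2]["assignment"]
        assert all(a.lick_events == b.lick_events
                   for a, b in zip(out1[0], out2[0]))

    def test_truth_supports_expected_cell_means(self):
        """The truth record carries enough to compute each subject's
        expected context drink fraction; cohort means must track it."""
        spec = CohortSpec(n_per_group=8, n_baseline_sessions=1,
                          tones_per_ext_session=8)
        params = SimParams(subject_sd=0.3)
        logs, _, truth = simulate_cohort(spec, params,
                                         np.random.default_rng(11))
        table = build_behavior_table(logs, None, truth["assignment"])
        # late EXT2 ITI drinking should exceed early EXT1 ITI drinking
        # (the generating factors say recovery is monotone)
        iti = table[(table.measure == "drink_pct") & (table.window == "iti")]
        early = iti[(iti.session == "EXT1") & (iti.trial <= 2)]["value"].mean()
        late = iti[(iti.session == "EXT2") & (iti.trial >= 7)]["value"].mean()
        assert late > early
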
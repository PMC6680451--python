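import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phraseseg.errors import DesignError, DomainError
from phraseseg.inference import (
    anova_frame,
    independent_t,
    mixed_anova,
    mixed_anova_from_array,
    paired_t,
    summary_t,
    wilcoxon_signed_rank,
)


def _long_table(y, groups, w1, w2=None):
    rows = []
    for s in range(y.shape[0]):
        for j in range(y.shape[1]):
            if w2 is None:
                rows.append(
                    {"participant_id": f"p{s:03d}", "grp": groups[s], "w1": w1[j], "y": y[s, j]}
                )
            else:
                for k in range(y.shape[2]):
                    rows.append(
                        {
                            "participant_id": f"p{s:03d}",
                            "grp": groups[s],
                            "w1": w1[j],
                            "w2": w2[k],
                            "y": y[s, j, k],
                        }
                    )
    return pd.DataFrame(rows)


def projection_ss_oracle(y, g_idx, a, n, b, c):
    """Independent sums-of-squares via orthogonal projections onto effect
    subspaces (balanced design): brute-force average-and-subtract on the full
    data cube, never reusing the implementation's marginal-mean formulas."""
    # data cube indexed (group, subject-within-group, b, c)
    cube = np.empty((a, n, b, c))
    counters = [0] * a
    for s in range(y.shape[0]):
        g = g_idx[s]
        cube[g, counters[g]] = y[s]
        counters[g] += 1

    def P(axes_keep):
        # projection: mean over all axes not kept, broadcast back
        axes_all = (0, 1, 2, 3)
        axes_avg = tuple(ax for ax in axes_all if ax not in axes_keep)
        return np.broadcast_to(cube.mean(axis=axes_avg, keepdims=True), cube.shape)

    full = {}
    full["mu"] = P(())
    full["A"] = P((0,)) - full["mu"]
    full["S"] = P((0, 1)) - P((0,))
    full["B"] = P((2,)) - full["mu"]
    full["AB"] = P((0, 2)) - P((0,)) - P((2,)) + full["mu"]
    full["BS"] = P((0, 1, 2)) - P((0, 1)) - P((0, 2)) + P((0,))
    full["C"] = P((3,)) - full["mu"]
    full["AC"] = P((0, 3)) - P((0,)) - P((3,)) + full["mu"]
    full["CS"] = P((0, 1, 3)) - P((0, 1)) - P((0, 3)) + P((0,))
    full["BC"] = P((2, 3)) - P((2,)) - P((3,)) + full["mu"]
    full["ABC"] = (
        P((0, 2, 3)) - P((0, 2)) - P((0, 3)) - P((2, 3)) + P((0,)) + P((2,)) + P((3,)) - full["mu"]
    )
    full["BCS"] = cube - sum(full.values())
    return {k: float((v**2).sum()) for k, v in full.items() if k != "mu"}


class TestMixedAnova:
    def test_additive_zero_noise_interaction_is_zero(self):
        # cell means additive in group and within factor, no noise
        groups = np.repeat([0, 1], 4)
        y = np.array([[g * 2.0 + j for j in range(3)] for g in groups])
        res = mixed_anova_from_array(y, groups, factor_names=("g", "w", "z"))
        inter = next(r for r in res if r.effect == "g x w")
        assert inter.F == 0.0

    def test_two_way_against_projection_oracle(self, rng):
        a, n, b, c = 2, 3, 2, 1
        groups = np.repeat([0, 1], n)
        y = rng.normal(size=(a * n, b, c))
        res = mixed_anova_from_array(y, groups, factor_names=("g", "w1", "w2"))
        ss = projection_ss_oracle(y, groups, a, n, b, c)
        by_effect = {r.effect: r for r in res}
        assert by_effect["g"].F == pytest.approx((ss["A"] / 1) / (ss["S"] / 4), rel=1e-9)
        assert by_effect["w1"].F == pytest.approx((ss["B"] / 1) / (ss["BS"] / 4), rel=1e-9)
        assert by_effect["g x w1"].F == pytest.approx((ss["AB"] / 1) / (ss["BS"] / 4), rel=1e-9)

    def test_three_way_against_projection_oracle(self, rng):
        a, n, b, c = 2, 3, 2, 4
        groups = np.repeat([0, 1], n)
        y = rng.normal(size=(a * n, b, c))
        res = mixed_anova_from_array(y, groups, factor_names=("g", "v", "m"))
        ss = projection_ss_oracle(y, groups, a, n, b, c)
        df = {
            "g": (1, "A", "S", 1 * (a * (n - 1))),
            "v": (1, "B", "BS", a * (n - 1) * (b - 1)),
            "g x v": (1, "AB", "BS", a * (n - 1) * (b - 1)),
            "m": (c - 1, "C", "CS", a * (n - 1) * (c - 1)),
            "g x m": (c - 1, "AC", "CS", a * (n - 1) * (c - 1)),
            "v x m": ((b - 1) * (c - 1), "BC", "BCS", a * (n - 1) * (b - 1) * (c - 1)),
            "g x v x m": ((b - 1) * (c - 1), "ABC", "BCS", a * (n - 1) * (b - 1) * (c - 1)),
        }
        df["g"] = (1, "A", "S", a * (n - 1))
        for r in res:
            dnum, eff_key, err_key, dden = df[r.effect]
            expected_f = (ss[eff_key] / dnum) / (ss[err_key] / dden)
            assert r.F == pytest.approx(expected_f, rel=1e-8), r.effect
            assert (r.df_num, r.df_den) == (dnum, dden)
            assert r.partial_eta_sq == pytest.approx(
                ss[eff_key] / (ss[eff_key] + ss[err_key]), rel=1e-8
            )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n, b = 8, 3
        groups = ["A"] * n + ["B"] * n
        y = rng.normal(size=(2 * n, b))
        table = _long_table(y[:, :, None], groups, [f"l{j}" for j in range(b)], ["x"])
        table = table.drop(columns="w2")
        mine = {r.effect: r for r in mixed_anova(table, "y", ["w1"], "grp")}
        ref = pg.mixed_anova(data=table, dv="y", within="w1", between="grp", subject="participant_id")
        ref = ref.set_index("Source")
        assert mine["grp"].F == pytest.approx(ref.loc["grp", "F"], rel=1e-9)
        assert mine["w1"].F == pytest.approx(ref.loc["w1", "F"], rel=1e-9)
        assert mine["grp x w1"].F == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)
        assert mine["w1"].partial_eta_sq == pytest.approx(ref.loc["w1", "np2"], rel=1e-9)
        assert mine["grp"].p == pytest.approx(ref.loc["grp", "p_unc"], rel=1e-9)

    def test_ss_conservation(self, rng):
        groups = np.repeat([0, 1, 2], 4)
        y = rng.normal(size=(12, 2, 7))
        res = mixed_anova_from_array(y, groups)
        ss_effects = sum(r.ss_effect for r in res)
        # error terms: S, BS, CS, BCS each appear as ss_error for >=1 effect
        errors = {}
        for r in res:
            errors[(r.df_den, round(r.ss_error, 9))] = r.ss_error
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert ss_effects + sum(errors.values()) == pytest.approx(ss_total, rel=1e-9)

    def test_partial_eta_reproduces_f(self, rng):
        groups = np.repeat([0, 1], 10)
        y = rng.normal(size=(20, 2, 3))
        for r in mixed_anova_from_array(y, groups):
            e = r.partial_eta_sq
            assert r.F == pytest.approx(e / (1 - e) * (r.df_den / r.df_num), rel=1e-9)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(2024)
        n, reps, alpha = 35, 600, 0.05
        groups = np.repeat([0, 1], n)
        rej = 0
        for _ in range(reps):
            y = rng.normal(size=(2 * n, 2))
            res = mixed_anova_from_array(y, groups, factor_names=("g", "v", "w"))
            inter = next(r for r in res if r.effect == "g x v")
            rej += inter.p < alpha
        assert 0.03 <= rej / reps <= 0.07

    def test_design_errors(self, rng):
        y = rng.normal(size=(6, 2))
        with pytest.raises(DesignError):
            mixed_anova_from_array(y, np.array([0, 0, 0, 0, 1, 1]))  # unbalanced
        table = _long_table(y[:, :, None], ["A"] * 3 + ["B"] * 3, ["l0", "l1"], ["x"]).drop(columns="w2")
        incomplete = table.iloc[:-1]
        with pytest.raises(DesignError):
            mixed_anova(incomplete, "y", ["w1"], "grp")
        dup = pd.concat([table, table.iloc[:1]])
        with pytest.raises(DesignError):
            mixed_anova(dup, "y", ["w1"], "grp")
        with pytest.raises(DesignError):
            mixed_anova_from_array(y[:1], None)  # single participant

    def test_within_only_design(self, rng):
        # no between factor: df mirror a one-group repeated-measures test
        y = rng.normal(size=(35, 2))
        res = mixed_anova_from_array(y, None, factor_names=("g", "v", "w"))
        effects = {r.effect: r for r in res}
        assert set(effects) == {"v"}
        assert (effects["v"].df_num, effects["v"].df_den) == (1, 34)
        # equivalent to a paired t-test: F == t^2
        t = paired_t(y[:, 0], y[:, 1])
        assert effects["v"].F == pytest.approx(t.statistic**2, rel=1e-9)
        assert effects["v"].p == pytest.approx(t.p, rel=1e-9)


class TestTTests:
    def test_group_matching_check_from_raw_data(self, rng):
        # construct samples with the printed summary stats, then compare paths
        a = rng.normal(size=35)
        a = (a - a.mean()) / a.std(ddof=1) * 2.85 + 20.54
        b = rng.normal(size=35)
        b = (b - b.mean()) / b.std(ddof=1) * 1.52 + 20.28
        raw = independent_t(a, b)
        summ = summary_t(20.54, 2.85, 35, 20.28, 1.52, 35)
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-9)
        assert raw.df == summ.df == 68
        assert summ.statistic == pytest.approx(0.476, abs=5e-4)

    def test_identical_samples(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.effect_size == 0.0
        assert r.degenerate

    def test_paired_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            mine = paired_t(x, y)
            ref = sps.ttest_rel(x, y)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)
            d = (x - y).mean() / (x - y).std(ddof=1)
            assert mine.effect_size == pytest.approx(d, abs=1e-10)

    def test_independent_matches_scipy(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(loc=0.4, size=25)
        mine = independent_t(x, y)
        ref = sps.ttest_ind(x, y)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_summary_sign_symmetry(self):
        a = summary_t(10.0, 2.0, 10, 12.0, 3.0, 10)
        b = summary_t(12.0, 3.0, 10, 10.0, 2.0, 10)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            summary_t(1.0, 0.0, 10, 2.0, 1.0, 10)
        with pytest.raises(DomainError):
            summary_t(1.0, 1.0, 1, 2.0, 1.0, 10)


def _signflip_pvalue(diffs):
    """Exact two-sided p by explicit enumeration of all 2^n sign patterns."""
    diffs = np.asarray([d for d in diffs if d != 0], dtype=float)
    n = diffs.size
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = min(ranks[diffs > 0].sum(), ranks[diffs < 0].sum())
    total = ranks.sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_neg = sum(r for r, s in zip(ranks, signs) if s)
        w = min(w_neg, total - w_neg)
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_all_positive_n5(self):
        r = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert r.statistic == 0.0
        assert r.p == pytest.approx(0.0625)

    def test_single_pair(self):
        assert wilcoxon_signed_rank([3.0]).p == 1.0

    def test_all_zero_differences_degenerate(self):
        r = wilcoxon_signed_rank([0.0, 0.0])
        assert r.degenerate
        assert r.p == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            d = rng.integers(-6, 7, size=int(rng.integers(2, 11))).astype(float)
            if np.all(d == 0):
                continue
            mine = wilcoxon_signed_rank(d)
            assert mine.p == pytest.approx(_signflip_pvalue(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(40):
            d = rng.normal(size=int(rng.integers(3, 20)))
            mine = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, method="exact")
            assert mine.statistic == pytest.approx(ref.statistic)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_large_n(self, rng):
        d = rng.normal(loc=0.3, size=60)
        mine = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="approx", correction=False)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_paired_form(self):
        x = [5.0, 6.0, 7.0]
        y = [4.0, 5.0, 6.0]
        assert wilcoxon_signed_rank(x, y).statistic == 0.0


class TestAnovaFrame:
    def test_schema(self, rng):
        res = mixed_anova_from_array(rng.normal(size=(6, 2)), np.repeat([0, 1], 3))
        df = anova_frame(res)
        assert list(df.columns) == ["effect", "F", "df_num", "df_den", "p", "partial_eta_sq"]


class TestCorrections:
    def test_greenhouse_geisser_raises_p_for_multilevel_within(self, rng):
        groups = np.repeat([0, 1], 8)
        y = rng.normal(size=(16, 7)) + np.linspace(0, 1.5, 7)  # real within effect
        # correlate levels unevenly to depress epsilon
        y[:, 1] = y[:, 0] * 0.95 + rng.normal(scale=0.1, size=16)
        plain = {r.effect: r for r in mixed_anova_from_array(y, groups, factor_names=("g", "m", "x"))}
        gg = {
            r.effect: r
            for r in mixed_anova_from_array(y, groups, factor_names=("g", "m", "x"), gg_correction=True)
        }
        assert gg["m"].gg_epsilon is not None
        assert 1.0 / 6.0 <= gg["m"].gg_epsilon < 1.0
        assert plain["m"].F > 1
        assert gg["m"].p >= plain["m"].p  # fewer effective df, larger p when F > 1
        assert gg["m"].F == pytest.approx(plain["m"].F)  # F itself unchanged

    def test_holm_adjustment_monotone(self):
        from phraseseg.inference import _holm

        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = _holm(p)
        assert np.all(adj >= p)
        assert adj[0] == pytest.approx(0.04)
        assert adj[3] == pytest.approx(0.5)


class TestAnalyzeExperiment:
    def _tables(self, rng, interaction=0.0):
        rows_scores, rows_seg, rows_conf = [], [], []
        for g, instr in enumerate(("speech", "music")):
            for i in range(6):
                pid = f"{instr}{i}"
                for v, version in enumerate(("natural", "delexicalized")):
                    bump = interaction if (g == 1 and v == 1) else 0.0
                    for model in ("pause", "pitch_break", "pause_pitch_break", "pitch_rise",
                                  "pitch_drop", "pause_pitch_rise", "pause_pitch_drop"):
                        rows_scores.append(
                            {"participant_id": pid, "instruction": instr, "stimulus_id": "s1",
                             "version": version, "model": model,
                             "score": float(rng.normal(0.3 + bump, 0.05))}
                        )
                    rows_seg.append(
                        {"participant_id": pid, "instruction": instr, "stimulus_id": "s1",
                         "version": version,
                         "mean_len_ms": float(rng.normal(7000 + bump * 1e4, 300)),
                         "sd_len_ms": float(rng.normal(2000, 100))}
                    )
                    rows_conf.append(
                        {"participant_id": pid, "instruction": instr, "stimulus_id": "s1",
                         "version": version, "confidence": float(rng.normal(3.5, 0.4))}
                    )
        return (pd.DataFrame(rows_scores), pd.DataFrame(rows_seg), pd.DataFrame(rows_conf))

    def test_gate_and_followups(self, rng):
        from phraseseg.inference import analyze_experiment

        scores, seglens, conf = self._tables(rng, interaction=0.4)
        out = analyze_experiment(scores, seglens, confidence=conf, holm=True)
        assert {"seglen_mean", "seglen_sd", "matching", "per_model", "followup_t", "confidence"} <= set(out)
        if out["three_way_significant"]:
            assert len(out["per_model"]) == 7
            assert "p_holm" in out["followup_t"].columns
        assert len(out["confidence"]) == 3

    def test_missing_column_raises(self, rng):
        from phraseseg.inference import analyze_experiment

        scores, seglens, _ = self._tables(rng)
        with pytest.raises(DesignError):
            analyze_experiment(scores.drop(columns="model"), seglens)
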
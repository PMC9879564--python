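"""Mixed ANOVAs, post-hocs, t-tests, correlations and recognition scoring."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from gart.stats import (
    correlation_matrix,
    mixed_anova,
    mixed_anova_2x3,
    posthoc_bonferroni,
    recognition_accuracy,
    ttest_independent,
    ttest_one_sample,
)

CONDS = ["real", "sham", "none"]
PHASES = ["DP", "NDP"]


def make_design(n_per_group=6, seed=0, g_eff=0.0, c_eff=0.0, p_eff=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(2 * n_per_group):
        g = "ADHD" if s < n_per_group else "HC"
        subj_int = rng.normal(0, 1.0)
        for c in CONDS:
            for p in PHASES:
                y = (rng.normal() + subj_int
                     + (g_eff if g == "ADHD" else 0.0)
                     + (c_eff if c == "real" else 0.0)
                     + (p_eff if p == "DP" else 0.0))
                rows.append(dict(participant=f"s{s:02d}", group=g,
                                 condition=c, phase=p, y=y))
    return pd.DataFrame(rows)


def naive_ss(df):
    """Loop-based sums-of-squares oracle for the 2x3x2 design."""
    gm = df.y.mean()
    subs = sorted(df.participant.unique())
    grp = {s: df[df.participant == s].group.iloc[0] for s in subs}
    glv = sorted(set(grp.values()))
    ng = {g: sum(1 for s in subs if grp[s] == g) for g in glv}

    def m(**kw):
        mask = np.ones(len(df), bool)
        for k, v in kw.items():
            mask &= (df[k] == v).to_numpy()
        return df.y[mask].mean()

    ss = {}
    ss["group"] = 6 * sum(ng[g] * (m(group=g) - gm) ** 2 for g in glv)
    n = len(subs)
    ss["condition"] = n * 2 * sum((m(condition=c) - gm) ** 2 for c in CONDS)
    ss["phase"] = n * 3 * sum((m(phase=p) - gm) ** 2 for p in PHASES)
    ss["group * condition"] = 2 * sum(
        ng[g] * (m(group=g, condition=c) - m(group=g) - m(condition=c)
                 + gm) ** 2 for g in glv for c in CONDS)
    ss["group * phase"] = 3 * sum(
        ng[g] * (m(group=g, phase=p) - m(group=g) - m(phase=p) + gm) ** 2
        for g in glv for p in PHASES)
    ss["condition * phase"] = n * sum(
        (m(condition=c, phase=p) - m(condition=c) - m(phase=p) + gm) ** 2
        for c in CONDS for p in PHASES)
    ss["group * condition * phase"] = sum(
        ng[g] * (m(group=g, condition=c, phase=p) - m(group=g, condition=c)
                 - m(group=g, phase=p) - m(condition=c, phase=p)
                 + m(group=g) + m(condition=c) + m(phase=p) - gm) ** 2
        for g in glv for c in CONDS for p in PHASES)
    return ss


class TestMixedAnova:
    def test_effect_ss_match_naive_oracle(self):
        df = make_design(seed=3, g_eff=0.4, p_eff=0.3)
        res = mixed_anova(df, "y").set_index("effect")
        for effect, ss in naive_ss(df).items():
            assert res.loc[effect, "ss"] == pytest.approx(ss, abs=1e-8)

    def test_total_ss_decomposition_is_conserved(self):
        df = make_design(seed=4)
        res = mixed_anova(df, "y").set_index("effect")
        # effect SS + subjects(G) + the three within error terms must
        # reproduce the total SS exactly (error SS recovered as MS_err * df)
        err = {}
        for eff in ("condition", "phase", "condition * phase"):
            row = res.loc[eff]
            err[eff] = (row.ss / row.df_num) / (row.F / row.df_den) \
                if row.F > 0 else 0.0
            # equivalently: MS_err * df_err
            err[eff] = (row.ss / row.df_num) / row.F * row.df_den
        total = (res.ss.sum() + res.attrs["ss_subjects_within_groups"]
                 + sum(err.values()))
        assert total == pytest.approx(res.attrs["ss_total"], rel=1e-9)
        assert res.attrs["ss_total"] == pytest.approx(
            float(((df.y - df.y.mean()) ** 2).sum()))

    def test_2x3_matches_pingouin(self):
        df = make_design(seed=5, g_eff=0.5, c_eff=0.3)
        d2 = df.groupby(["participant", "group", "condition"],
                        as_index=False).y.mean()
        mine = mixed_anova_2x3(d2, "y").set_index("effect")
        ref = pg.mixed_anova(d2, dv="y", within="condition",
                             subject="participant", between="group")
        ref = ref.set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(
            float(ref.loc["group", "F"]))
        assert mine.loc["condition", "F"] == pytest.approx(
            float(ref.loc["condition", "F"]))
        assert mine.loc["group * condition", "F"] == pytest.approx(
            float(ref.loc["Interaction", "F"]))
        assert mine.loc["condition", "p"] == pytest.approx(
            float(ref.loc["condition", "p_unc"]))
        assert mine.loc["condition", "eps_gg"] == pytest.approx(
            float(ref.loc["condition", "eps"]), abs=1e-6)
        assert mine.loc["group", "partial_eta_sq"] == pytest.approx(
            float(ref.loc["group", "np2"]))

    def test_constant_dv_reported_as_zero_or_undefined(self):
        df = make_design(seed=6)
        df["y"] = 5.0
        res = mixed_anova(df, "y").set_index("effect")
        for eff in res.index:
            assert res.loc[eff, "F"] == 0.0 or np.isnan(res.loc[eff, "F"])

    def test_missing_cell_names_participant(self):
        df = make_design(seed=7)
        df = df[~((df.participant == "s03") & (df.condition == "sham")
                  & (df.phase == "DP"))]
        with pytest.raises(ValueError, match="s03"):
            mixed_anova(df, "y")

    def test_sphericity_correction_rule(self):
        df = make_design(seed=8, c_eff=0.2)
        res = mixed_anova(df, "y").set_index("effect")
        row = res.loc["condition"]
        assert row.correction_applied in ("GG", "HF")
        if row.eps_gg > 0.75:
            assert row.correction_applied == "HF"
        else:
            assert row.correction_applied == "GG"
        assert res.loc["phase", "correction_applied"] == "none"

    def test_type_i_error_near_nominal(self):
        """Null data: Group effect rejected ~5% of the time."""
        rej = 0
        n_rep = 300
        for i in range(n_rep):
            df = make_design(n_per_group=5, seed=1000 + i)
            res = mixed_anova(df, "y").set_index("effect")
            if res.loc["group", "p"] < 0.05:
                rej += 1
        rate = rej / n_rep
        assert 0.02 <= rate <= 0.09


class TestPosthoc:
    def test_two_levels_adjusted_equals_raw(self):
        df = make_design(seed=9)
        out = posthoc_bonferroni(df, "y", "phase")
        assert len(out) == 1
        assert out.p_bonferroni[0] == pytest.approx(out.p_raw[0])

    def test_three_levels_multiplied_by_three(self):
        df = make_design(seed=10)
        out = posthoc_bonferroni(df, "y", "condition")
        assert len(out) == 3
        for _, r in out.iterrows():
            assert r.p_bonferroni == pytest.approx(min(1.0, 3 * r.p_raw))
            assert r.p_bonferroni >= r.p_raw


class TestTTests:
    def test_identical_groups_give_t0_p1(self):
        x = [1.0, 2.0, 3.0, 4.0]
        out = ttest_independent(x, x)
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)
        assert out["cohen_d"] == pytest.approx(0.0)

    def test_two_sample_matches_permutation_oracle(self, rng):
        x = rng.normal(0.0, 1.0, 12)
        y = rng.normal(0.8, 1.0, 12)
        out = ttest_independent(x, y)
        pooled = np.concatenate([x, y])
        obs = abs(np.mean(x) - np.mean(y))
        perm_rng = np.random.default_rng(0)
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = perm_rng.permutation(pooled)
            if abs(perm[:12].mean() - perm[12:].mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert out["p"] == pytest.approx(p_perm, abs=0.03)

    def test_one_sample_null_ts_are_small(self):
        rng = np.random.default_rng(3)
        ts = [abs(ttest_one_sample(rng.normal(0, 1, 20))["t"])
              for _ in range(100)]
        assert np.mean(ts) < 1.2  # E|t| for t19 under H0 is ~0.8

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ttest_one_sample([2.0, 2.0, 2.0])


class TestCorrelations:
    def test_perfect_linear_relation(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2 * df.x
        r, p = correlation_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert np.allclose(np.diag(r), 1.0)

    def test_bh_stepup_hand_example(self):
        from statsmodels.stats.multitest import multipletests
        raw = [0.01, 0.02, 0.03, 0.04]
        rej, _, _, _ = multipletests(raw, alpha=0.05, method="fdr_bh")
        assert rej.all()  # p_i <= (i/4)*0.05 for the largest -> all rejected

    def test_bh_adjustment_monotone_in_raw_p(self, rng):
        n = 30
        df = pd.DataFrame(rng.normal(size=(n, 5)),
                          columns=list("abcde"))
        from scipy import stats as sps
        r, p_adj = correlation_matrix(df)
        raws = {}
        for i, a in enumerate("abcde"):
            for b in "abcde"[i + 1:]:
                raws[(a, b)] = sps.pearsonr(df[a], df[b])[1]
        pairs = sorted(raws, key=raws.get)
        adj = [p_adj.loc[a, b] for a, b in pairs]
        assert all(x <= y + 1e-12 for x, y in zip(adj, adj[1:]))
        assert all(p_adj.loc[a, b] >= raws[(a, b)] - 1e-12
                   for a, b in raws)

    def test_spearman_invariant_under_monotone_transform(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=25)})
        df["y"] = df.x + rng.normal(0, 0.5, 25)
        r1, _ = correlation_matrix(df, method="spearman")
        df2 = pd.DataFrame({"x": np.exp(df.x), "y": df.y ** 3})
        r2, _ = correlation_matrix(df2, method="spearman")
        assert r1.loc["x", "y"] == pytest.approx(r2.loc["x", "y"])

    def test_constant_column_warns_and_yields_nan(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            r, p = correlation_matrix(df)
        assert np.isnan(r.loc["x", "y"])


class TestRecognition:
    def test_all_correct(self):
        truth = np.arange(60) % 2 == 0
        assert recognition_accuracy(truth, truth) == 1.0

    def test_all_seen_equals_prevalence(self):
        truth = np.arange(60) < 30
        judg = np.ones(60, bool)
        assert recognition_accuracy(judg, truth) == 0.5

    def test_random_guessing_near_half(self, rng):
        truth = np.arange(60) < 30
        accs = [recognition_accuracy(rng.uniform(size=60) < 0.5, truth)
                for _ in range(200)]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            recognition_accuracy([True], [True, False])
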
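"""Mixed-ANOVA layer: effect sizes, sphericity, family alpha, post hocs.

The mixed ANOVA is checked against (a) an explicit loop-based cell-means
sums-of-squares oracle written here, and (b) pingouin's independent
implementation.
"""

import numpy as np
import pandas as pd
import pytest

from postprime.errors import (DataError, DegenerateDataError, MissingCellError,
                              PosthocRefusedError)
from postprime.stats_engine import (gg_epsilon, holm_family_alpha,
                                    holm_sequential, mauchly_test,
                                    mixed_rm_anova, partial_eta_squared,
                                    posthoc_pairwise)


def make_design(rng, n_a=6, n_b=6, k=4, cond_effect=0.0, inter_effect=0.0,
                subj_sd=1.0, noise_sd=0.5, group_effect=0.0):
    rows = []
    for g, n in (("A", n_a), ("B", n_b)):
        for i in range(n):
            pid = f"{g}{i}"
            base = rng.normal(0, subj_sd) + (group_effect if g == "B" else 0.0)
            for j in range(k):
                v = base + cond_effect * j + rng.normal(0, noise_sd)
                if g == "B":
                    v += inter_effect * j
                rows.append((pid, g, f"c{j}", v))
    return pd.DataFrame(rows, columns=["participant", "group", "condition",
                                       "value"])


def anova_oracle(df):
    """First-principles cell-means computation with explicit loops."""
    subjects = sorted(df.participant.unique())
    conds = sorted(df.condition.unique())
    groups = {p: df[df.participant == p].group.iloc[0] for p in subjects}
    glabels = sorted(set(groups.values()))
    y = {(p, c): df[(df.participant == p) & (df.condition == c)].value.mean()
         for p in subjects for c in conds}
    grand = np.mean(list(y.values()))
    k, n = len(conds), len(subjects)
    subj_mean = {p: np.mean([y[p, c] for c in conds]) for p in subjects}
    cond_mean = {c: np.mean([y[p, c] for p in subjects]) for c in conds}
    gmembers = {g: [p for p in subjects if groups[p] == g] for g in glabels}
    group_mean = {g: np.mean([y[p, c] for p in gmembers[g] for c in conds])
                  for g in glabels}
    cell_mean = {(g, c): np.mean([y[p, c] for p in gmembers[g]])
                 for g in glabels for c in conds}

    ss_group = k * sum(len(gmembers[g]) * (group_mean[g] - grand) ** 2
                       for g in glabels)
    ss_bs = k * sum((subj_mean[p] - grand) ** 2 for p in subjects)
    ss_subj = ss_bs - ss_group
    ss_cond = n * sum((cond_mean[c] - grand) ** 2 for c in conds)
    ss_cells = sum(len(gmembers[g]) * (cell_mean[g, c] - grand) ** 2
                   for g in glabels for c in conds)
    ss_inter = ss_cells - ss_group - ss_cond
    ss_within = sum((y[p, c] - subj_mean[p]) ** 2 for p in subjects for c in conds)
    ss_err = ss_within - ss_cond - ss_inter

    g = len(glabels)
    return {
        "group": (ss_group / (g - 1)) / (ss_subj / (n - g)),
        "condition": (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - g))),
        "condition:group": (ss_inter / ((g - 1) * (k - 1)))
                           / (ss_err / ((k - 1) * (n - g))),
        "ss_total": ss_group + ss_subj + ss_cond + ss_inter + ss_err,
    }


class TestEffectSize:
    @pytest.mark.parametrize("F,df1,df2,expected", [
        (36.463, 1.845, 29.518, 0.695),
        (31.343, 3, 48, 0.662),
        (11.06, 1, 18, 0.381),
        (11.630, 1, 18, 0.392),
        (19.020, 1, 18, 0.514),
    ])
    def test_reported_triplets(self, F, df1, df2, expected):
        assert round(partial_eta_squared(F, df1, df2), 3) == pytest.approx(
            expected, abs=0.0011)

    def test_zero_F(self):
        assert partial_eta_squared(0.0, 3, 48) == 0.0

    def test_identity_on_computed_tables(self, rng):
        df = make_design(rng, cond_effect=0.4)
        table = mixed_rm_anova(df, gg="never")
        for _, row in table.iterrows():
            assert row.eta_p2 == pytest.approx(
                partial_eta_squared(row.F, row.df1, row.df2), abs=1e-12)


class TestSphericity:
    def test_compound_symmetry_gives_one(self, rng):
        # iid + shared subject intercept -> compound symmetric covariance
        base = rng.normal(0, 2, (2000, 1))
        y = base + rng.normal(0, 1, (2000, 4))
        assert gg_epsilon(y) > 0.97

    def test_rank_one_contrast_covariance_hits_lower_bound(self):
        t = np.linspace(-1, 1, 40)
        y = np.outer(t, [0.0, 1.0, 2.0, 3.0])  # all variance on one contrast
        assert gg_epsilon(y) == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_matches_eigenvalue_formula(self, rng):
        """Independent oracle: ε from eigenvalues of the double-centred
        covariance, ε = (Σλ)² / ((k−1)Σλ²)."""
        y = rng.normal(0, 1, (15, 4)) @ rng.normal(0, 1, (4, 4))
        s = np.cov(y, rowvar=False)
        sc = (s - s.mean(0, keepdims=True) - s.mean(1, keepdims=True) + s.mean())
        lam = np.linalg.eigvalsh(sc)
        eps_oracle = lam.sum() ** 2 / (3 * (lam ** 2).sum())
        assert gg_epsilon(y) == pytest.approx(eps_oracle, abs=1e-10)

    def test_matches_pingouin_single_group(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, (12, 4)) + rng.normal(0, 1, (12, 1))
        assert gg_epsilon(y) == pytest.approx(
            float(pg.epsilon(pd.DataFrame(y), correction="gg")), abs=1e-9)
        w_ours, _ = mauchly_test(y)
        sph = pg.sphericity(pd.DataFrame(y))
        assert w_ours == pytest.approx(float(sph.W), abs=1e-9)

    def test_gg_never_inflates_dfs_or_shrinks_p(self, rng):
        y_df = make_design(rng, cond_effect=0.5, inter_effect=0.4)
        plain = mixed_rm_anova(y_df, gg="never")
        corrected = mixed_rm_anova(y_df, gg="always")
        for effect in ("condition", "condition:group"):
            a = plain[plain.effect == effect].iloc[0]
            b = corrected[corrected.effect == effect].iloc[0]
            assert b.df1 <= a.df1 + 1e-12 and b.df2 <= a.df2 + 1e-12
            if a.F >= 1.0:
                # shrinking dfs is conservative for supra-unity F ratios
                assert b.p >= a.p - 1e-12


class TestMixedAnova:
    def test_all_identical_gives_zero_F(self):
        rows = [(f"p{i}", "A" if i < 3 else "B", c, 5.0)
                for i in range(6) for c in ("c1", "c2", "c3")]
        df = pd.DataFrame(rows, columns=["participant", "group", "condition",
                                         "value"])
        table = mixed_rm_anova(df, gg="never")
        assert (table.F == 0).all()
        assert (table.p == 1.0).all()

    def test_matches_loop_oracle_on_random_designs(self, rng):
        for _ in range(20):
            df = make_design(rng, n_a=int(rng.integers(3, 7)),
                             n_b=int(rng.integers(3, 7)),
                             k=int(rng.integers(2, 5)),
                             cond_effect=rng.uniform(0, 1),
                             inter_effect=rng.uniform(0, 0.5),
                             group_effect=rng.uniform(0, 1))
            table = mixed_rm_anova(df, gg="never").set_index("effect")
            oracle = anova_oracle(df)
            for effect in ("group", "condition", "condition:group"):
                assert table.loc[effect, "F"] == pytest.approx(
                    oracle[effect], abs=1e-10, rel=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = make_design(rng, cond_effect=0.3, inter_effect=0.2)
        ours = mixed_rm_anova(df, gg="never").set_index("effect")
        theirs = pg.mixed_anova(data=df, dv="value", within="condition",
                                between="group", subject="participant",
                                correction=False).set_index("Source")
        assert ours.loc["group", "F"] == pytest.approx(theirs.loc["group", "F"])
        assert ours.loc["condition", "F"] == pytest.approx(
            theirs.loc["condition", "F"])
        assert ours.loc["condition:group", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"])
        assert ours.loc["condition", "eta_p2"] == pytest.approx(
            theirs.loc["condition", "np2"])

    def test_missing_cell_names_participant(self, rng):
        df = make_design(rng)
        df = df[~((df.participant == "A2") & (df.condition == "c1"))]
        with pytest.raises(MissingCellError, match="A2"):
            mixed_rm_anova(df)

    def test_zero_error_variance_with_effect_is_degenerate(self):
        rows = []
        for g, ps in (("A", ["a0", "a1"]), ("B", ["b0", "b1"])):
            for i, p in enumerate(ps):
                for j, c in enumerate(("c1", "c2", "c3")):
                    rows.append((p, g, c, float(j) + i))  # no residual noise
        df = pd.DataFrame(rows, columns=["participant", "group", "condition",
                                         "value"])
        with pytest.raises(DegenerateDataError):
            mixed_rm_anova(df, gg="never")

    def test_trials_averaged_before_anova(self, rng):
        df = make_design(rng, cond_effect=0.5)
        # replicate every row as 3 jittered trials; condition means unchanged
        trials = pd.concat([df.assign(value=df.value + d)
                            for d in (-0.1, 0.0, 0.1)])
        a = mixed_rm_anova(df, gg="never")
        b = mixed_rm_anova(trials, gg="never")
        assert np.allclose(a.F, b.F)

    def test_power_for_one_sd_condition_effect(self, rng):
        """Injected condition effect of 1 within-subject SD, n=10/group:
        detected in > 80% of 500 replicates."""
        hits = 0
        for _ in range(500):
            df = make_design(rng, n_a=10, n_b=10, k=4, cond_effect=1.0,
                             subj_sd=1.0, noise_sd=1.0)
            table = mixed_rm_anova(df, gg="never")
            p = table[table.effect == "condition"].iloc[0].p
            hits += p < 0.05
        assert hits / 500 > 0.8


class TestFamilies:
    @pytest.mark.parametrize("n_dvs,expected", [(5, 0.005), (2, 0.0125),
                                                (1, 0.025), (7, 0.05 / 14)])
    def test_divided_alpha(self, n_dvs, expected):
        assert holm_family_alpha(n_dvs) == pytest.approx(expected)

    def test_sequential_holm_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(0, 0.2, 12)
        ours = holm_sequential(p, 0.05)
        theirs = sm.multipletests(p, alpha=0.05, method="holm")[0]
        assert np.array_equal(ours, theirs)


class TestPosthoc:
    def test_multiplier_is_six_for_four_conditions(self, rng):
        df = make_design(rng, k=4, cond_effect=1.0)
        out = posthoc_pairwise(df, omnibus_significant=True)
        assert (out.n_comparisons == 6).all()
        assert len(out) == 12  # 6 pairs × 2 groups

    def test_large_raw_p_caps_at_one(self, rng):
        df = make_design(rng, k=4, cond_effect=0.0)
        out = posthoc_pairwise(df, omnibus_significant=True)
        assert (out.p_adj <= 1.0).all()
        assert np.allclose(out.p_adj, np.minimum(1.0, out.p_raw * 6))

    def test_identical_samples_give_p_one(self):
        rows = [(f"p{i}", "A" if i < 2 else "B", c, 1.0 * i)
                for i in range(4) for c in ("c1", "c2")]
        df = pd.DataFrame(rows, columns=["participant", "group", "condition",
                                         "value"])
        out = posthoc_pairwise(df, omnibus_significant=True)
        assert (out.p_adj == 1.0).all()

    def test_refused_without_omnibus(self, rng):
        with pytest.raises(PosthocRefusedError):
            posthoc_pairwise(make_design(rng), omnibus_significant=False)
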
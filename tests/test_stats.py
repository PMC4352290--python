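import itertools

import numpy as np
import pandas as pd
import pytest

from sfgamma.stats import (
    bootstrap_ci,
    generalized_eta_squared,
    gg_epsilon,
    holm_adjust,
    posthoc_pairwise,
    rm_anova,
    rm_anova_array,
)


def anova_2x2_ss_oracle(Y):
    """Direct sums-of-squares decomposition for a 2x2 within design.

    Hand-transcribed textbook formulas: effect SS from marginal means,
    error SS from the subject x effect interaction residuals.
    """
    n = Y.shape[0]
    grand = Y.mean()
    a_means = Y.mean(axis=(0, 2))
    b_means = Y.mean(axis=(0, 1))
    s_means = Y.mean(axis=(1, 2))
    cell = Y.mean(axis=0)
    ss_a = n * 2 * ((a_means - grand) ** 2).sum()
    ss_b = n * 2 * ((b_means - grand) ** 2).sum()
    ss_ab = n * (
        (cell - a_means[:, None] - b_means[None, :] + grand) ** 2
    ).sum()
    out = {}
    for name, ss_eff, margin, df in [
        ("A", ss_a, Y.mean(axis=2), 1),
        ("B", ss_b, Y.mean(axis=1), 1),
        ("A:B", ss_ab, Y, 1),
    ]:
        if name == "A:B":
            resid = (
                Y
                - Y.mean(axis=1, keepdims=True)
                - Y.mean(axis=2, keepdims=True)
                - cell[None]
                + a_means[None, :, None]
                + b_means[None, None, :]
                + s_means[:, None, None]
                - grand
            )
            ss_err = (resid**2).sum()
        else:
            dev = (
                margin
                - margin.mean(axis=0, keepdims=True)
                - margin.mean(axis=1, keepdims=True)
                + grand
            )
            ss_err = 2 * (dev**2).sum()
        out[name] = (ss_eff, ss_err, df, (n - 1) * df)
    return out


class TestRmAnova:
    def test_matches_hand_ss_oracle_on_2x2_fixture(self):
        # fixed 4-subject fixture
        Y = np.array(
            [
                [[4.0, 6.0], [5.0, 9.0]],
                [[3.0, 5.0], [4.0, 8.0]],
                [[6.0, 7.0], [5.0, 10.0]],
                [[5.0, 8.0], [6.0, 12.0]],
            ]
        )
        res = rm_anova_array(Y, ["A", "B"]).set_index("effect")
        oracle = anova_2x2_ss_oracle(Y)
        for name, (ss_eff, ss_err, df, df_err) in oracle.items():
            F = (ss_eff / df) / (ss_err / df_err)
            assert res.loc[name, "F"] == pytest.approx(F, abs=1e-10)
            assert res.loc[name, "SS"] == pytest.approx(ss_eff, abs=1e-10)
            assert res.loc[name, "SS_error"] == pytest.approx(ss_err, abs=1e-10)

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        Y = rng.normal(0, 1, (12, 2, 3)) + rng.normal(0, 1, (12, 1, 1))
        Y[:, 0, :] += 0.8
        rows = [
            {"participant": s, "A": a, "B": b, "dv": Y[s, i, j]}
            for s in range(12)
            for i, a in enumerate(["a1", "a2"])
            for j, b in enumerate(["b1", "b2", "b3"])
        ]
        mine = rm_anova(pd.DataFrame(rows), "dv", ["A", "B"]).set_index("effect")
        ref = pg.rm_anova(
            data=pd.DataFrame(rows), dv="dv", within=["A", "B"],
            subject="participant", detailed=True, effsize="ng2",
        ).set_index("Source")
        for mine_key, ref_key in [("A", "A"), ("B", "B"), ("A:B", "A * B")]:
            assert mine.loc[mine_key, "F"] == pytest.approx(ref.loc[ref_key, "F"], rel=1e-9)
            assert mine.loc[mine_key, "p_uncorrected"] == pytest.approx(
                ref.loc[ref_key, "p_unc"], rel=1e-9
            )
            assert mine.loc[mine_key, "ges"] == pytest.approx(ref.loc[ref_key, "ng2"], rel=1e-9)
            assert mine.loc[mine_key, "epsilon"] == pytest.approx(ref.loc[ref_key, "eps"], rel=1e-6)
            assert mine.loc[mine_key, "p_GG"] == pytest.approx(
                ref.loc[ref_key, "p_GG_corr"], rel=1e-6
            )

    def test_three_way_decomposition_sums_to_total(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(8, 2, 3, 2))
        res = rm_anova_array(Y, ["A", "B", "C"])
        ss_total = ((Y - Y.mean()) ** 2).sum()
        ss_subject = res.attrs["ss_subject"]
        assert res["SS"].sum() + res["SS_error"].sum() + ss_subject == pytest.approx(
            ss_total, rel=1e-10
        )
        assert len(res) == 7  # 3 mains + 3 two-way + 1 three-way

    def test_subject_offsets_only_give_null_f(self):
        rng = np.random.default_rng(7)
        offsets = rng.normal(0, 3, 10)
        Y = np.tile(offsets[:, None, None], (1, 2, 3))
        res = rm_anova_array(Y, ["A", "B"])
        assert np.allclose(res["F"], 0.0, atol=1e-20)
        assert np.allclose(res["p"], 1.0)
        assert np.allclose(res["ges"], 0.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(8)
        rows = [
            {"participant": s, "A": a, "B": b, "dv": rng.normal()}
            for s in range(6)
            for a in ["x", "y"]
            for b in ["u", "v", "w"]
        ]
        df = pd.DataFrame(rows)
        shuffled = df.sample(frac=1.0, random_state=1)
        a = rm_anova(df, "dv", ["A", "B"])
        b = rm_anova(shuffled, "dv", ["A", "B"])
        assert np.allclose(a["F"], b["F"])

    def test_missing_cells_rejected(self):
        df = pd.DataFrame(
            {
                "participant": [1, 1, 2],
                "A": ["a", "b", "a"],
                "dv": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="balanced"):
            rm_anova(df, "dv", ["A"])

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError, match="two subjects"):
            rm_anova_array(np.zeros((1, 2, 3)), ["A", "B"])

    def test_gg_correction_conservative_where_it_matters(self):
        # shrinking both dfs raises the p-value whenever F >= 1 (the
        # regime where a sphericity correction can change a decision)
        rng = np.random.default_rng(9)
        for _ in range(30):
            Y = rng.normal(size=(10, 2, 3))
            Y[:, 0, :] += rng.uniform(0, 1)
            res = rm_anova_array(Y, ["A", "B"])
            near = res["p_uncorrected"] < 0.1
            assert (res.loc[near, "p_GG"] >= res.loc[near, "p_uncorrected"] - 1e-12).all()


class TestGGEpsilon:
    def test_two_levels_give_unity(self):
        rng = np.random.default_rng(10)
        assert gg_epsilon(rng.normal(size=(10, 2))) == 1.0

    def test_compound_symmetry_approaches_unity(self):
        rng = np.random.default_rng(11)
        n, k = 4000, 4
        subject = rng.normal(0, 1.0, (n, 1))
        scores = subject + rng.normal(0, 1.0, (n, k))
        assert gg_epsilon(scores) > 0.98

    def test_single_dominant_contrast_near_lower_bound(self):
        # one contrast carries almost all variance: epsilon -> 1/(k-1)
        rng = np.random.default_rng(12)
        n, k = 200, 4
        contrast = np.array([1.0, -1.0, 0.0, 0.0])
        scores = rng.normal(0, 10.0, (n, 1)) * contrast + rng.normal(0, 0.01, (n, k))
        eps = gg_epsilon(scores)
        assert eps == pytest.approx(1.0 / (k - 1), abs=0.02)

    def test_clipped_to_valid_range(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            eps = gg_epsilon(rng.normal(size=(5, 4)))
            assert 1.0 / 3.0 <= eps <= 1.0


class TestGES:
    def test_zero_effect_is_zero(self):
        assert generalized_eta_squared(0.0, 5.0, 3.0) == 0.0
        assert generalized_eta_squared(0.0, 0.0, 0.0) == 0.0

    def test_reduces_to_classical_eta_squared(self):
        # no subject SS and single error term: SS_e / (SS_e + SS_err)
        assert generalized_eta_squared(4.0, 0.0, 12.0) == pytest.approx(0.25)

    def test_fixed_toy_decomposition(self):
        assert generalized_eta_squared(2.0, 6.0, 2.0) == pytest.approx(0.2)


class TestHolm:
    def test_worked_step_down_example(self):
        adj = holm_adjust(np.array([0.01, 0.02, 0.04]))
        assert adj == pytest.approx([0.03, 0.04, 0.04])

    def test_dominance_and_order_preservation(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(0, 1, 20)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(15)
        p = rng.uniform(0, 0.2, 12)
        assert np.allclose(holm_adjust(p), sm.multipletests(p, method="holm")[1])


class TestPosthoc:
    def _table(self, n=10, seed=16):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            base = rng.normal()
            for c, shift in [("a", 0.0), ("b", 1.0), ("c", 0.1)]:
                rows.append(
                    {"participant": s, "cond": c, "dv": base + shift + rng.normal(0, 0.3)}
                )
        return pd.DataFrame(rows)

    def test_identical_samples_give_unit_p(self):
        df = self._table()
        df.loc[df["cond"] == "b", "dv"] = df.loc[df["cond"] == "a", "dv"].to_numpy()
        res = posthoc_pairwise(df, "dv", "cond")
        row = res[(res["A"] == "a") & (res["B"] == "b")].iloc[0]
        assert row["t"] == 0.0 and row["p_raw"] == 1.0

    def test_family_covers_all_pairs_with_holm(self):
        res = posthoc_pairwise(self._table(), "dv", "cond")
        assert len(res) == 3
        assert res.attrs["family_size"] == 3
        assert np.all(res["p_holm"] >= res["p_raw"])
        assert np.allclose(res["p_holm"], holm_adjust(res["p_raw"].to_numpy()))

    def test_single_subject_rejected(self):
        df = self._table(n=1)
        with pytest.raises(ValueError, match="two subjects"):
            posthoc_pairwise(df, "dv", "cond")


class TestBootstrap:
    def test_degenerate_distribution(self):
        lo, hi = bootstrap_ci(np.full(15, 3.3), b=1000, seed=1)
        assert lo == hi == pytest.approx(3.3)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=15)
        assert bootstrap_ci(x, b=2000, seed=5) == bootstrap_ci(x, b=2000, seed=5)
        assert bootstrap_ci(x, b=2000, seed=5) != bootstrap_ci(x, b=2000, seed=6)

    def test_coverage_of_true_mean(self):
        # ~95% nominal coverage for the normal mean at n=15
        rng = np.random.default_rng(18)
        hits = 0
        sims = 600
        for _ in range(sims):
            x = rng.normal(0, 1, 15)
            lo, hi = bootstrap_ci(x, b=1000, seed=rng.integers(2**31))
            hits += lo <= 0.0 <= hi
        assert 0.91 <= hits / sims <= 0.975

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([1.0]), b=1000)


def test_type_one_error_calibrated_at_study_size():
    # 2x3 within design, n=15: empirical size of each effect's test at
    # alpha = .05 over null simulations
    rng = np.random.default_rng(42)
    reps = 2000
    rej = np.zeros(3)
    for _ in range(reps):
        Y = rng.normal(0, 1, (15, 2, 3)) + rng.normal(0, 1, (15, 1, 1))
        res = rm_anova_array(Y, ["A", "B"])
        rej += res["p"].to_numpy() < 0.05
    rates = rej / reps
    assert np.all(rates > 0.035) and np.all(rates < 0.065)
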
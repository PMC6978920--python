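"""Group statistics: z-scoring, pooled correlation, mixed ANOVA, per-k bands."""

import numpy as np
import pandas as pd
import pytest

from connectomaze.stats import (
    mixed_anova,
    permutation_mixed_anova,
    pooled_correlation,
    posthoc_contrasts,
    richclub_group_comparison,
    within_group_zscore,
)
from oracles import mixed_anova_cellmeans, pearson_direct


def _long(Y, groups):
    """subjects x sessions matrix -> long table."""
    rows = []
    for i, row in enumerate(Y):
        for j, v in enumerate(row):
            rows.append({"subject": f"s{i}", "group": groups[i], "session": j,
                         "value": v})
    return pd.DataFrame(rows)


class TestWithinGroupZscore:
    def test_group_means_zero_sds_one(self, rng):
        values = rng.normal(5, 2, size=40)
        groups = np.repeat(["a", "b"], 20)
        z = within_group_zscore(values, groups)
        for g in ("a", "b"):
            assert z[groups == g].mean() == pytest.approx(0.0, abs=1e-12)
            assert z[groups == g].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_location_invariance(self, rng):
        pattern = rng.normal(size=10)
        values = np.concatenate([pattern, pattern + 100])
        groups = np.repeat(["a", "b"], 10)
        z = within_group_zscore(values, groups)
        np.testing.assert_allclose(z[:10], z[10:], atol=1e-12)

    def test_removes_simpsons_paradox_confound(self, rng):
        """Between-group offsets alone create a spurious pooled correlation
        that within-group standardization removes."""
        n = 30
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(10, 1, n)])
        y = np.concatenate([rng.normal(0, 1, n), rng.normal(10, 1, n)])
        groups = np.repeat(["young", "aged"], n)
        raw_r = np.corrcoef(x, y)[0, 1]
        zx = within_group_zscore(x, groups)
        zy = within_group_zscore(y, groups)
        std_r, _, _ = pooled_correlation(zx, zy)
        assert abs(raw_r) > 0.9
        assert abs(std_r) < 0.3

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            within_group_zscore([1.0, 2.0, 3.0], ["a", "b", "b"])
        with pytest.raises(ValueError, match="zero variance"):
            within_group_zscore([1.0, 1.0, 2.0, 3.0], ["a", "a", "b", "b"])


class TestPooledCorrelation:
    def test_identity_gives_r_one(self, rng):
        x = rng.normal(size=20)
        r, f, p = pooled_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_textbook_formula(self):
        x = [1.0, 2.0, 2.5, 3.1, 4.0, 4.2, 5.5, 6.1, 7.0, 8.2]
        y = [1.2, 1.9, 3.1, 2.8, 4.4, 3.9, 5.0, 6.5, 6.2, 8.0]
        r, f, p = pooled_correlation(x, y)
        expected = pearson_direct(x, y)
        assert r == pytest.approx(expected, abs=1e-12)
        assert f == pytest.approx(expected**2 * 8 / (1 - expected**2), abs=1e-9)

    def test_independent_pairs_rarely_correlate(self, rng):
        hits = 0
        for _ in range(20):
            x, y = rng.normal(size=(2, 1000))
            r, _, _ = pooled_correlation(x, y)
            hits += abs(r) >= 0.1
        assert hits == 0  # P(|R|>=0.1) ~ 0.002 per draw

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pooled_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMixedAnova:
    def test_flat_cells_give_zero_f(self):
        Y = np.tile([3.0, 3.0, 3.0], (6, 1))
        Y += np.random.default_rng(0).normal(0, 0, Y.shape)  # exactly flat
        res = mixed_anova(_long(Y, ["a"] * 3 + ["b"] * 3))
        assert res.f_between == pytest.approx(0.0, abs=1e-12)
        assert res.f_within == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_sums_of_squares(self, rng):
        Y = rng.normal(size=(8, 3)) + np.array([0, 0.5, 1.0])
        Y[4:] += 1.5
        res = mixed_anova(_long(Y, ["a"] * 4 + ["b"] * 4))
        f_a, f_b, f_ab = mixed_anova_cellmeans(Y, n_groups=2)
        assert res.f_between == pytest.approx(f_a, rel=1e-10)
        assert res.f_within == pytest.approx(f_b, rel=1e-10)
        assert res.f_interaction == pytest.approx(f_ab, rel=1e-10)
        assert res.df_between == (1, 6)
        assert res.df_within == (2, 12)
        assert res.df_interaction == (2, 12)

    def test_matches_pingouin_cross_check(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(10, 3)) + np.linspace(0, 1, 3)
        table = _long(Y, ["a"] * 5 + ["b"] * 5)
        res = mixed_anova(table)
        ref = pg.mixed_anova(data=table, dv="value", within="session",
                             subject="subject", between="group")
        ref = ref.set_index("Source")
        assert res.f_between == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res.f_within == pytest.approx(ref.loc["session", "F"], rel=1e-6)
        assert res.f_interaction == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)

    def test_affine_rescaling_invariance(self, rng):
        Y = rng.normal(size=(6, 3))
        a = mixed_anova(_long(Y, ["a"] * 3 + ["b"] * 3))
        b = mixed_anova(_long(7.5 * Y - 3.0, ["a"] * 3 + ["b"] * 3))
        assert a.f_between == pytest.approx(b.f_between, rel=1e-9)
        assert a.f_interaction == pytest.approx(b.f_interaction, rel=1e-9)

    def test_unbalanced_design_rejected(self, rng):
        Y = rng.normal(size=(5, 3))
        table = _long(Y, ["a"] * 3 + ["b"] * 2)
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(table)
        missing = _long(rng.normal(size=(6, 3)), ["a"] * 3 + ["b"] * 3).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(missing)

    def test_gg_correction_matches_pingouin(self, rng):
        """The Greenhouse-Geisser-corrected within-factor p agrees with an
        independent implementation; two sessions are always spherical
        (epsilon = 1) and stay untouched."""
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(8, 4)) + np.array([0.0, 0.4, 0.8, 1.2])
        Y[:, 3] += rng.normal(0, 3, size=8)  # break sphericity
        table = _long(Y, ["a"] * 4 + ["b"] * 4)
        gg = mixed_anova(table, gg_correction=True)
        assert gg.p_between == mixed_anova(table).p_between
        # epsilon pools covariance within groups; group-centering the data
        # makes pingouin's pooled-subject epsilon an exact independent
        # oracle (epsilon is scale-invariant)
        from connectomaze.stats import _gg_epsilon
        centered = np.vstack([Y[:4] - Y[:4].mean(axis=0), Y[4:] - Y[4:].mean(axis=0)])
        eps_ref = float(pg.epsilon(pd.DataFrame(centered), correction="gg"))
        eps = _gg_epsilon(Y, np.array([4, 4]))
        assert eps == pytest.approx(eps_ref, rel=1e-10)
        import scipy.stats as st
        raw = mixed_anova(table)
        assert gg.p_within == pytest.approx(
            float(st.f.sf(raw.f_within, eps * 3, eps * 18)), rel=1e-12)
        Y2 = rng.normal(size=(8, 2))
        t2 = _long(Y2, ["a"] * 4 + ["b"] * 4)
        assert mixed_anova(t2, gg_correction=True).p_within == pytest.approx(
            mixed_anova(t2).p_within)

    def test_posthoc_contrasts_bonferroni(self, rng):
        """A group difference planted at one session is flagged at the
        alpha/n_sessions threshold; flat sessions are not."""
        Y = rng.normal(size=(12, 4), scale=0.5)
        Y[6:, 2] += 3.0
        table = _long(Y, ["a"] * 6 + ["b"] * 6)
        out = posthoc_contrasts(table, alpha=0.05)
        assert out["alpha_corrected"].iloc[0] == pytest.approx(0.05 / 4)
        assert bool(out.loc[out.session == 2, "significant"].iloc[0])
        assert not out.loc[out.session != 2, "significant"].any()

    def test_permutation_p_agrees_with_parametric(self, rng):
        """Under normal errors the subject-relabelling permutation p matches
        the parametric p closely."""
        Y = rng.normal(size=(10, 3))
        Y[5:, 2] += 1.2  # group x session interaction
        table = _long(Y, ["a"] * 5 + ["b"] * 5)
        res = mixed_anova(table)
        perm = permutation_mixed_anova(table, n_perm=10_000, rng_seed=3)
        assert perm["p_interaction"] == pytest.approx(res.p_interaction, abs=0.02)
        assert perm["p_between"] == pytest.approx(res.p_between, abs=0.05)


class TestRichclubComparison:
    def _table(self, Y_by_k, groups):
        frames = []
        for k, Y in Y_by_k.items():
            df = _long(Y, groups)
            df["k"] = k
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_identical_curves_nothing_significant(self):
        Y = np.tile(np.array([0.3, 0.4, 0.5]), (10, 1))
        table = self._table({1: Y, 2: Y}, ["a"] * 5 + ["b"] * 5)
        out = richclub_group_comparison(table)
        assert not out["significant"].any()

    def test_planted_high_k_interaction_detected(self, rng):
        groups = ["young"] * 5 + ["aged"] * 5
        flat = rng.normal(0.4, 0.02, size=(10, 3))
        Y_by_k = {k: flat + rng.normal(0, 0.02, size=(10, 3)) for k in range(1, 5)}
        for k in (8, 9, 10):
            Y = flat + rng.normal(0, 0.02, size=(10, 3))
            Y[5:, 1] += 0.3  # aged increase after session 0
            Y[5:, 2] += 0.3
            Y_by_k[k] = Y
        out = richclub_group_comparison(self._table(Y_by_k, groups))
        sig_k = set(out.loc[out["significant"], "k"])
        assert {8, 9, 10} <= sig_k
        assert not sig_k & {1, 2, 3, 4}

    def test_per_k_f_matches_manual_anova(self, rng):
        groups = ["a"] * 4 + ["b"] * 4
        Y = rng.normal(size=(8, 3))
        out = richclub_group_comparison(self._table({5: Y}, groups))
        manual = mixed_anova(_long(Y, groups))
        row = out[out["k"] == 5].iloc[0]
        assert row["f_interaction"] == pytest.approx(manual.f_interaction)
        assert row["p_between"] == pytest.approx(manual.p_between)

    def test_underpowered_k_flagged_undefined(self, rng):
        groups = ["a"] * 4 + ["b"] * 4
        Y = rng.normal(size=(8, 3))
        table = self._table({1: Y, 2: Y}, groups)
        table.loc[(table.k == 2) & (table.subject == "s0"), "value"] = np.nan
        out = richclub_group_comparison(table)
        assert bool(out.loc[out.k == 1, "defined"].iloc[0])
        assert not bool(out.loc[out.k == 2, "defined"].iloc[0])

    def test_contiguous_band_labels(self, rng):
        groups = ["a"] * 5 + ["b"] * 5
        quiet = rng.normal(0.4, 0.02, size=(10, 3))
        loud = quiet.copy()
        loud[5:, 1:] += 0.5
        table = self._table({1: quiet, 2: loud, 3: loud, 4: quiet, 5: loud}, groups)
        out = richclub_group_comparison(table)
        bands = out.set_index("k")["band"]
        assert bands[2] == bands[3] == 1 and bands[5] == 2 and bands[1] == 0
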
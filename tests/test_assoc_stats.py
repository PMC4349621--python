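import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats

from mirhd import assoc_stats as st
from mirhd import normalize as nm
from mirhd import synthetic_data as sd

from oracles import bh_stepup, cld_is_valid, complete_linkage_heights, trapezoid_auc


def _expr(mat, prefix="s"):
    mat = np.asarray(mat, dtype=float)
    return pd.DataFrame(mat, index=[f"m{i}" for i in range(mat.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(mat.shape[1])])


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

class TestBhFdr:
    def test_single_p_unchanged(self):
        assert st.bh_fdr([0.01]) == pytest.approx([0.01])

    def test_arithmetic_sequence_all_equal(self):
        # p_i = i*0.01, m = 4: every q equals 0.04
        assert st.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_nan_propagates_and_family_shrinks(self):
        q = st.bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(0.02)  # family size 2, rank 1

    def test_monotone_in_p_order(self, rng):
        p = rng.uniform(size=200)
        q = st.bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    @settings(max_examples=200, deadline=None)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=60))
    def test_matches_literal_stepup(self, p):
        assert np.allclose(st.bh_fdr(p), bh_stepup(np.array(p)), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.uniform(size=100)
            _rej, q, *_ = multipletests(p, method="fdr_bh")
            assert np.allclose(st.bh_fdr(p), q, atol=1e-12)


# ---------------------------------------------------------------------------
# Moderated differential expression
# ---------------------------------------------------------------------------

class TestModeratedDe:
    def _toy(self, rng, n_genes=200, n=20, lfc=None):
        cond = pd.Series(["control"] * (n // 2) + ["HD"] * (n // 2),
                         index=[f"s{j}" for j in range(n)])
        age = pd.DataFrame({"age_death": rng.normal(60, 10, size=n)},
                           index=cond.index)
        mat = rng.normal(8, 1, size=(n_genes, n))
        if lfc is not None:
            mat[:, n // 2:] += lfc[:, None].T if lfc.ndim > 1 else 0
            mat[: len(lfc), n // 2:] += 0  # placeholder
        return _expr(mat), cond, age

    def test_prior_df_zero_recovers_ordinary_t(self, rng):
        expr, cond, age = self._toy(rng)
        res = st.moderated_de(expr, cond, age, prior_df=0)
        x = (cond == "HD").astype(float).to_numpy()
        X = np.column_stack([np.ones(len(x)), x, age["age_death"]])
        for g in range(0, 200, 17):
            y = expr.iloc[g].to_numpy()
            beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
            df = len(y) - 3
            s2 = float(res_ss[0]) / df
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            t = beta[1] / se
            p = 2 * stats.t.sf(abs(t), df)
            assert res["p_value"].iloc[g] == pytest.approx(p, abs=1e-10)

    def test_prior_df_infinite_pools_variance(self, rng):
        expr, cond, age = self._toy(rng)
        res = st.moderated_de(expr, cond, age, prior_df=np.inf)
        # all genes share one posterior variance: |t| proportional to |beta|
        ratio = np.abs(res["moderated_t"]) / np.abs(res["log2_fold_change"])
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-10)

    def test_collinear_design_rejected(self, rng):
        expr, cond, _age = self._toy(rng)
        dup = pd.DataFrame({"c1": (cond == "HD").astype(float)}, index=cond.index)
        with pytest.raises(ValueError, match="collinear"):
            st.moderated_de(expr, cond, dup)

    def test_recovers_planted_logfc(self):
        """30 planted DE features at |log2FC| in [1.5, 4]: median absolute
        estimation error below 0.2 in a 30v30 cohort."""
        errs = []
        for seed in range(3):
            cfg = sd.SimulationConfig(
                seed=300 + seed, n_mirnas=400, n_hd=30, n_grade0=0, n_control=30,
                n_de=30, logfc_range=(1.5, 4.0), frac_de_up=1.0,
                expr_severity_coupling=0.0, base_log2_mean_range=(6.0, 11.0))
            samples, counts, truth = sd.simulate_cohort(cfg)
            expr, _sf, _trend = nm.normalize_counts(counts, samples["batch"])
            res = st.moderated_de(expr, samples["condition"],
                                  covariates=samples[["age_death"]].astype(float))
            t = truth.per_mirna.loc[res.index]
            de = t["is_de"]
            errs.append(np.median(np.abs(
                res.loc[de, "log2_fold_change"] - t.loc[de, "log2fc"])))
        assert np.median(errs) < 0.2

    def test_q_monotone_with_p(self, rng):
        expr, cond, age = self._toy(rng)
        res = st.moderated_de(expr, cond, age)
        by_p = res.sort_values("p_value", kind="stable")
        assert (by_p["q_value"].diff().dropna() >= -1e-12).all()
        assert ((res["q_value"] - res["p_value"]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# Grade machinery
# ---------------------------------------------------------------------------

class TestGradeAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        expr = _expr(rng.normal(size=(50, 16)))
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=expr.columns)
        p_f = st.grade_anova(expr, groups)
        for g in range(50):
            t, p_t = stats.ttest_ind(expr.iloc[g, :8], expr.iloc[g, 8:],
                                     equal_var=True)
            assert p_f.iloc[g] == pytest.approx(p_t, abs=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        expr = _expr(rng.normal(size=(30, 25)))
        groups = pd.Series(["a"] * 7 + ["b"] * 6 + ["c"] * 5 + ["d"] * 7,
                           index=expr.columns)
        p = st.grade_anova(expr, groups)
        for g in range(30):
            parts = [expr.iloc[g][groups == lev] for lev in ["a", "b", "c", "d"]]
            assert p.iloc[g] == pytest.approx(stats.f_oneway(*parts).pvalue,
                                              abs=1e-12)

    def test_null_p_uniform(self):
        """Under equal group means the p distribution is uniform (KS)."""
        rng = np.random.default_rng(31)
        expr = _expr(rng.normal(size=(500, 30)))
        groups = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10,
                           index=expr.columns)
        p = st.grade_anova(expr, groups)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_small_group_rejected(self, rng):
        expr = _expr(rng.normal(size=(5, 5)))
        groups = pd.Series(["a", "a", "a", "a", "b"], index=expr.columns)
        with pytest.raises(ValueError, match="fewer than 2"):
            st.grade_anova(expr, groups)


class TestTukey:
    def test_two_groups_reduce_to_pooled_t(self, rng):
        values = rng.normal(size=14)
        groups = ["a"] * 8 + ["b"] * 6
        res = st.tukey_hsd(values, groups)
        t, p_t = stats.ttest_ind(values[:8], values[8:], equal_var=True)
        assert res["p_adjusted"].iloc[0] == pytest.approx(p_t, abs=1e-8)

    def test_matches_scipy_tukey_hsd(self, rng):
        samples = [rng.normal(loc, 1, size=n)
                   for loc, n in [(0, 6), (0.5, 9), (1.2, 5), (0.2, 7), (2.0, 6)]]
        values = np.concatenate(samples)
        groups = sum(([f"g{k}"] * len(s) for k, s in enumerate(samples)), [])
        res = st.tukey_hsd(values, groups)
        ref = stats.tukey_hsd(*samples)
        for row in res.itertuples():
            i, j = int(row.group1[1]), int(row.group2[1])
            assert row.p_adjusted == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_zero_variance_degenerate(self):
        values = np.array([1.0, 1.0, 2.0, 2.0])
        with pytest.warns(UserWarning, match="zero within-group"):
            res = st.tukey_hsd(values, ["a", "a", "b", "b"])
        assert res["p_adjusted"].iloc[0] == 0.0
        with pytest.warns(UserWarning):
            res = st.tukey_hsd(np.ones(4), ["a", "a", "b", "b"])
        assert res["p_adjusted"].iloc[0] == 1.0

    def test_monte_carlo_tail_probability(self):
        """Adjusted p approximates the studentized-range tail probability
        estimated by simulation under the null."""
        rng = np.random.default_rng(32)
        k, n_per = 4, 6
        values = rng.normal(size=k * n_per)
        groups = np.repeat([f"g{i}" for i in range(k)], n_per)
        res = st.tukey_hsd(values, groups)
        # Monte-Carlo null distribution of the max studentized range
        reps = 20_000
        draws = rng.normal(size=(reps, k, n_per))
        means = draws.mean(axis=2)
        s2 = draws.var(axis=2, ddof=1).mean(axis=1)
        qmax = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(s2 / n_per)
        # largest observed pair should match the MC tail of the max range
        top = res.loc[res["p_adjusted"].idxmin()]
        pooled_s2 = ((np.reshape(values, (k, n_per)).var(axis=1, ddof=1)).mean())
        q_obs = abs(top.mean_diff) / np.sqrt(pooled_s2 / n_per)
        mc_p = (qmax >= q_obs).mean()
        assert top.p_adjusted == pytest.approx(mc_p, abs=0.02)


class TestCompactLetterDisplay:
    def test_no_significant_pairs_single_letter(self):
        groups = ["a", "b", "c"]
        sig = {frozenset(p): False for p in
               [("a", "b"), ("a", "c"), ("b", "c")]}
        letters = st.compact_letter_display(sig, groups)
        assert set(letters.values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        groups = ["g1", "g2", "g3", "g4"]
        from itertools import combinations
        sig = {frozenset(p): True for p in combinations(groups, 2)}
        letters = st.compact_letter_display(sig, groups)
        assert sorted(letters.values()) == ["a", "b", "c", "d"]
        assert len(set(letters.values())) == 4

    def test_exhaustive_validity_on_five_groups(self):
        """Every one of the 2^10 significance patterns yields a valid display."""
        from itertools import combinations
        groups = ["control", "0", "2", "3", "4"]
        pairs = list(combinations(groups, 2))
        for mask in range(1024):
            sig = {frozenset(p): bool(mask >> i & 1) for i, p in enumerate(pairs)}
            letters = st.compact_letter_display(sig, groups)
            assert cld_is_valid(letters, sig), (mask, letters)


class TestGradeAssociation:
    def test_dual_criterion_recovers_planted_trend(self):
        """miRNAs coupled to the latent severity scale (hence to grade) are
        found by the dual ANOVA at q < 0.05 with sensitivity >= 0.8."""
        cfg = sd.SimulationConfig(
            seed=33, n_mirnas=75, n_hd=40, n_grade0=6, n_control=30, n_de=12,
            logfc_range=(1.5, 3.0), expr_severity_coupling=0.9,
            grade0_effect=0.15, base_log2_mean_range=(5.0, 9.0))
        samples, counts, truth = sd.simulate_cohort(cfg)
        expr, _sf, _t = nm.normalize_counts(counts, samples["batch"])
        res = st.grade_association(expr, samples, de_set=list(expr.index))
        de_ids = truth.per_mirna.index[truth.per_mirna["is_de"]]
        de_ids = [m for m in de_ids if m in res.index]
        sens = res.loc[de_ids, "significant_both"].mean()
        assert sens >= 0.8
        # letters are emitted and valid for every tested miRNA
        for mirna in res.index:
            letters = dict(part.split(":") for part in
                           res.loc[mirna, "letters"].split(";"))
            assert all(letters.values())


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ci = st.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_all_ties(self):
        auc, _ci = st.roc_auc([5.0] * 10, [0, 1] * 5)
        assert auc == 0.5

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="both label classes"):
            st.roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_trapezoid_integration(self, rng):
        """AUC equals trapezoidal ROC integration to 1e-12, ties included."""
        for _ in range(25):
            scores = rng.integers(0, 12, size=40).astype(float)  # many ties
            labels = rng.integers(0, 2, size=40)
            if labels.sum() in (0, 40):
                continue
            auc, _ci = st.roc_auc(scores, labels)
            assert auc == pytest.approx(trapezoid_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        auc, _ci = st.roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_ci_covers_auc(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        labels = np.array([0] * 30 + [1] * 30)
        auc, (lo, hi) = st.roc_auc(scores, labels)
        assert lo <= auc <= hi and 0 <= lo and hi <= 1


# ---------------------------------------------------------------------------
# CAG residualization and feature regressions
# ---------------------------------------------------------------------------

class TestCagResidualize:
    def test_exact_linear_feature_zero_residuals(self):
        cag = pd.Series(np.arange(40, 52, dtype=float))
        feature = 3.0 + 0.25 * cag
        resid, fit = st.cag_residualize(feature, cag, "linear_on_cag")
        assert np.abs(resid).max() < 1e-10
        assert fit.slope == pytest.approx(0.25)

    def test_cag_over_55_excluded(self):
        cag = pd.Series([42.0, 45.0, 48.0, 50.0, 56.0, np.nan])
        feature = pd.Series([40.0, 38.0, 35.0, 33.0, 20.0, 41.0])
        resid, fit = st.cag_residualize(feature, cag, "linear_on_cag")
        assert fit.n_fit == 4
        assert np.isnan(resid.iloc[4]) and np.isnan(resid.iloc[5])

    def test_residuals_orthogonal_to_cag(self, rng):
        cag = pd.Series(rng.integers(40, 56, size=100).astype(float))
        feature = 60.0 - 0.8 * cag + rng.normal(0, 3, size=100)
        resid, _fit = st.cag_residualize(feature, cag, "linear_on_cag")
        r = np.corrcoef(resid, cag)[0, 1]
        assert abs(r) < 1e-8

    def test_log_onset_model_requires_positive(self):
        cag = pd.Series([42.0, 44.0, 46.0, 48.0])
        onset = pd.Series([50.0, 45.0, -1.0, 38.0])
        with pytest.raises(ValueError, match="non-positive onset"):
            st.cag_residualize(onset, cag, "log_onset_on_cag")

    def test_recovers_onset_slope_within_3se(self):
        """Refit ln(onset) ~ CAG on a simulated reference cohort of n=346."""
        cfg = sd.SimulationConfig(seed=34, onset_severity_coupling=0.0)
        ref = sd.simulate_reference_cohort(cfg)
        resid, fit = st.cag_residualize(ref["onset_age"], ref["cag"],
                                        "log_onset_on_cag")
        b_true = cfg.onset_model[1]
        assert abs(fit.slope - b_true) < 3 * fit.slope_se
        ok = resid.notna()
        assert abs(np.corrcoef(resid[ok], ref.loc[ok, "cag"])[0, 1]) < 1e-8

    def test_too_few_points_rejected(self):
        cag = pd.Series([42.0, 44.0])
        with pytest.raises(ValueError, match="fewer than 3"):
            st.cag_residualize(pd.Series([50.0, 45.0]), cag, "linear_on_cag")


class TestFeatureRegression:
    def test_exact_linear_expression(self, rng):
        feat = pd.Series(rng.normal(size=20), index=[f"s{j}" for j in range(20)])
        expr = _expr(np.outer([2.0, -1.5], feat.to_numpy()))
        res = st.feature_regression(expr, feat, ["m0", "m1"])
        assert res.loc["m0", "beta"] == pytest.approx(2.0, abs=1e-10)
        assert res.loc["m1", "beta"] == pytest.approx(-1.5, abs=1e-10)
        assert (res["p"] < 1e-12).all()

    def test_constant_feature_rejected(self, rng):
        feat = pd.Series(np.ones(10), index=[f"s{j}" for j in range(10)])
        expr = _expr(rng.normal(size=(3, 10)))
        with pytest.raises(ValueError, match="constant"):
            st.feature_regression(expr, feat, ["m0"])

    def test_fdr_family_is_de_set_size(self, rng):
        feat = pd.Series(rng.normal(size=26), index=[f"s{j}" for j in range(26)])
        expr = _expr(rng.normal(size=(75, 26)))
        res = st.feature_regression(expr, feat, list(expr.index))
        # smallest p re-scaled by family size 75 at rank 1
        i = res["p"].idxmin()
        assert res.loc[i, "q"] >= min(res.loc[i, "p"] * 75, 1.0) - 1e-12

    def test_planted_coupled_mirnas_rank_top(self):
        """3 of 75 miRNAs built from the feature rank in the top 5 by p."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            n = 26
            feat = pd.Series(rng.normal(size=n), index=[f"s{j}" for j in range(n)])
            mat = rng.normal(0, 1, size=(75, n))
            mat[:3] += 1.2 * feat.to_numpy()[None, :]
            res = st.feature_regression(_expr(mat), feat, [f"m{i}" for i in range(75)])
            top5 = set(res.sort_values("p").index[:5])
            hits += {"m0", "m1", "m2"} <= top5
        assert hits >= 9

    def test_null_fdr_controlled(self):
        """With no real coupling, q < 0.05 discoveries are rare."""
        false_rates = []
        for seed in range(20):
            rng = np.random.default_rng(600 + seed)
            feat = pd.Series(rng.normal(size=26), index=[f"s{j}" for j in range(26)])
            expr = _expr(rng.normal(size=(75, 26)))
            res = st.feature_regression(expr, feat, list(expr.index))
            false_rates.append((res["q"] < 0.05).mean())
        assert np.mean(false_rates) <= 0.10


class TestMultivariate:
    def test_orthogonal_covariate_leaves_p_close(self, rng):
        n = 26
        s = rng.normal(size=n)
        s -= s.mean()
        c = rng.normal(size=n)
        c -= c.mean()
        c -= c @ s / (s @ s) * s  # orthogonalize against [1, s]
        idx = [f"s{j}" for j in range(n)]
        sr = pd.Series(s, index=idx)
        cr = pd.Series(c, index=idx)
        expr = _expr(rng.normal(size=(20, n)) + 0.8 * s[None, :])
        multi = st.multivariate_feature_regression(expr, sr, cr)
        uni = st.feature_regression(expr, sr, list(expr.index))
        # orthogonality: betas identical, p differs only via one df
        assert np.allclose(multi["beta_striatal"], uni["beta"], atol=1e-10)

    def test_collinear_residuals_rejected(self, rng):
        n = 26
        s = rng.normal(size=n)
        idx = [f"s{j}" for j in range(n)]
        expr = _expr(rng.normal(size=(5, n)))
        with pytest.raises(ValueError, match="collinear"):
            st.multivariate_feature_regression(
                expr, pd.Series(s, index=idx), pd.Series(s * 2.0, index=idx))

    def test_cortical_only_signal_gives_null_striatal_p(self):
        ps = []
        for seed in range(30):
            rng = np.random.default_rng(700 + seed)
            n = 26
            s = rng.normal(size=n)
            c = 0.5 * s + np.sqrt(0.75) * rng.normal(size=n)
            idx = [f"s{j}" for j in range(n)]
            expr = _expr(rng.normal(size=(1, n)) + 1.0 * c[None, :])
            multi = st.multivariate_feature_regression(
                expr, pd.Series(s, index=idx), pd.Series(c, index=idx))
            ps.append(multi["p_striatal"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_striatal_signal_survives_correlated_cortical(self):
        sig = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(800 + seed)
            n = 26
            s = rng.normal(size=n)
            c = 0.5 * s + np.sqrt(0.75) * rng.normal(size=n)
            idx = [f"s{j}" for j in range(n)]
            # planted R^2 = 0.5: signal sd == noise sd
            y = s + rng.normal(0, 1, size=n)
            expr = _expr(y[None, :])
            multi = st.multivariate_feature_regression(
                expr, pd.Series(s, index=idx), pd.Series(c, index=idx))
            sig += multi["p_striatal"].iloc[0] < 0.05
        assert sig / n_seeds >= 0.80


# ---------------------------------------------------------------------------
# Correlation clustering
# ---------------------------------------------------------------------------

class TestCorrelationCluster:
    def _features(self, rng, n=26):
        idx = [f"s{j}" for j in range(n)]
        return pd.DataFrame(rng.normal(size=(n, 5)), index=idx,
                            columns=list(st.CLINICAL_FEATURES))

    def test_identical_vector_gives_r_one(self, rng):
        feats = self._features(rng)
        expr = _expr(np.vstack([feats["onset"].to_numpy(),
                                rng.normal(size=26)]))
        ordered, *_ = st.correlation_cluster(expr, feats)
        assert ordered.loc["m0", "onset"] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self, rng):
        feats = self._features(rng, n=2)
        expr = _expr(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="fewer than 3"):
            st.correlation_cluster(expr, feats)

    def test_merge_heights_match_bruteforce_agglomerator(self, rng):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist
        X = rng.normal(size=(10, 5))
        Z = hierarchy.linkage(pdist(X), method="complete")
        assert np.allclose(sorted(Z[:, 2]), sorted(complete_linkage_heights(X)),
                           atol=1e-10)

    def test_opposite_sign_groups_split_at_two_clusters(self):
        """Planted up- and down-coupled miRNA groups separate exactly at the
        2-cluster cut of the row dendrogram, over 20 seeds."""
        from scipy.cluster import hierarchy
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            n = 26
            feats = self._features(rng, n)
            latent = feats["striatal"].to_numpy()
            up = 1.0 * latent[None, :] + rng.normal(0, 0.6, size=(6, n))
            down = -1.0 * latent[None, :] + rng.normal(0, 0.6, size=(6, n))
            expr = _expr(np.vstack([up, down]))
            ordered, row_order, _c, row_linkage, _cl = st.correlation_cluster(
                expr, feats)
            cut = hierarchy.fcluster(row_linkage, 2, criterion="maxclust")
            # linkage rows follow the unordered coefficient matrix (expr order)
            coef_index = [m for m in expr.index if m in set(ordered.index)]
            groups = {}
            for mirna, lab in zip(coef_index, cut):
                groups.setdefault(lab, set()).add(mirna)
            expected = [{f"m{i}" for i in range(6)},
                        {f"m{i}" for i in range(6, 12)}]
            assert sorted(groups.values(), key=lambda s: sorted(s)[0]) == expected
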
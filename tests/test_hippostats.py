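import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hippodev.cohort import make_cohort
from hippodev.hippostats import (TIER_ALPHAS, fdr_bh, full_model_formula,
                                 gradient_correlation, nested_f_test,
                                 pearson_screen, positional_gradients,
                                 reduced_model_formula, smooth_random_field,
                                 spin_test, vertexwise_age_contrast)
from hippodev.mesh import SUBFIELD_NAMES, build_template_mesh


def study_long_table(n_subjects=88, hemispheres=False, seed=0):
    coh = make_cohort(n_subjects, seed=seed)
    rng = np.random.default_rng(seed + 100)
    hemis = ("L", "R") if hemispheres else ("avg",)
    rows = []
    for _, s in coh.table.iterrows():
        for h in hemis:
            for sf in SUBFIELD_NAMES:
                rows.append({"age": s.age, "sex": s.sex, "hemisphere": h,
                             "subfield": sf, "value": rng.normal()})
    return pd.DataFrame(rows)


class TestPearsonScreen:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p, tier = pearson_screen(x, x)
        assert r == pytest.approx(1.0)
        assert tier == "0.0005"

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        r, _, _ = pearson_screen(x, -2 * x + 7)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_screen(np.ones(5), np.arange(5.0))

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            pearson_screen([1, 2], [3, 4])

    def test_tier_assignment(self):
        # n and r chosen to land between thresholds
        rng = np.random.default_rng(0)
        x = rng.normal(size=88)
        y = x * 0.28 + rng.normal(size=88)
        r, p, tier = pearson_screen(x, y)
        assert (tier == "ns") == (p >= 0.01)


class TestNestedFTest:
    def test_study_degrees_of_freedom(self):
        """88 subjects x 5 subfields, hemisphere-averaged: the age-by-sex
        test has df (1, 424)."""
        res = nested_f_test(study_long_table(), full_model_formula(),
                            reduced_model_formula())
        assert (res.df1, res.df2) == (1, 424)

    def test_hemisphere_degrees_of_freedom(self):
        """Both hemispheres retained, hemisphere replacing sex: df2 = 864."""
        res = nested_f_test(
            study_long_table(hemispheres=True),
            full_model_formula(group="hemisphere", interaction="age:hemisphere"),
            reduced_model_formula(group="hemisphere"))
        assert (res.df1, res.df2) == (1, 864)

    def test_age_by_subfield_numerator(self):
        full = full_model_formula()
        reduced = ("value ~ age + C(subfield) + C(sex) "
                   "+ C(sex):C(subfield) + age:sex")
        res = nested_f_test(study_long_table(), full, reduced)
        assert res.df1 == 4

    def test_agrees_with_bruteforce_design_matrices(self):
        """Explicit design-matrix RSS computation matches to 1e-10."""
        rng = np.random.default_rng(2)
        n = 40
        df = pd.DataFrame({
            "age": rng.uniform(8, 19, n),
            "sex": rng.choice(["M", "F"], n),
            "value": rng.normal(size=n),
        })
        res = nested_f_test(df, "value ~ age + C(sex) + age:C(sex)",
                            "value ~ age + C(sex)")
        male = (df["sex"] == "M").to_numpy(float)
        Xf = np.column_stack([np.ones(n), df["age"], male, df["age"] * male])
        Xr = Xf[:, :3]
        y = df["value"].to_numpy()

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        df1 = 1
        df2 = n - Xf.shape[1]
        F = ((rss(Xr) - rss(Xf)) / df1) / (rss(Xf) / df2)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert (res.df1, res.df2) == (df1, df2)

    def test_non_nested_rejected(self):
        df = study_long_table(n_subjects=10)
        with pytest.raises(ValueError):
            nested_f_test(df, "value ~ age + C(sex)", "value ~ C(subfield)")

    def test_coding_invariance(self):
        """Treatment coding with any reference level gives the same F."""
        df = study_long_table(n_subjects=20, seed=5)
        res_a = nested_f_test(df, full_model_formula(), reduced_model_formula())
        full_b = ("value ~ age + C(subfield, Treatment('CA3')) + C(sex) "
                  "+ age:C(subfield, Treatment('CA3')) "
                  "+ C(sex):C(subfield, Treatment('CA3')) + age:sex")
        red_b = ("value ~ age + C(subfield, Treatment('CA3')) + C(sex) "
                 "+ age:C(subfield, Treatment('CA3')) "
                 "+ C(sex):C(subfield, Treatment('CA3'))")
        res_b = nested_f_test(df, full_b, red_b)
        assert res_a.F == pytest.approx(res_b.F, abs=1e-9)

    def test_null_f_distribution_ks(self):
        """F for a pure-noise added column follows F(1, df2)."""
        rng = np.random.default_rng(7)
        n, reps = 50, 1000
        x = rng.uniform(0, 1, n)
        Xr = np.column_stack([np.ones(n), x])
        noise_col = rng.normal(size=n)
        Xf = np.column_stack([Xr, noise_col])
        Pr = Xr @ np.linalg.pinv(Xr)
        Pf = Xf @ np.linalg.pinv(Xf)
        Y = rng.normal(size=(n, reps))
        rss_r = np.sum((Y - Pr @ Y) ** 2, axis=0)
        rss_f = np.sum((Y - Pf @ Y) ** 2, axis=0)
        df2 = n - 3
        F = (rss_r - rss_f) / (rss_f / df2)
        ks = stats.kstest(F, stats.f(1, df2).cdf)
        assert ks.pvalue > 0.01


class TestFdrBH:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.03])[0] == pytest.approx(0.03)

    def test_stepup_hand_example(self):
        out = fdr_bh([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(out, 0.05)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_order_preserving(self, pvals):
        adj = fdr_bh(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestVertexwiseContrast:
    def test_strong_positive_slope(self):
        coh = make_cohort(40, seed=3)
        rng = np.random.default_rng(3)
        vals = (2.0 * coh.ages[:, None]
                + 1e-8 * rng.standard_normal((40, 50)))
        cmap = vertexwise_age_contrast(vals, coh.ages, coh.sexes)
        assert np.all(cmap.t_age > 1e3)
        assert cmap.df_resid == 36

    def test_null_matches_student_t(self):
        coh = make_cohort(50, seed=4)
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((50, 1000))
        cmap = vertexwise_age_contrast(vals, coh.ages, coh.sexes)
        ks = stats.kstest(cmap.t_age, stats.t(df=cmap.df_resid).cdf)
        assert ks.pvalue > 0.01

    def test_subject_permutation_invariance(self):
        coh = make_cohort(30, seed=5)
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((30, 20))
        perm = rng.permutation(30)
        a = vertexwise_age_contrast(vals, coh.ages, coh.sexes)
        b = vertexwise_age_contrast(vals[perm], coh.ages[perm],
                                    coh.sexes[perm])
        assert np.allclose(a.t_age, b.t_age, atol=1e-10)

    def test_constant_vertex_masked(self):
        coh = make_cohort(20, seed=6)
        vals = np.random.default_rng(6).standard_normal((20, 5))
        vals[:, 2] = 1.0
        cmap = vertexwise_age_contrast(vals, coh.ages, coh.sexes)
        assert np.isnan(cmap.t_age[2])
        assert np.all(np.isfinite(np.delete(cmap.t_age, 2)))


class TestGradientCorrelation:
    def test_map_equal_to_ap_gradient(self, small_mesh):
        grads = positional_gradients(small_mesh)
        r_ap, r_pd, _ = gradient_correlation(grads.ap, grads)
        assert r_ap == pytest.approx(1.0)
        inter = abs(stats.pearsonr(grads.ap, grads.pd)[0])
        assert r_pd == pytest.approx(inter, abs=1e-12)

    def test_noise_map_low_correlation(self):
        mesh = build_template_mesh()  # 7262 vertices
        grads = positional_gradients(mesh)
        noise = np.random.default_rng(8).standard_normal(mesh.n_vertices)
        r_ap, r_pd, _ = gradient_correlation(noise, grads)
        assert r_ap < 0.1 and r_pd < 0.1

    def test_constant_map_rejected(self, small_mesh):
        grads = positional_gradients(small_mesh)
        with pytest.raises(ValueError):
            gradient_correlation(np.ones(small_mesh.n_vertices), grads)


class TestSpinTest:
    def test_identical_maps_r_one(self, small_mesh):
        rng = np.random.default_rng(9)
        m = smooth_random_field(small_mesh, rng)
        res = spin_test(m, m, small_mesh.unfolded, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.5

    def test_seed_determinism(self, small_mesh):
        rng = np.random.default_rng(10)
        a = smooth_random_field(small_mesh, rng)
        b = smooth_random_field(small_mesh, rng)
        r1 = spin_test(a, b, small_mesh.unfolded, n_perm=200, seed=3)
        r2 = spin_test(a, b, small_mesh.unfolded, n_perm=200, seed=3)
        assert r1.r == r2.r and r1.p == r2.p

    def test_add_one_p_bounds(self, small_mesh):
        rng = np.random.default_rng(11)
        a = smooth_random_field(small_mesh, rng)
        b = smooth_random_field(small_mesh, rng)
        res = spin_test(a, b, small_mesh.unfolded, n_perm=200, seed=1)
        assert 1 / 201 <= res.p <= 1.0

    def test_missing_coordinates_rejected(self):
        with pytest.raises(ValueError):
            spin_test(np.ones(5), np.ones(5), np.ones((4, 2)))
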
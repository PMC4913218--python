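"""Per-region GLM: recovery, symmetries, shared-design equivalence."""

import numpy as np
import pytest

from mesoproj import (
    AnimalRecord,
    CohortTable,
    fit_region_glm,
    generate_cohort,
    mean_condition_effect,
    normalize_by_volume,
    residualize_covariates,
    threshold_regions,
    unit_mean_normalize,
)
from mesoproj.glm import GLMError, _design_matrix

from conftest import make_animals, make_cohort, make_regions


def toy_unit_mean_cohort(seed=0, n=8, m=5, kc=None, slopes=None):
    """Cohort built exactly from known coefficients (unit-mean by construction)."""
    rng = np.random.default_rng(seed)
    animals = make_animals(
        n,
        conditions=[1] * (n // 2) + [-1] * (n // 2),
        volumes=list(rng.uniform(0.5, 2.0, n)),
        centroids=[tuple(v) for v in rng.uniform([700, 1500, 550], [950, 2000, 700], (n, 3))],
    )
    cov = np.array([[a.ml_um, a.ap_um, a.dv_um] for a in animals])
    cov = cov - cov.mean(axis=0)
    cond = np.array([a.condition for a in animals], dtype=float)
    kc = rng.normal(0, 0.05, m) if kc is None else np.asarray(kc, float)
    slopes = rng.normal(0, 2e-4, (m, 3)) if slopes is None else np.asarray(slopes, float)
    vals = 1.0 + cov @ slopes.T + np.outer(cond, kc)
    vals = vals / vals.mean(axis=0)  # guard against rounding of the mean
    cohort = CohortTable(animals, make_regions([f"R{j}" for j in range(m)]), vals, stage="unit_mean")
    return cohort, kc, slopes


class TestFit:
    def test_identical_rows_give_intercept_only(self):
        c = make_cohort(np.ones((6, 4)), stage="unit_mean",
                        conditions=[1, 1, 1, -1, -1, -1])
        fit = fit_region_glm(c)
        np.testing.assert_allclose(fit.table["beta"], 1.0, atol=1e-12)
        for col in ("kx", "ky", "kz", "kc"):
            np.testing.assert_allclose(fit.table[col], 0.0, atol=1e-12)

    def test_exact_recovery_from_known_coefficients(self):
        c, kc, slopes = toy_unit_mean_cohort(seed=1)
        fit = fit_region_glm(c)
        np.testing.assert_allclose(fit.kc.to_numpy(), kc, atol=1e-10)
        np.testing.assert_allclose(fit.table[["kx", "ky", "kz"]].to_numpy(), slopes, atol=1e-10)
        np.testing.assert_allclose(fit.table["resid_var"], 0.0, atol=1e-16)

    def test_condition_flip_negates_kc_only(self):
        c, _, _ = toy_unit_mean_cohort(seed=2)
        flipped = CohortTable(
            tuple(
                AnimalRecord(a.animal_id, -a.condition, a.sex, a.injection_volume,
                             a.ml_um, a.ap_um, a.dv_um)
                for a in c.animals
            ),
            c.regions, c.values, stage="unit_mean",
        )
        f1, f2 = fit_region_glm(c), fit_region_glm(flipped)
        np.testing.assert_allclose(f1.kc.to_numpy(), -f2.kc.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(
            f1.table[["beta", "kx", "ky", "kz"]], f2.table[["beta", "kx", "ky", "kz"]], atol=1e-12
        )

    def test_single_condition_rejected(self):
        c = make_cohort(np.ones((6, 3)), stage="unit_mean", conditions=[1] * 6)
        with pytest.raises(GLMError, match="condition"):
            fit_region_glm(c)

    def test_shared_design_matches_per_region_statsmodels(self):
        import statsmodels.api as sm

        c, _, _ = toy_unit_mean_cohort(seed=3, n=10, m=6)
        noisy = c.values * np.exp(np.random.default_rng(4).normal(0, 0.05, c.values.shape))
        noisy = noisy / noisy.mean(axis=0)
        c2 = CohortTable(c.animals, c.regions, noisy, stage="unit_mean")
        fit = fit_region_glm(c2)
        X, _ = _design_matrix(c2.covariates_um, c2.condition_codes)
        for j in range(c2.n_regions):
            ols = sm.OLS(c2.values[:, j], X).fit()
            np.testing.assert_allclose(
                fit.table.iloc[j][["beta", "kx", "ky", "kz", "kc"]].to_numpy(),
                ols.params, atol=1e-12,
            )

    def test_covariate_shift_invariance(self):
        c, _, _ = toy_unit_mean_cohort(seed=5)
        shifted = CohortTable(
            tuple(
                AnimalRecord(a.animal_id, a.condition, a.sex, a.injection_volume,
                             a.ml_um + 250.0, a.ap_um, a.dv_um)
                for a in c.animals
            ),
            c.regions, c.values, stage="unit_mean",
        )
        f1, f2 = fit_region_glm(c), fit_region_glm(shifted)
        np.testing.assert_allclose(f1.table.to_numpy(), f2.table.to_numpy(), atol=1e-10)

    def test_permuting_within_condition_preserves_kc(self):
        c, _, _ = toy_unit_mean_cohort(seed=6)
        order = [1, 0, 2, 3, 4, 5, 7, 6]  # swap two controls and two CSR
        permuted = CohortTable(
            tuple(c.animals[i] for i in order), c.regions, c.values[order], stage="unit_mean"
        )
        np.testing.assert_allclose(
            fit_region_glm(c).kc.to_numpy(), fit_region_glm(permuted).kc.to_numpy(), atol=1e-12
        )


class TestMeanConditionEffect:
    def test_zero_effects_give_zero_mean(self):
        c, _, _ = toy_unit_mean_cohort(seed=7, kc=np.zeros(5))
        assert mean_condition_effect(fit_region_glm(c)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_mean(self):
        c, _, _ = toy_unit_mean_cohort(seed=8, m=3, kc=[0.1, -0.05, 0.07])
        assert mean_condition_effect(fit_region_glm(c)) == pytest.approx(0.04, abs=1e-10)

    def test_condition_free_fit_has_no_kc(self):
        c, _, _ = toy_unit_mean_cohort(seed=9)
        fit = fit_region_glm(c, include_condition=False)
        with pytest.raises(GLMError, match="condition"):
            fit.mean_condition_effect()


class TestResidualize:
    @staticmethod
    def _expected_residual(cohort, kc, slopes, fit_idx):
        """Closed-form oracle for residualizing the exact generative model
        1 + slopes·x̃ + kc·c: the condition-free fit absorbs the OLS
        projection ĉ of the condition code onto the training covariates,
        and the difference between the training centering constants and the
        cohort centering the model was generated with leaves a per-region
        offset (μ_train − μ_all)·slopes."""
        cov = cohort.covariates_um
        mu_all = cov.mean(axis=0)
        mu_tr = cov[fit_idx].mean(axis=0)
        Xtr = np.column_stack([np.ones(len(fit_idx)), cov[fit_idx] - mu_tr])
        g, *_ = np.linalg.lstsq(Xtr, cohort.condition_codes[fit_idx], rcond=None)
        chat = (cov - mu_tr) @ g[1:]
        offset = (mu_tr - mu_all) @ slopes.T  # (m,)
        return 1.0 + offset[None, :] + np.outer(cohort.condition_codes - chat, kc)

    def test_zero_slopes_leave_condition_plus_baseline(self):
        c, kc, _ = toy_unit_mean_cohort(seed=10, slopes=np.zeros((5, 3)))
        res = residualize_covariates(c)
        expected = self._expected_residual(c, kc, np.zeros((5, 3)), list(range(c.n_animals)))
        np.testing.assert_allclose(res.to_numpy(), expected, atol=1e-10)

    def test_held_out_animal_residual_matches_generative_truth(self, noiseless_design):
        c, t = generate_cohort(noiseless_design, seed=6)
        th, _ = threshold_regions(c)
        um = unit_mean_normalize(normalize_by_volume(th, t.exponent))
        held_out = um.animal_ids[-1]
        train_idx = list(range(um.n_animals - 1))
        res = residualize_covariates(um, fit_animals=um.animal_ids[:-1])
        kc = t.effect_for(th.region_abbreviations)
        idx = [list(t.region_abbreviations).index(a) for a in th.region_abbreviations]
        expected = self._expected_residual(um, kc, t.slopes_per_um[idx], train_idx)
        np.testing.assert_allclose(res.to_numpy(), expected, atol=1e-8)
        assert held_out in res.index

    def test_fit_on_all_is_default(self):
        c, _, _ = toy_unit_mean_cohort(seed=11)
        r1 = residualize_covariates(c)
        r2 = residualize_covariates(c, fit_animals=c.animal_ids)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-14)

    def test_unknown_fit_animal_rejected(self):
        c, _, _ = toy_unit_mean_cohort(seed=12)
        with pytest.raises(GLMError, match="zz"):
            residualize_covariates(c, fit_animals=["zz"])
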
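"""Per-region general linear model.

For every retained region j the model is

    PF_ij = β_j + kx_j·x̃_i + ky_j·ỹ_i + kz_j·z̃_i + kc_j·c_i

on unit-mean-normalized projection fractions, where x̃, ỹ, z̃ are the
injection-centroid distances centered to zero mean across the fitted
animals and c_i is +1 for control and −1 for sleep-restricted animals.
With a Gaussian likelihood and identity link, maximum likelihood is
ordinary least squares, and because every region shares one design matrix
all regions are fitted in a single solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortError, CohortTable

COEF_COLUMNS = ("beta", "kx", "ky", "kz", "kc")


class GLMError(ValueError):
    """Raised for design problems in the per-region model."""


@dataclass(frozen=True)
class GLMFitTable:
    """Per-region coefficients and residual variances.

    ``table`` is indexed by region abbreviation with columns
    beta, kx, ky, kz[, kc], resid_var.  ``covariate_means_um`` are the
    ML/AP/DV centering constants of the fitted animals (needed to apply the
    fit to animals outside the fitted set).
    """

    table: pd.DataFrame
    include_condition: bool
    covariate_means_um: np.ndarray  # (3,)
    n_animals: int

    @property
    def kc(self) -> pd.Series:
        if not self.include_condition:
            raise GLMError("this fit was made without a condition term")
        return self.table["kc"]

    def mean_condition_effect(self) -> float:
        """Unweighted mean of kc_j over retained regions (μ_kc)."""
        return float(self.kc.to_numpy().mean())


def _design_matrix(
    covariates_um: np.ndarray,
    condition: np.ndarray | None,
    center_at: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build [1, x̃, ỹ, z̃(, c)]; returns (design, centering constants)."""
    mu = covariates_um.mean(axis=0) if center_at is None else np.asarray(center_at, float)
    centered = covariates_um - mu
    cols = [np.ones(len(covariates_um)), centered[:, 0], centered[:, 1], centered[:, 2]]
    if condition is not None:
        cols.append(np.asarray(condition, float))
    return np.column_stack(cols), mu


def solve_shared_design(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and residual variance for all columns of Y.

    Returns (coef with shape (p, m), resid_var with shape (m,)) where the
    residual variance uses the unbiased denominator n − p (0 when n == p).
    """
    n, p = X.shape
    if n < p:
        raise GLMError(f"need at least {p} animals for a {p}-parameter model, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise GLMError("design matrix is rank deficient (collinear covariates or single condition)")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = n - p
    resid_var = (resid**2).sum(axis=0) / dof if dof > 0 else np.zeros(Y.shape[1])
    return coef, resid_var


def fit_region_glm(cohort: CohortTable, include_condition: bool = True) -> GLMFitTable:
    """Fit the shared-design per-region model on a unit-mean cohort."""
    if cohort.stage != "unit_mean":
        raise CohortError(f"fit_region_glm expects stage='unit_mean', got {cohort.stage!r}")
    condition = cohort.condition_codes if include_condition else None
    if include_condition and len(np.unique(condition)) < 2:
        raise GLMError("only one condition present; condition coefficient not identifiable")
    X, mu = _design_matrix(cohort.covariates_um, condition)
    coef, resid_var = solve_shared_design(X, cohort.values)
    cols = list(COEF_COLUMNS if include_condition else COEF_COLUMNS[:4])
    table = pd.DataFrame(coef.T, index=cohort.region_abbreviations, columns=cols)
    table["resid_var"] = resid_var
    return GLMFitTable(
        table=table,
        include_condition=include_condition,
        covariate_means_um=mu,
        n_animals=cohort.n_animals,
    )


def mean_condition_effect(fit: GLMFitTable) -> float:
    """μ_kc: unweighted arithmetic mean of the per-region condition coefficients."""
    return fit.mean_condition_effect()


def residualize_covariates(
    cohort: CohortTable, fit_animals: Sequence[str] | None = None
) -> pd.DataFrame:
    """Remove the injection-geometry contribution from every animal's row.

    A condition-free model is fitted on ``fit_animals`` (default: all), and
    the fitted covariate contribution kx·x̃ + ky·ỹ + kz·z̃ is subtracted
    from EVERY animal — including animals outside the fitted set, whose
    covariates are centered with the fitted set's constants.  Fitting per
    training subset keeps cross-validation folds free of leakage.
    """
    if cohort.stage != "unit_mean":
        raise CohortError(f"residualize_covariates expects stage='unit_mean', got {cohort.stage!r}")
    ids = cohort.animal_ids
    if fit_animals is None:
        fit_idx = list(range(cohort.n_animals))
    else:
        lookup = {a: i for i, a in enumerate(ids)}
        unknown = [a for a in fit_animals if a not in lookup]
        if unknown:
            raise GLMError(f"fit_animals not in cohort: {unknown}")
        fit_idx = [lookup[a] for a in fit_animals]
    cov = cohort.covariates_um
    Xfit, mu = _design_matrix(cov[fit_idx], condition=None)
    coef, _ = solve_shared_design(Xfit, cohort.values[fit_idx])
    slopes = coef[1:4]  # (3, m)
    centered_all = cov - mu
    residual = cohort.values - centered_all @ slopes
    return pd.DataFrame(residual, index=ids, columns=cohort.region_abbreviations)
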
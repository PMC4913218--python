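"""One-tailed bootstrap test of the mean condition coefficient μ_kc.

Each condition group is resampled with replacement R times at its own
size; every one of the R² control × CSR pairings is recombined into a
cohort, the full per-region model (condition included, covariates
re-centered on the resampled animals) is refitted, and μ_kc is recomputed.
The p value is the fraction of pairings whose μ_kc falls in the
non-claimed tail, floored at 1/R² — the best p value the design can claim.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .cohort import CONTROL, CSR, CohortError, CohortTable
from .glm import GLMError, fit_region_glm

logger = logging.getLogger(__name__)

TAILS = ("positive", "negative")

_SINGULAR_RTOL = 1e-10
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class BootstrapResult:
    """Outcome of the resampling test.

    ``tail='positive'`` tests μ_kc > 0 (p = fraction of resampled μ_kc
    that are negative); ``tail='negative'`` is the opposite one-tailed
    test.  ``p_value = max(tail_fraction, p_floor)`` with
    ``p_floor = 1/R²``.
    """

    observed_mu_kc: float
    tail: str
    resamples_per_group: int
    comparisons: int
    tail_fraction: float
    p_value: float
    p_floor: float
    mu_kc_samples: np.ndarray = field(repr=False)
    seed: int = 0
    redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "observed_mu_kc": self.observed_mu_kc,
            "tail": self.tail,
            "resamples_per_group": self.resamples_per_group,
            "comparisons": self.comparisons,
            "tail_fraction": self.tail_fraction,
            "p_value": self.p_value,
            "p_floor": self.p_floor,
            "seed": self.seed,
            "redraws": self.redraws,
            "mu_kc_samples": [float(v) for v in self.mu_kc_samples],
        }


def _group_rng(seed: int, animal_ids: list[str]) -> np.random.Generator:
    # Keyed on group membership, not group label, so that swapping the
    # condition labels reuses identical draws (exact label-flip symmetry).
    key = zlib.crc32(",".join(animal_ids).encode("utf-8"))
    return np.random.default_rng([int(seed), key])


def _batched_mu_kc(
    values: np.ndarray,
    covariates: np.ndarray,
    condition_pattern: np.ndarray,
    rows: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """μ_kc for a batch of resampled cohorts.

    ``rows`` has shape (B, n) of animal indices; the condition pattern is
    fixed by position (controls first).  Returns (mu, bad) where ``bad``
    flags numerically singular designs.
    """
    B, n = rows.shape
    cov = covariates[rows]  # (B, n, 3)
    cov = cov - cov.mean(axis=1, keepdims=True)  # re-center per resample
    ones = np.ones((B, n, 1))
    cond = np.broadcast_to(condition_pattern[None, :, None], (B, n, 1))
    D = np.concatenate([ones, cov, cond], axis=2)  # (B, n, 5)
    Y = values[rows]  # (B, n, m)
    XtX = np.einsum("bnp,bnq->bpq", D, D)
    XtY = np.einsum("bnp,bnm->bpm", D, Y)
    svals = np.linalg.svd(XtX, compute_uv=False)
    bad = svals[:, -1] <= svals[:, 0] * _SINGULAR_RTOL
    mu = np.full(B, np.nan)
    ok = ~bad
    if ok.any():
        coef = np.linalg.solve(XtX[ok], XtY[ok])  # (B_ok, 5, m)
        mu[ok] = coef[:, 4, :].mean(axis=1)
    return mu, bad


def bootstrap_condition_test(
    cohort: CohortTable,
    R: int = 50,
    tail: str = "positive",
    seed: int = 0,
) -> BootstrapResult:
    """Run the R × R cross-group bootstrap on a unit-mean cohort.

    Resampling is of whole animals (rows with their metadata), never of
    regions.  Exact zeros of μ_kc count against rejection (strict
    inequality in the tail count).  A resampled design that loses rank is
    redrawn (logged), never silently skipped.  Deterministic for fixed
    (cohort, R, tail, seed).
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    if cohort.stage != "unit_mean":
        raise CohortError(f"bootstrap_condition_test expects stage='unit_mean', got {cohort.stage!r}")
    cond = cohort.condition_codes
    ctrl_idx = np.flatnonzero(cond == CONTROL)
    csr_idx = np.flatnonzero(cond == CSR)
    if len(ctrl_idx) == 0 or len(csr_idx) == 0:
        raise GLMError("both conditions must be present for the bootstrap test")

    observed = fit_region_glm(cohort, include_condition=True).mean_condition_effect()

    ids = cohort.animal_ids
    rng_ctrl = _group_rng(seed, [ids[i] for i in ctrl_idx])
    rng_csr = _group_rng(seed, [ids[i] for i in csr_idx])
    ctrl_draws = ctrl_idx[rng_ctrl.integers(0, len(ctrl_idx), size=(R, len(ctrl_idx)))]
    csr_draws = csr_idx[rng_csr.integers(0, len(csr_idx), size=(R, len(csr_idx)))]

    # all R² pairings; rows ordered controls then CSR, so the condition
    # pattern is fixed by position
    pair_ctrl = np.repeat(ctrl_draws, R, axis=0)  # (R², n_ctrl)
    pair_csr = np.tile(csr_draws, (R, 1))  # (R², n_csr)
    rows = np.concatenate([pair_ctrl, pair_csr], axis=1)
    pattern = np.concatenate(
        [np.full(len(ctrl_idx), float(CONTROL)), np.full(len(csr_idx), float(CSR))]
    )

    mu, bad = _batched_mu_kc(cohort.values, cohort.covariates_um, pattern, rows)
    redraws = 0
    if bad.any():
        repair = np.random.default_rng([int(seed), 0xDEAD])
        for b in np.flatnonzero(bad):
            for attempt in range(_MAX_REDRAWS):
                new_rows = np.concatenate(
                    [
                        ctrl_idx[repair.integers(0, len(ctrl_idx), size=len(ctrl_idx))],
                        csr_idx[repair.integers(0, len(csr_idx), size=len(csr_idx))],
                    ]
                )[None, :]
                m2, b2 = _batched_mu_kc(cohort.values, cohort.covariates_um, pattern, new_rows)
                redraws += 1
                if not b2[0]:
                    mu[b] = m2[0]
                    break
            else:
                raise GLMError("could not redraw a full-rank resampled design")
        logger.warning("redrew %d rank-deficient bootstrap pairings", int(bad.sum()))

    comparisons = R * R
    if tail == "positive":
        tail_fraction = float(np.count_nonzero(mu < 0) / comparisons)
    else:
        tail_fraction = float(np.count_nonzero(mu > 0) / comparisons)
    p_floor = 1.0 / comparisons
    return BootstrapResult(
        observed_mu_kc=float(observed),
        tail=tail,
        resamples_per_group=R,
        comparisons=comparisons,
        tail_fraction=tail_fraction,
        p_value=max(tail_fraction, p_floor),
        p_floor=p_floor,
        mu_kc_samples=mu,
        seed=int(seed),
        redraws=redraws,
    )
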
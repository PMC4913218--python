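"""Preprocessing chain: region thresholding, injection-volume power-law
normalization, unit-mean normalization, and injection-geometry diagnostics.

The canonical order is threshold → volume-normalize → unit-mean; the stage
tags on :class:`~mesoproj.cohort.CohortTable` enforce it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortError, CohortTable

#: Regions whose mean projection fraction falls below 0.1% carry signal too
#: weak to be reliable across animals and are removed.
DEFAULT_MIN_MEAN_PF = 0.001

AXES = {"ML": 0, "AP": 1, "DV": 2}


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of ∑PF = A · InjVol^n (+ B, with B fixed at 0).

    B is identically zero because an empty injection produces no
    fluorescence, so the fit is an ordinary least-squares line in log–log
    coordinates: log ∑PF = n log InjVol + log A.
    """

    exponent: float
    prefactor: float
    r_squared: float
    intercept: float = 0.0  # B, fixed

    def __post_init__(self) -> None:
        if self.intercept != 0.0:
            raise ValueError("power-law intercept B is fixed at 0")
        if not (self.prefactor > 0):
            raise ValueError("prefactor A = exp(log-intercept) must be > 0")


def threshold_regions(
    cohort: CohortTable, min_mean_pf: float = DEFAULT_MIN_MEAN_PF
) -> tuple[CohortTable, list[str]]:
    """Drop regions whose across-animal mean projection fraction is below
    ``min_mean_pf``.

    Retention uses ≥ (a region exactly at the boundary stays).  Returns the
    thresholded cohort and the removed abbreviations in ontology order.
    """
    if cohort.stage != "raw":
        raise CohortError(f"threshold_regions expects stage='raw', got {cohort.stage!r}")
    means = cohort.values.mean(axis=0)
    keep = means >= min_mean_pf
    if not keep.any():
        raise CohortError(f"all {cohort.n_regions} regions fall below min_mean_pf={min_mean_pf}")
    removed = [r.abbreviation for r, k in zip(cohort.regions, keep) if not k]
    kept_regions = tuple(r for r, k in zip(cohort.regions, keep) if k)
    out = cohort.with_values(cohort.values[:, keep], stage="thresholded", regions=kept_regions)
    return out, removed


def fit_volume_exponent(cohort: CohortTable) -> PowerLawFit:
    """OLS fit of log(∑_j PF_ij) on log(InjVol_i) over retained regions.

    Natural logs (the base cancels in the exponent).  Requires ≥ 3 animals
    and non-constant injection volumes; an animal with zero total projection
    makes the log undefined and is an error.
    """
    if cohort.stage != "thresholded":
        raise CohortError(f"fit_volume_exponent expects stage='thresholded', got {cohort.stage!r}")
    if cohort.n_animals < 3:
        raise CohortError(f"need >= 3 animals to fit a power law, got {cohort.n_animals}")
    total = cohort.values.sum(axis=1)
    if np.any(total <= 0):
        bad = cohort.animal_ids[int(np.argmax(total <= 0))]
        raise CohortError(f"animal {bad!r} has zero total projection fraction; log undefined")
    vols = cohort.injection_volumes
    logv = np.log(vols)
    if np.allclose(logv, logv[0]):
        raise CohortError("injection volumes are all equal; exponent not identifiable")
    res = stats.linregress(logv, np.log(total))
    return PowerLawFit(
        exponent=float(res.slope),
        prefactor=float(np.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
    )


def normalize_by_volume(cohort: CohortTable, exponent: float) -> CohortTable:
    """Divide every projection fraction by (InjVol_i)^exponent.

    After this step values are no longer bounded by 1.
    """
    if cohort.stage != "thresholded":
        raise CohortError(f"normalize_by_volume expects stage='thresholded', got {cohort.stage!r}")
    if not np.isfinite(exponent):
        raise CohortError(f"exponent must be finite, got {exponent!r}")
    vols = cohort.injection_volumes
    if np.any(vols <= 0):
        bad = cohort.animal_ids[int(np.argmax(vols <= 0))]
        raise CohortError(f"animal {bad!r} has non-positive injection volume")
    scaled = cohort.values / vols[:, None] ** exponent
    return cohort.with_values(scaled, stage="volume_normalized")


def unit_mean_normalize(cohort: CohortTable) -> CohortTable:
    """Scale every region column to unit mean across animals (idempotent)."""
    if cohort.stage not in ("volume_normalized", "unit_mean"):
        raise CohortError(
            f"unit_mean_normalize expects stage='volume_normalized' (or 'unit_mean'), got {cohort.stage!r}"
        )
    means = cohort.values.mean(axis=0)
    if np.any(means <= 0):
        bad = cohort.region_abbreviations[int(np.argmax(means <= 0))]
        raise CohortError(f"region {bad!r} has non-positive mean; should have been thresholded away")
    return cohort.with_values(cohort.values / means[None, :], stage="unit_mean")


def injection_distance_correlations(
    cohort: CohortTable, axis: str, normalize: bool = True
) -> pd.Series:
    """Per-animal Pearson correlation of projection patterns against the
    animal with the most extreme injection distance on ``axis``.

    ``axis`` is 'ML' (from midline), 'AP' (from the anterior commissure) or
    'DV' (from the pia).  With ``normalize`` set, region columns are first
    scaled to unit mean so that differences between injections do not
    dominate (this is what lets negative correlations appear).  The
    reference animal's own value is exactly 1.  Ties on distance break to
    the first animal in file order.
    """
    if axis not in AXES:
        raise CohortError(f"axis must be one of {sorted(AXES)}, got {axis!r}")
    if cohort.n_animals < 2:
        raise CohortError("need >= 2 animals for injection-distance diagnostics")
    values = cohort.values
    if normalize:
        means = values.mean(axis=0)
        if np.any(means <= 0):
            bad = cohort.region_abbreviations[int(np.argmax(means <= 0))]
            raise CohortError(f"region {bad!r} has non-positive mean; cannot unit-mean normalize")
        values = values / means[None, :]
    sds = values.std(axis=1)
    if np.any(sds == 0):
        bad = cohort.animal_ids[int(np.argmax(sds == 0))]
        raise CohortError(f"animal {bad!r} has a zero-variance projection vector")
    dist = cohort.covariates_um[:, AXES[axis]]
    ref = int(np.argmax(dist))  # first index on ties
    centered = values - values.mean(axis=1, keepdims=True)
    r = centered @ centered[ref] / (np.linalg.norm(centered, axis=1) * np.linalg.norm(centered[ref]))
    r[ref] = 1.0
    return pd.Series(np.clip(r, -1.0, 1.0), index=cohort.animal_ids, name=f"pearson_r_{axis}")
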
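"""Synthetic tracer-injection cohorts with known ground truth.

The generator emulates the statistical structure the analysis chain
assumes: a 28-animal cohort (14 control / 14 sleep-restricted), ~293
ipsilateral regions in 11 macro-categories, log-normally distributed
baseline projection fractions spanning several orders of magnitude (a
realistic share below the 0.1% reliability threshold), total projection
scaling with injection volume as a power law with exponent ≈0.216,
injection centroids spread as in a real surgical series, and small
heterogeneous per-region condition effects.

The generative model for animal ``i`` and region ``j`` is

    PF_ij = clip_[0,1]( b_j · InjVol_i^n
                        · (1 + sx_j·x̃_i + sy_j·ỹ_i + sz_j·z̃_i + kc_j·c_i)
                        · exp(σ·ε_ij) )

with ε_ij standard normal and x̃, ỹ, z̃ the injection-centroid distances
centered across the cohort (the same centering the downstream linear model
applies).  Because effects enter multiplicatively on the baseline with an
additive structure inside the parenthesis, the downstream per-region linear
model is correctly specified after unit-mean normalization in the σ=0
limit, which makes exact coefficient recovery a valid end-to-end check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .cohort import CATEGORIES, CONTROL, CSR, AnimalRecord, CohortError, CohortTable, RegionInfo

#: Rough relative sizes of the macro-categories (region counts are allocated
#: proportionally by largest remainder; weights sum to 293).
_CATEGORY_WEIGHTS = {
    "Isocortex": 40,
    "Olfactory areas": 25,
    "Hippocampal formation": 20,
    "Claustrum + amygdala": 15,
    "Striatum + pallidum": 25,
    "Thalamus": 40,
    "Hypothalamus": 30,
    "Midbrain + pons": 45,
    "Medulla": 35,
    "Cerebellum": 15,
    "Fiber tracts": 3,
}

CONDITION_SCHEMES = ("null", "homogeneous", "heterogeneous")


class GeneratorError(ValueError):
    """Raised when a generator configuration cannot be honoured."""


@dataclass(frozen=True)
class CohortDesign:
    """Generator settings.

    Defaults describe the emulated study cohort; distances in µm, injection
    volumes in arbitrary units with median 1.
    """

    n_control: int = 14
    n_csr: int = 14
    n_regions: int = 293
    control_males: int = 8
    csr_males: int = 6
    baseline_median: float = 0.002
    baseline_log10_sd: float = 1.0
    #: upper truncation of the baseline distribution (redraw above); a single
    #: injection source never fills most of a target structure's voxels
    baseline_cap: float = 0.8
    true_exponent: float = 0.216
    volume_log_sd: float = 0.4
    centroid_means_um: tuple[float, float, float] = (826.0, 1771.0, 636.0)
    centroid_sds_um: tuple[float, float, float] = (140.0, 262.0, 60.0)
    #: SD of a region's covariate effect at one SD of centroid displacement
    #: (converted internally to a per-µm slope).
    slope_effect_per_sd: float = 0.05
    condition_scheme: str = "heterogeneous"
    #: homogeneous scheme: every region's condition coefficient.
    effect_size: float = 0.02
    #: heterogeneous scheme: fraction of regions affected, and the normal
    #: distribution of their coefficients.
    effect_fraction: float = 0.3
    effect_mean: float = 0.03
    effect_sd: float = 0.05
    noise_sd: float = 0.3
    hemisphere: str = "ipsilateral"
    volume_unit: str = "au"
    #: generation aborts if clipping would touch at least this fraction of entries
    max_clipped_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_csr < 1:
            raise GeneratorError("both conditions need at least one animal")
        if not (0 <= self.control_males <= self.n_control and 0 <= self.csr_males <= self.n_csr):
            raise GeneratorError("male counts must fit within their condition groups")
        if self.n_regions < 1:
            raise GeneratorError("n_regions must be >= 1")
        if self.condition_scheme not in CONDITION_SCHEMES:
            raise GeneratorError(
                f"unknown condition scheme {self.condition_scheme!r}; expected one of {CONDITION_SCHEMES}"
            )
        if self.noise_sd < 0:
            raise GeneratorError("noise_sd must be >= 0")
        if self.baseline_median <= 0:
            raise GeneratorError("baseline_median must be > 0")
        if not (0 <= self.effect_fraction <= 1):
            raise GeneratorError("effect_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Every parameter the generator drew, for recovery tests.

    ``prefactor`` is the sum of all baselines b_j, i.e. the power-law
    prefactor A of ∑PF vs injection volume before thresholding; use
    :meth:`prefactor_for` for the post-threshold region set.
    """

    exponent: float
    baseline: np.ndarray  # (n_regions,)
    slopes_per_um: np.ndarray  # (n_regions, 3) columns ML/AP/DV
    condition_effect: np.ndarray  # (n_regions,) true kc_j
    noise_sd: float
    seed: int
    region_abbreviations: tuple[str, ...]
    clipped_fraction: float
    design: CohortDesign

    @property
    def prefactor(self) -> float:
        return float(self.baseline.sum())

    def prefactor_for(self, abbreviations: Sequence[str]) -> float:
        idx = {a: i for i, a in enumerate(self.region_abbreviations)}
        return float(sum(self.baseline[idx[a]] for a in abbreviations))

    def effect_for(self, abbreviations: Sequence[str]) -> np.ndarray:
        """True condition coefficients restricted to the given regions."""
        idx = {a: i for i, a in enumerate(self.region_abbreviations)}
        return np.array([self.condition_effect[idx[a]] for a in abbreviations])


def _allocate_categories(n_regions: int) -> list[str]:
    """Deterministic largest-remainder allocation of regions to categories."""
    total = sum(_CATEGORY_WEIGHTS.values())
    quotas = {c: n_regions * w / total for c, w in _CATEGORY_WEIGHTS.items()}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = n_regions - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda c: (-(quotas[c] - counts[c]), c))
    for c in by_remainder[:short]:
        counts[c] += 1
    out: list[str] = []
    for c in CATEGORIES:  # stable ontology order
        out.extend([c] * counts.get(c, 0))
    return out[:n_regions]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draw truncated at 0 by redraw (negligible mass for defaults)."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out < 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise GeneratorError("could not draw non-negative centroids; sd too large for mean")


def generate_cohort(design: CohortDesign | None = None, seed: int = 0) -> tuple[CohortTable, SyntheticTruth]:
    """Draw one cohort and its ground truth.

    Identical (design, seed) pairs produce bit-identical output.  Generation
    refuses configurations whose clipping to [0, 1] (or to non-negative
    mean factors) would touch at least ``max_clipped_fraction`` of entries,
    rather than silently distorting the generative model.
    """
    design = design or CohortDesign()
    rng = np.random.default_rng(int(seed))
    m = design.n_regions
    n = design.n_control + design.n_csr

    # regions
    categories = _allocate_categories(m)
    regions = tuple(
        RegionInfo(j + 1, f"R{j + 1:03d}", f"Synthetic region {j + 1}", categories[j])
        for j in range(m)
    )
    baseline = design.baseline_median * np.power(
        10.0, rng.normal(0.0, design.baseline_log10_sd, size=m)
    )
    for _ in range(1000):
        over = baseline > design.baseline_cap
        if not over.any():
            break
        baseline[over] = design.baseline_median * np.power(
            10.0, rng.normal(0.0, design.baseline_log10_sd, size=int(over.sum()))
        )
    else:
        raise GeneratorError("baseline_cap too low for the baseline distribution")

    # per-region covariate slopes, expressed per µm
    sds = np.asarray(design.centroid_sds_um, dtype=float)
    slopes = rng.normal(0.0, 1.0, size=(m, 3)) * (design.slope_effect_per_sd / sds)

    # per-region condition coefficients
    if design.condition_scheme == "null":
        kc = np.zeros(m)
    elif design.condition_scheme == "homogeneous":
        kc = np.full(m, design.effect_size)
    else:  # heterogeneous: sparse signed effects
        affected = rng.random(m) < design.effect_fraction
        kc = np.where(affected, rng.normal(design.effect_mean, design.effect_sd, size=m), 0.0)

    # animals: controls first, then CSR; sex split deterministic within group
    condition = np.array([CONTROL] * design.n_control + [CSR] * design.n_csr, dtype=float)
    sexes = (
        ["M"] * design.control_males
        + ["F"] * (design.n_control - design.control_males)
        + ["M"] * design.csr_males
        + ["F"] * (design.n_csr - design.csr_males)
    )
    volumes = np.exp(rng.normal(0.0, design.volume_log_sd, size=n))
    centroids = np.column_stack(
        [
            _truncated_normal(rng, design.centroid_means_um[k], design.centroid_sds_um[k], n)
            for k in range(3)
        ]
    )
    animals = tuple(
        AnimalRecord(
            animal_id=f"{'C' if condition[i] == CONTROL else 'S'}{i + 1:02d}",
            condition=int(condition[i]),
            sex=sexes[i],
            injection_volume=float(volumes[i]),
            ml_um=float(centroids[i, 0]),
            ap_um=float(centroids[i, 1]),
            dv_um=float(centroids[i, 2]),
        )
        for i in range(n)
    )

    centered = centroids - centroids.mean(axis=0)
    factor = 1.0 + centered @ slopes.T + np.outer(condition, kc)
    noise = np.exp(design.noise_sd * rng.standard_normal((n, m))) if design.noise_sd > 0 else 1.0
    pf = baseline[None, :] * volumes[:, None] ** design.true_exponent * factor * noise

    clipped = (factor < 0) | (pf > 1.0) | (pf < 0.0)
    clipped_fraction = float(clipped.mean())
    if clipped_fraction >= design.max_clipped_fraction:
        raise GeneratorError(
            f"configuration would clip {clipped_fraction:.2%} of entries "
            f"(limit {design.max_clipped_fraction:.2%}); reduce slopes/effects/noise"
        )
    pf = np.clip(pf, 0.0, 1.0)

    cohort = CohortTable(
        animals=animals,
        regions=regions,
        values=pf,
        hemisphere=design.hemisphere,
        stage="raw",
        volume_unit=design.volume_unit,
    )
    truth = SyntheticTruth(
        exponent=design.true_exponent,
        baseline=baseline,
        slopes_per_um=slopes,
        condition_effect=kc,
        noise_sd=design.noise_sd,
        seed=int(seed),
        region_abbreviations=tuple(r.abbreviation for r in regions),
        clipped_fraction=clipped_fraction,
        design=design,
    )
    return cohort, truth


def ensemble_seeds(seed: int, n_cohorts: int) -> list[int]:
    """Deterministic distinct child seeds (< 2**31) for an ensemble."""
    if n_cohorts < 1:
        raise GeneratorError("n_cohorts must be >= 1")
    state = np.random.SeedSequence(int(seed)).generate_state(n_cohorts, dtype=np.uint64)
    seeds = [int(s % (2**31)) for s in state]
    if len(set(seeds)) != len(seeds):  # astronomically unlikely; keep determinism
        seeds = [int((s + i) % (2**31)) for i, s in enumerate(seeds)]
    assert len(set(seeds)) == len(seeds)
    return seeds


def make_null_ensemble(
    design: CohortDesign | None = None, n_cohorts: int = 1, seed: int = 0
) -> Iterator[CohortTable]:
    """Yield independent cohorts generated under the no-effect scheme.

    Child seeds derive deterministically from the master seed; cohort ``k``
    equals ``generate_cohort(null_design, ensemble_seeds(seed, n)[k])``.
    """
    design = replace(design or CohortDesign(), condition_scheme="null")
    for child in ensemble_seeds(seed, n_cohorts):
        cohort, _ = generate_cohort(design, child)
        yield cohort
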
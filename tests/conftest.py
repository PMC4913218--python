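import numpy as np
import pytest

from mesoproj import AnimalRecord, CohortDesign, CohortTable, RegionInfo, generate_cohort
from dataclasses import replace


def make_regions(abbrs, category="Isocortex"):
    return tuple(
        RegionInfo(i + 1, a, f"Region {a}", category) for i, a in enumerate(abbrs)
    )


def make_animals(n, conditions=None, volumes=None, centroids=None, sexes=None):
    conditions = conditions if conditions is not None else [1 if i % 2 == 0 else -1 for i in range(n)]
    volumes = volumes if volumes is not None else [1.0 + 0.1 * i for i in range(n)]
    if centroids is None:
        # deterministic but non-collinear spread (a collinear design would be
        # rank deficient in the GLM)
        rng = np.random.default_rng(1000 + n)
        centroids = [
            tuple(v) for v in rng.uniform([700, 1500, 550], [950, 2050, 720], size=(n, 3))
        ]
    sexes = sexes if sexes is not None else ["M" if i % 2 == 0 else "F" for i in range(n)]
    return tuple(
        AnimalRecord(f"a{i:02d}", conditions[i], sexes[i], volumes[i], *centroids[i])
        for i in range(n)
    )


def make_cohort(values, stage="raw", **kwargs):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return CohortTable(
        animals=make_animals(n, **kwargs),
        regions=make_regions([f"R{j:02d}" for j in range(m)]),
        values=values,
        stage=stage,
    )


@pytest.fixture(scope="session")
def small_design():
    """Reduced cohort for fast end-to-end tests (fewer regions, same animals)."""
    return replace(CohortDesign(), n_regions=60)


@pytest.fixture(scope="session")
def noiseless_design():
    """Exactly linear generative model: zero noise, heterogeneous effects."""
    return replace(
        CohortDesign(),
        noise_sd=0.0,
        condition_scheme="heterogeneous",
        baseline_log10_sd=0.6,
    )


@pytest.fixture(scope="session")
def separable_design():
    """Condition effects strong enough that groups are almost perfectly separable."""
    return replace(
        CohortDesign(),
        condition_scheme="heterogeneous",
        effect_mean=0.4,
        effect_sd=0.05,
        effect_fraction=0.6,
        noise_sd=0.03,
        baseline_log10_sd=0.6,
    )


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = generate_cohort(CohortDesign(), seed=11)
    return cohort, truth
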
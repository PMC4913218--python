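"""Core data model for tracer-injection cohorts.

A cohort is an animals × regions matrix of projection fractions (the
fraction of voxels in a target brain structure containing detected axonal
fluorescence) together with per-animal injection metadata and a region
ontology.  The matrix carries a processing-stage tag so that the analysis
chain (threshold → volume-normalize → unit-mean) can enforce its order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

#: Macro-anatomical categories used by the region ontology.
CATEGORIES = (
    "Isocortex",
    "Olfactory areas",
    "Hippocampal formation",
    "Claustrum + amygdala",
    "Striatum + pallidum",
    "Thalamus",
    "Hypothalamus",
    "Midbrain + pons",
    "Medulla",
    "Cerebellum",
    "Fiber tracts",
)

STAGES = ("raw", "thresholded", "volume_normalized", "unit_mean")
HEMISPHERES = ("ipsilateral", "contralateral")

#: Condition coding used throughout: control = +1, chronic sleep restriction = −1.
CONTROL = 1
CSR = -1

_UNIT_MEAN_TOL = 1e-12


class CohortError(ValueError):
    """Raised for any violation of the cohort data contracts."""


@dataclass(frozen=True)
class RegionInfo:
    """One row of the region ontology."""

    region_id: int
    abbreviation: str
    name: str
    category: str

    def __post_init__(self) -> None:
        if not (isinstance(self.region_id, (int, np.integer)) and self.region_id > 0):
            raise CohortError(f"region_id must be a positive integer, got {self.region_id!r}")
        if not self.abbreviation:
            raise CohortError("region abbreviation must be non-empty")
        if self.category not in CATEGORIES:
            raise CohortError(
                f"unknown category {self.category!r} for region {self.abbreviation!r}; "
                f"expected one of {CATEGORIES}"
            )


@dataclass(frozen=True)
class AnimalRecord:
    """Per-animal metadata.

    Injection-centroid distances are in µm: ``ml_um`` from the midline
    (medial–lateral), ``ap_um`` from the anterior commissure
    (anterior–posterior), ``dv_um`` from the pial surface (depth).
    ``injection_volume`` is in whatever unit the cohort declares.
    """

    animal_id: str
    condition: int  # +1 control, −1 CSR
    sex: str  # 'M' or 'F'
    injection_volume: float
    ml_um: float
    ap_um: float
    dv_um: float

    def __post_init__(self) -> None:
        if self.condition not in (CONTROL, CSR):
            raise CohortError(
                f"animal {self.animal_id!r}: condition must be +1 (control) or -1 (CSR), "
                f"got {self.condition!r}"
            )
        if self.sex not in ("M", "F"):
            raise CohortError(f"animal {self.animal_id!r}: sex must be 'M' or 'F', got {self.sex!r}")
        if not (self.injection_volume > 0):
            raise CohortError(
                f"animal {self.animal_id!r}: injection_volume must be > 0, got {self.injection_volume!r}"
            )
        for attr in ("ml_um", "ap_um", "dv_um"):
            v = getattr(self, attr)
            if not (np.isfinite(v) and v >= 0):
                raise CohortError(f"animal {self.animal_id!r}: {attr} must be finite and >= 0, got {v!r}")


@dataclass(eq=False)
class CohortTable:
    """Animals × regions projection-fraction matrix with metadata.

    Invariants (enforced at construction):

    * at ``stage='raw'`` every value lies in [0, 1];
    * at later stages values are ≥ 0 but may exceed 1 (volume normalization
      removes the voxel-ratio bound);
    * at ``stage='unit_mean'`` every region column has mean 1 within 1e−12;
    * animal ids and region abbreviations are unique; the matrix is dense
      (no NaN) and shaped (n_animals, n_regions).
    """

    animals: tuple[AnimalRecord, ...]
    regions: tuple[RegionInfo, ...]
    values: np.ndarray
    hemisphere: str = "ipsilateral"
    stage: str = "raw"
    volume_unit: str = "au"

    def __post_init__(self) -> None:
        self.animals = tuple(self.animals)
        self.regions = tuple(self.regions)
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in STAGES:
            raise CohortError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.hemisphere not in HEMISPHERES:
            raise CohortError(f"unknown hemisphere {self.hemisphere!r}")
        if self.values.ndim != 2 or self.values.shape != (len(self.animals), len(self.regions)):
            raise CohortError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.animals)} animals × {len(self.regions)} regions"
            )
        ids = [a.animal_id for a in self.animals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate animal ids: {dup}")
        abbrs = [r.abbreviation for r in self.regions]
        if len(set(abbrs)) != len(abbrs):
            dup = sorted({a for a in abbrs if abbrs.count(a) > 1})
            raise CohortError(f"duplicate region abbreviations: {dup}")
        rids = [r.region_id for r in self.regions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise CohortError(f"duplicate region ids: {dup}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise CohortError(
                f"non-finite value at animal {ids[i]!r}, region {abbrs[j]!r} "
                "(missing values are not supported)"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise CohortError(
                f"negative value {self.values[i, j]!r} at animal {ids[i]!r}, region {abbrs[j]!r}"
            )
        if self.stage == "raw" and np.any(self.values > 1):
            i, j = np.argwhere(self.values > 1)[0]
            raise CohortError(
                f"raw projection fraction {self.values[i, j]!r} > 1 at "
                f"animal {ids[i]!r}, region {abbrs[j]!r}"
            )
        if self.stage == "unit_mean" and len(self.animals) > 0:
            means = self.values.mean(axis=0)
            off = np.abs(means - 1.0)
            if np.any(off > _UNIT_MEAN_TOL):
                j = int(np.argmax(off))
                raise CohortError(
                    f"stage=unit_mean but column {abbrs[j]!r} has mean {means[j]!r}"
                )

    # -- convenience accessors ------------------------------------------------

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def animal_ids(self) -> list[str]:
        return [a.animal_id for a in self.animals]

    @property
    def region_abbreviations(self) -> list[str]:
        return [r.abbreviation for r in self.regions]

    @property
    def condition_codes(self) -> np.ndarray:
        """±1 condition vector in animal order."""
        return np.array([a.condition for a in self.animals], dtype=float)

    @property
    def injection_volumes(self) -> np.ndarray:
        return np.array([a.injection_volume for a in self.animals], dtype=float)

    @property
    def covariates_um(self) -> np.ndarray:
        """(n_animals, 3) raw injection-centroid distances, columns ML/AP/DV."""
        return np.array([[a.ml_um, a.ap_um, a.dv_um] for a in self.animals], dtype=float)

    def values_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=self.animal_ids, columns=self.region_abbreviations
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return (
            self.animals == other.animals
            and self.regions == other.regions
            and self.hemisphere == other.hemisphere
            and self.stage == other.stage
            and self.volume_unit == other.volume_unit
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
        )

    def with_values(self, values: np.ndarray, stage: str, regions: Sequence[RegionInfo] | None = None) -> "CohortTable":
        """Clone with a new matrix (and optionally region list) at a new stage."""
        return CohortTable(
            animals=self.animals,
            regions=tuple(regions) if regions is not None else self.regions,
            values=values,
            hemisphere=self.hemisphere,
            stage=stage,
            volume_unit=self.volume_unit,
        )


# -- file I/O -----------------------------------------------------------------


def _format_value(v: float) -> str:
    # repr() is the shortest decimal that round-trips a binary double
    return repr(float(v))


def write_cohort(cohort: CohortTable, out_prefix: str | Path) -> dict[str, Path]:
    """Write a cohort as ``<prefix>_values.csv``, ``<prefix>_metadata.json``,
    ``<prefix>_ontology.csv``.

    The CSV dialect is comma-separated UTF-8 with a mandatory header row and
    '.' decimals; floats are written in shortest round-trip form so a
    write/load cycle is value-exact.  Output is byte-deterministic.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": prefix.parent / f"{prefix.name}_values.csv",
        "metadata": prefix.parent / f"{prefix.name}_metadata.json",
        "ontology": prefix.parent / f"{prefix.name}_ontology.csv",
    }

    lines = [",".join(["animal_id"] + cohort.region_abbreviations)]
    for i, a in enumerate(cohort.animals):
        lines.append(",".join([a.animal_id] + [_format_value(v) for v in cohort.values[i]]))
    paths["values"].write_text("\n".join(lines) + "\n", encoding="utf-8")

    meta = {
        "stage": cohort.stage,
        "hemisphere": cohort.hemisphere,
        "volume_unit": cohort.volume_unit,
        "animals": [
            {
                "animal_id": a.animal_id,
                "condition": a.condition,
                "sex": a.sex,
                "injection_volume": a.injection_volume,
                "ml_um": a.ml_um,
                "ap_um": a.ap_um,
                "dv_um": a.dv_um,
            }
            for a in cohort.animals
        ],
    }
    paths["metadata"].write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")

    olines = ["region_id,abbreviation,name,category"]
    for r in cohort.regions:
        olines.append(f"{r.region_id},{r.abbreviation},{r.name},{r.category}")
    paths["ontology"].write_text("\n".join(olines) + "\n", encoding="utf-8")
    return paths


def load_ontology(ontology_path: str | Path) -> dict[str, RegionInfo]:
    """Read an ontology CSV (region_id, abbreviation, name, category) keyed
    by abbreviation.  Gaps in region_id numbering are accepted."""
    df = pd.read_csv(ontology_path, dtype={"abbreviation": str, "name": str, "category": str})
    required = {"region_id", "abbreviation", "name", "category"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"ontology file missing columns: {sorted(missing)}")
    regions: dict[str, RegionInfo] = {}
    for row in df.itertuples(index=False):
        info = RegionInfo(int(row.region_id), str(row.abbreviation), str(row.name), str(row.category))
        if info.abbreviation in regions:
            raise CohortError(f"duplicate abbreviation in ontology: {info.abbreviation!r}")
        regions[info.abbreviation] = info
    rids = [r.region_id for r in regions.values()]
    if len(set(rids)) != len(rids):
        dup = sorted({i for i in rids if rids.count(i) > 1})
        raise CohortError(f"duplicate region_id in ontology: {dup}")
    return regions


def load_cohort(
    values_path: str | Path,
    metadata_path: str | Path,
    ontology_path: str | Path,
) -> CohortTable:
    """Load a cohort from the three files written by :func:`write_cohort`.

    The values file is animals × regions with a header row of region
    abbreviations and a first column of animal ids; metadata is keyed by
    animal_id; the ontology must cover every region column.
    """
    ontology = load_ontology(ontology_path)

    raw_meta = json.loads(Path(metadata_path).read_text(encoding="utf-8"))
    if isinstance(raw_meta, list):  # bare array of animal records
        raw_meta = {"animals": raw_meta}
    stage = raw_meta.get("stage", "raw")
    hemisphere = raw_meta.get("hemisphere", "ipsilateral")
    volume_unit = raw_meta.get("volume_unit", "au")
    meta_by_id: dict[str, AnimalRecord] = {}
    for rec in raw_meta["animals"]:
        a = AnimalRecord(
            animal_id=str(rec["animal_id"]),
            condition=int(rec["condition"]),
            sex=str(rec["sex"]),
            injection_volume=float(rec["injection_volume"]),
            ml_um=float(rec["ml_um"]),
            ap_um=float(rec["ap_um"]),
            dv_um=float(rec["dv_um"]),
        )
        if a.animal_id in meta_by_id:
            raise CohortError(f"duplicate animal_id in metadata: {a.animal_id!r}")
        meta_by_id[a.animal_id] = a

    df = pd.read_csv(values_path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    for abbr in df.columns:
        if abbr not in ontology:
            raise CohortError(f"region column {abbr!r} absent from ontology")
    animals = []
    for aid in df.index:
        if aid not in meta_by_id:
            raise CohortError(f"animal {aid!r} in values file missing from metadata")
        animals.append(meta_by_id[aid])
    extra = set(meta_by_id) - set(df.index)
    if extra:
        raise CohortError(f"metadata animals absent from values file: {sorted(extra)}")

    regions = [ontology[abbr] for abbr in df.columns]
    return CohortTable(
        animals=tuple(animals),
        regions=tuple(regions),
        values=df.to_numpy(dtype=float),
        hemisphere=hemisphere,
        stage=stage,
        volume_unit=volume_unit,
    )


def subset_cohort(cohort: CohortTable, animal_filter: Callable[[AnimalRecord], bool]) -> CohortTable:
    """Restrict a cohort to the animals matched by ``animal_filter``.

    Regions, stage and retained values are unchanged.  An empty selection is
    an error (downstream fits are undefined on it).  Stratified reanalyses
    should subset at stage='raw' and re-run the processing chain, since a
    subset of a unit-mean table generally no longer has unit column means.
    """
    keep = [i for i, a in enumerate(cohort.animals) if animal_filter(a)]
    if not keep:
        raise CohortError("animal filter matched no animals")
    try:
        return CohortTable(
            animals=tuple(cohort.animals[i] for i in keep),
            regions=cohort.regions,
            values=cohort.values[keep],
            hemisphere=cohort.hemisphere,
            stage=cohort.stage,
            volume_unit=cohort.volume_unit,
        )
    except CohortError as exc:
        raise CohortError(
            f"subset violates stage={cohort.stage!r} invariants ({exc}); "
            "subset at stage='raw' and re-run the processing chain"
        ) from exc
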
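"""Domain types and tabular I/O for team-level hunting reports.

The reporting unit is the hunting team: each report carries the team's
hunting area (ha) and its harvest count for one focal species, located in
a hunting management precinct (HMP) nested within a county.  Identifiers
are opaque strings and never arithmetic operands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REPORT_COLUMNS = ["report_id", "county_id", "hmp_id", "area_ha", "harvest"]
REGISTRY_COLUMNS = ["county_id", "hmp_id", "huntable_area_ha", "excluded"]


class DataError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class Report:
    """One team's report: hunting area (ha) and harvest count of the focal species."""

    report_id: str
    county_id: str
    hmp_id: str
    area_ha: float
    harvest: int

    def __post_init__(self) -> None:
        if not self.area_ha > 0:
            raise DataError(f"report {self.report_id!r}: area_ha must be > 0, got {self.area_ha}")
        if self.harvest < 0 or int(self.harvest) != self.harvest:
            raise DataError(
                f"report {self.report_id!r}: harvest must be a non-negative integer, got {self.harvest}"
            )


@dataclass(frozen=True)
class RegionRegistry:
    """County -> HMP hierarchy with total huntable area per HMP.

    ``excluded`` flags HMPs that the estimating agency leaves out of
    harvest estimation (e.g. above the tree line, or small urban HMPs).
    """

    county_of: dict[str, str]          # hmp_id -> county_id
    huntable_area: dict[str, float]    # hmp_id -> ha
    excluded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for hmp, area in self.huntable_area.items():
            if not area > 0:
                raise DataError(f"HMP {hmp!r}: huntable area must be > 0, got {area}")
        if set(self.county_of) != set(self.huntable_area):
            raise DataError("registry: county mapping and huntable areas cover different HMPs")

    @property
    def counties(self) -> list[str]:
        return sorted(set(self.county_of.values()))

    def hmps_in(self, county_id: str) -> list[str]:
        return sorted(h for h, c in self.county_of.items() if c == county_id)

    @property
    def hmps(self) -> list[str]:
        return sorted(self.county_of)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.county_of[h], h, self.huntable_area[h], int(h in self.excluded))
            for h in self.hmps
        ]
        return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)


@dataclass(frozen=True)
class Dataset:
    """A set of validated reports for one species plus the region registry."""

    reports: tuple[Report, ...]
    registry: RegionRegistry
    species_label: str = "species"

    def __post_init__(self) -> None:
        reported: dict[str, float] = {}
        for r in self.reports:
            if r.hmp_id not in self.registry.county_of:
                raise DataError(f"report {r.report_id!r}: HMP {r.hmp_id!r} absent from registry")
            if self.registry.county_of[r.hmp_id] != r.county_id:
                raise DataError(
                    f"report {r.report_id!r}: HMP {r.hmp_id!r} belongs to county "
                    f"{self.registry.county_of[r.hmp_id]!r}, not {r.county_id!r}"
                )
            reported[r.hmp_id] = reported.get(r.hmp_id, 0.0) + r.area_ha
        for hmp, tot in reported.items():
            T = self.registry.huntable_area[hmp]
            if tot > T * (1 + 1e-9):
                raise DataError(
                    f"HMP {hmp!r}: reported area {tot} ha exceeds huntable area {T} ha"
                )

    def __len__(self) -> int:
        return len(self.reports)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.report_id, r.county_id, r.hmp_id, r.area_ha, r.harvest) for r in self.reports],
            columns=REPORT_COLUMNS,
        )

    def reports_in_hmp(self, hmp_id: str) -> list[Report]:
        return [r for r in self.reports if r.hmp_id == hmp_id]

    def reports_in_county(self, county_id: str) -> list[Report]:
        return [r for r in self.reports if r.county_id == county_id]


def load_registry(registry_path) -> RegionRegistry:
    df = pd.read_csv(registry_path, dtype={"county_id": str, "hmp_id": str})
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"registry file missing column(s): {sorted(missing)}")
    dup = df["hmp_id"].duplicated()
    if dup.any():
        raise DataError(f"registry: duplicated HMP id(s): {df.loc[dup, 'hmp_id'].tolist()}")
    return RegionRegistry(
        county_of=dict(zip(df["hmp_id"], df["county_id"])),
        huntable_area=dict(zip(df["hmp_id"], df["huntable_area_ha"].astype(float))),
        excluded=frozenset(df.loc[df["excluded"].astype(int) == 1, "hmp_id"]),
    )


def load_dataset(reports_path, registry_path, species_label: str = "species") -> Dataset:
    """Read the reports and registry tables and return a validated ``Dataset``.

    Row order of the reports file is preserved.  Any invariant violation
    (missing column, non-positive area, negative or fractional harvest,
    HMP absent from the registry, reported area exceeding huntable area)
    raises :class:`DataError` naming the offending row.
    """
    registry = load_registry(registry_path)
    df = pd.read_csv(reports_path, dtype={"report_id": str, "county_id": str, "hmp_id": str})
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"reports file missing column(s): {sorted(missing)}")
    reports = []
    for _, row in df.iterrows():
        harvest = float(row["harvest"])
        if not float(harvest).is_integer():
            raise DataError(f"report {row['report_id']!r}: harvest must be integral, got {harvest}")
        reports.append(
            Report(
                report_id=str(row["report_id"]),
                county_id=str(row["county_id"]),
                hmp_id=str(row["hmp_id"]),
                area_ha=float(row["area_ha"]),
                harvest=int(harvest),
            )
        )
    return Dataset(reports=tuple(reports), registry=registry, species_label=species_label)


def write_dataset(dataset: Dataset, reports_path, registry_path) -> None:
    dataset.to_frame().to_csv(reports_path, index=False)
    dataset.registry.to_frame().to_csv(registry_path, index=False)


def reported_area(dataset: Dataset, hmp_id: str) -> float:
    if hmp_id not in dataset.registry.county_of:
        raise KeyError(f"unknown HMP {hmp_id!r}")
    return float(sum(r.area_ha for r in dataset.reports if r.hmp_id == hmp_id))


def unreported_area(dataset: Dataset, hmp_id: str) -> float:
    """Huntable area of the HMP minus its total reported area (ha, >= 0)."""
    if hmp_id not in dataset.registry.county_of:
        raise KeyError(f"unknown HMP {hmp_id!r}")
    U = dataset.registry.huntable_area[hmp_id] - reported_area(dataset, hmp_id)
    # the Dataset invariant guarantees non-negativity up to rounding
    return float(max(U, 0.0))


def apply_species_exclusions(dataset: Dataset) -> tuple[Dataset, dict[str, list[str]]]:
    """Drop counties whose every report has zero harvest, and registry-excluded HMPs.

    Counties where no report recorded the focal species are treated as
    outside the species' range and removed entirely (reports and registry
    entries).  HMPs flagged ``excluded`` in the registry are likewise
    dropped.  Returns the filtered dataset and ``{"counties": [...],
    "hmps": [...]}`` listing the dropped units.  Idempotent.
    """
    harvest_by_county: dict[str, int] = {}
    for r in dataset.reports:
        harvest_by_county[r.county_id] = harvest_by_county.get(r.county_id, 0) + r.harvest
    dropped_counties = sorted(c for c, k in harvest_by_county.items() if k == 0)
    dropped_hmps = sorted(dataset.registry.excluded)

    keep_hmp = {
        h
        for h in dataset.registry.hmps
        if h not in dataset.registry.excluded
        and dataset.registry.county_of[h] not in dropped_counties
    }
    registry = RegionRegistry(
        county_of={h: dataset.registry.county_of[h] for h in keep_hmp},
        huntable_area={h: dataset.registry.huntable_area[h] for h in keep_hmp},
        excluded=frozenset(),
    )
    reports = tuple(r for r in dataset.reports if r.hmp_id in keep_hmp)
    if not reports:
        warnings.warn("all reports removed by species exclusions", stacklevel=2)
    filtered = Dataset(reports=reports, registry=registry, species_label=dataset.species_label)
    return filtered, {"counties": dropped_counties, "hmps": dropped_hmps}


@dataclass(frozen=True)
class IndexedData:
    """Dense integer indexing of a Dataset for vectorized likelihoods.

    Counties and HMPs are sorted lexically; every registry HMP is indexed
    even if it has no report (prediction needs rates for those too).
    """

    counties: tuple[str, ...]
    hmps: tuple[str, ...]
    county_of_hmp: np.ndarray     # (n_hmp,) int
    hmp_of_report: np.ndarray     # (n_rep,) int
    county_of_report: np.ndarray  # (n_rep,) int
    area: np.ndarray              # (n_rep,) float
    harvest: np.ndarray           # (n_rep,) int

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "IndexedData":
        counties = tuple(dataset.registry.counties)
        hmps = tuple(dataset.registry.hmps)
        c_ix = {c: i for i, c in enumerate(counties)}
        h_ix = {h: i for i, h in enumerate(hmps)}
        county_of_hmp = np.array([c_ix[dataset.registry.county_of[h]] for h in hmps], dtype=int)
        hmp_of_report = np.array([h_ix[r.hmp_id] for r in dataset.reports], dtype=int)
        return cls(
            counties=counties,
            hmps=hmps,
            county_of_hmp=county_of_hmp,
            hmp_of_report=hmp_of_report,
            county_of_report=county_of_hmp[hmp_of_report] if len(dataset.reports) else np.array([], dtype=int),
            area=np.array([r.area_ha for r in dataset.reports], dtype=float),
            harvest=np.array([r.harvest for r in dataset.reports], dtype=int),
        )

    @property
    def n_counties(self) -> int:
        return len(self.counties)

    @property
    def n_hmps(self) -> int:
        return len(self.hmps)

    @property
    def n_reports(self) -> int:
        return len(self.area)
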
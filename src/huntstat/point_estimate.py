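"""The currently implemented linear-extrapolation point estimate (P.E.).

For each HMP the harvest-per-area rate is total reported harvest divided
by total reported area (falling back to the county-level ratio for HMPs
with no reports).  The HMP total is the reported harvest plus the rate
times the unreported area.  The estimator is deterministic and carries
no uncertainty; it is the baseline the hierarchical models improve on,
and it is deliberately sensitive to single low-coverage reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_model import Dataset, unreported_area


@dataclass(frozen=True)
class PointEstimateResult:
    nu: dict[str, float]            # hmp -> animals per ha
    hmp_total: dict[str, float]     # hmp -> estimated harvest
    county_total: dict[str, float]
    national_total: float

    def to_frame(self) -> pd.DataFrame:
        rows = [("hmp", h, e) for h, e in sorted(self.hmp_total.items())]
        rows += [("county", c, e) for c, e in sorted(self.county_total.items())]
        rows.append(("nation", "total", self.national_total))
        return pd.DataFrame(rows, columns=["level", "unit_id", "estimate"])


def harvest_rate(dataset: Dataset, hmp_id: str) -> float:
    """Reported harvest per reported area for one HMP (county fallback).

    HMPs with reports use their own totals; HMPs without reports inherit
    the ratio of their county's reports.  A county with no reports is an
    error - such counties are excluded from estimation upstream.
    """
    if hmp_id not in dataset.registry.county_of:
        raise KeyError(f"unknown HMP {hmp_id!r}")
    own = dataset.reports_in_hmp(hmp_id)
    if own:
        return sum(r.harvest for r in own) / sum(r.area_ha for r in own)
    county = dataset.registry.county_of[hmp_id]
    in_county = dataset.reports_in_county(county)
    if not in_county:
        raise ValueError(
            f"county {county!r} has no reports; exclude it before estimation")
    return sum(r.harvest for r in in_county) / sum(r.area_ha for r in in_county)


def estimate(dataset: Dataset) -> PointEstimateResult:
    """Linear extrapolation per HMP, aggregated to county and nation."""
    nu: dict[str, float] = {}
    hmp_total: dict[str, float] = {}
    county_total: dict[str, float] = {}
    for hmp in dataset.registry.hmps:
        rate = harvest_rate(dataset, hmp)
        reported_harvest = sum(r.harvest for r in dataset.reports_in_hmp(hmp))
        E = reported_harvest + rate * unreported_area(dataset, hmp)
        nu[hmp] = rate
        hmp_total[hmp] = E
        county = dataset.registry.county_of[hmp]
        county_total[county] = county_total.get(county, 0.0) + E
    return PointEstimateResult(
        nu=nu,
        hmp_total=hmp_total,
        county_total=county_total,
        national_total=float(sum(county_total.values())),
    )
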
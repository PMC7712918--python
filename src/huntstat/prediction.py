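"""Posterior-predictive simulation of harvest on unreported area.

For each predictive sample, one draw from the area posterior and one from
the harvest posterior are paired uniformly at random.  Within each HMP,
hypothetical non-reporting team areas are drawn from
Log-Normal(log m_kl, s_l) recursively until their sum overshoots the
unreported area U_kl; the overshooting team's area is clipped so the
areas sum to U_kl exactly (clipping the exposure before sampling its
harvest keeps E[total] = mu * U exact under the Poisson model).  Each
team's harvest is then drawn according to the harvest model: Poisson at
mean mu*A*delta, or Gamma team rate (shape alpha, mean mu*A*delta)
followed by Poisson.  Totals aggregate exactly from HMP to county to
nation within every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .area_model import AreaPosterior
from .data_model import Dataset, unreported_area
from .harvest_model import HarvestPosterior, ModelSpec


@dataclass
class PredictiveSamples:
    """Per-sample unreported-harvest totals at HMP, county and national level."""

    model: str
    counties: tuple[str, ...]
    hmps: tuple[str, ...]
    county_of_hmp: tuple[str, ...]
    kappa: np.ndarray          # (Q, n_hmps) integer harvest on unreported area
    n_teams: np.ndarray        # (Q, n_hmps) sampled non-reporting team counts
    seed: int = 0

    @property
    def Q(self) -> int:
        return self.kappa.shape[0]

    @property
    def kappa_county(self) -> np.ndarray:
        out = np.zeros((self.Q, len(self.counties)), dtype=self.kappa.dtype)
        for j, c in enumerate(self.county_of_hmp):
            out[:, self.counties.index(c)] += self.kappa[:, j]
        return out

    @property
    def kappa_national(self) -> np.ndarray:
        return self.kappa.sum(axis=1)

    def hmp_column(self, hmp_id: str) -> np.ndarray:
        try:
            return self.kappa[:, self.hmps.index(hmp_id)]
        except ValueError:
            raise KeyError(f"unknown HMP {hmp_id!r}") from None


def sample_team_areas(m: float, s: float, U: float, rng: np.random.Generator) -> np.ndarray:
    """Draw Log-Normal(log m, s) team areas summing exactly to U (ha).

    Areas are drawn until the cumulative sum reaches U; the final area is
    replaced by the remainder.  Returns an empty array when U = 0.
    """
    if U < 0:
        raise ValueError(f"unreported area must be >= 0, got {U}")
    if U == 0:
        return np.empty(0)
    mean_area = m * np.exp(0.5 * s * s)
    areas: list[np.ndarray] = []
    total = 0.0
    while total < U:
        expect = max(int((U - total) / mean_area) + 1, 4)
        block = rng.lognormal(np.log(m), s, size=min(expect, 100_000))
        areas.append(block)
        total += float(block.sum())
    flat = np.concatenate(areas)
    cum = np.cumsum(flat)
    n = int(np.searchsorted(cum, U, side="left")) + 1
    out = flat[:n].copy()
    out[-1] = U - (cum[n - 2] if n > 1 else 0.0)
    return out


def sample_team_harvest(spec: ModelSpec, mu: float, alpha: float, phi: float,
                        area: float, m_bar: float, rng: np.random.Generator) -> int:
    """One team's harvest count under the given model variant."""
    d = (area / m_bar) ** phi if spec.include_phi else 1.0
    mean = mu * area * d
    if mean == 0:
        return 0
    if spec.include_alpha:
        rate = rng.gamma(alpha, mean / alpha)
        return int(rng.poisson(rate))
    return int(rng.poisson(mean))


def _harvest_block(spec: ModelSpec, mu: float, alpha: float, phi: float,
                   areas: np.ndarray, m_bar: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorized team harvests for all sampled teams of one HMP."""
    if areas.size == 0:
        return np.zeros(0, dtype=int)
    d = (areas / m_bar) ** phi if spec.include_phi else 1.0
    mean = mu * areas * d
    if spec.include_alpha:
        rate = rng.gamma(alpha, mean / alpha)
        return rng.poisson(rate)
    return rng.poisson(mean)


def predict_unreported(area_post: AreaPosterior, harvest_post: HarvestPosterior,
                       dataset: Dataset, Q: int, seed: int = 0,
                       U_override: dict[str, float] | None = None) -> PredictiveSamples:
    """Q posterior-predictive samples of unreported harvest per HMP.

    Each sample pairs one area-posterior draw with one harvest-posterior
    draw, sampled independently and uniformly with replacement.
    ``U_override`` replaces the per-HMP unreported area, which the
    train/validation workflow uses to predict harvest on the area covered
    by the held-out reports.  Reproducible given ``seed``.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    hmps = dataset.registry.hmps
    for h in hmps:
        area_post.hmp_index(h)      # raises KeyError if missing
        harvest_post.hmp_index(h)
    spec = harvest_post.spec
    m_bar = area_post.m_bar()
    if U_override is None:
        U = np.array([unreported_area(dataset, h) for h in hmps])
    else:
        U = np.array([float(U_override.get(h, 0.0)) for h in hmps])
    county_of = tuple(dataset.registry.county_of[h] for h in hmps)
    a_ix_hmp = np.array([area_post.hmp_index(h) for h in hmps])
    a_ix_cty = np.array([area_post.county_index(dataset.registry.county_of[h]) for h in hmps])
    h_ix_hmp = np.array([harvest_post.hmp_index(h) for h in hmps])

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9CED]))
    draw_a = rng.integers(0, area_post.n_draws, size=Q)
    draw_h = rng.integers(0, harvest_post.n_draws, size=Q)

    kappa = np.zeros((Q, len(hmps)), dtype=np.int64)
    n_teams = np.zeros((Q, len(hmps)), dtype=np.int64)
    for q in range(Q):
        ia, ih = draw_a[q], draw_h[q]
        for j, h in enumerate(hmps):
            if U[j] == 0:
                continue
            m = area_post.m[ia, a_ix_hmp[j]]
            s = area_post.s[ia, a_ix_cty[j]]
            areas = sample_team_areas(m, s, U[j], rng)
            mu = harvest_post.mu[ih, h_ix_hmp[j]]
            alpha = harvest_post.alpha[ih, h_ix_hmp[j]]
            phi = harvest_post.phi[ih]
            counts = _harvest_block(spec, mu, alpha, phi, areas, m_bar[h], rng)
            kappa[q, j] = counts.sum()
            n_teams[q, j] = areas.size
    return PredictiveSamples(
        model=spec.name, counties=tuple(dataset.registry.counties), hmps=tuple(hmps),
        county_of_hmp=county_of, kappa=kappa, n_teams=n_teams, seed=seed,
    )


def summarize(samples: PredictiveSamples, reported: Dataset, level: str,
              unit_id: str | None = None,
              probs: tuple[float, float] = (0.025, 0.975)) -> dict[str, float]:
    """Median and central interval of total harvest (reported + predicted).

    Totals include the observed reported harvest of the requested unit, so
    they are directly comparable with the point estimate.  Quantiles use
    the nearest-order-statistic empirical definition (method="nearest"),
    appropriate for the integer-valued predictive samples.
    """
    if not all(0 < p < 1 for p in probs):
        raise ValueError("probs must lie strictly inside (0, 1)")
    if level == "hmp":
        draws = samples.hmp_column(unit_id)
        rep = sum(r.harvest for r in reported.reports_in_hmp(unit_id))
    elif level == "county":
        if unit_id not in samples.counties:
            raise KeyError(f"unknown county {unit_id!r}")
        draws = samples.kappa_county[:, samples.counties.index(unit_id)]
        rep = sum(r.harvest for r in reported.reports_in_county(unit_id))
    elif level == "nation":
        draws = samples.kappa_national
        rep = sum(r.harvest for r in reported.reports)
    else:
        raise ValueError(f"unknown level {level!r}")
    total = draws + rep
    lo, hi = (float(np.quantile(total, p, method="nearest")) for p in probs)
    return {
        "level": level, "unit_id": unit_id or "total", "reported": float(rep),
        "median": float(np.quantile(total, 0.5, method="nearest")),
        "lower": lo, "upper": hi, "prob": float(probs[1] - probs[0]),
    }
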
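import numpy as np
import pytest

from huntstat import Dataset, RegionRegistry, Report, default_priors


def make_registry(spec: dict[str, dict[str, float]], excluded=()) -> RegionRegistry:
    """spec: {county: {hmp: huntable_area}}"""
    county_of, area = {}, {}
    for county, hmps in spec.items():
        for hmp, a in hmps.items():
            county_of[hmp] = county
            area[hmp] = a
    return RegionRegistry(county_of=county_of, huntable_area=area,
                          excluded=frozenset(excluded))


def make_dataset(registry: RegionRegistry, rows, species="test") -> Dataset:
    """rows: iterable of (hmp_id, area_ha, harvest)."""
    reports = tuple(
        Report(report_id=f"r{i}", county_id=registry.county_of[hmp],
               hmp_id=hmp, area_ha=float(a), harvest=int(k))
        for i, (hmp, a, k) in enumerate(rows)
    )
    return Dataset(reports=reports, registry=registry, species_label=species)


@pytest.fixture
def toy_registry():
    return make_registry({
        "A": {"A1": 1000.0, "A2": 2000.0},
        "B": {"B1": 5000.0},
    })


@pytest.fixture
def toy_dataset(toy_registry):
    return make_dataset(toy_registry, [
        ("A1", 300.0, 2), ("A1", 200.0, 3), ("A2", 400.0, 0), ("B1", 1000.0, 10),
    ])


@pytest.fixture
def priors():
    return default_priors()


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def make_samples_registry(values, registry):
    """PredictiveSamples with given national draws (single-HMP registry)."""
    from huntstat.prediction import PredictiveSamples

    assert len(registry.hmps) == 1
    values = np.asarray(values, dtype=np.int64)[:, None]
    return PredictiveSamples(
        model="m0", counties=tuple(registry.counties), hmps=tuple(registry.hmps),
        county_of_hmp=tuple(registry.county_of[h] for h in registry.hmps),
        kappa=values, n_teams=np.ones_like(values))


def constant_area_posterior(registry, m, s, n_draws=1):
    """Degenerate area posterior: every draw identical (point mass)."""
    from huntstat import AreaPosterior

    counties = tuple(registry.counties)
    hmps = tuple(registry.hmps)
    nc, nh = len(counties), len(hmps)
    ones = np.ones(n_draws)
    return AreaPosterior(
        counties=counties, hmps=hmps,
        W=np.log(m) * ones, T_sd=0.1 * ones, t_sd=0.1 * ones,
        u=np.log(s) * ones, z=0.1 * ones,
        L=np.zeros((n_draws, nc)), C=np.zeros((n_draws, nh)),
        v=np.zeros((n_draws, nc)),
        m=np.full((n_draws, nh), m), s=np.full((n_draws, nc), s),
        diagnostics={},
    )


def constant_harvest_posterior(registry, mu, alpha=np.inf, phi=0.0,
                               model="m0", n_draws=1, n_reports=1):
    """Degenerate harvest posterior: every draw identical (point mass)."""
    from huntstat import HarvestPosterior, ModelSpec

    counties = tuple(registry.counties)
    hmps = tuple(registry.hmps)
    nc, nh = len(counties), len(hmps)
    ones = np.ones(n_draws)
    return HarvestPosterior(
        spec=ModelSpec.from_name(model), counties=counties, hmps=hmps,
        report_ids=tuple(f"r{i}" for i in range(n_reports)),
        omega=np.log(mu) * ones, tau=0.1 * ones, sigma=0.1 * ones,
        upsilon=(np.log(alpha) if np.isfinite(alpha) else 0.0) * ones,
        gamma=np.zeros(n_draws), phi=phi * ones,
        lam=np.zeros((n_draws, nc)), chi=np.zeros((n_draws, nh)),
        mu=np.full((n_draws, nh), mu), alpha=np.full((n_draws, nh), alpha),
        loglik=np.zeros((n_draws, n_reports)),
    )
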
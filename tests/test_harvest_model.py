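import numpy as np
import pytest
from scipy import integrate, optimize, stats

from huntstat import McmcSettings, Report, default_priors
from huntstat.data_model import IndexedData
from huntstat.harvest_model import (HarvestParams, HarvestPosterior, ModelSpec, delta,
                                    fit_harvest_model, gamma_poisson_loglik,
                                    harvest_log_density, make_harvest_logp_grad,
                                    ml_rate, poisson_loglik, seed_chain)
from huntstat.harvest_model import _Layout

from conftest import make_dataset, make_registry


def report(K, A, hmp="A1", county="A"):
    return Report(report_id="r", county_id=county, hmp_id=hmp, area_ha=A, harvest=K)


# ---------------------------------------------------------------- model spec

def test_model_spec_names_round_trip():
    for name in ("m0", "ma", "mag", "mp", "map", "magp"):
        assert ModelSpec.from_name(name).name == name


def test_gamma_requires_alpha():
    with pytest.raises(ValueError, match="requires"):
        ModelSpec(include_alpha=False, include_gamma=True)
    with pytest.raises(ValueError, match="unknown model"):
        ModelSpec.from_name("mx")


# ---------------------------------------------------------------- delta

@pytest.mark.parametrize("A,m_bar,phi,expected", [
    (123.0, 77.0, 0.0, 1.0),
    (250.0, 250.0, -0.8, 1.0),
    (400.0, 100.0, -0.5, 0.5),
])
def test_delta_values(A, m_bar, phi, expected):
    assert delta(A, m_bar, phi) == pytest.approx(expected)


def test_delta_rejects_non_positive():
    with pytest.raises(ValueError):
        delta(0.0, 1.0, 0.5)
    with pytest.raises(ValueError):
        delta(1.0, -1.0, 0.5)


# ---------------------------------------------------------------- likelihoods

def test_poisson_loglik_zero_count_closed_form():
    assert poisson_loglik(report(0, 200.0), mu=0.01, delta_=1.5) == pytest.approx(-3.0)


def test_poisson_loglik_matches_scipy_oracle(rng):
    for _ in range(20):
        K = int(rng.integers(0, 30))
        A = float(rng.uniform(10, 5000))
        mu = float(rng.uniform(1e-4, 0.1))
        d = float(rng.uniform(0.2, 3.0))
        assert poisson_loglik(report(K, A), mu, d) == pytest.approx(
            stats.poisson.logpmf(K, mu * A * d), abs=1e-10)


def test_poisson_sum_derivative_identity(rng):
    # d/dmu of the summed per-report log-pmf equals sum(K)/mu - sum(A),
    # the stationarity condition behind the ML plug-in rate
    reports = [report(int(k), float(a)) for k, a in
               zip(rng.integers(0, 10, 6), rng.uniform(50, 500, 6))]
    mu0 = 0.013

    def total(mu):
        return sum(poisson_loglik(r, mu) for r in reports)

    eps = 1e-7
    num = (total(mu0 + eps) - total(mu0 - eps)) / (2 * eps)
    expected = sum(r.harvest for r in reports) / mu0 - sum(r.area_ha for r in reports)
    assert num == pytest.approx(expected, rel=1e-5)


def test_gamma_poisson_zero_count_closed_form():
    m = 0.02 * 300.0
    got = gamma_poisson_loglik(report(0, 300.0), mu=0.02, alpha=0.7)
    assert got == pytest.approx(0.7 * np.log(0.7 / (0.7 + m)), abs=1e-12)


def test_gamma_poisson_approaches_poisson_for_huge_shape(rng):
    for _ in range(10):
        K = int(rng.integers(0, 21))
        A = float(rng.uniform(20, 400))
        mu = float(rng.uniform(1e-4, 5.0 / 400))
        lp = poisson_loglik(report(K, A), mu)
        lgp = gamma_poisson_loglik(report(K, A), mu, alpha=1e8)
        assert lgp == pytest.approx(lp, abs=1e-5)


def test_gamma_poisson_matches_quadrature_oracle(rng):
    for _ in range(10):
        K = int(rng.integers(0, 12))
        A = float(rng.uniform(20, 800))
        mu = float(rng.uniform(1e-4, 0.02))
        alpha = float(rng.uniform(0.3, 5.0))
        d = float(rng.uniform(0.5, 2.0))
        mean = mu * A * d

        def integrand(theta):
            return stats.poisson.pmf(K, theta) * stats.gamma.pdf(
                theta, a=alpha, scale=mean / alpha)

        val, err = integrate.quad(integrand, 0, np.inf, limit=200)
        assert gamma_poisson_loglik(report(K, A), mu, alpha, d) == pytest.approx(
            np.log(val), abs=1e-8)


def test_gamma_poisson_pmf_normalizes():
    for alpha, mean in [(0.5, 3.0), (2.0, 10.0), (8.0, 0.4)]:
        mu, A = mean / 100.0, 100.0
        total = sum(np.exp(gamma_poisson_loglik(report(k, A), mu, alpha))
                    for k in range(2000))
        assert total == pytest.approx(1.0, abs=1e-8)


def test_gamma_poisson_converges_monotonically_in_tail():
    K, A, mu = 4, 200.0, 0.01
    lp = poisson_loglik(report(K, A), mu)
    gaps = [abs(gamma_poisson_loglik(report(K, A), mu, a) - lp)
            for a in (1e1, 1e2, 1e3, 1e4)]
    assert all(g1 > g2 for g1, g2 in zip(gaps, gaps[1:]))


# ---------------------------------------------------------------- predictors

def params_with(chi, lam, **kw):
    return HarvestParams(omega=kw.get("omega", -5.0), tau=0.5, sigma=0.4,
                         lam={"A": lam}, chi={"A1": chi},
                         upsilon=kw.get("upsilon", -0.5), gamma=kw.get("gamma", 0.0),
                         phi=kw.get("phi", 0.0))


def test_linear_predictor_intercept():
    from huntstat.harvest_model import linear_predictors

    mu, alpha = linear_predictors(params_with(0.0, 0.0), ModelSpec(), "A1", "A")
    assert mu == pytest.approx(np.exp(-5.0))
    assert alpha == np.inf


def test_alpha_rises_with_rate_when_gamma_positive():
    from huntstat.harvest_model import linear_predictors

    spec = ModelSpec(include_alpha=True, include_gamma=True)
    _, a_hi = linear_predictors(params_with(0.5, 0.3, gamma=0.8), spec, "A1", "A")
    _, a_0 = linear_predictors(params_with(0.0, 0.0, gamma=0.8), spec, "A1", "A")
    assert a_hi > a_0 == pytest.approx(np.exp(-0.5))


def test_alpha_constant_without_gamma():
    from huntstat.harvest_model import linear_predictors

    spec = ModelSpec(include_alpha=True)
    _, a1 = linear_predictors(params_with(0.9, -0.4, gamma=2.0), spec, "A1", "A")
    assert a1 == pytest.approx(np.exp(-0.5))
    with pytest.raises(KeyError):
        linear_predictors(params_with(0, 0), spec, "ZZ", "A")


# ---------------------------------------------------------------- ML rate

def test_ml_rate_arithmetic():
    assert ml_rate([report(2, 100.0), report(3, 400.0)]) == pytest.approx(0.01)
    assert ml_rate([report(0, 50.0), report(0, 150.0)]) == 0.0
    with pytest.raises(ValueError):
        ml_rate([])


def test_ml_rate_maximizes_single_hmp_poisson_likelihood(rng):
    reports = [report(int(k), float(a)) for k, a in
               zip(rng.integers(0, 8, 5), rng.uniform(50, 800, 5))]

    def nll(mu):
        return -sum(poisson_loglik(r, mu) for r in reports)

    res = optimize.minimize_scalar(nll, bounds=(1e-8, 1.0), method="bounded",
                                   options={"xatol": 1e-12})
    assert ml_rate(reports) == pytest.approx(res.x, abs=1e-6)


# ---------------------------------------------------------------- seeding

def small_dataset():
    reg = make_registry({"A": {"A1": 50000.0, "A2": 50000.0}, "B": {"B1": 50000.0}})
    return make_dataset(reg, [("A1", 200.0, 4), ("A1", 100.0, 2), ("A2", 150.0, 0),
                              ("B1", 300.0, 6)])


def test_seed_chain_deterministic():
    ds = small_dataset()
    spec = ModelSpec.from_name("magp")
    a = seed_chain(ds, spec, np.random.default_rng(3))
    b = seed_chain(ds, spec, np.random.default_rng(3))
    assert a == b
    assert a.tau > 0 and a.sigma > 0


def test_seed_chain_centers_on_observed_ratios():
    reg = make_registry({"A": {"A1": 1e6}, "B": {"B1": 1e6}})
    r = 0.01  # both counties share harvest/area ratio r
    ds = make_dataset(reg, [("A1", 1000.0, 10), ("B1", 2000.0, 20)])
    omegas = [seed_chain(ds, ModelSpec(), np.random.default_rng(s)).omega
              for s in range(300)]
    assert np.mean(omegas) == pytest.approx(np.log(r), abs=0.2)
    assert np.std(omegas) == pytest.approx(1.0, abs=0.2)


def test_seed_chain_zero_harvest_hmp_uses_neutral_fallback():
    reg = make_registry({"A": {"A1": 1e6, "A2": 1e6}})
    ds = make_dataset(reg, [("A1", 1000.0, 12), ("A2", 1000.0, 0)])
    chis = np.array([seed_chain(ds, ModelSpec(), np.random.default_rng(s)).chi["A2"]
                     for s in range(300)])
    # fallback is Normal(0, 0.5)
    assert abs(chis.mean()) < 0.15
    assert 0.4 <= chis.std() <= 0.65


# ---------------------------------------------------------------- fitting

def test_noncentered_density_matches_centered_up_to_constant():
    ds = small_dataset()
    pr = default_priors()
    idx = IndexedData.from_dataset(ds)
    spec = ModelSpec.from_name("magp")
    m_bar = {h: 250.0 for h in ds.registry.hmps}
    f = make_harvest_logp_grad(idx, spec, pr, m_bar)
    lay = _Layout(spec, idx.n_counties, idx.n_hmps)
    rng = np.random.default_rng(5)
    diffs = []
    for _ in range(5):
        q = rng.normal(0, 0.4, lay.dim)
        q[0] -= 5.0
        lp_internal, _ = f(q)
        omega, logtau, logsigma, upsilon, gamma, phi, lamstar, chistar = lay.unpack(q)
        tau, sigma = np.exp(logtau), np.exp(logsigma)
        params = HarvestParams(
            omega=float(omega), tau=float(tau), sigma=float(sigma),
            lam={c: float(tau * lamstar[i]) for i, c in enumerate(idx.counties)},
            chi={h: float(sigma * chistar[j]) for j, h in enumerate(idx.hmps)},
            upsilon=float(upsilon), gamma=float(gamma), phi=float(phi))
        centered = harvest_log_density(params, spec, ds, pr, m_bar)
        jac = (1 + idx.n_counties) * logtau + (1 + idx.n_hmps) * logsigma
        diffs.append(lp_internal - centered - jac)
    assert np.ptp(diffs) < 1e-8


def test_fit_requires_m_bar_only_with_phi():
    ds = small_dataset()
    with pytest.raises(ValueError, match="m_bar"):
        fit_harvest_model(ds, ModelSpec.from_name("mp"), default_priors(),
                          mcmc=McmcSettings(chains=1, iterations=40, warmup=20), seed=0)


def test_fit_deterministic_and_saves_loglik(tmp_path):
    ds = small_dataset()
    s = McmcSettings(chains=1, iterations=120, warmup=60, thin=2)
    a = fit_harvest_model(ds, ModelSpec.from_name("ma"), default_priors(), mcmc=s, seed=4)
    b = fit_harvest_model(ds, ModelSpec.from_name("ma"), default_priors(), mcmc=s, seed=4)
    assert np.array_equal(a.mu, b.mu)
    assert a.loglik.shape == (a.n_draws, len(ds))
    assert np.all(a.loglik <= 0.0) and np.all(np.exp(a.loglik) > 0)
    a.save(tmp_path / "post")
    back = HarvestPosterior.load(tmp_path / "post")
    assert back.spec == a.spec
    np.testing.assert_allclose(back.mu, a.mu)
    np.testing.assert_allclose(back.loglik, a.loglik, atol=1e-12)


def test_nested_density_reduces_exactly_at_gamma_phi_zero():
    """The full model's log density at gamma=phi=0 equals the M_a density."""
    ds = small_dataset()
    pr = default_priors()
    idx = IndexedData.from_dataset(ds)
    m_bar = {h: 250.0 for h in ds.registry.hmps}
    full = make_harvest_logp_grad(idx, ModelSpec.from_name("magp"), pr, m_bar)
    red = make_harvest_logp_grad(idx, ModelSpec.from_name("ma"), pr)
    lay_f = _Layout(ModelSpec.from_name("magp"), idx.n_counties, idx.n_hmps)
    rng = np.random.default_rng(6)
    for _ in range(5):
        q_red = rng.normal(0, 0.4, 4 + idx.n_counties + idx.n_hmps)
        q_red[0] -= 5.0
        q_full = np.concatenate([q_red[:4], [0.0, 0.0], q_red[4:]])
        assert lay_f.i_gamma == 4 and lay_f.i_phi == 5
        lp_f, _ = full(q_full)
        lp_r, _ = red(q_red)
        assert lp_f == pytest.approx(lp_r, abs=1e-10)


def test_nesting_point_mass_gamma_phi_reproduces_m_alpha():
    """M_agp with gamma and phi priors collapsed to ~0 behaves like M_a."""
    from huntstat.synthetic import TruthConfig, generate

    cfg = TruthConfig(n_counties=3, hmps_per_county=4, teams_per_hmp=20,
                      coverage=0.5, gamma=0.0, phi=0.0)
    ds = generate(cfg, seed=12).dataset
    pr = default_priors()
    pinned = pr.with_overrides(gamma=(0.0, 1e-3), phi=(0.0, 1e-3))
    s = McmcSettings(chains=1, iterations=1500, warmup=600, thin=1)
    m_bar = {h: 1000.0 for h in ds.registry.hmps}
    base_init = seed_chain(ds, ModelSpec.from_name("ma"), np.random.default_rng(12))
    full_init = HarvestParams(omega=base_init.omega, tau=base_init.tau,
                              sigma=base_init.sigma, lam=base_init.lam,
                              chi=base_init.chi, upsilon=base_init.upsilon,
                              gamma=0.0, phi=0.0)
    full = fit_harvest_model(ds, ModelSpec.from_name("magp"), pinned, m_bar=m_bar,
                             mcmc=s, seed=1, inits=[full_init])
    reduced = fit_harvest_model(ds, ModelSpec.from_name("ma"), pr, mcmc=s, seed=1,
                                inits=[base_init])
    assert abs(full.gamma.mean()) < 5e-3 and abs(full.phi.mean()) < 5e-3
    for name in ("omega", "upsilon"):
        x, y = getattr(full, name), getattr(reduced, name)
        se = np.sqrt(x.var() / 200 + y.var() / 200)  # conservative ESS guess
        assert abs(x.mean() - y.mean()) < 5 * se + 0.05
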
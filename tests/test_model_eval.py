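import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln, logsumexp

from huntstat import McmcSettings, compare_elpd, default_priors, ppm, psis_loo, split_reports
from huntstat.harvest_model import ModelSpec, fit_harvest_model
from huntstat.model_eval import LooResult, loo_with_refits, ppm_ratio_bins

from conftest import make_dataset, make_registry, make_samples_registry


# ---------------------------------------------------------------- splitting

def test_split_halves_deterministically():
    reg = make_registry({"A": {"A1": 1e6}})
    ds = make_dataset(reg, [("A1", 100.0 + i, i % 3) for i in range(10)])
    train, valid = split_reports(ds, 0.5, seed=3)
    assert (len(train), len(valid)) == (5, 5)
    train2, valid2 = split_reports(ds, 0.5, seed=3)
    assert [r.report_id for r in train.reports] == [r.report_id for r in train2.reports]
    ids = {r.report_id for r in train.reports} | {r.report_id for r in valid.reports}
    assert ids == {r.report_id for r in ds.reports}
    assert not ({r.report_id for r in train.reports}
                & {r.report_id for r in valid.reports})


def test_split_validates_inputs():
    reg = make_registry({"A": {"A1": 1e6}})
    ds = make_dataset(reg, [("A1", 10.0, 0)])
    with pytest.raises(ValueError):
        split_reports(ds, 0.5, seed=0)
    two = make_dataset(reg, [("A1", 10.0, 0), ("A1", 20.0, 1)])
    with pytest.raises(ValueError):
        split_reports(two, 1.0, seed=0)


# ---------------------------------------------------------------- PPM

def nation_samples(values):
    reg = make_registry({"A": {"A1": 1e6}})
    return make_samples_registry(values, reg)


def test_ppm_all_samples_at_observed():
    s = nation_samples(np.full(20_000, 5))
    res = ppm(s, "nation", None, 5)
    assert res.ppm == 1.0
    assert res.method == "empirical-mass"
    assert res.samples_at_observed == 20_000


def test_ppm_poisson_empirical_branch():
    rng = np.random.default_rng(11)
    s = nation_samples(rng.poisson(1.0, size=200_000))
    res = ppm(s, "nation", None, 0)
    assert res.method == "empirical-mass"
    assert res.ppm == pytest.approx(np.exp(-1.0), abs=0.005)


def test_ppm_switches_method_exactly_at_cutoff():
    values = np.concatenate([np.full(50, 3), np.arange(1000)])
    s = nation_samples(values)
    n_at3 = int(np.sum(values == 3))
    assert ppm(s, "nation", None, 3, cutoff=n_at3).method == "empirical-mass"
    assert ppm(s, "nation", None, 3, cutoff=n_at3 + 1).method == "jittered-kde"


def test_ppm_kde_branch_is_normalized_density():
    rng = np.random.default_rng(12)
    s = nation_samples(rng.poisson(30.0, size=5000))
    far = ppm(s, "nation", None, 200, cutoff=10_000)
    assert far.method == "jittered-kde"
    assert 0.0 <= far.ppm < 1e-4
    grid = [ppm(s, "nation", None, k, cutoff=10**9, seed=1).ppm for k in range(0, 100)]
    assert sum(grid) == pytest.approx(1.0, abs=0.02)


def test_ppm_rejects_bad_inputs():
    s = nation_samples(np.arange(10))
    with pytest.raises(ValueError):
        ppm(s, "nation", None, -1)
    with pytest.raises(ValueError):
        ppm(s, "galaxy", None, 1)


def test_ppm_ratio_bins():
    out = ppm_ratio_bins([0.01, 0.3, 1.0, 1.9, 5.0, 100.0])
    assert out == {"<0.05": 1, "0.05-0.5": 1, "0.5-2": 2, "2-20": 1, ">20": 1}


# ---------------------------------------------------------------- PSIS-LOO

def test_identical_draws_give_exact_pointwise_density():
    ll = np.tile(np.array([[-1.3, -0.2, -2.5]]), (400, 1))
    res = psis_loo(ll)
    np.testing.assert_allclose(res.pointwise, [-1.3, -0.2, -2.5], atol=1e-10)
    assert res.elpd == pytest.approx(-4.0)
    assert (res.pareto_k <= 0).all()


def test_pareto_k_invariant_to_per_report_constants(rng):
    ll = rng.normal(-2.0, 0.5, size=(500, 4))
    base = psis_loo(ll)
    shifted = psis_loo(ll + np.array([1.0, -3.0, 0.5, 2.0]))
    np.testing.assert_allclose(base.pareto_k, shifted.pareto_k, atol=1e-10)


def test_psis_loo_rejects_non_finite():
    ll = np.zeros((200, 3))
    ll[0, 0] = np.inf
    with pytest.raises(ValueError, match="non-finite"):
        psis_loo(ll)


def conjugate_poisson_toy(a=2.0, b=1.0, y=(1, 0, 2, 1, 3), n_draws=4000, seed=0):
    """Gamma(a, b) prior on a Poisson rate observed n times: exact LOO known."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    theta = rng.gamma(a + y.sum(), 1.0 / (b + y.size), size=n_draws)
    ll = stats.poisson.logpmf(y[None, :], theta[:, None])
    exact = []
    for i in range(y.size):
        r = a + y.sum() - y[i]
        p = (b + y.size - 1) / (b + y.size)
        k = y[i]
        exact.append(gammaln(k + r) - gammaln(r) - gammaln(k + 1)
                     + r * np.log(p) + k * np.log(1 - p))
    return ll, float(np.sum(exact))


def test_psis_loo_matches_conjugate_exact_loo():
    ll, exact = conjugate_poisson_toy()
    res = psis_loo(ll)
    assert abs(res.elpd - exact) < 0.1


def test_loo_penalizes_relative_to_in_sample_density():
    ll, _ = conjugate_poisson_toy()
    res = psis_loo(ll)
    in_sample = float(np.sum(logsumexp(ll, axis=0) - np.log(ll.shape[0])))
    assert res.elpd <= in_sample


# ---------------------------------------------------------------- refits

def tiny_dataset():
    reg = make_registry({"A": {"A1": 1e5, "A2": 1e5}})
    rng = np.random.default_rng(21)
    areas = rng.lognormal(5.0, 0.5, size=10)
    ks = rng.poisson(0.01 * areas)
    rows = [("A1" if i < 5 else "A2", float(a), int(k))
            for i, (a, k) in enumerate(zip(areas, ks))]
    return make_dataset(reg, rows)


def test_no_flagged_reports_short_circuits():
    ds = tiny_dataset()
    s = McmcSettings(chains=1, iterations=700, warmup=300, thin=1)
    post = fit_harvest_model(ds, ModelSpec.from_name("m0"), default_priors(),
                             mcmc=s, seed=2)
    base = psis_loo(post.loglik, report_ids=post.report_ids)
    res = loo_with_refits(ds, ModelSpec.from_name("m0"), default_priors(),
                          mcmc=s, seed=2, posterior=post,
                          k_threshold=max(base.pareto_k.max() + 0.1, 0.7))
    assert res.n_refit == 0
    np.testing.assert_array_equal(res.pointwise, base.pointwise)


def test_exhaustive_refits_agree_with_psis():
    """Forcing exact LOO for every report should track the PSIS estimate."""
    ds = tiny_dataset()
    s = McmcSettings(chains=1, iterations=900, warmup=300, thin=1)
    post = fit_harvest_model(ds, ModelSpec.from_name("m0"), default_priors(),
                             mcmc=s, seed=3)
    base = psis_loo(post.loglik, report_ids=post.report_ids)
    res = loo_with_refits(ds, ModelSpec.from_name("m0"), default_priors(),
                          mcmc=s, seed=3, posterior=post, k_threshold=-np.inf)
    assert res.n_refit == len(ds)
    ok = np.abs(res.pointwise - base.pointwise) < 0.3
    assert ok.mean() >= 0.9
    assert abs(res.elpd - base.elpd) < 1.0


# ---------------------------------------------------------------- validation

def test_validation_workflow_scores_held_out_harvest():
    from huntstat.area_model import fit_area_model
    from huntstat.model_eval import score_validation
    from huntstat.prediction import predict_unreported
    from huntstat.synthetic import TruthConfig, generate

    ds = generate(TruthConfig(n_counties=2, hmps_per_county=3, teams_per_hmp=15,
                              coverage=0.8), seed=9).dataset
    train, valid = split_reports(ds, 0.5, seed=1)
    s = McmcSettings(chains=1, iterations=500, warmup=250, thin=1)
    ap = fit_area_model(train, default_priors(), mcmc=s, seed=1)
    hp = fit_harvest_model(train, ModelSpec.from_name("ma"), default_priors(),
                           mcmc=s, seed=1)
    U_valid = {h: sum(r.area_ha for r in valid.reports_in_hmp(h))
               for h in ds.registry.hmps}
    pred = predict_unreported(ap, hp, train, Q=400, seed=1, U_override=U_valid)
    score = score_validation(pred, valid, seed=1)
    assert 0.0 <= score.national.ppm <= 1.0
    assert set(score.hmp) == set(ds.registry.hmps)
    assert set(score.county) == set(ds.registry.counties)
    # HMPs with no held-out area should put all mass near zero harvest
    for h, r in score.hmp.items():
        assert 0.0 <= r.ppm <= 1.0


# ---------------------------------------------------------------- comparison

def loo_from_pointwise(vals):
    vals = np.asarray(vals, dtype=float)
    return LooResult(elpd=float(vals.sum()), pointwise=vals,
                     pareto_k=np.zeros_like(vals),
                     report_ids=tuple(str(i) for i in range(vals.size)))


def test_compare_self_is_zero():
    r = loo_from_pointwise([-1.0, -2.0, -3.0])
    tab = compare_elpd({"m": r})
    assert tab.loc[0, "elpd_diff"] == 0.0
    assert tab.loc[0, "se_diff"] == 0.0


def test_compare_hand_computed_three_observations():
    a = loo_from_pointwise([-1.0, -2.0, -3.0])
    b = loo_from_pointwise([-1.5, -2.0, -4.0])
    tab = compare_elpd({"a": a, "b": b}).set_index("model")
    d = np.array([-0.5, 0.0, -1.0])
    assert tab.loc["b", "elpd_diff"] == pytest.approx(d.sum())
    assert tab.loc["b", "se_diff"] == pytest.approx(np.sqrt(3 * np.var(d, ddof=1)))
    assert tab.loc["a", "elpd_diff"] == 0.0
    # identical pointwise values -> zero difference
    tab2 = compare_elpd({"a": a, "c": loo_from_pointwise([-1.0, -2.0, -3.0])})
    assert (tab2["elpd_diff"] == 0.0).all()


def test_compare_requires_matching_report_sets():
    a = loo_from_pointwise([-1.0, -2.0])
    b = LooResult(elpd=-3.0, pointwise=np.array([-1.0, -2.0]),
                  pareto_k=np.zeros(2), report_ids=("x", "y"))
    with pytest.raises(ValueError, match="different report sets"):
        compare_elpd({"a": a, "b": b})
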
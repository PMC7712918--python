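"""Hierarchical harvest-rate models for team-level harvest counts.

Six nested model variants describe a team's harvest count K given its
hunting area A (ha):

* M0        - Poisson with HMP-level rate mu_kl (animals / ha / yr),
              log mu_kl = omega + lambda_l + chi_kl.
* M_a       - Gamma-Poisson mixture (negative binomial) with shape
              alpha_kl = exp(upsilon): team rates vary within an HMP.
* M_ag      - adds the rate-variability association,
              log alpha_kl = upsilon + gamma (chi_kl + lambda_l).
* M_p       - Poisson with a relative-area effect
              delta = (A / m̄_kl)^phi on the per-area rate.
* M_ap, M_agp - the combinations.

County effects lambda_l ~ Normal(0, tau) and HMP effects
chi_kl ~ Normal(0, sigma); tau and sigma carry Log-Normal priors.
Fitting uses HMC on the non-centered parameterization
(lambda = tau lambda*, chi = sigma chi*, primitives standard normal),
with over-dispersed chain initialization from observed county/HMP
harvest-per-area ratios.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .data_model import Dataset, IndexedData, Report
from .mcmc import (McmcSettings, check_interchain_logp_spread,
                   convergence_diagnostics, run_hmc)
from .priors import PriorConfig

MODEL_NAMES = {
    "m0": (False, False, False),
    "ma": (True, False, False),
    "mag": (True, True, False),
    "mp": (False, False, True),
    "map": (True, False, True),
    "magp": (True, True, True),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which structural features a harvest model includes."""

    include_alpha: bool = False
    include_gamma: bool = False
    include_phi: bool = False

    def __post_init__(self) -> None:
        if self.include_gamma and not self.include_alpha:
            raise ValueError("rate-variability association (gamma) requires "
                             "within-HMP variability (alpha)")

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            a, g, p = MODEL_NAMES[name.lower()]
        except KeyError:
            raise ValueError(f"unknown model {name!r}; choose from {sorted(MODEL_NAMES)}") from None
        return cls(include_alpha=a, include_gamma=g, include_phi=p)

    @property
    def name(self) -> str:
        for k, flags in MODEL_NAMES.items():
            if flags == (self.include_alpha, self.include_gamma, self.include_phi):
                return k
        raise AssertionError("unreachable")


def delta(area_ha: float, m_bar: float, phi: float) -> float:
    """Relative-area effect (A / m̄)^phi on a team's per-area harvest rate."""
    if not (area_ha > 0 and m_bar > 0):
        raise ValueError("area_ha and m_bar must be positive")
    return float((area_ha / m_bar) ** phi)


def poisson_loglik(report: Report, mu: float, delta_: float = 1.0) -> float:
    """Poisson log-pmf of the report's harvest at mean mu * A * delta."""
    if not (mu > 0 and delta_ > 0):
        raise ValueError("mu and delta must be positive")
    mean = mu * report.area_ha * delta_
    k = report.harvest
    return float(k * np.log(mean) - mean - gammaln(k + 1))


def gamma_poisson_loglik(report: Report, mu: float, alpha: float, delta_: float = 1.0) -> float:
    """Gamma-Poisson (negative binomial) log-pmf, mean mu*A*delta, shape alpha."""
    if not (mu > 0 and alpha > 0 and delta_ > 0):
        raise ValueError("mu, alpha and delta must be positive")
    m = mu * report.area_ha * delta_
    k = report.harvest
    return float(
        gammaln(k + alpha) - gammaln(alpha) - gammaln(k + 1)
        + alpha * (np.log(alpha) - np.log(alpha + m))
        + k * (np.log(m) - np.log(alpha + m))
    )


def ml_rate(reports) -> float:
    """Maximum-likelihood harvest rate: total harvest / total reported area."""
    reports = list(reports)
    if not reports:
        raise ValueError("ml_rate needs at least one report")
    total_area = sum(r.area_ha for r in reports)
    if not total_area > 0:
        raise ValueError("total reported area must be positive")
    return float(sum(r.harvest for r in reports) / total_area)


@dataclass(frozen=True)
class HarvestParams:
    """Centered harvest-model parameters for one draw (or an initialization)."""

    omega: float
    tau: float
    sigma: float
    lam: dict[str, float]   # county -> effect
    chi: dict[str, float]   # hmp -> effect
    upsilon: float = 0.0
    gamma: float = 0.0
    phi: float = 0.0

    def mu(self, hmp_id: str, county_id: str) -> float:
        return float(np.exp(self.chi[hmp_id] + self.lam[county_id] + self.omega))

    def alpha(self, hmp_id: str, county_id: str, spec: ModelSpec) -> float:
        if not spec.include_alpha:
            return np.inf
        g = self.gamma if spec.include_gamma else 0.0
        return float(np.exp(self.upsilon + g * (self.chi[hmp_id] + self.lam[county_id])))


def linear_predictors(params: HarvestParams, spec: ModelSpec,
                      hmp_id: str, county_id: str) -> tuple[float, float]:
    """(mu, alpha) for one HMP; alpha is the infinity sentinel without alpha."""
    if hmp_id not in params.chi or county_id not in params.lam:
        raise KeyError(f"unknown unit ({hmp_id!r}, {county_id!r})")
    return params.mu(hmp_id, county_id), params.alpha(hmp_id, county_id, spec)


def seed_chain(dataset: Dataset, spec: ModelSpec, rng: np.random.Generator) -> HarvestParams:
    """Over-dispersed chain initialization from observed harvest/area ratios.

    The nationwide intercept is seeded around the mean of county
    log-ratios, county effects around their county log-ratio residual,
    and HMP effects around their HMP log-ratio residual when the HMP has
    harvested at least one animal (Normal(0, 0.5) otherwise - the same
    fallback guards counties whose total harvest is zero, which training
    splits can create even after exclusions).  tau and sigma are seeded
    from Gamma(5, 5); upsilon, gamma, phi from standard normals.
    """
    idx = IndexedData.from_dataset(dataset)
    if idx.n_reports == 0:
        raise ValueError("cannot seed a chain for an empty dataset")
    K_county = np.bincount(idx.county_of_report, weights=idx.harvest, minlength=idx.n_counties)
    A_county = np.bincount(idx.county_of_report, weights=idx.area, minlength=idx.n_counties)
    K_hmp = np.bincount(idx.hmp_of_report, weights=idx.harvest, minlength=idx.n_hmps)
    A_hmp = np.bincount(idx.hmp_of_report, weights=idx.area, minlength=idx.n_hmps)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio_county = np.log(K_county / A_county)
        log_ratio_hmp = np.log(K_hmp / A_hmp)
    pos = np.isfinite(log_ratio_county)
    if not pos.any():
        raise ValueError("no county with positive harvest and reported area; "
                         "apply species exclusions first")
    omega0 = float(rng.normal(log_ratio_county[pos].mean(), 1.0))
    lam0 = np.where(pos, log_ratio_county - omega0, 0.0) + rng.normal(0.0, 0.5, idx.n_counties)
    resid_hmp = log_ratio_hmp - lam0[idx.county_of_hmp] - omega0
    chi0 = np.where(np.isfinite(resid_hmp), resid_hmp, 0.0) + rng.normal(0.0, 0.5, idx.n_hmps)
    return HarvestParams(
        omega=omega0,
        tau=float(rng.gamma(5.0, 1.0 / 5.0)),
        sigma=float(rng.gamma(5.0, 1.0 / 5.0)),
        lam={c: float(lam0[i]) for i, c in enumerate(idx.counties)},
        chi={h: float(chi0[j]) for j, h in enumerate(idx.hmps)},
        upsilon=float(rng.normal(0.0, 1.0)) if spec.include_alpha else 0.0,
        gamma=float(rng.normal(0.0, 1.0)) if spec.include_gamma else 0.0,
        phi=float(rng.normal(0.0, 1.0)) if spec.include_phi else 0.0,
    )


# ---------------------------------------------------------------------------
# unconstrained vectorization:
#   q = [omega, logtau, logsigma, (upsilon), (gamma), (phi), lam*(nc), chi*(nh)]
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Layout:
    spec: ModelSpec
    nc: int
    nh: int

    @property
    def i_upsilon(self) -> int | None:
        return 3 if self.spec.include_alpha else None

    @property
    def i_gamma(self) -> int | None:
        if not self.spec.include_gamma:
            return None
        return 4

    @property
    def i_phi(self) -> int | None:
        if not self.spec.include_phi:
            return None
        return 3 + int(self.spec.include_alpha) + int(self.spec.include_gamma)

    @property
    def n_scalars(self) -> int:
        return 3 + int(self.spec.include_alpha) + int(self.spec.include_gamma) \
            + int(self.spec.include_phi)

    @property
    def dim(self) -> int:
        return self.n_scalars + self.nc + self.nh

    def scalar_names(self) -> list[str]:
        names = ["omega", "tau", "sigma"]
        if self.spec.include_alpha:
            names.append("upsilon")
        if self.spec.include_gamma:
            names.append("gamma")
        if self.spec.include_phi:
            names.append("phi")
        return names

    def unpack(self, q: np.ndarray):
        omega, logtau, logsigma = q[0], q[1], q[2]
        upsilon = q[self.i_upsilon] if self.i_upsilon is not None else 0.0
        gamma = q[self.i_gamma] if self.i_gamma is not None else 0.0
        phi = q[self.i_phi] if self.i_phi is not None else 0.0
        lamstar = q[self.n_scalars:self.n_scalars + self.nc]
        chistar = q[self.n_scalars + self.nc:]
        return omega, logtau, logsigma, upsilon, gamma, phi, lamstar, chistar

    def pack(self, params: HarvestParams, counties, hmps) -> np.ndarray:
        q = np.zeros(self.dim)
        q[0] = params.omega
        q[1] = np.log(params.tau)
        q[2] = np.log(params.sigma)
        if self.i_upsilon is not None:
            q[self.i_upsilon] = params.upsilon
        if self.i_gamma is not None:
            q[self.i_gamma] = params.gamma
        if self.i_phi is not None:
            q[self.i_phi] = params.phi
        q[self.n_scalars:self.n_scalars + self.nc] = \
            np.array([params.lam[c] for c in counties]) / params.tau
        q[self.n_scalars + self.nc:] = \
            np.array([params.chi[h] for h in hmps]) / params.sigma
        return q


def _nb_loglik_and_grads(K, m, a):
    """Vectorized NB log-pmf plus d/dlog(mean) and d/dlog(shape)."""
    ll = (gammaln(K + a) - gammaln(a) - gammaln(K + 1)
          + a * (np.log(a) - np.log(a + m)) + K * (np.log(m) - np.log(a + m)))
    g_m = K - m * (K + a) / (a + m)
    g_a = a * (digamma(K + a) - digamma(a) + np.log(a) - np.log(a + m)
               + 1.0 - (K + a) / (a + m))
    return ll, g_m, g_a


def make_harvest_logp_grad(idx: IndexedData, spec: ModelSpec, priors: PriorConfig,
                           m_bar: dict[str, float] | None = None):
    """logp_and_grad(q) for the unconstrained harvest-model vector."""
    lay = _Layout(spec, idx.n_counties, idx.n_hmps)
    jr, lr, lc = idx.hmp_of_report, idx.county_of_report, idx.county_of_hmp
    K = idx.harvest.astype(float)
    logA = np.log(idx.area)
    if spec.include_phi:
        if m_bar is None:
            raise ValueError("m_bar (typical HMP areas) is required when include_phi")
        log_mbar = np.array([np.log(m_bar[h]) for h in idx.hmps])
        rel_area = logA - log_mbar[jr]
    else:
        rel_area = np.zeros_like(logA)
    const = float(-np.sum(gammaln(K + 1)))

    p_om, p_tau, p_sig = priors["omega"], priors["tau"], priors["sigma"]
    p_ups, p_gam, p_phi = priors["upsilon"], priors["gamma"], priors["phi"]

    def logp_grad(q: np.ndarray) -> tuple[float, np.ndarray]:
        # non-finite values at extreme exploratory points surface as
        # rejected divergences in the sampler
        with np.errstate(all="ignore"):
            return _logp_grad(q)

    def _logp_grad(q: np.ndarray) -> tuple[float, np.ndarray]:
        omega, logtau, logsigma, upsilon, gamma, phi, lamstar, chistar = lay.unpack(q)
        tau, sigma = np.exp(logtau), np.exp(logsigma)
        lam, chi = tau * lamstar, sigma * chistar
        eta = chi + lam[lc]                       # (nh,) log mu minus omega
        logmean = omega + eta[jr] + logA + phi * rel_area

        if spec.include_alpha:
            logalpha = upsilon + gamma * eta
            a_r = np.exp(logalpha[jr])
            m_r = np.exp(logmean)
            ll_r, g_m, g_a = _nb_loglik_and_grads(K, m_r, a_r)
            lp = float(np.sum(ll_r))
        else:
            m_r = np.exp(logmean)
            lp = float(np.sum(K * logmean - m_r)) + const
            g_m = K - m_r
            g_a = np.zeros_like(g_m)

        # primitives and top-level priors
        lp -= 0.5 * (lamstar @ lamstar + chistar @ chistar)
        lp -= 0.5 * ((omega - p_om.location) / p_om.scale) ** 2
        lp -= 0.5 * ((logtau - p_tau.location) / p_tau.scale) ** 2
        lp -= 0.5 * ((logsigma - p_sig.location) / p_sig.scale) ** 2
        if spec.include_alpha:
            lp -= 0.5 * ((upsilon - p_ups.location) / p_ups.scale) ** 2
        if spec.include_gamma:
            lp -= 0.5 * ((gamma - p_gam.location) / p_gam.scale) ** 2
        if spec.include_phi:
            lp -= 0.5 * ((phi - p_phi.location) / p_phi.scale) ** 2

        # chain rule into effects
        g_eta_hmp = np.bincount(jr, weights=g_m, minlength=lay.nh)
        if spec.include_alpha:
            h_hmp = np.bincount(jr, weights=g_a, minlength=lay.nh)
            g_eta_hmp = g_eta_hmp + gamma * h_hmp
        g_eta_county = np.bincount(lc, weights=g_eta_hmp, minlength=lay.nc)

        grad = np.empty_like(q)
        grad[0] = float(np.sum(g_m)) - (omega - p_om.location) / p_om.scale ** 2
        dlam = g_eta_county
        dchi = g_eta_hmp
        grad[1] = float(lam @ dlam) - (logtau - p_tau.location) / p_tau.scale ** 2
        grad[2] = float(chi @ dchi) - (logsigma - p_sig.location) / p_sig.scale ** 2
        if lay.i_upsilon is not None:
            grad[lay.i_upsilon] = float(np.sum(g_a)) \
                - (upsilon - p_ups.location) / p_ups.scale ** 2
        if lay.i_gamma is not None:
            h_hmp_eta = float(eta @ np.bincount(jr, weights=g_a, minlength=lay.nh))
            grad[lay.i_gamma] = h_hmp_eta - (gamma - p_gam.location) / p_gam.scale ** 2
        if lay.i_phi is not None:
            grad[lay.i_phi] = float(np.sum(g_m * rel_area)) \
                - (phi - p_phi.location) / p_phi.scale ** 2
        grad[lay.n_scalars:lay.n_scalars + lay.nc] = tau * dlam - lamstar
        grad[lay.n_scalars + lay.nc:] = sigma * dchi - chistar
        return lp, grad

    return logp_grad


def harvest_log_density(params: HarvestParams, spec: ModelSpec, dataset: Dataset,
                        priors: PriorConfig, m_bar: dict[str, float] | None = None) -> float:
    """Joint log posterior at centered parameters, up to a constant.

    Independent of the sampler's vectorized path; used to verify that the
    non-centered computation matches the centered hierarchy exactly.
    """
    from scipy import stats

    lp = 0.0
    for r in dataset.reports:
        mu, alpha = linear_predictors(params, spec, r.hmp_id, r.county_id)
        d = delta(r.area_ha, m_bar[r.hmp_id], params.phi) if spec.include_phi else 1.0
        if spec.include_alpha:
            lp += gamma_poisson_loglik(r, mu, alpha, d)
        else:
            lp += poisson_loglik(r, mu, d)
    for c in dataset.registry.counties:
        lp += stats.norm.logpdf(params.lam[c], 0.0, params.tau)
    for h in dataset.registry.hmps:
        lp += stats.norm.logpdf(params.chi[h], 0.0, params.sigma)
    lp += stats.norm.logpdf(params.omega, priors["omega"].location, priors["omega"].scale)
    lp += stats.lognorm.logpdf(params.tau, s=priors["tau"].scale,
                               scale=np.exp(priors["tau"].location))
    lp += stats.lognorm.logpdf(params.sigma, s=priors["sigma"].scale,
                               scale=np.exp(priors["sigma"].location))
    if spec.include_alpha:
        lp += stats.norm.logpdf(params.upsilon, priors["upsilon"].location,
                                priors["upsilon"].scale)
    if spec.include_gamma:
        lp += stats.norm.logpdf(params.gamma, priors["gamma"].location, priors["gamma"].scale)
    if spec.include_phi:
        lp += stats.norm.logpdf(params.phi, priors["phi"].location, priors["phi"].scale)
    return float(lp)


@dataclass
class HarvestPosterior:
    """Pooled, thinned draws of one harvest model plus derived quantities.

    ``mu`` and ``alpha`` are (n_draws, n_hmps); ``alpha`` is +inf for
    models without within-HMP variability.  ``loglik`` is the per-draw,
    per-report pointwise log-likelihood matrix used by LOO-CV.
    """

    spec: ModelSpec
    counties: tuple[str, ...]
    hmps: tuple[str, ...]
    report_ids: tuple[str, ...]
    omega: np.ndarray
    tau: np.ndarray
    sigma: np.ndarray
    upsilon: np.ndarray
    gamma: np.ndarray
    phi: np.ndarray
    lam: np.ndarray      # (n_draws, n_counties)
    chi: np.ndarray      # (n_draws, n_hmps)
    mu: np.ndarray       # (n_draws, n_hmps)
    alpha: np.ndarray    # (n_draws, n_hmps)
    loglik: np.ndarray   # (n_draws, n_reports)
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)
    n_chains: int = 1
    converged: bool = True
    n_divergences: int = 0

    @property
    def n_draws(self) -> int:
        return self.omega.shape[0]

    def hmp_index(self, hmp_id: str) -> int:
        try:
            return self.hmps.index(hmp_id)
        except ValueError:
            raise KeyError(f"unknown HMP {hmp_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        cols = {"omega": self.omega, "tau": self.tau, "sigma": self.sigma,
                "upsilon": self.upsilon, "gamma": self.gamma, "phi": self.phi}
        for i, c in enumerate(self.counties):
            cols[f"lam[{c}]"] = self.lam[:, i]
        for i, h in enumerate(self.hmps):
            cols[f"chi[{h}]"] = self.chi[:, i]
            cols[f"mu[{h}]"] = self.mu[:, i]
            cols[f"alpha[{h}]"] = self.alpha[:, i]
        return pd.DataFrame(cols)

    def save(self, prefix) -> None:
        """Write ``<prefix>.csv`` (draws), ``<prefix>_loglik.csv``, ``<prefix>.json``."""
        prefix = str(prefix)
        self.to_frame().to_csv(prefix + ".csv", index=False)
        pd.DataFrame(self.loglik, columns=list(self.report_ids)).to_csv(
            prefix + "_loglik.csv", index=False)
        with open(prefix + ".json", "w") as fh:
            json.dump({"model": self.spec.name, "counties": list(self.counties),
                       "hmps": list(self.hmps), "n_chains": self.n_chains}, fh)

    @classmethod
    def load(cls, prefix) -> "HarvestPosterior":
        prefix = str(prefix)
        with open(prefix + ".json") as fh:
            meta = json.load(fh)
        spec = ModelSpec.from_name(meta["model"])
        df = pd.read_csv(prefix + ".csv")
        ll = pd.read_csv(prefix + "_loglik.csv")
        counties = tuple(meta["counties"])
        hmps = tuple(meta["hmps"])
        return cls(
            spec=spec, counties=counties, hmps=hmps,
            report_ids=tuple(ll.columns),
            omega=df["omega"].to_numpy(), tau=df["tau"].to_numpy(),
            sigma=df["sigma"].to_numpy(), upsilon=df["upsilon"].to_numpy(),
            gamma=df["gamma"].to_numpy(), phi=df["phi"].to_numpy(),
            lam=df[[f"lam[{c}]" for c in counties]].to_numpy(),
            chi=df[[f"chi[{h}]" for h in hmps]].to_numpy(),
            mu=df[[f"mu[{h}]" for h in hmps]].to_numpy(),
            alpha=df[[f"alpha[{h}]" for h in hmps]].to_numpy(),
            loglik=ll.to_numpy(),
            n_chains=meta.get("n_chains", 1),
        )


def pointwise_loglik(idx: IndexedData, spec: ModelSpec, mu: np.ndarray, alpha: np.ndarray,
                     phi: np.ndarray, m_bar: dict[str, float] | None) -> np.ndarray:
    """(n_draws, n_reports) log-likelihood matrix from derived draws."""
    jr = idx.hmp_of_report
    K = idx.harvest.astype(float)[None, :]
    logA = np.log(idx.area)
    if spec.include_phi:
        log_mbar = np.array([np.log(m_bar[h]) for h in idx.hmps])
        rel = (logA - log_mbar[jr])[None, :]
    else:
        rel = 0.0
    logmean = np.log(mu[:, jr]) + logA[None, :] + phi[:, None] * rel
    m = np.exp(logmean)
    if spec.include_alpha:
        a = alpha[:, jr]
        ll, _, _ = _nb_loglik_and_grads(K, m, a)
    else:
        ll = K * logmean - m - gammaln(K + 1)
    return ll


def fit_harvest_model(dataset: Dataset, spec: ModelSpec, priors: PriorConfig,
                      m_bar: dict[str, float] | None = None,
                      mcmc: McmcSettings | None = None, seed: int = 0,
                      inits: list[HarvestParams] | None = None) -> HarvestPosterior:
    """Fit one harvest model by HMC with over-dispersed seeding.

    ``m_bar`` (typical team area per HMP, from the area posterior) is
    required iff the model includes the relative-area effect.  Emits a
    warning if split-R-hat of any top-level parameter exceeds 1.05 or the
    chains' mean log posteriors are widely spread (stuck chain; reseed).
    ``inits`` replaces the default per-chain initialization draws, e.g.
    to reseed a stuck chain by hand.
    """
    if len(dataset) == 0:
        raise ValueError("cannot fit a harvest model to an empty dataset")
    if spec.include_phi and m_bar is None:
        raise ValueError("m_bar is required for models including the area effect")
    idx = IndexedData.from_dataset(dataset)
    mcmc = mcmc or McmcSettings()
    lay = _Layout(spec, idx.n_counties, idx.n_hmps)
    logp_grad = make_harvest_logp_grad(idx, spec, priors, m_bar)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4A57]))
    if inits is None:
        inits = [seed_chain(dataset, spec, rng) for _ in range(mcmc.chains)]
    init_vectors = [lay.pack(p, idx.counties, idx.hmps) for p in inits]
    res = run_hmc(logp_grad, init_vectors, mcmc, seed)
    check_interchain_logp_spread(res.logp)

    names = lay.scalar_names()
    diag = convergence_diagnostics(res.draws, names, select=list(range(lay.n_scalars)))
    converged = all(d["rhat"] <= 1.05 for d in diag.values())
    if not converged:
        worst = max(diag, key=lambda k: diag[k]["rhat"])
        warnings.warn(
            f"harvest model {spec.name}: split-R-hat {diag[worst]['rhat']:.3f} for {worst} "
            "exceeds 1.05; increase iterations or reseed", stacklevel=2)

    pooled = res.pooled
    omega = pooled[:, 0]
    tau = np.exp(pooled[:, 1])
    sigma = np.exp(pooled[:, 2])
    n = pooled.shape[0]
    upsilon = pooled[:, lay.i_upsilon] if lay.i_upsilon is not None else np.zeros(n)
    gam = pooled[:, lay.i_gamma] if lay.i_gamma is not None else np.zeros(n)
    phi = pooled[:, lay.i_phi] if lay.i_phi is not None else np.zeros(n)
    lam = tau[:, None] * pooled[:, lay.n_scalars:lay.n_scalars + idx.n_counties]
    chi = sigma[:, None] * pooled[:, lay.n_scalars + idx.n_counties:]
    eta = chi + lam[:, idx.county_of_hmp]
    mu = np.exp(omega[:, None] + eta)
    if spec.include_alpha:
        alpha = np.exp(upsilon[:, None] + (gam[:, None] if spec.include_gamma else 0.0) * eta)
    else:
        alpha = np.full_like(mu, np.inf)
    ll = pointwise_loglik(idx, spec, mu, alpha, phi, m_bar)

    return HarvestPosterior(
        spec=spec, counties=idx.counties, hmps=idx.hmps,
        report_ids=tuple(r.report_id for r in dataset.reports),
        omega=omega, tau=tau, sigma=sigma, upsilon=upsilon, gamma=gam, phi=phi,
        lam=lam, chi=chi, mu=mu, alpha=alpha, loglik=ll,
        diagnostics=diag, n_chains=mcmc.chains, converged=converged,
        n_divergences=int(res.divergences.sum()),
    )
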
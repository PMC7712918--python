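"""Hierarchical log-normal model of hunting-team areas.

A team's reported area A (ha) in HMP k of county l is modelled as

    A ~ Log-Normal(log m_kl, s_l),     m_kl = exp(W + L_l + C_kl),
    s_l = exp(u + v_l),

with county effects L_l ~ Normal(0, T), HMP effects C_kl ~ Normal(0, t)
and county effects on the within-HMP log-area spread v_l ~ Normal(0, z).
The scale parameters T, t, z carry Log-Normal priors, W and u Normal
priors.  Fitting uses HMC on the non-centered parameterization with the
positive parameters on the log scale.

The per-HMP typical area m̄_kl (posterior median of m_kl, pooled over
chains) is computed once here and passed to every harvest model that
includes the relative-area effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Dataset, IndexedData
from .mcmc import McmcSettings, convergence_diagnostics, run_hmc
from .priors import PriorConfig

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class AreaParams:
    """Centered area-model parameters for one posterior draw (or truth)."""

    W: float
    T_sd: float
    t_sd: float
    u: float
    z: float
    L: dict[str, float]   # county -> effect
    C: dict[str, float]   # hmp -> effect
    v: dict[str, float]   # county -> effect on log spread

    def m(self, hmp_id: str, county_id: str) -> float:
        return float(np.exp(self.W + self.L[county_id] + self.C[hmp_id]))

    def s(self, county_id: str) -> float:
        return float(np.exp(self.u + self.v[county_id]))


@dataclass
class AreaPosterior:
    """Pooled, thinned posterior draws of the area model.

    ``m`` has one column per HMP (sorted registry order), ``s`` one per
    county.  ``diagnostics`` holds split-R-hat / bulk-ESS for the five
    top-level parameters.
    """

    counties: tuple[str, ...]
    hmps: tuple[str, ...]
    W: np.ndarray        # (n_draws,)
    T_sd: np.ndarray
    t_sd: np.ndarray
    u: np.ndarray
    z: np.ndarray
    L: np.ndarray        # (n_draws, n_counties)
    C: np.ndarray        # (n_draws, n_hmps)
    v: np.ndarray        # (n_draws, n_counties)
    m: np.ndarray        # (n_draws, n_hmps)
    s: np.ndarray        # (n_draws, n_counties)
    diagnostics: dict[str, dict[str, float]]
    n_chains: int = 1
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return self.W.shape[0]

    def hmp_index(self, hmp_id: str) -> int:
        try:
            return self.hmps.index(hmp_id)
        except ValueError:
            raise KeyError(f"unknown HMP {hmp_id!r}") from None

    def county_index(self, county_id: str) -> int:
        try:
            return self.counties.index(county_id)
        except ValueError:
            raise KeyError(f"unknown county {county_id!r}") from None

    def m_bar(self) -> dict[str, float]:
        """Posterior median of m_kl per HMP, pooled over chains."""
        med = np.median(self.m, axis=0)
        return {h: float(med[i]) for i, h in enumerate(self.hmps)}

    def to_frame(self) -> pd.DataFrame:
        cols = {"W": self.W, "T_sd": self.T_sd, "t_sd": self.t_sd, "u": self.u, "z": self.z}
        for i, c in enumerate(self.counties):
            cols[f"L[{c}]"] = self.L[:, i]
            cols[f"v[{c}]"] = self.v[:, i]
            cols[f"s[{c}]"] = self.s[:, i]
        for i, h in enumerate(self.hmps):
            cols[f"C[{h}]"] = self.C[:, i]
            cols[f"m[{h}]"] = self.m[:, i]
        return pd.DataFrame(cols)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "AreaPosterior":
        df = pd.read_csv(path)
        counties = tuple(c[2:-1] for c in df.columns if c.startswith("L["))
        hmps = tuple(c[2:-1] for c in df.columns if c.startswith("C["))
        return cls(
            counties=counties,
            hmps=hmps,
            W=df["W"].to_numpy(),
            T_sd=df["T_sd"].to_numpy(),
            t_sd=df["t_sd"].to_numpy(),
            u=df["u"].to_numpy(),
            z=df["z"].to_numpy(),
            L=df[[f"L[{c}]" for c in counties]].to_numpy(),
            C=df[[f"C[{h}]" for h in hmps]].to_numpy(),
            v=df[[f"v[{c}]" for c in counties]].to_numpy(),
            m=df[[f"m[{h}]" for h in hmps]].to_numpy(),
            s=df[[f"s[{c}]" for c in counties]].to_numpy(),
            diagnostics={},
        )


def typical_area(posterior: AreaPosterior, hmp_id: str) -> float:
    """Posterior median of m_kl for one HMP (pooled chains)."""
    return float(np.median(posterior.m[:, posterior.hmp_index(hmp_id)]))


def area_log_density(params: AreaParams, dataset: Dataset, priors: PriorConfig) -> float:
    """Joint log posterior density at centered parameters, up to a constant.

    Log-Normal likelihood for every report plus the stated priors
    (Normal for W and u; Log-Normal for T, t, z; Normal random effects).
    Written with scipy's distributions rather than the sampler's internal
    vectorized form, so the two can cross-check each other.
    """
    lp = 0.0
    for r in dataset.reports:
        m = params.m(r.hmp_id, r.county_id)
        s = params.s(r.county_id)
        lp += stats.lognorm.logpdf(r.area_ha, s=s, scale=m)
    T, t, z = params.T_sd, params.t_sd, params.z
    for c in dataset.registry.counties:
        lp += stats.norm.logpdf(params.L[c], 0.0, T)
        lp += stats.norm.logpdf(params.v[c], 0.0, z)
    for h in dataset.registry.hmps:
        lp += stats.norm.logpdf(params.C[h], 0.0, t)
    lp += stats.norm.logpdf(params.W, priors["W"].location, priors["W"].scale)
    lp += stats.norm.logpdf(params.u, priors["u"].location, priors["u"].scale)
    lp += stats.lognorm.logpdf(T, s=priors["T"].scale, scale=np.exp(priors["T"].location))
    lp += stats.lognorm.logpdf(t, s=priors["t"].scale, scale=np.exp(priors["t"].location))
    lp += stats.lognorm.logpdf(z, s=priors["z"].scale, scale=np.exp(priors["z"].location))
    return float(lp)


# ---------------------------------------------------------------------------
# unconstrained vectorization:
#   q = [W, logT, logt, u, logz, Lstar(nc), vstar(nc), Cstar(nh)]
# ---------------------------------------------------------------------------

def _unpack(q: np.ndarray, nc: int, nh: int):
    W, logT, logt, u, logz = q[0], q[1], q[2], q[3], q[4]
    Lstar = q[5:5 + nc]
    vstar = q[5 + nc:5 + 2 * nc]
    Cstar = q[5 + 2 * nc:5 + 2 * nc + nh]
    return W, logT, logt, u, logz, Lstar, vstar, Cstar


def vector_to_params(q: np.ndarray, idx: IndexedData) -> AreaParams:
    nc, nh = idx.n_counties, idx.n_hmps
    W, logT, logt, u, logz, Lstar, vstar, Cstar = _unpack(q, nc, nh)
    T, t, z = np.exp(logT), np.exp(logt), np.exp(logz)
    return AreaParams(
        W=float(W), T_sd=float(T), t_sd=float(t), u=float(u), z=float(z),
        L={c: float(T * Lstar[i]) for i, c in enumerate(idx.counties)},
        C={h: float(t * Cstar[j]) for j, h in enumerate(idx.hmps)},
        v={c: float(z * vstar[i]) for i, c in enumerate(idx.counties)},
    )


def make_area_logp_grad(idx: IndexedData, priors: PriorConfig):
    """Return logp_and_grad(q) for the unconstrained area-model vector.

    The density includes the change-of-variable Jacobians for the
    log-scale and non-centered transforms, so HMC targets exactly the
    posterior of :func:`area_log_density`.
    """
    nc, nh = idx.n_counties, idx.n_hmps
    logA = np.log(idx.area)
    jr, lr, lc = idx.hmp_of_report, idx.county_of_report, idx.county_of_hmp
    const = float(-np.sum(logA) - idx.n_reports * _HALF_LOG_2PI)

    pW, pT, pt, pu, pz = (priors[k] for k in ("W", "T", "t", "u", "z"))

    def logp_grad(q: np.ndarray) -> tuple[float, np.ndarray]:
        # extreme exploratory points overflow to inf/nan; the sampler
        # treats the resulting non-finite density as a rejected divergence
        with np.errstate(all="ignore"):
            return _logp_grad(q)

    def _logp_grad(q: np.ndarray) -> tuple[float, np.ndarray]:
        W, logT, logt, u, logz, Lstar, vstar, Cstar = _unpack(q, nc, nh)
        T, t, z = np.exp(logT), np.exp(logt), np.exp(logz)
        L, C, v = T * Lstar, t * Cstar, z * vstar
        logm = W + L[lc] + C                  # (nh,)
        s = np.exp(u + v)                     # (nc,)
        s_r = s[lr]
        resid = logA - logm[jr]
        zsc = resid / s_r

        lp = const - np.sum(np.log(s_r)) - 0.5 * np.sum(zsc * zsc)
        # standard-normal primitives
        lp -= 0.5 * (Lstar @ Lstar + vstar @ vstar + Cstar @ Cstar)
        # top-level priors on the unconstrained scale
        lp -= 0.5 * ((W - pW.location) / pW.scale) ** 2
        lp -= 0.5 * ((logT - pT.location) / pT.scale) ** 2
        lp -= 0.5 * ((logt - pt.location) / pt.scale) ** 2
        lp -= 0.5 * ((u - pu.location) / pu.scale) ** 2
        lp -= 0.5 * ((logz - pz.location) / pz.scale) ** 2

        # gradient of the likelihood
        w_m = resid / (s_r * s_r)                       # d ll / d logm_(jr), per report
        g_m = np.bincount(jr, weights=w_m, minlength=nh)
        g_m_county = np.bincount(lc, weights=g_m, minlength=nc)
        dW = float(np.sum(w_m))
        dLstar = T * g_m_county
        dlogT = float(L @ g_m_county)
        dCstar = t * g_m
        dlogt = float(C @ g_m)

        w_s = zsc * zsc - 1.0                           # d ll / d (u + v_l), per report
        g_s = np.bincount(lr, weights=w_s, minlength=nc)
        du = float(np.sum(w_s))
        dvstar = z * g_s
        dlogz = float(v @ g_s)

        grad = np.empty_like(q)
        grad[0] = dW - (W - pW.location) / pW.scale ** 2
        grad[1] = dlogT - (logT - pT.location) / pT.scale ** 2
        grad[2] = dlogt - (logt - pt.location) / pt.scale ** 2
        grad[3] = du - (u - pu.location) / pu.scale ** 2
        grad[4] = dlogz - (logz - pz.location) / pz.scale ** 2
        grad[5:5 + nc] = dLstar - Lstar
        grad[5 + nc:5 + 2 * nc] = dvstar - vstar
        grad[5 + 2 * nc:] = dCstar - Cstar
        return float(lp), grad

    return logp_grad


def _default_inits(idx: IndexedData, n_chains: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Data-centered jittered inits (the sampler's default seeding)."""
    nc, nh = idx.n_counties, idx.n_hmps
    logA = np.log(idx.area)
    w0 = float(np.mean(logA))
    u0 = float(np.log(max(np.std(logA), 0.1)))
    inits = []
    for _ in range(n_chains):
        q = rng.uniform(-1.0, 1.0, size=5 + 2 * nc + nh)
        q[0] += w0
        q[3] += u0
        q[1] -= 1.0   # start scales modest to avoid wild first trajectories
        q[2] -= 1.0
        q[4] -= 1.0
        inits.append(q)
    return inits


def fit_area_model(dataset: Dataset, priors: PriorConfig,
                   mcmc: McmcSettings | None = None, seed: int = 0) -> AreaPosterior:
    """Fit the hierarchical log-normal area model by HMC.

    Requires at least one report per registry county (counties violating
    this must have been excluded upstream).  Emits a convergence warning
    when any top-level split-R-hat exceeds 1.01.
    """
    if len(dataset) == 0:
        raise ValueError("cannot fit the area model to an empty dataset")
    idx = IndexedData.from_dataset(dataset)
    counties_with_reports = set(idx.county_of_report.tolist())
    missing = [c for i, c in enumerate(idx.counties) if i not in counties_with_reports]
    if missing:
        raise ValueError(f"counties without reports must be excluded upstream: {missing}")

    mcmc = mcmc or McmcSettings()
    logp_grad = make_area_logp_grad(idx, priors)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0A12EA]))
    inits = _default_inits(idx, mcmc.chains, rng)
    res = run_hmc(logp_grad, inits, mcmc, seed)

    nc, nh = idx.n_counties, idx.n_hmps
    names = ["W", "T_sd", "t_sd", "u", "z"]
    diag = convergence_diagnostics(res.draws, names, select=[0, 1, 2, 3, 4])
    converged = all(d["rhat"] <= 1.01 for d in diag.values())
    if not converged:
        worst = max(diag, key=lambda k: diag[k]["rhat"])
        warnings.warn(
            f"area model: split-R-hat {diag[worst]['rhat']:.3f} for {worst} exceeds 1.01; "
            "increase iterations or warmup", stacklevel=2)

    pooled = res.pooled
    W = pooled[:, 0]
    T = np.exp(pooled[:, 1])
    t = np.exp(pooled[:, 2])
    u = pooled[:, 3]
    z = np.exp(pooled[:, 4])
    L = T[:, None] * pooled[:, 5:5 + nc]
    v = z[:, None] * pooled[:, 5 + nc:5 + 2 * nc]
    C = t[:, None] * pooled[:, 5 + 2 * nc:]
    m = np.exp(W[:, None] + L[:, idx.county_of_hmp] + C)
    s = np.exp(u[:, None] + v)
    return AreaPosterior(
        counties=idx.counties, hmps=idx.hmps,
        W=W, T_sd=T, t_sd=t, u=u, z=z, L=L, C=C, v=v, m=m, s=s,
        diagnostics=diag, n_chains=mcmc.chains, converged=converged,
    )
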
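"""Synthetic registries, ground-truth parameters and report tables.

The generator draws data from exactly the generative structure the
models assume: log-normal team areas with county/HMP random effects and
county-specific within-HMP spread, and Gamma-Poisson team harvests with
HMP/county random effects on the log rate, optional rate-variability
association (gamma) and optional power effect of relative team area on
the per-area rate (phi).  Every team - reporting or not - is retained in
a truth table, and each HMP's huntable area is the sum of its generated
team areas, so the true unreported harvest is known exactly and
predictive calibration can be measured.

Reporting is independent of harvest by construction (each team reports
with probability ``coverage``); an optional ``reporting_bias`` knob
exists strictly for robustness experiments and defaults to off.

The default scenario (4 counties x 6 HMPs x 25 teams, coverage 0.3) is
large enough for the top-level parameters to be identifiable yet small
enough for minutes-scale MCMC.  Default parameter values sit at the
spread of the reference analysis' area posteriors (T=0.83, t=0.42,
z=0.22) and at plausible mid-range harvest settings (see docs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .area_model import AreaParams
from .data_model import Dataset, RegionRegistry, Report
from .harvest_model import HarvestParams, ModelSpec


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth scenario for the generator; defaults are the study conditions."""

    n_counties: int = 4
    hmps_per_county: int = 6
    teams_per_hmp: int = 25
    coverage: float = 0.3
    # area model truth
    W: float = 7.0
    T_sd: float = 0.83
    t_sd: float = 0.42
    u: float = -0.7
    z: float = 0.22
    # harvest model truth (upsilon=None means no within-HMP variability, alpha -> inf)
    omega: float = -6.2
    tau: float = 0.5
    sigma: float = 0.4
    upsilon: float | None = -0.5
    gamma: float = 0.5
    phi: float = -0.3
    reporting_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must be in (0, 1]")
        for name in ("T_sd", "t_sd", "z", "tau", "sigma"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_counties, self.hmps_per_county, self.teams_per_hmp) < 1:
            raise ValueError("scenario dimensions must be >= 1")

    @property
    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            include_alpha=self.upsilon is not None,
            include_gamma=self.upsilon is not None and self.gamma != 0.0,
            include_phi=self.phi != 0.0,
        )


@dataclass
class SyntheticData:
    """A generated dataset plus the withheld full truth."""

    dataset: Dataset                       # reporting teams only
    teams: pd.DataFrame                    # every team: area, harvest, reported flag
    area_truth: AreaParams
    harvest_truth: HarvestParams
    config: TruthConfig

    def true_unreported_harvest(self) -> dict[str, int]:
        """Harvest actually taken by the non-reporting teams, per HMP."""
        t = self.teams[~self.teams["reported"]]
        out = {h: 0 for h in self.dataset.registry.hmps}
        for h, k in t.groupby("hmp_id")["harvest"].sum().items():
            out[h] = int(k)
        return out

    def true_national_unreported(self) -> int:
        return int(sum(self.true_unreported_harvest().values()))


def _county_id(i: int) -> str:
    return f"c{i + 1:02d}"


def _hmp_id(i: int, j: int) -> str:
    return f"c{i + 1:02d}-h{j + 1:02d}"


def generate_truth(config: TruthConfig, seed: int | None = None
                   ) -> tuple[AreaParams, HarvestParams, RegionRegistry]:
    """Sample true effects and build a provisional registry.

    Huntable areas are set to teams_per_hmp times the expected team area
    (rounded up); :func:`generate_reports` replaces them with the exact
    sum of drawn team areas so that truth is known exactly.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7271]))
    counties = [_county_id(i) for i in range(config.n_counties)]
    hmps = {c: [_hmp_id(i, j) for j in range(config.hmps_per_county)]
            for i, c in enumerate(counties)}

    L = {c: float(rng.normal(0.0, config.T_sd)) for c in counties}
    v = {c: float(rng.normal(0.0, config.z)) for c in counties}
    C = {h: float(rng.normal(0.0, config.t_sd)) for c in counties for h in hmps[c]}
    area_truth = AreaParams(W=config.W, T_sd=config.T_sd, t_sd=config.t_sd,
                            u=config.u, z=config.z, L=L, C=C, v=v)

    lam = {c: float(rng.normal(0.0, config.tau)) for c in counties}
    chi = {h: float(rng.normal(0.0, config.sigma)) for c in counties for h in hmps[c]}
    harvest_truth = HarvestParams(
        omega=config.omega, tau=config.tau, sigma=config.sigma, lam=lam, chi=chi,
        upsilon=config.upsilon if config.upsilon is not None else 0.0,
        gamma=config.gamma, phi=config.phi,
    )

    county_of, huntable = {}, {}
    for c in counties:
        s_l = area_truth.s(c)
        for h in hmps[c]:
            county_of[h] = c
            mean_area = area_truth.m(h, c) * np.exp(0.5 * s_l * s_l)
            huntable[h] = float(np.ceil(config.teams_per_hmp * mean_area))
    registry = RegionRegistry(county_of=county_of, huntable_area=huntable)
    return area_truth, harvest_truth, registry


def generate_reports(area_truth: AreaParams, harvest_truth: HarvestParams,
                     registry: RegionRegistry, config: TruthConfig,
                     seed: int | None = None,
                     species_label: str = "synthetic") -> SyntheticData:
    """Draw all teams' areas and harvests; return reporting teams as a Dataset.

    Harvest follows the full mechanism: team rate theta ~ Gamma(shape
    alpha_kl, mean mu_kl * A * delta) and K ~ Poisson(theta); setting
    upsilon=None gives the Poisson limit (alpha -> inf), gamma=0 removes
    the rate-variability association, phi=0 the area effect.  The
    relative-area effect uses the true typical area m_kl.  The returned
    registry's huntable areas equal each HMP's summed team areas exactly.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x2E7041]))
    spec = config.model_spec
    rows = []
    county_of, huntable = {}, {}
    for h in registry.hmps:
        c = registry.county_of[h]
        m = area_truth.m(h, c)
        s = area_truth.s(c)
        mu = harvest_truth.mu(h, c)
        alpha = harvest_truth.alpha(h, c, spec)
        areas = rng.lognormal(np.log(m), s, size=config.teams_per_hmp)
        d = (areas / m) ** config.phi if spec.include_phi else np.ones_like(areas)
        mean = mu * areas * d
        if spec.include_alpha:
            theta = rng.gamma(alpha, mean / alpha)
        else:
            theta = mean
        K = rng.poisson(theta)
        if config.reporting_bias == 0.0:
            reported = rng.random(config.teams_per_hmp) < config.coverage
        else:
            logit = np.log(config.coverage / (1 - config.coverage)) \
                + config.reporting_bias * np.log1p(K)
            reported = rng.random(config.teams_per_hmp) < 1 / (1 + np.exp(-logit))
        county_of[h] = c
        huntable[h] = float(areas.sum())
        for t in range(config.teams_per_hmp):
            rows.append((f"{h}-t{t + 1:03d}", c, h, float(areas[t]), int(K[t]),
                         bool(reported[t])))
    teams = pd.DataFrame(
        rows, columns=["report_id", "county_id", "hmp_id", "area_ha", "harvest", "reported"])
    final_registry = RegionRegistry(county_of=county_of, huntable_area=huntable)
    reports = tuple(
        Report(report_id=r.report_id, county_id=r.county_id, hmp_id=r.hmp_id,
               area_ha=r.area_ha, harvest=r.harvest)
        for r in teams.itertuples() if r.reported
    )
    dataset = Dataset(reports=reports, registry=final_registry, species_label=species_label)
    return SyntheticData(dataset=dataset, teams=teams, area_truth=area_truth,
                         harvest_truth=harvest_truth, config=config)


def generate(config: TruthConfig, seed: int | None = None,
             species_label: str = "synthetic") -> SyntheticData:
    """Convenience: generate_truth followed by generate_reports."""
    area_truth, harvest_truth, registry = generate_truth(config, seed)
    return generate_reports(area_truth, harvest_truth, registry, config, seed,
                            species_label=species_label)


def recovery_experiment(config: TruthConfig, mcmc, seeds,
                        model: str | None = None, Q: int = 500,
                        ci: float = 0.95) -> pd.DataFrame:
    """Generate -> fit -> predict loop; one row per replicate.

    Records, per replicate, whether each top-level harvest parameter's
    central credible interval covers the truth, the posterior-predictive
    mean and interval of the national unreported harvest next to its
    true value, and the point-estimate national total for comparison.
    """
    from .area_model import fit_area_model
    from .harvest_model import fit_harvest_model
    from .point_estimate import estimate as point_estimate
    from .prediction import predict_unreported
    from .priors import default_priors

    spec = ModelSpec.from_name(model) if model else config.model_spec
    priors = default_priors()
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    truth_values = {"omega": config.omega, "tau": config.tau, "sigma": config.sigma,
                    "upsilon": config.upsilon, "gamma": config.gamma, "phi": config.phi}
    rows = []
    for seed in seeds:
        data = generate(config, seed)
        area_post = fit_area_model(data.dataset, priors, mcmc=mcmc, seed=seed)
        harvest_post = fit_harvest_model(
            data.dataset, spec, priors,
            m_bar=area_post.m_bar() if spec.include_phi else None,
            mcmc=mcmc, seed=seed)
        row: dict[str, float] = {"seed": seed}
        for name in ("omega", "tau", "sigma", "upsilon", "gamma", "phi"):
            use = {"upsilon": spec.include_alpha, "gamma": spec.include_gamma,
                   "phi": spec.include_phi}.get(name, True)
            if not use or truth_values[name] is None:
                continue
            draws = getattr(harvest_post, name)
            ql, qh = np.quantile(draws, [lo, hi])
            row[f"covered_{name}"] = bool(ql <= truth_values[name] <= qh)
        pred = predict_unreported(area_post, harvest_post, data.dataset, Q=Q, seed=seed)
        nat = pred.kappa_national
        truth_nat = data.true_national_unreported()
        row.update({
            "pred_mean": float(nat.mean()),
            "pred_lo": float(np.quantile(nat, lo, method="nearest")),
            "pred_hi": float(np.quantile(nat, hi, method="nearest")),
            "true_unreported": truth_nat,
            "covered_national": bool(
                np.quantile(nat, lo, method="nearest") <= truth_nat
                <= np.quantile(nat, hi, method="nearest")),
            "pe_national": point_estimate(data.dataset).national_total,
        })
        rows.append(row)
    return pd.DataFrame(rows)
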
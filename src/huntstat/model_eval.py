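"""Model comparison and validation.

Two complementary routes:

* Train/validation split - fit on a random half of the reports, predict
  the harvest on the area covered by the held-out half, and score each
  model by the posterior predictive mass (PPM) at the observed value.
  When fewer than ``cutoff`` predictive samples hit the observed value
  exactly, the PPM is estimated by jittered kernel density estimation
  (add uniform [-0.5, 0.5) jitter to the integer samples, fit a 1-D
  Gaussian KDE, evaluate at the observed integer), which is unbiased for
  discrete data.

* PSIS-LOO cross-validation - expected log pointwise predictive density
  (ELPD) from Pareto-smoothed importance sampling of the in-sample fit,
  with exact refits for reports whose Pareto shape diagnostic exceeds
  0.7.  ELPD differences between models are judged against 2 and 4
  standard errors of the pointwise differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import gaussian_kde

from .data_model import Dataset
from .harvest_model import (HarvestPosterior, ModelSpec, fit_harvest_model,
                            pointwise_loglik)
from .mcmc import McmcSettings
from .prediction import PredictiveSamples
from .priors import PriorConfig

PARETO_K_THRESHOLD = 0.7
PPM_CUTOFF = 10_000


def split_reports(dataset: Dataset, fraction: float = 0.5,
                  seed: int = 0) -> tuple[Dataset, Dataset]:
    """Random permutation split into disjoint train/validation datasets.

    The training set receives round(fraction * n) reports, so sizes are
    deterministic; both halves share the full registry.  Reproducible by
    seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least two reports to split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B117]))
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    train_ix = set(perm[:n_train].tolist())
    train = tuple(r for i, r in enumerate(dataset.reports) if i in train_ix)
    valid = tuple(r for i, r in enumerate(dataset.reports) if i not in train_ix)
    return (
        Dataset(reports=train, registry=dataset.registry, species_label=dataset.species_label),
        Dataset(reports=valid, registry=dataset.registry, species_label=dataset.species_label),
    )


@dataclass(frozen=True)
class PPMResult:
    level: str
    unit_id: str
    observed: int
    ppm: float
    method: str               # "empirical-mass" or "jittered-kde"
    samples_at_observed: int


def ppm(samples: PredictiveSamples, level: str, unit_id: str | None,
        observed: int, cutoff: int = PPM_CUTOFF, bw_method=None,
        seed: int = 0) -> PPMResult:
    """Posterior predictive mass at the observed harvest for one unit."""
    if observed < 0:
        raise ValueError("observed harvest must be >= 0")
    if level == "hmp":
        draws = samples.hmp_column(unit_id)
    elif level == "county":
        draws = samples.kappa_county[:, samples.counties.index(unit_id)]
    elif level == "nation":
        draws = samples.kappa_national
    else:
        raise ValueError(f"unknown level {level!r}")
    Q = draws.shape[0]
    if Q == 0:
        raise ValueError("no predictive samples")
    n_at = int(np.sum(draws == observed))
    if n_at >= cutoff:
        return PPMResult(level, unit_id or "total", observed, n_at / Q,
                         "empirical-mass", n_at)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x77B]))
    jittered = draws + rng.uniform(-0.5, 0.5, size=Q)
    kde = gaussian_kde(jittered, bw_method=bw_method)
    dens = float(kde(np.array([float(observed)]))[0])
    return PPMResult(level, unit_id or "total", observed, max(dens, 0.0),
                     "jittered-kde", n_at)


def ppm_ratio_bins(ratios, edges=(0.05, 0.5, 2.0, 20.0)) -> dict[str, int]:
    """Bin reduced-vs-full PPM ratios the way the validation figures report them."""
    ratios = np.asarray(list(ratios), dtype=float)
    labels = ["<0.05", "0.05-0.5", "0.5-2", "2-20", ">20"]
    counts = np.histogram(ratios, bins=[0.0, *edges, np.inf])[0]
    return dict(zip(labels, counts.tolist()))


@dataclass
class LooResult:
    elpd: float
    pointwise: np.ndarray          # (n_reports,)
    pareto_k: np.ndarray           # (n_reports,)
    report_ids: tuple[str, ...]
    n_refit: int = 0

    def __post_init__(self) -> None:
        assert np.isclose(self.elpd, float(np.sum(self.pointwise)))


def psis_loo(pointwise_loglik_matrix: np.ndarray,
             report_ids=None) -> LooResult:
    """PSIS-LOO ELPD from a (draws x reports) pointwise log-likelihood matrix.

    Importance ratios per report are 1/likelihood; their upper tail is
    smoothed by a fitted generalized Pareto (delegated to arviz), and the
    leave-one-out predictive density is the smoothed-weight average of
    the likelihood over draws.
    """
    import arviz as az

    ll = np.asarray(pointwise_loglik_matrix, dtype=float)
    if ll.ndim != 2:
        raise ValueError("expected a (draws, reports) matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    n_draws, n_reports = ll.shape
    if n_draws < 100:
        warnings.warn(f"only {n_draws} draws; PSIS-LOO may be unstable", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(-ll.T)       # (reports, draws) smoothed normalized log-weights
    lw = np.asarray(lw)
    k = np.asarray(k, dtype=float)
    # constant weights (e.g. all draws identical) are exact, not pathological
    degenerate = np.ptp(ll, axis=0) < 1e-12
    k[degenerate] = -np.inf
    lw[degenerate] = -np.log(n_draws)
    pointwise = logsumexp(lw + ll.T, axis=1)
    if report_ids is None:
        report_ids = tuple(str(i) for i in range(n_reports))
    return LooResult(
        elpd=float(np.sum(pointwise)), pointwise=pointwise, pareto_k=k,
        report_ids=tuple(report_ids),
    )


def _exact_lpd(post: HarvestPosterior, dataset: Dataset, left_out_index: int,
               m_bar: dict[str, float] | None) -> float:
    """Exact log predictive density of one held-out report under a refit."""
    from .data_model import IndexedData

    single = Dataset(
        reports=(dataset.reports[left_out_index],),
        registry=dataset.registry, species_label=dataset.species_label,
    )
    idx = IndexedData.from_dataset(single)
    ll = pointwise_loglik(idx, post.spec, post.mu, post.alpha, post.phi, m_bar)
    return float(logsumexp(ll[:, 0]) - np.log(ll.shape[0]))


def loo_with_refits(dataset: Dataset, spec: ModelSpec, priors: PriorConfig,
                    m_bar: dict[str, float] | None = None,
                    mcmc: McmcSettings | None = None, seed: int = 0,
                    k_threshold: float = PARETO_K_THRESHOLD,
                    posterior: HarvestPosterior | None = None) -> LooResult:
    """PSIS-LOO with exact refits for reports whose Pareto k exceeds threshold.

    ``posterior`` may supply an existing full-data fit; otherwise the
    model is fitted here.  For each flagged report the model is refitted
    on the remaining reports and the flagged pointwise value is replaced
    by the exact log predictive density averaged over refit draws.
    """
    if posterior is None:
        posterior = fit_harvest_model(dataset, spec, priors, m_bar=m_bar,
                                      mcmc=mcmc, seed=seed)
    base = psis_loo(posterior.loglik, report_ids=posterior.report_ids)
    flagged = np.nonzero(base.pareto_k > k_threshold)[0]
    if flagged.size == 0:
        return base
    pointwise = base.pointwise.copy()
    for offset, i in enumerate(flagged):
        reduced = Dataset(
            reports=tuple(r for j, r in enumerate(dataset.reports) if j != i),
            registry=dataset.registry, species_label=dataset.species_label,
        )
        refit = fit_harvest_model(reduced, spec, priors, m_bar=m_bar,
                                  mcmc=mcmc, seed=seed + 1000 + offset)
        pointwise[i] = _exact_lpd(refit, dataset, int(i), m_bar)
    return LooResult(
        elpd=float(np.sum(pointwise)), pointwise=pointwise,
        pareto_k=base.pareto_k, report_ids=base.report_ids,
        n_refit=int(flagged.size),
    )


def compare_elpd(results: dict[str, LooResult]) -> pd.DataFrame:
    """ELPD difference of each model vs the best, with SE of the difference.

    SE of a pairwise difference is sqrt(n * var(pointwise differences)).
    Flags mark differences beyond two and four SE.  All results must
    cover the identical report set.
    """
    if not results:
        raise ValueError("no LOO results to compare")
    ids = {name: r.report_ids for name, r in results.items()}
    ref_ids = next(iter(ids.values()))
    if any(v != ref_ids for v in ids.values()):
        raise ValueError("LOO results cover different report sets")
    best = max(results, key=lambda k: results[k].elpd)
    rows = []
    for name, r in sorted(results.items(), key=lambda kv: -kv[1].elpd):
        d = r.pointwise - results[best].pointwise
        n = d.size
        se = float(np.sqrt(n * np.var(d, ddof=1))) if name != best else 0.0
        diff = float(r.elpd - results[best].elpd)
        rows.append({
            "model": name, "elpd": r.elpd, "elpd_diff": diff, "se_diff": se,
            "beyond_2se": bool(diff < -2 * se) if name != best else False,
            "beyond_4se": bool(diff < -4 * se) if name != best else False,
            "n_refit": r.n_refit,
        })
    return pd.DataFrame(rows)


@dataclass
class ValidationScore:
    model: str
    national: PPMResult
    county: dict[str, PPMResult] = field(default_factory=dict)
    hmp: dict[str, PPMResult] = field(default_factory=dict)


def score_validation(samples: PredictiveSamples, validation: Dataset,
                     cutoff: int = PPM_CUTOFF, seed: int = 0) -> ValidationScore:
    """PPM of predicted harvest at the observed held-out harvest, per level.

    ``samples`` must have been generated with the unreported area set to
    the area covered by the validation reports (``U_override``).
    """
    obs_hmp = {h: sum(r.harvest for r in validation.reports_in_hmp(h))
               for h in validation.registry.hmps}
    obs_cty = {c: sum(r.harvest for r in validation.reports_in_county(c))
               for c in validation.registry.counties}
    obs_nat = sum(r.harvest for r in validation.reports)
    return ValidationScore(
        model=samples.model,
        national=ppm(samples, "nation", None, obs_nat, cutoff=cutoff, seed=seed),
        county={c: ppm(samples, "county", c, o, cutoff=cutoff, seed=seed)
                for c, o in obs_cty.items()},
        hmp={h: ppm(samples, "hmp", h, o, cutoff=cutoff, seed=seed)
             for h, o in obs_hmp.items()},
    )
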
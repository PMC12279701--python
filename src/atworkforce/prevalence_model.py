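"""Fourth-root-scale Bayesian mixed model for the prevalence of need.

Surveyed-country prevalences of need (pN) are strongly right-skewed; taking
the fourth root makes their distribution close to normal.  On that scale a
linear mixed-effects model relates prevalence to two country covariates —
median age (medAge, years) and the Human Development Index (HDI) — with
separate slopes per product domain and exchangeable domain random
intercepts:

    pN^(1/4) ~ medAge:domain + HDI:domain + (1 | domain)

Before fitting, a preliminary least-squares fit with the same fixed-effect
structure screens observations by Cook's distance and removes gross
influence outliers.  The mixed model is then sampled by MCMC (an affine-
invariant ensemble sampler) and its posterior predictive distribution is
used to estimate prevalence, with 95% intervals, for countries without
surveys.  Predicted summaries on the transformed scale are verified to be
non-negative (truncating and counting any that are not) before being raised
back to the fourth power.

Priors are weakly informative: N(0, 10^2) on fixed effects (covariates are
centred and scaled internally for sampler stability), half-Cauchy(1) on the
residual and intercept scales, and a non-centred parameterisation for the
domain intercepts, which are weakly identified with only five domains.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import arviz as az
import emcee
import numpy as np
import statsmodels.api as sm

from .domains import DOMAINS

TRANSFORM_EXPONENT = 0.25


@dataclass(frozen=True)
class CountryRecord:
    """Covariates and population structure of one country."""

    country_id: str
    population_total: float
    population_under18: float
    population_18plus: float
    median_age: float
    hdi: float
    surveyed: bool

    def __post_init__(self) -> None:
        if self.population_total <= 0:
            raise ValueError(f"{self.country_id}: population must be positive")
        if abs(self.population_under18 + self.population_18plus - self.population_total) > 1.0:
            raise ValueError(f"{self.country_id}: age split does not sum to total population")
        if not 10.0 < self.median_age < 60.0:
            raise ValueError(f"{self.country_id}: implausible median age {self.median_age}")
        if not 0.0 <= self.hdi <= 1.0:
            raise ValueError(f"{self.country_id}: HDI must be in [0, 1]")


@dataclass
class TransformedObservation:
    """One country-domain prevalence observation on the fourth-root scale."""

    country_id: str
    domain: str
    y: float
    median_age: float
    hdi: float
    influence: float = 0.0  # Cook's distance from the screening fit

    def __post_init__(self) -> None:
        if not 0.0 <= self.y <= 1.0:
            raise ValueError(f"{self.country_id}/{self.domain}: transformed prevalence outside [0, 1]")


@dataclass
class PrevalenceModelFit:
    """Posterior draws and diagnostics for the mixed prevalence model.

    Coefficient draws are on the natural covariate scale (per year of median
    age; per unit HDI) even though sampling uses standardised covariates.
    """

    domains: tuple[str, ...]
    intercepts: np.ndarray  # (n_draws, n_domains), natural scale
    slopes_medage: np.ndarray  # (n_draws, n_domains)
    slopes_hdi: np.ndarray  # (n_draws, n_domains)
    sigma: np.ndarray  # (n_draws,) residual sd on the transformed scale
    intercept_mu: np.ndarray  # (n_draws,) random-intercept mean
    intercept_tau: np.ndarray  # (n_draws,) random-intercept sd
    n_draws: int
    seed: int
    ess: dict[str, float]
    rhat: dict[str, float]
    converged: bool
    warnings: list[str] = field(default_factory=list)
    transform_exponent: float = TRANSFORM_EXPONENT

    def summary(self):
        """Posterior summary table: mean, 95% interval, ESS, R-hat."""
        import pandas as pd

        rows = []
        for name, draws in self._named_draws().items():
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(draws)),
                    "q2.5": float(lo),
                    "q97.5": float(hi),
                    "ess": self.ess.get(name, np.nan),
                    "rhat": self.rhat.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def _named_draws(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for j, d in enumerate(self.domains):
            out[f"intercept[{d}]"] = self.intercepts[:, j]
            out[f"medage[{d}]"] = self.slopes_medage[:, j]
            out[f"hdi[{d}]"] = self.slopes_hdi[:, j]
        out["sigma"] = self.sigma
        out["intercept_mu"] = self.intercept_mu
        out["intercept_tau"] = self.intercept_tau
        return out


@dataclass(frozen=True)
class PrevalencePrediction:
    """Predicted prevalence of need, natural scale, for one country-domain."""

    country_id: str
    domain: str
    p_hat: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0:
            raise ValueError(
                f"{self.country_id}/{self.domain}: invalid prediction interval"
            )


@dataclass
class PredictionResult:
    """Predictions plus the non-negativity verification report."""

    predictions: list[PrevalencePrediction]
    n_truncated_negative: int = 0
    n_clipped_above_one: int = 0

    def __iter__(self):
        return iter(self.predictions)

    def __len__(self):
        return len(self.predictions)


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative prior scales (on the standardised-covariate scale)."""

    coef_sd: float = 10.0
    sigma_scale: float = 1.0  # half-Cauchy scale on the residual sd
    tau_scale: float = 1.0  # half-Cauchy scale on the intercept sd


def transform_prevalence(p):
    """Fourth-root transform mapping prevalences to a near-normal scale."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("prevalence must lie in [0, 1]")
    out = arr**TRANSFORM_EXPONENT
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def inverse_transform(y):
    """Back-transform: fourth power, inverse of :func:`transform_prevalence`."""
    arr = np.asarray(y, dtype=float)
    out = arr**4
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def _design_matrix(
    obs: Sequence[TransformedObservation], domains: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Fixed-effect design: domain intercepts + domain-interacted slopes."""
    idx = {d: j for j, d in enumerate(domains)}
    n, k = len(obs), len(domains)
    X = np.zeros((n, 3 * k))
    y = np.empty(n)
    names = (
        [f"intercept[{d}]" for d in domains]
        + [f"medage[{d}]" for d in domains]
        + [f"hdi[{d}]" for d in domains]
    )
    for i, o in enumerate(obs):
        j = idx[o.domain]
        X[i, j] = 1.0
        X[i, k + j] = o.median_age
        X[i, 2 * k + j] = o.hdi
        y[i] = o.y
    return X, y, names


def screen_outliers(
    observations: Sequence[TransformedObservation],
    threshold: float = 0.5,
    max_flagged: int = 2,
) -> tuple[list[TransformedObservation], list[TransformedObservation]]:
    """Flag high-influence observations by Cook's distance.

    A preliminary ordinary-least-squares fit with the mixed model's fixed-
    effect structure (domain intercepts plus domain-interacted median-age and
    HDI slopes) computes Cook's distance for every observation.  Observations
    with distance above ``threshold`` are flagged, keeping at most
    ``max_flagged`` (the largest distances) to guard against mass removal.
    Every returned observation carries its distance in ``influence``.
    """
    obs = list(observations)
    domains = tuple(d for d in DOMAINS if any(o.domain == d for o in obs))
    if not domains:
        domains = tuple(sorted({o.domain for o in obs}))
    for d in domains:
        if sum(o.domain == d for o in obs) < 2:
            raise ValueError(f"need at least 2 observations per domain; {d} has fewer")
    X, y, names = _design_matrix(obs, domains)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"singular preliminary design (rank {rank} < {X.shape[1]}); "
            f"collinear columns among {names}"
        )
    fit = sm.OLS(y, X).fit()
    cooks = fit.get_influence().cooks_distance[0]
    for o, c in zip(obs, cooks):
        o.influence = float(c)
    over = sorted((o for o in obs if o.influence > threshold), key=lambda o: -o.influence)
    flagged = over[:max_flagged]
    flagged_ids = {id(o) for o in flagged}
    kept = [o for o in obs if id(o) not in flagged_ids]
    return kept, flagged


def _log_posterior(
    theta: np.ndarray,
    y: np.ndarray,
    dom_idx: np.ndarray,
    z1: np.ndarray,
    z2: np.ndarray,
    k: int,
    priors: PriorConfig,
) -> float:
    """Log posterior with the domain intercepts integrated out.

    Given tau and sigma the model is linear-Gaussian, so the exchangeable
    intercepts alpha_d ~ N(mu, tau^2) can be marginalised in closed form:
    within domain d the residuals s_i = y_i - mu - b1_d z1_i - b2_d z2_i have
    covariance sigma^2 I + tau^2 J, whose inverse and determinant follow from
    the Sherman–Morrison identity.  Sampling the 3 + 2k remaining parameters
    avoids the funnel geometry of the hierarchy; the intercepts are
    recovered afterwards from their exact Gaussian conditional.
    """
    mu = theta[0]
    log_tau = theta[1]
    log_sigma = theta[2]
    b1 = theta[3 : 3 + k]
    b2 = theta[3 + k : 3 + 2 * k]
    tau = np.exp(log_tau)
    sigma = np.exp(log_sigma)
    if not np.isfinite(tau) or not np.isfinite(sigma) or sigma <= 0:
        return -np.inf

    s = y - mu - b1[dom_idx] * z1 - b2[dom_idx] * z2
    sig2, tau2 = sigma**2, tau**2
    n_d = np.bincount(dom_idx, minlength=k).astype(float)
    sum_s = np.bincount(dom_idx, weights=s, minlength=k)
    sum_s2 = np.bincount(dom_idx, weights=s**2, minlength=k)
    denom = sig2 + n_d * tau2
    quad = sum_s2 / sig2 - (tau2 / sig2) * sum_s**2 / denom
    logdet = (n_d - 1.0) * np.log(sig2) + np.log(denom)
    loglik = -0.5 * float(np.sum(quad) + np.sum(logdet))

    lp = -0.5 * (mu / priors.coef_sd) ** 2
    lp += -0.5 * np.sum((b1 / priors.coef_sd) ** 2) - 0.5 * np.sum((b2 / priors.coef_sd) ** 2)
    # half-Cauchy on tau and sigma, with the log-scale Jacobian
    lp += -np.log1p((tau / priors.tau_scale) ** 2) + log_tau
    lp += -np.log1p((sigma / priors.sigma_scale) ** 2) + log_sigma
    return loglik + lp


def _conditional_intercepts(
    flat: np.ndarray,
    y: np.ndarray,
    dom_idx: np.ndarray,
    z1: np.ndarray,
    z2: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw alpha_d (standardised scale) from its exact conditional per draw."""
    mu = flat[:, 0]
    tau2 = np.exp(2 * flat[:, 1])
    sig2 = np.exp(2 * flat[:, 2])
    b1 = flat[:, 3 : 3 + k]
    b2 = flat[:, 3 + k : 3 + 2 * k]
    n_d = np.bincount(dom_idx, minlength=k).astype(float)
    alpha = np.empty((flat.shape[0], k))
    # s_i depends on the draw through mu and the slopes
    for j in range(k):
        mask = dom_idx == j
        s_sum = (
            np.sum(y[mask]) - n_d[j] * mu
            - b1[:, j] * np.sum(z1[mask])
            - b2[:, j] * np.sum(z2[mask])
        )
        denom = sig2 + n_d[j] * tau2
        post_mean = tau2 * s_sum / denom
        post_var = tau2 * sig2 / denom
        alpha[:, j] = mu + post_mean + rng.standard_normal(flat.shape[0]) * np.sqrt(post_var)
    return alpha


def fit_mcmc(
    observations: Sequence[TransformedObservation],
    priors: PriorConfig | None = None,
    n_iter: int = 13_000,
    burn_in: int = 3_000,
    seed: int = 0,
    n_walkers: int = 40,
    convergence_cutoff: float = 1.05,
) -> PrevalenceModelFit:
    """Sample the mixed prevalence model by ensemble MCMC.

    ``n_iter`` is the number of sampler steps; the first ``burn_in`` steps of
    every walker are discarded and the remainder thinned so that at least
    1,000 draws are retained.  The fit records split-R-hat and effective
    sample size per parameter; ``converged`` is False (with a recorded
    warning, never an exception) if any R-hat exceeds ``convergence_cutoff``.
    Fully reproducible given ``seed``.
    """
    obs = list(observations)
    priors = priors or PriorConfig()
    domains = tuple(d for d in DOMAINS if any(o.domain == d for o in obs))
    if not domains:
        domains = tuple(sorted({o.domain for o in obs}))
    if len(domains) < 2:
        raise ValueError("mixed model requires observations spanning at least 2 domains")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    k = len(domains)
    idx = {d: j for j, d in enumerate(domains)}
    y = np.array([o.y for o in obs])
    dom_idx = np.array([idx[o.domain] for o in obs])
    x1 = np.array([o.median_age for o in obs])
    x2 = np.array([o.hdi for o in obs])
    m1, s1 = x1.mean(), x1.std()
    m2, s2 = x2.mean(), x2.std()
    if s1 == 0 or s2 == 0:
        raise ValueError("degenerate covariates: zero variance in medAge or HDI")
    z1 = (x1 - m1) / s1
    z2 = (x2 - m2) / s2

    # OLS on the standardised design seeds the walkers near the posterior bulk
    X, _, _ = _design_matrix(
        [
            TransformedObservation(o.country_id, o.domain, o.y, z1i, z2i)
            for o, z1i, z2i in zip(obs, z1, z2)
        ],
        domains,
    )
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    alpha0, b1_0, b2_0 = beta_hat[:k], beta_hat[k : 2 * k], beta_hat[2 * k : 3 * k]
    resid_sd = float(np.std(y - X @ beta_hat)) or 1e-3
    mu0 = float(np.mean(alpha0))
    tau0 = float(np.std(alpha0)) or 0.05

    ndim = 3 + 2 * k
    center = np.concatenate([[mu0, np.log(tau0), np.log(resid_sd)], b1_0, b2_0])
    rng = np.random.default_rng(seed)
    p0 = center + 1e-2 * rng.standard_normal((n_walkers, ndim))

    sampler = emcee.EnsembleSampler(
        n_walkers,
        ndim,
        _log_posterior,
        args=(y, dom_idx, z1, z2, k, priors),
        # differential-evolution moves mix far better than the stretch move
        # on the correlated hierarchical posterior
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_iter, progress=False)

    # thin to ~500 retained steps per walker; always >= 1,000 total draws
    kept_steps = n_iter - burn_in
    thin = max(1, kept_steps // 500)
    chain = sampler.get_chain(discard=burn_in, thin=thin)  # (steps, walkers, ndim)

    n_steps, _, _ = chain.shape
    flat = chain.reshape(-1, ndim)  # step-major: index = step * n_walkers + walker
    alpha_rng = np.random.default_rng((seed, 0xA1FA))
    alpha_std = _conditional_intercepts(flat, y, dom_idx, z1, z2, k, alpha_rng)
    alpha_chain = alpha_std.reshape(n_steps, n_walkers, k)

    # walker-wise diagnostics before flattening
    names = (
        ["intercept_mu", "log_tau", "log_sigma"]
        + [f"medage_z[{d}]" for d in domains]
        + [f"hdi_z[{d}]" for d in domains]
    )
    posterior = {name: chain[:, :, j].T for j, name in enumerate(names)}  # (chains, draws)
    for j, d in enumerate(domains):
        posterior[f"a[{d}]"] = alpha_chain[:, :, j].T
    idata = az.from_dict(posterior=posterior)
    names = names + [f"a[{d}]" for d in domains]
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {name: float(rhat_ds[name].values) for name in names}
    ess = {name: float(ess_ds[name].values) for name in names}
    warnings: list[str] = []
    worst = max(rhat.values())
    converged = bool(worst <= convergence_cutoff)
    if not converged:
        warnings.append(
            f"split-chain diagnostic {worst:.3f} exceeds cutoff {convergence_cutoff}; "
            "treat posterior summaries with caution"
        )

    mu = flat[:, 0]
    tau = np.exp(flat[:, 1])
    sigma = np.exp(flat[:, 2])
    b1_std = flat[:, 3 : 3 + k]
    b2_std = flat[:, 3 + k : 3 + 2 * k]
    # back to natural covariate scale
    slopes_medage = b1_std / s1
    slopes_hdi = b2_std / s2
    intercepts = alpha_std - b1_std * (m1 / s1) - b2_std * (m2 / s2)

    # natural-scale names for reporting: reuse the diagnostics of the
    # standardised parameters they are linear images of
    report_rhat = {}
    report_ess = {}
    for j, d in enumerate(domains):
        report_rhat[f"intercept[{d}]"] = rhat[f"a[{d}]"]
        report_rhat[f"medage[{d}]"] = rhat[f"medage_z[{d}]"]
        report_rhat[f"hdi[{d}]"] = rhat[f"hdi_z[{d}]"]
        report_ess[f"intercept[{d}]"] = ess[f"a[{d}]"]
        report_ess[f"medage[{d}]"] = ess[f"medage_z[{d}]"]
        report_ess[f"hdi[{d}]"] = ess[f"hdi_z[{d}]"]
    report_rhat["sigma"] = rhat["log_sigma"]
    report_rhat["intercept_mu"] = rhat["intercept_mu"]
    report_rhat["intercept_tau"] = rhat["log_tau"]
    report_ess["sigma"] = ess["log_sigma"]
    report_ess["intercept_mu"] = ess["intercept_mu"]
    report_ess["intercept_tau"] = ess["log_tau"]

    return PrevalenceModelFit(
        domains=domains,
        intercepts=intercepts,
        slopes_medage=slopes_medage,
        slopes_hdi=slopes_hdi,
        sigma=sigma,
        intercept_mu=mu,
        intercept_tau=tau,
        n_draws=flat.shape[0],
        seed=seed,
        ess=report_ess,
        rhat=report_rhat,
        converged=converged,
        warnings=warnings,
    )


def predict_prevalence(
    fit: PrevalenceModelFit,
    countries: Iterable[CountryRecord],
    include_residual: bool = True,
    seed: int | None = None,
) -> PredictionResult:
    """Posterior predictive prevalence for countries without surveys.

    For every country-domain the posterior draws of the linear predictor on
    the transformed scale (plus residual noise when ``include_residual``) are
    summarised by their median and 2.5/97.5 percentiles.  Each summary is
    verified to be non-negative — negative values are truncated to zero and
    counted — then raised to the fourth power.  Residual noise is seeded per
    country-domain, so results do not depend on input order.
    """
    missing = [
        c.country_id
        for c in countries
        if c.median_age is None or c.hdi is None or np.isnan(c.median_age) or np.isnan(c.hdi)
    ]
    if missing:
        raise ValueError(f"missing covariates for countries: {missing}")
    base_seed = fit.seed + 1 if seed is None else seed
    predictions: list[PrevalencePrediction] = []
    n_trunc = 0
    n_clip = 0
    for country in countries:
        for j, domain in enumerate(fit.domains):
            y_draws = (
                fit.intercepts[:, j]
                + fit.slopes_medage[:, j] * country.median_age
                + fit.slopes_hdi[:, j] * country.hdi
            )
            if include_residual:
                tag = zlib.crc32(f"{country.country_id}/{domain}".encode()) & 0x7FFFFFFF
                rng = np.random.default_rng((base_seed, tag))
                y_draws = y_draws + rng.standard_normal(len(y_draws)) * fit.sigma
            lo, mid, hi = np.percentile(y_draws, [2.5, 50.0, 97.5])
            summaries = []
            for v in (lo, mid, hi):
                if v < 0:
                    n_trunc += 1
                    v = 0.0
                summaries.append(v)
            p_lo, p_hat, p_hi = (v**4 for v in summaries)
            if p_hi > 1.0:
                n_clip += 1
            p_lo, p_hat, p_hi = (min(v, 1.0) for v in (p_lo, p_hat, p_hi))
            predictions.append(
                PrevalencePrediction(
                    country_id=country.country_id,
                    domain=domain,
                    p_hat=p_hat,
                    ci_low=p_lo,
                    ci_high=p_hi,
                )
            )
    return PredictionResult(
        predictions=predictions, n_truncated_negative=n_trunc, n_clipped_above_one=n_clip
    )
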
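"""Posterior sampling and summaries for the cure-rate model.

Sampling is component-wise adaptive random-walk Metropolis.  Regression
coefficients are sampled on their natural scale; the three positive GBS
parameters are sampled as logarithms with the Jacobian folded into the
log posterior.  Proposal step sizes adapt toward a target acceptance rate
during burn-in only, so the retained chain is a valid (non-adaptive)
Metropolis chain.

Interval estimation uses empirical highest-posterior-density (HPD)
intervals: among all windows containing ceil(mass * n) sorted draws, the
narrowest (Chen-Shao).  A coefficient is flagged significant when its 95%
HPD interval excludes zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cure import CureLikelihood, build_design, validate_cohort
from .gbs import GBSParams

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "HPDInterval",
    "log_posterior",
    "adaptive_metropolis",
    "run_mcmc",
    "hpd_interval",
    "summarize",
    "effective_sample_size",
    "geweke_z",
]


@dataclass
class PriorSpec:
    """Weakly-informative defaults; the study this emulates printed none.

    beta_sd: sd of the independent normal(0, sd) priors on coefficients.
    alpha_sd / nu_sd: sd of half-normal priors on the positive scale.
    scale_sd: sd of the half-normal prior on beta_scale; when None it is set
        at fit time to twice the median follow-up, keeping the prior weakly
        informative on the cohort's own time scale.
    """

    beta_sd: float = 10.0
    alpha_sd: float = 5.0
    nu_sd: float = 5.0
    scale_sd: float | None = None

    def __post_init__(self) -> None:
        for name in ("beta_sd", "alpha_sd", "nu_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.scale_sd is not None and self.scale_sd <= 0:
            raise ValueError("scale_sd must be > 0")

    def resolved(self, median_followup: float) -> "PriorSpec":
        if self.scale_sd is not None:
            return self
        return PriorSpec(self.beta_sd, self.alpha_sd, self.nu_sd, 2.0 * median_followup)


@dataclass
class MCMCConfig:
    n_iter: int = 20000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    init: np.ndarray | str = "default"
    adapt_interval: int = 100
    target_accept: float = 0.3
    init_step: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must be in (0, 1)")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws (rows) by parameter (columns).

    Positive GBS parameters are stored on the natural scale even though they
    are sampled as logarithms.
    """

    draws: np.ndarray
    names: list[str]
    accept_rates: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite draws")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names)


@dataclass(frozen=True)
class HPDInterval:
    low: float
    high: float
    mass: float = 0.95


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _half_normal_logpdf(x: float, sd: float) -> float:
    return math.log(2.0) - 0.5 * (x / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI


def log_posterior(
    vec: np.ndarray,
    like: CureLikelihood,
    priors: PriorSpec,
    eta: np.ndarray | None = None,
) -> float:
    """Unnormalized log posterior over (beta_vec, log alpha, log scale, log nu).

    Positive parameters enter on the log scale; each contributes its
    half-normal log prior at x = exp(u) plus the log-Jacobian u.
    Out-of-support or numerically impossible points return -inf.
    """
    p = len(vec) - 3
    beta_vec = vec[:p]
    la, lb, ln = vec[p:]
    if max(abs(la), abs(lb), abs(ln)) > 50:  # guard exp overflow
        return -np.inf
    gbs = GBSParams(math.exp(la), math.exp(lb), math.exp(ln))
    ll = like(beta_vec, gbs, eta=eta)
    if not np.isfinite(ll):
        return -np.inf
    sd = priors.beta_sd
    lp = -0.5 * float(beta_vec @ beta_vec) / (sd * sd) - p * (math.log(sd) + _LOG_SQRT_2PI)
    lp += _half_normal_logpdf(gbs.alpha, priors.alpha_sd) + la
    lp += _half_normal_logpdf(gbs.beta_scale, priors.scale_sd) + lb
    lp += _half_normal_logpdf(gbs.nu, priors.nu_sd) + ln
    return ll + lp


def adaptive_metropolis(
    logpost: Callable[[np.ndarray], float],
    init: np.ndarray,
    config: MCMCConfig,
    names: Sequence[str] | None = None,
) -> PosteriorDraws:
    """Generic component-wise random-walk Metropolis with burn-in adaptation.

    Each scan updates every coordinate in turn with a Gaussian proposal.
    During burn-in, each coordinate's step size is rescaled every
    ``adapt_interval`` scans toward ``target_accept``; after burn-in the
    steps are frozen so the retained draws come from a fixed kernel.
    """
    rng = np.random.default_rng(config.seed)
    x = np.asarray(init, dtype=float).copy()
    d = x.shape[0]
    if names is None:
        names = [f"p{i}" for i in range(d)]
    steps = np.full(d, config.init_step)
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("log posterior is not finite at the initial point")

    n_keep = (config.n_iter - config.burn_in) // config.thin
    out = np.empty((n_keep, d))
    acc = np.zeros(d)
    acc_window = np.zeros(d)
    kept = 0
    for it in range(config.n_iter):
        for j in range(d):
            prop = x.copy()
            prop[j] += steps[j] * rng.standard_normal()
            lp_prop = logpost(prop)
            if np.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                acc[j] += 1
                acc_window[j] += 1
        if it < config.burn_in and (it + 1) % config.adapt_interval == 0:
            rates = acc_window / config.adapt_interval
            if np.all(rates == 0):
                warnings.warn(
                    "no proposals accepted over an entire adaptation window; "
                    f"step sizes {steps}, current log posterior {lp:.2f}",
                    RuntimeWarning,
                )
            steps *= np.exp(np.clip(rates - config.target_accept, -0.5, 0.5))
            acc_window[:] = 0.0
        if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
            out[kept] = x
            kept += 1
    return PosteriorDraws(
        draws=out[:kept],
        names=list(names),
        accept_rates=acc / config.n_iter,
        seed=config.seed,
    )


def _default_init(p: int, median_followup: float) -> np.ndarray:
    vec = np.zeros(p + 3)
    vec[p] = math.log(0.5)  # alpha
    vec[p + 1] = math.log(max(median_followup, 1e-6))
    vec[p + 2] = math.log(0.5)  # nu
    return vec


def run_mcmc(
    data: pd.DataFrame,
    covariates: list[str] | None = None,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Fit the cure-rate model to a cohort table by MCMC.

    Returns draws for the regression coefficients (named after design
    columns) and the GBS parameters alpha, beta_scale, nu on their natural
    scale.
    """
    validate_cohort(data)
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    X, names = build_design(data, covariates)
    like = CureLikelihood(data["time"].to_numpy(), data["event"].to_numpy(), X)
    med = float(np.median(like.time))
    priors = priors.resolved(med)
    p = X.shape[1]
    init = _default_init(p, med) if isinstance(config.init, str) else np.asarray(config.init, float)

    def logpost(vec: np.ndarray) -> float:
        return log_posterior(vec, like, priors)

    if not np.isfinite(logpost(init)):
        raise ValueError("log posterior is not finite at the initial point")

    all_names = names + ["alpha", "beta_scale", "nu"]
    from ._sampler import run_cure_chain

    if run_cure_chain is not None:
        col_rows = [np.flatnonzero(X[:, j]) for j in range(p)]
        prior_sds = (priors.beta_sd, priors.alpha_sd, priors.scale_sd, priors.nu_sd)
        mat, acc = run_cure_chain(like.time, like.event, col_rows, prior_sds, init, config)
        if np.any(acc == 0.0):
            warnings.warn(
                f"zero accepted proposals for {[all_names[j] for j in np.flatnonzero(acc == 0)]}",
                RuntimeWarning,
            )
        draws = PosteriorDraws(draws=mat, names=all_names, accept_rates=acc, seed=config.seed)
    else:  # pragma: no cover - exercised only without numba
        draws = adaptive_metropolis(logpost, init, config, names=all_names)
    # report positive parameters on the natural scale
    draws.draws[:, p:] = np.exp(draws.draws[:, p:])
    return draws


def hpd_interval(draws, mass: float = 0.95) -> HPDInterval:
    """Chen-Shao empirical HPD: minimum-width window of ceil(mass*n) sorted
    draws; ties broken by the earliest window."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.shape[0]
    if n < 20:
        raise ValueError("need at least 20 draws for an empirical HPD interval")
    m = math.ceil(mass * n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return HPDInterval(low=float(x[i]), high=float(x[i + m - 1]), mass=mass)


def summarize(draws: PosteriorDraws, mass: float = 0.95) -> pd.DataFrame:
    """Posterior digest: one row per parameter.

    Columns: mean, sd, p25, p50, p75, exp_mean, hpd_low, hpd_high,
    significant (HPD excludes 0).  Quartiles are quartiles of the retained
    draws; exp_mean = exp(mean) is the cure odds ratio for coefficients.
    """
    rows = []
    for j, name in enumerate(draws.names):
        col = draws.draws[:, j]
        hpd = hpd_interval(col, mass)
        mean = float(np.mean(col))
        rows.append(
            {
                "parameter": name,
                "mean": mean,
                "sd": float(np.std(col, ddof=1)),
                "p25": float(np.percentile(col, 25)),
                "p50": float(np.percentile(col, 50)),
                "p75": float(np.percentile(col, 75)),
                "exp_mean": float(np.exp(mean)),
                "hpd_low": hpd.low,
                "hpd_high": hpd.high,
                "significant": bool(hpd.low > 0 or hpd.high < 0),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def effective_sample_size(col: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator."""
    import arviz as az

    return float(az.ess(np.asarray(col, dtype=float)))


def geweke_z(col: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    Segment variances use ESS-adjusted standard errors; |z| > 2 suggests the
    chain had not reached its stationary distribution.  Advisory only.
    """
    col = np.asarray(col, dtype=float)
    n = col.shape[0]
    a, b = col[: int(first * n)], col[int((1 - last) * n) :]
    if min(a.size, b.size) < 20:
        raise ValueError("chain too short for a Geweke diagnostic")
    va = np.var(a, ddof=1) / max(effective_sample_size(a), 1.0)
    vb = np.var(b, ddof=1) / max(effective_sample_size(b), 1.0)
    return float((np.mean(a) - np.mean(b)) / np.sqrt(va + vb))
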
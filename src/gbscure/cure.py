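"""Non-mixture (promotion-time) cure-rate model with geometric latent causes.

Each subject carries a latent number M of competing causes (initiated but
undetectable lesions); each cause, if any, has an i.i.d. event time from the
generalized Birnbaum-Saunders law and the observed event time is the minimum.
Subjects with M = 0 never experience the event: they are the cured fraction.

Here M ~ Geometric(theta) on {0, 1, 2, ...} with P(M = m) = theta (1-theta)^m,
so the cure fraction IS the geometric parameter: P(cured) = P(M = 0) = theta.
The population (improper) survival function is the probability generating
function of M evaluated at the latent survival S(t):

    Sp(t) = G(S(t)) = theta / (1 - (1 - theta) S(t))

which decreases from 1 to the plateau theta as t -> infinity, and

    fp(t) = -dSp/dt = theta (1 - theta) f(t) / (1 - (1 - theta) S(t))^2.

Covariates act on the cure fraction through a logistic link,
theta_i = expit(x_i' beta), so exp(beta_j) is the multiplicative change in
the odds of cure for level j versus its reference level.  The latent GBS
time law is shared across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .gbs import GBSParams, gbs_log_pdf, gbs_sf

__all__ = [
    "COVARIATE_LEVELS",
    "REFERENCE_LEVELS",
    "CureModelParams",
    "validate_cohort",
    "build_design",
    "cure_fraction",
    "population_survival",
    "population_density",
    "log_likelihood",
    "CureLikelihood",
]

# Data dictionary for the cohort CSV schema.  Level order below is the order
# dummies appear in the design matrix; the reference level (last) gets no
# column.  References follow the regression table conventions of the study
# design this emulates: oldest age, mastectomy, largest tumor, most nodes,
# highest stage, poorest grade, and negative receptor/invasion status.
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("<40", "40-60", ">60"),
    "surgery": ("BCS", "MRM"),
    "tumor_size": ("T1", "T2", "T3+"),
    "nodes": ("N0", "N1", "N2+"),
    "stage": ("I", "II", "III+"),
    "grade": ("well", "moderately", "poorly"),
    "lvi": ("pos", "neg"),
    "er": ("pos", "neg"),
    "pr": ("pos", "neg"),
}

REFERENCE_LEVELS: dict[str, str] = {k: v[-1] for k, v in COVARIATE_LEVELS.items()}

REQUIRED_COLUMNS = ("time", "event") + tuple(COVARIATE_LEVELS)


@dataclass
class CureModelParams:
    """Regression coefficients (cure log-odds scale) plus the shared GBS law.

    ``beta_vec[0]`` is the intercept when the design matrix carries one.
    """

    beta_vec: np.ndarray
    gbs: GBSParams

    def __post_init__(self) -> None:
        self.beta_vec = np.atleast_1d(np.asarray(self.beta_vec, dtype=float))
        if not np.all(np.isfinite(self.beta_vec)):
            raise ValueError("beta_vec must be finite")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the schema; returns the frame unchanged.

    Raises ValueError naming every offending column/level, with row indices
    for undeclared categorical levels.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")
    t = pd.to_numeric(df["time"], errors="coerce")
    if t.isna().any() or (t <= 0).any():
        raise ValueError("column 'time' must be numeric and strictly positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("column 'event' must be 0 (censored) or 1 (event)")
    problems = []
    for cov, levels in COVARIATE_LEVELS.items():
        bad = ~df[cov].isin(levels)
        if bad.any():
            rows = df.index[bad].tolist()[:10]
            problems.append(f"{cov}: undeclared levels {sorted(df[cov][bad].unique())} at rows {rows}")
    if problems:
        raise ValueError("invalid covariate levels:\n" + "\n".join(problems))
    return df


def build_design(
    df: pd.DataFrame, covariates: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded dummy design matrix.

    Column names are ``covariate[level]``; the reference level of each
    covariate is omitted.  ``covariates`` selects a subset (default: all, in
    data-dictionary order) so both univariate and joint fits use one code path.
    """
    if covariates is None:
        covariates = list(COVARIATE_LEVELS)
    unknown = [c for c in covariates if c not in COVARIATE_LEVELS]
    if unknown:
        raise ValueError(f"unknown covariates: {unknown}")
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for cov in covariates:
        for level in COVARIATE_LEVELS[cov][:-1]:
            cols.append((df[cov].to_numpy() == level).astype(float))
            names.append(f"{cov}[{level}]")
    return np.column_stack(cols), names


def cure_fraction(x, beta_vec) -> np.ndarray | float:
    """theta = expit(x . beta): probability of never experiencing the event."""
    x = np.asarray(x, dtype=float)
    beta_vec = np.asarray(beta_vec, dtype=float)
    if x.shape[-1] != beta_vec.shape[0]:
        raise ValueError(
            f"design row has {x.shape[-1]} columns but beta_vec has {beta_vec.shape[0]}"
        )
    return expit(x @ beta_vec)


def _theta_array(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta > 1):
        raise ValueError("cure fraction theta must lie in (0, 1]")
    return theta


def population_survival(t, theta, gbs: GBSParams):
    """Sp(t) = theta / (1 - (1-theta) S(t)); Sp(0+) = 1, Sp(inf) = theta."""
    theta = _theta_array(theta)
    s = gbs_sf(t, gbs)
    return theta / (1.0 - (1.0 - theta) * s)


def population_density(t, theta, gbs: GBSParams):
    """fp(t) = theta (1-theta) f(t) / (1 - (1-theta) S(t))^2 = -dSp/dt."""
    theta = _theta_array(theta)
    s = gbs_sf(t, gbs)
    f = np.exp(gbs_log_pdf(t, gbs))
    return theta * (1.0 - theta) * f / (1.0 - (1.0 - theta) * s) ** 2


def _loglik_terms(eta, logf, s, event):
    """Censored-data log likelihood from precomputed latent-law pieces.

    eta: linear predictor; logf, s: GBS log-density and survival at the
    observed times; event: 0/1 indicator.  Everything stays in log domain:
    log Sp = log theta - log(1 - (1-theta) S)
    log fp = log theta + log(1-theta) + log f - 2 log(1 - (1-theta) S).
    For an event with theta -> 1 the density vanishes and the term is -inf,
    which the caller treats as an impossible-parameter signal, never silently.
    """
    # log theta = -log1p(exp(-eta)), log(1-theta) = -log1p(exp(eta))
    log_theta = -np.logaddexp(0.0, -eta)
    log_one_minus = -np.logaddexp(0.0, eta)
    denom = -np.log1p(-np.exp(log_one_minus) * s)  # -log(1-(1-theta)S) >= 0
    with np.errstate(invalid="ignore"):
        terms = np.where(
            event == 1,
            log_theta + log_one_minus + logf + 2.0 * denom,
            log_theta + denom,
        )
    return terms


def log_likelihood(time, event, X, beta_vec, gbs: GBSParams) -> float:
    """Right-censored log likelihood: sum_i [d_i log fp + (1-d_i) log Sp]."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be finite and positive")
    eta = np.asarray(X, dtype=float) @ np.asarray(beta_vec, dtype=float)
    terms = _loglik_terms(eta, gbs_log_pdf(time, gbs), gbs_sf(time, gbs), event)
    return float(np.sum(terms))


def _loglik_kernel_numpy(eta, sf, logf, event) -> float:
    return float(np.sum(_loglik_terms(eta, logf, sf, event)))


def _build_numba_kernel():
    try:
        import numba
    except ImportError:  # pragma: no cover - numba is an optional speedup
        return None

    import math

    @numba.njit(cache=False, fastmath=False)
    def kernel(eta, sf, logf, event):  # pragma: no cover - compiled
        total = 0.0
        for i in range(eta.shape[0]):
            e = eta[i]
            if e < 0.0:
                log_theta = e - math.log1p(math.exp(e))
            else:
                log_theta = -math.log1p(math.exp(-e))
            log_one_minus = log_theta - e
            one_minus = math.exp(log_one_minus)
            inner = 1.0 - one_minus * sf[i]
            if inner <= 0.0:
                return -np.inf
            denom = -math.log(inner)
            total += log_theta + denom
            if event[i] == 1:
                total += log_one_minus + logf[i] + denom
        return total

    return kernel


_NUMBA_KERNEL = _build_numba_kernel()


class CureLikelihood:
    """Log likelihood with the GBS pieces cached per (alpha, beta_scale, nu).

    The MCMC sampler updates one parameter at a time; proposals that move a
    regression coefficient leave the latent time law untouched, so logf(t)
    and S(t) are reused across those evaluations.  The per-subject summation
    runs through a compiled kernel when numba is importable, with an exactly
    equivalent vectorized numpy fallback.
    """

    def __init__(self, time, event, X):
        self.time = np.asarray(time, dtype=float)
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("times must be finite and positive")
        self.event = np.asarray(event, dtype=np.int64)
        self.X = np.asarray(X, dtype=float)
        self._cache_key = None
        self._logf = None
        self._sf = None
        self._kernel = _NUMBA_KERNEL or _loglik_kernel_numpy

    @property
    def n(self) -> int:
        return self.time.shape[0]

    def _latent(self, gbs: GBSParams):
        key = (gbs.alpha, gbs.beta_scale, gbs.nu)
        if key != self._cache_key:
            self._logf = gbs_log_pdf(self.time, gbs)
            self._sf = gbs_sf(self.time, gbs)
            self._cache_key = key
        return self._logf, self._sf

    def __call__(self, beta_vec: np.ndarray, gbs: GBSParams, eta=None) -> float:
        logf, sf = self._latent(gbs)
        if eta is None:
            eta = self.X @ np.asarray(beta_vec, dtype=float)
        return float(self._kernel(eta, sf, logf, self.event))
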
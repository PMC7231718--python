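"""Synthetic breast-cancer cohort generator.

Emulates the statistical structure of a hospital-registry cohort of 3184
women with right-censored follow-up (83% censored) accrued over a 23-year
window: categorical prognostic covariates with fixed marginal frequencies,
a cure fraction driven by those covariates through a logistic model, and
event times for the non-cured generated by the exact promotion-time
construction the likelihood assumes (M ~ Geometric(theta) latent causes,
observed event = minimum of M generalized Birnbaum-Saunders times), so the
generator and the fitted model share the same population survival function
by construction.

Covariates are drawn independently of one another: the registry's joint
covariate distribution is unpublished, only the marginals are.  That is a
documented limitation, not an estimate of the real dependence structure.

Administrative censoring is uniform on [1, 23] years, a stand-in for
staggered accrual with a common closing date.  The baseline GBS parameters
and the intercept are calibrated knobs -- chosen so the cohort-average cure
fraction is 0.46 (the survival plateau) and the realized censoring
proportion is about 83% -- and are not estimates of the registry's values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cure import COVARIATE_LEVELS, build_design, cure_fraction
from .gbs import GBSParams, gbs_sample

__all__ = [
    "TABLE1_MARGINALS",
    "TABLE2_BETA",
    "CohortConfig",
    "calibrate_intercept",
    "default_config",
    "default_table1_config",
    "generate_cohort",
]

# Marginal level counts of the emulated registry cohort (n = 3184), stored
# as counts so each covariate's probabilities sum to exactly 1.
_TABLE1_COUNTS: dict[str, tuple[int, ...]] = {
    "age_group": (670, 1926, 588),
    "surgery": (1997, 1187),
    "tumor_size": (1009, 1707, 468),
    "nodes": (1479, 1389, 316),
    "stage": (663, 1467, 1054),
    "grade": (391, 1680, 1113),
    "lvi": (1367, 1817),
    "er": (906, 2278),
    "pr": (1058, 2126),
}

TABLE1_MARGINALS: dict[str, tuple[float, ...]] = {
    k: tuple(c / 3184 for c in v) for k, v in _TABLE1_COUNTS.items()
}

# Cure-odds coefficients (posterior means of the emulated analysis), keyed
# by design-matrix column name; reference levels are implicitly 0.
TABLE2_BETA: dict[str, float] = {
    "age_group[<40]": 0.461,
    "age_group[40-60]": 0.283,
    "surgery[BCS]": -0.034,
    "tumor_size[T1]": 1.325,
    "tumor_size[T2]": 0.523,
    "nodes[N0]": 1.011,
    "nodes[N1]": 0.081,
    "stage[I]": 0.618,
    "stage[II]": 0.044,
    "grade[well]": 1.097,
    "grade[moderately]": 0.203,
    "lvi[pos]": -1.139,
    "er[pos]": 0.440,
    "pr[pos]": 0.475,
}

# Baseline latent-time law for the non-cured.  Calibrated (with the
# intercept) to the target censoring proportion and plateau under the
# uniform [1, 23] administrative window; NOT registry estimates.
DEFAULT_GBS = GBSParams(alpha=0.25, beta_scale=17.0, nu=1.0)


@dataclass
class CohortConfig:
    """Generator settings; defaults encode the emulated cohort's structure."""

    n: int = 3184
    covariate_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(TABLE1_MARGINALS)
    )
    beta: dict[str, float] = field(default_factory=lambda: dict(TABLE2_BETA))
    intercept: float | None = None  # None -> calibrate to target_cure
    target_cure: float = 0.46
    gbs: GBSParams = DEFAULT_GBS
    censor_low: float = 1.0
    censor_high: float = 23.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 < self.censor_low < self.censor_high):
            raise ValueError("censoring window bounds must be positive and ordered")
        for cov, probs in self.covariate_probs.items():
            levels = COVARIATE_LEVELS[cov]
            if len(probs) != len(levels):
                raise ValueError(f"{cov}: {len(probs)} probabilities for {len(levels)} levels")
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"{cov}: level probabilities must sum to 1")
            if any(p < 0 for p in probs):
                raise ValueError(f"{cov}: negative probability")

    def resolved_intercept(self) -> float:
        if self.intercept is not None:
            return self.intercept
        return calibrate_intercept(self.target_cure, self.covariate_probs, self.beta)


def _linear_predictor_distribution(
    covariate_probs: dict[str, tuple[float, ...]], beta: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of x'beta under independent covariates."""
    dist: dict[float, float] = {0.0: 1.0}
    for cov, probs in covariate_probs.items():
        levels = COVARIATE_LEVELS[cov]
        new: dict[float, float] = {}
        for s, p in dist.items():
            for level, pl in zip(levels, probs):
                b = beta.get(f"{cov}[{level}]", 0.0)
                key = round(s + b, 12)
                new[key] = new.get(key, 0.0) + p * pl
        dist = new
    vals = np.array(list(dist.keys()))
    wts = np.array(list(dist.values()))
    return vals, wts


def calibrate_intercept(
    target_cure: float,
    covariate_probs: dict[str, tuple[float, ...]] | None = None,
    beta: dict[str, float] | None = None,
) -> float:
    """Intercept b0 solving E[expit(b0 + x'beta)] = target_cure exactly,
    by enumerating the (discrete) distribution of the linear predictor."""
    if not (0 < target_cure < 1):
        raise ValueError("target_cure must be in (0, 1)")
    covariate_probs = covariate_probs or TABLE1_MARGINALS
    beta = beta if beta is not None else TABLE2_BETA
    vals, wts = _linear_predictor_distribution(covariate_probs, beta)

    def gap(b0: float) -> float:
        return float(np.sum(wts * expit(b0 + vals)) - target_cure)

    return brentq(gap, -30.0, 30.0, xtol=1e-12)


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The study-conditions configuration; alias of default_table1_config."""
    return CohortConfig(seed=seed, **overrides)


def default_table1_config(seed: int = 0) -> CohortConfig:
    """Config encoding the emulated cohort's covariate marginals and
    cure-odds coefficients."""
    return default_config(seed=seed)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Draw one cohort; returns (cohort table, truth record).

    Per subject: covariates ~ independent categoricals; theta = expit of the
    cure linear predictor; M ~ Geometric(theta) on {0,1,...}; M = 0 means
    cured (always administratively censored); otherwise the latent event
    time is the minimum of M GBS draws; observed time = min(event, censor).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    cols = {}
    for cov, probs in config.covariate_probs.items():
        levels = COVARIATE_LEVELS[cov]
        cols[cov] = rng.choice(levels, size=n, p=np.asarray(probs))
    df = pd.DataFrame(cols)

    b0 = config.resolved_intercept()
    X, names = build_design(df)
    beta_vec = np.array([b0] + [config.beta.get(nm, 0.0) for nm in names[1:]])
    theta = cure_fraction(X, beta_vec)

    # numpy's geometric is on {1, 2, ...}; shift to put mass theta at 0
    m = rng.geometric(theta) - 1
    cured = m == 0

    event_time = np.full(n, np.inf)
    susceptible = np.flatnonzero(~cured)
    if susceptible.size:
        total = int(m[susceptible].sum())
        draws = gbs_sample(total, config.gbs, rng)
        splits = np.cumsum(m[susceptible])[:-1]
        event_time[susceptible] = np.fromiter(
            (chunk.min() for chunk in np.split(draws, splits)),
            dtype=float,
            count=susceptible.size,
        )

    censor_time = rng.uniform(config.censor_low, config.censor_high, size=n)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    df.insert(0, "time", observed)
    df.insert(1, "event", event)

    truth = {
        "intercept": b0,
        "beta": {"intercept": b0, **{nm: config.beta.get(nm, 0.0) for nm in names[1:]}},
        "gbs": config.gbs.as_dict(),
        "seed": config.seed,
        "n": n,
        "mean_cure_fraction": float(np.mean(theta)),
        "n_cured": int(cured.sum()),
        "n_events": int(event.sum()),
        "censoring_proportion": float(1.0 - event.mean()),
        "censor_window": [config.censor_low, config.censor_high],
    }
    return df, truth
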
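"""Synthetic cohorts with known outcome structure.

Emulates a surgical lung-adenocarcinoma cohort: per-subject feature and
clinical-covariate values, overall-survival times from an exponential
proportional-hazards model, independent exponential censoring calibrated
to a target censoring fraction, and a binary micropapillary-subtype label
from a logistic link.  The exponential PH choice gives closed-form
censoring calibration and exact concordance expectations, which the test
suite exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = ["CohortSpec", "simulate_cohort", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Infeasible cohort configuration (e.g. censoring target out of range)."""


#: default clinical covariates: name -> ("normal" | "binary", params)
DEFAULT_CLINICAL = {
    "age": ("normal", {}),
    "sex": ("binary", {"p": 0.5}),
    "tumor_size": ("normal", {}),
    "differentiation": ("binary", {"p": 0.5}),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of one simulated cohort.

    ``true_coefficients`` are log-hazard ratios per unit of the covariate;
    ``mp_link`` are log-odds slopes for the micropapillary label, whose
    marginal prevalence is held at ``mp_prevalence`` (0.437 by default,
    echoing the observed frequency of the pattern in resected
    adenocarcinoma) by solving for the intercept.
    """

    n_subjects: int = 300
    n_features: int = 76
    feature_names: tuple[str, ...] | None = None
    clinical: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL))
    true_coefficients: dict = field(default_factory=dict)
    baseline_hazard: float = 0.02  # events per month; median OS ~ 35 months
    censoring_fraction_target: float = 0.3
    mp_link: dict = field(default_factory=dict)
    mp_prevalence: float = 0.437
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 20:
            raise ConfigurationError("n_subjects must be >= 20")
        if not 0.0 <= self.censoring_fraction_target <= 0.95:
            raise ConfigurationError("censoring_fraction_target must be in [0, 0.95]")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if not 0.0 < self.mp_prevalence < 1.0:
            raise ConfigurationError("mp_prevalence must be in (0, 1)")

    def resolved_feature_names(self) -> list[str]:
        if self.feature_names is not None:
            return list(self.feature_names)
        return [f"feature_{i + 1}" for i in range(self.n_features)]


def _calibrate_censoring_rate(rates: np.ndarray, target: float) -> float:
    """Censoring rate c with E[P(C < T)] = mean_i c/(c + rate_i) = target.

    The expectation is monotone in c, from 0 (c -> 0) to 1 (c -> inf), so
    any target in (0, 1) admits a unique root.
    """

    def frac(log_c: float) -> float:
        c = np.exp(log_c)
        return float(np.mean(c / (c + rates))) - target

    lo, hi = -30.0, 30.0
    if frac(lo) > 0 or frac(hi) < 0:  # pragma: no cover - defensive
        raise ConfigurationError("censoring target not attainable for these hazards")
    return float(np.exp(brentq(frac, lo, hi, xtol=1e-12)))


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table: id, features, covariates, time, event, mp.

    Features are i.i.d. standard normal; clinical covariates follow their
    declared distribution.  Survival times are exponential with rate
    ``baseline_hazard * exp(sum coef * x)``; censoring is independent
    exponential with rate calibrated so the expected censoring fraction
    matches the target.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cols: dict[str, np.ndarray] = {}
    for name in spec.resolved_feature_names():
        cols[name] = rng.standard_normal(n)
    for name, (kind, params) in spec.clinical.items():
        if kind == "binary":
            cols[name] = rng.binomial(1, params.get("p", 0.5), size=n).astype(float)
        else:
            cols[name] = rng.normal(params.get("mean", 0.0), params.get("sd", 1.0), size=n)

    lp = np.zeros(n)
    for name, beta in spec.true_coefficients.items():
        if name not in cols:
            raise ConfigurationError(f"coefficient on unknown column {name!r}")
        lp += beta * cols[name]
    rates = spec.baseline_hazard * np.exp(lp)
    event_times = rng.exponential(1.0 / rates)

    if spec.censoring_fraction_target == 0.0:
        time, event = event_times, np.ones(n, dtype=int)
    else:
        c_rate = _calibrate_censoring_rate(rates, spec.censoring_fraction_target)
        censor_times = rng.exponential(1.0 / c_rate, size=n)
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)

    eta = np.zeros(n)
    for name, slope in spec.mp_link.items():
        if name not in cols:
            raise ConfigurationError(f"mp_link on unknown column {name!r}")
        eta += slope * cols[name]
    # intercept solved so the marginal prevalence matches the target
    b0 = brentq(lambda b: float(np.mean(expit(b + eta))) - spec.mp_prevalence, -40, 40)
    mp = rng.binomial(1, expit(b0 + eta))

    table = pd.DataFrame({"subject_id": [f"S{i + 1:04d}" for i in range(n)], **cols})
    table["time"] = time
    table["event"] = event
    table["mp"] = mp
    return table
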
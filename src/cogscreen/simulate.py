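"""Synthetic participant-cohort simulator.

Generates tabular populations with the joint structure the downstream
analyses assume: five latent disease classes (healthy, single-domain
amnestic MCI, multi-domain amnestic MCI, non-amnestic MCI, probable mild
ADRD), per-class score distributions for six cognitive/functional measures,
demographic covariates, and configurable demographic bias effects.

Generative model
----------------
Each participant draws a latent class from ``cohort_mixture`` and a latent
severity factor ``u ~ N(0, 1)``. For each test, a correlated standard normal
``z = rho * s * u + sqrt(1 - rho^2) * eps`` (``s`` = +1 when higher scores
are worse, -1 otherwise) is mapped through a Gaussian copula onto a
truncated normal with the class's configured (mean, sd) and the test's valid
range. The truncated-normal location is calibrated by root finding so the
expected value *after* truncation (and, for integer-valued tests, after
rounding) equals the configured class mean; the configured means are
therefore exact generative means, not pre-truncation parameters.

Demographic bias effects are additive shifts expressed in units of the
test's *marginal* (population) SD — the metric the downstream bias analysis
standardizes scores into — applied uniformly across classes to members of
the affected subgroup (female, Non-White, Hispanic, or education < 15
years). The marginal SD is derived from the mixture and the per-class
(mean, sd) parameters by the law of total variance. The location is
re-calibrated per shifted target mean, so configured subgroup mean
differences are exact generative differences despite truncation.

All randomness flows from ``SimulationConfig.seed``; identical configs
reproduce identical populations.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CLASSES",
    "SCORE_TESTS",
    "ConfigError",
    "SimulationConfig",
    "generate_population",
    "subscore_columns",
]

#: Latent generating classes, in fixed order.
CLASSES = ("healthy", "aMCI", "mdMCI", "naMCI", "mild_adrd")

#: (lower bound, upper bound, integer-valued, severity sign) per test.
#: severity sign +1 = higher is worse, -1 = higher is better.
SCORE_SPECS: dict[str, tuple[float, float, bool, int]] = {
    "ravlt_long_delay": (0.0, 15.0, False, -1),
    "tmtb_seconds": (0.0, math.inf, False, +1),
    "faq": (0.0, 30.0, True, +1),
    "mmse": (0.0, 30.0, True, -1),
    "dct_summary": (0.0, 100.0, False, -1),
    "delayed_recall": (0.0, 3.0, True, -1),
}

SCORE_TESTS = tuple(SCORE_SPECS)

#: Bias-effect factor -> predicate name; the shifted subgroup per factor.
BIAS_FACTORS = ("sex", "race", "ethnicity", "education")

# Default per-class (mean, sd) per test. Chosen so each class's scores sit
# >= 2 class-SDs from the default impairment cutoffs implied by the shipped
# synthetic norms (RAVLT cut ~6 words, TMT-B cut ~150 s, FAQ cuts 6/9), so
# that rules-based cohorting recovers the generating class with high
# probability. mild_adrd has FAQ centred inside the analysable 6-9 window.
_DEFAULT_CLASS_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "healthy": {
        "ravlt_long_delay": (10.5, 1.5),
        "tmtb_seconds": (95.0, 25.0),
        "faq": (1.5, 2.0),
        "mmse": (29.0, 1.2),
        "dct_summary": (82.0, 10.0),
        "delayed_recall": (2.6, 0.6),
    },
    "aMCI": {
        "ravlt_long_delay": (3.0, 1.5),
        "tmtb_seconds": (95.0, 25.0),
        "faq": (1.5, 2.0),
        "mmse": (27.5, 1.8),
        "dct_summary": (68.0, 12.0),
        "delayed_recall": (1.2, 0.8),
    },
    "mdMCI": {
        "ravlt_long_delay": (3.0, 1.5),
        "tmtb_seconds": (200.0, 25.0),
        "faq": (1.5, 2.0),
        "mmse": (26.5, 2.0),
        "dct_summary": (60.0, 12.0),
        "delayed_recall": (1.0, 0.8),
    },
    "naMCI": {
        "ravlt_long_delay": (10.5, 1.5),
        "tmtb_seconds": (200.0, 25.0),
        "faq": (1.5, 2.0),
        "mmse": (27.5, 1.8),
        "dct_summary": (65.0, 12.0),
        "delayed_recall": (1.8, 0.8),
    },
    "mild_adrd": {
        "ravlt_long_delay": (3.0, 1.5),
        "tmtb_seconds": (200.0, 25.0),
        "faq": (7.5, 0.75),
        "mmse": (24.0, 2.5),
        "dct_summary": (48.0, 12.0),
        "delayed_recall": (0.6, 0.6),
    },
}

# Mixture from the five rules-based cohort sizes of the motivating study
# (331, 176, 61, 71, 59), normalised to their 698 total.
_DEFAULT_MIXTURE = {
    "healthy": 331 / 698,
    "aMCI": 176 / 698,
    "mdMCI": 61 / 698,
    "naMCI": 71 / 698,
    "mild_adrd": 59 / 698,
}


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the bad field."""


def _default_class_params():
    return {c: dict(v) for c, v in _DEFAULT_CLASS_PARAMS.items()}


@dataclass
class SimulationConfig:
    """Full specification of a synthetic population.

    Defaults emulate the motivating study's sample: n=706, age 71.5 +/- 6.7,
    58.9% female, 85.1% White, 9.3% Hispanic, education 15.4 +/- 2.7 years,
    and a five-class mixture proportional to the published rules-based cohort
    counts.
    """

    n_participants: int = 706
    cohort_mixture: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURE)
    )
    class_score_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_class_params
    )
    n_clock_subscores: int = 22
    sex_female_p: float = 0.589
    race_white_p: float = 0.851
    ethnicity_hispanic_p: float = 0.093
    education_mean: float = 15.4
    education_sd: float = 2.7
    age_mean: float = 71.5
    age_sd: float = 6.7
    age_range: tuple[float, float] = (55.0, 90.0)
    severity_correlation: float = 0.4
    subscore_noise_sd: float = 8.0
    bias_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    education_split: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if set(self.cohort_mixture) != set(CLASSES):
            raise ConfigError(
                f"cohort_mixture must have exactly the keys {CLASSES}"
            )
        props = np.array([self.cohort_mixture[c] for c in CLASSES], dtype=float)
        if np.any(props < 0) or np.any(props > 1):
            raise ConfigError("cohort_mixture proportions must lie in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"cohort_mixture must sum to 1 (got {props.sum():.12g})"
            )
        for cls in CLASSES:
            params = self.class_score_params.get(cls)
            if params is None or set(params) != set(SCORE_TESTS):
                raise ConfigError(
                    f"class_score_params[{cls!r}] must define all of {SCORE_TESTS}"
                )
            for test, (mean, sd) in params.items():
                low, high, _, _ = SCORE_SPECS[test]
                if not sd > 0:
                    raise ConfigError(
                        f"class_score_params[{cls!r}][{test!r}] sd must be > 0"
                    )
                if not (low < mean < high):
                    raise ConfigError(
                        f"class_score_params[{cls!r}][{test!r}] mean {mean} "
                        f"outside open range ({low}, {high})"
                    )
        for name in ("sex_female_p", "race_white_p", "ethnicity_hispanic_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("education_sd", "age_sd", "subscore_noise_sd"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0.0 <= self.severity_correlation < 1.0:
            raise ConfigError("severity_correlation must lie in [0, 1)")
        if self.n_clock_subscores < 0:
            raise ConfigError("n_clock_subscores must be >= 0")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigError("age_range must be an increasing pair")
        for test, factors in self.bias_effects.items():
            if test not in SCORE_TESTS:
                raise ConfigError(f"bias_effects key {test!r} is not a known test")
            for factor in factors:
                if factor not in BIAS_FACTORS:
                    raise ConfigError(
                        f"bias_effects[{test!r}] key {factor!r} is not one of "
                        f"{BIAS_FACTORS}"
                    )
            # every achievable combined shift must keep every class mean in
            # range (deterministic check, independent of which subgroups are
            # actually drawn)
            import itertools as _it

            low, high, _, _ = SCORE_SPECS[test]
            msd = marginal_sd(self, test)
            shifts = list(factors.values())
            sums = {
                sum(c)
                for r in range(len(shifts) + 1)
                for c in _it.combinations(shifts, r)
            }
            for cls in CLASSES:
                mean = self.class_score_params[cls][test][0]
                for s in sums:
                    target = mean + s * msd
                    if not low < target < high:
                        raise ConfigError(
                            f"bias_effects push class {cls!r} {test!r} mean to "
                            f"{target}, outside the open range ({low}, {high})"
                        )

    # -- JSON round-trip (used by the CLI) --------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["class_score_params"] = {
            c: {t: list(v) for t, v in params.items()}
            for c, params in self.class_score_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        if "class_score_params" in raw:
            raw["class_score_params"] = {
                c: {t: tuple(v) for t, v in params.items()}
                for c, params in raw["class_score_params"].items()
            }
        return cls(**raw)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def marginal_sd(config: "SimulationConfig", test: str) -> float:
    """Population SD of a test under the configured class mixture.

    Law of total variance over the mixture, using the configured per-class
    (mean, sd); the unit in which ``bias_effects`` shifts are expressed.
    """
    props = np.array([config.cohort_mixture[c] for c in CLASSES], dtype=float)
    props = props / props.sum()
    means = np.array([config.class_score_params[c][test][0] for c in CLASSES])
    sds = np.array([config.class_score_params[c][test][1] for c in CLASSES])
    m = float(props @ means)
    var = float(props @ (sds**2 + means**2)) - m * m
    return math.sqrt(var)


def subscore_columns(n: int) -> list[str]:
    """Column names of the age-scaled clock subscores."""
    return [f"dct_sub_{i + 1:02d}" for i in range(n)]


# -- calibrated truncated-normal sampling ---------------------------------


def _trunc_mean(loc: float, sd: float, low: float, high: float) -> float:
    a, b = (low - loc) / sd, (high - loc) / sd if math.isfinite(high) else math.inf
    return stats.truncnorm.mean(a, b, loc=loc, scale=sd)


def _rounded_trunc_mean(loc: float, sd: float, low: float, high: float) -> float:
    # E[round(X)] for X ~ TruncNormal(loc, sd, [low, high]); integer bounds.
    a, b = (low - loc) / sd, (high - loc) / sd
    dist = stats.truncnorm(a, b, loc=loc, scale=sd)
    ks = np.arange(int(low), int(high) + 1)
    uppers = np.minimum(ks + 0.5, high)
    lowers = np.maximum(ks - 0.5, low)
    probs = dist.cdf(uppers) - dist.cdf(lowers)
    return float(np.sum(ks * probs))


def _calibrated_loc(
    target: float, sd: float, low: float, high: float, integer: bool
) -> float:
    """Location such that the (rounded) truncated-normal mean equals target."""
    fn = _rounded_trunc_mean if integer else _trunc_mean

    def objective(loc: float) -> float:
        return fn(loc, sd, low, high) - target

    span = 10.0 * sd
    lo = (low if math.isfinite(low) else target) - span
    hi = (high if math.isfinite(high) else target) + span
    return optimize.brentq(objective, lo, hi, xtol=1e-10)


def _sample_scores(
    u: np.ndarray,
    eps: np.ndarray,
    locs: np.ndarray,
    sds: np.ndarray,
    low: float,
    high: float,
    sign: int,
    rho: float,
) -> np.ndarray:
    z = rho * sign * u + math.sqrt(1.0 - rho * rho) * eps
    p = stats.norm.cdf(z)
    # clip away exact 0/1 to keep ppf finite
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    a = (low - locs) / sds
    b = np.full_like(locs, math.inf) if not math.isfinite(high) else (high - locs) / sds
    return stats.truncnorm.ppf(p, a, b, loc=locs, scale=sds)


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Generate a synthetic population as a tidy DataFrame.

    Columns: ``participant_id, age, sex, education_years, race, ethnicity,
    ravlt_long_delay, tmtb_seconds, faq, mmse, dct_summary,
    dct_sub_01..dct_sub_NN, delayed_recall, true_state``. ``true_state`` is
    the hidden generating class, retained for recovery tests only.
    """
    config.validate()
    n = config.n_participants
    rng = np.random.default_rng(config.seed)

    props = np.array([config.cohort_mixture[c] for c in CLASSES], dtype=float)
    props = props / props.sum()
    class_idx = rng.choice(len(CLASSES), size=n, p=props)
    true_state = np.array(CLASSES, dtype=object)[class_idx]

    sex = np.where(rng.random(n) < config.sex_female_p, "female", "male")
    race = np.where(rng.random(n) < config.race_white_p, "White", "Non-White")
    ethnicity = np.where(
        rng.random(n) < config.ethnicity_hispanic_p, "Hispanic", "Non-Hispanic"
    )

    def _truncated(mean, sd, low, high, size):
        a, b = (low - mean) / sd, (high - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    age_low, age_high = config.age_range
    age = _truncated(config.age_mean, config.age_sd, age_low, age_high - 1e-9, n)
    education = _truncated(config.education_mean, config.education_sd, 0.0, 30.0, n)

    subgroup_masks = {
        "sex": sex == "female",
        "race": race == "Non-White",
        "ethnicity": ethnicity == "Hispanic",
        "education": education < config.education_split,
    }

    u = rng.standard_normal(n)
    rho = config.severity_correlation

    loc_cache: dict[tuple, float] = {}

    def calibrated(mean, sd, low, high, integer):
        key = (mean, sd, low, high, integer)
        if key not in loc_cache:
            loc_cache[key] = _calibrated_loc(mean, sd, low, high, integer)
        return loc_cache[key]

    data: dict[str, np.ndarray] = {}
    for test in SCORE_TESTS:
        low, high, integer, sign = SCORE_SPECS[test]
        # Bias shifts move the *target mean* by shift * marginal-SD for
        # affected subgroups (uniform across classes); the location is
        # re-calibrated per shifted mean so the configured subgroup mean
        # difference is exact despite truncation.
        shifts = config.bias_effects.get(test, {})
        shift_raw = np.zeros(n)
        if shifts:
            msd = marginal_sd(config, test)
            for factor, shift in shifts.items():
                shift_raw = shift_raw + np.where(
                    subgroup_masks[factor], shift * msd, 0.0
                )
        locs = np.empty(n)
        sds = np.empty(n)
        for ci, cls in enumerate(CLASSES):
            mask = class_idx == ci
            if not np.any(mask):
                continue
            mean, sd = config.class_score_params[cls][test]
            sds[mask] = sd
            for su in np.unique(shift_raw[mask]):
                target = mean + su
                if not low < target < high:
                    raise ConfigError(
                        f"bias_effects push class {cls!r} {test!r} mean to "
                        f"{target}, outside the open range ({low}, {high})"
                    )
                sub = mask & (shift_raw == su)
                locs[sub] = calibrated(target, sd, low, high, integer)
        eps = rng.standard_normal(n)
        scores = _sample_scores(u, eps, locs, sds, low, high, sign, rho)
        if integer:
            scores = np.clip(np.rint(scores), low, high)
        data[test] = scores

    # Age-scaled clock subscores: noisy positive linear transforms of the
    # summary score, clipped to [0, 100].
    n_sub = config.n_clock_subscores
    slopes = rng.uniform(0.6, 1.0, size=n_sub)
    sub_data = {}
    for i, col in enumerate(subscore_columns(n_sub)):
        base = 50.0 + slopes[i] * (data["dct_summary"] - 50.0)
        noise = rng.standard_normal(n) * config.subscore_noise_sd
        sub_data[col] = np.clip(base + noise, 0.0, 100.0)

    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education_years": education,
            "race": race,
            "ethnicity": ethnicity,
            "ravlt_long_delay": data["ravlt_long_delay"],
            "tmtb_seconds": data["tmtb_seconds"],
            "faq": data["faq"].astype(int),
            "mmse": data["mmse"].astype(int),
            "dct_summary": data["dct_summary"],
            **sub_data,
            "delayed_recall": data["delayed_recall"].astype(int),
            "true_state": true_state,
        }
    )
    return df
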
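"""Synthetic survey generator for the AI-trust / health-care-delay study.

The generator emulates a cross-sectional online survey of adults asked about
their trust in AI-generated health advice (ordinal 0-5, 0 = never used), how
often they act on such advice (ordinal 0-5), chronic-disease status, and
whether AI advice ever led them to postpone or cancel seeking care (binary).
Marginal distributions and the generating effect sizes default to the values
the downstream analyses are calibrated against:

* trust distribution with a 38% "never used" mass at level 0;
* a linear trust -> frequency link (slope 0.5754 on the latent scale,
  Gaussian noise, rounded and clamped to 0-5; frequency is identically 0
  for never-users);
* a logistic delay model with odds ratios 1.09 (per trust unit),
  1.40 (per frequency unit) and 1.42 (chronic disease), whose intercept is
  calibrated by bisection so the population delay rate matches 11.6%;
* chronic prevalence 30.1%, 54.7% female, age ~ N(34.46, 11.62) truncated
  to 18-75, four occupation categories, submission dates uniform over
  Dec 2024 - May 2025.

Records are plain :class:`pandas.DataFrame` rows with the documented column
schema (:data:`SCHEMA_COLUMNS`); real survey data in the same schema can be
fed to every downstream analysis unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "GeneratorConfig",
    "ExclusionReport",
    "SCHEMA_COLUMNS",
    "calibrate_intercept",
    "generate_population",
    "generate_raw_population",
    "apply_exclusions",
    "read_survey_csv",
    "write_survey_csv",
]

#: Column schema of a survey table, one row per respondent.
SCHEMA_COLUMNS = [
    "id",
    "age",
    "sex",
    "occupation",
    "trust",
    "frequency",
    "chronic",
    "delay",
    "exposure",
    "willingness",
    "submission_date",
    "completion_seconds",
]

OCCUPATIONS = ["students", "technology", "other", "healthcare"]

#: Minimum questionnaire completion time considered valid (seconds).
MIN_COMPLETION_SECONDS = 90.0


def _as_probs(v: Sequence[float], name: str, length: int) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (length,):
        raise ValueError(f"{name} must have length {length}, got {arr.shape}")
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be nonnegative and sum to 1 (+/-1e-9)")
    return arr


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey generator.

    Defaults reproduce the target marginals and effect sizes listed in the
    module docstring; ``intercept=None`` means "calibrate at generation time
    so the expected delay rate equals ``target_delay_rate``".
    """

    n_respondents: int = 2460
    seed: int = 1
    trust_probs: tuple = (0.380, 0.130, 0.118, 0.114, 0.140, 0.118)
    beta_trust: float = math.log(1.09)
    beta_freq: float = math.log(1.40)
    beta_chronic: float = math.log(1.42)
    intercept: float | None = None
    path_a_slope: float = 0.5754
    path_a_noise_sd: float = 2.0
    chronic_prev: float = 0.301
    target_delay_rate: float = 0.116
    female_prop: float = 0.547
    age_mean: float = 34.46
    age_sd: float = 11.62
    occupation_probs: tuple = (0.335, 0.291, 0.260, 0.114)
    exposure_probs: tuple = (0.15, 0.25, 0.30, 0.20, 0.10)
    willingness_probs: tuple = (0.15, 0.25, 0.30, 0.20, 0.10)
    date_range: tuple = (date(2024, 12, 1), date(2025, 5, 20))
    dirty_fraction: float = 0.117

    def __post_init__(self) -> None:
        if self.n_respondents < 0:
            raise ValueError("n_respondents must be nonnegative")
        _as_probs(self.trust_probs, "trust_probs", 6)
        _as_probs(self.occupation_probs, "occupation_probs", 4)
        _as_probs(self.exposure_probs, "exposure_probs", 5)
        _as_probs(self.willingness_probs, "willingness_probs", 5)
        for name in ("chronic_prev", "target_delay_rate", "female_prop",
                     "dirty_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.path_a_noise_sd <= 0:
            raise ValueError("path_a_noise_sd must be positive")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["date_range"] = [d.isoformat() for d in self.date_range]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "date_range" in d:
            d["date_range"] = tuple(date.fromisoformat(x)
                                    for x in d["date_range"])
        for key in ("trust_probs", "occupation_probs", "exposure_probs",
                    "willingness_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        """Load a config from a YAML or JSON file."""
        with open(path) as fh:
            text = fh.read()
        d = yaml.safe_load(text) if not str(path).endswith(".json") \
            else json.loads(text)
        return cls.from_dict(d)


def calibrate_intercept(coefs: Sequence[float],
                        covariates,
                        target_rate: float,
                        *,
                        tol: float = 1e-6,
                        max_iter: int = 200) -> float:
    """Find the logistic intercept matching a target mean outcome rate.

    Solves ``mean(expit(c + X @ coefs)) == target_rate`` for ``c`` by
    bisection; the mean predicted probability is strictly increasing in the
    intercept, so the root is unique.

    Parameters
    ----------
    coefs
        Slope coefficients (log odds ratios), one per covariate column.
    covariates
        Array-like of shape (n, len(coefs)); a DataFrame works.
    target_rate
        Desired mean predicted probability, strictly inside (0, 1).
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must lie strictly inside (0, 1)")
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        raise ValueError("covariate sample must be nonempty")
    lp = X @ np.asarray(coefs, dtype=float)

    def rate(c: float) -> float:
        return float(expit(c + lp).mean())

    lo, hi = -40.0, 40.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target_rate) < tol:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
    raise ArithmeticError(
        f"intercept bisection did not converge in {max_iter} iterations")


def _truncated_normal(rng, mean, sd, low, high, size):
    # rejection sampling; acceptance ~0.9 for the default age settings
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = rng.normal(mean, sd, need.size)
        ok = (draw >= low) & (draw <= high)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def generate_population(config: GeneratorConfig,
                        rng: np.random.Generator | None = None,
                        start_id: int = 0) -> pd.DataFrame:
    """Generate ``config.n_respondents`` clean survey records.

    Deterministic given ``config`` (its ``seed``) unless an explicit ``rng``
    is passed. The delay intercept is taken from ``config.intercept`` or,
    when that is None, calibrated on the generated covariates so that the
    mean delay probability equals ``config.target_delay_rate``.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_respondents
    if n == 0:
        return pd.DataFrame(columns=SCHEMA_COLUMNS)

    trust = rng.choice(6, size=n, p=np.asarray(cfg.trust_probs))
    latent = cfg.path_a_slope * trust + rng.normal(0.0, cfg.path_a_noise_sd, n)
    frequency = np.where(
        trust == 0, 0, np.clip(np.rint(latent), 0, 5)).astype(int)
    chronic = (rng.random(n) < cfg.chronic_prev).astype(int)

    covs = np.column_stack([trust, frequency, chronic]).astype(float)
    coefs = (cfg.beta_trust, cfg.beta_freq, cfg.beta_chronic)
    intercept = (cfg.intercept if cfg.intercept is not None
                 else calibrate_intercept(coefs, covs, cfg.target_delay_rate))
    p_delay = expit(intercept + covs @ np.asarray(coefs))
    delay = (rng.random(n) < p_delay).astype(int)

    age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, 18, 75, n)
    sex = np.where(rng.random(n) < cfg.female_prop, "female", "male")
    occupation = rng.choice(OCCUPATIONS, size=n,
                            p=np.asarray(cfg.occupation_probs))
    exposure = rng.choice(np.arange(1, 6), size=n,
                          p=np.asarray(cfg.exposure_probs))
    willingness = rng.choice(np.arange(1, 6), size=n,
                             p=np.asarray(cfg.willingness_probs))

    d0, d1 = cfg.date_range
    span = (d1 - d0).days
    dates = [d0 + timedelta(days=int(k)) for k in rng.integers(0, span + 1, n)]
    completion = MIN_COMPLETION_SECONDS + 1.0 + rng.gamma(4.0, 60.0, n)

    return pd.DataFrame({
        "id": np.arange(start_id, start_id + n),
        "age": np.round(age, 1),
        "sex": sex,
        "occupation": occupation,
        "trust": trust,
        "frequency": frequency,
        "chronic": chronic,
        "delay": delay,
        "exposure": exposure,
        "willingness": willingness,
        "submission_date": dates,
        "completion_seconds": np.round(completion, 1),
    })


def generate_raw_population(config: GeneratorConfig) -> pd.DataFrame:
    """Generate an uncleaned submission set including invalid records.

    Produces roughly ``n / (1 - dirty_fraction)`` submissions of which a
    ``dirty_fraction`` share violate one of the four cleaning rules (fast
    completion, duplicate id, missing value, trust/frequency inconsistency),
    so that :func:`apply_exclusions` recovers approximately
    ``config.n_respondents`` clean records.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_raw = int(round(cfg.n_respondents / (1.0 - cfg.dirty_fraction)))
    base = generate_population(
        dataclasses.replace(cfg, n_respondents=n_raw), rng=rng)
    n_dirty = n_raw - cfg.n_respondents
    if n_dirty <= 0:
        return base
    dirty_idx = rng.choice(n_raw, size=n_dirty, replace=False)
    kinds = rng.integers(0, 4, n_dirty)
    for i, kind in zip(dirty_idx, kinds):
        if kind == 0 or (kind == 1 and i == 0):   # rushed submission
            base.loc[i, "completion_seconds"] = float(rng.uniform(10, 89))
        elif kind == 1:                   # duplicate of an earlier entry
            base.loc[i, "id"] = base.loc[int(rng.integers(0, i)), "id"]
        elif kind == 2:                   # missing answer
            col = ["age", "frequency", "willingness"][int(rng.integers(0, 3))]
            base[col] = base[col].astype(float)
            base.loc[i, col] = np.nan
        else:                             # never-user reporting usage
            base.loc[i, "trust"] = 0
            base.loc[i, "frequency"] = int(rng.integers(1, 6))
            base.loc[i, "delay"] = 0
    return base


@dataclass
class ExclusionReport:
    """Counts of records removed by each cleaning rule."""

    n_input: int = 0
    n_retained: int = 0
    duplicate: int = 0
    missing: int = 0
    fast_completion: int = 0
    inconsistent: int = 0

    @property
    def n_excluded(self) -> int:
        return self.duplicate + self.missing + self.fast_completion \
            + self.inconsistent

    def to_dict(self) -> dict:
        return dataclasses.asdict(self) | {"n_excluded": self.n_excluded}


def apply_exclusions(records: pd.DataFrame
                     ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the four survey cleaning rules and report exclusion counts.

    A record is dropped if it (in this precedence order, each record counted
    once) repeats an earlier id, has any missing value, was completed in
    under 90 seconds, or reports usage frequency > 0 while trust is 0
    ("never used"). The first occurrence of a duplicated id is retained.
    """
    rep = ExclusionReport(n_input=len(records))
    if len(records) == 0:
        return records.copy(), rep

    dup = records["id"].duplicated(keep="first").to_numpy()
    missing = records.isna().any(axis=1).to_numpy()
    fast = (records["completion_seconds"].to_numpy(dtype=float)
            < MIN_COMPLETION_SECONDS)
    incons = ((records["trust"].fillna(-1).to_numpy() == 0)
              & (records["frequency"].fillna(0).to_numpy() > 0))

    reason = np.full(len(records), "", dtype=object)
    for mask, name in [(dup, "duplicate"), (missing, "missing"),
                       (fast, "fast_completion"), (incons, "inconsistent")]:
        hit = mask & (reason == "")
        reason[hit] = name
        setattr(rep, name, int(hit.sum()))

    clean = records.loc[reason == ""].reset_index(drop=True)
    rep.n_retained = len(clean)
    return clean, rep


def write_survey_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_survey_csv(path) -> pd.DataFrame:
    """Read a survey table, parsing dates and checking the column schema."""
    df = pd.read_csv(path)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey CSV is missing columns: {missing}")
    df["submission_date"] = pd.to_datetime(df["submission_date"]).dt.date
    return df
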
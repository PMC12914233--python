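"""Mediation of the trust -> delay association through usage frequency.

Classical product-of-coefficients mediation on the log-odds scale:

* path ``a`` -- ordinary least squares of usage frequency on trust
  (frequency units per trust unit);
* path ``b`` -- log-OR of delay per frequency unit from the multivariable
  logistic model that also contains trust (so ``c'``, the direct effect of
  trust, comes from the same fit);
* path ``c`` -- total-effect log-OR of trust from the logistic model with
  the mediator omitted;
* indirect effect ``a * b``, tested with the Sobel normal approximation and
  with a nonparametric bootstrap (case resampling at full n, 500 replicates
  by default, percentile intervals).

All models adjust for age, sex, and chronic-disease status. Because the
outcome model is logistic, ``c`` and ``c' + a*b`` need not agree exactly
(non-collapsibility of the odds ratio); the decomposition is reported on
the scale the component models are fitted on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .regression import LogisticFit, build_design, fit_logistic

__all__ = ["MediationResult", "estimate_paths", "sobel_test",
           "bootstrap_indirect"]

DEFAULT_ADJUSTERS = ("age", "sex", "chronic")
MAX_FAILED_FRACTION = 0.20


@dataclass
class MediationResult:
    """Paths, Sobel test and (optionally) bootstrap of the indirect effect."""

    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    c_prime: float
    sobel_z: float
    sobel_p: float
    n_obs: int
    adjusters: tuple = DEFAULT_ADJUSTERS
    boot_mean: float | None = None
    boot_ci: tuple | None = None
    boot_p: float | None = None
    n_boot: int | None = None
    n_boot_failed: int = 0
    boot_flagged: bool = False
    boot_samples: np.ndarray | None = field(default=None, repr=False)

    @property
    def indirect(self) -> float:
        return self.a * self.b

    @property
    def indirect_or(self) -> float:
        return float(np.exp(self.indirect))

    def to_dict(self) -> dict:
        d = {
            "a": self.a, "se_a": self.se_a,
            "b": self.b, "se_b": self.se_b, "b_or": float(np.exp(self.b)),
            "c": self.c, "c_or": float(np.exp(self.c)),
            "c_prime": self.c_prime,
            "c_prime_or": float(np.exp(self.c_prime)),
            "indirect": self.indirect, "indirect_or": self.indirect_or,
            "sobel_z": self.sobel_z, "sobel_p": self.sobel_p,
            "n_obs": self.n_obs, "adjusters": list(self.adjusters),
        }
        if self.n_boot is not None:
            d.update({
                "boot_mean": self.boot_mean,
                "boot_ci_low": self.boot_ci[0],
                "boot_ci_high": self.boot_ci[1],
                "boot_p": self.boot_p,
                "n_boot": self.n_boot,
                "n_boot_failed": self.n_boot_failed,
                "boot_flagged": self.boot_flagged,
                "boot_p_definition":
                    "2 * min(frac(ab <= 0), frac(ab >= 0)) over replicates",
            })
        return d


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and standard errors; X includes the intercept."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se


def _path_a(records: pd.DataFrame, adjusters) -> tuple[float, float]:
    X = build_design(records, ["trust", *adjusters])
    X = np.column_stack([np.ones(len(records)), X])
    beta, se = _ols(records["frequency"].to_numpy(float), X)
    return float(beta[1]), float(se[1])


def estimate_paths(records: pd.DataFrame,
                   adjusters=DEFAULT_ADJUSTERS) -> MediationResult:
    """Estimate paths a, b, c, c' and the Sobel test (bootstrap fields empty).

    ``a`` from OLS of frequency on trust + adjusters; ``b`` and ``c'`` from
    the logistic model delay ~ trust + frequency + adjusters; ``c`` from
    delay ~ trust + adjusters.
    """
    a, se_a = _path_a(records, adjusters)
    full: LogisticFit = fit_logistic(records, "delay",
                                     ["trust", "frequency", *adjusters])
    total: LogisticFit = fit_logistic(records, "delay",
                                      ["trust", *adjusters])
    b, se_b = full.coef("frequency"), full.se("frequency")
    z, p = sobel_test(a, se_a, b, se_b)
    return MediationResult(
        a=a, se_a=se_a, b=b, se_b=se_b,
        c=total.coef("trust"), c_prime=full.coef("trust"),
        sobel_z=z, sobel_p=p, n_obs=len(records),
        adjusters=tuple(adjusters))


def sobel_test(a: float, se_a: float, b: float, se_b: float
               ) -> tuple[float, float]:
    """Normal-approximation z-test of the product of two coefficients.

    ``z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2)``, two-sided p from the
    standard normal. Returns ``(0.0, 1.0)`` exactly when the product is 0.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    num = a * b
    if num == 0.0:
        return 0.0, 1.0
    z = num / np.sqrt(b * b * se_a * se_a + a * a * se_b * se_b)
    return float(z), float(2.0 * norm.sf(abs(z)))


def bootstrap_indirect(records: pd.DataFrame, n_boot: int = 500,
                       seed: int = 0,
                       adjusters=DEFAULT_ADJUSTERS) -> MediationResult:
    """Nonparametric bootstrap of the indirect effect ``a * b``.

    Case-resamples the records with replacement at full n; each replicate
    re-estimates paths a (OLS) and b (logistic). Percentile 2.5/97.5
    bounds; the bootstrap p-value is the doubled proportion of replicates
    on the minority side of zero. Replicates whose logistic fit fails or
    does not converge are dropped and counted; losing more than 20% of
    replicates flags the result. Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    result = estimate_paths(records, adjusters)
    rng = np.random.default_rng(seed)
    n = len(records)
    samples = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        boot = records.iloc[idx]
        try:
            a, _ = _path_a(boot, adjusters)
            full = fit_logistic(boot, "delay",
                                ["trust", "frequency", *adjusters])
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        if not full.converged:
            failed += 1
            continue
        samples.append(a * full.coef("frequency"))
    ab = np.asarray(samples)
    if ab.size == 0:
        raise ArithmeticError("all bootstrap replicates failed")
    # order-statistic percentiles: endpoints are actual replicate values
    lo, hi = np.percentile(ab, [2.5, 97.5], method="closest_observation")
    frac_le = float(np.mean(ab <= 0.0))
    frac_ge = float(np.mean(ab >= 0.0))
    return dataclasses.replace(
        result,
        boot_mean=float(ab.mean()),
        boot_ci=(float(lo), float(hi)),
        boot_p=min(1.0, 2.0 * min(frac_le, frac_ge)),
        n_boot=int(ab.size),
        n_boot_failed=failed,
        boot_flagged=failed > MAX_FAILED_FRACTION * n_boot,
        boot_samples=ab,
    )
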
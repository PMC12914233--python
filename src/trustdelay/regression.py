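"""Logistic-regression engine and the study's regression analyses.

Provides a thin, typed surface over statsmodels' binomial GLM (fitted by
iteratively reweighted least squares) plus the four analysis patterns used
throughout the study: univariate screening, hierarchical covariate blocks,
stratified models, and moderation via interaction terms. All effect sizes
are reported as odds ratios with Wald 95% confidence intervals,
``exp(beta +/- 1.96 SE)``, and two-sided Wald p-values.

Encoding conventions (recorded in each fit's metadata): sex enters as
``male`` (female = 0), occupation as one-hot indicators with ``students``
as the reference category. Ordinal trust/frequency/exposure/willingness
scores are treated as continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LogisticFit",
    "InteractionFit",
    "build_design",
    "fit_logistic",
    "univariate_screen",
    "hierarchical_models",
    "stratified_analysis",
    "interaction_model",
    "date_stratifier",
    "threshold_stratifier",
    "HIERARCHICAL_BLOCKS",
]

Z95 = 1.959963984540054          # two-sided 95% normal quantile
MAX_ABS_COEF = 15.0              # |beta| beyond this flags separation
IRLS_MAX_ITER = 100
IRLS_TOL = 1e-8

#: Covariate blocks of the hierarchical models. Model 1 holds individual
#: characteristics, model 2 adds recommendation exposure, model 3 the AI
#: usage pattern (trust + frequency), model 4 social influence
#: (willingness to recommend); model 4 is the fully adjusted model.
HIERARCHICAL_BLOCKS = {
    "model1": ["age", "sex", "chronic"],
    "model2": ["age", "sex", "chronic", "exposure"],
    "model3": ["age", "sex", "chronic", "exposure", "trust", "frequency"],
    "model4": ["age", "sex", "chronic", "exposure", "trust", "frequency",
               "willingness"],
}


@dataclass
class LogisticFit:
    """A fitted logistic regression with odds-ratio reporting."""

    outcome: str
    predictors: list[str]                 # design column names, no intercept
    coefficients: np.ndarray              # incl. intercept at position 0
    standard_errors: np.ndarray
    n_obs: int
    converged: bool
    status: str = "ok"
    llf: float = float("nan")
    metadata: dict = field(default_factory=dict)

    @property
    def param_names(self) -> list[str]:
        return ["intercept"] + self.predictors

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coefficients - Z95 * self.standard_errors)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coefficients + Z95 * self.standard_errors)

    @property
    def p_values(self) -> np.ndarray:
        from scipy.stats import norm
        z = self.coefficients / self.standard_errors
        return 2.0 * norm.sf(np.abs(z))

    def term(self, name: str) -> dict:
        """Report (coef, SE, OR, CI, p) for one design column."""
        i = self.param_names.index(name)
        return {
            "term": name,
            "coef": float(self.coefficients[i]),
            "se": float(self.standard_errors[i]),
            "or": float(self.odds_ratios[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "p": float(self.p_values[i]),
        }

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.param_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.param_names.index(name)])

    def odds_ratio(self, name: str) -> float:
        return float(self.odds_ratios[self.param_names.index(name)])

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        """Predicted probabilities for records in the survey schema."""
        X = build_design(records, self.predictors, from_design=True)
        lp = self.coefficients[0] + X @ self.coefficients[1:]
        from scipy.special import expit
        return expit(lp)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "status": self.status,
            "log_likelihood": None if np.isnan(self.llf) else float(self.llf),
            "terms": [self.term(p) for p in self.param_names],
            "metadata": self.metadata,
        }


@dataclass
class InteractionFit:
    """A logistic fit augmented with a focal x moderator interaction."""

    fit: LogisticFit
    focal: str
    moderator: str
    interaction_term: str
    probability_grid: pd.DataFrame

    def interaction(self) -> dict:
        return self.fit.term(self.interaction_term)

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "moderator": self.moderator,
            "interaction": self.interaction(),
            "fit": self.fit.to_dict(),
            "probability_grid": self.probability_grid.to_dict("records"),
        }


def _encode_column(records: pd.DataFrame, name: str) -> dict[str, np.ndarray]:
    """Translate one survey field into numeric design column(s)."""
    if name == "sex":
        return {"male": (records["sex"] == "male").to_numpy(float)}
    if name == "occupation":
        return {f"occupation_{lvl}":
                (records["occupation"] == lvl).to_numpy(float)
                for lvl in ("technology", "other", "healthcare")}
    col = records[name]
    if not np.issubdtype(np.asarray(col).dtype, np.number):
        raise ValueError(f"predictor {name!r} is not numeric")
    return {name: col.to_numpy(float)}


def build_design(records: pd.DataFrame, predictors: Sequence[str],
                 from_design: bool = False) -> np.ndarray:
    """Assemble the (n, p) design matrix, without the intercept column.

    With ``from_design=True`` the names are taken to be already-encoded
    design columns (e.g. ``male``), as stored in a fitted model.
    """
    cols: list[np.ndarray] = []
    for name in predictors:
        if from_design:
            if name == "male":
                cols.append((records["sex"] == "male").to_numpy(float)
                            if "sex" in records else
                            records["male"].to_numpy(float))
            elif name.startswith("occupation_"):
                lvl = name.split("_", 1)[1]
                cols.append((records["occupation"] == lvl).to_numpy(float)
                            if "occupation" in records else
                            records[name].to_numpy(float))
            else:
                cols.append(records[name].to_numpy(float))
        else:
            if name not in records.columns and name not in ("sex",
                                                            "occupation"):
                raise ValueError(f"required field {name!r} absent from records")
            cols.extend(_encode_column(records, name).values())
    if not cols:
        return np.empty((len(records), 0))
    return np.column_stack(cols)


def _design_names(records: pd.DataFrame, predictors: Sequence[str]
                  ) -> list[str]:
    names: list[str] = []
    for name in predictors:
        if name == "sex":
            names.append("male")
        elif name == "occupation":
            names.extend(f"occupation_{lvl}"
                         for lvl in ("technology", "other", "healthcare"))
        else:
            names.append(name)
    return names


def fit_logistic(records: pd.DataFrame, outcome: str,
                 predictors: Sequence[str],
                 metadata: dict | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression of ``outcome`` on predictors.

    Fitted with statsmodels' binomial GLM (IRLS, coefficient tolerance
    1e-8, at most 100 iterations). Degenerate designs -- a constant
    predictor, perfect separation (any |beta| > 15), or non-convergence --
    yield a fit flagged ``converged=False`` with a descriptive ``status``
    rather than an exception; a constant outcome raises ``ValueError``.
    """
    for name in list(predictors) + [outcome]:
        if name not in records.columns:
            raise ValueError(f"required field {name!r} absent from records")
    y = records[outcome].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} is constant; cannot fit")

    names = _design_names(records, predictors)
    X = build_design(records, predictors)
    Xc = sm.add_constant(X, has_constant="add")
    meta = {"encoding": {"sex": "male=1", "occupation": "ref=students"}}
    meta.update(metadata or {})

    degenerate = [nm for j, nm in enumerate(names)
                  if np.ptp(X[:, j]) == 0.0]
    if degenerate:
        k = len(names) + 1
        return LogisticFit(outcome, names, np.full(k, np.nan),
                           np.full(k, np.nan), len(records), False,
                           status=f"constant predictor: {degenerate}",
                           metadata=meta)

    try:
        res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(
            maxiter=IRLS_MAX_ITER, tol=IRLS_TOL)
    except Exception as exc:  # singular design, separation blow-ups
        k = len(names) + 1
        return LogisticFit(outcome, names, np.full(k, np.nan),
                           np.full(k, np.nan), len(records), False,
                           status=f"fit failed: {exc}", metadata=meta)

    coefs = np.asarray(res.params, float)
    ses = np.asarray(res.bse, float)
    converged = bool(res.converged)
    status = "ok"
    if np.any(np.abs(coefs) > MAX_ABS_COEF) or not np.all(np.isfinite(ses)):
        converged, status = False, "possible separation (|beta| > 15)"
    elif not converged:
        status = "IRLS did not converge"
    return LogisticFit(outcome, names, coefs, ses, len(records), converged,
                       status=status, llf=float(res.llf), metadata=meta)


def univariate_screen(records: pd.DataFrame, candidates: Sequence[str],
                      outcome: str = "delay") -> pd.DataFrame:
    """One single-predictor logistic fit per candidate variable.

    Returns a table in input order with one row per design column (so
    ``occupation`` expands to its indicator rows); degenerate candidates
    appear as flagged rows with NaN estimates.
    """
    rows = []
    for cand in candidates:
        fit = fit_logistic(records, outcome, [cand])
        for name in fit.predictors:
            t = fit.term(name) if fit.converged else {
                "term": name, "coef": np.nan, "se": np.nan, "or": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
            rows.append({"candidate": cand, **t,
                         "converged": fit.converged, "status": fit.status})
    return pd.DataFrame(rows)


def hierarchical_models(records: pd.DataFrame, outcome: str = "delay"
                        ) -> dict[str, LogisticFit]:
    """The four nested covariate-block models (see HIERARCHICAL_BLOCKS)."""
    fits = {}
    for label, block in HIERARCHICAL_BLOCKS.items():
        fits[label] = fit_logistic(records, outcome, block,
                                   metadata={"model": label,
                                             "covariates": list(block)})
    return fits


def date_stratifier(cutoff: date, column: str = "submission_date"
                    ) -> Callable[[pd.DataFrame], pd.Series]:
    """Partition records into pre/post strata at a calendar cutoff."""
    def strat(records: pd.DataFrame) -> pd.Series:
        dates = pd.to_datetime(records[column])
        return pd.Series(np.where(dates < pd.Timestamp(cutoff),
                                  "pre", "post"), index=records.index)
    return strat


def threshold_stratifier(column: str, threshold: float,
                         labels: tuple[str, str] = ("low", "high")
                         ) -> Callable[[pd.DataFrame], pd.Series]:
    """Partition records at ``column <= threshold`` vs above."""
    def strat(records: pd.DataFrame) -> pd.Series:
        return pd.Series(np.where(records[column] <= threshold,
                                  labels[0], labels[1]), index=records.index)
    return strat


def stratified_analysis(records: pd.DataFrame,
                        stratifier: Callable[[pd.DataFrame], pd.Series],
                        outcome: str, predictors: Sequence[str]
                        ) -> dict[str, LogisticFit]:
    """Fit the same model separately inside each stratum.

    The stratifier maps the record table to a label per record and must
    produce at least two nonempty strata. Strata whose outcome is constant
    are reported as flagged entries instead of fits.
    """
    labels = stratifier(records)
    groups = {str(lbl): records.loc[labels == lbl]
              for lbl in pd.unique(labels)}
    groups = {k: g for k, g in groups.items() if len(g)}
    if len(groups) < 2:
        raise ValueError("stratifier produced fewer than two nonempty strata")
    out: dict[str, LogisticFit] = {}
    for lbl, grp in groups.items():
        try:
            out[lbl] = fit_logistic(grp, outcome, predictors,
                                    metadata={"stratum": lbl})
        except ValueError as exc:
            k = len(_design_names(grp, predictors)) + 1
            out[lbl] = LogisticFit(outcome, _design_names(grp, predictors),
                                   np.full(k, np.nan), np.full(k, np.nan),
                                   len(grp), False, status=str(exc),
                                   metadata={"stratum": lbl})
    return out


def interaction_model(records: pd.DataFrame, focal: str, moderator_col: str,
                      adjusters: Sequence[str], outcome: str = "delay",
                      moderator_rule: Callable[[pd.Series], np.ndarray]
                      | None = None,
                      grid_values: Sequence[float] | None = None
                      ) -> InteractionFit:
    """Moderation analysis with a focal x moderator product term.

    ``moderator_rule`` dichotomises the moderator column (default:
    ``> median`` split is *not* assumed -- pass e.g. ``lambda s: s > 2``);
    identity is used if the column is already 0/1. Emits a predicted
    probability grid over focal values for each moderator level, with
    adjusters held at their sample means.
    """
    work = records.copy()
    mod = work[moderator_col]
    binary = moderator_rule(mod).astype(float) if moderator_rule is not None \
        else mod.to_numpy(float)
    if set(np.unique(binary)) - {0.0, 1.0}:
        raise ValueError("moderator must be binary after the grouping rule")
    if np.ptp(binary) == 0.0:
        raise ValueError("moderator is constant after the grouping rule")

    mod_name = f"{moderator_col}_high"
    inter_name = f"{focal}_x_{mod_name}"
    work[mod_name] = binary
    work[inter_name] = work[focal].to_numpy(float) * binary
    predictors = [focal, mod_name, inter_name, *adjusters]
    fit = fit_logistic(work, outcome, predictors,
                       metadata={"moderator_source": moderator_col})

    if grid_values is None:
        vals = work[focal].to_numpy(float)
        grid_values = np.arange(np.floor(vals.min()), np.ceil(vals.max()) + 1)
    grid_rows = []
    adj_names = _design_names(work, adjusters)
    adj_X = build_design(work, adjusters)
    adj_means = adj_X.mean(axis=0) if adj_X.size else np.array([])
    for level in (0.0, 1.0):
        for v in grid_values:
            row = {focal: float(v), mod_name: level,
                   inter_name: float(v) * level}
            for nm, mean in zip(adj_names, adj_means):
                row[nm] = float(mean)
            grid_rows.append(row)
    grid = pd.DataFrame(grid_rows)
    if fit.converged:
        X = grid[fit.predictors].to_numpy(float)
        from scipy.special import expit
        grid["predicted_probability"] = expit(
            fit.coefficients[0] + X @ fit.coefficients[1:])
    else:
        grid["predicted_probability"] = np.nan
    return InteractionFit(fit, focal, mod_name, inter_name, grid)
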
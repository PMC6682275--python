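"""Linear baseline models of city-hour sentiment proportions.

Each model regresses a cell-level sentiment proportion (positive or
negative) on a chosen subset of factors: city, hour of day, day of week and
weather enter as dummy-coded categoricals against fixed reference levels
(first city alphabetically, hour 0, Monday, clear weather); the social share
of the cell enters as a continuous covariate; an intercept is always
included.  Fitting is ordinary least squares, unweighted by default, with an
optional per-cell tweet-count weighting.

Model quality is reported two ways, mirroring how such baselines are
compared in practice: the training-period r-squared (as a percentage of
variance explained) and the Pearson correlation between predicted and
observed proportions on a temporally held-out test period, with a 95%
Fisher-z confidence interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

FACTORS = ("city", "hour", "dow", "weather", "social")

#: Column in the cell table backing each categorical factor.
_FACTOR_COLUMNS = {"city": "city", "hour": "local_hour", "dow": "dow", "weather": "weather"}

#: The standard comparison family: all factors, three nested combinations,
#: then each factor alone.
STANDARD_FACTOR_SUBSETS: dict[str, tuple[str, ...]] = {
    "All factors": ("social", "city", "hour", "dow", "weather"),
    "Social, city, hour, day": ("social", "city", "hour", "dow"),
    "Social, city": ("social", "city"),
    "Hour, day": ("hour", "dow"),
    "City": ("city",),
    "Hour of day": ("hour",),
    "Day of week": ("dow",),
    "Weather": ("weather",),
    "Social proportion": ("social",),
}


@dataclass(frozen=True)
class ModelSpec:
    """Outcome and factor subset for one baseline model."""

    outcome: str  # "p_pos" or "p_neg"
    factors: tuple[str, ...] = ()
    reference_levels: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in ("p_pos", "p_neg"):
            raise ValueError(f"outcome must be p_pos or p_neg, got {self.outcome!r}")
        unknown = set(self.factors) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown factors: {sorted(unknown)}")


def _levels_from_cells(cells: pd.DataFrame, spec: ModelSpec) -> dict[str, list]:
    """Ordered level lists per categorical factor, reference level first.

    Hour, day-of-week and weather have fixed canonical level sets, so
    coefficient counts do not depend on which levels happen to be observed;
    city levels are learned from the training cells.
    """
    from .synth import WEATHER_CATEGORIES

    canonical = {
        "hour": list(range(24)),
        "dow": list(range(7)),
        "weather": list(WEATHER_CATEGORIES),
    }
    levels: dict[str, list] = {}
    for factor in spec.factors:
        if factor == "social":
            continue
        if factor == "city":
            pool = sorted(cells[_FACTOR_COLUMNS[factor]].unique())
        else:
            pool = canonical[factor]
        default_ref = pool[0] if factor == "city" else {"hour": 0, "dow": 0,
                                                        "weather": "clear"}[factor]
        ref = spec.reference_levels.get(factor, default_ref)
        if ref not in pool:
            pool = [ref] + pool
        levels[factor] = [ref] + [lv for lv in pool if lv != ref]
    return levels


def build_design(
    cells: pd.DataFrame,
    spec: ModelSpec,
    levels: dict[str, list] | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list]]:
    """Build the dummy-coded design matrix and response vector.

    ``levels`` fixes the categorical levels (as learned at training time);
    when predicting, a level unseen in training maps to the reference with a
    warning.  Returns ``(X, y, levels)`` with deterministic column order:
    intercept, then each factor's dummies in level order, then the social
    share.
    """
    if levels is None:
        levels = _levels_from_cells(cells, spec)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(cells))}
    for factor in spec.factors:
        if factor == "social":
            continue
        col = _FACTOR_COLUMNS[factor]
        ordered = levels[factor]
        known = set(ordered)
        values = cells[col]
        n_unseen = int((~values.isin(known)).sum())
        if n_unseen:
            logger.warning(
                "build_design: %d cells have unseen %s levels; mapped to reference %r",
                n_unseen, factor, ordered[0],
            )
        for lv in ordered[1:]:  # reference level is absorbed by the intercept
            cols[f"{factor}[{lv}]"] = (values == lv).to_numpy(dtype=float)
    if "social" in spec.factors:
        cols["p_social"] = cells["p_social"].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=cells.index)
    y = cells[spec.outcome].astype(float)
    return X, y, levels


@dataclass
class FittedModel:
    """An OLS fit of one ModelSpec, with everything needed to predict."""

    spec: ModelSpec
    levels: dict[str, list]
    coefficients: pd.Series
    p_values: pd.Series
    r2_train: float  # percentage
    std_errors: pd.Series | None = None
    df_resid: float | None = None

    @property
    def n_coefficients(self) -> int:
        return len(self.coefficients)

    @property
    def n_significant(self) -> int:
        return int((self.p_values < 0.05).sum())

    def predict(self, cells: pd.DataFrame) -> np.ndarray:
        X, _, _ = build_design(cells, self.spec, levels=self.levels)
        return X.to_numpy() @ self.coefficients.to_numpy()

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Per-coefficient t-based confidence intervals."""
        if self.std_errors is None or self.df_resid is None:
            raise ValueError("model was fitted without standard errors")
        half = stats.t.ppf(0.5 + level / 2, self.df_resid) * self.std_errors
        return pd.DataFrame(
            {"low": self.coefficients - half, "high": self.coefficients + half}
        )

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "factors": list(self.spec.factors),
            "levels": {k: list(map(str, v)) for k, v in self.levels.items()},
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "r2_train": self.r2_train,
            "n_coefficients": self.n_coefficients,
            "n_significant": self.n_significant,
        }


def fit(cells_train: pd.DataFrame, spec: ModelSpec, weight_by_n: bool = False) -> FittedModel:
    """Fit the baseline model by (optionally n-weighted) least squares.

    Raises on rank deficiency, naming the collinear design columns.
    """
    X, y, levels = build_design(cells_train, spec)
    if len(X) < X.shape[1]:
        raise ValueError(f"{len(X)} cells cannot identify {X.shape[1]} coefficients")
    A = X.to_numpy()
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        _, _, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
        collinear = sorted(X.columns[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear terms: {collinear}")
    if weight_by_n:
        model = sm.WLS(y.to_numpy(), A, weights=cells_train["n"].to_numpy(dtype=float))
    else:
        model = sm.OLS(y.to_numpy(), A)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # perfect fits: zero residual variance
        res = model.fit()
        p_values = pd.Series(np.asarray(res.pvalues), index=X.columns)
    if np.ptp(y.to_numpy()) == 0.0:
        r2 = 0.0  # constant response: variance explained is undefined, report none
    else:
        r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 0.0
    return FittedModel(
        spec=spec,
        levels=levels,
        coefficients=pd.Series(np.asarray(res.params), index=X.columns),
        p_values=p_values.fillna(0.0),
        r2_train=100.0 * r2,
        std_errors=pd.Series(np.asarray(res.bse), index=X.columns),
        df_resid=float(res.df_resid),
    )


@dataclass(frozen=True)
class EvaluationResult:
    """Held-out Pearson correlation with its 95% Fisher-z interval."""

    pearson_r: float
    ci_low: float
    ci_high: float
    n_test_cells: int
    degenerate: bool = False  # constant predictions: r reported as 0


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a Pearson correlation via the Fisher z transform."""
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    # keep the point estimate inside the interval at the |r| = 1 boundary
    return float(min(np.tanh(z - half), r)), float(max(np.tanh(z + half), r))


def evaluate(model: FittedModel, cells_test: pd.DataFrame) -> EvaluationResult:
    """Correlate model predictions with observed proportions on held-out cells.

    Constant prediction vectors (e.g. an intercept-only model) leave the
    correlation undefined; those are reported as r = 0 with a degenerate
    flag so baselines remain comparable rather than erroring.
    """
    if len(cells_test) < 4:
        raise ValueError("need at least 4 test cells to evaluate")
    pred = model.predict(cells_test)
    obs = cells_test[model.spec.outcome].to_numpy(dtype=float)
    if np.ptp(pred) == 0.0 or np.ptp(obs) == 0.0:
        return EvaluationResult(0.0, 0.0, 0.0, len(cells_test), degenerate=True)
    r = float(stats.pearsonr(pred, obs).statistic)
    lo, hi = fisher_ci(r, len(cells_test))
    return EvaluationResult(r, lo, hi, len(cells_test))


def model_family(
    cells_train: pd.DataFrame,
    cells_test: pd.DataFrame,
    outcome: str,
    factor_subsets: Mapping[str, Sequence[str]] | None = None,
    weight_by_n: bool = False,
) -> tuple[pd.DataFrame, dict[str, FittedModel]]:
    """Fit and evaluate a family of factor subsets for one outcome.

    Returns a comparison table (one row per subset, in the given order) and
    the fitted models keyed by subset label.
    """
    subsets = dict(factor_subsets) if factor_subsets is not None else dict(STANDARD_FACTOR_SUBSETS)
    if not subsets:
        raise ValueError("need at least one factor subset")
    rows = []
    models: dict[str, FittedModel] = {}
    for label, factors in subsets.items():
        spec = ModelSpec(outcome=outcome, factors=tuple(factors))
        m = fit(cells_train, spec, weight_by_n=weight_by_n)
        ev = evaluate(m, cells_test)
        models[label] = m
        rows.append(
            {
                "model": label,
                "n_coefficients": m.n_coefficients,
                "n_significant": m.n_significant,
                "r2_train_pct": m.r2_train,
                "pearson_r": ev.pearson_r,
                "ci_low": ev.ci_low,
                "ci_high": ev.ci_high,
                "n_test_cells": ev.n_test_cells,
            }
        )
    return pd.DataFrame(rows), models
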
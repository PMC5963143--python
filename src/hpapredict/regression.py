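"""Hybrid-performance regression and testcross cross-validation.

The simple predictor regresses the trait on a single binary-distance
predictor (ordinary least squares, intercept + slope)::

    Y(i,j) = b0 + b1 * D_b(i,j)

The multivariate model (MLR) uses four predictors::

    Y_m(i,j) = b0 + b1*D_b,pos + b2*D_b,neg + b3*m_f + b4*m_d

Cross-validation follows the testcross scenarios of hybrid breeding: per
run, 3 Flint and 5 Dent lines form the estimation set; validation hybrids
are all crosses among the remaining lines.  Training hybrids depend on the
scheme:

* type-2: every hybrid with at least one estimation-line parent (both
  parents of each validation hybrid then appear in training testcrosses);
* type-1: one heterotic group, drawn at random per run, is "tested" - the
  training set crosses all lines of the tested group with the estimation
  lines of the other group;
* type-0: only the estimation x estimation crosses (no validation parent
  has testcross data).

Marker association and selection are re-run on the training hybrids of each
run; runs without associated markers in a direction the predictor requires
are recorded as failures and excluded from the accuracy mean, with the
success count reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .association import BinomialTraitAssociation, _as_calls, _as_traits
from .datatypes import DifferentialCalls, MatingDesign, TraitTable, ValidationError
from .distances import MF_UNDEFINED_FILL, predictor_table

logger = logging.getLogger(__name__)

__all__ = [
    "FitError",
    "RegressionModel",
    "fit_simple",
    "fit_mlr",
    "HybridPerformanceRegressor",
    "CVRun",
    "cross_validate",
    "summarize_cv",
    "PREDICTOR_SETS",
    "SCHEMES",
]

PREDICTOR_SETS = ("D_b_pos", "D_b_neg", "D_b_com", "MLR")
SCHEMES = ("type2", "type1", "type0")

MLR_COLUMNS = ["D_b_pos", "D_b_neg", "m_f", "m_d"]


class FitError(RuntimeError):
    """Model cannot be fitted (no markers, zero variance, too few hybrids)."""


@dataclass
class RegressionModel:
    """Fitted OLS model with diagnostics."""

    kind: str  # 'simple' or 'MLR'
    predictor_names: list[str]
    intercept: float
    coefficients: np.ndarray
    r_squared: float
    resid_sd: float

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        arr = (
            X[self.predictor_names].to_numpy(float)
            if isinstance(X, pd.DataFrame)
            else np.atleast_2d(np.asarray(X, float))
        )
        return self.intercept + arr @ self.coefficients


def _ols(X: np.ndarray, y: np.ndarray, names: list[str], kind: str) -> RegressionModel:
    design = sm.add_constant(X, has_constant="add")
    if design.shape[0] <= design.shape[1] - 1:
        raise FitError(f"{kind}: fewer hybrids than coefficients")
    res = sm.OLS(y, design).fit()
    params = np.asarray(res.params, float)
    return RegressionModel(
        kind=kind,
        predictor_names=list(names),
        intercept=float(params[0]),
        coefficients=params[1:],
        r_squared=float(res.rsquared) if y.var() > 0 else float("nan"),
        resid_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
    )


def fit_simple(distances: pd.Series | np.ndarray, traits: pd.Series | np.ndarray,
               name: str = "D_b_com") -> RegressionModel:
    """OLS of the trait on one binary-distance predictor."""
    x = np.asarray(distances, float)
    y = np.asarray(traits, float)
    if len(x) < 3:
        raise FitError("simple regression needs >=3 training hybrids")
    if np.ptp(x) == 0:
        raise FitError("predictor has zero variance")
    return _ols(x[:, None], y, [name], "simple")


def fit_mlr(predictors: pd.DataFrame, traits: pd.Series | np.ndarray) -> RegressionModel:
    """OLS on D_b,pos, D_b,neg, m_f, m_d; constant columns are dropped with a warning."""
    y = np.asarray(traits, float)
    if len(predictors) < 6:
        raise FitError("multivariate regression needs >=6 training hybrids")
    cols = [c for c in MLR_COLUMNS if c in predictors.columns]
    X = predictors[cols].to_numpy(float)
    if np.isnan(X).any():
        raise FitError("undefined predictor values (missing direction)")
    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
    if len(keep) < len(cols):
        dropped = [cols[i] for i in range(len(cols)) if i not in keep]
        warnings.warn(f"dropping constant predictor column(s): {dropped}")
    if not keep:
        raise FitError("all predictors constant")
    names = [cols[i] for i in keep]
    return _ols(X[:, keep], y, names, "MLR")


class HybridPerformanceRegressor(RegressorMixin, BaseEstimator):
    """Trait prediction from parental differentiality calls.

    ``fit(X, y)`` takes the hybrid x marker boolean differentiality table
    (``DifferentialCalls`` or DataFrame indexed by hybrid) and the hybrid
    trait values.  Fitting (i) splits the training hybrids into low/high
    trait classes, (ii) selects trait-associated markers by the
    FDR-controlled binomial test, (iii) computes the distance predictors
    over the selected markers and (iv) fits the OLS model of the chosen
    predictor set.  ``predict(X)`` evaluates the model on new hybrids'
    calls using the markers selected during training.

    Parameters
    ----------
    predictor : {'D_b_pos', 'D_b_neg', 'D_b_com', 'MLR'}
    fdr_level : float, default 0.05
    direction_convention : {'high_enriched', 'low_enriched'}
    mf_fill : float, default 0.5
        m_f value for hybrids with no differential associated marker.
    """

    def __init__(
        self,
        predictor: str = "D_b_com",
        fdr_level: float = 0.05,
        direction_convention: str = "high_enriched",
        mf_fill: float = MF_UNDEFINED_FILL,
    ):
        self.predictor = predictor
        self.fdr_level = fdr_level
        self.direction_convention = direction_convention
        self.mf_fill = mf_fill

    def fit(self, X, y) -> "HybridPerformanceRegressor":
        if self.predictor not in PREDICTOR_SETS:
            raise ValidationError(f"unknown predictor set {self.predictor!r}")
        calls = _as_calls(X)
        traits = _as_traits(y, calls)
        assoc = BinomialTraitAssociation(
            fdr_level=self.fdr_level,
            direction_convention=self.direction_convention,
        ).fit(calls, traits)
        self.association_ = assoc
        self.positive_markers_ = assoc.positive_
        self.negative_markers_ = assoc.negative_
        _check_required_markers(self.predictor, assoc.positive_, assoc.negative_)
        train = predictor_table(
            calls, assoc.positive_, assoc.negative_, mf_fill=self.mf_fill
        )
        y_arr = traits.values.loc[calls.calls.index].to_numpy(float)
        if self.predictor == "MLR":
            self.model_ = fit_mlr(train, y_arr)
        else:
            self.model_ = fit_simple(train[self.predictor], y_arr, name=self.predictor)
        self.coef_ = self.model_.coefficients
        self.intercept_ = self.model_.intercept
        self.n_features_in_ = len(calls.markers)
        return self

    def _predictors(self, X) -> pd.DataFrame:
        calls = _as_calls(X)
        missing = (
            set(self.positive_markers_) | set(self.negative_markers_)
        ) - set(calls.markers)
        if missing:
            raise ValidationError(f"calls lack selected markers: {sorted(missing)[:5]} ...")
        return predictor_table(
            calls, self.positive_markers_, self.negative_markers_, mf_fill=self.mf_fill
        )

    def predict(self, X) -> np.ndarray:
        table = self._predictors(X)
        if self.predictor == "MLR":
            return self.model_.predict(table)
        return self.model_.predict(table[[self.predictor]])


def _check_required_markers(predictor: str, positive, negative) -> None:
    n_pos, n_neg = len(positive), len(negative)
    if n_pos + n_neg == 0:
        raise FitError("no associated markers")
    if predictor in ("D_b_pos", "MLR") and n_pos == 0:
        raise FitError("no positively associated markers")
    if predictor in ("D_b_neg", "MLR") and n_neg == 0:
        raise FitError("no negatively associated markers")


@dataclass
class CVRun:
    """One cross-validation run (all predictor sets share the marker selection)."""

    run: int
    scheme: str
    estimation_flint: tuple[str, ...]
    estimation_dent: tuple[str, ...]
    tested_group: str | None
    n_training: int
    n_validation: int
    n_positive: int
    n_negative: int
    accuracy: dict[str, float]
    failed: dict[str, str]


def _training_hybrids(
    design: MatingDesign,
    est_flint: set[str],
    est_dent: set[str],
    scheme: str,
    tested_group: str | None,
) -> list[tuple[str, str]]:
    if scheme == "type2":
        return [
            (f, d) for f, d in design.hybrids if f in est_flint or d in est_dent
        ]
    if scheme == "type1":
        if tested_group == "Flint":
            # every Flint line is tested via crosses to estimation Dent lines
            return [(f, d) for f, d in design.hybrids if d in est_dent]
        return [(f, d) for f, d in design.hybrids if f in est_flint]
    if scheme == "type0":
        return [
            (f, d) for f, d in design.hybrids if f in est_flint and d in est_dent
        ]
    raise ValidationError(f"unknown scheme {scheme!r}")


def cross_validate(
    calls: DifferentialCalls,
    design: MatingDesign,
    traits: TraitTable,
    scheme: str = "type2",
    predictor_sets: tuple[str, ...] = PREDICTOR_SETS,
    n_runs: int = 100,
    n_estimation_flint: int = 3,
    n_estimation_dent: int = 5,
    fdr_level: float = 0.05,
    direction_convention: str = "high_enriched",
    mf_fill: float = MF_UNDEFINED_FILL,
    seed: int | np.random.SeedSequence | None = None,
) -> list[CVRun]:
    """Run the testcross cross-validation scheme.

    Per run the estimation lines are drawn at random, marker association is
    re-run on the training hybrids only, one model per predictor set is
    fitted, and the prediction accuracy is the Pearson correlation of
    observed and predicted trait values over the validation hybrids.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    for p in predictor_sets:
        if p not in PREDICTOR_SETS:
            raise ValidationError(f"unknown predictor set {p!r}")
    if n_estimation_flint >= len(design.flint_lines) or n_estimation_dent >= len(
        design.dent_lines
    ):
        raise ValidationError("estimation set leaves no validation lines")
    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    runs: list[CVRun] = []
    for i, child in enumerate(master.spawn(n_runs)):
        rng = np.random.default_rng(child)
        est_flint = set(rng.choice(design.flint_lines, n_estimation_flint, replace=False))
        est_dent = set(rng.choice(design.dent_lines, n_estimation_dent, replace=False))
        tested_group = (
            str(rng.choice(["Flint", "Dent"])) if scheme == "type1" else None
        )
        validation = [
            (f, d)
            for f, d in design.hybrids
            if f not in est_flint and d not in est_dent
        ]
        training = _training_hybrids(design, est_flint, est_dent, scheme, tested_group)
        training = [h for h in training if h in traits.values.index]
        validation = [h for h in validation if h in traits.values.index]
        run = _run_one(
            i, scheme, calls, traits, training, validation,
            est_flint, est_dent, tested_group, predictor_sets,
            fdr_level, direction_convention, mf_fill,
        )
        runs.append(run)
    return runs


def _run_one(
    i, scheme, calls, traits, training, validation,
    est_flint, est_dent, tested_group, predictor_sets,
    fdr_level, direction_convention, mf_fill,
) -> CVRun:
    accuracy: dict[str, float] = {}
    failed: dict[str, str] = {}
    n_pos = n_neg = 0
    try:
        train_calls = calls.restrict(training)
        assoc = BinomialTraitAssociation(
            fdr_level=fdr_level, direction_convention=direction_convention
        ).fit(train_calls, traits.values.loc[train_calls.calls.index].to_numpy(float))
        n_pos, n_neg = len(assoc.positive_), len(assoc.negative_)
    except ValidationError as exc:
        for p in predictor_sets:
            failed[p] = str(exc)
        return CVRun(i, scheme, tuple(sorted(est_flint)), tuple(sorted(est_dent)),
                     tested_group, len(training), len(validation), 0, 0, accuracy, failed)

    y_train = traits.values.loc[train_calls.calls.index].to_numpy(float)
    val_calls = calls.restrict(validation)
    y_val = traits.values.loc[val_calls.calls.index].to_numpy(float)
    train_table = val_table = None
    if n_pos + n_neg > 0:
        train_table = predictor_table(train_calls, assoc.positive_, assoc.negative_, mf_fill)
        val_table = predictor_table(val_calls, assoc.positive_, assoc.negative_, mf_fill)

    for p in predictor_sets:
        try:
            _check_required_markers(p, assoc.positive_, assoc.negative_)
            if p == "MLR":
                model = fit_mlr(train_table, y_train)
                pred = model.predict(val_table)
            else:
                model = fit_simple(train_table[p], y_train, name=p)
                pred = model.predict(val_table[[p]])
            if np.ptp(pred) == 0 or np.ptp(y_val) == 0:
                raise FitError("constant predictions or trait in validation set")
            accuracy[p] = float(stats.pearsonr(y_val, pred)[0])
        except FitError as exc:
            failed[p] = str(exc)
    return CVRun(
        i, scheme, tuple(sorted(est_flint)), tuple(sorted(est_dent)), tested_group,
        len(training), len(validation), n_pos, n_neg, accuracy, failed,
    )


def summarize_cv(runs: list[CVRun]) -> pd.DataFrame:
    """Mean +/- SD accuracy and success count per predictor set (failed runs excluded)."""
    if not runs:
        raise ValidationError("no CV runs to summarize")
    rows = []
    predictors = sorted({p for r in runs for p in (*r.accuracy, *r.failed)})
    for p in predictors:
        acc = np.array([r.accuracy[p] for r in runs if p in r.accuracy])
        rows.append(
            {
                "predictor": p,
                "scheme": runs[0].scheme,
                "mean_accuracy": float(acc.mean()) if acc.size else float("nan"),
                "sd_accuracy": float(acc.std(ddof=1)) if acc.size > 1 else float("nan"),
                "n_success": int(acc.size),
                "n_runs": len(runs),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def runs_to_frame(runs: list[CVRun]) -> pd.DataFrame:
    """Flat per-run table (one row per run x predictor set)."""
    rows = []
    for r in runs:
        for p in sorted({*r.accuracy, *r.failed}):
            rows.append(
                {
                    "run": r.run,
                    "scheme": r.scheme,
                    "predictor": p,
                    "accuracy": r.accuracy.get(p, float("nan")),
                    "failed": p in r.failed,
                    "reason": r.failed.get(p, ""),
                    "n_positive": r.n_positive,
                    "n_negative": r.n_negative,
                    "tested_group": r.tested_group or "",
                }
            )
    return pd.DataFrame(rows)
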
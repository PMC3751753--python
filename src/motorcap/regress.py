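"""Linear capacity-rating model with significance-gated features.

The rating model is ordinary least squares, ``y(x, w) = w0 + sum_j w_j x_j``,
on features and targets min-max standardized to [0, 1].  To limit
over-fitting on small clinical datasets, only features whose coefficient is
significantly non-zero (t-test, p < alpha) are retained, and the model is
refit once on the retained set.  Evaluation is leave-one-session-out (LOSO):
folds are (subject, week) assessments, left- and right-hand executions of a
task share a fold and a model, and all held-out predictions are pooled into
one RMSE / Pearson-r summary.

:class:`CapacityRegressor` follows the scikit-learn estimator contract
(``fit``/``predict``, ``get_params``/``set_params``, trailing-underscore
fitted attributes) and composes with scikit-learn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.utils.validation import check_is_fitted

from .types import SINGLE_HAND_TASKS, RatedInstance, TaskClass

__all__ = [
    "CapacityRegressor",
    "EvaluationResult",
    "minmax_fit_transform",
    "minmax_apply",
    "loso_cv",
    "evaluate",
    "pooled_generalization",
]


def minmax_fit_transform(
    X, feature_names: list[str] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Min-max scale training columns onto [0, 1]; returns (scaled, (min, max)).

    A constant column cannot be scaled and is rejected by name.
    """
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    constant = np.flatnonzero(hi <= lo)
    if len(constant):
        names = feature_names or [f"x{j}" for j in range(X.shape[1])]
        raise ValueError(
            "constant training feature(s): " + ", ".join(names[j] for j in constant)
        )
    return (X - lo) / (hi - lo), (lo, hi)


def minmax_apply(scaler: tuple[np.ndarray, np.ndarray], X) -> np.ndarray:
    """Apply training bounds to new data; values may fall outside [0, 1]."""
    lo, hi = scaler
    return (np.asarray(X, dtype=float) - lo) / (hi - lo)


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    if y.shape != (X.shape[0],):
        raise ValueError(f"y shape {y.shape} does not match X rows {X.shape[0]}")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("X and y must be finite")
    return X, y


class CapacityRegressor(RegressorMixin, BaseEstimator):
    """Min-max-scaled OLS with per-coefficient significance gating.

    Parameters
    ----------
    alpha : float
        Significance level of the per-coefficient t-test; features with
        p >= alpha are dropped.
    gate : bool
        Disable to keep every feature (plain scaled OLS).
    selection : {"single", "backward"}
        ``"single"`` drops every non-significant feature at once and refits
        once.  ``"backward"`` eliminates the least significant feature one
        at a time until all retained coefficients are significant — more
        robust when many correlated features share the signal, as on small
        samples the one-shot test can discard all of them.
    scale_target : bool
        Min-max scale the target on the training data; predictions are
        mapped back to the original scale.

    Attributes
    ----------
    intercept_, coef_ : weights in the scaled space (dropped features have
        coefficient 0).
    pvalues_ : per-feature p-values of the initial full fit.
    support_ : boolean retained-feature mask.
    x_min_, x_max_, y_min_, y_max_ : training scaler bounds.
    intercept_only_ : True when every feature was dropped.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        gate: bool = True,
        selection: str = "single",
        scale_target: bool = True,
    ):
        self.alpha = alpha
        self.gate = gate
        self.selection = selection
        self.scale_target = scale_target

    # -- scaling -----------------------------------------------------------
    def _scale_X(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_min_) / (self.x_max_ - self.x_min_)

    def fit(self, X, y, feature_names: list[str] | None = None) -> "CapacityRegressor":
        X, y = _validate_xy(X, y)
        n, k = X.shape
        if n <= k + 1:
            raise ValueError(
                f"need more rows than features + 1 to fit: n={n}, features={k}"
            )
        names = list(feature_names) if feature_names is not None else [
            f"x{j}" for j in range(k)
        ]
        if len(names) != k:
            raise ValueError("feature_names length does not match X columns")
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = k

        self.x_min_ = X.min(axis=0)
        self.x_max_ = X.max(axis=0)
        constant = np.flatnonzero(self.x_max_ <= self.x_min_)
        if len(constant):
            bad = ", ".join(names[j] for j in constant)
            raise ValueError(f"constant training feature(s): {bad}")
        if self.scale_target:
            self.y_min_, self.y_max_ = float(y.min()), float(y.max())
            if self.y_max_ <= self.y_min_:
                raise ValueError("target is constant on the training data")
        else:
            self.y_min_, self.y_max_ = 0.0, 1.0
        Xs = self._scale_X(X)
        ys = (y - self.y_min_) / (self.y_max_ - self.y_min_)

        design = sm.add_constant(Xs, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            # name the columns involved in the deficiency via correlations
            corr = np.corrcoef(Xs, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            pairs = np.argwhere(np.abs(corr) > 1 - 1e-10)
            involved = sorted({names[j] for p in pairs for j in p}) or names
            raise ValueError(f"rank-deficient design; collinear feature(s): {involved}")
        if self.selection not in ("single", "backward"):
            raise ValueError(
                f"selection must be 'single' or 'backward', got {self.selection!r}"
            )
        full = sm.OLS(ys, design).fit()
        self.pvalues_ = np.asarray(full.pvalues[1:], dtype=float)

        if not self.gate:
            support = np.ones(k, dtype=bool)
        elif self.selection == "single":
            support = np.nan_to_num(self.pvalues_, nan=1.0) < self.alpha
        else:
            support = np.ones(k, dtype=bool)
            while support.any():
                sel = np.flatnonzero(support)
                fit = sm.OLS(ys, sm.add_constant(Xs[:, sel], has_constant="add")).fit()
                p = np.nan_to_num(np.asarray(fit.pvalues[1:], dtype=float), nan=1.0)
                worst = int(np.argmax(p))
                if p[worst] < self.alpha:
                    break
                support[sel[worst]] = False
        self.support_ = support
        self.intercept_only_ = not support.any()
        self.coef_ = np.zeros(k)
        if self.intercept_only_:
            self.intercept_ = float(ys.mean())
        elif support.all():
            self.intercept_ = float(full.params[0])
            self.coef_[:] = full.params[1:]
        else:  # refit once on the retained features
            reduced = sm.OLS(
                ys, sm.add_constant(Xs[:, support], has_constant="add")
            ).fit()
            self.intercept_ = float(reduced.params[0])
            self.coef_[support] = reduced.params[1:]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have shape (n, {self.n_features_in_}), got {X.shape}"
            )
        ys = self.intercept_ + self._scale_X(X) @ self.coef_
        return self.y_min_ + (self.y_max_ - self.y_min_) * ys

    def raw_coefficients(self) -> tuple[float, np.ndarray]:
        """Intercept and weights expressed on the original feature/target scales."""
        check_is_fitted(self, "coef_")
        span_y = self.y_max_ - self.y_min_
        span_x = self.x_max_ - self.x_min_
        coef = span_y * self.coef_ / span_x
        intercept = (
            self.y_min_
            + span_y * self.intercept_
            - float(np.sum(coef * self.x_min_))
        )
        return intercept, coef


@dataclass
class EvaluationResult:
    """Pooled held-out predictions of one task's LOSO evaluation."""

    task_class: TaskClass | None
    rmse: float
    r: float
    r_p_value: float
    n_instances: int
    truths: np.ndarray
    predictions: np.ndarray
    degenerate: bool = False  # zero-variance truth or prediction: r undefined
    models: list[CapacityRegressor] = field(default_factory=list)
    fold_keys: list[tuple] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "task_class": self.task_class.value if self.task_class else None,
            "rmse": self.rmse,
            "r": None if self.degenerate else self.r,
            "r_p_value": None if self.degenerate else self.r_p_value,
            "degenerate_correlation": self.degenerate,
            "n_instances": self.n_instances,
            "truths": [float(v) for v in self.truths],
            "predictions": [float(v) for v in self.predictions],
        }


def evaluate(truth, prediction) -> tuple[float, float, float]:
    """RMSE, Pearson r, and the no-correlation p-value of paired lists."""
    truth = np.asarray(truth, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if truth.shape != prediction.shape or truth.ndim != 1:
        raise ValueError(
            f"truth and prediction must be equal-length 1-D, got "
            f"{truth.shape} vs {prediction.shape}"
        )
    if len(truth) < 2:
        raise ValueError("need at least 2 pairs to evaluate")
    rmse = float(np.sqrt(np.mean((truth - prediction) ** 2)))
    if np.all(truth == truth[0]) or np.all(prediction == prediction[0]):
        # zero-variance input: correlation is undefined, flagged via NaN
        return rmse, float("nan"), float("nan")
    r, p = stats.pearsonr(truth, prediction)
    return rmse, float(r), float(p)


def _instances_matrix(instances: list[RatedInstance]):
    names = list(instances[0].features.names)
    X = np.array([inst.features.as_array() for inst in instances])
    y = np.array([inst.target for inst in instances])
    groups = [inst.session_key for inst in instances]
    return X, y, groups, names


def loso_cv(
    instances: list[RatedInstance],
    task_class: TaskClass | None = None,
    alpha: float = 0.05,
    gate_scope: str = "fold",
    selection: str = "single",
) -> EvaluationResult:
    """Leave-one-session-out evaluation of the gated linear model.

    Folds are (subject, week) session keys; left- and right-hand executions
    of a single-handed task fall into the same fold and share one model.

    ``gate_scope`` controls where the p < alpha feature selection happens:
    ``"fold"`` (default) scales and selects within each training fold only —
    no test-session leakage; ``"dataset"`` selects once on the full dataset
    before cross-validating, reproducing protocols that report a single
    p-value per feature.
    """
    if gate_scope not in ("fold", "dataset"):
        raise ValueError(f"gate_scope must be 'fold' or 'dataset', got {gate_scope!r}")
    if task_class is not None:
        task_class = TaskClass(task_class)
        instances = [i for i in instances if i.task_class == task_class]
    if not instances:
        raise ValueError("no instances to evaluate")
    X, y, groups, names = _instances_matrix(instances)
    keys = sorted(set(groups))
    if len(keys) < 3:
        raise ValueError(
            f"need at least 3 distinct sessions for LOSO, got {len(keys)}"
        )
    group_idx = np.array([keys.index(g) for g in groups])

    preselect: np.ndarray | None = None
    if gate_scope == "dataset":
        full = CapacityRegressor(alpha=alpha, gate=True, selection=selection).fit(
            X, y, feature_names=names
        )
        preselect = full.support_.copy()

    truths, preds = [], []
    models, fold_keys = [], []
    for train, test in LeaveOneGroupOut().split(X, y, groups=group_idx):
        if preselect is not None and not preselect.any():
            # whole-dataset gate kept nothing: intercept-only folds
            model = None
            p = np.full(len(test), y[train].mean())
        elif preselect is not None:
            model = CapacityRegressor(alpha=alpha, gate=False)
            model.fit(
                X[np.ix_(train, np.flatnonzero(preselect))],
                y[train],
                feature_names=[n for n, s in zip(names, preselect) if s],
            )
            p = model.predict(X[np.ix_(test, np.flatnonzero(preselect))])
        else:
            model = CapacityRegressor(alpha=alpha, gate=True, selection=selection)
            model.fit(X[train], y[train], feature_names=names)
            p = model.predict(X[test])
        truths.extend(y[test])
        preds.extend(p)
        models.append(model)
        fold_keys.append(keys[group_idx[test[0]]])

    truths = np.asarray(truths)
    preds = np.asarray(preds)
    rmse, r, pval = evaluate(truths, preds)
    return EvaluationResult(
        task_class=task_class,
        rmse=rmse,
        r=r,
        r_p_value=pval,
        n_instances=len(truths),
        truths=truths,
        predictions=preds,
        degenerate=bool(np.isnan(r)),
        models=models,
        fold_keys=fold_keys,
    )


def pooled_generalization(instances: list[RatedInstance]):
    """Task-independent summary per (subject, week): mean SM, ARE, RANG.

    Averages the three task-independent features over every single-hand task
    instance of a session and sums the ratings, for scatter analysis of how
    capacity moves the session through feature space.  TIME and DF are
    excluded: they depend strongly on which task was performed.
    """
    import pandas as pd

    rows = []
    for inst in instances:
        if inst.task_class not in SINGLE_HAND_TASKS:
            continue
        rows.append(
            {
                "subject_id": inst.subject_id,
                "week": inst.week,
                "SM": inst.features.values["SM"],
                "ARE": inst.features.values["ARE"],
                "RANG": inst.features.values["RANG"],
                "rating": inst.target,
            }
        )
    if not rows:
        raise ValueError("no single-hand task instances to pool")
    df = pd.DataFrame(rows)
    out = df.groupby(["subject_id", "week"]).agg(
        SM=("SM", "mean"),
        ARE=("ARE", "mean"),
        RANG=("RANG", "mean"),
        rating_sum=("rating", "sum"),
        n_tasks=("rating", "size"),
    )
    return out.reset_index()
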
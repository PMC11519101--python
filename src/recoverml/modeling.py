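"""Group- and individual-level prediction models for daily recovery.

Group models are validated with leave-one-subject-out cross-validation
(LOSO): each participant in turn is the out-of-sample test set, hyper-
parameters are tuned by inner cross-validation on the remaining
participants, and reported performance is the across-fold mean with a
t-interval from the fold distribution.  Individual models are selected per
participant by 10x10-fold cross-validation over a learner/hyperparameter
grid (ties broken toward the simpler learner class) and their accuracy
metrics come from out-of-bag evaluation over bootstrap resamples.

The learner registry covers regularized linear models (ridge, LASSO, LASSO
with planned interaction terms), k-nearest neighbours, an RBF support
vector machine, gradient-boosted trees (two adapter-backed variants), and a
single-layer neural network; adapters that cannot be constructed in the
running environment are skipped with a warning.  R-squared is the squared
Pearson correlation between observed and predicted values, defined as 0
when predictions are constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import Lasso, LassoCV, Ridge, RidgeCV
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
import statsmodels.api as sm

from .preprocess import UnfoldedDataset

__all__ = [
    "LearnerSpec",
    "FitResult",
    "GroupModelFit",
    "make_learner",
    "available_learners",
    "score_predictions",
    "fit_group_model",
    "fit_baseline",
    "fit_lmm_top5",
    "fit_individual_models",
    "bootstrap_metrics",
]

#: preference order for tie-breaking (simpler / more interpretable first)
_SIMPLICITY_ORDER = (
    "intercept",
    "lasso",
    "ridge",
    "lasso_interactions",
    "mars",
    "knn",
    "svm_rbf",
    "gbdt_a",
    "gbdt_b",
    "nnet",
)

_ALPHAS = np.logspace(-3, 1.5, 15)


@dataclass
class LearnerSpec:
    name: str
    implemented: bool
    build: Callable[[int], object] | None = None
    grid: dict = field(default_factory=dict)


def _lasso(seed: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "model",
                LassoCV(
                    alphas=_ALPHAS,
                    cv=KFold(3, shuffle=True, random_state=seed),
                    max_iter=5000,
                    tol=1e-3,
                ),
            ),
        ]
    )


def _ridge(seed: int) -> Pipeline:
    return Pipeline(
        [("scale", StandardScaler()), ("model", RidgeCV(alphas=np.logspace(-2, 4, 13)))]
    )


def _knn(seed: int) -> Pipeline:
    grid = {"model__n_neighbors": [5, 10, 20]}
    pipe = Pipeline([("scale", StandardScaler()), ("model", KNeighborsRegressor())])
    return GridSearchCV(
        pipe, grid, cv=KFold(3, shuffle=True, random_state=seed),
        scoring="neg_root_mean_squared_error",
    )


def _svm(seed: int):
    from sklearn.svm import SVR

    pipe = Pipeline([("scale", StandardScaler()), ("model", SVR(kernel="rbf"))])
    return GridSearchCV(
        pipe, {"model__C": [1.0, 10.0], "model__gamma": ["scale"]},
        cv=KFold(3, shuffle=True, random_state=seed),
        scoring="neg_root_mean_squared_error",
    )


def _nnet(seed: int):
    from sklearn.neural_network import MLPRegressor

    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "model",
                MLPRegressor(
                    hidden_layer_sizes=(8,), max_iter=800, random_state=seed, alpha=1e-2
                ),
            ),
        ]
    )


def _gbdt_a(seed: int):
    from xgboost import XGBRegressor

    return XGBRegressor(
        n_estimators=150, max_depth=3, learning_rate=0.1, random_state=seed,
        n_jobs=1, verbosity=0,
    )


def _gbdt_b(seed: int):
    from lightgbm import LGBMRegressor

    return LGBMRegressor(
        n_estimators=150, max_depth=3, learning_rate=0.1, random_state=seed,
        n_jobs=1, verbose=-1,
    )


def _intercept(seed: int):
    return DummyRegressor(strategy="mean")


_BUILDERS: dict[str, Callable[[int], object]] = {
    "intercept": _intercept,
    "lasso": _lasso,
    "lasso_interactions": _lasso,  # interaction columns supplied by the dataset
    "ridge": _ridge,
    "knn": _knn,
    "svm_rbf": _svm,
    "nnet": _nnet,
    "gbdt_a": _gbdt_a,
    "gbdt_b": _gbdt_b,
}


def make_learner(name: str, seed: int = 0):
    """Instantiate a learner by registry name; None when unavailable."""
    if name == "mars":
        return None  # no multivariate-adaptive-regression-splines backend
    if name not in _BUILDERS:
        raise ValueError(f"unknown learner {name!r}")
    try:
        return _BUILDERS[name](seed)
    except ImportError:
        return None


def available_learners() -> list[LearnerSpec]:
    specs = []
    for name in _SIMPLICITY_ORDER:
        est = make_learner(name, 0)
        specs.append(LearnerSpec(name=name, implemented=est is not None))
    return specs


def score_predictions(observed, predicted) -> tuple[float, float]:
    """(RMSE, R^2) where R^2 is the squared Pearson correlation.

    R^2 is defined as 0 when predictions are constant (no association can
    be claimed for a flat predictor).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 values")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    if np.std(yhat) == 0 or np.std(y) == 0:
        return rmse, 0.0
    r = float(np.corrcoef(y, yhat)[0, 1])
    return rmse, r * r


@dataclass
class FitResult:
    outcome: str
    level: str  # group | individual
    variable_set: str
    learner: str
    rmse: float
    rmse_ci: tuple[float, float]
    r_squared: float
    per_fold: pd.DataFrame | None = None
    hyperparameters: dict = field(default_factory=dict)
    participant_id: str | None = None
    rmse_sd: float | None = None
    r_squared_sd: float | None = None

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "level": self.level,
            "model": self.learner,
            "variables": self.variable_set,
            "participant_id": self.participant_id or "",
            "rmse": self.rmse,
            "rmse_lo": self.rmse_ci[0],
            "rmse_hi": self.rmse_ci[1],
            "r_squared": self.r_squared,
        }


@dataclass
class GroupModelFit:
    """A LOSO-validated group model: summary plus per-fold artifacts."""

    result: FitResult
    folds: list[dict]  # {participant_id, estimator, test_idx, rmse, r2}
    dataset: UnfoldedDataset

    def heldout_predictions(self) -> pd.DataFrame:
        frames = []
        for f in self.folds:
            X = self.dataset.X.iloc[f["test_idx"]].to_numpy(float)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": f["participant_id"],
                        "observed": self.dataset.y.iloc[f["test_idx"]].to_numpy(),
                        "predicted": f["estimator"].predict(X),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _fold_ci(values: np.ndarray) -> tuple[float, float]:
    """95% t-interval for the mean of the per-fold metric distribution."""
    values = values[~np.isnan(values)]
    k = len(values)
    if k < 2:
        return float("nan"), float("nan")
    se = values.std(ddof=1) / np.sqrt(k)
    t = stats.t.ppf(0.975, k - 1)
    m = values.mean()
    return float(m - t * se), float(m + t * se)


def fit_group_model(
    ds: UnfoldedDataset,
    learner: str = "lasso",
    seed: int = 0,
    variable_set: str = "MAIN",
) -> GroupModelFit:
    """Fit and LOSO-validate one group model.

    Each participant serves once as the full test set; the learner's inner
    cross-validation tunes hyperparameters on the training participants
    only, so no test participant's rows ever touch training.
    """
    pids = ds.groups.unique()
    if len(pids) < 3:
        raise ValueError("group models need at least 3 participants")
    proto = make_learner(learner, seed)
    if proto is None:
        warnings.warn(f"learner {learner!r} unavailable; skipped")
        return GroupModelFit(
            result=FitResult(ds.outcome, "group", variable_set, learner,
                             float("nan"), (float("nan"), float("nan")), float("nan")),
            folds=[],
            dataset=ds,
        )
    Xall = ds.X.to_numpy(float)
    yall = ds.y.to_numpy(float)
    gall = ds.groups.to_numpy()
    folds = []
    for pid in pids:
        test = gall == pid
        est = clone(proto)
        try:
            est.fit(Xall[~test], yall[~test])
        except Exception as exc:  # singular / failed fit: excluded with warning
            warnings.warn(f"fold {pid}: fit failed ({exc}); excluded")
            continue
        pred = est.predict(Xall[test])
        rmse, r2 = score_predictions(yall[test], pred)
        folds.append(
            {
                "participant_id": pid,
                "estimator": est,
                "test_idx": np.flatnonzero(test),
                "rmse": rmse,
                "r2": r2,
            }
        )
    per_fold = pd.DataFrame(
        [{"participant_id": f["participant_id"], "rmse": f["rmse"], "r2": f["r2"]} for f in folds]
    )
    rmses = per_fold["rmse"].to_numpy()
    r2s = per_fold["r2"].to_numpy()
    hyper = {}
    if folds and learner in ("lasso", "lasso_interactions"):
        hyper["alpha"] = [float(f["estimator"].named_steps["model"].alpha_) for f in folds]
    result = FitResult(
        outcome=ds.outcome,
        level="group",
        variable_set=variable_set,
        learner=learner,
        rmse=float(np.nanmean(rmses)),
        rmse_ci=_fold_ci(rmses),
        r_squared=0.0 if learner == "intercept" else float(np.nanmean(r2s)),
        per_fold=per_fold,
        hyperparameters=hyper,
    )
    return GroupModelFit(result=result, folds=folds, dataset=ds)


def fit_baseline(ds: UnfoldedDataset, variable_set: str = "baseline") -> GroupModelFit:
    """LOSO intercept-only model predicting the training-fold outcome mean."""
    return fit_group_model(ds, learner="intercept", variable_set=variable_set)


def _fit_mixedlm(y, exog, groups):
    """REML fit with optimizer fallback (zero random-effect variance sits
    on the parameter boundary and can break a single optimizer)."""
    last = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                return sm.MixedLM(y, exog, groups=groups).fit(
                    reml=True, method=method, maxiter=300
                )
            except Exception as exc:  # singular V / line-search failures
                last = exc
    raise RuntimeError(f"mixed model failed to converge: {last}")


def fit_lmm_top5(
    ds: UnfoldedDataset, top5: Sequence[str], variable_set: str = "top5_group"
) -> GroupModelFit:
    """Random-intercept linear mixed model on the top-importance features.

    Evaluated under the same LOSO scheme as the learners; the held-out
    participant's random effect is unknown and set to 0, so predictions use
    fixed effects only.
    """
    cols = [c for c in top5 if c in ds.X.columns]
    if len(cols) < len(top5):
        warnings.warn(
            f"only {len(cols)}/{len(top5)} requested features present; fitting with those"
        )
    if not cols:
        raise ValueError("none of the requested features exist in the design matrix")
    pids = ds.groups.unique()
    X = ds.X[cols].to_numpy(float)
    y = ds.y.to_numpy(float)
    g = ds.groups.to_numpy()
    folds = []
    for pid in pids:
        test = g == pid
        exog = sm.add_constant(X[~test], has_constant="add")
        fit = _fit_mixedlm(y[~test], exog, g[~test])
        # a new subject's random effect is 0 in expectation; re-centering the
        # intercept on the mean training residual guards against optimizer
        # runs that park part of the fixed intercept inside the (weakly
        # identified) random effects — the correction is ~0 for a proper fit
        params = np.asarray(fit.fe_params, dtype=float).copy()
        params[0] += float(np.mean(y[~test] - exog @ params))
        exog_test = sm.add_constant(X[test], has_constant="add")
        pred = exog_test @ params
        rmse, r2 = score_predictions(y[test], pred)
        folds.append(
            {"participant_id": pid, "estimator": _FrozenLMM(params, cols, ds.X.columns),
             "test_idx": np.flatnonzero(test), "rmse": rmse, "r2": r2}
        )
    per_fold = pd.DataFrame(
        [{"participant_id": f["participant_id"], "rmse": f["rmse"], "r2": f["r2"]} for f in folds]
    )
    result = FitResult(
        outcome=ds.outcome,
        level="group",
        variable_set=variable_set,
        learner="lmm",
        rmse=float(per_fold["rmse"].mean()),
        rmse_ci=_fold_ci(per_fold["rmse"].to_numpy()),
        r_squared=float(per_fold["r2"].mean()),
        per_fold=per_fold,
    )
    return GroupModelFit(result=result, folds=folds, dataset=ds)


class _FrozenLMM:
    """Fixed-effect-only predictor wrapping fitted mixed-model coefficients."""

    def __init__(self, fe_params, cols, all_columns):
        self.fe_params = np.asarray(fe_params, dtype=float)
        self.cols = list(cols)
        self.all_columns = list(all_columns)

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            mat = X[self.cols].to_numpy(float)
        else:
            idx = [self.all_columns.index(c) for c in self.cols]
            mat = np.asarray(X, dtype=float)[:, idx]
        return self.fe_params[0] + mat @ self.fe_params[1:]


def bootstrap_metrics(
    estimator_factory: Callable[[], object],
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    B: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-bag RMSE/R^2 over ``B`` bootstrap resamples.

    Each resample refits the model on the drawn rows and scores it on the
    rows left out of the bag; a resample with no out-of-bag rows is redrawn.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(B):
        while True:
            idx = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), idx)
            if len(oob) >= 2:
                break
        est = estimator_factory()
        est.fit(X[idx], y[idx])
        rmse, r2 = score_predictions(y[oob], est.predict(X[oob]))
        rows.append({"rmse": rmse, "r2": r2})
    return pd.DataFrame(rows)


def _cv_rmse(est_proto, X, y, cv_folds, cv_repeats, seed) -> float:
    rkf = RepeatedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    errs = []
    for tr, te in rkf.split(X):
        est = clone(est_proto)
        est.fit(X[tr], y[tr])
        errs.append(float(np.sqrt(np.mean((y[te] - est.predict(X[te])) ** 2))))
    return float(np.mean(errs))


def fit_individual_models(
    ds: UnfoldedDataset,
    learners: Sequence[str] = ("lasso", "ridge", "knn"),
    seed: int = 0,
    min_rows: int = 30,
    cv_folds: int = 10,
    cv_repeats: int = 10,
    n_bootstrap: int = 500,
    variable_set: str = "MAIN",
) -> list[FitResult]:
    """Select and evaluate the best per-participant model.

    For each participant with at least ``min_rows`` usable rows, every
    requested learner is scored by repeated k-fold CV; the lowest mean RMSE
    wins with ties broken toward the simpler learner class.  Final accuracy
    metrics are out-of-bag bootstrap means (+/- SD).  Deterministic given
    ``seed``.
    """
    results = []
    ss = np.random.SeedSequence([seed, 2024])
    pid_list = list(ds.groups.unique())
    children = ss.spawn(len(pid_list))
    for pid, child in zip(pid_list, children):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        mask = (ds.groups == pid).to_numpy()
        if mask.sum() < min_rows:
            warnings.warn(f"participant {pid}: {mask.sum()} rows < {min_rows}; skipped")
            continue
        X = ds.X.loc[mask].to_numpy(float)
        y = ds.y.loc[mask].to_numpy(float)
        scores = {}
        for name in learners:
            proto = make_learner(name, child_seed)
            if proto is None:
                warnings.warn(f"learner {name!r} unavailable; skipped")
                continue
            scores[name] = _cv_rmse(proto, X, y, cv_folds, cv_repeats, child_seed)
        if not scores:
            continue
        best = min(
            scores, key=lambda nm: (round(scores[nm], 10), _SIMPLICITY_ORDER.index(nm))
        )
        boot = bootstrap_metrics(
            lambda: make_learner(best, child_seed), X, y, B=n_bootstrap, seed=child_seed
        )
        final = make_learner(best, child_seed)
        final.fit(X, y)
        results.append(
            FitResult(
                outcome=ds.outcome,
                level="individual",
                variable_set=variable_set,
                learner=best,
                rmse=float(boot["rmse"].mean()),
                rmse_sd=float(boot["rmse"].std(ddof=1)),
                rmse_ci=(
                    float(boot["rmse"].quantile(0.025)),
                    float(boot["rmse"].quantile(0.975)),
                ),
                r_squared=float(boot["r2"].mean()),
                r_squared_sd=float(boot["r2"].std(ddof=1)),
                participant_id=pid,
                hyperparameters={"cv_rmse": scores, "fitted": final},
            )
        )
    return results
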
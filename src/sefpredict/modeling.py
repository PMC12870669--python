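"""Elastic-net prediction protocol for treatment response.

Protocol: assemble the per-subject feature matrix (spectral event features,
averaged power features, or both; baseline HAM-D appended to SEF-containing
sets), z-score features and impute missing values with 2-nearest-neighbor
interpolation (statistics from training rows only), split subjects 2/3-1/3
stratified by responder status, select elastic-net hyperparameters
(regularization strength, L1/L2 mixing, intercept) by 3-fold stratified CV
grid search under negative-RMSE loss, refit on the full training set,
evaluate on the held-out test set, and assess both phases with one-sided
permutation tests that refit the model on outcome-shuffled data.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.impute import KNNImputer
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.linear_model import ElasticNet, LinearRegression, Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import (
    StratifiedKFold,
    permutation_test_score as _sk_permutation_test_score,
    train_test_split,
)

from .bands import DEFAULT_BANDS, FRONTAL_CHANNELS, SEF_FEATURES

logger = logging.getLogger(__name__)

_SEF_COLUMN_OF = {
    "power": "mean_peak_power_fom",
    "rate": "event_rate",
    "duration": "mean_duration_s",
    "freq_span": "mean_freq_span_hz",
}

FEATURE_SETS = ("sef", "apf", "both")


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Subjects x named features, with outcome and stratification labels."""

    X: pd.DataFrame
    y: pd.Series          # pct_change
    strata: pd.Series     # responder flag
    feature_set: str

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("feature names must be unique")

    @property
    def n_subjects(self) -> int:
        return len(self.X)


def sef_feature_columns(
    channels: tuple[str, ...] = FRONTAL_CHANNELS, bands=DEFAULT_BANDS,
) -> list[str]:
    """Deterministic SEF column order: channel-major, band-minor,
    feature-innermost (4 features x 3 bands x 8 channels = 96)."""
    return [
        f"{ch}_{band}_{feat}"
        for ch in channels for band in bands.labels for feat in SEF_FEATURES
    ]


def assemble_features(
    clinical: pd.DataFrame,
    sef: pd.DataFrame | None = None,
    apf_channel: pd.DataFrame | None = None,
    apf_pairs: pd.DataFrame | None = None,
    feature_set: str = "sef",
    channels: tuple[str, ...] = FRONTAL_CHANNELS,
    bands=DEFAULT_BANDS,
) -> FeatureMatrix:
    """Build the wide subjects x features matrix for one cohort.

    ``sef`` has SefTable layout (subject_id, channel, band, event_rate,
    mean_duration_s, mean_freq_span_hz, mean_peak_power_fom); ``apf_channel``
    is indexed by (subject_id, channel) or has those columns;
    ``apf_pairs`` has (subject_id, channel_a, channel_b, band, pec).
    Subjects present in the clinical table but missing from a feature table
    keep their row with NaN entries (imputed later).  Baseline HAM-D is
    appended for SEF-containing sets; PEC columns belong to APF sets.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    subjects = list(clinical["subject_id"])
    X = pd.DataFrame(index=pd.Index(subjects, name="subject_id"))

    if feature_set in ("sef", "both"):
        if sef is None:
            raise ValueError("sef table required for this feature set")
        wide = {}
        for (sid, ch, band), cell in sef.groupby(["subject_id", "channel", "band"]):
            for feat, col in _SEF_COLUMN_OF.items():
                wide.setdefault(f"{ch}_{band}_{feat}", {})[sid] = cell[col].iloc[0]
        for name in sef_feature_columns(channels, bands):
            X[name] = pd.Series(wide.get(name, {})).reindex(subjects).to_numpy()

    if feature_set in ("apf", "both"):
        if apf_channel is None or apf_pairs is None:
            raise ValueError("apf tables required for this feature set")
        apf = apf_channel.reset_index() if "subject_id" not in apf_channel.columns else apf_channel
        value_cols = [c for c in apf.columns if c not in ("subject_id", "channel")]
        for ch in channels:
            sub = apf[apf["channel"] == ch].set_index("subject_id")
            for col in value_cols:
                X[f"{ch}_{col}"] = sub[col].reindex(subjects).to_numpy()
        for (a, b, band), cell in apf_pairs.groupby(["channel_a", "channel_b", "band"]):
            vals = cell.set_index("subject_id")["pec"].reindex(subjects)
            X[f"pec_{a}_{b}_{band}"] = vals.to_numpy()

    if feature_set in ("sef", "both"):
        X["baseline_hamd"] = clinical.set_index("subject_id")["baseline_hamd"].reindex(subjects).to_numpy()

    n_missing = int(X.isna().any(axis=1).sum())
    if n_missing:
        logger.info("%d subjects have missing feature values (left to imputation)", n_missing)

    cl = clinical.set_index("subject_id")
    return FeatureMatrix(
        X=X,
        y=cl["pct_change"].reindex(subjects).rename("pct_change"),
        strata=cl["responder"].reindex(subjects).rename("responder"),
        feature_set=feature_set,
    )


# ---------------------------------------------------------------------------
# normalization + imputation
# ---------------------------------------------------------------------------

class FeatureTransform:
    """Z-scoring followed by 2-nearest-neighbor imputation.

    Column means/sds come from the rows passed to :meth:`fit` (training
    rows), so applying the transform to held-out rows leaks nothing.
    Imputation replaces each NaN with the mean of that feature in the k
    nearest rows by Euclidean distance over mutually observed features.
    Zero-variance columns are set to 0 with a warning.
    """

    def __init__(self, k: int = 2):
        self.k = k
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None

    def fit(self, X: pd.DataFrame) -> "FeatureTransform":
        if len(X) < self.k + 1:
            raise ValueError(f"need at least k+1={self.k + 1} rows")
        self.mean_ = X.mean()
        sd = X.std(ddof=0)
        if (sd == 0).any():
            logger.warning(
                "zero-variance features set to 0: %s", list(sd.index[sd == 0])
            )
        self.sd_ = sd.replace(0.0, np.inf)
        self._train_z = self._zscore(X)
        self._imputer = KNNImputer(n_neighbors=self.k, weights="uniform").fit(self._train_z)
        return self

    def _zscore(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.mean_) / self.sd_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        z = self._zscore(X)
        out = self._imputer.transform(z)
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def normalize_and_impute(fm: FeatureMatrix, k: int = 2) -> FeatureMatrix:
    """Fit the transform on the whole matrix and apply it (single-set use;
    the split protocol fits on training rows only)."""
    tr = FeatureTransform(k=k).fit(fm.X)
    return FeatureMatrix(X=tr.transform(fm.X), y=fm.y, strata=fm.strata,
                         feature_set=fm.feature_set)


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def stratified_split(
    fm: FeatureMatrix, test_fraction: float = 1 / 3, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """2/3-1/3 split preserving the responder proportion (within one
    subject); returns (train_indices, test_indices), reproducible by seed."""
    strata = fm.strata.to_numpy().astype(bool)
    counts = np.bincount(strata.astype(int), minlength=2)
    if counts.min() == 0:
        raise ValueError("both responder strata must be non-empty")
    if counts.min() < 3:
        raise ValueError("smallest stratum smaller than the 3 CV folds")
    idx = np.arange(fm.n_subjects)
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=strata, random_state=int(seed)
    )
    return np.sort(train), np.sort(test)


# ---------------------------------------------------------------------------
# elastic-net grid
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Hyperparameter grid; must bracket the selected point alpha=3.0,
    l1_ratio=0.5, fit_intercept=False."""

    alphas: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0)
    l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    fit_intercept: tuple[bool, ...] = (True, False)
    cv_folds: int = 3
    scoring: str = "neg_root_mean_squared_error"

    def __post_init__(self) -> None:
        if not (self.alphas and self.l1_ratios and self.fit_intercept):
            raise ValueError("grids must be non-empty")
        if not (3.0 in self.alphas and 0.5 in self.l1_ratios and False in self.fit_intercept):
            raise ValueError("grid must contain alpha=3.0, l1_ratio=0.5, intercept=False")

    def points(self):
        for a in self.alphas:
            for r in self.l1_ratios:
                for fi in self.fit_intercept:
                    yield {"alpha": a, "l1_ratio": r, "fit_intercept": fi}


class ElasticNetPoint(BaseEstimator, RegressorMixin):
    """Elastic-net linear model at one grid point.

    alpha=0 is solved by ordinary least squares and l1_ratio=0 by the ridge
    closed form (the coordinate-descent objective 1/(2n)||y-Xw||^2 +
    a*r*||w||_1 + a*(1-r)/2*||w||^2 reduces to Ridge with penalty a*n).
    """

    def __init__(self, alpha: float = 3.0, l1_ratio: float = 0.5,
                 fit_intercept: bool = False):
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.alpha == 0:
            self._model = LinearRegression(fit_intercept=self.fit_intercept)
        elif self.l1_ratio == 0:
            self._model = Ridge(alpha=self.alpha * len(y), fit_intercept=self.fit_intercept)
        else:
            self._model = ElasticNet(
                alpha=self.alpha, l1_ratio=self.l1_ratio,
                fit_intercept=self.fit_intercept, max_iter=20000, tol=1e-7,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._model.fit(X, y)
        self.coef_ = self._model.coef_
        self.intercept_ = self._model.intercept_
        return self

    def predict(self, X):
        return self._model.predict(np.asarray(X, dtype=float))


def make_cv_folds(strata: np.ndarray, n_folds: int = 3, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds over the responder flag, frozen as index lists so the
    same folds serve grid search and the training-phase permutation test."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed))
    return list(skf.split(np.zeros(len(strata)), strata.astype(int)))


def _neg_rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return -float(np.sqrt(np.mean((np.asarray(y_true) - np.asarray(y_pred)) ** 2)))


def grid_search_fit(
    X: pd.DataFrame, y: pd.Series, folds: list[tuple[np.ndarray, np.ndarray]],
    grid: GridSpec | None = None,
) -> tuple[dict, ElasticNetPoint, pd.DataFrame]:
    """CV grid search by maximal mean negative RMSE; ties break toward the
    larger alpha, then larger l1_ratio (the sparser model), then no
    intercept.  Returns (best params, model refit on all rows, cv table)."""
    grid = grid or GridSpec()
    if len(X) < 3 * grid.cv_folds:
        raise ValueError("training set smaller than 3x the fold count")
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    records = []
    for params in grid.points():
        scores = []
        for tr, va in folds:
            m = ElasticNetPoint(**params).fit(Xv[tr], yv[tr])
            scores.append(_neg_rmse(yv[va], m.predict(Xv[va])))
        mean_score = float(np.mean(scores))
        if not np.isfinite(mean_score):
            logger.warning("non-finite CV loss at %s; grid point skipped", params)
            continue
        records.append({**params, "mean_neg_rmse": mean_score})
    if not records:
        raise RuntimeError("every grid point produced a non-finite loss")
    cv_table = pd.DataFrame(records)
    best = max(
        records,
        key=lambda r: (r["mean_neg_rmse"], r["alpha"], r["l1_ratio"], not r["fit_intercept"]),
    )
    best_params = {k: best[k] for k in ("alpha", "l1_ratio", "fit_intercept")}
    model = ElasticNetPoint(**best_params).fit(Xv, yv)
    return best_params, model, cv_table


def evaluate(model, X: pd.DataFrame, y: pd.Series) -> dict:
    """Negative RMSE on the %change scale, coefficient of determination,
    and the Pearson correlation between predicted and true values."""
    pred = model.predict(X.to_numpy(dtype=float))
    yv = np.asarray(y, dtype=float)
    out = {"nrmse": _neg_rmse(yv, pred)}
    if np.std(yv) == 0 or np.std(pred) == 0:
        # degenerate: correlation undefined; r2 <= 0 for constant predictions
        out["r2"] = float(r2_score(yv, pred)) if np.std(yv) > 0 else float("nan")
        out["pearson_r"] = float("nan")
    else:
        out["r2"] = float(r2_score(yv, pred))
        out["pearson_r"] = float(pearsonr(yv, pred)[0])
    return out


# ---------------------------------------------------------------------------
# permutation testing
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    p_value: float
    null_scores: np.ndarray

    def summary(self) -> dict:
        return {
            "observed": self.observed, "p_value": self.p_value,
            "null_mean": float(self.null_scores.mean()),
            "null_sd": float(self.null_scores.std()),
            "n_permutations": int(self.null_scores.size),
        }


def _grid_cv_score(Xv: np.ndarray, yv: np.ndarray,
                   folds: list[tuple[np.ndarray, np.ndarray]],
                   grid: GridSpec) -> float:
    """The model-selection statistic: best mean fold neg-RMSE over the grid.

    Hot path of the full-refit permutation test, so the elastic-net points
    are solved along a warm-started descending-alpha path per
    (l1_ratio, intercept, fold) with input validation disabled; grids
    containing the OLS/ridge limit points fall back to the plain solver.
    """
    if 0 in grid.alphas or 0 in grid.l1_ratios:
        best = -np.inf
        for params in grid.points():
            s = 0.0
            for tr, va in folds:
                m = ElasticNetPoint(**params).fit(Xv[tr], yv[tr])
                s += _neg_rmse(yv[va], m.predict(Xv[va]))
            best = max(best, s / len(folds))
        return best

    prep = [
        (np.asfortranarray(Xv[tr]), np.ascontiguousarray(yv[tr]), Xv[va], yv[va])
        for tr, va in folds
    ]
    alphas_desc = sorted(grid.alphas, reverse=True)
    best = -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fit_intercept in grid.fit_intercept:
            for l1_ratio in grid.l1_ratios:
                scores = {a: 0.0 for a in alphas_desc}
                for Xtr, ytr, Xva, yva in prep:
                    est = ElasticNet(
                        alpha=alphas_desc[0], l1_ratio=l1_ratio,
                        fit_intercept=fit_intercept, warm_start=True,
                        max_iter=10000, tol=1e-4,
                    )
                    for a in alphas_desc:
                        est.alpha = a
                        est.fit(Xtr, ytr, check_input=False)
                        pred = Xva @ est.coef_ + est.intercept_
                        scores[a] += _neg_rmse(yva, pred)
                best = max(best, max(scores.values()) / len(folds))
    return best


def permutation_test(
    params: dict, X: pd.DataFrame, y: pd.Series,
    cv: list[tuple[np.ndarray, np.ndarray]],
    n_perm: int = 5000, seed: int = 0,
    grid: GridSpec | None = None,
    strata: np.ndarray | None = None,
    folds_seed: int = 0,
) -> PermutationResult:
    """One-sided permutation test; p = (#{null >= observed} + 1)/(n_perm + 1).

    ``cv`` carries the evaluation scheme: the 3 training folds for the
    training phase, or the single (train, test) split for the held-out
    phase.  With ``grid`` given, every permutation repeats the *full* fit
    procedure: outcome labels are shuffled together with their responder
    flags (the flag is a function of the outcome), folds are re-stratified
    from the shuffled flags, and the grid search is rerun — so the null
    statistic carries the same selection optimism and stratification
    advantage as the observed one, which is the selected best CV score.
    Without ``grid`` the model is refit at the fixed ``params`` on the given
    ``cv`` (held-out phase: selection happened on the training data, outside
    this statistic)."""
    if n_perm < 20:
        logger.warning("n_perm=%d gives poor p-value resolution", n_perm)
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if grid is None:
        score, null, p = _sk_permutation_test_score(
            ElasticNetPoint(**params), Xv, yv,
            cv=cv, n_permutations=n_perm, random_state=int(seed),
            scoring="neg_root_mean_squared_error",
        )
        return PermutationResult(observed=float(score), p_value=float(p),
                                 null_scores=np.asarray(null))

    if strata is None:
        raise ValueError("full-refit permutation test needs the stratification flags")
    strata = np.asarray(strata).astype(bool)
    rng = np.random.default_rng(int(seed))
    observed = _grid_cv_score(Xv, yv, cv, grid)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(yv))
        folds_p = make_cv_folds(strata[perm], n_folds=len(cv), seed=folds_seed)
        null[i] = _grid_cv_score(Xv, yv[perm], folds_p, grid)
    p = (np.sum(null >= observed) + 1) / (n_perm + 1)
    return PermutationResult(observed=float(observed), p_value=float(p),
                             null_scores=null)


def permutation_importance(
    model, X: pd.DataFrame, y: pd.Series, n_repeats: int = 10, seed: int = 0,
) -> pd.DataFrame:
    """Mean degradation of negative RMSE when each feature column is
    shuffled, sorted by absolute importance (ties break alphabetically)."""
    res = _sk_permutation_importance(
        model, X.to_numpy(dtype=float), np.asarray(y, dtype=float),
        scoring="neg_root_mean_squared_error", n_repeats=n_repeats,
        random_state=int(seed),
    )
    out = pd.DataFrame(
        {"feature": X.columns, "importance": res.importances_mean,
         "importance_sd": res.importances_std}
    )
    out["abs_importance"] = out["importance"].abs()
    out = out.sort_values(
        ["abs_importance", "feature"], ascending=[False, True], kind="mergesort"
    ).drop(columns="abs_importance").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Everything the prediction protocol produced, JSON-serializable."""

    feature_set: str
    best_params: dict
    train_cv_nrmse: float
    train_nrmse: float
    test_nrmse: float
    train_r2: float
    test_r2: float
    train_pearson_r: float
    test_pearson_r: float
    perm_train: dict
    perm_test: dict
    coefficients: dict
    importances: list
    n_train: int
    n_test: int
    seed: int
    n_perm: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, allow_nan=True)


def run_model_protocol(
    fm: FeatureMatrix,
    grid: GridSpec | None = None,
    seed: int = 0,
    n_perm: int = 5000,
    n_importance_repeats: int = 10,
    k_impute: int = 2,
) -> ModelReport:
    """The full prediction protocol on one cohort's feature matrix.

    Independent RNG streams (spawned from ``seed``) drive the split, the CV
    folds, the two permutation tests, and the importance shuffles; two runs
    with the same inputs and seed produce identical reports.
    """
    grid = grid or GridSpec()
    ss = np.random.SeedSequence(seed)
    s_split, s_folds, s_ptrain, s_ptest, s_imp = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(5)
    )

    train_idx, test_idx = stratified_split(fm, seed=s_split)
    X_train_raw, X_test_raw = fm.X.iloc[train_idx], fm.X.iloc[test_idx]
    y_train = fm.y.iloc[train_idx]
    y_test = fm.y.iloc[test_idx]
    strata_train = fm.strata.iloc[train_idx].to_numpy().astype(bool)

    tr = FeatureTransform(k=k_impute).fit(X_train_raw)
    X_train = tr.transform(X_train_raw)
    X_test = tr.transform(X_test_raw)

    folds = make_cv_folds(strata_train, grid.cv_folds, seed=s_folds)
    best_params, model, cv_table = grid_search_fit(X_train, y_train, folds, grid)
    cv_nrmse = float(
        cv_table.set_index(["alpha", "l1_ratio", "fit_intercept"]).loc[
            (best_params["alpha"], best_params["l1_ratio"], best_params["fit_intercept"]),
            "mean_neg_rmse",
        ]
    )

    train_eval = evaluate(model, X_train, y_train)
    test_eval = evaluate(model, X_test, y_test)

    perm_train = permutation_test(best_params, X_train, y_train, folds,
                                  n_perm=n_perm, seed=s_ptrain, grid=grid,
                                  strata=strata_train, folds_seed=s_folds)
    X_all = pd.concat([X_train, X_test])
    y_all = pd.concat([y_train, y_test])
    n_tr = len(train_idx)
    single_split = [(np.arange(n_tr), np.arange(n_tr, n_tr + len(test_idx)))]
    perm_test = permutation_test(best_params, X_all, y_all, single_split,
                                 n_perm=n_perm, seed=s_ptest)

    imp = permutation_importance(model, X_train, y_train,
                                 n_repeats=n_importance_repeats, seed=s_imp)

    return ModelReport(
        feature_set=fm.feature_set,
        best_params=best_params,
        train_cv_nrmse=cv_nrmse,
        train_nrmse=train_eval["nrmse"], test_nrmse=test_eval["nrmse"],
        train_r2=train_eval["r2"], test_r2=test_eval["r2"],
        train_pearson_r=train_eval["pearson_r"], test_pearson_r=test_eval["pearson_r"],
        perm_train=perm_train.summary(), perm_test=perm_test.summary(),
        coefficients={f: float(c) for f, c in zip(fm.X.columns, model.coef_)},
        importances=imp.to_dict(orient="records"),
        n_train=int(len(train_idx)), n_test=int(len(test_idx)),
        seed=int(seed), n_perm=int(n_perm),
    )
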
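"""The three-parameter detection-time model, its evaluation protocol and the
easy/hard classifier.

The predictor is a plain multivariate linear regression without intercept,

    T~ = b1 * f_cm + b2 * f_si + b3 * f_ue,

whose three coefficients are the model's only parameters.  Construct a
:class:`DetectionTimeModel` from a feature matrix and target times (per-pair
dominant modes, or individual trial times) and call :meth:`fit` to obtain a
:class:`DetectionTimeResults` with the estimates, their standard errors and
a summary table.  Evaluation follows the standard protocol for perceptual
models: Pearson (PLCC) and Spearman (SROCC) correlations plus RMSE, averaged
over repeated random 70/30 train/test splits with correlations pooled
through Fisher's z transform.

Difficulty classification (easy C1 vs hard C2, split at the critical time)
uses quadratic discriminant analysis in the three-feature space, with a
small decision tree (at most four split nodes) as an interpretable
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DegenerateClassError, InsufficientDataError, SingularFitError

__all__ = [
    "ModelParams",
    "EvalResult",
    "DetectionTimeModel",
    "DetectionTimeResults",
    "predict",
    "evaluate",
    "fisher_average",
    "fisher_z_difference",
    "cross_validate",
    "classify_difficulty",
]

FEATURE_NAMES = ["f_cm", "f_si", "f_ue"]


@dataclass
class ModelParams:
    """The regression coefficients: seconds per unit of each feature."""

    b1: float  # s per ΔE unit of change magnitude
    b2: float  # s per unit of salience imbalance
    b3: float  # s per squared-sequence-index unit
    intercept: float | None = None

    def as_array(self) -> np.ndarray:
        core = [self.b1, self.b2, self.b3]
        if self.intercept is not None:
            return np.array([self.intercept] + core, dtype=float)
        return np.array(core, dtype=float)


@dataclass
class EvalResult:
    """Correlation/error metrics, optionally pooled over many splits."""

    plcc: float
    srocc: float
    rmse_s: float
    n_splits: int = 1
    per_split: pd.DataFrame | None = field(default=None, repr=False)


def _design(features, intercept: bool) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if intercept:
        X = sm.add_constant(X, has_constant="add")
    return X


class DetectionTimeModel:
    """Linear detection-time model over (f_cm, f_si, f_ue).

    Parameters
    ----------
    features : (n, 3) array-like
        One row per sample: change magnitude, salience imbalance, user
        experience.
    targets : (n,) array-like
        Observed detection times in seconds (per-pair modes or individual
        trial times).
    intercept : bool
        Include an intercept term (off by default: the model is purely
        proportional in its three features).
    """

    def __init__(self, features, targets, intercept: bool = False):
        self.exog = np.asarray(features, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"features must be (n, {len(FEATURE_NAMES)}), got {self.exog.shape}"
            )
        self.endog = np.asarray(targets, dtype=float)
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("features and targets length mismatch")
        if self.exog.shape[0] < 4:
            raise InsufficientDataError("need at least 4 samples to fit")
        if not (np.isfinite(self.exog).all() and np.isfinite(self.endog).all()):
            raise ValueError("non-finite values in features or targets")
        self.intercept = intercept

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        target_col: str = "mode_time",
        feature_cols=tuple(FEATURE_NAMES),
        intercept: bool = False,
    ) -> "DetectionTimeModel":
        return cls(df[list(feature_cols)].to_numpy(), df[target_col].to_numpy(),
                   intercept=intercept)

    def fit(self) -> "DetectionTimeResults":
        X = _design(self.exog, self.intercept)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the offending columns via near-zero R diagonal of a QR
            names = (["intercept"] if self.intercept else []) + FEATURE_NAMES
            diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
            bad = [names[i] for i in np.where(diag < 1e-10 * max(diag.max(), 1))[0]]
            raise SingularFitError(
                f"rank-deficient design (rank {rank} < {X.shape[1]}); "
                f"collinear columns: {bad or names}"
            )
        res = sm.OLS(self.endog, X).fit()
        offset = 1 if self.intercept else 0
        params = ModelParams(
            b1=float(res.params[offset]),
            b2=float(res.params[offset + 1]),
            b3=float(res.params[offset + 2]),
            intercept=float(res.params[0]) if self.intercept else None,
        )
        return DetectionTimeResults(model=self, params=params, _sm_results=res)


@dataclass
class DetectionTimeResults:
    """Fit results: coefficients, uncertainties and diagnostics."""

    model: DetectionTimeModel
    params: ModelParams
    _sm_results: object = field(repr=False)

    @property
    def bse(self) -> np.ndarray:
        """Standard errors, ordered like ``params.as_array()``."""
        return np.asarray(self._sm_results.bse, dtype=float)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._sm_results.fittedvalues, dtype=float)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._sm_results.resid, dtype=float)

    def predict(self, features, clip: tuple[float, float] | None = None) -> np.ndarray:
        return predict(self.params, features, clip=clip)

    def evaluate_in_sample(self) -> EvalResult:
        return evaluate(self.fittedvalues, self.model.endog)

    def summary(self) -> str:
        names = (["intercept"] if self.model.intercept else []) + FEATURE_NAMES
        return str(self._sm_results.summary(xname=names))


def predict(
    params: ModelParams,
    features,
    clip: tuple[float, float] | None = None,
) -> np.ndarray:
    """Apply the linear predictor; optionally clip to a time window."""
    arr = params.as_array()
    if not np.isfinite(arr).all():
        raise ValueError("non-finite model parameters")
    X = _design(features, params.intercept is not None)
    pred = X @ arr
    if clip is not None:
        pred = np.clip(pred, *clip)
    return pred


def evaluate(pred, obs) -> EvalResult:
    """PLCC, SROCC (average-rank ties) and RMSE between two time vectors."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise ValueError("correlation undefined for constant input")
    plcc = float(stats.pearsonr(p, o).statistic)
    srocc = float(stats.spearmanr(p, o).statistic)
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    return EvalResult(plcc=plcc, srocc=srocc, rmse_s=rmse)


def fisher_average(r_values) -> float:
    """Average correlations through Fisher's z: tanh(mean(atanh(r)))."""
    r = np.asarray(r_values, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher averaging requires |r| < 1")
    return float(np.tanh(np.mean(np.arctanh(r))))


def fisher_z_difference(r1: float, r2: float, n1: int, n2: int) -> tuple[float, float]:
    """z statistic and two-sided p for the difference of two correlations.

    Standard test on Fisher-transformed correlations from independent
    samples of sizes ``n1`` and ``n2``.
    """
    if min(n1, n2) < 4:
        raise InsufficientDataError("need n >= 4 per sample for the z test")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(z), float(2 * stats.norm.sf(abs(z)))


def cross_validate(
    features,
    targets,
    n_splits: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    intercept: bool = False,
) -> EvalResult:
    """Repeated random-split validation of the three-feature model.

    ``n_splits`` unique random train/test partitions (duplicates are
    redrawn); the model is fitted on the training fraction and scored on the
    held-out part.  PLCC/SROCC are pooled with Fisher averaging, RMSE with a
    plain mean; per-split values are kept on the result.  With
    ``train_frac=1`` a single in-sample evaluation on the full data is
    returned.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if train_frac >= 1.0:
        res = DetectionTimeModel(X, y, intercept=intercept).fit()
        ev = res.evaluate_in_sample()
        ev.n_splits = 1
        return ev
    if n < 10:
        raise InsufficientDataError("need at least 10 samples for split validation")
    n_train = int(round(train_frac * n))
    if not 4 <= n_train <= n - 3:
        raise InsufficientDataError("train fraction leaves too small a train/test set")
    rng = np.random.default_rng(seed)
    seen: set[tuple] = set()
    rows = []
    attempts = 0
    while len(rows) < n_splits:
        attempts += 1
        if attempts > 100 * n_splits:
            raise RuntimeError("could not draw enough unique splits")
        perm = rng.permutation(n)
        test_key = tuple(sorted(perm[n_train:].tolist()))
        if test_key in seen:
            continue
        seen.add(test_key)
        train, test = perm[:n_train], perm[n_train:]
        res = DetectionTimeModel(X[train], y[train], intercept=intercept).fit()
        pred = res.predict(X[test])
        ev = evaluate(pred, y[test])
        rows.append({"plcc": ev.plcc, "srocc": ev.srocc, "rmse_s": ev.rmse_s,
                     "n_test": len(test)})
    per_split = pd.DataFrame(rows)
    # a split scored exactly |r| = 1 (e.g. noiseless targets) would make the
    # z transform infinite; nudge inside the open interval at machine scale
    eps = 1e-15
    return EvalResult(
        plcc=fisher_average(np.clip(per_split["plcc"], -1 + eps, 1 - eps)),
        srocc=fisher_average(np.clip(per_split["srocc"], -1 + eps, 1 - eps)),
        rmse_s=float(per_split["rmse_s"].mean()),
        n_splits=n_splits,
        per_split=per_split,
    )


def classify_difficulty(
    features,
    labels,
    method: str = "qda",
    folds: int = 10,
    seed: int = 0,
    reg_param: float = 1e-3,
) -> dict:
    """Stratified k-fold easy/hard classification in the feature space.

    ``method="qda"`` fits quadratic discriminant analysis; ``method="tree"``
    fits a small decision tree capped at four split nodes and reports its
    rules.  Returns overall cross-validated accuracy, the per-sample
    held-out predictions, and (for the tree) a text rendering of the rules
    refitted on the full data.
    """
    from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
    from sklearn.model_selection import StratifiedKFold
    from sklearn.tree import DecisionTreeClassifier, export_text

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateClassError("both difficulty classes must be present")
    if X.shape[0] < folds:
        raise InsufficientDataError("fewer samples than folds")

    def make_clf():
        if method == "qda":
            # light covariance regularisation keeps folds with few or nearly
            # coplanar class members well-posed
            return QuadraticDiscriminantAnalysis(reg_param=reg_param)
        if method == "tree":
            # max_leaf_nodes=5 bounds a binary tree at 4 internal (split) nodes
            return DecisionTreeClassifier(max_leaf_nodes=5, random_state=seed)
        raise ValueError(f"unknown method: {method!r}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(X.shape[0], dtype=y.dtype)
    for train, test in skf.split(X, y):
        clf = make_clf()
        clf.fit(X[train], y[train])
        pred[test] = clf.predict(X[test])
    out = {
        "method": method,
        "accuracy": float(np.mean(pred == y)),
        "predictions": pred,
        "folds": folds,
    }
    if method == "tree":
        full = make_clf().fit(X, y)
        out["n_split_nodes"] = int(full.tree_.node_count - full.tree_.n_leaves)
        out["rules"] = export_text(full, feature_names=FEATURE_NAMES)
    return out
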
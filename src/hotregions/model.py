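"""Elastic-net discrimination of HOT vs control regions.

A penalized (elastic-net) logistic regression is trained per species on the
standardized 339-feature matrix of HOT regions against an equal number of
control regions sampled from below the 85th occupancy percentile (optionally
CpG-island-matched). The penalty strength is chosen by 10-fold
cross-validated deviance; accuracy is reported as the mean out-of-fold ROC
AUC at the chosen penalty. Variable importance is |coefficient| scaled to
0-100 per model and averaged across species; the top features feed a PCA
that visualizes the HOT/COLD separation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, check_X_y

from .intervals import overlaps_any


def sample_controls(
    regions: pd.DataFrame,
    n: int,
    ceiling_percentile: float = 85.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample n control regions uniformly from below the occupancy ceiling.

    Without replacement; reproducible under ``seed``. Raises ValueError
    stating the pool size when fewer than n regions sit below the ceiling.
    """
    pool = regions[regions["percentile"] < ceiling_percentile]
    if len(pool) < n:
        raise ValueError(
            f"control pool below the {ceiling_percentile}th percentile has only "
            f"{len(pool)} regions, need {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool.iloc[np.sort(idx)].reset_index(drop=True)


def cpg_matched_sampling(
    hot_regions: pd.DataFrame,
    control_pool: pd.DataFrame,
    cgi: pd.DataFrame,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample |HOT| controls whose CpG-island overlap fraction matches HOT's.

    The number of CGI-overlapping controls is round(|HOT| * hot_fraction)
    (so the fractions agree to within one region); the remainder is drawn
    from non-overlapping pool members. Raises ValueError with required vs
    available counts when either stratum of the pool is too small.
    """
    n = len(hot_regions)
    hot_in_cgi = overlaps_any(hot_regions, cgi)
    frac = hot_in_cgi.mean() if n else 0.0
    n_cgi = int(round(n * frac))
    n_non = n - n_cgi
    in_cgi = overlaps_any(control_pool, cgi)
    pool_cgi = control_pool[in_cgi]
    pool_non = control_pool[~in_cgi]
    if len(pool_cgi) < n_cgi:
        raise ValueError(
            f"need {n_cgi} CGI-overlapping controls, only {len(pool_cgi)} available"
        )
    if len(pool_non) < n_non:
        raise ValueError(
            f"need {n_non} non-CGI controls, only {len(pool_non)} available"
        )
    rng = np.random.default_rng(seed)
    take_cgi = np.sort(rng.choice(len(pool_cgi), size=n_cgi, replace=False))
    take_non = np.sort(rng.choice(len(pool_non), size=n_non, replace=False))
    out = pd.concat([pool_cgi.iloc[take_cgi], pool_non.iloc[take_non]])
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _lambda_path(
    X: np.ndarray, y01: np.ndarray, alpha: float, n_lambdas: int, eps: float = 1e-3
) -> np.ndarray:
    """glmnet-style decreasing lambda grid for the logistic elastic net."""
    n = X.shape[0]
    resid = y01 - y01.mean()
    lam_max = np.abs(X.T @ resid).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


class HotRegionClassifier(BaseEstimator, ClassifierMixin):
    """Elastic-net logistic discriminator of HOT vs control regions.

    Parameters
    ----------
    alpha : float, default 0.5
        Elastic-net mixing parameter (1 = lasso, 0 = ridge).
    n_folds : int, default 10
        Stratified cross-validation folds for choosing the penalty and
        measuring out-of-fold AUC.
    n_lambdas : int, default 15
        Length of the geometric penalty path.
    lambdas : sequence of float or None
        Explicit penalty grid; overrides ``n_lambdas`` when given.
    max_iter : int, default 5000
        saga iterations per fit.
    random_state : int or None
        Seeds the fold assignment and the solver.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Coefficients of the refit on the full data at the chosen penalty.
    intercept_ : float
    lambda_ : float
        Penalty chosen by cross-validated deviance minimum.
    cv_auc_ : float
        Mean out-of-fold ROC AUC (rank-based) at the chosen penalty.
    cv_deviance_ : ndarray
        Mean out-of-fold deviance per grid point.
    classes_ : ndarray
    """

    def __init__(
        self,
        alpha: float = 0.5,
        n_folds: int = 10,
        n_lambdas: int = 15,
        lambdas: Sequence[float] | None = None,
        max_iter: int = 5000,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambdas = lambdas
        self.max_iter = max_iter
        self.random_state = random_state

    def _make_estimator(self, lam: float, n: int, warm: bool = False) -> LogisticRegression:
        # sklearn's C multiplies the unpenalized likelihood; glmnet's lambda
        # scales the penalty per observation, hence C = 1/(n*lambda)
        return LogisticRegression(
            solver="saga",
            l1_ratio=self.alpha,
            C=1.0 / (n * lam),
            max_iter=self.max_iter,
            tol=1e-4,
            warm_start=warm,
            random_state=self.random_state,
        )

    def fit(self, X, y) -> "HotRegionClassifier":
        X, y = check_X_y(X, y, dtype=np.float64)
        classes, y01 = np.unique(y, return_inverse=True)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 classes, got {classes.size}")
        self.classes_ = classes
        n = X.shape[0]
        if self.lambdas is not None:
            lams = np.asarray(self.lambdas, dtype=float)
        else:
            lams = _lambda_path(X, y01.astype(float), self.alpha, self.n_lambdas)
        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        folds = list(skf.split(X, y01))
        deviance = np.zeros(lams.size)
        oof_scores = np.zeros((lams.size, n))
        # lambdas run strongest-first so warm starts walk the path cheaply
        path_order = np.argsort(-lams)
        for tr, te in folds:
            if np.unique(y01[tr]).size < 2:
                raise ValueError("a CV fold lost one class; need >=2 per class per fold")
            est = self._make_estimator(lams[path_order[0]], len(tr), warm=True)
            for j in path_order:
                est.C = 1.0 / (len(tr) * lams[j])
                est.fit(X[tr], y01[tr])
                p = est.predict_proba(X[te])[:, 1]
                oof_scores[j, te] = p
                deviance[j] += log_loss(y01[te], p, labels=[0, 1]) * len(te)
        deviance /= n
        best = int(np.argmin(deviance))
        self.lambda_ = float(lams[best])
        self.cv_deviance_ = deviance
        self.lambda_path_ = lams
        aucs = []
        for tr, te in folds:
            if np.unique(y01[te]).size == 2:
                aucs.append(roc_auc_score(y01[te], oof_scores[best, te]))
        self.cv_auc_ = float(np.mean(aucs)) if aucs else float("nan")
        final = self._make_estimator(self.lambda_, n)
        final.fit(X, y01)
        self.coef_ = final.coef_.ravel()
        self.intercept_ = float(final.intercept_[0])
        self._estimator = final
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def train_elastic_net(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    folds: int = 10,
    alpha: float = 0.5,
    seed: int | None = None,
) -> HotRegionClassifier:
    """Functional wrapper: fit a HotRegionClassifier on a labelled matrix."""
    clf = HotRegionClassifier(alpha=alpha, n_folds=folds, random_state=seed)
    return clf.fit(matrix.to_numpy(dtype=float), np.asarray(labels))


def variable_importance(
    fit: HotRegionClassifier | Mapping[str, float],
    feature_names: Sequence[str] | None = None,
) -> pd.Series:
    """|coefficient| scaled so the largest is 100 (all 0 if all coefs are 0)."""
    if isinstance(fit, HotRegionClassifier):
        check_is_fitted(fit, "coef_")
        names = feature_names if feature_names is not None else range(len(fit.coef_))
        coefs = pd.Series(fit.coef_, index=list(names))
    else:
        coefs = pd.Series(dict(fit), dtype=float)
    imp = coefs.abs()
    m = imp.max()
    if m == 0:
        return imp * 0.0
    return imp / m * 100.0


def average_importance(tables: Sequence[pd.Series]) -> pd.Series:
    """Per-feature mean of importance tables; features absent in a table count 0."""
    if len(tables) == 0:
        raise ValueError("need at least one importance table")
    df = pd.DataFrame({i: t for i, t in enumerate(tables)}).fillna(0.0)
    return df.mean(axis=1)


def top_features(importance: pd.Series, k: int = 10) -> list[str]:
    """Top-k feature names by score, lexicographic tie-break (deterministic)."""
    order = sorted(importance.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in order[:k]]


def pca_top_features(
    matrix: pd.DataFrame,
    features: Sequence[str],
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA on the standardized submatrix of the given features.

    Returns (coordinates on PC1/PC2 as a DataFrame indexed like ``matrix``,
    explained-variance fractions). Raises when a feature is missing, when
    there are fewer rows than components, or when the submatrix is constant.
    """
    missing = [f for f in features if f not in matrix.columns]
    if missing:
        raise ValueError(f"features not in matrix: {missing}")
    sub = matrix[list(features)].to_numpy(dtype=float)
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 regions for a 2-component PCA")
    mean = sub.mean(axis=0)
    std = sub.std(axis=0)
    if (std == 0).all():
        raise ValueError("all selected features have zero variance")
    std = np.where(std == 0, 1.0, std)
    z = (sub - mean) / std
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(z)
    out = pd.DataFrame(coords, columns=["PC1", "PC2"], index=matrix.index)
    return out, pca.explained_variance_ratio_
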
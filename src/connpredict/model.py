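"""Sparse prediction of trait scores from edge features.

The modeling procedure:

1. Sex is regressed out of every edge feature on the full cohort (simple
   linear regression on a binary indicator with intercept; the residual of
   a subject's feature equals its value minus the mean of the subject's
   own sex group).
2. The LASSO penalty weight lambda is chosen once, before the prediction
   cross-validation, by maximizing the Pearson correlation between
   leave-one-out predictions and the observed scores over the candidate
   lambdas given by the LARS path knots.
3. Predictive power is measured by repeated leave-k-subjects-out
   cross-validation (k = 10, 10 repeats): in each repeat the cohort is
   randomly partitioned into folds, a LASSO model is fitted on each
   training complement and applied (intercept + betas) to the held-out
   subjects, and the pooled held-out predictions are correlated with the
   observed scores. The final statistic R is the mean of the 10 per-repeat
   correlations.

Selecting lambda on the full cohort before the prediction CV (and
residualizing on the full cohort) is the original form of this analysis
design and is the default here; both choices leak information across the
CV boundary and inflate R under the null. A fully nested variant (lambda
re-selected inside every training fold) is available via ``nested=True`` /
the CLI ``--nested-lambda`` flag.

The LASSO objective throughout is
``(1/(2n)) * sum((y - b0 - X @ b)**2) + lam * sum(|b|)``.
Features are z-scored with training-set statistics inside every fit; the
lambda scale therefore refers to standardized features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.linear_model import Lasso, lars_path

from .connectivity import FeatureTable
from .exceptions import CovariateError, DataError, NumericError, PartitionError

log = logging.getLogger(__name__)

__all__ = [
    "LassoModel",
    "PredictionResult",
    "CohortFeatures",
    "residualize_on_sex",
    "fit_lasso",
    "lars_lambda_path",
    "select_lambda_loocv",
    "leave_k_out_cv",
    "predict_trait",
    "SexResidualizer",
    "StandardizedLasso",
    "LassoLarsLOOCV",
]


# --------------------------------------------------------------------------
# residualization
# --------------------------------------------------------------------------

class SexResidualizer(BaseEstimator, TransformerMixin):
    """Column-wise removal of a binary covariate by linear regression.

    ``fit(X, sex)`` regresses every feature column on the covariate (with
    intercept); ``transform(X, sex)`` subtracts the fitted values. For a
    binary covariate the fitted value of a subject is the mean of the
    subject's covariate group in the training data.
    """

    def fit(self, X, sex):
        X = np.asarray(X, dtype=float)
        sex = np.asarray(sex, dtype=float)
        levels = np.unique(sex)
        if levels.size < 2:
            raise CovariateError("both sexes must be present to residualize")
        s = sex - sex.mean()
        denom = float(s @ s)
        self.slope_ = (s @ X) / denom
        self.sex_mean_ = float(sex.mean())
        self.intercept_ = X.mean(axis=0)
        return self

    def transform(self, X, sex):
        X = np.asarray(X, dtype=float)
        s = np.asarray(sex, dtype=float) - self.sex_mean_
        return X - (self.intercept_ + np.outer(s, self.slope_))


def residualize_on_sex(features: FeatureTable | np.ndarray, sex):
    """Replace each feature column by its residual from a regression on sex."""
    X = features.X if isinstance(features, FeatureTable) else np.asarray(features, float)
    res = SexResidualizer().fit(X, sex).transform(X, sex)
    if isinstance(features, FeatureTable):
        return FeatureTable(list(features.subjects), res, list(features.edge_labels))
    return res


# --------------------------------------------------------------------------
# LASSO primitives
# --------------------------------------------------------------------------

@dataclass
class LassoModel:
    """Fitted LASSO coefficients at a given penalty weight."""

    intercept: float
    betas: np.ndarray
    lam: float

    def predict(self, X) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.betas


def _check_finite(X, y):
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise NumericError("non-finite values in design matrix or response")


def fit_lasso(X, y, lam: float) -> LassoModel:
    """Minimize (1/(2n))||y - b0 - Xb||^2 + lam * ||b||_1.

    No internal standardization: coefficients refer to the columns of X as
    given. ``lam = 0`` reduces to least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(X, y)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if y.std() == 0:
        raise DataError("constant response")
    if lam == 0:
        A = np.column_stack([np.ones(len(y)), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return LassoModel(float(coef[0]), coef[1:], 0.0)
    est = Lasso(alpha=lam, fit_intercept=True, max_iter=500_000, tol=1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return LassoModel(float(est.intercept_), est.coef_.copy(), float(lam))


def lars_lambda_path(X, y) -> np.ndarray:
    """Penalty weights at which the LASSO active set changes.

    Strictly decreasing sequence from lambda_max = max_j |x_j'(y - ybar)|/n
    down to 0 (the least-angle-regression knots of the LASSO path).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(X, y)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc.std(axis=0) > 0):
        raise DataError("design has no non-constant columns")
    yc = y - y.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alphas, _, _ = lars_path(Xc, yc, method="lasso")
    alphas = np.asarray(alphas, dtype=float)
    if alphas[-1] > 0:
        alphas = np.append(alphas, 0.0)
    keep = np.concatenate([[True], np.diff(alphas) < 0])  # enforce strict decrease
    return alphas[keep]


def _path_coefs_at(X, y, lambdas: np.ndarray) -> tuple[float, np.ndarray]:
    """Coefficients of the LASSO path evaluated at arbitrary lambdas.

    Exploits piecewise linearity of the path in lambda: one LARS pass,
    then linear interpolation between knots. X is expected pre-centered /
    standardized by the caller; y is centered internally. Returns
    (y_mean, coefs with shape (m, len(lambdas)))."""
    yc = y - y.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alphas, _, coefs = lars_path(X, yc, method="lasso")
    # np.interp needs increasing x
    order = np.argsort(alphas)
    a_sorted = alphas[order]
    out = np.empty((X.shape[1], len(lambdas)))
    for j in range(X.shape[1]):
        cj = coefs[j, order]
        out[j] = np.interp(lambdas, a_sorted, cj, left=cj[0], right=0.0)
    return float(y.mean()), out


class StandardizedLasso(BaseEstimator, RegressorMixin):
    """LASSO at a fixed penalty with training-set z-scoring of features.

    Test-set features are standardized with the training means and
    standard deviations; constant training columns are centered only.
    """

    def __init__(self, lam: float = 0.1):
        self.lam = lam

    def _standardize(self, X):
        return (np.asarray(X, dtype=float) - self.mu_) / self.scale_

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        _check_finite(X, y)
        self.mu_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        model = fit_lasso(self._standardize(X), y, self.lam)
        self.coef_ = model.betas
        self.intercept_ = model.intercept
        self.model_ = model
        return self

    def predict(self, X):
        return self.model_.predict(self._standardize(X))


def _safe_corr(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def select_lambda_loocv(
    X, y, candidates=None, eps: float = 1e-3, return_scores: bool = False
):
    """Choose lambda by leave-one-out prediction correlation.

    For every candidate lambda, each subject is predicted from a LASSO
    model fitted (with fold-internal z-scoring) on the other N-1 subjects;
    the candidate maximizing corr(yhat_loo, y) wins, ties broken toward
    the largest lambda (sparsest model). Candidates with degenerate
    (zero-variance) predictions are skipped; if every candidate is
    degenerate the largest candidate is returned with a warning.

    Auto-generated candidates are the LARS path knots of the standardized
    full-data problem plus the geometric midpoint of every consecutive
    knot pair (between knots the active set is constant but predictions
    still move, so knots alone can all be degenerate — e.g. a single-knot
    path whose only knot is lambda_max). The grid is floored at
    ``eps * lambda_max`` — the same ratio convention sklearn's own alpha
    grids use — because coordinate descent is numerically degenerate at
    penalties near machine precision when features outnumber subjects.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise DataError("need at least 4 subjects for leave-one-out selection")
    if candidates is None:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Z = (X - mu) / np.where(sd > 0, sd, 1.0)
        knots = lars_lambda_path(Z, y)
        knots = np.unique(np.clip(knots, eps * knots[0], None))[::-1]
        mids = np.sqrt(knots[:-1] * knots[1:])
        candidates = np.unique(np.concatenate([knots, mids]))[::-1]
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0:
        raise DataError("empty candidate sequence")
    order = np.argsort(candidates)[::-1]
    candidates = candidates[order]  # decreasing: argmax tie -> largest lambda

    preds = np.empty((n, candidates.size))
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        Xtr, ytr = X[tr], y[tr]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        scale = np.where(sd > 0, sd, 1.0)
        ybar, coefs = _path_coefs_at((Xtr - mu) / scale, ytr, candidates)
        preds[i] = ybar + ((X[i] - mu) / scale) @ coefs

    scores = np.array([_safe_corr(preds[:, c], y) for c in range(candidates.size)])
    if np.all(np.isnan(scores)):
        warnings.warn(
            "all candidate lambdas gave degenerate LOO predictions; "
            "falling back to lambda_max", RuntimeWarning,
        )
        best = 0
    else:
        best = int(np.nanargmax(scores))
    lam = float(candidates[best])
    if return_scores:
        return lam, candidates, scores
    return lam


# --------------------------------------------------------------------------
# repeated leave-k-out cross-validation
# --------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """Cross-validated prediction of one subscale from one network's edges."""

    subscale: str
    network_set: str
    lam: float
    per_repeat_R: np.ndarray          # (repeats,)
    predicted: np.ndarray             # (N, repeats) pooled held-out predictions
    actual: np.ndarray                # (N,)
    n_subjects: int = field(init=False)

    def __post_init__(self) -> None:
        self.per_repeat_R = np.asarray(self.per_repeat_R, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.actual = np.asarray(self.actual, dtype=float)
        self.n_subjects = self.actual.shape[0]

    @property
    def R(self) -> float:
        """Mean over repeats of corr(pooled held-out predictions, actual)."""
        return float(self.per_repeat_R.mean())


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into floor(n/k) folds of size k plus a remainder fold."""
    perm = rng.permutation(n)
    sizes = [k] * (n // k)
    if n % k:
        sizes.append(n % k)
    folds, start = [], 0
    for s in sizes:
        folds.append(perm[start:start + s])
        start += s
    return folds


def leave_k_out_cv(
    X,
    y,
    lam: float | None,
    k: int = 10,
    repeats: int = 10,
    seed: int | np.random.SeedSequence = 0,
    subscale: str = "",
    network_set: str = "",
    nested: bool = False,
) -> PredictionResult:
    """Repeated leave-k-subjects-out cross-validated prediction.

    Per repeat, subjects are randomly partitioned into folds (all of size
    `k` except a smaller remainder fold); each fold is predicted by a
    LASSO model fitted on its complement at penalty `lam`; the per-repeat
    statistic is the Pearson correlation between the pooled held-out
    predictions and `y`. With ``nested=True`` (or ``lam=None``) lambda is
    re-selected by leave-one-out within every training complement.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k >= n:
        raise PartitionError(f"fold size k={k} must be smaller than N={n}")
    if k < 1 or repeats < 1:
        raise PartitionError("k and repeats must be positive")
    if lam is not None and lam < 0:
        raise ValueError("lam must be >= 0")
    nested = nested or lam is None

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    repeat_seeds = ss.spawn(repeats)

    per_R = np.empty(repeats)
    preds = np.empty((n, repeats))
    for r in range(repeats):
        rng = np.random.default_rng(repeat_seeds[r])
        yhat = np.empty(n)
        for f, test in enumerate(_fold_indices(n, k, rng)):
            log.debug("%s x %s repeat %d fold %d held-out subjects: %s",
                      network_set, subscale, r, f, test.tolist())
            train = np.setdiff1d(np.arange(n), test)
            lam_fold = (
                select_lambda_loocv(X[train], y[train]) if nested else float(lam)
            )
            est = StandardizedLasso(lam=lam_fold).fit(X[train], y[train])
            yhat[test] = est.predict(X[test])
        c = _safe_corr(yhat, y)
        if np.isnan(c):
            warnings.warn(
                "held-out predictions constant in one repeat; scoring R=0",
                RuntimeWarning,
            )
            c = 0.0
        per_R[r] = c
        preds[:, r] = yhat
    return PredictionResult(
        subscale=subscale,
        network_set=network_set,
        lam=float(lam) if lam is not None else float("nan"),
        per_repeat_R=per_R,
        predicted=preds,
        actual=y,
    )


@dataclass
class CohortFeatures:
    """Edge features, trait scores and sex for one cohort, subject-aligned."""

    features: FeatureTable
    traits: "object"  # pandas DataFrame with FS/EC/PT/PD columns
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex)
        n = len(self.features.subjects)
        if len(self.traits) != n or len(self.sex) != n:
            raise DataError("features, traits and sex must align")
        if n < 12:
            raise DataError("cohort too small for leave-10-out (need N >= 12)")

    @property
    def N(self) -> int:
        return len(self.features.subjects)


def predict_trait(
    cohort: CohortFeatures,
    subscale: str,
    k: int = 10,
    repeats: int = 10,
    seed: int | np.random.SeedSequence = 0,
    nested: bool = False,
    network_set: str = "",
) -> PredictionResult:
    """Full modeling path for one (network set, subscale) cell.

    Residualizes the features on sex (full cohort), selects lambda by
    leave-one-out on the full cohort (unless `nested`), and runs the
    repeated leave-k-out prediction CV.
    """
    y = np.asarray(cohort.traits[subscale], dtype=float)
    Xr = residualize_on_sex(cohort.features.X, cohort.sex)
    lam = None if nested else select_lambda_loocv(Xr, y)
    return leave_k_out_cv(
        Xr, y, lam, k=k, repeats=repeats, seed=seed,
        subscale=subscale, network_set=network_set, nested=nested,
    )


class LassoLarsLOOCV(BaseEstimator, RegressorMixin):
    """LASSO regressor whose penalty is tuned by leave-one-out correlation.

    ``fit`` z-scores the features, takes the LARS path knots as candidate
    penalties, selects the one maximizing the leave-one-out prediction
    correlation (ties toward the sparsest model) and refits on all data.

    Attributes
    ----------
    lambda_ : float
        Selected penalty (standardized-feature scale).
    coef_, intercept_ : fitted coefficients.
    """

    def __init__(self, candidates=None):
        self.candidates = candidates

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.lambda_ = select_lambda_loocv(X, y, candidates=self.candidates)
        self._inner = StandardizedLasso(lam=self.lambda_).fit(X, y)
        self.coef_ = self._inner.coef_
        self.intercept_ = self._inner.intercept_
        return self

    def predict(self, X):
        return self._inner.predict(X)
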
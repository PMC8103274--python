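"""Statistical comparison layer.

Implements the study-style analysis: the clinically-important-difference
(CID) label on the UPDRS-III motor score, laterality t-tests, a linear-kernel
SVM classifier with sigmoid-calibrated posterior scores evaluated with and
without stratified 5-fold cross-validation, nonparametric ROC analysis with a
placement-based (DeLong) correlated-AUC comparison, logistic regression with
Wald inference, and linear-kernel SVM regression of UPDRS-III with a
stratified 70/30 hold-out.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .errors import AnalysisError

#: UPDRS-III threshold above which motor dysfunction counts as a clinically
#: important difference (strict inequality).
CID_THRESHOLD = 10
UPDRS_MAX = 132


@dataclass(frozen=True)
class PatientRecord:
    """Demographics and clinical scores for one enrolled patient."""

    patient_id: str
    age: float
    male: bool
    right_handed: bool
    pd_meds: bool
    updrs3: int
    hy: float
    moca: int

    def __post_init__(self):
        if not 0 <= self.updrs3 <= UPDRS_MAX:
            raise AnalysisError(f"updrs3 {self.updrs3} outside [0, {UPDRS_MAX}]")

    @property
    def cid(self) -> bool:
        return label_cid(self.updrs3)


def label_cid(updrs3: float) -> bool:
    """CID in motor dysfunction: UPDRS-III strictly greater than 10."""
    if not 0 <= updrs3 <= UPDRS_MAX:
        raise AnalysisError(f"updrs3 {updrs3} outside [0, {UPDRS_MAX}]")
    return updrs3 > CID_THRESHOLD


# ---------------------------------------------------------------------------
# laterality t-tests


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool = False  # zero-variance paired difference


def laterality_ttest(left, right, mode: str = "two_sample") -> TTestResult:
    """Compare left vs right measurements with Student's t-test.

    ``mode='two_sample'`` (default) is the classic equal-variance test;
    ``mode='paired'`` pairs observations by position.  A paired comparison
    whose differences have zero variance is degenerate: identical sides give
    (t=0, p=1); a pure constant shift gives the p->0 limit, flagged.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size < 2 or right.size < 2:
        raise AnalysisError("need at least 2 observations per side")
    if mode == "two_sample":
        t, p = sstats.ttest_ind(left, right, equal_var=True)
        return TTestResult(float(t), float(p))
    if mode == "paired":
        if left.size != right.size:
            raise AnalysisError("paired mode requires equal-length sides")
        diff = left - right
        if np.ptp(diff) == 0:
            if diff[0] == 0:
                return TTestResult(0.0, 1.0, degenerate=True)
            return TTestResult(math.copysign(math.inf, diff[0]), 0.0, degenerate=True)
        t, p = sstats.ttest_rel(left, right)
        return TTestResult(float(t), float(p))
    raise AnalysisError(f"unknown t-test mode {mode!r}")


# ---------------------------------------------------------------------------
# ROC / AUC with placement (DeLong) variance


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    diff: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float


def _split_by_label(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise AnalysisError("scores and labels must have equal length")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise AnalysisError("both classes must be present")
    return pos, neg


def auc_placements(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Midrank placements underlying the Mann-Whitney AUC.

    Returns ``(V10, V01)``: for each positive case the fraction of negatives
    it outranks (ties count half), and symmetrically for each negative case.
    ``V10.mean() == V01.mean() == AUC``.
    """
    pos, neg = _split_by_label(scores, labels)
    cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC with a placement-variance (DeLong) standard error.

    The AUC equals the Mann-Whitney probability that a random positive
    outscores a random negative, ties counted half.  The 95% CI is normal on
    the AUC scale, clipped to [0, 1].
    """
    v10, v01 = auc_placements(scores, labels)
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = math.sqrt(max(var, 0.0))
    half = 1.959963984540054 * se
    fpr, tpr, _ = roc_curve(np.asarray(labels).astype(int), scores)
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        auc_se=se,
        ci95=(max(0.0, auc - half), min(1.0, auc + half)),
        n_pos=m,
        n_neg=n,
    )


def compare_auc(scores_a, scores_b, labels) -> AucComparison:
    """Two-sided test of equal AUCs for two score vectors on the same cases.

    Placement-based correlated-ROC (DeLong) test: the covariance between the
    two AUCs is estimated from the empirical covariance of the per-case
    placements, so within-patient correlation of the two markers is
    respected.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise AnalysisError("score vectors must have equal length")
    v10a, v01a = auc_placements(scores_a, labels)
    v10b, v01b = auc_placements(scores_b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var_a = s10[0, 0] / m + s01[0, 0] / n
    var_b = s10[1, 1] / m + s01[1, 1] / n
    cov = s10[0, 1] / m + s01[0, 1] / n
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    diff = auc_a - auc_b
    var_diff = var_a + var_b - 2 * cov
    if diff == 0.0:
        z, p = 0.0, 1.0
    elif var_diff <= 0:
        z, p = math.copysign(math.inf, diff), 0.0
    else:
        z = diff / math.sqrt(var_diff)
        p = 2 * sstats.norm.sf(abs(z))
    return AucComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        diff=diff,
        var_a=float(var_a),
        var_b=float(var_b),
        cov_ab=float(cov),
        z=float(z),
        p=float(p),
    )


# ---------------------------------------------------------------------------
# SVM classification with posterior scores


@dataclass(frozen=True)
class ClassifierEval:
    """Posterior scores plus ROC summary for one feature set."""

    scores: np.ndarray  # posterior P(CID) per patient, in [0, 1]
    folds: np.ndarray | None  # held-out fold index per patient, None = resub
    roc: RocResult
    labels: np.ndarray

    @property
    def auc(self) -> float:
        return self.roc.auc


def _as_matrix(features) -> np.ndarray:
    X = features.to_numpy(dtype=float) if hasattr(features, "to_numpy") else np.asarray(
        features, dtype=float
    )
    if X.ndim != 2:
        raise AnalysisError("feature matrix must be 2-D")
    if np.isnan(X).any():
        raise AnalysisError("feature matrix contains missing values; drop those rows")
    return X


def _platt_posteriors(clf, scaler, X_train, y_train, X_eval):
    """Sigmoid calibration of SVM decision values on the training data."""
    d_train = clf.decision_function(scaler.transform(X_train)).reshape(-1, 1)
    cal = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10_000)
    cal.fit(d_train, y_train)
    d_eval = clf.decision_function(scaler.transform(X_eval)).reshape(-1, 1)
    return cal.predict_proba(d_eval)[:, 1]


def fit_svm_classifier(
    features,
    labels,
    cv_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> ClassifierEval:
    """Linear-kernel SVM detection of CID with posterior probability scores.

    Features are standardised internally (scaler fitted on the training
    portion only).  With ``cv_folds >= 2`` each patient's posterior comes
    from the fold where it was held out (stratified K-fold, shuffled by
    ``seed``); with ``cv_folds=0`` the scores are resubstitution scores.
    Posteriors are obtained by fitting a sigmoid to the SVM decision values.
    """
    X = _as_matrix(features)
    y = np.asarray(labels).astype(int)
    if y.shape[0] != X.shape[0]:
        raise AnalysisError("labels and features must have equal length")
    if np.unique(y).size < 2:
        raise AnalysisError("labels contain a single class")
    scores = np.empty(X.shape[0])
    if cv_folds == 0:
        scaler = StandardScaler().fit(X)
        clf = SVC(kernel="linear", C=C)
        clf.fit(scaler.transform(X), y)
        scores = _platt_posteriors(clf, scaler, X, y, X)
        folds = None
    else:
        if cv_folds < 2:
            raise AnalysisError("cv_folds must be 0 or >= 2")
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = np.empty(X.shape[0], dtype=int)
        for k, (tr, te) in enumerate(skf.split(X, y)):
            scaler = StandardScaler().fit(X[tr])
            clf = SVC(kernel="linear", C=C)
            clf.fit(scaler.transform(X[tr]), y[tr])
            scores[te] = _platt_posteriors(clf, scaler, X[tr], y[tr], X[te])
            folds[te] = k
    return ClassifierEval(scores=scores, folds=folds, roc=roc_auc(scores, y), labels=y)


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class LogisticFit:
    """Per-feature Wald inference from a maximum-likelihood logistic fit."""

    table: pd.DataFrame  # index: feature; columns: beta, se, odds_ratio, p_value
    converged: bool
    separation: bool
    llf: float


def fit_logistic(design: pd.DataFrame, labels) -> LogisticFit:
    """Logistic regression of the CID label on clinical + score features.

    An intercept is added; inference is Wald (SE from the observed
    information).  Complete or quasi-complete separation is detected and
    flagged on the result rather than raised.
    """
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design, dtype=float))
    y = np.asarray(labels).astype(int)
    if design.shape[0] != y.size:
        raise AnalysisError("design and labels must have equal length")
    if design.shape[0] <= design.shape[1]:
        raise AnalysisError("need more observations than features")
    for col in design.columns:
        if design[col].nunique() <= 1:
            raise AnalysisError(f"constant design column {col!r}")
    X = sm.add_constant(design.astype(float), has_constant="raise")
    separation = False
    model = sm.Logit(y, X)
    # (quasi-)separation produces benign overflow/invalid warnings on the way
    # to the flagged result; suppress them and report the flag instead
    with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # PerfectSeparationError and friends
            separation = True
            res = model.fit(disp=0, method="bfgs", maxiter=500, skip_hessian=False)
            converged = False
        fitted = res.predict(X)
    if np.all((fitted > 0.999) == (y == 1)) and np.all((fitted < 0.001) == (y == 0)):
        separation = True
    table = pd.DataFrame(
        {
            "beta": res.params,
            "se": res.bse,
            "odds_ratio": np.exp(res.params),
            "p_value": res.pvalues,
        }
    )
    return LogisticFit(
        table=table, converged=converged, separation=separation, llf=float(res.llf)
    )


# ---------------------------------------------------------------------------
# SVM regression of UPDRS-III


@dataclass(frozen=True)
class SplitEval:
    split: str  # all | train | test
    n: int
    r_squared: float  # squared Pearson correlation of predicted vs observed
    p_value: float  # two-sided test of zero correlation
    r_squared_sse: float  # 1 - SSE/SST alternative
    degenerate: bool = False


@dataclass(frozen=True)
class RegressionEval:
    mse_resub: float
    splits: dict = field(default_factory=dict)  # name -> SplitEval
    predictions: pd.DataFrame | None = None  # index, observed, predicted, split
    n_dropped_missing: int = 0


def mse(predicted, targets) -> float:
    """Mean squared error between prediction and target vectors."""
    predicted = np.asarray(predicted, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predicted.shape != targets.shape or predicted.size == 0:
        raise AnalysisError("predicted and targets must be nonempty, equal-length")
    return float(np.mean((predicted - targets) ** 2))


def _split_eval(name: str, observed, predicted) -> SplitEval:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    sse = float(np.sum((observed - predicted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    r2_sse = 1.0 - sse / sst if sst > 0 else math.nan
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return SplitEval(name, observed.size, 0.0, 1.0, r2_sse, degenerate=True)
    r, p = sstats.pearsonr(observed, predicted)
    return SplitEval(name, observed.size, float(r**2), float(p), r2_sse)


def fit_svm_regressor(
    features,
    updrs3,
    holdout_frac: float = 0.30,
    seed: int = 0,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> RegressionEval:
    """Linear-kernel SVM regression of the UPDRS-III motor score.

    Rows with any missing feature or target are dropped first.  A model fit
    on all remaining rows supplies the resubstitution MSE and the "all"
    split; a stratified (by CID label) 70/30 hold-out supplies the train and
    test splits.  Goodness of fit per split is the squared Pearson
    correlation between predicted and observed scores, with the two-sided
    p-value of zero correlation; 1 - SSE/SST is reported alongside.
    """
    if isinstance(features, pd.DataFrame):
        X_all = features.to_numpy(dtype=float)
        index = features.index.to_numpy()
    else:
        X_all = np.asarray(features, dtype=float)
        index = np.arange(X_all.shape[0])
    y_all = np.asarray(updrs3, dtype=float)
    if y_all.size != X_all.shape[0]:
        raise AnalysisError("updrs3 and features must have equal length")
    keep = ~(np.isnan(X_all).any(axis=1) | np.isnan(y_all))
    n_dropped = int((~keep).sum())
    X, y, index = X_all[keep], y_all[keep], index[keep]
    if X.shape[0] < 10:
        raise AnalysisError(
            f"only {X.shape[0]} complete rows after missing-value exclusion (need >= 10)"
        )

    def make_model():
        return Pipeline(
            [("scale", StandardScaler()), ("svr", SVR(kernel="linear", C=C, epsilon=epsilon))]
        )

    full = make_model().fit(X, y)
    pred_all = full.predict(X)
    mse_resub = mse(pred_all, y)

    strat = np.array([label_cid(min(v, UPDRS_MAX)) for v in np.clip(y, 0, UPDRS_MAX)])
    idx = np.arange(X.shape[0])
    tr, te = train_test_split(
        idx, test_size=holdout_frac, random_state=seed, stratify=strat
    )
    held = make_model().fit(X[tr], y[tr])
    pred_tr = held.predict(X[tr])
    pred_te = held.predict(X[te])

    split_tag = np.empty(X.shape[0], dtype=object)
    split_tag[tr], split_tag[te] = "train", "test"
    predicted = np.empty(X.shape[0])
    predicted[tr], predicted[te] = pred_tr, pred_te
    predictions = pd.DataFrame(
        {
            "observed": y,
            "predicted_all": pred_all,
            "predicted_holdout": predicted,
            "split": split_tag,
        },
        index=index,
    )
    return RegressionEval(
        mse_resub=mse_resub,
        splits={
            "all": _split_eval("all", y, pred_all),
            "train": _split_eval("train", y[tr], pred_tr),
            "test": _split_eval("test", y[te], pred_te),
        },
        predictions=predictions,
        n_dropped_missing=n_dropped,
    )
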
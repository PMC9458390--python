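"""Classification of KS feature vectors: BO-SVM and baseline families.

The protocol mirrors a clinical two-class study: stratified 80/20
train/test split, per-feature min-max scaling fitted on the training rows
only, 10-fold cross-validation on the training split, and evaluation with
accuracy, sensitivity, specificity, precision and F1 (CHF is the positive
class throughout, so sensitivity is the patient detection rate).

The headline classifier is an RBF-kernel SVM whose penalty c and kernel
scale g are chosen by Bayesian optimization: a Gaussian-process surrogate
over (log10 c, log10 g) is fitted to the cross-validated accuracies
observed so far and the next point maximizes expected improvement.
Baselines are the preset families a clinical ML study would report:
fine/medium/coarse decision trees, fine/medium/cosine KNN, Gaussian and
kernel-density Naive Bayes, and 30-learner AdaBoost / bagged-tree /
RUSBoost ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .audio_io import logger

__all__ = [
    "FAMILIES", "POSITIVE_CLASS", "MinMaxScalerParams", "DatasetSplit",
    "TrainedModel", "MetricsReport", "minmax_scale", "split_dataset",
    "crossval_score", "bo_svm_train", "train_baseline", "evaluate",
]

POSITIVE_CLASS = "chf"

FAMILIES = [
    "dt_fine", "dt_medium", "dt_coarse",
    "knn_fine", "knn_medium", "knn_cosine",
    "nb_gaussian", "nb_kernel",
    "em_adaboost", "em_bagged", "em_rusboost",
    "bo_svm",
]

#: preset maximum split counts for the decision-tree family
DT_MAX_SPLITS = {"dt_fine": 100, "dt_medium": 20, "dt_coarse": 4}
#: learners per ensemble
N_ENSEMBLE = 30
#: BO search box: log10 penalty c and log10 RBF kernel scale g
BO_BOUNDS = np.array([[-3.0, 3.0], [-4.0, 1.0]])
BO_N_INITIAL = 5


# ------------------------------------------------------------- containers

@dataclass
class MinMaxScalerParams:
    """Per-feature min/max learned from training rows only."""

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        out = np.zeros_like(X, dtype=np.float64)
        ok = span > 0
        out[:, ok] = (X[:, ok] - self.mins[ok]) / span[ok]
        return out


@dataclass
class DatasetSplit:
    """Stratified train/test partition of one feature set."""

    train_X: np.ndarray
    train_y: np.ndarray
    test_X: np.ndarray
    test_y: np.ndarray
    feature_set: str = "C"
    seed: int = 0


@dataclass
class TrainedModel:
    """A fitted preset with its scaler and training CV accuracy."""

    family: str
    hyperparams: dict
    scaler: MinMaxScalerParams
    estimator: object
    cv_score: float = float("nan")
    history: list = field(default_factory=list)


@dataclass
class MetricsReport:
    """Confusion counts and the five evaluation metrics.

    The metric identities (accuracy as the weighted mean of sensitivity
    and specificity, F1 as the harmonic mean of sensitivity and
    precision) are asserted on construction.
    """

    TP: int
    FN: int
    TN: int
    FP: int
    Acc: float
    Se: float
    Sp: float
    Ps: float
    F1: float

    def __post_init__(self) -> None:
        total = self.TP + self.FN + self.TN + self.FP
        assert abs(self.Acc - (self.TP + self.TN) / total) < 1e-12
        assert abs(self.Se - self.TP / (self.TP + self.FN)) < 1e-12
        assert abs(self.Sp - self.TN / (self.TN + self.FP)) < 1e-12
        assert abs(self.Ps - self.TP / (self.TP + self.FP)) < 1e-12
        f1 = 2 * self.Se * self.Ps / (self.Se + self.Ps) if self.Se + self.Ps else 0.0
        assert abs(self.F1 - f1) < 1e-12

    @classmethod
    def from_counts(cls, TP: int, FN: int, TN: int, FP: int) -> "MetricsReport":
        if TP + FN == 0:
            raise ValueError("sensitivity undefined: no positive samples")
        if TN + FP == 0:
            raise ValueError("specificity undefined: no negative samples")
        if TP + FP == 0:
            raise ValueError("precision undefined: no positive predictions")
        Se = TP / (TP + FN)
        Sp = TN / (TN + FP)
        Ps = TP / (TP + FP)
        F1 = 2 * Se * Ps / (Se + Ps) if Se + Ps else 0.0
        return cls(TP=TP, FN=FN, TN=TN, FP=FP,
                   Acc=(TP + TN) / (TP + FN + TN + FP),
                   Se=Se, Sp=Sp, Ps=Ps, F1=F1)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("TP", "FN", "TN", "FP", "Acc", "Se", "Sp", "Ps", "F1")}


# ------------------------------------------------------- custom learners

class TieBreakKNN:
    """K-nearest-neighbour vote with ties broken by the nearest neighbour."""

    def __init__(self, k: int, metric: str = "euclidean"):
        self.k = k
        self.metric = metric

    def fit(self, X, y):
        self._nn = NearestNeighbors(n_neighbors=self.k, metric=self.metric).fit(X)
        self._y = np.asarray(y)
        self.classes_ = np.unique(self._y)
        return self

    def predict(self, X):
        _, idx = self._nn.kneighbors(np.asarray(X))
        out = np.empty(len(X), dtype=self._y.dtype)
        for i, neigh in enumerate(idx):
            labels = self._y[neigh]
            counts = {c: int(np.sum(labels == c)) for c in self.classes_}
            top = max(counts.values())
            winners = [c for c, n in counts.items() if n == top]
            out[i] = labels[0] if len(winners) > 1 else winners[0]
        return out


class KernelNaiveBayes:
    """Naive Bayes with per-feature Gaussian kernel density estimates.

    Rule-of-thumb (Silverman) bandwidth per class and feature; features
    are treated as conditionally independent, as in Gaussian NB.
    """

    _MIN_BW = 1e-6

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._train, self._bw, self._log_prior = {}, {}, {}
        for c in self.classes_:
            Xc = X[y == c]
            n = len(Xc)
            std = np.std(Xc, axis=0, ddof=1) if n > 1 else np.zeros(X.shape[1])
            iqr = np.subtract(*np.percentile(Xc, [75, 25], axis=0))
            spread = np.where(iqr > 0, np.minimum(std, iqr / 1.34), std)
            bw = 0.9 * spread * n ** (-0.2)
            self._train[c] = Xc
            self._bw[c] = np.maximum(bw, self._MIN_BW)
            self._log_prior[c] = np.log(n / len(X))
        return self

    def _log_likelihood(self, X, c):
        Xc, bw = self._train[c], self._bw[c]
        # (n_test, n_train, n_feat) kernel matrix, summed feature-wise
        diff = (X[:, None, :] - Xc[None, :, :]) / bw
        log_k = -0.5 * diff ** 2 - np.log(bw * np.sqrt(2 * np.pi))
        return np.sum(logsumexp(log_k, axis=1) - np.log(len(Xc)), axis=1)

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        scores = np.stack([self._log_likelihood(X, c) + self._log_prior[c]
                           for c in self.classes_], axis=1)
        return self.classes_[np.argmax(scores, axis=1)]


class RUSBoost:
    """Boosting with random undersampling of the majority class.

    Each round draws a class-balanced subsample (weight-proportional,
    without replacement), fits a depth-1 stump, and reweights the full
    training set as in discrete AdaBoost.  Well suited to imbalanced
    classes: the minority class is never discarded.
    """

    def __init__(self, n_estimators: int = N_ENSEMBLE, seed: int = 0):
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("RUSBoost here is binary")
        sign = np.where(y == self.classes_[1], 1.0, -1.0)
        rng = np.random.default_rng(self.seed)
        n = len(y)
        w = np.full(n, 1.0 / n)
        self._stumps, self._alphas = [], []
        for t in range(self.n_estimators):
            m = min(int(np.sum(y == c)) for c in self.classes_)
            chosen = []
            for c in self.classes_:
                idx = np.flatnonzero(y == c)
                p = w[idx] / w[idx].sum()
                take = min(m, idx.size)
                chosen.append(rng.choice(idx, size=take, replace=False, p=p))
            sel = np.concatenate(chosen)
            stump = DecisionTreeClassifier(max_depth=1,
                                           random_state=int(rng.integers(2 ** 31)))
            stump.fit(X[sel], y[sel], sample_weight=w[sel])
            pred = np.where(stump.predict(X) == self.classes_[1], 1.0, -1.0)
            err = float(np.sum(w[pred != sign]))
            if err >= 0.5:  # weak learner no better than chance; reset weights
                w = np.full(n, 1.0 / n)
                continue
            err = max(err, 1e-10)
            alpha = 0.5 * np.log((1.0 - err) / err)
            self._stumps.append(stump)
            self._alphas.append(alpha)
            w *= np.exp(-alpha * sign * pred)
            w /= w.sum()
        if not self._stumps:
            raise RuntimeError("no usable weak learner found")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        score = np.zeros(len(X))
        for stump, alpha in zip(self._stumps, self._alphas):
            score += alpha * np.where(stump.predict(X) == self.classes_[1], 1.0, -1.0)
        return np.where(score >= 0, self.classes_[1], self.classes_[0])


# ------------------------------------------------------------ operations

def minmax_scale(train_X: np.ndarray, test_X: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray | None, MinMaxScalerParams]:
    """Min-max scale with train-derived parameters (no test leakage).

    Constant training columns map to 0 with a warning; test values outside
    the training range are not clipped, so they may fall outside [0, 1].
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    if train_X.ndim != 2 or train_X.shape[0] < 2:
        raise ValueError("need a 2-D training matrix with at least 2 rows")
    scaler = MinMaxScalerParams(mins=train_X.min(axis=0), maxs=train_X.max(axis=0))
    if np.any(scaler.maxs == scaler.mins):
        warnings.warn("constant training column(s) scaled to 0")
    train_s = scaler.transform(train_X)
    test_s = scaler.transform(np.asarray(test_X, dtype=np.float64)) \
        if test_X is not None else None
    return train_s, test_s, scaler


def split_dataset(X: np.ndarray, y: np.ndarray, test_frac: float = 0.2,
                  seed: int = 0, feature_set: str = "C") -> DatasetSplit:
    """Stratified train/test split, reproducible given the seed."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    train_X, test_X, train_y, test_y = train_test_split(
        np.asarray(X, dtype=np.float64), y, test_size=test_frac,
        random_state=seed, stratify=y)
    return DatasetSplit(train_X=train_X, train_y=train_y,
                        test_X=test_X, test_y=test_y,
                        feature_set=feature_set, seed=seed)


def _make_estimator(family: str, hyperparams: dict | None, seed: int):
    hp = hyperparams or {}
    if family in DT_MAX_SPLITS:
        return DecisionTreeClassifier(max_leaf_nodes=DT_MAX_SPLITS[family] + 1,
                                      random_state=seed)
    if family == "knn_fine":
        return TieBreakKNN(k=1)
    if family == "knn_medium":
        return TieBreakKNN(k=10)
    if family == "knn_cosine":
        return TieBreakKNN(k=10, metric="cosine")
    if family == "nb_gaussian":
        return GaussianNB()
    if family == "nb_kernel":
        return KernelNaiveBayes()
    if family == "em_adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=N_ENSEMBLE, random_state=seed)
    if family == "em_bagged":
        return BaggingClassifier(estimator=DecisionTreeClassifier(),
                                 n_estimators=N_ENSEMBLE, random_state=seed)
    if family == "em_rusboost":
        return RUSBoost(n_estimators=N_ENSEMBLE, seed=seed)
    if family in ("svm", "bo_svm"):
        return SVC(kernel="rbf", C=hp.get("c", 1.0), gamma=hp.get("g", "scale"),
                   random_state=seed)
    raise ValueError(f"unknown family: {family}")


def crossval_score(family: str, hyperparams: dict | None, train_X: np.ndarray,
                   train_y: np.ndarray, k: int = 10, seed: int = 0) -> float:
    """Stratified k-fold mean accuracy, min-max scaling refit per fold."""
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y)
    counts = np.unique(train_y, return_counts=True)[1]
    if k > counts.min():
        raise ValueError(f"k={k} exceeds smallest class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for fold, (tr, te) in enumerate(skf.split(train_X, train_y)):
        Xtr, Xte, _ = minmax_scale(train_X[tr], train_X[te])
        est = _make_estimator(family, hyperparams, seed + fold)
        est.fit(Xtr, train_y[tr])
        accs.append(float(np.mean(est.predict(Xte) == train_y[te])))
    return float(np.mean(accs))


# ------------------------------------------------------ Bayesian optimization

def _cv_accuracy_scaled(X, y, c, g, k, seed) -> float:
    """k-fold CV accuracy of an RBF SVM on already-scaled data."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        est = SVC(kernel="rbf", C=c, gamma=g)
        est.fit(X[tr], y[tr])
        accs.append(float(np.mean(est.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def _expected_improvement(mu, sigma, best, xi=0.01):
    from scipy.stats import norm
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best - xi) / sigma
    return (mu - best - xi) * norm.cdf(z) + sigma * norm.pdf(z)


def bo_svm_train(train_X: np.ndarray, train_y: np.ndarray, n_iter: int = 30,
                 seed: int = 0, cv: int = 10) -> TrainedModel:
    """RBF SVM with (c, g) chosen by GP-surrogate Bayesian optimization.

    Searches log10 c in [-3, 3] and log10 g in [-4, 1]; the objective is
    cv-fold cross-validated accuracy.  BO_N_INITIAL random points seed the
    surrogate, then expected improvement picks each of the remaining
    n_iter - BO_N_INITIAL evaluations; the best observed objective is
    non-decreasing by construction.  The returned model is refit on the
    full training split at the selected (c, g); min-max scaling is fitted
    here on the training rows.
    """
    if n_iter < BO_N_INITIAL:
        raise ValueError(f"n_iter must be at least {BO_N_INITIAL}")
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("both classes must be present")
    Xs, _, scaler = minmax_scale(train_X)
    rng = np.random.default_rng(seed)
    lo, hi = BO_BOUNDS[:, 0], BO_BOUNDS[:, 1]
    pts = list(rng.uniform(lo, hi, size=(BO_N_INITIAL, 2)))
    scores = [_cv_accuracy_scaled(Xs, train_y, 10.0 ** p[0], 10.0 ** p[1],
                                  cv, seed) for p in pts]
    kernel = ConstantKernel(1.0) * Matern(length_scale=[1.0, 1.0], nu=2.5) \
        + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-8, 1e-1))
    for it in range(BO_N_INITIAL, n_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # GP length-scale bound hits are benign
            gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                          random_state=seed)
            gp.fit(np.array(pts), np.array(scores))
            cand = rng.uniform(lo, hi, size=(1024, 2))
            mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, max(scores))
        nxt = cand[int(np.argmax(ei))]
        pts.append(nxt)
        scores.append(_cv_accuracy_scaled(Xs, train_y, 10.0 ** nxt[0],
                                          10.0 ** nxt[1], cv, seed))
        logger.debug("BO iter %d: best CV acc %.4f", it, max(scores))
    best = int(np.argmax(scores))
    c, g = 10.0 ** pts[best][0], 10.0 ** pts[best][1]
    est = SVC(kernel="rbf", C=c, gamma=g, random_state=seed).fit(Xs, train_y)
    history = [{"log10_c": float(p[0]), "log10_g": float(p[1]), "cv_acc": s}
               for p, s in zip(pts, scores)]
    return TrainedModel(family="bo_svm", hyperparams={"c": c, "g": g},
                        scaler=scaler, estimator=est,
                        cv_score=float(scores[best]), history=history)


def train_baseline(family: str, train_X: np.ndarray, train_y: np.ndarray,
                   seed: int = 0, cv: int | None = 10) -> TrainedModel:
    """Fit one preset family on the training split (scaling included).

    cv controls the k of the recorded cross-validation score; pass None to
    skip it (the fitted model is unaffected).
    """
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("both classes must be present")
    Xs, _, scaler = minmax_scale(np.asarray(train_X, dtype=np.float64))
    est = _make_estimator(family, None, seed)
    est.fit(Xs, train_y)
    cv_score = crossval_score(family, None, train_X, train_y, k=cv, seed=seed) \
        if cv else float("nan")
    hp = {"max_splits": DT_MAX_SPLITS[family]} if family in DT_MAX_SPLITS else {}
    return TrainedModel(family=family, hyperparams=hp, scaler=scaler,
                        estimator=est, cv_score=cv_score)


def evaluate(model: TrainedModel, test_X: np.ndarray,
             test_y: np.ndarray) -> MetricsReport:
    """Confusion counts and metrics on a test split (CHF positive)."""
    test_y = np.asarray(test_y)
    if test_y.size == 0:
        raise ValueError("empty test set")
    pred = model.estimator.predict(model.scaler.transform(
        np.asarray(test_X, dtype=np.float64)))
    pos = test_y == POSITIVE_CLASS
    hit = pred == test_y
    return MetricsReport.from_counts(
        TP=int(np.sum(pos & hit)), FN=int(np.sum(pos & ~hit)),
        TN=int(np.sum(~pos & hit)), FP=int(np.sum(~pos & ~hit)))
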
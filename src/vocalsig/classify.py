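"""Cross-validated vocalizer discrimination from acoustic features.

The discrimination design is pairwise: for every unordered pair of vocalizers
a classifier is trained and tested by stratified cross-validation, performance
is reported as percent correct classification (PCC, 50% is chance) and tested
against chance with an exact binomial test.  Pairwise performance is
comparable across call types with different numbers of vocalizers, and
directly comparable to the two-alternative operant task.

Three classifiers are supported: a shrinkage-regularized LDA (Ledoit-Wolf
shrinkage of the pooled covariance), a per-class shrinkage QDA, and a random
forest.  Feature spaces: all 18 features, or the spectral (8) / temporal (5) /
fundamental (5) subsets, or the raw log-spectrogram projected on training-fold
principal components.

Cross-call-type generalization trains on one set of call types and tests on
another; if identity cues are a shared "voice", performance transfers, while
call-type-specific signatures make it collapse to chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.covariance import LedoitWolf
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import (
    FUNDAMENTAL_FEATURES,
    PAF_FEATURES,
    SPECTRAL_FEATURES,
    TEMPORAL_FEATURES,
)
from .synth import CallRecord

logger = logging.getLogger(__name__)

FEATURE_SPACES: dict[str, list[str]] = {
    "All": PAF_FEATURES,
    "Spect": SPECTRAL_FEATURES,
    "Temp": TEMPORAL_FEATURES,
    "Fund": FUNDAMENTAL_FEATURES,
}
CLASSIFIERS = ("lda", "qda", "rf")
ALPHA = 0.05


@dataclass(frozen=True)
class ClassificationTask:
    vocalizer_pair: tuple[str, str]
    train_types: frozenset[str]
    test_type: str
    feature_space: str = "All"
    classifier: str = "lda"

    def __post_init__(self) -> None:
        if self.vocalizer_pair[0] == self.vocalizer_pair[1]:
            raise ValueError("vocalizer pair must be two distinct ids")


@dataclass
class PairwiseResult:
    """Cross-validated pairwise discrimination outcome for one condition."""

    task: ClassificationTask
    n_tested: int
    n_correct: int
    p_value: float

    @property
    def pcc(self) -> float:
        return 100.0 * self.n_correct / self.n_tested

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def exact_binomial_p(n_correct: int, n_tested: int, p: float = 0.5) -> float:
    """Two-sided exact binomial test of ``n_correct / n_tested`` against ``p``."""
    return binomtest(n_correct, n_tested, p).pvalue


def filter_min_renditions(features: pd.DataFrame, min_n: int = 5) -> pd.DataFrame:
    """Drop (vocalizer, call type) cells with fewer than ``min_n`` renditions."""
    counts = features.groupby(["vocalizer_id", "call_type"])["rendition_id"].transform("size")
    out = features[counts >= min_n].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"no (vocalizer, call_type) cell has >= {min_n} renditions; "
            f"input had {features.shape[0]} rows"
        )
    return out


def make_folds(
    labels: np.ndarray, n_max: int = 10, n_min: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds: tenfold when every class has >= 10 members, else fivefold.

    Every rendition is tested exactly once; train/test are disjoint.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    smallest = counts.min()
    if smallest < n_min:
        raise ValueError(f"smallest class has {smallest} < {n_min} members")
    k = n_max if smallest >= n_max else n_min
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def _preprocess(X_train: np.ndarray, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Impute missing values and standardize, using training statistics only.

    NaNs (unvoiced calls lack f0 features) are replaced by the training-fold
    class-unconditional column mean; a binary missingness indicator column is
    appended for every feature column with any missing value.
    """
    miss_cols = np.flatnonzero(np.isnan(X_train).any(axis=0) | np.isnan(X_test).any(axis=0))
    ind_train = np.isnan(X_train[:, miss_cols]).astype(float)
    ind_test = np.isnan(X_test[:, miss_cols]).astype(float)
    import warnings

    with warnings.catch_warnings():
        # a column that is all-missing in the training fold imputes to 0
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X_train, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    X_train = np.where(np.isnan(X_train), col_mean, X_train)
    X_test = np.where(np.isnan(X_test), col_mean, X_test)
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    X_train = np.hstack([(X_train - mu) / sd, ind_train])
    X_test = np.hstack([(X_test - mu) / sd, ind_test])
    return X_train, X_test


class ShrinkageQDA:
    """Quadratic discriminant with Ledoit-Wolf shrinkage per class covariance.

    Falls back to a diagonal covariance for a class whose shrunk covariance is
    still not invertible.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageQDA":
        self.classes_ = np.unique(y)
        self.means_, self.precisions_, self.logdets_, self.priors_ = [], [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            self.means_.append(Xc.mean(axis=0))
            cov = LedoitWolf().fit(Xc).covariance_
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0 or not np.isfinite(logdet):
                logger.warning("singular class covariance despite shrinkage; using diagonal")
                cov = np.diag(np.maximum(np.diag(cov), 1e-12))
                sign, logdet = np.linalg.slogdet(cov)
            self.precisions_.append(np.linalg.inv(cov))
            self.logdets_.append(logdet)
            self.priors_.append(np.log(Xc.shape[0] / X.shape[0]))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = np.empty((X.shape[0], len(self.classes_)))
        for j, (mu, prec, logdet, prior) in enumerate(
            zip(self.means_, self.precisions_, self.logdets_, self.priors_)
        ):
            d = X - mu
            maha = np.einsum("ij,jk,ik->i", d, prec, d)
            scores[:, j] = -0.5 * (logdet + maha) + prior
        # argmax takes the first maximum: ties resolve to the smaller class id
        return self.classes_[np.argmax(scores, axis=1)]


def _make_classifier(classifier: str, seed: int):
    if classifier == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if classifier == "qda":
        return ShrinkageQDA()
    if classifier == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown classifier {classifier!r}; choose from {CLASSIFIERS}")


def fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    classifier: str = "lda",
    seed: int = 0,
    pca_variance: float | None = None,
) -> np.ndarray:
    """Train one classifier on a fold and predict test labels.

    Standardization and imputation statistics come from the training rows
    only.  With ``pca_variance`` set (spectrogram space), the standardized
    training fold is first projected on principal components retaining that
    fraction of variance.
    """
    X_train, X_test = _preprocess(np.asarray(X_train, float), np.asarray(X_test, float))
    if pca_variance is not None:
        n_comp = min(X_train.shape[0] - 1, X_train.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full").fit(X_train)
        ratio = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(ratio, pca_variance) + 1)
        X_train = pca.transform(X_train)[:, :keep]
        X_test = pca.transform(X_test)[:, :keep]
    model = _make_classifier(classifier, seed)
    if classifier == "rf":
        # predict via vote fractions; ties break to the lexicographically
        # smaller vocalizer id (classes_ is sorted, argmax takes the first max)
        model.fit(X_train, y_train)
        proba = model.predict_proba(X_test)
        return model.classes_[np.argmax(proba, axis=1)]
    model.fit(X_train, y_train)
    return model.predict(X_test)


def _space_matrix(df: pd.DataFrame, feature_space: str) -> np.ndarray:
    if feature_space == "Spectrogram":
        cols = [c for c in df.columns if c.startswith("sg")]
        if not cols:
            raise ValueError("no spectrogram (sg*) columns in table")
    else:
        cols = FEATURE_SPACES[feature_space]
    return df[cols].to_numpy(dtype=float)


def _cv_counts(
    df: pd.DataFrame, feature_space: str, classifier: str, seed: int,
    n_max: int = 10, n_min: int = 5,
) -> tuple[int, int]:
    """Cross-validated (n_correct, n_tested) over a labelled table."""
    X = _space_matrix(df, feature_space)
    y = df["vocalizer_id"].to_numpy()
    pca = 0.95 if feature_space == "Spectrogram" else None
    n_correct = 0
    for train_idx, test_idx in make_folds(y, n_max=n_max, n_min=n_min, seed=seed):
        pred = fit_predict(
            X[train_idx], y[train_idx], X[test_idx],
            classifier=classifier, seed=seed, pca_variance=pca,
        )
        n_correct += int(np.sum(pred == y[test_idx]))
    return n_correct, len(y)


def pairwise_within_type(
    features: pd.DataFrame,
    call_type: str,
    feature_space: str = "All",
    classifier: str = "lda",
    seed: int = 0,
    min_renditions: int = 5,
) -> list[PairwiseResult]:
    """Cross-validated PCC for every unordered vocalizer pair of one call type."""
    sub = filter_min_renditions(features[features["call_type"] == call_type], min_renditions)
    vocalizers = sorted(sub["vocalizer_id"].unique())
    if len(vocalizers) < 2:
        raise ValueError(f"fewer than 2 vocalizers survive the filter for {call_type!r}")
    results = []
    for a, b in combinations(vocalizers, 2):
        pair_df = sub[sub["vocalizer_id"].isin([a, b])].reset_index(drop=True)
        n_correct, n_tested = _cv_counts(pair_df, feature_space, classifier, seed)
        task = ClassificationTask((a, b), frozenset([call_type]), call_type, feature_space, classifier)
        results.append(PairwiseResult(task, n_tested, n_correct, exact_binomial_p(n_correct, n_tested)))
    return results


def multiclass_within_type(
    features: pd.DataFrame,
    call_type: str,
    feature_space: str = "All",
    classifier: str = "lda",
    seed: int = 0,
    min_renditions: int = 5,
) -> tuple[float, pd.DataFrame]:
    """Single multi-class cross-validated PCC and confusion matrix.

    Chance is 100 / n_vocalizers percent.
    """
    sub = filter_min_renditions(features[features["call_type"] == call_type], min_renditions)
    vocalizers = sorted(sub["vocalizer_id"].unique())
    if len(vocalizers) < 3:
        raise ValueError("multiclass task needs >= 3 vocalizers")
    X = _space_matrix(sub, feature_space)
    y = sub["vocalizer_id"].to_numpy()
    pca = 0.95 if feature_space == "Spectrogram" else None
    confusion = pd.DataFrame(0, index=vocalizers, columns=vocalizers)
    for train_idx, test_idx in make_folds(y, seed=seed):
        pred = fit_predict(X[train_idx], y[train_idx], X[test_idx],
                           classifier=classifier, seed=seed, pca_variance=pca)
        for truth, guess in zip(y[test_idx], pred):
            confusion.loc[truth, guess] += 1
    pcc = 100.0 * np.trace(confusion.to_numpy()) / len(y)
    return pcc, confusion


def _train_test_counts(
    train_df: pd.DataFrame, test_df: pd.DataFrame,
    feature_space: str, classifier: str, seed: int,
) -> tuple[int, int]:
    X_train = _space_matrix(train_df, feature_space)
    X_test = _space_matrix(test_df, feature_space)
    pca = 0.95 if feature_space == "Spectrogram" else None
    pred = fit_predict(
        X_train, train_df["vocalizer_id"].to_numpy(), X_test,
        classifier=classifier, seed=seed, pca_variance=pca,
    )
    return int(np.sum(pred == test_df["vocalizer_id"].to_numpy())), len(test_df)


def cross_type_generalization(
    features: pd.DataFrame,
    vocalizer_pair: tuple[str, str],
    feature_space: str = "All",
    classifier: str = "lda",
    seed: int = 0,
    min_renditions: int = 5,
    min_other_types: int = 5,
) -> dict:
    """Same- vs. other-call-type discrimination for one vocalizer pair.

    For each call type the pair produces: *Same* = within-type cross-validated
    PCC; *Other* = classifier trained on the pooled renditions of the other
    call types (at least ``min_other_types`` of them when available, else all
    that exist, logged) and tested on every rendition of the test type.  The
    train-type x test-type matrix holds single-train-type transfer, with the
    diagonal equal to the Same condition.
    """
    a, b = vocalizer_pair
    sub = filter_min_renditions(features[features["vocalizer_id"].isin([a, b])], min_renditions)
    common = sorted(
        t for t in sub["call_type"].unique()
        if set(sub.loc[sub["call_type"] == t, "vocalizer_id"]) == {a, b}
    )
    if len(common) < 2:
        raise ValueError(f"pair {vocalizer_pair} shares fewer than 2 call types after filtering")
    same: dict[str, PairwiseResult] = {}
    other: dict[str, PairwiseResult] = {}
    pcc_matrix = pd.DataFrame(np.nan, index=common, columns=common)
    sig_matrix = pd.DataFrame(False, index=common, columns=common)
    for test_type in common:
        test_df = sub[sub["call_type"] == test_type].reset_index(drop=True)
        n_c, n_t = _cv_counts(test_df, feature_space, classifier, seed)
        task = ClassificationTask((a, b), frozenset([test_type]), test_type, feature_space, classifier)
        res = PairwiseResult(task, n_t, n_c, exact_binomial_p(n_c, n_t))
        same[test_type] = res
        pcc_matrix.loc[test_type, test_type] = res.pcc
        sig_matrix.loc[test_type, test_type] = res.significant

        others = [t for t in common if t != test_type]
        if len(others) < min_other_types:
            logger.info(
                "pair %s test type %s: only %d other types available (< %d); using all",
                vocalizer_pair, test_type, len(others), min_other_types,
            )
        train_df = sub[sub["call_type"].isin(others)].reset_index(drop=True)
        n_c, n_t = _train_test_counts(train_df, test_df, feature_space, classifier, seed)
        task = ClassificationTask((a, b), frozenset(others), test_type, feature_space, classifier)
        other[test_type] = PairwiseResult(task, n_t, n_c, exact_binomial_p(n_c, n_t))

        for train_type in others:
            tr = sub[sub["call_type"] == train_type].reset_index(drop=True)
            n_c, n_t = _train_test_counts(tr, test_df, feature_space, classifier, seed)
            pcc_matrix.loc[test_type, train_type] = 100.0 * n_c / n_t
            sig_matrix.loc[test_type, train_type] = exact_binomial_p(n_c, n_t) < ALPHA
    return {"same": same, "other": other, "matrix": pcc_matrix, "significant": sig_matrix}


def subspace_comparison(
    features: pd.DataFrame,
    spaces: tuple[str, ...] = ("All", "Spect", "Temp", "Fund"),
    classifier: str = "lda",
    seed: int = 0,
    min_renditions: int = 5,
) -> pd.DataFrame:
    """Mean PCC per feature space for identity and for call-type classification.

    Identity: pairwise vocalizer PCC pooled over call types.  Call type: the
    feature vectors are first averaged per vocalizer within each call type and
    the classifier sorts these mean vectors by call type.
    """
    filt = filter_min_renditions(features, min_renditions)
    rows = []
    for space in spaces:
        n_c = n_t = 0
        for ct in sorted(filt["call_type"].unique()):
            if filt.loc[filt["call_type"] == ct, "vocalizer_id"].nunique() < 2:
                continue
            for res in pairwise_within_type(filt, ct, space, classifier, seed, min_renditions):
                n_c += res.n_correct
                n_t += res.n_tested
        ci = binomtest(n_c, n_t).proportion_ci(0.95)
        rows.append((space, "Identity", 100.0 * n_c / n_t, n_t, 100 * ci.low, 100 * ci.high))

        means = (
            filt.groupby(["vocalizer_id", "call_type"])[list(FEATURE_SPACES[space])]
            .mean()
            .reset_index()
        )
        y = means["call_type"].to_numpy()
        X = means[FEATURE_SPACES[space]].to_numpy(dtype=float)
        n_c = 0
        for train_idx, test_idx in make_folds(y, seed=seed):
            pred = fit_predict(X[train_idx], y[train_idx], X[test_idx],
                               classifier=classifier, seed=seed)
            n_c += int(np.sum(pred == y[test_idx]))
        ci = binomtest(n_c, len(y)).proportion_ci(0.95)
        rows.append((space, "CallType", 100.0 * n_c / len(y), len(y), 100 * ci.low, 100 * ci.high))
    return pd.DataFrame(rows, columns=["space", "objective", "pcc", "n_tested", "ci_low", "ci_high"])


def spectrogram_table(
    calls: list[CallRecord],
    window_sd: float = 0.002,
    step: float = 0.005,
    max_freq: float = 12000.0,
    freq_decim: int = 8,
    floor_db: float = 80.0,
) -> pd.DataFrame:
    """Fixed-dimension log-spectrogram pixels for spectrogram-space tasks.

    Within each call type, every spectrogram is center-cropped or padded (at
    the floor level) to the type's median frame count; all types are then
    right-padded to a common width so one table holds the whole dataset.
    Columns ``sg<k>`` hold the flattened (freq x time) pixels.
    """
    from .features import compute_spectrogram

    specs, meta = [], []
    for call in calls:
        sg = compute_spectrogram(call, window_sd=window_sd, step=step, floor_db=floor_db)
        keep = sg.freqs <= max_freq
        specs.append(sg.log_power[keep][::freq_decim])
        meta.append((call.vocalizer_id, call.call_type, call.rendition_id))
    types = [m[1] for m in meta]
    med_frames = {
        t: int(np.median([s.shape[1] for s, m in zip(specs, meta) if m[1] == t]))
        for t in set(types)
    }

    def _fit_width(mat: np.ndarray, width: int) -> np.ndarray:
        cur = mat.shape[1]
        if cur > width:
            start = (cur - width) // 2
            return mat[:, start : start + width]
        pad = width - cur
        left = pad // 2
        return np.pad(mat, ((0, 0), (left, pad - left)), constant_values=-floor_db)

    fitted = [_fit_width(s, med_frames[m[1]]) for s, m in zip(specs, meta)]
    max_w = max(f.shape[1] for f in fitted)
    flat = [
        np.pad(f, ((0, 0), (0, max_w - f.shape[1])), constant_values=-floor_db).ravel()
        for f in fitted
    ]
    df = pd.DataFrame(meta, columns=["vocalizer_id", "call_type", "rendition_id"])
    pix = pd.DataFrame(np.vstack(flat), columns=[f"sg{k}" for k in range(flat[0].size)])
    return pd.concat([df, pix], axis=1)


def results_table(results: list[PairwiseResult]) -> pd.DataFrame:
    """Flatten PairwiseResults to the results CSV dialect."""
    rows = []
    for r in results:
        rows.append({
            "vocalizer_a": r.task.vocalizer_pair[0],
            "vocalizer_b": r.task.vocalizer_pair[1],
            "train_types": "+".join(sorted(r.task.train_types)),
            "test_type": r.task.test_type,
            "feature_space": r.task.feature_space,
            "classifier": r.task.classifier,
            "n_tested": r.n_tested,
            "n_correct": r.n_correct,
            "pcc": r.pcc,
            "p_value": r.p_value,
            "significant": r.significant,
        })
    return pd.DataFrame(rows)
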
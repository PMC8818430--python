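"""SVM classification of visual-imagery feature vectors.

The protocol mirrors the study: a class-stratified split into training and
test halves (100/100 per class at the defaults), features z-scored with
training-set statistics only, an RBF-kernel SVM (C=1, inverse bandwidth
from the median pairwise-distance heuristic on the training set), and
percent accuracy on the held-out test set.  "Subjects" in synthetic mode
are independent generator seeds; summaries report mean +/- standard error,
maximum and minimum across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import TrialSet, FeatureMatrix, CLASSES

__all__ = ["SVMConfig", "ClassificationResult", "AccuracyCurve",
           "train_eval", "repeated_train_eval", "subject_summary",
           "time_resolved_accuracy"]


@dataclass
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "median"  # median heuristic on the training set


@dataclass
class ClassificationResult:
    accuracy: float
    per_class_accuracy: dict[str, float]
    n_train: int
    n_test: int
    kernel: str
    regularization: float
    gamma: float | str
    seed: int
    confusion: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    test_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    predictions: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


@dataclass
class AccuracyCurve:
    window_end_s: np.ndarray
    accuracy_pct: np.ndarray

    def __post_init__(self) -> None:
        self.window_end_s = np.asarray(self.window_end_s, dtype=float)
        if np.any(np.diff(self.window_end_s) <= 0):
            raise ValueError("window end times must be strictly increasing")


def _median_gamma(X: np.ndarray) -> float:
    d = pdist(X)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med ** 2)


def _stratified_split(labels: np.ndarray, n_train_per_class: int,
                      n_test_per_class: int, rng: np.random.Generator):
    train_idx, test_idx = [], []
    for cls in CLASSES:
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_train_per_class + n_test_per_class:
            raise ValueError(
                f"class {cls!r} has {idx.size} trials; split needs "
                f"{n_train_per_class}+{n_test_per_class}")
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train_per_class])
        test_idx.append(perm[n_train_per_class:n_train_per_class + n_test_per_class])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def train_eval(features: FeatureMatrix, n_train_per_class: int,
               n_test_per_class: int, svm_cfg: SVMConfig | None = None,
               seed: int = 0) -> ClassificationResult:
    """One stratified split, train an SVM, report test accuracy in percent."""
    svm_cfg = svm_cfg or SVMConfig()
    rng = np.random.default_rng(seed)
    tr, te = _stratified_split(features.labels, n_train_per_class,
                               n_test_per_class, rng)
    scaler = StandardScaler().fit(features.X[tr])
    Xtr = scaler.transform(features.X[tr])
    Xte = scaler.transform(features.X[te])
    gamma = svm_cfg.gamma
    if gamma == "median":
        gamma = _median_gamma(Xtr)
    clf = SVC(kernel=svm_cfg.kernel, C=svm_cfg.C,
              gamma=gamma if svm_cfg.kernel != "linear" else "scale")
    clf.fit(Xtr, features.labels[tr])
    pred = clf.predict(Xte)
    truth = features.labels[te]
    acc = float(np.mean(pred == truth) * 100.0)
    per_class = {}
    conf = np.zeros((2, 2), dtype=int)
    for i, cls in enumerate(CLASSES):
        mask = truth == cls
        per_class[cls] = float(np.mean(pred[mask] == cls) * 100.0)
        for j, cls2 in enumerate(CLASSES):
            conf[i, j] = int(np.sum(pred[mask] == cls2))
    return ClassificationResult(
        accuracy=acc, per_class_accuracy=per_class,
        n_train=tr.size, n_test=te.size, kernel=svm_cfg.kernel,
        regularization=svm_cfg.C, gamma=gamma, seed=seed, confusion=conf,
        test_indices=te, predictions=pred)


def repeated_train_eval(features: FeatureMatrix, n_train_per_class: int,
                        n_test_per_class: int, svm_cfg: SVMConfig | None = None,
                        seed: int = 0, n_repeats: int = 10):
    """Average accuracy over ``n_repeats`` independent stratified splits."""
    results = [train_eval(features, n_train_per_class, n_test_per_class,
                          svm_cfg, seed=int(np.random.default_rng([seed, r]).integers(2 ** 31)))
               for r in range(n_repeats)]
    return float(np.mean([r.accuracy for r in results])), results


def subject_summary(per_subject: dict[str, list[float]]):
    """Mean +/- SE, maximum and minimum accuracy per feature method.

    ``per_subject`` maps method name to one accuracy (%) per subject.
    Returns a dict of rows with a formatted ``average`` string like
    ``"68.14 ± 3.06"``.
    """
    table = {}
    for method, accs in per_subject.items():
        a = np.asarray(accs, dtype=float)
        se = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0
        table[method] = {
            "mean": float(a.mean()),
            "se": se,
            "average": f"{a.mean():.2f} ± {se:.2f}",
            "max": float(a.max()),
            "min": float(a.min()),
            "n_subjects": int(a.size),
        }
    return table


def time_resolved_accuracy(ts: TrialSet, feature_fn, window_s: float = 1.0,
                           step_s: float = 0.1, svm_cfg: SVMConfig | None = None,
                           seed: int = 0, n_train_per_class: int | None = None,
                           n_test_per_class: int | None = None) -> AccuracyCurve:
    """Accuracy of features re-extracted from a sliding window over the epoch.

    ``feature_fn(sub_trialset) -> FeatureMatrix`` is applied to each
    windowed copy of the trials; the split is fixed by ``seed`` so windows
    are comparable.
    """
    t0, t1 = ts.window
    epoch_len = t1 - t0
    if window_s > epoch_len:
        raise ValueError("window_s exceeds the epoch length")
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    n_per_class = min(int(np.sum(ts.labels == c)) for c in CLASSES)
    ntr = n_train_per_class or n_per_class // 2
    nte = n_test_per_class or n_per_class - ntr
    ends, accs = [], []
    n_windows = int(np.floor((epoch_len - window_s) / step_s + 1e-9)) + 1
    for w in range(n_windows):
        start = t0 + w * step_s
        i0 = round((start - t0) * ts.fs)
        i1 = i0 + round(window_s * ts.fs)
        sub = TrialSet(ts.trials[:, :, i0:i1], ts.labels, ts.fs,
                       list(ts.channel_labels), window=(start, start + window_s))
        fm = feature_fn(sub)
        res = train_eval(fm, ntr, nte, svm_cfg, seed=seed)
        ends.append(start + window_s)
        accs.append(res.accuracy)
    return AccuracyCurve(np.asarray(ends), np.asarray(accs))
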
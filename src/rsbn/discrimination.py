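"""State discrimination from directed-edge features: RFE-ranked linear SVC.

The classifier input is the per-recording table of directed-edge weights
(81 features for 9 nodes).  Recursive feature elimination (RFE) with a
linear soft-margin support vector classifier ranks the features: the SVC is
fit, the feature with the smallest absolute hyperplane coefficient is
dropped, and the process repeats until none remain; the ranking is the
reverse elimination order.  Nested subsets of the top-ranked features
(first one, first two, ...) are then scored by leave-one-out accuracy,
yielding an accuracy-versus-subset-size curve and a best discriminative
pattern.

Two cross-validation units are supported: ``by_subject`` (default) holds
out both recordings of one subject per fold, respecting the within-subject
pairing; ``by_sample`` is classic per-recording leave-one-out.  In either
mode, feature standardization uses training-fold statistics only.

The default protocol computes the RFE ranking once on all samples and then
cross-validates each subset — the conventional procedure for this analysis,
which is optimistically biased because the ranking has seen the held-out
samples.  ``nested=True`` recomputes the ranking inside every training fold
instead, removing that selection bias at extra cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .bn_learning import FeatureTable

__all__ = [
    "FeatureRanking",
    "ClassificationReport",
    "rfe_ranking",
    "loo_accuracy",
    "accuracy_curve",
    "discriminative_pattern",
    "plot_accuracy_curve",
]

CV_MODES = ("by_subject", "by_sample")


@dataclass(frozen=True)
class FeatureRanking:
    """A permutation of feature indices, most discriminative first."""

    order: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.order))):
            raise ValueError("ranking must be a permutation of 0..n_features-1")

    def top(self, k: int) -> list[int]:
        if not 1 <= k <= len(self.order):
            raise ValueError(f"k must be in 1..{len(self.order)}")
        return list(self.order[:k])


@dataclass
class ClassificationReport:
    """Accuracy over nested feature subsets plus the ranking that defined them."""

    accuracy_by_k: list[float]
    ranking: FeatureRanking
    best_k: int
    best_accuracy: float
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        best = max(self.accuracy_by_k)
        if abs(self.best_accuracy - best) > 1e-12:
            raise ValueError("best_accuracy must equal max(accuracy_by_k)")
        if self.accuracy_by_k[self.best_k - 1] != self.best_accuracy:
            raise ValueError("best_k must attain best_accuracy")


def _unpack(features, labels):
    if isinstance(features, FeatureTable):
        return features.matrix, np.asarray(features.labels)
    if labels is None:
        raise ValueError("labels are required when features is a plain matrix")
    return np.asarray(features, dtype=float), np.asarray(labels)


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size != 2:
        raise ValueError(f"need exactly 2 classes, got {np.unique(y)}")


def _zscore_train(train: np.ndarray, *others: np.ndarray):
    """Standardize columns by training statistics; constant columns map to 0."""
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = [(train - mean) / sd_safe]
    out[0][:, sd == 0] = 0.0
    for x in others:
        z = (x - mean) / sd_safe
        z[:, sd == 0] = 0.0
        out.append(z)
    return out if others else out[0]


def _fit_svc(x: np.ndarray, y: np.ndarray, cost: float) -> SVC:
    clf = SVC(kernel="linear", C=cost)
    clf.fit(x, y)
    return clf


def _rfe_order(x: np.ndarray, y: np.ndarray, cost: float) -> tuple[int, ...]:
    """Eliminate one feature per round; ties drop the higher column index."""
    surviving = list(range(x.shape[1]))
    eliminated: list[int] = []
    while len(surviving) > 1:
        clf = _fit_svc(x[:, surviving], y, cost)
        coefs = np.abs(np.asarray(clf.coef_).ravel())
        weakest = min(
            range(len(surviving)), key=lambda i: (coefs[i], -surviving[i])
        )
        eliminated.append(surviving.pop(weakest))
    eliminated.extend(surviving)
    return tuple(reversed(eliminated))


def rfe_ranking(features, labels=None, svc_cost: float = 1.0) -> FeatureRanking:
    """Rank all features by recursive elimination with a linear SVC.

    Features are z-scored per column before fitting (constant columns become
    all-zero and carry zero hyperplane weight, so they drop out first).
    Each round removes the surviving feature with the smallest absolute
    coefficient; ties remove the higher column index first.  The ranking is
    the reverse elimination order.
    """
    x, y = _unpack(features, labels)
    _check_two_classes(y)
    return FeatureRanking(order=_rfe_order(_zscore_train(x), y, svc_cost))


def _folds(y: np.ndarray, subject_ids, mode: str):
    n = len(y)
    if mode == "by_sample":
        return [np.array([i]) for i in range(n)]
    if mode == "by_subject":
        if subject_ids is None:
            raise ValueError("subject_ids are required for by_subject folds")
        sids = np.asarray(subject_ids)
        seen: list[str] = []
        for s in sids:
            if s not in seen:
                seen.append(s)
        return [np.nonzero(sids == s)[0] for s in seen]
    raise ValueError(f"unknown CV mode {mode!r}; expected one of {CV_MODES}")


def loo_accuracy(
    features,
    labels=None,
    subject_ids=None,
    subset=None,
    mode: str = "by_subject",
    svc_cost: float = 1.0,
) -> float:
    """Leave-one-out accuracy of a linear SVC on a feature subset.

    ``by_subject`` holds out both recordings of each subject in turn;
    ``by_sample`` holds out single recordings.  Standardization statistics
    come from the training fold only, so held-out rows never leak into the
    fitted model.
    """
    x, y = _unpack(features, labels)
    if subject_ids is None and isinstance(features, FeatureTable):
        subject_ids = features.subject_ids
    _check_two_classes(y)
    if subset is None:
        subset = np.arange(x.shape[1])
    subset = np.asarray(list(subset), dtype=int)
    if subset.size == 0:
        raise ValueError("feature subset must be nonempty")
    correct = 0
    for heldout in _folds(y, subject_ids, mode):
        train = np.setdiff1d(np.arange(len(y)), heldout)
        if np.unique(y[train]).size != 2:
            raise ValueError("a training fold lost one of the classes")
        xtr, xte = _zscore_train(x[np.ix_(train, subset)], x[np.ix_(heldout, subset)])
        clf = _fit_svc(xtr, y[train], svc_cost)
        correct += int((clf.predict(xte) == y[heldout]).sum())
    return correct / len(y)


def accuracy_curve(
    features,
    labels=None,
    subject_ids=None,
    ranking: FeatureRanking | None = None,
    mode: str = "by_subject",
    svc_cost: float = 1.0,
    nested: bool = False,
) -> ClassificationReport:
    """Leave-one-out accuracy of every nested top-k feature subset.

    With ``nested=False`` (default) the supplied ranking — computed once on
    all samples — defines the subsets for every fold.  With ``nested=True``
    the ranking is recomputed on each training fold, so feature selection
    never sees the held-out rows; the reported ranking is then the
    all-samples one, kept for the pattern read-out.
    """
    x, y = _unpack(features, labels)
    if subject_ids is None and isinstance(features, FeatureTable):
        subject_ids = features.subject_ids
    _check_two_classes(y)
    if ranking is None:
        ranking = rfe_ranking(x, y, svc_cost)
    n_feat = x.shape[1]
    if len(ranking.order) != n_feat:
        raise ValueError("ranking length does not match feature count")
    if nested:
        n = len(y)
        correct = np.zeros(n_feat)
        for heldout in _folds(y, subject_ids, mode):
            train = np.setdiff1d(np.arange(n), heldout)
            xtr_all, xte_all = _zscore_train(x[train], x[heldout])
            fold_order = _rfe_order(xtr_all, y[train], svc_cost)
            for k in range(1, n_feat + 1):
                cols = list(fold_order[:k])
                clf = _fit_svc(xtr_all[:, cols], y[train], svc_cost)
                correct[k - 1] += (clf.predict(xte_all[:, cols]) == y[heldout]).sum()
        acc = list(correct / n)
    else:
        acc = [
            loo_accuracy(x, y, subject_ids, ranking.top(k), mode, svc_cost)
            for k in range(1, n_feat + 1)
        ]
    best_accuracy = max(acc)
    best_k = 1 + min(i for i, a in enumerate(acc) if a == best_accuracy)
    return ClassificationReport(
        accuracy_by_k=acc,
        ranking=ranking,
        best_k=best_k,
        best_accuracy=best_accuracy,
        config={"svc_cost": svc_cost, "cv_mode": mode, "nested": nested},
    )


def plot_accuracy_curve(report: ClassificationReport, path=None):
    """Plot leave-one-out accuracy against feature-subset size.

    Requires matplotlib (optional dependency).  Returns the figure; saves
    to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = range(1, len(report.accuracy_by_k) + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ks, report.accuracy_by_k, lw=1.5)
    ax.axvline(report.best_k, ls="--", c="grey", lw=0.8)
    ax.annotate(
        f"best {report.best_accuracy:.2f} at k={report.best_k}",
        xy=(report.best_k, report.best_accuracy),
        xytext=(report.best_k + 2, min(report.best_accuracy, 0.9)),
        fontsize=9,
    )
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("LOO accuracy")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def discriminative_pattern(
    report: ClassificationReport, features: FeatureTable, k: int | None = None
) -> pd.DataFrame:
    """The top-k ranked edges with per-condition mean weights.

    Returns a DataFrame with one row per selected edge: source, target,
    rank (1 = most discriminative), the mean weight within each condition,
    and their difference (second condition minus first, conditions in sorted
    label order — EO minus EC for the default labels).
    """
    if k is None:
        k = report.best_k
    pairs = features.column_pairs()
    if not 1 <= k <= len(pairs):
        raise ValueError(f"k must be in 1..{len(pairs)}")
    conds = sorted(set(features.labels))
    if len(conds) != 2:
        raise ValueError("feature table must hold exactly 2 conditions")
    masks = {c: features.rows_for(c) for c in conds}
    rows = []
    for rank, col in enumerate(report.ranking.top(k), start=1):
        src, tgt = pairs[col]
        means = {c: float(features.matrix[masks[c], col].mean()) for c in conds}
        rows.append(
            {
                "source": src,
                "target": tgt,
                "rank": rank,
                f"mean_{conds[0]}": means[conds[0]],
                f"mean_{conds[1]}": means[conds[1]],
                "difference": means[conds[1]] - means[conds[0]],
            }
        )
    return pd.DataFrame(rows)
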
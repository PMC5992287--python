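"""LDA decoding of deviant-locked epochs and yes/no answer decoding.

The classifier is a pooled-covariance linear discriminant on the 56-feature
matrix.  With ~54 deviant training trials per cross-validation fold and 56
features the pooled covariance is near-singular, so shrinkage toward the
scaled identity (Ledoit-Wolf by default) is on by default.

BCI performance is the percentage of detected deviant trials: the
deviant-class sensitivity over held-out folds of a seeded, stratified
10-fold cross-validation.  Under the paradigm's 1:7 class imbalance an LDA
with empirical priors detects almost nothing absent signal, which is why
chance-level scores sit near zero rather than 50%; equal priors are
available behind the ``priors`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .paradigm import ANSWER_MAP, LEFT, RIGHT
from .preprocessing import EpochSet, FeatureMatrix, downsample_features

__all__ = [
    "ClassifierModel",
    "PerformanceResult",
    "AnswerResult",
    "train_lda",
    "crossval_performance",
    "classify_vt3",
    "decode_answer",
    "infer_attended_site",
    "recover_block_sites",
]


@dataclass
class ClassifierModel:
    """Trained linear discriminant: ``score(x) = w @ x + b``, class 1
    (deviant/target) when the score is strictly positive (ties break to
    the standard class)."""

    weights: np.ndarray
    bias: float
    shrinkage: float | str
    class_means: np.ndarray  # 2 x n_features, rows = (class 0, class 1)
    priors_mode: str = "empirical"
    training_meta: dict = field(default_factory=dict)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score(X) > 0).astype(int)


@dataclass
class PerformanceResult:
    """Cross-validated BCI performance.

    ``performance_pct`` = 100 x (held-out deviant/target trials classified
    as such) / (non-rejected deviant/target trials), in [0, 100].
    """

    performance_pct: float
    n_deviant: int
    n_rejected: int
    fold_assignments: np.ndarray
    per_fold_detected: list[int]
    per_fold_total: list[int]
    seed: int
    k: int

    def to_dict(self) -> dict:
        return {
            "performance_pct": self.performance_pct,
            "n_deviant": self.n_deviant,
            "n_rejected": self.n_rejected,
            "per_fold_detected": list(self.per_fold_detected),
            "per_fold_total": list(self.per_fold_total),
            "seed": self.seed,
            "k": self.k,
        }


@dataclass
class AnswerResult:
    """Outcome of decoding one communication block."""

    answer: str  # 'yes' | 'no' | 'none'
    score_diff: float | None
    p_value: float | None
    reason: str = ""


def _priors(priors: str, y: np.ndarray) -> list[float] | None:
    if priors == "equal":
        return [0.5, 0.5]
    if priors == "empirical":
        return None  # sklearn uses class frequencies
    raise ValueError(f"priors must be 'empirical' or 'equal', got {priors!r}")


def train_lda(
    features: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    shrinkage: float | str = "auto",
    priors: str = "empirical",
) -> ClassifierModel:
    """Fit a shrinkage-regularized pooled-covariance LDA.

    ``shrinkage='auto'`` uses the Ledoit-Wolf analytic estimate toward the
    scaled identity; a scalar in [0, 1] fixes it; 0 requires a well-posed
    covariance and raises a numerical error otherwise, advising shrinkage.
    Weights are deterministic functions of the training data.
    """
    if isinstance(features, FeatureMatrix):
        X, y = features.X, features.y
    else:
        X = np.asarray(features, dtype=float)
        if y is None:
            raise ValueError("y is required when passing a raw matrix")
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training trials")

    unregularized = isinstance(shrinkage, (int, float)) and shrinkage == 0
    if unregularized:
        # sklearn's lsqr solver quietly falls back to a least-squares
        # pseudo-solution on a rank-deficient covariance; insist on a
        # well-posed problem instead
        pooled = sum(
            (np.count_nonzero(y == c) / len(y))
            * np.cov(X[y == c], rowvar=False, bias=True)
            for c in classes
        )
        if (len(y) - len(classes) < X.shape[1]
                or np.linalg.cond(pooled) > 1e10):
            raise np.linalg.LinAlgError(
                "singular pooled covariance; use shrinkage > 0 (e.g. 'auto')"
            )
    clf = LinearDiscriminantAnalysis(
        solver="lsqr", shrinkage=None if unregularized else shrinkage,
        priors=_priors(priors, y)
    )
    clf.fit(X, y)
    w = clf.coef_.ravel().copy()
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError(
            "non-finite LDA weights; use shrinkage > 0 (e.g. 'auto')"
        )
    return ClassifierModel(
        weights=w,
        bias=float(clf.intercept_[0]),
        shrinkage=shrinkage,
        class_means=np.vstack([X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)]),
        priors_mode=priors,
        training_meta={
            "n_per_class": {int(c): int(n) for c, n in zip(classes, counts)},
        },
    )


def crossval_performance(
    features: FeatureMatrix,
    k: int = 10,
    seed: int = 0,
    shrinkage: float | str = "auto",
    priors: str = "empirical",
    n_rejected: int = 0,
) -> PerformanceResult:
    """Seeded stratified k-fold cross-validated detection rate.

    Folds are disjoint and cover every retained trial exactly once; per
    fold the LDA is trained on the other k-1 folds and the held-out
    positive-class trials (deviants, or targets in VT3 mode) count as
    detected when classified positive.
    """
    X, y = features.X, features.y
    n_pos = int(y.sum())
    if n_pos < k:
        raise ValueError(
            f"only {n_pos} positive trials for {k} folds; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    fold_assign = np.full(len(y), -1, dtype=int)
    detected, totals = [], []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        fold_assign[te] = f
        model = train_lda(X[tr], y[tr], shrinkage=shrinkage, priors=priors)
        pred = model.predict(X[te])
        pos = y[te] == 1
        detected.append(int((pred[pos] == 1).sum()))
        totals.append(int(pos.sum()))
    perf = 100.0 * sum(detected) / n_pos
    return PerformanceResult(
        performance_pct=perf,
        n_deviant=n_pos,
        n_rejected=n_rejected,
        fold_assignments=fold_assign,
        per_fold_detected=detected,
        per_fold_total=totals,
        seed=seed,
        k=k,
    )


def classify_vt3(
    features: FeatureMatrix,
    k: int = 10,
    seed: int = 0,
    shrinkage: float | str = "auto",
    priors: str = "empirical",
    n_rejected: int = 0,
) -> PerformanceResult:
    """VT3 performance: target-deviant vs everything else.

    ``features`` must have been built with ``label_mode='target'`` so that
    the positive class is the attended wrist's deviants and the rest
    (non-target deviants and standards) form the negative class.
    """
    if features.label_mode != "target":
        raise ValueError("classify_vt3 needs features with label_mode='target'")
    if not features.y.any() or features.y.all():
        raise ValueError("need both target and non-target trials")
    return crossval_performance(features, k=k, seed=seed, shrinkage=shrinkage,
                                priors=priors, n_rejected=n_rejected)


def _block_scores(block_epochs: EpochSet, model: ClassifierModel):
    """Classifier scores of retained deviant epochs, split by wrist."""
    feats = downsample_features(block_epochs, label_mode="deviant")
    dev = feats.labels["trial_type"] == "deviant"
    sites = feats.labels["site"].to_numpy()
    scores = model.score(feats.X)
    left = scores[dev.to_numpy() & (sites == LEFT)]
    right = scores[dev.to_numpy() & (sites == RIGHT)]
    return left, right


def decode_answer(
    block_epochs: EpochSet,
    model: ClassifierModel,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> AnswerResult:
    """Decode one question block into yes / no / none.

    The statistic is the mean classifier score over left-wrist deviant
    epochs minus the mean over right-wrist deviant epochs; its two-sided
    permutation null (shuffling wrist labels) gives a p-value, and the
    block abstains ("none") unless p <= alpha.  Attending left means "yes",
    right means "no".
    """
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999 for a stable permutation null")
    left, right = _block_scores(block_epochs, model)
    if len(left) == 0 or len(right) == 0:
        return AnswerResult("none", None, None,
                            reason="no deviant epochs survive rejection on "
                                   "one or both wrists")
    diff = float(left.mean() - right.mean())
    pooled = np.concatenate([left, right])
    n_left = len(left)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = perm[:n_left].mean() - perm[n_left:].mean()
    p = (1 + np.sum(np.abs(null) >= abs(diff))) / (n_perm + 1)
    if p <= alpha:
        answer = ANSWER_MAP[LEFT] if diff > 0 else ANSWER_MAP[RIGHT]
    else:
        answer = "none"
    return AnswerResult(answer, diff, float(p))


def recover_block_sites(
    epochs: EpochSet,
    shrinkage: float | str = "auto",
    priors: str = "empirical",
) -> list[str]:
    """Leave-one-block-out attended-wrist recovery for a VT3 session.

    For each attended-wrist block, an LDA is trained on the remaining
    blocks (whose instructions, hence target labels, are known) and the
    held-out block's attended wrist is inferred from the wrist whose
    deviants score higher.  Returns one wrist per block.
    """
    if "block" not in epochs.labels.columns:
        raise ValueError("epochs carry no block labels")
    blocks = sorted(epochs.labels["block"].unique())
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks to leave one out")
    recovered = []
    block_col = epochs.labels["block"].to_numpy()
    for b in blocks:
        train = epochs.subset(np.flatnonzero(block_col != b))
        feats = downsample_features(train, label_mode="target")
        model = train_lda(feats, shrinkage=shrinkage, priors=priors)
        recovered.append(infer_attended_site(epochs.select_block(int(b)), model))
    return recovered


def infer_attended_site(block_epochs: EpochSet, model: ClassifierModel) -> str:
    """Best-guess attended wrist for one block (no abstention): the wrist
    whose deviant epochs score higher under the model."""
    left, right = _block_scores(block_epochs, model)
    if len(left) == 0 or len(right) == 0:
        raise ValueError("need deviant epochs on both wrists")
    return LEFT if left.mean() >= right.mean() else RIGHT
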
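"""Classifiers: dividing-line rules, the joint criterion with its alpha sweep,
the fused rank+dARD RBF-SVM, and the K-NN and ellipse-ovality baselines.

Labels are the strings ``"normal"`` and ``"abnormal"`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .rankcode import ModelSet, RankProfile, pairwise_dm, select_representatives

__all__ = [
    "JointCriterion",
    "SvmConfig",
    "EvalReport",
    "joint_criterion",
    "find_dividing_line",
    "alpha_sweep",
    "build_fused_features",
    "representative_split",
    "svm_train_test",
    "knn_classify",
    "ellipse_classify",
    "evaluate",
]

NORMAL = "normal"
ABNORMAL = "abnormal"

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass(frozen=True)
class JointCriterion:
    """A fitted joint-criterion rule: weight alpha and dividing line."""

    alpha: float
    dividing_line: float
    direction: str = "below"  # "below": values under the line are normal

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class SvmConfig:
    """C-SVC with an RBF kernel; defaults follow the published settings."""

    svm_type: str = "c_svc"
    kernel: str = "rbf"
    gamma: float | None = None  # None -> 1/k for k feature dimensions
    cost: float = 1.0
    cache_mb: float = 40.0
    eps: float = 0.001
    shrinking: bool = True
    class_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def to_dict(self) -> dict:
        return {
            "svm_type": self.svm_type,
            "kernel": self.kernel,
            "gamma": self.gamma if self.gamma is not None else "1/k",
            "cost": self.cost,
            "cache_mb": self.cache_mb,
            "eps": self.eps,
            "shrinking": self.shrinking,
            "class_weight": self.class_weight,
        }


@dataclass
class EvalReport:
    """Accuracy plus per-class confusion counts and a config echo."""

    n_correct: int
    n_total: int
    accuracy: float
    per_class: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "config_echo": self.config_echo,
        }


def joint_criterion(dard: float, p: float, alpha: float) -> float:
    """The weighted combination ``C = alpha*dARD + (1-alpha)*255*P``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("darkness fraction p must lie in [0, 1]")
    return float(alpha * dard + (1.0 - alpha) * 255.0 * p)


def _accuracy_at(values: np.ndarray, normal: np.ndarray, dl: float, direction: str) -> float:
    pred_normal = values < dl if direction == "below" else values > dl
    return float((pred_normal == normal).mean())


def find_dividing_line(
    values: np.ndarray, labels: list[str], direction: str = "below"
) -> tuple[float, float]:
    """Best scalar threshold for the rule "<direction> the line means normal".

    Candidate thresholds are the midpoints of consecutive sorted unique
    values plus the two trivial all-one-class rules; ties resolve to the
    smallest dividing line.  Returns ``(dividing_line, accuracy)``.
    """
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    values = np.asarray(values, dtype=float)
    normal = np.asarray([lab == NORMAL for lab in labels])
    if len(values) != len(normal):
        raise ValueError("values and labels must be aligned")
    if normal.all() or not normal.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(values)
    candidates = np.concatenate(([uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]))
    best_dl, best_acc = candidates[0], -1.0
    for dl in candidates:
        acc = _accuracy_at(values, normal, float(dl), direction)
        if acc > best_acc:
            best_dl, best_acc = float(dl), acc
    return best_dl, best_acc


def alpha_sweep(
    dards: np.ndarray,
    ps: np.ndarray,
    labels: list[str],
    alphas: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    direction: str = "below",
) -> pd.DataFrame:
    """Dividing line and accuracy of the joint criterion over an alpha grid.

    Returns one row per alpha with columns ``alpha``, ``dl``, ``accuracy``;
    the best alpha (ties to the smaller value) is flagged in column ``best``.
    """
    if len(alphas) == 0:
        raise ValueError("alpha grid must not be empty")
    dards = np.asarray(dards, dtype=float)
    ps = np.asarray(ps, dtype=float)
    if not (len(dards) == len(ps) == len(labels)):
        raise ValueError("dards, ps and labels must be aligned")
    rows = []
    for alpha in alphas:
        c = np.array([joint_criterion(d, p, alpha) for d, p in zip(dards, ps)])
        dl, acc = find_dividing_line(c, labels, direction)
        rows.append({"alpha": float(alpha), "dl": dl, "accuracy": acc})
    table = pd.DataFrame(rows)
    best_idx = int(table["accuracy"].idxmax())
    table["best"] = False
    table.loc[best_idx, "best"] = True
    return table


def build_fused_features(
    gray_profiles: list[RankProfile], dards: np.ndarray
) -> np.ndarray:
    """Fused SVM features: the 256 gray-spiral word ranks plus dARD appended.

    Requires m=8 profiles; returns an ``(n, 257)`` float array.
    """
    dards = np.asarray(dards, dtype=float)
    if len(gray_profiles) != len(dards):
        raise ValueError("gray_profiles and dards must be aligned")
    for p in gray_profiles:
        if p.m != 8:
            raise ValueError("fused features require m=8 gray profiles")
    ranks = np.stack([p.ranks for p in gray_profiles]).astype(float)
    return np.hstack([ranks, dards[:, None]])


def representative_split(
    profiles: list[RankProfile],
    labels: list[str],
    per_class: int = 5,
    dm: np.ndarray | None = None,
) -> np.ndarray:
    """Training indices: the ``per_class`` most representative per class.

    Representativeness is the smallest total D_m to the other profiles of the
    same class, evaluated on the given (gray-spiral) profiles.
    """
    labels_arr = np.asarray(labels)
    if dm is None:
        dm = pairwise_dm(profiles)
    train: list[int] = []
    for cls in (NORMAL, ABNORMAL):
        idx = np.flatnonzero(labels_arr == cls)
        if len(idx) < per_class:
            raise ValueError(f"need >= {per_class} samples of class {cls!r}")
        sub = dm[np.ix_(idx, idx)]
        chosen = select_representatives(
            [profiles[i] for i in idx], per_class, label=cls, dm=sub
        ).indices
        train.extend(int(idx[i]) for i in chosen)
    return np.asarray(sorted(train))


def svm_train_test(
    features: np.ndarray,
    labels: list[str],
    train_idx: np.ndarray,
    config: SvmConfig = SvmConfig(),
) -> EvalReport:
    """Fit a C-SVC on the training rows and score the remaining rows.

    Features are standardized per dimension on the training set (constant
    dimensions are left unscaled).  gamma defaults to 1/k for k dimensions.
    """
    features = np.asarray(features, dtype=float)
    labels_arr = np.asarray(labels)
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.setdiff1d(np.arange(len(features)), train_idx)
    if len(np.unique(labels_arr[train_idx])) < 2:
        raise ValueError("training split must contain both classes")

    mu = features[train_idx].mean(axis=0)
    sd = features[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    X = (features - mu) / sd

    k = features.shape[1]
    model = SVC(
        C=config.cost,
        kernel=config.kernel,
        gamma=config.gamma if config.gamma is not None else 1.0 / k,
        tol=config.eps,
        shrinking=config.shrinking,
        cache_size=config.cache_mb,
    )
    model.fit(X[train_idx], labels_arr[train_idx])
    pred = model.predict(X[test_idx])
    report = evaluate(list(pred), list(labels_arr[test_idx]))
    report.config_echo = {
        **config.to_dict(),
        "gamma_effective": config.gamma if config.gamma is not None else 1.0 / k,
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "standardized": True,
    }
    return report


def _resample_nearest(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize onto a common frame."""
    h, w = image.shape
    rows = np.minimum((np.arange(shape[0]) * h / shape[0]).astype(int), h - 1)
    cols = np.minimum((np.arange(shape[1]) * w / shape[1]).astype(int), w - 1)
    return image[np.ix_(rows, cols)]


def knn_classify(
    test: np.ndarray,
    refs: list[tuple[np.ndarray, str]],
    k: int = 10,
    normal_cut: int | None = None,
    frame: tuple[int, int] | None = None,
) -> str:
    """Label a crop by the k references with the smallest pixel difference.

    All images are resampled to a common frame (the median reference extent
    by default) and compared by summed absolute gray difference.  With the
    published cut (``normal_cut=3`` at ``k=10``) a crop is normal iff more
    than 3 of its 10 nearest references are normal; by default a plain
    majority vote is used.
    """
    if not 1 <= k <= len(refs):
        raise ValueError("k must lie in [1, len(refs)]")
    if frame is None:
        hs = sorted(img.shape[0] for img, _ in refs)
        ws = sorted(img.shape[1] for img, _ in refs)
        frame = (hs[len(hs) // 2], ws[len(ws) // 2])
    test_r = _resample_nearest(np.asarray(test, dtype=float), frame)
    diffs = np.array(
        [
            np.abs(test_r - _resample_nearest(np.asarray(img, dtype=float), frame)).sum()
            for img, _ in refs
        ]
    )
    nearest = np.argsort(diffs, kind="stable")[:k]
    n_normal = sum(1 for i in nearest if refs[i][1] == NORMAL)
    if normal_cut is None:
        return NORMAL if 2 * n_normal > k else ABNORMAL
    return NORMAL if n_normal > normal_cut else ABNORMAL


def ellipse_classify(
    mask: np.ndarray, band: tuple[float, float] = (1.2, 1.8)
) -> tuple[float, str]:
    """Ovality baseline: long/short side ratio of the principal-axis-aligned
    bounding rectangle; normal iff the ratio lies strictly inside ``band``.

    The principal axis comes from the mask's second moments, so the measure
    is rotation invariant up to discretization.  Degenerate (line-like) masks
    get infinite ovality and are abnormal.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must be non-empty")
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([rows, cols]).astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    angle = 0.5 * np.arctan2(2.0 * cov[0, 1], cov[1, 1] - cov[0, 0])
    axis = np.array([np.sin(angle), np.cos(angle)])
    ortho = np.array([-axis[1], axis[0]])
    span_a = pts @ axis
    span_o = pts @ ortho
    ext_a = float(span_a.max() - span_a.min())
    ext_o = float(span_o.max() - span_o.min())
    long_side, short_side = max(ext_a, ext_o), min(ext_a, ext_o)
    if short_side == 0:
        return float("inf"), ABNORMAL
    ovality = long_side / short_side
    label = NORMAL if band[0] < ovality < band[1] else ABNORMAL
    return ovality, label


def evaluate(pred: list[str], truth: list[str], config_echo: dict | None = None) -> EvalReport:
    """Accuracy and per-class confusion counts of a prediction list."""
    if len(pred) != len(truth):
        raise ValueError("pred and truth must be aligned")
    n_total = len(truth)
    n_correct = sum(1 for p, t in zip(pred, truth) if p == t)
    per_class: dict[str, dict[str, int]] = {}
    for t, p in zip(truth, pred):
        per_class.setdefault(t, {}).setdefault(p, 0)
        per_class[t][p] += 1
    return EvalReport(
        n_correct=n_correct,
        n_total=n_total,
        accuracy=n_correct / n_total if n_total else float("nan"),
        per_class=per_class,
        config_echo=config_echo or {},
    )
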
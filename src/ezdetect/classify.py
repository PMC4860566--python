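"""Imbalanced voxel classification: random under-sampling + discrete AdaBoost.

EZ disruption detection is a heavily imbalanced problem (non-disrupted
voxels outnumber disrupted ones by one to two orders of magnitude), tackled
on two levels: the training set is balanced by randomly under-sampling the
majority class, and the classifier is an AdaBoost ensemble of depth-1
decision stumps over the 10 PCA scores.

Labels are ``+1`` (disrupted) and ``-1`` (non-disrupted) throughout.  The
leave-one-out driver trains one model per held-out eye on all other eyes'
voxels, fitting the PCA model strictly inside the training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import PcaModel, apply_pca, fit_pca

__all__ = [
    "Stump",
    "AdaboostModel",
    "undersample",
    "train_adaboost",
    "predict",
    "loo_cv",
    "FoldResult",
]

_EPS_CLAMP = 1e-10


@dataclass
class Stump:
    """Depth-1 weak learner: predict ``polarity * sign(x[feature] - threshold)``."""

    feature: int
    threshold: float
    polarity: int  # +1 or -1

    def decide(self, X: np.ndarray) -> np.ndarray:
        h = np.where(X[:, self.feature] > self.threshold, 1, -1)
        return self.polarity * h


@dataclass
class AdaboostModel:
    """Ordered weak learners with their vote weights."""

    stumps: list
    alphas: list
    #: per-round weighted errors (diagnostics)
    epsilons: list = field(default_factory=list)

    @property
    def rounds(self) -> int:
        return len(self.stumps)

    def __post_init__(self):
        if len(self.stumps) != len(self.alphas):
            raise ValueError("stumps and alphas must have equal length")

    def to_dict(self) -> dict:
        return {
            "stumps": [
                {"feature": s.feature, "threshold": s.threshold, "polarity": s.polarity}
                for s in self.stumps
            ],
            "alphas": [float(a) for a in self.alphas],
            "epsilons": [float(e) for e in self.epsilons],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdaboostModel":
        stumps = [Stump(int(s["feature"]), float(s["threshold"]), int(s["polarity"]))
                  for s in d["stumps"]]
        return cls(stumps, [float(a) for a in d["alphas"]],
                   [float(e) for e in d.get("epsilons", [])])


def undersample(X: np.ndarray, y: np.ndarray, seed: int):
    """Balance a skewed training set by dropping random majority samples.

    All minority samples are kept; an equal number of majority samples is
    drawn uniformly without replacement.  The balanced set is returned in a
    seeded random order.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(f"undersample requires both classes; got only {classes}")
    minority = classes[np.argmin(counts)]
    rng = np.random.default_rng(seed)
    idx_min = np.flatnonzero(y == minority)
    idx_maj = np.flatnonzero(y != minority)
    pick = rng.choice(idx_maj, size=idx_min.size, replace=False)
    keep = np.concatenate([idx_min, pick])
    keep = keep[rng.permutation(keep.size)]
    return X[keep], y[keep]


def _best_stump(X, y, w):
    """Exhaustive weighted-error stump search over all features and midpoints."""
    n, d = X.shape
    best = (None, np.inf)
    for f in range(d):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y[order]
        ws = w[order]
        # err(theta) for polarity +1 (predict + above theta):
        #   sum w[y=+1, x<=theta] + sum w[y=-1, x>theta]
        wp = np.where(ys > 0, ws, 0.0)
        wn = ws - wp
        cum_p = np.concatenate([[0.0], np.cumsum(wp)])  # <= split position
        cum_n = np.concatenate([[0.0], np.cumsum(wn)])
        total_n = cum_n[-1]
        # split positions k = 0..n: theta below x[k]
        errs_pos = cum_p + (total_n - cum_n)
        # candidate splits: only between distinct consecutive values (+ ends)
        distinct = np.concatenate(
            [[True], xs[1:] > xs[:-1], [True]]
        )
        errs_pos = np.where(distinct, errs_pos, np.inf)
        k_pos = int(np.argmin(errs_pos))
        e_pos = errs_pos[k_pos]
        errs_neg = (cum_p[-1] - cum_p) + cum_n
        errs_neg = np.where(distinct, errs_neg, np.inf)
        k_neg = int(np.argmin(errs_neg))
        e_neg = errs_neg[k_neg]
        for pol, k, e in ((1, k_pos, e_pos), (-1, k_neg, e_neg)):
            if e < best[1]:
                if k == 0:
                    theta = xs[0] - 1.0
                elif k == n:
                    theta = xs[-1] + 1.0
                else:
                    theta = 0.5 * (xs[k - 1] + xs[k])
                best = (Stump(f, float(theta), pol), float(e))
    return best


def train_adaboost(X: np.ndarray, y: np.ndarray, T: int = 100) -> AdaboostModel:
    """Classic discrete AdaBoost with decision stumps.

    Uniform initial weights; per round the stump minimizing the weighted
    error ``eps_t`` is chosen over all features and candidate thresholds
    (midpoints of sorted distinct values), ``alpha_t = 0.5 ln((1-eps)/eps)``
    with ``eps`` clamped to ``[1e-10, 1 - 1e-10]``; multiplicative weight
    update with renormalization.  Stops early when ``eps_t >= 0.5`` (no
    better than chance) or ``eps_t <= 1e-10`` (separable).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if T < 1:
        raise ValueError("T must be >= 1")
    n = X.shape[0]
    w = np.full(n, 1.0 / n)
    stumps, alphas, epsilons = [], [], []
    for _ in range(T):
        stump, eps = _best_stump(X, y, w)
        if eps >= 0.5:
            if not stumps:  # degenerate data: keep one zero-weight stump
                stumps.append(stump)
                alphas.append(0.0)
                epsilons.append(float(eps))
            break
        eps_c = float(np.clip(eps, _EPS_CLAMP, 1 - _EPS_CLAMP))
        alpha = 0.5 * np.log((1 - eps_c) / eps_c)
        stumps.append(stump)
        alphas.append(float(alpha))
        epsilons.append(float(eps))
        if eps <= _EPS_CLAMP:
            break
        h = stump.decide(X)
        w = w * np.exp(-alpha * y * h)
        w /= w.sum()
    return AdaboostModel(stumps, alphas, epsilons)


def predict(model: AdaboostModel, X: np.ndarray):
    """Labels (+1/-1) and real margins.  Ties (margin 0) go to non-disrupted."""
    X = np.asarray(X, dtype=float)
    if model.stumps and X.shape[1] <= max(s.feature for s in model.stumps):
        raise ValueError("feature dimension smaller than stump indices")
    margins = np.zeros(X.shape[0])
    for stump, alpha in zip(model.stumps, model.alphas):
        margins += alpha * stump.decide(X)
    labels = np.where(margins > 0, 1, -1)
    return labels, margins


@dataclass
class FoldResult:
    """One leave-one-out fold: model trained with the named eye held out."""

    eye_id: str
    pca: PcaModel
    model: AdaboostModel
    pred_labels: np.ndarray   # predicted labels of the held-out eye's VOI voxels
    margins: np.ndarray
    undersample_seed: int


def loo_cv(eyes: list, T: int = 100, seed: int = 0, n_components: int = 10):
    """Leave-one-out over eyes.

    ``eyes`` is a list of dicts ``{"id": str, "X": (n_i, 57), "y": (n_i,)}``
    with labels in {+1, -1}.  For each held-out eye: PCA is fitted on the
    training voxels only, the training set is under-sampled to balance, an
    AdaBoost model is trained, and every VOI voxel of the held-out eye is
    classified.  Deterministic given ``seed``.
    """
    if len(eyes) < 2:
        raise ValueError("leave-one-out needs at least 2 eyes")
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(eyes))]
    results = []
    for i, eye in enumerate(eyes):
        train = [e for j, e in enumerate(eyes) if j != i]
        Xtr = np.concatenate([e["X"] for e in train], axis=0)
        ytr = np.concatenate([e["y"] for e in train], axis=0)
        if not np.any(ytr > 0):
            raise ValueError(
                f"fold holding out {eye['id']!r}: no disrupted training samples"
            )
        pca = fit_pca(Xtr, n_components=n_components)
        Ztr = apply_pca(pca, Xtr)
        Xb, yb = undersample(Ztr, ytr, seed=fold_seeds[i])
        model = train_adaboost(Xb, yb, T=T)
        Zte = apply_pca(pca, np.asarray(eye["X"], dtype=float))
        labels, margins = predict(model, Zte)
        results.append(
            FoldResult(eye["id"], pca, model, labels, margins, fold_seeds[i])
        )
    return results
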
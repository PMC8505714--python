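"""Sliding-window shrinkage-LDA decoding of single-trial MRCPs.

The decoder the rest of the package exists to evaluate: within a time
region of interest (tROI, default (−1.0, 2.5] s around movement onset) a
500-ms window slides in 50-ms steps; each window yields one classifier
trained on the 10 per-channel amplitudes spaced 50 ms apart inside the
window (33 channels × 10 = 330 features). Windows are labeled by their END
time under a half-open convention, giving exactly 70 models for the default
scheme, each causal (the model at time t sees only the preceding 500 ms).

The classifier is LDA with the pooled covariance shrunk toward a scaled
identity νI (ν = trace/d) at an analytically chosen intensity λ* (the
Ledoit–Wolf/Schäfer–Strimmer estimator), which keeps the inversion stable
when the feature count rivals the trial count. Multiclass decisions use
one-vs-one majority voting with summed-signed-margin tie-breaking.
Accuracy curves come from stratified 5-fold cross-validation repeated 10
times; chance is bounded by a one-sided adjusted-Wald binomial interval
around 1/k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from sklearn.model_selection import StratifiedKFold

from .io import EpochSet

__all__ = [
    "WindowScheme",
    "SLDAModel",
    "AccuracyCurve",
    "ConfusionMatrix",
    "ChanceBound",
    "extract_window_features",
    "fit_slda",
    "slda_decision",
    "OneVsOneSLDA",
    "cross_validated_curve",
    "peak_performance",
    "confusion_at",
    "chance_upper_bound",
]


# ---------------------------------------------------------------------------
# windows and features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window layout over the tROI.

    Window end times tile the half-open interval (troi_lo, troi_hi] in
    ``step_s`` steps: the default (−1.0, 2.5] at 50 ms gives exactly 70
    models, ends −0.95 … 2.50 s. A window labeled t uses the half-open
    sample range [t − window_len_s, t), i.e. the 10 amplitudes at
    t − 0.50 … t − 0.05 s for the defaults.
    """

    troi_s: tuple[float, float] = (-1.0, 2.5)
    window_len_s: float = 0.5
    step_s: float = 0.05
    samples_per_channel: int = 10

    def window_end_times(self) -> np.ndarray:
        lo, hi = self.troi_s
        n = int(round((hi - lo) / self.step_s))
        return np.round(lo + self.step_s * np.arange(1, n + 1), 10)

    @property
    def n_windows(self) -> int:
        return len(self.window_end_times())

    def feature_offsets(self) -> np.ndarray:
        """Sample offsets (s, relative to window end) of the amplitudes."""
        k = self.samples_per_channel
        dt = self.window_len_s / k
        return np.round(-self.window_len_s + dt * np.arange(k), 10)

    def n_features(self, n_channels: int) -> int:
        return n_channels * self.samples_per_channel


def extract_window_features(
    epochs: EpochSet, window_end_s: float, scheme: WindowScheme | None = None
) -> np.ndarray:
    """trials × (channels × samples_per_channel) amplitude matrix.

    Channels are concatenated in montage order, each contributing its
    ``samples_per_channel`` amplitudes on the 50-ms grid inside the window.
    """
    scheme = scheme or WindowScheme()
    times = np.round(window_end_s + scheme.feature_offsets(), 10)
    idx = [epochs.time_index(t) for t in times]  # raises if outside epoch
    n_tr, n_ch = epochs.data.shape[0], epochs.data.shape[1]
    return epochs.data[:, :, idx].reshape(n_tr, n_ch * len(idx))


# ---------------------------------------------------------------------------
# shrinkage LDA
# ---------------------------------------------------------------------------


@dataclass
class SLDAModel:
    """Binary shrinkage-LDA: decide class ``classes[1]`` iff w·x + b > 0."""

    weights: np.ndarray
    bias: float
    shrinkage: float  # λ* ∈ [0, 1]
    nu: float  # shrinkage target level, trace(Σ̂)/d
    classes: tuple

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision(X)
        return np.where(d > 0, self.classes[1], self.classes[0])


def _analytic_shrinkage(xc: np.ndarray, s_ml: np.ndarray, nu_ml: float) -> float:
    """Ledoit–Wolf λ* for shrinkage toward νI, from class-centered rows."""
    n = xc.shape[0]
    sq_norms = np.einsum("ij,ij->i", xc, xc)
    s_fro2 = float((s_ml * s_ml).sum())
    b2 = (sq_norms**2).sum() / n**2 - s_fro2 / n
    d_mat = s_ml.copy()
    d_mat[np.diag_indices_from(d_mat)] -= nu_ml
    d2 = float((d_mat * d_mat).sum())
    if d2 <= 0:
        return 0.0
    return float(np.clip(min(b2, d2) / d2, 0.0, 1.0))


def fit_slda(
    X: np.ndarray, y: np.ndarray, shrinkage: float | None = None
) -> SLDAModel:
    """Fit binary shrinkage-regularized LDA.

    Pooled class-mean-centered covariance Σ̂ (1/(n−1)); target νI with
    ν = trace(Σ̂)/d; analytic λ* unless ``shrinkage`` forces a value;
    Σ̃ = (1−λ)Σ̂ + λνI; w = Σ̃⁻¹(μ₂ − μ₁); b = −wᵀ(μ₁+μ₂)/2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary sLDA needs exactly 2 classes, got {len(classes)}")
    n, d = X.shape
    if n < 4:
        raise ValueError("need at least 4 training trials")
    if d == 0:
        raise ValueError("empty feature space")
    m1 = X[y == classes[0]].mean(axis=0)
    m2 = X[y == classes[1]].mean(axis=0)
    xc = X.copy()
    xc[y == classes[0]] -= m1
    xc[y == classes[1]] -= m2
    s_ml = (xc.T @ xc) / n
    nu_ml = float(np.trace(s_ml)) / d
    lam = (
        _analytic_shrinkage(xc, s_ml, nu_ml)
        if shrinkage is None
        else float(np.clip(shrinkage, 0.0, 1.0))
    )
    sigma_hat = s_ml * (n / (n - 1))
    nu = float(np.trace(sigma_hat)) / d
    sigma_t = (1.0 - lam) * sigma_hat
    sigma_t[np.diag_indices_from(sigma_t)] += lam * nu
    w = np.linalg.solve(sigma_t, m2 - m1)
    b = -float(w @ (m1 + m2)) / 2.0
    return SLDAModel(w, b, lam, nu, (classes[0], classes[1]))


def slda_decision(model: SLDAModel, X: np.ndarray) -> np.ndarray:
    return model.decision(X)


class OneVsOneSLDA:
    """k-class decoder: majority vote over all k(k−1)/2 pairwise models.

    Ties are broken by the largest sum of signed decision values over the
    tied classes' models, then by the lowest class label — deterministic.
    """

    def __init__(self, shrinkage: float | None = None):
        self.shrinkage = shrinkage
        self.models: dict[tuple, SLDAModel] = {}
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsOneSLDA":
        self.classes_ = np.unique(y)
        self.models = {}
        for i, a in enumerate(self.classes_):
            for b in self.classes_[i + 1 :]:
                m = (y == a) | (y == b)
                self.models[(a, b)] = fit_slda(X[m], y[m], self.shrinkage)
        return self

    @property
    def n_models(self) -> int:
        return len(self.models)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise RuntimeError("predict before fit")
        X = np.atleast_2d(X)
        k = len(self.classes_)
        cls_index = {c: i for i, c in enumerate(self.classes_)}
        votes = np.zeros((X.shape[0], k))
        margins = np.zeros((X.shape[0], k))
        for (a, b), model in self.models.items():
            dv = model.decision(X)
            ia, ib = cls_index[a], cls_index[b]
            win_b = dv > 0
            votes[win_b, ib] += 1
            votes[~win_b, ia] += 1
            margins[:, ib] += dv
            margins[:, ia] -= dv
        out = np.empty(X.shape[0], dtype=self.classes_.dtype)
        for r in range(X.shape[0]):
            top = votes[r].max()
            tied = np.flatnonzero(votes[r] == top)
            if len(tied) > 1:
                best = margins[r, tied].max()
                tied = tied[margins[r, tied] == best]
            out[r] = self.classes_[tied[0]]
        return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class AccuracyCurve:
    """Cross-validated accuracy per window end time."""

    window_time_s: np.ndarray
    accuracy: np.ndarray  # mean over folds × repetitions
    accuracy_sd: np.ndarray  # SD over folds × repetitions
    n_trials: int
    n_classes: int
    subject_id: str = "grand"
    contrast: str = ""

    def __len__(self) -> int:
        return len(self.window_time_s)


@dataclass
class ConfusionMatrix:
    """Pooled held-out counts at one window."""

    classes: np.ndarray
    counts: np.ndarray  # k × k, rows = true class
    window_time_s: float = float("nan")

    @property
    def normalized(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        return np.divide(
            self.counts, sums, out=np.zeros_like(self.counts, dtype=float),
            where=sums > 0,
        )

    @property
    def tpr(self) -> np.ndarray:
        return np.diag(self.normalized)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


@dataclass
class ChanceBound:
    n_trials: int
    n_classes: int
    alpha: float
    bound: float


def _fit_predictor(X, y, shrinkage):
    classes = np.unique(y)
    if len(classes) == 2:
        return fit_slda(X, y, shrinkage)
    return OneVsOneSLDA(shrinkage).fit(X, y)


def _cv_predictions(
    features_by_window: list[np.ndarray],
    y: np.ndarray,
    folds: int,
    repetitions: int,
    seed: int,
    shrinkage: float | None,
):
    """Yield (window_idx, rep, fold, test_idx, predictions)."""
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} trials; cannot stratify "
            f"into {folds} folds"
        )
    for r in range(repetitions):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        splits = list(skf.split(np.zeros(len(y)), y))
        for wi, X in enumerate(features_by_window):
            for fi, (train, test) in enumerate(splits):
                model = _fit_predictor(X[train], y[train], shrinkage)
                yield wi, r, fi, test, model.predict(X[test])


def cross_validated_curve(
    epochs: EpochSet,
    classes: list | None = None,
    scheme: WindowScheme | None = None,
    folds: int = 5,
    repetitions: int = 10,
    seed: int = 0,
    shrinkage: float | None = None,
    subject_id: str = "",
    contrast: str = "",
) -> AccuracyCurve:
    """Accuracy vs window end time over the tROI.

    Repetition r reshuffles the stratified folds with ``seed + r``; the
    reported accuracy is the mean over the folds × repetitions fold
    accuracies. Deterministic given the seed.
    """
    scheme = scheme or WindowScheme()
    sel = epochs.kept()
    if sel.labels is None:
        raise ValueError("epochs carry no labels")
    y = np.asarray(sel.labels)
    if classes is not None:
        m = np.isin(y, classes)
        sel = EpochSet(
            sel.data[m], sel.time_axis, list(sel.channel_labels),
            sel.sampling_rate_hz, labels=y[m], subject_id=sel.subject_id,
        )
        y = np.asarray(sel.labels)
    times = scheme.window_end_times()
    feats = [extract_window_features(sel, t, scheme) for t in times]
    fold_acc = np.zeros((len(times), repetitions * folds))
    for wi, r, fi, test, pred in _cv_predictions(
        feats, y, folds, repetitions, seed, shrinkage
    ):
        fold_acc[wi, r * folds + fi] = np.mean(pred == y[test])
    return AccuracyCurve(
        window_time_s=times,
        accuracy=fold_acc.mean(axis=1),
        accuracy_sd=fold_acc.std(axis=1, ddof=1),
        n_trials=len(y),
        n_classes=len(np.unique(y)),
        subject_id=subject_id,
        contrast=contrast,
    )


def peak_performance(curve: AccuracyCurve) -> tuple[float, float]:
    """(peak accuracy, window end time); ties resolve to the earliest time."""
    if len(curve) == 0:
        raise ValueError("empty curve")
    i = int(np.argmax(curve.accuracy))  # argmax returns the first maximum
    return float(curve.accuracy[i]), float(curve.window_time_s[i])


def confusion_at(
    epochs: EpochSet,
    window_time_s: float,
    classes: list | None = None,
    scheme: WindowScheme | None = None,
    folds: int = 5,
    repetitions: int = 10,
    seed: int = 0,
    shrinkage: float | None = None,
) -> ConfusionMatrix:
    """Held-out confusion counts pooled over folds × repetitions at one window."""
    scheme = scheme or WindowScheme()
    sel = epochs.kept()
    y = np.asarray(sel.labels)
    if classes is not None:
        m = np.isin(y, classes)
        sel = EpochSet(
            sel.data[m], sel.time_axis, list(sel.channel_labels),
            sel.sampling_rate_hz, labels=y[m],
        )
        y = np.asarray(sel.labels)
    cls = np.unique(y)
    cls_index = {c: i for i, c in enumerate(cls)}
    X = extract_window_features(sel, window_time_s, scheme)
    counts = np.zeros((len(cls), len(cls)))
    for _, _, _, test, pred in _cv_predictions(
        [X], y, folds, repetitions, seed, shrinkage
    ):
        for t, p in zip(y[test], pred):
            counts[cls_index[t], cls_index[p]] += 1
    return ConfusionMatrix(cls, counts, window_time_s)


# ---------------------------------------------------------------------------
# chance level
# ---------------------------------------------------------------------------


def chance_upper_bound(
    n_trials: int, n_classes: int, alpha: float = 0.05
) -> ChanceBound:
    """One-sided adjusted-Wald upper confidence bound on guessing accuracy.

    With p₀ = 1/k, x = n·p₀ and z the one-sided normal quantile at 1−α:
    p̃ = (x + z²/2)/(n + z²) and bound = p̃ + z·√(p̃(1−p̃)/(n + z²)).
    Accuracies above the bound are deemed better than chance.
    """
    if n_trials < 1 or n_classes < 2:
        raise ValueError("need n ≥ 1 trials and k ≥ 2 classes")
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must lie in (0, 0.5)")
    z = float(_sps.norm.ppf(1 - alpha))
    p0 = 1.0 / n_classes
    x = n_trials * p0
    p_t = (x + z**2 / 2.0) / (n_trials + z**2)
    bound = p_t + z * np.sqrt(p_t * (1 - p_t) / (n_trials + z**2))
    return ChanceBound(n_trials, n_classes, alpha, float(bound))
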
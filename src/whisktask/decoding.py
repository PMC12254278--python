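"""Cross-validated decoding of aperture width from spike counts, whisker
angle trajectories, and calcium transients, with shuffle controls.

Three decoders mirror the three recording modalities: a linear-kernel SVM
retrained per time bin with 10-fold stratified cross-validation (spikes), a
smooth additive classifier -- logistic regression on per-frame spline basis
expansions -- with a bootstrap ROC (whisker angles), and a small
convolutional network on trial-aligned dF/F snippets (calcium).  Label
shuffling before training provides the chance-level control in each case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import BSpline
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cnn import CalciumCNN
from .core import AngleTrace, CalciumTrace, SpikeTrain

__all__ = [
    "TrialFeatureSet",
    "DecodingResult",
    "balance_classes",
    "spike_count_features",
    "whisker_angle_features",
    "calcium_features",
    "decode_spikes",
    "decode_whisker_angles",
    "decode_calcium_cnn",
]


@dataclass
class TrialFeatureSet:
    """One row per trial: a channels x time feature tensor plus labels.

    ``t`` holds the sample times relative to touch (t = 0 at touch).
    """

    labels: np.ndarray                  # {"wide", "narrow"} per trial
    tensor: np.ndarray                  # (n_trials, n_channels, n_time)
    t: np.ndarray                       # seconds relative to touch
    fs: float
    allow_imbalance: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3 or self.tensor.shape[0] != self.labels.size:
            raise ValueError("tensor must be (n_trials, n_channels, n_time)")
        classes, counts = np.unique(self.labels, return_counts=True)
        if classes.size == 1:
            raise ValueError("feature set contains a single class")
        if not self.allow_imbalance and counts.min() / counts.sum() < 0.4:
            raise ValueError(
                "labels imbalanced beyond 10% of parity; pass allow_imbalance=True")

    @property
    def y(self) -> np.ndarray:
        return (self.labels == np.unique(self.labels)[1]).astype(int)

    @property
    def n_trials(self) -> int:
        return int(self.labels.size)


@dataclass
class DecodingResult:
    accuracy: float                               # windowed or validation accuracy
    accuracy_series: Optional[np.ndarray] = None  # per time bin (spike decoder)
    bin_times: Optional[np.ndarray] = None
    fold_assignment: Optional[np.ndarray] = None
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None  # bootstrap 95% CI
    roc_fpr: Optional[np.ndarray] = None
    roc_tpr: Optional[np.ndarray] = None
    roc_tpr_ci: Optional[np.ndarray] = None       # (2, n) pointwise 95% CI
    seed: int = 0


def balance_classes(features: TrialFeatureSet, seed: int = 0) -> TrialFeatureSet:
    """Subsample trials to exactly equal class counts (random without
    replacement), so chance-level accuracy is exactly 0.5."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(features.labels, return_counts=True)
    n = counts.min()
    keep = np.concatenate([
        rng.choice(np.flatnonzero(features.labels == c), n, replace=False)
        for c in classes])
    keep.sort()
    return TrialFeatureSet(labels=features.labels[keep],
                           tensor=features.tensor[keep], t=features.t,
                           fs=features.fs)


# --------------------------------------------------------------------------
# feature construction
# --------------------------------------------------------------------------

def spike_count_features(
    units: Sequence[SpikeTrain],
    touch_times: Sequence[float],
    labels: Sequence[str],
    window_s: tuple[float, float] = (-0.2, 0.4),
    bin_s: float = 0.05,
    allow_imbalance: bool = False,
) -> TrialFeatureSet:
    """Per-trial spike-count tensor (trials x units x time bins) aligned to
    touch."""
    touch_times = np.asarray(touch_times, dtype=float)
    edges = np.arange(window_s[0], window_s[1] + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    tensor = np.zeros((touch_times.size, len(units), centers.size))
    for j, u in enumerate(units):
        for i, tt in enumerate(touch_times):
            tensor[i, j], _ = np.histogram(u.spike_times - tt, bins=edges)
    return TrialFeatureSet(labels=np.asarray(labels), tensor=tensor,
                           t=centers, fs=1.0 / bin_s,
                           allow_imbalance=allow_imbalance)


def whisker_angle_features(
    trace: AngleTrace,
    touch_times: Sequence[float],
    labels: Sequence[str],
    frames: tuple[int, int] = (-20, 100),
    allow_imbalance: bool = False,
) -> TrialFeatureSet:
    """Whisker angle snippets from ``frames[0]`` before to ``frames[1]``
    after touch (240 fps), one channel."""
    i_touch = np.round((np.asarray(touch_times) - trace.t0) * trace.fps).astype(int)
    rel = np.arange(frames[0], frames[1])
    keep = (i_touch + frames[0] >= 0) & (i_touch + frames[1] <= len(trace))
    snippets = np.stack([trace.values[i + rel] for i in i_touch[keep]])
    return TrialFeatureSet(labels=np.asarray(labels)[keep],
                           tensor=snippets[:, None, :],
                           t=rel / trace.fps, fs=trace.fps,
                           allow_imbalance=allow_imbalance)


def calcium_features(
    traces: Sequence[CalciumTrace],
    touch_times: Sequence[float],
    labels: Sequence[str],
    frames_pre: int = 12,
    frames_post: int = 12,
    allow_imbalance: bool = False,
) -> TrialFeatureSet:
    """dF/F snippets (trials x neurons x 24 frames) straddling touch."""
    fps = traces[0].fps
    labels = np.asarray(labels)
    rel = np.arange(-frames_pre, frames_post)
    n_len = min(len(tr) for tr in traces)
    i_touch = np.round((np.asarray(touch_times) - traces[0].t0) * fps).astype(int)
    keep = (i_touch - frames_pre >= 0) & (i_touch + frames_post <= n_len)
    tensor = np.stack([
        np.stack([tr.values[i + rel] for tr in traces])
        for i in i_touch[keep]])
    return TrialFeatureSet(labels=labels[keep], tensor=tensor, t=rel / fps,
                           fs=fps, allow_imbalance=allow_imbalance)


# --------------------------------------------------------------------------
# decoders
# --------------------------------------------------------------------------

def decode_spikes(
    features: TrialFeatureSet,
    folds: int = 10,
    window_s: tuple[float, float] = (0.0, 0.4),
    shuffle_labels: bool = False,
    seed: int = 0,
) -> DecodingResult:
    """Time-resolved aperture decoding with a linear-kernel SVM.

    A maximum-margin classifier is retrained per time bin under
    ``folds``-fold stratified cross-validation (feature scaling fitted on
    the training folds only); the headline accuracy is the mean over bins
    from touch onset to 400 ms post-touch.
    """
    if features.n_trials < 20:
        raise ValueError("need at least 20 trials")
    rng = np.random.default_rng(seed)
    y = features.y
    if shuffle_labels:
        y = rng.permutation(y)
    n_bins = features.tensor.shape[2]
    acc = np.zeros(n_bins)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = np.full(features.n_trials, -1)
    splits = list(skf.split(features.tensor[:, :, 0], y))
    for k, (_, test) in enumerate(splits):
        fold_of[test] = k
    for b in range(n_bins):
        X = features.tensor[:, :, b]
        correct = 0
        for train, test in splits:
            scaler = StandardScaler().fit(X[train])
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(scaler.transform(X[train]), y[train])
            correct += int((clf.predict(scaler.transform(X[test])) == y[test]).sum())
        acc[b] = correct / features.n_trials
    in_win = (features.t >= window_s[0]) & (features.t < window_s[1])
    return DecodingResult(accuracy=float(acc[in_win].mean()),
                          accuracy_series=acc, bin_times=features.t,
                          fold_assignment=fold_of, seed=seed)


def _spline_basis(x: np.ndarray, knots: np.ndarray, k: int = 3) -> np.ndarray:
    """B-spline design matrix of a scalar feature; values are clipped to the
    knot range so test points never extrapolate."""
    t = np.concatenate([[knots[0]] * k, knots, [knots[-1]] * k])
    xc = np.clip(x, knots[0], knots[-1] - 1e-9 * max(abs(knots[-1]), 1.0))
    return BSpline.design_matrix(xc, t, k).toarray()


def decode_whisker_angles(
    features: TrialFeatureSet,
    test_fraction: float = 0.2,
    n_basis: int = 4,
    n_boot: int = 100,
    shuffle_control: bool = False,
    seed: int = 0,
) -> DecodingResult:
    """Additive-model decoding of aperture width from angle trajectories.

    Each per-frame angle is expanded in a cubic B-spline basis (knots at
    training-set quantiles) and a logistic regression over the concatenated
    expansions is fitted on 80% of trials; the ROC on the held-out 20% is
    reported with pointwise 95% CIs from ``n_boot`` bootstrap resamples.
    ``shuffle_control`` permutes labels before training.
    """
    rng = np.random.default_rng(seed)
    X = features.tensor.reshape(features.n_trials, -1)
    y = features.y
    if shuffle_control:
        y = rng.permutation(y)
    idx_train, idx_test = train_test_split(
        np.arange(features.n_trials), test_size=test_fraction,
        stratify=y, random_state=seed)
    # per-frame spline expansion with knots from the training data only
    n_feat = X.shape[1]
    blocks_train, blocks_test = [], []
    for j in range(n_feat):
        q = np.quantile(X[idx_train, j], np.linspace(0, 1, n_basis))
        q = np.unique(q)
        if q.size < 2:
            continue
        blocks_train.append(_spline_basis(X[idx_train, j], q))
        blocks_test.append(_spline_basis(X[idx_test, j], q))
    Xtr = np.hstack(blocks_train)
    Xte = np.hstack(blocks_test)
    clf = LogisticRegression(max_iter=2000, C=1.0)
    clf.fit(Xtr, y[idx_train])
    scores = clf.decision_function(Xte)
    y_test = y[idx_test]
    auc = float(roc_auc_score(y_test, scores))
    acc = float((clf.predict(Xte) == y_test).mean())
    fpr_grid = np.linspace(0, 1, 101)
    tpr_boot = np.empty((n_boot, fpr_grid.size))
    auc_boot = np.full(n_boot, np.nan)
    for b in range(n_boot):
        bi = rng.integers(0, y_test.size, y_test.size)
        if np.unique(y_test[bi]).size < 2:
            tpr_boot[b] = np.nan
            continue
        tpr_boot[b] = _roc_on_grid(y_test[bi], scores[bi], fpr_grid)
        auc_boot[b] = roc_auc_score(y_test[bi], scores[bi])
    tpr = _roc_on_grid(y_test, scores, fpr_grid)
    ci = np.nanpercentile(tpr_boot, [2.5, 97.5], axis=0)
    auc_ci = tuple(np.nanpercentile(auc_boot, [2.5, 97.5]))
    return DecodingResult(accuracy=acc, auc=auc, auc_ci=auc_ci,
                          roc_fpr=fpr_grid, roc_tpr=tpr, roc_tpr_ci=ci,
                          seed=seed)


def _roc_on_grid(y: np.ndarray, scores: np.ndarray, fpr_grid: np.ndarray) -> np.ndarray:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, scores)
    return np.interp(fpr_grid, fpr, tpr)


def decode_calcium_cnn(
    features: TrialFeatureSet,
    epochs: int = 100,
    lr: float = 0.01,
    momentum: float = 0.9,
    val_fraction: float = 0.25,
    shuffle_labels: bool = False,
    seed: int = 0,
) -> DecodingResult:
    """Binary classification of neurons x 24-frame calcium snippets with the
    compact convolutional network (see :class:`whisktask.cnn.CalciumCNN`).
    Returns the held-out validation accuracy; fully seeded."""
    n_neurons = features.tensor.shape[1]
    if n_neurons < 8 or features.n_trials < 40:
        raise ValueError("need at least 8 neurons and 40 trials")
    rng = np.random.default_rng(seed)
    y = features.y
    if shuffle_labels:
        y = rng.permutation(y)
    idx_train, idx_val = train_test_split(
        np.arange(features.n_trials), test_size=val_fraction,
        stratify=y, random_state=seed)
    X = features.tensor
    mu, sd = X[idx_train].mean(), X[idx_train].std() + 1e-9
    Xn = (X - mu) / sd
    net = CalciumCNN(input_shape=X.shape[1:], seed=seed)
    net.fit(Xn[idx_train], y[idx_train], epochs=epochs, lr=lr, momentum=momentum)
    acc = float((net.predict(Xn[idx_val]) == y[idx_val]).mean())
    fold = np.zeros(features.n_trials, dtype=int)
    fold[idx_val] = 1
    return DecodingResult(accuracy=acc, fold_assignment=fold, seed=seed)
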
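"""Single-trial target/nontarget classification and symbol decoding.

A single binary classifier — linear discriminant analysis with shrinkage
of the pooled covariance toward a scaled identity — is trained on
spatio-temporal features: the mean amplitude per (channel, temporal window)
with windows placed by a heuristic on the point-biserial correlation
between the two classes. Symbols are decoded by averaging classifier
outputs per selection group over the first ``n`` core sequences and taking
the argmax per decision stage (row and column for the Matrix; group then
disc for the Hex-o-Spell, where the second stage counts only if the first
was correct).

The shrinkage intensity can be fixed or chosen analytically (Ledoit-Wolf):
with pooled class-centered data ``z_k`` and sample covariance ``S``,

    gamma* = sum_ij Var^(S_ij) / sum_ij (S_ij - nu * I_ij)^2,

clipped to [0, 1], with ``nu = mean(diag(S))`` and ``Var^`` the empirical
variance of the entrywise covariance estimates. This shrinks the
high-variance off-diagonal structure exactly when n is small relative to
the 385-dimensional feature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .paradigm import BACKDOOR, TrialSchedule, decode_selection
from .preprocessing import EpochSet


# ---------------------------------------------------------------------------
# Feature construction


@dataclass(frozen=True)
class FeatureSpec:
    """Spatio-temporal feature layout: channels x temporal windows."""

    channels: tuple[str, ...]
    windows: tuple[tuple[float, float], ...]   # (start_ms, end_ms)

    @property
    def dimensionality(self) -> int:
        return len(self.channels) * len(self.windows)


def point_biserial(data: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Point-biserial correlation per feature between the two classes.

    *data* has observations on the first axis (any trailing shape); the
    result has the trailing shape. Zero-variance features map to r = 0.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    x = np.asarray(data, dtype=float)
    n = len(labels)
    n1 = labels.sum()
    n0 = n - n1
    m1 = x[labels].mean(axis=0)
    m0 = x[~labels].mean(axis=0)
    s = x.std(axis=0)  # population sd over all observations
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (m1 - m0) / s * np.sqrt(n1 * n0 / (n * n))
    return np.where(s > 0, r, 0.0)


def select_temporal_windows(
    score_map: np.ndarray,
    times_ms: np.ndarray,
    k: int = 7,
    width_ms: float = 40.0,
    min_separation_ms: float = 50.0,
    t_min_ms: float = 0.0,
) -> tuple[tuple[float, float], ...]:
    """Greedy peak picking on a channels x time discriminability map.

    The map is collapsed to a time score (maximum of \\|r\\| over channels);
    the k highest-scoring time points with pairwise separation of at least
    *min_separation_ms* become window centers. Windows of *width_ms* are
    clipped to the epoch range and returned sorted by time. Only post-onset
    samples (``t >= t_min_ms``) are considered. Fewer than *k* pickable
    peaks yields fewer windows with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    score = np.max(np.abs(np.atleast_2d(score_map)), axis=0)
    valid = times_ms >= t_min_ms
    order = np.argsort(score)[::-1]
    centers: list[float] = []
    for i in order:
        if not valid[i] or score[i] <= 0:
            continue
        t = times_ms[i]
        if all(abs(t - c) >= min_separation_ms for c in centers):
            centers.append(float(t))
        if len(centers) == k:
            break
    if len(centers) < k:
        warnings.warn(
            f"only {len(centers)} of {k} separated discriminability peaks "
            "found", stacklevel=2,
        )
    t_lo, t_hi = float(times_ms[0]), float(times_ms[-1])
    windows = []
    for c in sorted(centers):
        lo = max(t_lo, c - width_ms / 2.0)
        hi = min(t_hi, c + width_ms / 2.0)
        windows.append((lo, hi))
    return tuple(windows)


def build_features(
    epochs: EpochSet, spec: FeatureSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Mean amplitude per (channel, window), flattened channel-major.

    Uses every epoch in the set (the classification path applies no
    contamination filtering). Returns ``(X, y)`` with X of shape
    ``(n_epochs, spec.dimensionality)``.
    """
    ch_idx = []
    for ch in spec.channels:
        if ch not in epochs.channels:
            raise ValueError(f"channel {ch!r} not in epochs")
        ch_idx.append(epochs.channels.index(ch))
    t = epochs.times_ms
    cols = []
    for lo, hi in spec.windows:
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            raise ValueError(f"window ({lo}, {hi}) outside epoch range")
        cols.append(epochs.data[:, ch_idx][:, :, mask].mean(axis=2))
    # cols: list over windows of (n_epochs, n_channels) -> channel-major flat
    X = np.stack(cols, axis=2).reshape(len(epochs), -1)
    return X, epochs.labels.astype(int)


# ---------------------------------------------------------------------------
# Shrinkage LDA


@dataclass
class LDAModel:
    """Trained shrinkage-LDA discriminant."""

    weights: np.ndarray
    bias: float
    gamma: float
    feature_spec: FeatureSpec | None = None
    class_means: tuple[np.ndarray, np.ndarray] | None = None


def _ledoit_wolf_gamma(Z: np.ndarray) -> float:
    """Analytic shrinkage intensity toward nu*I from class-centered data."""
    n, d = Z.shape
    S = (Z.T @ Z) / (n - 1)
    nu = np.trace(S) / d
    wbar = (Z.T @ Z) / n
    sq = (Z**2).T @ (Z**2)                      # sum_k z_ki^2 z_kj^2
    var_s = n / (n - 1) ** 3 * (sq - n * wbar**2)
    target = nu * np.eye(d)
    denom = ((S - target) ** 2).sum()
    if denom <= 0:
        return 0.0
    return float(np.clip(var_s.sum() / denom, 0.0, 1.0))


class ShrinkageLDA:
    """Binary LDA with covariance shrinkage toward a scaled identity.

    Parameters
    ----------
    gamma : float in [0, 1] or "auto"
        Shrinkage intensity; "auto" uses the analytic Ledoit-Wolf estimate.

    After :meth:`fit`, ``decision_function`` returns ``w @ x + b`` with the
    threshold midway between the projected class means, so positive outputs
    are more target-like.
    """

    def __init__(self, gamma: float | str = "auto"):
        if gamma != "auto" and not 0.0 <= float(gamma) <= 1.0:
            raise ValueError("gamma must be 'auto' or lie in [0, 1]")
        self.gamma = gamma
        self.model_: LDAModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("exactly two classes required")
        X0, X1 = X[y == classes[0]], X[y == classes[1]]
        if len(X0) < 2 or len(X1) < 2:
            raise ValueError("each class needs at least 2 samples")
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        Z = np.concatenate([X0 - mu0, X1 - mu1])
        n, d = Z.shape
        S = (Z.T @ Z) / (n - 1)
        nu = np.trace(S) / d
        gamma = (
            _ledoit_wolf_gamma(Z) if self.gamma == "auto" else float(self.gamma)
        )
        S_shrunk = (1.0 - gamma) * S + gamma * nu * np.eye(d)
        w = np.linalg.solve(S_shrunk, mu1 - mu0)
        b = -float(w @ (mu0 + mu1)) / 2.0
        self.model_ = LDAModel(
            weights=w, bias=b, gamma=gamma, class_means=(mu0, mu1)
        )
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return score(self.model_, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def train_shrinkage_lda(
    X: np.ndarray,
    y: np.ndarray,
    gamma: float | str = "auto",
    feature_spec: FeatureSpec | None = None,
) -> LDAModel:
    clf = ShrinkageLDA(gamma=gamma).fit(X, y)
    clf.model_.feature_spec = feature_spec
    return clf.model_


def score(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Classifier output ``w @ x + b`` per epoch (higher = more target-like)."""
    if model is None:
        raise ValueError("model is not fitted")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.weights):
        raise ValueError(
            f"feature length {X.shape[1]} != model dimension "
            f"{len(model.weights)}"
        )
    return X @ model.weights + model.bias


# ---------------------------------------------------------------------------
# Symbol decoding


def decode_trial(
    outputs: np.ndarray,
    schedule: TrialSchedule,
    n_sequences: int,
) -> str:
    """Select a symbol from per-event classifier outputs for one trial.

    *outputs* is aligned with the schedule's flat event table (levels
    concatenated, stream order). Only core events of the first
    *n_sequences* sequences enter; outputs are averaged per selection group
    and the argmax wins per decision stage (ties resolve to the lowest
    group id). Returns the decoded symbol, or :data:`~erpspeller.paradigm.BACKDOOR`
    when the Hex-o-Spell empty disc wins the symbol level.
    """
    if not 1 <= n_sequences <= schedule.timing.n_sequences:
        raise ValueError("n_sequences outside the scheduled range")
    frame = schedule.to_frame()
    if len(outputs) != len(frame):
        raise ValueError("outputs length must match schedule events")
    frame = frame.assign(output=np.asarray(outputs, dtype=float))
    layout = schedule.layout
    selections = []
    for lvl in schedule.levels:
        n_groups = layout.n_groups(lvl)
        sub = frame[(frame["level"] == lvl) & (frame["phase"] == "core")]
        prequel_len = int(
            (frame["level"] == lvl).sum() - len(sub)
        ) // 2
        core_pos = sub["index"].to_numpy() - prequel_len
        seq_idx = core_pos // n_groups
        sub = sub[seq_idx < n_sequences]
        means = sub.groupby("element_id")["output"].mean()
        if layout.kind == "matrix":
            rows = means.reindex(range(0, 6)).to_numpy()
            cols = means.reindex(range(6, 11)).to_numpy()
            selections = [int(np.argmax(rows)), 6 + int(np.argmax(cols))]
        else:
            vals = means.reindex(range(n_groups)).to_numpy()
            selections.append(int(np.argmax(vals)))
    return decode_selection(layout, tuple(selections))


@dataclass
class DecodingResult:
    """Per-trial selections and the accuracy-vs-sequences curve."""

    n_sequences: np.ndarray                  # 1..max
    accuracy_curve: np.ndarray               # fraction correct per n
    selections: pd.DataFrame                 # trial, n_sequences, true, selected
    condition: tuple = ()


def accuracy_curve(
    trials: list[tuple[str, np.ndarray, TrialSchedule]],
    max_sequences: int | None = None,
    condition: tuple = (),
) -> DecodingResult:
    """Decode every trial at each sequence count and tally accuracy.

    *trials* holds ``(true_symbol, per-event outputs, schedule)`` tuples —
    in the offline design these are test-block trials scored by a model
    trained on the first block.
    """
    if not trials:
        raise ValueError("at least one trial required")
    if max_sequences is None:
        max_sequences = trials[0][2].timing.n_sequences
    ns = np.arange(1, max_sequences + 1)
    rows = []
    for trial_i, (true_symbol, outputs, schedule) in enumerate(trials):
        for n in ns:
            sel = decode_trial(outputs, schedule, int(n))
            rows.append((trial_i, int(n), true_symbol, sel,
                         sel == true_symbol))
    frame = pd.DataFrame(
        rows, columns=["trial", "n_sequences", "true", "selected", "correct"]
    )
    curve = frame.groupby("n_sequences")["correct"].mean().to_numpy()
    return DecodingResult(
        n_sequences=ns, accuracy_curve=curve, selections=frame,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# Discriminability maps


def _cv_error(
    X: np.ndarray, y: np.ndarray, gamma: float | str = "auto",
    n_folds: int = 5, seed: int = 0,
) -> float:
    """Cross-validated balanced classification error (mean class error)."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = []
    for tr, te in skf.split(X, y):
        clf = ShrinkageLDA(gamma=gamma).fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        yt = y[te]
        e1 = (pred[yt == 1] != 1).mean() if (yt == 1).any() else np.nan
        e0 = (pred[yt == 0] != 0).mean() if (yt == 0).any() else np.nan
        errs.append(np.nanmean([e0, e1]))
    return float(np.mean(errs))


def electrode_errors(
    epochs: EpochSet,
    gamma: float | str = "auto",
    n_folds: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Per-electrode cross-validated error, time samples as features."""
    y = epochs.labels.astype(int)
    post = epochs.times_ms >= 0
    out = {}
    for k, ch in enumerate(epochs.channels):
        X = epochs.data[:, k, post]
        out[ch] = _cv_error(X, y, gamma=gamma, n_folds=n_folds, seed=seed)
    return pd.Series(out, name="error")


def window_errors(
    epochs: EpochSet,
    width_ms: float = 40.0,
    step_ms: float = 10.0,
    gamma: float | str = "auto",
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Error for a single sliding temporal feature: a 40 ms window mean.

    All electrodes contribute one feature each (the window mean); the
    window center steps across the post-onset epoch. Returns a frame with
    columns ``center_ms`` and ``error``.
    """
    y = epochs.labels.astype(int)
    t = epochs.times_ms
    centers = np.arange(width_ms / 2.0, t[-1] - width_ms / 2.0 + 1e-9, step_ms)
    rows = []
    for c in centers:
        mask = (t >= c - width_ms / 2.0) & (t <= c + width_ms / 2.0)
        X = epochs.data[:, :, mask].mean(axis=2)
        rows.append((float(c),
                     _cv_error(X, y, gamma=gamma, n_folds=n_folds, seed=seed)))
    return pd.DataFrame(rows, columns=["center_ms", "error"])
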
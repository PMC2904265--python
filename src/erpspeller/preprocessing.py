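"""Downsampling, epoching, baseline correction, and contamination filters.

Because successive intensifications are only one SOA (166 ms) apart, the
evoked response to any event overlaps its neighbors'. For ERP measurement,
epochs are therefore screened on the *event stream alone*:

* a target epoch is kept only if the nearest preceding and following target
  intensifications are at least 3 stream positions (~500 ms) away;
* a nontarget epoch is kept only if no target occurs among the 3 preceding
  or the 2 following intensifications.

Both filters are pure functions of the schedule, so identical schedules
yield identical kept sets regardless of the signal. The classification
path uses all epochs and skips these filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .synth import Recording


@dataclass(frozen=True)
class EpochWindow:
    """Epoch extent relative to event onset, in ms; baseline is pre-stimulus."""

    start_ms: float = -170.0
    end_ms: float = 670.0
    baseline: tuple[float, float] = (-170.0, 0.0)

    def __post_init__(self) -> None:
        if not self.start_ms < 0 < self.end_ms:
            raise ValueError("window must straddle the event onset")
        b0, b1 = self.baseline
        if not (self.start_ms <= b0 < b1 <= 0):
            raise ValueError("baseline must lie within [start_ms, 0]")


@dataclass
class EpochSet:
    """Time-locked segments with labels, kept flags, and event metadata."""

    data: np.ndarray            # epochs x channels x time, microvolts
    times_ms: np.ndarray
    channels: tuple[str, ...]
    labels: np.ndarray          # bool, True = target
    kept: np.ndarray            # bool
    reasons: np.ndarray         # str, "" when kept
    meta: pd.DataFrame          # level, index, phase, element_id, ...
    fs_hz: float

    def __len__(self) -> int:
        return self.data.shape[0]

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            times_ms=self.times_ms,
            channels=self.channels,
            labels=self.labels[mask],
            kept=self.kept[mask],
            reasons=self.reasons[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            fs_hz=self.fs_hz,
        )


def resample(recording: Recording, target_fs: float) -> Recording:
    """Integer-factor decimation with FIR anti-alias filtering.

    Event sample indices are rescaled by the decimation factor; rejects
    target rates that do not divide the original rate.
    """
    ratio = recording.fs_hz / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"target_fs={target_fs} must divide fs={recording.fs_hz} "
            "by an integer factor"
        )
    if q == 1:
        return recording
    data = scipy.signal.decimate(
        recording.samples, q, ftype="fir", zero_phase=True, axis=1
    )
    events = recording.events.copy()
    events["sample"] = events["sample"] // q
    return Recording(
        channel_labels=recording.channel_labels,
        fs_hz=target_fs,
        samples=data,
        events=events,
    )


def extract_epochs(
    recording: Recording, window: EpochWindow | None = None
) -> EpochSet:
    """One baseline-corrected epoch per event marker.

    Events too close to the recording edges for the full window are kept in
    the set but flagged excluded with reason ``"boundary"``. Baseline
    correction subtracts, per channel, the mean over the pre-stimulus
    baseline interval.
    """
    window = window or EpochWindow()
    if not len(recording.events):
        raise ValueError("recording has no events to epoch")
    fs = recording.fs_hz
    start = int(round(window.start_ms * fs / 1000.0))
    end = int(round(window.end_ms * fs / 1000.0))
    n_t = end - start + 1
    times_ms = (start + np.arange(n_t)) * 1000.0 / fs
    b_mask = (times_ms >= window.baseline[0]) & (times_ms <= window.baseline[1])

    n_ep = len(recording.events)
    n_ch = recording.samples.shape[0]
    data = np.zeros((n_ep, n_ch, n_t))
    kept = np.ones(n_ep, dtype=bool)
    reasons = np.array([""] * n_ep, dtype=object)
    onsets = recording.events["sample"].to_numpy()
    for i, onset in enumerate(onsets):
        lo, hi = onset + start, onset + end
        if lo < 0 or hi >= recording.n_samples:
            kept[i] = False
            reasons[i] = "boundary"
            continue
        seg = recording.samples[:, lo:hi + 1]
        data[i] = seg - seg[:, b_mask].mean(axis=1, keepdims=True)

    return EpochSet(
        data=data,
        times_ms=times_ms,
        channels=recording.channel_labels,
        labels=recording.events["is_target"].to_numpy(dtype=bool),
        kept=kept,
        reasons=reasons,
        meta=recording.events.reset_index(drop=True),
        fs_hz=fs,
    )


def filter_target_epochs(
    is_target: np.ndarray, min_gap: int = 3
) -> np.ndarray:
    """Indices of target events isolated from other targets in the stream.

    A target at stream position ``i`` is kept iff the nearest preceding and
    the nearest following target (when they exist) are both at least
    *min_gap* positions away; stream edges count as satisfied.
    """
    is_target = np.asarray(is_target, dtype=bool)
    pos = np.flatnonzero(is_target)
    kept = []
    for k, p in enumerate(pos):
        ok_prev = k == 0 or p - pos[k - 1] >= min_gap
        ok_next = k == len(pos) - 1 or pos[k + 1] - p >= min_gap
        if ok_prev and ok_next:
            kept.append(p)
    return np.asarray(kept, dtype=int)


def filter_nontarget_epochs(
    is_target: np.ndarray, n_before: int = 3, n_after: int = 2
) -> np.ndarray:
    """Indices of nontarget events unconfounded by nearby targets.

    A nontarget at position ``i`` is kept iff no target occupies positions
    ``i-n_before .. i-1`` or ``i+1 .. i+n_after``; the checked ranges are
    truncated at the stream edges.
    """
    is_target = np.asarray(is_target, dtype=bool)
    n = len(is_target)
    kept = []
    for i in np.flatnonzero(~is_target):
        before = is_target[max(0, i - n_before):i]
        after = is_target[i + 1:min(n, i + n_after + 1)]
        if not before.any() and not after.any():
            kept.append(i)
    return np.asarray(kept, dtype=int)


def schedule_kept_events(schedule) -> dict[int, dict[str, np.ndarray]]:
    """Per-level kept target/nontarget stream indices for a trial schedule."""
    out = {}
    for lvl in schedule.levels:
        flags = np.array([ev.is_target for ev in schedule.events[lvl]])
        out[lvl] = {
            "target": filter_target_epochs(flags),
            "nontarget": filter_nontarget_epochs(flags),
        }
    return out


def apply_erp_filters(epochs: EpochSet) -> EpochSet:
    """Mark epochs excluded by the target/nontarget contamination rules.

    Streams are identified by the ``level`` metadata column (plus ``trial``
    when present); within each stream the filters run on the is_target flag
    sequence in stream order. Boundary exclusions are preserved.
    """
    meta = epochs.meta
    kept = epochs.kept.copy()
    reasons = epochs.reasons.copy()
    stream_keys = ["level"]
    if "trial" in meta.columns:
        stream_keys = ["trial", "level"]
    for _, idx in meta.groupby(stream_keys, sort=False).groups.items():
        idx = np.asarray(idx)
        order = np.argsort(meta.loc[idx, "index"].to_numpy())
        idx = idx[order]
        flags = epochs.labels[idx]
        ok = np.zeros(len(idx), dtype=bool)
        ok[filter_target_epochs(flags)] = True
        ok[filter_nontarget_epochs(flags)] = True
        for local, global_i in enumerate(idx):
            if kept[global_i] and not ok[local]:
                kept[global_i] = False
                reasons[global_i] = (
                    "target_proximity" if flags[local] else "nontarget_context"
                )
    out = EpochSet(
        data=epochs.data,
        times_ms=epochs.times_ms,
        channels=epochs.channels,
        labels=epochs.labels,
        kept=kept,
        reasons=reasons,
        meta=epochs.meta,
        fs_hz=epochs.fs_hz,
    )
    return out
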
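"""ERP averaging and component measurement.

Component amplitudes are measured on condition averages by picking the
largest peak of the component's polarity inside a fixed latency window;
when the window contains no local extremum of the right polarity, the mean
amplitude over the window is used instead (and no latency is reported).
P1/N1/N2 are read off parieto-occipital electrodes, P2/P3 off the midline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import MIDLINE_SUBSET, POSTERIOR_SUBSET
from .preprocessing import EpochSet

#: Component measurement windows (ms) and polarities.
COMPONENT_WINDOWS: dict[str, tuple[float, float]] = {
    "P1": (80.0, 150.0),
    "N1": (150.0, 230.0),
    "P2": (210.0, 290.0),
    "N2": (280.0, 360.0),
    "P3": (350.0, 440.0),
}

COMPONENT_POLARITY: dict[str, int] = {
    "P1": +1, "N1": -1, "P2": +1, "N2": -1, "P3": +1,
}

#: Electrode subset on which each component is measured.
COMPONENT_ELECTRODES: dict[str, tuple[str, ...]] = {
    "P1": POSTERIOR_SUBSET,
    "N1": POSTERIOR_SUBSET,
    "N2": POSTERIOR_SUBSET,
    "P2": MIDLINE_SUBSET,
    "P3": MIDLINE_SUBSET,
}


@dataclass(frozen=True)
class ComponentMeasure:
    component: str
    electrode: str
    condition: tuple
    amplitude_uV: float
    latency_ms: float | None
    method: str                  # "peak" | "mean_fallback"

    def __post_init__(self) -> None:
        if self.method == "peak":
            lo, hi = COMPONENT_WINDOWS[self.component]
            if self.latency_ms is None or not lo <= self.latency_ms <= hi:
                raise ValueError("peak latency must lie inside the window")
        elif self.method == "mean_fallback":
            if self.latency_ms is not None:
                raise ValueError("mean_fallback carries no latency")
        else:
            raise ValueError(f"unknown method {self.method!r}")


def average_erp(
    epochs: EpochSet, grouping: tuple[str, ...] = ("is_target",)
) -> dict[tuple, tuple[np.ndarray, int]]:
    """Per-group mean waveform over *kept* epochs.

    Groups are defined by metadata columns (``is_target`` refers to the
    epoch labels). Returns ``{group_key: (channels x time mean, n_epochs)}``;
    empty groups are omitted.
    """
    meta = epochs.meta.copy()
    meta["is_target"] = epochs.labels
    out: dict[tuple, tuple[np.ndarray, int]] = {}
    kept_idx = np.flatnonzero(epochs.kept)
    if not len(kept_idx):
        return out
    sub = meta.iloc[kept_idx]
    for key, idx in sub.groupby(list(grouping), sort=True).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        rows = np.asarray(idx)
        out[key] = (epochs.data[rows].mean(axis=0), len(rows))
    return out


def _local_extrema(x: np.ndarray, polarity: int) -> np.ndarray:
    """Indices of strict 3-point local extrema of the given polarity."""
    y = polarity * x
    interior = np.arange(1, len(x) - 1)
    mask = (y[interior] > y[interior - 1]) & (y[interior] > y[interior + 1])
    return interior[mask]


def extract_component(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    component: str,
    condition: tuple = (),
    electrode: str = "",
    windows: dict[str, tuple[float, float]] | None = None,
) -> ComponentMeasure:
    """Peak amplitude/latency of one component on a single-channel average.

    The peak is the largest strict local extremum of the component's
    polarity inside the window (window endpoints do not qualify). Without
    such an extremum the window mean is returned as ``mean_fallback``.
    """
    windows = windows or COMPONENT_WINDOWS
    lo, hi = windows[component]
    if times_ms[0] > lo or times_ms[-1] < hi:
        raise ValueError(
            f"epoch time axis does not cover the {component} window"
        )
    polarity = COMPONENT_POLARITY[component]
    in_win = np.flatnonzero((times_ms >= lo) & (times_ms <= hi))
    seg = waveform[in_win]
    # Extrema are found on the windowed segment but only interior samples
    # of the window count, matching the "no edge peaks" convention.
    ext = _local_extrema(seg, polarity)
    if len(ext):
        best = ext[np.argmax(polarity * seg[ext])]
        return ComponentMeasure(
            component=component,
            electrode=electrode,
            condition=condition,
            amplitude_uV=float(seg[best]),
            latency_ms=float(times_ms[in_win[best]]),
            method="peak",
        )
    return ComponentMeasure(
        component=component,
        electrode=electrode,
        condition=condition,
        amplitude_uV=float(seg.mean()),
        latency_ms=None,
        method="mean_fallback",
    )


def difference_amplitude(
    target: ComponentMeasure, nontarget: ComponentMeasure
) -> float:
    """Target-minus-nontarget amplitude for matched measures (µV)."""
    if (target.component, target.electrode, target.condition) != (
        nontarget.component, nontarget.electrode, nontarget.condition
    ):
        raise ValueError("measures must share component, electrode, condition")
    return target.amplitude_uV - nontarget.amplitude_uV


def component_table(
    epochs: EpochSet,
    condition: tuple = (),
    components: tuple[str, ...] = tuple(COMPONENT_WINDOWS),
) -> pd.DataFrame:
    """Tidy long-format component measures for one condition's epochs.

    One row per component x electrode x status (target/nontarget), measured
    on the kept-epoch averages. Columns: component, electrode, status,
    amplitude_uV, latency_ms, method, n_epochs.
    """
    averages = average_erp(epochs, ("is_target",))
    rows = []
    for status_key, (avg, n) in averages.items():
        status = "target" if status_key[0] else "nontarget"
        for comp in components:
            for elec in COMPONENT_ELECTRODES[comp]:
                ch = epochs.channels.index(elec)
                m = extract_component(
                    avg[ch], epochs.times_ms, comp,
                    condition=condition, electrode=elec,
                )
                rows.append(
                    (comp, elec, status, m.amplitude_uV, m.latency_ms,
                     m.method, n) + condition
                )
    cols = ["component", "electrode", "status", "amplitude_uV",
            "latency_ms", "method", "n_epochs"]
    cols += [f"cond_{i}" for i in range(len(condition))]
    return pd.DataFrame(rows, columns=cols)


def difference_table(table: pd.DataFrame) -> pd.DataFrame:
    """Target-minus-nontarget difference amplitudes from a component table."""
    idx = ["component", "electrode"] + [
        c for c in table.columns if c.startswith("cond_")
    ]
    wide = table.pivot_table(
        index=idx, columns="status", values="amplitude_uV"
    ).reset_index()
    wide["difference_uV"] = wide["target"] - wide["nontarget"]
    return wide
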
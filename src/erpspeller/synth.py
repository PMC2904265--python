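"""Synthetic multichannel EEG with known evoked ground truth.

Every intensification event contributes a set of evoked components (P1, N1,
P2, N2, P3), each a Gaussian bump in time multiplied by a smooth scalp
topography. Because the stimulus onset asynchrony (166 ms) is much shorter
than a component sweep, responses of neighboring events overlap; the
generator superposes them linearly, which is exactly the situation the
epoch-contamination filters in :mod:`erpspeller.preprocessing` are built
for. Attention is modeled as a multiplicative per-component gain applied to
target events only; preset gain profiles encode the qualitative modulation
pattern observed for overt vs covert attention and for the two spellers.
Background activity is spatially smoothed 1/f^alpha noise.

Amplitudes are free parameters of the generator (real ERP magnitudes vary
widely across participants); defaults are typical adult visual-oddball
values in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import CHANNELS_64, MIDLINE_SUBSET, POSTERIOR_SUBSET, \
    channel_positions, topography
from .paradigm import TrialSchedule

COMPONENT_NAMES = ("P1", "N1", "P2", "N2", "P3")

#: FWHM-to-sigma conversion for Gaussian kernels.
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.355


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked component: temporal Gaussian x spatial weight map."""

    name: str
    polarity: int
    peak_latency_ms: float
    width_ms: float          # full width at half maximum
    base_amplitude_uV: float
    topography: np.ndarray   # per-channel weights, unit maximum

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        expected = 1 if self.name.startswith("P") else -1
        if self.polarity != expected:
            raise ValueError(
                f"component {self.name} must have polarity {expected:+d}"
            )
        topo = np.asarray(self.topography, dtype=float)
        if np.any(np.abs(topo) > 1.0 + 1e-12):
            raise ValueError("topography weights must lie in [-1, 1]")


def default_components(
    channels: tuple[str, ...] = CHANNELS_64,
) -> tuple[ComponentSpec, ...]:
    """The five standard components with defaults tied to the analysis windows.

    Latencies sit at the centers of the component measurement windows
    (80-150, 150-230, 210-290, 280-360, 350-440 ms) so each simulated peak
    falls inside its detection window. Widths are typical empirical FWHMs,
    deliberately narrower than the window spans: the windows themselves
    overlap their neighbors, and window-wide kernels would bleed one
    component's modulation into the adjacent component's measurement,
    making the generator's ground-truth gains unrecoverable.
    P1/N1/N2 peak over parieto-occipital sites, P2/P3 along the midline.
    """
    posterior = topography(POSTERIOR_SUBSET, channels)
    midline = topography(MIDLINE_SUBSET, channels)
    table = (
        ("P1", +1, 115.0, 50.0, 3.0, posterior),
        ("N1", -1, 190.0, 50.0, 4.0, posterior),
        ("P2", +1, 250.0, 60.0, 4.0, midline),
        ("N2", -1, 320.0, 60.0, 3.0, posterior),
        ("P3", +1, 395.0, 80.0, 5.0, midline),
    )
    return tuple(
        ComponentSpec(name, pol, lat, width, amp, topo)
        for name, pol, lat, width, amp, topo in table
    )


@dataclass(frozen=True)
class ModulationProfile:
    """Per-component target gains for one attention x speller condition.

    Nontarget events always carry gain 1. Preset profiles follow the
    qualitative findings: under overt attention all five components are
    enhanced for targets (slightly more so for the Hex-o-Spell on P1/P2);
    under covert attention the Matrix modulates only N2 and P3 while the
    Hex-o-Spell additionally modulates N1 and P2 and shows a *reversed* N2
    (smaller amplitude for targets).
    """

    attention: str
    speller: str
    gains: dict[str, float]

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.gains.values()):
            raise ValueError("target gains must be >= 0")

    def gain(self, component: str) -> float:
        return self.gains.get(component, 1.0)

    @classmethod
    def preset(cls, attention: str, speller: str) -> "ModulationProfile":
        presets = {
            ("overt", "matrix"): {"P1": 1.7, "N1": 2.0, "P2": 1.8,
                                  "N2": 1.6, "P3": 1.8},
            ("overt", "hex"): {"P1": 1.9, "N1": 2.0, "P2": 2.0,
                               "N2": 1.6, "P3": 1.8},
            ("covert", "matrix"): {"P1": 1.0, "N1": 1.0, "P2": 1.0,
                                   "N2": 1.2, "P3": 1.32},
            ("covert", "hex"): {"P1": 1.0, "N1": 1.12, "P2": 1.2,
                                "N2": 0.85, "P3": 1.42},
        }
        try:
            gains = presets[(attention, speller)]
        except KeyError:
            raise ValueError(
                f"no preset for attention={attention!r}, speller={speller!r}"
            ) from None
        return cls(attention=attention, speller=speller, gains=dict(gains))


@dataclass(frozen=True)
class NoiseModel:
    """Spatially smoothed 1/f^alpha background noise."""

    rms_uV: float = 10.0
    spectral_exponent: float = 1.0
    channel_mixing: float = 0.5   # 0 = independent channels, ->1 = smoother

    def __post_init__(self) -> None:
        if self.rms_uV < 0:
            raise ValueError("rms_uV must be >= 0")
        if self.spectral_exponent < 0:
            raise ValueError("spectral_exponent must be >= 0")
        if not 0.0 <= self.channel_mixing < 1.0:
            raise ValueError("channel_mixing must lie in [0, 1)")


@dataclass
class Recording:
    """Continuous multichannel signal plus an event-marker table.

    ``events`` columns: sample, index, level, phase, element_id, is_target —
    one row per intensification, ordered by level then stream index.
    """

    channel_labels: tuple[str, ...]
    fs_hz: float
    samples: np.ndarray           # channels x time, microvolts
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples row count must match channel labels")
        if len(self.events):
            smp = self.events["sample"].to_numpy()
            if smp.min() < 0 or smp.max() >= self.samples.shape[1]:
                raise ValueError("event sample indices outside recording")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def component_waveform(spec: ComponentSpec, fs: float) -> tuple[int, np.ndarray]:
    """Single-channel kernel for one component.

    Returns ``(offset, kernel)`` where *offset* is the kernel's first sample
    relative to the event onset sample. The kernel is a Gaussian of FWHM
    ``width_ms`` centered at ``peak_latency_ms``, truncated at +-3 sigma.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    sigma_ms = spec.width_ms / _FWHM
    start_ms = spec.peak_latency_ms - 3.0 * sigma_ms
    stop_ms = spec.peak_latency_ms + 3.0 * sigma_ms
    offset = int(round(start_ms * fs / 1000.0))
    n = int(round((stop_ms - start_ms) * fs / 1000.0)) + 1
    t_ms = (offset + np.arange(n)) * 1000.0 / fs
    kernel = (
        spec.polarity
        * spec.base_amplitude_uV
        * np.exp(-((t_ms - spec.peak_latency_ms) ** 2) / (2.0 * sigma_ms**2))
    )
    return offset, kernel


def generate_noise(
    n_channels: int,
    n_samples: int,
    model: NoiseModel,
    rng: np.random.Generator | int = 0,
    fs: float = 1000.0,
    channels: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Colored, spatially correlated noise scaled to the model's rms.

    Per channel, white Gaussian noise is shaped to a 1/f^alpha amplitude
    spectrum (unit variance preserved), then channels are mixed with a
    row-normalized Gaussian spatial kernel over the schematic montage
    positions, and finally scaled so each channel has expected rms
    ``model.rms_uV``.
    """
    if n_channels <= 0 or n_samples <= 0:
        raise ValueError("n_channels and n_samples must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if model.rms_uV == 0.0:
        return np.zeros((n_channels, n_samples))

    white = rng.standard_normal((n_channels, n_samples))
    if model.spectral_exponent > 0:
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        shape = np.zeros_like(freqs)
        shape[1:] = freqs[1:] ** (-model.spectral_exponent / 2.0)
        # Preserve unit time-domain variance under the shaping filter.
        shape /= np.sqrt(np.mean(shape[1:] ** 2))
        colored = np.fft.irfft(np.fft.rfft(white, axis=1) * shape, n=n_samples,
                               axis=1)
    else:
        colored = white

    if model.channel_mixing > 0:
        if channels is None:
            channels = CHANNELS_64[:n_channels]
        pos = channel_positions(channels)
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        lam = 0.3 / (1.0 - model.channel_mixing)
        mix = np.exp(-d2 / (2.0 * lam**2))
        mix /= np.linalg.norm(mix, axis=1, keepdims=True)  # keep variance
        colored = mix @ colored
    return model.rms_uV * colored


def synthesize_recording(
    schedule: TrialSchedule,
    components: tuple[ComponentSpec, ...] | None = None,
    modulation: ModulationProfile | None = None,
    noise: NoiseModel | None = None,
    fs: float = 1000.0,
    seed: int = 0,
    channels: tuple[str, ...] = CHANNELS_64,
    pad_s: float = 1.0,
    level_gap_s: float = 2.0,
) -> Recording:
    """Render a trial schedule into a continuous recording.

    Every event adds each component's kernel (outer product with its
    topography) at the event's onset; target events are additionally scaled
    by the modulation profile's per-component gain. Hex-o-Spell levels are
    laid out sequentially with ``level_gap_s`` of silence between the
    streams. Noise is added last. Fully reproducible from *seed* (the
    schedule carries its own seed; this one drives only the noise).
    """
    if schedule.n_events == 0:
        raise ValueError("schedule has no events")
    components = default_components(channels) if components is None else components
    modulation = modulation or ModulationProfile("none", schedule.layout.kind, {})
    noise = noise or NoiseModel()
    for spec in components:
        if len(spec.topography) != len(channels):
            raise ValueError("component topography length != channel count")

    soa_samp = schedule.timing.soa_ms * fs / 1000.0
    pad = int(round(pad_s * fs))
    gap = int(round(level_gap_s * fs))

    # Absolute onset sample per event, levels laid out back to back.
    onset_rows = []
    cursor = pad
    kernels = [component_waveform(spec, fs) for spec in components]
    tail = max(off + len(k) for off, k in kernels)
    for lvl in schedule.levels:
        for ev in schedule.events[lvl]:
            onset_rows.append(
                (cursor + int(round(ev.index * soa_samp)), ev.index, lvl,
                 ev.phase, ev.element_id, ev.is_target)
            )
        cursor = onset_rows[-1][0] + tail + gap
    n_samples = onset_rows[-1][0] + tail + pad

    data = np.zeros((len(channels), n_samples))
    for onset, _idx, _lvl, _ph, _eid, is_target in onset_rows:
        for spec, (off, kernel) in zip(components, kernels):
            amp = modulation.gain(spec.name) if is_target else 1.0
            lo = onset + off
            data[:, lo:lo + len(kernel)] += (
                amp * spec.topography[:, None] * kernel[None, :]
            )

    data += generate_noise(
        len(channels), n_samples, noise, rng=np.random.default_rng(seed),
        fs=fs, channels=channels,
    )
    events = pd.DataFrame(
        onset_rows,
        columns=["sample", "index", "level", "phase", "element_id",
                 "is_target"],
    )
    return Recording(
        channel_labels=tuple(channels), fs_hz=fs, samples=data, events=events
    )


def with_amplitudes(
    components: tuple[ComponentSpec, ...], **amplitudes: float
) -> tuple[ComponentSpec, ...]:
    """Copy of *components* with selected base amplitudes replaced.

    ``with_amplitudes(specs, P3=5.0, P1=0.0)`` — setting an amplitude to 0
    removes that component from the simulation, which is how single-source
    presets (e.g. a P3-only generator) are expressed.
    """
    out = []
    for spec in components:
        if spec.name in amplitudes:
            out.append(replace(spec, base_amplitude_uV=amplitudes[spec.name]))
        else:
            out.append(spec)
    return tuple(out)
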
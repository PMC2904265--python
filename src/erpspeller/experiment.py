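"""End-to-end simulated copy-spelling experiment.

The design follows the standard offline copy-spelling protocol: for each
attention mode
(overt, covert) and each speller (Matrix, Hex-o-Spell), three blocks of
copy-spelled words are simulated; the first block trains a single binary
target/nontarget classifier and the remaining blocks are decoded at every
sequence count from 1 to the scheduled maximum. The ERP path runs in
parallel on 250 Hz epochs with the contamination filters applied; the
classification path uses all epochs at 100 Hz.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import classification as clf
from . import erp as erp_mod
from . import preprocessing as prep
from .montage import CHANNELS_55, CHANNELS_64
from .paradigm import (
    SpellerLayout, TimingParams, TrialSchedule, build_layout,
    generate_trial_schedule,
)
from .synth import (
    ComponentSpec, ModulationProfile, NoiseModel, default_components,
    synthesize_recording,
)

log = logging.getLogger("erpspeller")


@dataclass(frozen=True)
class PipelineParams:
    """Analysis-side parameters (sampling targets, features, shrinkage)."""

    erp_fs: float = 250.0
    clf_fs: float = 100.0
    n_temporal_windows: int = 7
    window_width_ms: float = 40.0
    min_separation_ms: float = 50.0
    channels: tuple[str, ...] = CHANNELS_55
    gamma: float | str = "auto"


@dataclass(frozen=True)
class GeneratorParams:
    """Signal-side parameters of the synthetic recordings."""

    fs: float = 1000.0
    channels: tuple[str, ...] = CHANNELS_64
    noise: NoiseModel = field(default_factory=NoiseModel)
    components: tuple[ComponentSpec, ...] | None = None   # None = defaults

    def resolved_components(self) -> tuple[ComponentSpec, ...]:
        if self.components is not None:
            return self.components
        return default_components(self.channels)


@dataclass(frozen=True)
class ExperimentConfig:
    spellers: tuple[str, ...] = ("matrix", "hex")
    attentions: tuple[str, ...] = ("overt", "covert")
    n_blocks: int = 3
    words_per_block: int = 3
    word_length: int = 5
    train_blocks: tuple[int, ...] = (0,)
    timing: TimingParams = field(default_factory=TimingParams)
    pipeline: PipelineParams = field(default_factory=PipelineParams)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    run_erp: bool = True
    seed: int = 0


@dataclass
class ConditionResult:
    speller: str
    attention: str
    decoding: clf.DecodingResult
    model: clf.LDAModel
    feature_spec: clf.FeatureSpec
    erp_table: pd.DataFrame | None
    n_train_epochs: int
    n_test_trials: int


@dataclass
class ResultsBundle:
    config: ExperimentConfig
    conditions: dict[tuple[str, str], ConditionResult]
    provenance: dict

    def accuracy_frame(self) -> pd.DataFrame:
        rows = []
        for (speller, attention), res in self.conditions.items():
            for n, acc in zip(res.decoding.n_sequences,
                              res.decoding.accuracy_curve):
                rows.append((speller, attention, int(n), float(acc)))
        return pd.DataFrame(
            rows, columns=["speller", "attention", "n_sequences", "accuracy"]
        )


def _draw_words(
    rng: np.random.Generator, layout: SpellerLayout, n_words: int, length: int
) -> list[str]:
    """Copy-spelling word targets: random draws from the letter vocabulary."""
    letters = [s for s in layout.symbols if s.isalpha()]
    return [
        "".join(rng.choice(letters, size=length)) for _ in range(n_words)
    ]


@dataclass
class SimulatedTrial:
    block: int
    target: str
    schedule: TrialSchedule
    clf_epochs: prep.EpochSet
    erp_epochs: prep.EpochSet | None


def simulate_trial(
    layout: SpellerLayout,
    target: str,
    modulation: ModulationProfile,
    config: ExperimentConfig,
    seed: int,
    block: int = 0,
    keep_erp: bool = True,
) -> SimulatedTrial:
    """Simulate one copy-spelling trial and epoch it along both paths."""
    gen = config.generator
    schedule = generate_trial_schedule(layout, target, config.timing, seed=seed)
    rec = synthesize_recording(
        schedule,
        components=gen.resolved_components(),
        modulation=modulation,
        noise=gen.noise,
        fs=gen.fs,
        seed=seed + 1,
        channels=gen.channels,
    )
    clf_epochs = prep.extract_epochs(prep.resample(rec, config.pipeline.clf_fs))
    erp_epochs = None
    if keep_erp:
        erp_epochs = prep.apply_erp_filters(
            prep.extract_epochs(prep.resample(rec, config.pipeline.erp_fs))
        )
    return SimulatedTrial(
        block=block, target=target, schedule=schedule,
        clf_epochs=clf_epochs, erp_epochs=erp_epochs,
    )


def _concat_epochs(sets: list[prep.EpochSet]) -> prep.EpochSet:
    """Stack epoch sets that share a time axis and montage."""
    first = sets[0]
    metas = []
    for t, es in enumerate(sets):
        m = es.meta.copy()
        if "trial" not in m.columns:
            m["trial"] = t
        metas.append(m)
    return prep.EpochSet(
        data=np.concatenate([es.data for es in sets]),
        times_ms=first.times_ms,
        channels=first.channels,
        labels=np.concatenate([es.labels for es in sets]),
        kept=np.concatenate([es.kept for es in sets]),
        reasons=np.concatenate([es.reasons for es in sets]),
        meta=pd.concat(metas, ignore_index=True),
        fs_hz=first.fs_hz,
    )


def run_condition(
    speller: str,
    attention: str,
    config: ExperimentConfig,
    seed: int,
) -> ConditionResult:
    """Simulate, train, and decode one attention x speller condition."""
    t0 = time.perf_counter()
    layout = build_layout(speller)
    modulation = ModulationProfile.preset(attention, speller)
    rng = np.random.default_rng(seed)
    pipe = config.pipeline

    trials: list[SimulatedTrial] = []
    for block in range(config.n_blocks):
        words = _draw_words(rng, layout, config.words_per_block,
                            config.word_length)
        for word in words:
            for letter in word:
                trial_seed = int(rng.integers(0, 2**31 - 1))
                trials.append(simulate_trial(
                    layout, letter, modulation, config, trial_seed,
                    block=block, keep_erp=config.run_erp,
                ))

    train = [t for t in trials if t.block in config.train_blocks]
    test = [t for t in trials if t.block not in config.train_blocks]
    if not train or not test:
        raise ValueError("both training and test blocks are required")

    # Temporal feature placement from the training block's discriminability.
    train_epochs = _concat_epochs([t.clf_epochs for t in train])
    ch_idx = [train_epochs.channels.index(c) for c in pipe.channels]
    r_map = clf.point_biserial(
        train_epochs.data[:, ch_idx, :], train_epochs.labels
    )
    windows = clf.select_temporal_windows(
        r_map, train_epochs.times_ms,
        k=pipe.n_temporal_windows, width_ms=pipe.window_width_ms,
        min_separation_ms=pipe.min_separation_ms,
    )
    spec = clf.FeatureSpec(channels=tuple(pipe.channels), windows=windows)

    X_train, y_train = clf.build_features(train_epochs, spec)
    model = clf.train_shrinkage_lda(X_train, y_train, gamma=pipe.gamma,
                                    feature_spec=spec)

    decode_trials = []
    for t in test:
        X, _ = clf.build_features(t.clf_epochs, spec)
        outputs = clf.score(model, X)
        decode_trials.append((t.target, outputs, t.schedule))
    decoding = clf.accuracy_curve(
        decode_trials, max_sequences=config.timing.n_sequences,
        condition=(speller, attention),
    )

    erp_table = None
    if config.run_erp:
        erp_all = _concat_epochs([t.erp_epochs for t in trials])
        erp_table = erp_mod.component_table(
            erp_all, condition=(speller, attention)
        )

    log.info(
        "condition %s/%s: %d trials, %d train epochs, %.1f s",
        speller, attention, len(trials), len(train_epochs),
        time.perf_counter() - t0,
    )
    return ConditionResult(
        speller=speller,
        attention=attention,
        decoding=decoding,
        model=model,
        feature_spec=spec,
        erp_table=erp_table,
        n_train_epochs=len(train_epochs),
        n_test_trials=len(test),
    )


def run_experiment(config: ExperimentConfig | None = None) -> ResultsBundle:
    """Run every configured attention x speller condition.

    Per-condition seeds are derived deterministically from ``config.seed``
    so conditions are independently reproducible.
    """
    config = config or ExperimentConfig()
    conditions: dict[tuple[str, str], ConditionResult] = {}
    ss = np.random.SeedSequence(config.seed)
    keys = [(sp, at) for sp in config.spellers for at in config.attentions]
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(len(keys))]
    for (speller, attention), cseed in zip(keys, child_seeds):
        conditions[(speller, attention)] = run_condition(
            speller, attention, config, cseed
        )
    provenance = {
        "seed": config.seed,
        "condition_seeds": dict(zip([f"{s}/{a}" for s, a in keys],
                                    child_seeds)),
        "config": json.loads(json.dumps(_config_dict(config), default=str)),
    }
    return ResultsBundle(config=config, conditions=conditions,
                         provenance=provenance)


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    gen = d.get("generator", {})
    comps = gen.get("components")
    if comps is not None:
        for c in comps:
            c["topography"] = list(np.asarray(c["topography"], dtype=float))
    return d
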
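"""Speller layouts and constrained oddball stimulus schedules.

Two visual spellers are modeled. The Matrix arranges 30 symbols in 6 rows
by 5 columns; a symbol is selected as the intersection of the row and the
column with the strongest evidence. The Hex-o-Spell is a two-level speller
of six discs on an invisible hexagon: level 1 selects a five-symbol group,
level 2 one symbol out of the group's five plus an empty "backdoor" disc
that would return to the group level.

A trial presents `n_sequences` randomized intensification sequences per
level, framed by a prequel and a sequel (one sequence-length each, uniform
draws with repeats, not analyzed). Within the core, every group is
intensified exactly once per sequence and two occurrences of the same group
are separated by at least `min_gap` other intensifications, including
across sequence boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel returned when the Hex-o-Spell empty disc wins the symbol level.
BACKDOOR = "<backdoor>"

#: 30-symbol vocabulary: the English alphabet plus four punctuation marks.
VOCABULARY: tuple[str, ...] = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ") + (
    ".", ",", "!", "?",
)

PHASES = ("prequel", "core", "sequel")


@dataclass(frozen=True)
class DisplayGeometry:
    """Flat screen viewed centrally; square pixels assumed."""

    width_px: int = 1280
    height_px: int = 1024
    diagonal_inch: float = 19.0
    viewing_distance_cm: float = 60.0
    refresh_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "diagonal_inch",
                     "viewing_distance_cm", "refresh_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pixel_pitch_cm(self) -> float:
        diag_px = math.hypot(self.width_px, self.height_px)
        return self.diagonal_inch * 2.54 / diag_px


@dataclass(frozen=True)
class TimingParams:
    """Stimulus timing; SOA is onset-to-onset time between intensifications."""

    soa_ms: float = 166.0
    intensification_ms: float = 100.0
    n_sequences: int = 10
    countdown_s: float = 4.0

    def __post_init__(self) -> None:
        if not self.intensification_ms < self.soa_ms:
            raise ValueError("intensification_ms must be shorter than soa_ms")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")


@dataclass(frozen=True)
class Element:
    element_id: int
    center_px: tuple[float, float]
    base_size_px: float
    intensified_size_px: float
    symbols: tuple[str, ...]


@dataclass(frozen=True)
class SpellerLayout:
    kind: str
    elements: tuple[Element, ...]
    selection_groups: dict[int, tuple[tuple[str, ...], ...]]
    n_levels: int
    symbols: tuple[str, ...]
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)

    def groups(self, level: int) -> tuple[tuple[str, ...], ...]:
        return self.selection_groups[level]

    def n_groups(self, level: int) -> int:
        return len(self.selection_groups[level])

    def target_group_ids(self, level: int, target: str) -> tuple[int, ...]:
        """Ids of the level's groups whose intensification includes *target*.

        Level 2 of the Hex-o-Spell is resolved under copy-spelling ground
        truth (the correct group was selected at level 1): the six discs
        carry the target's group symbols in order plus the empty disc, and
        only the disc holding the target itself is a target.
        """
        if target not in self.symbols:
            raise ValueError(f"target {target!r} not in layout vocabulary")
        if self.kind == "hex" and level == 2:
            group = next(g for g in self.selection_groups[1] if target in g)
            return (group.index(target),)
        return tuple(
            gid for gid, g in enumerate(self.selection_groups[level])
            if target in g
        )


def build_layout(
    kind: str,
    geometry: DisplayGeometry | None = None,
    *,
    symbols: tuple[str, ...] = VOCABULARY,
    matrix_grid_px: float = 500.0,
    matrix_base_px: float = 40.0,
    matrix_intensified_px: float = 65.0,
    hex_diameter_px: float = 440.0,
    hex_base_px: float = 148.0,
    hex_intensified_px: float = 200.0,
) -> SpellerLayout:
    """Construct a speller layout with default on-screen pixel sizes.

    Pixel sizes scale with horizontal resolution relative to the default
    1280-px-wide display; group topology never depends on geometry.
    """
    geometry = geometry or DisplayGeometry()
    if len(symbols) != 30:
        raise ValueError("layouts are defined over a 30-symbol vocabulary")
    scale = geometry.width_px / 1280.0
    cx, cy = geometry.width_px / 2.0, geometry.height_px / 2.0

    if kind == "matrix":
        grid = matrix_grid_px * scale
        elements = []
        for i, sym in enumerate(symbols):
            r, c = divmod(i, 5)
            elements.append(Element(
                element_id=i,
                center_px=(cx + (c - 2.0) * grid / 5.0,
                           cy + (r - 2.5) * grid / 6.0),
                base_size_px=matrix_base_px * scale,
                intensified_size_px=matrix_intensified_px * scale,
                symbols=(sym,),
            ))
        rows = tuple(tuple(symbols[5 * r:5 * r + 5]) for r in range(6))
        cols = tuple(tuple(symbols[c::5]) for c in range(5))
        return SpellerLayout(
            kind="matrix",
            elements=tuple(elements),
            selection_groups={1: rows + cols},
            n_levels=1,
            symbols=tuple(symbols),
            geometry=geometry,
        )

    if kind == "hex":
        radius = hex_diameter_px * scale / 2.0
        groups = tuple(tuple(symbols[5 * g:5 * g + 5]) for g in range(6))
        elements = tuple(
            Element(
                element_id=g,
                center_px=(cx + radius * math.sin(g * math.pi / 3.0),
                           cy - radius * math.cos(g * math.pi / 3.0)),
                base_size_px=hex_base_px * scale,
                intensified_size_px=hex_intensified_px * scale,
                symbols=groups[g],
            )
            for g in range(6)
        )
        return SpellerLayout(
            kind="hex",
            elements=elements,
            # Level 2 groups are the target group's symbols plus the empty
            # backdoor disc; resolved per trial, represented generically here.
            selection_groups={1: groups, 2: tuple(
                (f"<disc {d}>",) for d in range(6))},
            n_levels=2,
            symbols=tuple(symbols),
            geometry=geometry,
        )

    raise ValueError(f"unknown speller kind {kind!r}; expected 'matrix' or 'hex'")


def px_to_degrees(extent_px: float, geometry: DisplayGeometry | None = None) -> float:
    """Visual angle in degrees subtended by *extent_px* pixels."""
    geometry = geometry or DisplayGeometry()
    if extent_px <= 0:
        raise ValueError("extent_px must be positive")
    extent_cm = extent_px * geometry.pixel_pitch_cm
    return math.degrees(
        2.0 * math.atan(extent_cm / (2.0 * geometry.viewing_distance_cm))
    )


def intensification_increase(base_px: float, intensified_px: float) -> float:
    """Relative size increase upon intensification, in percent."""
    if base_px <= 0:
        raise ValueError("base_px must be positive")
    return round(100.0 * (intensified_px - base_px) / base_px, 1)


def generate_core_block(
    n_elements: int,
    n_sequences: int,
    min_gap: int = 2,
    seed: int | np.random.Generator = 0,
    max_retries: int = 10_000,
) -> np.ndarray:
    """Concatenated randomized sequences with a global repeat constraint.

    Each sequence is a permutation of ``0..n_elements-1``; across the whole
    block any two occurrences of the same element are separated by at least
    *min_gap* other events. Sequences are drawn by rejection: a candidate
    permutation is resampled until its head is compatible with the tail of
    the block so far.
    """
    if n_elements <= min_gap:
        raise ValueError(
            f"infeasible: n_elements={n_elements} must exceed min_gap={min_gap}"
        )
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    block: list[np.ndarray] = [rng.permutation(n_elements)]
    for _ in range(1, n_sequences):
        tail = block[-1][-min_gap:]
        for attempt in range(max_retries):
            cand = rng.permutation(n_elements)
            # Element at tail position -j (j=1..min_gap) must not reappear
            # within the first min_gap - j + 1 positions of the candidate.
            ok = all(
                tail[-j] not in cand[: min_gap - j + 1]
                for j in range(1, min_gap + 1)
            )
            if ok:
                block.append(cand)
                break
        else:
            raise RuntimeError(
                f"core-block generation exhausted {max_retries} retries "
                f"(n_elements={n_elements}, min_gap={min_gap})"
            )
    return np.concatenate(block)


@dataclass(frozen=True)
class IntensificationEvent:
    index: int          # ordinal within the level's event stream
    onset_ms: float
    element_id: int     # group id at this level
    phase: str          # prequel | core | sequel
    level: int
    is_target: bool


@dataclass(frozen=True)
class TrialSchedule:
    layout: SpellerLayout
    target_symbol: str
    timing: TimingParams
    events: dict[int, tuple[IntensificationEvent, ...]]
    rng_seed: int

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(sorted(self.events))

    @property
    def n_events(self) -> int:
        return sum(len(ev) for ev in self.events.values())

    def to_frame(self) -> pd.DataFrame:
        """Flat event table ordered by level then stream index."""
        rows = [
            (ev.index, ev.onset_ms, ev.level, ev.phase, ev.element_id,
             ev.is_target)
            for lvl in self.levels for ev in self.events[lvl]
        ]
        return pd.DataFrame(
            rows,
            columns=["index", "onset_ms", "level", "phase", "element_id",
                     "is_target"],
        )


def generate_trial_schedule(
    layout: SpellerLayout,
    target_symbol: str,
    timing: TimingParams | None = None,
    seed: int = 0,
) -> TrialSchedule:
    """Full per-level event streams: prequel, constrained core, sequel.

    Prequel and sequel are one sequence-length of unconstrained uniform
    draws (repeats allowed); the core satisfies the min-gap constraint and
    intensifies every group exactly once per sequence. Onsets advance by one
    SOA per event within a level's stream.
    """
    timing = timing or TimingParams()
    if target_symbol not in layout.symbols:
        raise ValueError(f"target {target_symbol!r} not in layout vocabulary")
    rng = np.random.default_rng(seed)
    events: dict[int, tuple[IntensificationEvent, ...]] = {}
    for level in range(1, layout.n_levels + 1):
        n_groups = layout.n_groups(level)
        target_ids = set(layout.target_group_ids(level, target_symbol))
        prequel = rng.integers(0, n_groups, size=n_groups)
        core = generate_core_block(
            n_groups, timing.n_sequences, min_gap=2, seed=rng
        )
        sequel = rng.integers(0, n_groups, size=n_groups)
        stream = np.concatenate([prequel, core, sequel])
        phases = (
            ["prequel"] * len(prequel)
            + ["core"] * len(core)
            + ["sequel"] * len(sequel)
        )
        events[level] = tuple(
            IntensificationEvent(
                index=i,
                onset_ms=i * timing.soa_ms,
                element_id=int(eid),
                phase=ph,
                level=level,
                is_target=int(eid) in target_ids,
            )
            for i, (eid, ph) in enumerate(zip(stream, phases))
        )
    return TrialSchedule(
        layout=layout,
        target_symbol=target_symbol,
        timing=timing,
        events=events,
        rng_seed=seed,
    )


def count_target_intensifications(
    schedule: TrialSchedule, phases: set[str] | None = None
) -> int:
    """Number of target intensifications within the given phases.

    With all phases this is the participant's counting-task ground truth;
    restricted to the core it is deterministic (2 per sequence for the
    Matrix row+column; 1 per sequence per Hex-o-Spell level).
    """
    phases = set(PHASES) if phases is None else set(phases)
    unknown = phases - set(PHASES)
    if unknown:
        raise ValueError(f"unknown phases: {sorted(unknown)}")
    return sum(
        ev.is_target
        for lvl in schedule.levels
        for ev in schedule.events[lvl]
        if ev.phase in phases
    )


def decode_selection(
    layout: SpellerLayout, selected_groups: tuple[int, ...]
) -> str:
    """Map per-level winning group ids to a symbol.

    Matrix: (row id in 0..5, column id in 6..10) -> their intersection.
    Hex: (group id in 0..5, disc id in 0..5) -> the disc's symbol within the
    group, or :data:`BACKDOOR` when the empty disc (id 5) wins.
    """
    if layout.kind == "matrix":
        row_id, col_id = selected_groups
        if not (0 <= row_id <= 5):
            raise ValueError(f"row id {row_id} outside 0..5")
        if not (6 <= col_id <= 10):
            raise ValueError(f"column id {col_id} outside 6..10")
        groups = layout.selection_groups[1]
        common = set(groups[row_id]) & set(groups[col_id])
        (symbol,) = common
        return symbol
    if layout.kind == "hex":
        group_id, disc_id = selected_groups
        if not (0 <= group_id <= 5):
            raise ValueError(f"group id {group_id} outside 0..5")
        if not (0 <= disc_id <= 5):
            raise ValueError(f"disc id {disc_id} outside 0..5")
        if disc_id == 5:
            return BACKDOOR
        return layout.selection_groups[1][group_id][disc_id]
    raise ValueError(f"unknown layout kind {layout.kind!r}")


def chance_level(layout: SpellerLayout) -> float:
    """Probability of selecting the correct symbol by uniform guessing.

    One independent uniform choice per decision stage: 1/6 x 1/5 = 1/30 for
    the Matrix (row and column), 1/6 x 1/6 = 1/36 for the Hex-o-Spell.
    """
    if layout.kind == "matrix":
        return (1.0 / 6.0) * (1.0 / 5.0)
    if layout.kind == "hex":
        p = 1.0
        for level in range(1, layout.n_levels + 1):
            p /= layout.n_groups(level)
        return p
    # Degenerate/custom layouts: product of per-level uniform probabilities.
    p = 1.0
    for level in layout.selection_groups:
        p /= len(layout.selection_groups[level])
    return p


def scale_layout(layout: SpellerLayout, geometry: DisplayGeometry) -> SpellerLayout:
    """Rebuild *layout* for a different display geometry (same topology)."""
    return build_layout(layout.kind, geometry, symbols=layout.symbols)
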
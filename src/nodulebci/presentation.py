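"""CT-image display preparation: window/level mapping, the three display
modes, a hexagonal coarse-to-fine search path over image tiles, and oddball
presentation-plan scheduling.

16-bit CT data cannot be shown on an 8-bit display in one frame; a window
mapping linearly maps the intensity interval [level - width/2,
level + width/2] to [0, 255] with clamping outside.  Mode 1 derives the
window from the frame's own statistics, Mode 2 uses the fixed radiological
lung window, and Mode 3 shows the lung window plus two frames with the
level floated down and up, so nodules near either end of the window remain
visible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "WindowMapping",
    "PlanEntry",
    "PresentationPlan",
    "window_map",
    "mode1_frames",
    "mode2_frames",
    "mode3_frames",
    "hexagon_path",
    "build_presentation_plan",
    "LUNG_WINDOW",
]


@dataclass(frozen=True)
class WindowMapping:
    """Linear display window: center (level) and total width, intensity units."""

    level: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("window width must be positive")


#: Standard radiological lung window on the Hounsfield scale.
LUNG_WINDOW = WindowMapping(level=-600.0, width=1500.0)


def window_map(image: np.ndarray, mapping: WindowMapping) -> np.ndarray:
    """Map 16-bit intensities to 8-bit through the window, clamped outside.

    Rounding is half-up, so a pixel exactly at the level maps to 128.
    The map is monotone non-decreasing in the input intensity.
    """
    img = np.asarray(image, dtype=float)
    lo = mapping.level - mapping.width / 2.0
    scaled = (img - lo) / mapping.width * 255.0
    out = np.floor(scaled + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def mode1_frames(
    image: np.ndarray,
    width_sigmas: float = 4.0,
    width_floor: float = 1.0,
) -> list[np.ndarray]:
    """Mode 1: one frame windowed on the image's own mean and spread.

    level = image mean; width = ``width_sigmas`` standard deviations (a
    zero-variance image falls back to ``width_floor`` so the mapping stays
    defined and renders uniform mid-gray).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValidationError("empty image")
    width = max(width_sigmas * float(img.std()), width_floor)
    return [window_map(img, WindowMapping(level=float(img.mean()), width=width))]


def mode2_frames(
    image: np.ndarray,
    mapping: WindowMapping = LUNG_WINDOW,
    intercept: float = 0.0,
) -> list[np.ndarray]:
    """Mode 2: one frame through the fixed lung window.

    ``intercept`` converts raw unsigned stacks to the Hounsfield scale
    (HU = raw + intercept); leave at 0 when the image is already in HU.
    """
    img = np.asarray(image, dtype=float) + intercept
    return [window_map(img, mapping)]


def mode3_frames(
    image: np.ndarray,
    float_offset: float = 200.0,
    mapping: WindowMapping = LUNG_WINDOW,
    intercept: float = 0.0,
) -> list[np.ndarray]:
    """Mode 3: lung-window frame plus level-floated companions.

    Frame order: [lung window, level - offset, level + offset].  Lowering
    the level brightens every pixel, so the frames are pixelwise ordered:
    lowered-level >= lung-window >= raised-level.
    """
    if float_offset < 0:
        raise ValidationError("float_offset must be >= 0")
    img = np.asarray(image, dtype=float) + intercept
    down = WindowMapping(level=mapping.level - float_offset, width=mapping.width)
    up = WindowMapping(level=mapping.level + float_offset, width=mapping.width)
    return [window_map(img, mapping), window_map(img, down), window_map(img, up)]


# ---------------------------------------------------------------------------
# Hexagonal search path
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tile:
    tile_id: int
    row: int
    col: int
    y0: int
    x0: int
    y1: int
    x1: int


def _hex_ring_and_angle(row: int, col: int, r0: int, c0: int) -> tuple[int, float]:
    """Hexagonal ring index and angular position of a grid tile.

    The rectangular tile grid is read as odd-row-offset hexagonal axial
    coordinates relative to the center tile; the ring is the hex distance
    and the angle orders tiles within a ring.
    """
    def to_axial(r: int, c: int) -> tuple[int, int]:
        q = c - (r - (r & 1)) // 2
        return q, r

    q1, r1 = to_axial(row, col)
    q0, rr0 = to_axial(r0, c0)
    dq, dr = q1 - q0, r1 - rr0
    ring = (abs(dq) + abs(dr) + abs(dq + dr)) // 2
    # axial -> cartesian for the angular ordering
    x = dq + dr / 2.0
    y = dr * math.sqrt(3.0) / 2.0
    return ring, math.atan2(y, x) % (2.0 * math.pi)


def hexagon_path(
    image_shape: tuple[int, int], tile_size: int
) -> list[Tile]:
    """Coarse-to-fine traversal of the tile grid on a hexagonal tiling.

    Tiles are grouped into concentric hexagonal rings around the central
    tile and visited outside-in ("from the largest hexagon to the
    smallest"), each ring in a fixed angular order.  Every tile appears
    exactly once and the traversal is deterministic.

    This is a documented stand-in traversal with the stated locality
    property (consecutive steps stay within a ring or move one ring
    inward); it is not a reconstruction of any published hexagon-path
    algorithm.
    """
    h, w = image_shape
    if tile_size < 1:
        raise ValidationError("tile_size must be >= 1")
    n_rows = max(1, math.ceil(h / tile_size))
    n_cols = max(1, math.ceil(w / tile_size))
    r0, c0 = n_rows // 2, n_cols // 2
    entries = []
    for r in range(n_rows):
        for c in range(n_cols):
            ring, ang = _hex_ring_and_angle(r, c, r0, c0)
            entries.append((ring, ang, r, c))
    entries.sort(key=lambda e: (-e[0], e[1], e[2], e[3]))
    tiles = []
    for tid, (_, _, r, c) in enumerate(entries):
        tiles.append(Tile(
            tile_id=tid, row=r, col=c,
            y0=r * tile_size, x0=c * tile_size,
            y1=min(h, (r + 1) * tile_size), x1=min(w, (c + 1) * tile_size),
        ))
    return tiles


# ---------------------------------------------------------------------------
# Oddball presentation plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanEntry:
    tile_id: int
    n_frames: int
    onset_ms: float
    duration_ms: float
    is_target: bool


@dataclass
class PresentationPlan:
    entries: list[PlanEntry] = field(default_factory=list)

    @property
    def duration_ms(self) -> float:
        if not self.entries:
            return 0.0
        last = self.entries[-1]
        return last.onset_ms + last.duration_ms

    @property
    def n_targets(self) -> int:
        return sum(e.is_target for e in self.entries)


def build_presentation_plan(
    tile_ids: list[int],
    target_flags: list[bool],
    mode: str = "mode3",
    duration_ms: float = 200.0,
    ratio: float = 1.0 / 6.0,
    repetitions: int = 13,
    seed: int = 0,
) -> PresentationPlan:
    """Schedule an oddball presentation of tiles at the configured ratio.

    Every selected tile repeats exactly ``repetitions`` times at a constant
    ``duration_ms`` onset spacing.  All target tiles are used; enough
    non-target tiles are drawn (seeded) to honour the target fraction
    exactly.  When the ratio is at most 1/3, targets are interleaved so no
    two target presentations are adjacent (oddball convention).
    """
    if len(tile_ids) != len(target_flags):
        raise ValidationError("tile_ids and target_flags must be parallel")
    if not (0.0 < ratio < 1.0):
        raise ValidationError("ratio must lie in (0, 1)")
    if repetitions < 1 or duration_ms <= 0:
        raise ValidationError("repetitions >= 1 and duration_ms > 0 required")
    if mode not in {"mode1", "mode2", "mode3"}:
        raise ValidationError(f"unknown mode {mode!r}")
    n_frames = 3 if mode == "mode3" else 1

    targets = [t for t, f in zip(tile_ids, target_flags) if f]
    backgrounds = [t for t, f in zip(tile_ids, target_flags) if not f]
    if not targets:
        raise ValidationError("need at least one target tile")
    n_bg_needed = int(round(len(targets) * (1.0 - ratio) / ratio))
    if len(backgrounds) < n_bg_needed:
        raise ValidationError(
            f"need {n_bg_needed} background tiles for ratio {ratio}, "
            f"have {len(backgrounds)}"
        )
    rng = np.random.default_rng(seed)
    bg_sel = list(rng.choice(backgrounds, size=n_bg_needed, replace=False)) \
        if n_bg_needed else []

    bg_events = [int(t) for t in bg_sel for _ in range(repetitions)]
    tg_events = [int(t) for t in targets for _ in range(repetitions)]
    rng.shuffle(bg_events)
    rng.shuffle(tg_events)

    if ratio <= 1.0 / 3.0 and bg_events:
        # insert each target event into a distinct gap between backgrounds
        n_gaps = len(bg_events) + 1
        if len(tg_events) > n_gaps:
            raise ValidationError("cannot interleave targets without adjacency")
        gaps = sorted(rng.choice(n_gaps, size=len(tg_events), replace=False))
        seq: list[tuple[int, bool]] = []
        ti = 0
        for g in range(n_gaps):
            if ti < len(gaps) and gaps[ti] == g:
                seq.append((tg_events[ti], True))
                ti += 1
            if g < len(bg_events):
                seq.append((bg_events[g], False))
    else:
        mixed = [(t, True) for t in tg_events] + [(t, False) for t in bg_events]
        order = rng.permutation(len(mixed))
        seq = [mixed[i] for i in order]

    entries = [
        PlanEntry(tile_id=tid, n_frames=n_frames, onset_ms=i * duration_ms,
                  duration_ms=duration_ms, is_target=flag)
        for i, (tid, flag) in enumerate(seq)
    ]
    return PresentationPlan(entries=entries)
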
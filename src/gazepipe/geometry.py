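"""Screen geometry primitives: AOI rectangles, trial layouts, gaze hit-testing.

Coordinates are screen pixels with the origin at the top-left corner and y
increasing downward.  AOI rectangles are half-open, ``[x_min, x_max) x
[y_min, y_max)``, so a point lying exactly on the right or bottom edge of a
rectangle is *outside* it; this makes hit-testing deterministic and lets
adjacent rectangles tile the screen without double assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AOI",
    "TrialLayout",
    "assign_aoi",
    "assign_aoi_array",
    "side_by_side_aois",
    "quadrant_aois",
    "DEFAULT_SCREEN_W",
    "DEFAULT_SCREEN_H",
]

DEFAULT_SCREEN_W = 1280
DEFAULT_SCREEN_H = 720

#: stimulus footprints (w, h) in px and the inner-edge spacing used by the
#: side-by-side displays
CASCADE_IMAGE_PX = (173, 173)
NOVELTY_IMAGE_PX = (472, 331)
VWP_IMAGE_PX = (265, 189)
SIDE_BY_SIDE_GAP_PX = 295


@dataclass(frozen=True)
class AOI:
    """A labelled half-open screen rectangle used as an area of interest."""

    label: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"AOI {self.label!r} is degenerate: "
                f"[{self.x_min}, {self.x_max}) x [{self.y_min}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: float, y: float) -> bool:
        return (self.x_min <= x < self.x_max) and (self.y_min <= y < self.y_max)

    def shifted(self, dx: float, dy: float = 0.0) -> "AOI":
        """Return a copy translated by (dx, dy)."""
        return replace(
            self,
            x_min=self.x_min + dx,
            x_max=self.x_max + dx,
            y_min=self.y_min + dy,
            y_max=self.y_max + dy,
        )

    def inner_box(self, margin_frac: float) -> "AOI":
        """Rectangle shrunk by ``margin_frac`` of its extent on every side."""
        mx = margin_frac * self.width
        my = margin_frac * self.height
        return replace(
            self,
            x_min=self.x_min + mx,
            x_max=self.x_max - mx,
            y_min=self.y_min + my,
            y_max=self.y_max - my,
        )


def _rects_overlap(a: AOI, b: AOI) -> bool:
    return a.x_min < b.x_max and b.x_min < a.x_max and a.y_min < b.y_max and b.y_min < a.y_max


@dataclass
class TrialLayout:
    """Geometry and event metadata for a single trial.

    Only the fields relevant to the paradigm at hand need to be filled in:
    ``response_time_ms`` and ``chosen_label`` for a two-alternative choice
    trial, ``novel_label`` for a preferential-looking trial,
    ``target_label``/``target_onset_ms`` for a four-quadrant spoken-word
    trial.  ``true_midline_y`` is only meaningful for four-AOI layouts.
    """

    screen_w: float = DEFAULT_SCREEN_W
    screen_h: float = DEFAULT_SCREEN_H
    fixation_point: tuple[float, float] = (DEFAULT_SCREEN_W / 2, DEFAULT_SCREEN_H / 2)
    fixation_duration_ms: float = 2000.0
    fix_start_ms: float = 0.0
    aois: list[AOI] = field(default_factory=list)
    true_midline_x: float = DEFAULT_SCREEN_W / 2
    true_midline_y: Optional[float] = None
    stim_start_ms: Optional[float] = None
    stim_end_ms: Optional[float] = None
    response_time_ms: Optional[float] = None
    chosen_label: Optional[str] = None
    novel_label: Optional[str] = None
    target_label: Optional[str] = None
    target_onset_ms: Optional[float] = None
    test_start_ms: Optional[float] = None
    test_end_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fixation_duration_ms <= 0:
            raise ValueError("fixation_duration_ms must be positive")
        if not (0 <= self.true_midline_x <= self.screen_w):
            raise ValueError("true_midline_x outside the screen")
        if self.true_midline_y is not None and not (0 <= self.true_midline_y <= self.screen_h):
            raise ValueError("true_midline_y outside the screen")
        for a in self.aois:
            if a.x_min < 0 or a.x_max > self.screen_w or a.y_min < 0 or a.y_max > self.screen_h:
                raise ValueError(f"AOI {a.label!r} extends beyond the screen")
        labels = [a.label for a in self.aois]
        if len(set(labels)) != len(labels):
            raise ValueError("AOI labels must be unique")
        for i, a in enumerate(self.aois):
            for b in self.aois[i + 1 :]:
                if _rects_overlap(a, b):
                    raise ValueError(f"AOIs {a.label!r} and {b.label!r} overlap")

    @property
    def fixation_end_ms(self) -> float:
        return self.fix_start_ms + self.fixation_duration_ms

    def aoi(self, label: str) -> AOI:
        for a in self.aois:
            if a.label == label:
                return a
        raise KeyError(label)


def assign_aoi(x: float, y: float, aois: Sequence[AOI]) -> Optional[str]:
    """Label of the (unique) AOI containing the point, or ``None``.

    Rectangles are half-open, so a point exactly on an AOI's x_max or y_max
    edge does not belong to it.  Layout validation guarantees disjointness,
    hence uniqueness of the hit.
    """
    for a in aois:
        if a.contains(x, y):
            return a.label
    return None


def assign_aoi_array(
    x: np.ndarray, y: np.ndarray, aois: Sequence[AOI]
) -> np.ndarray:
    """Vectorised :func:`assign_aoi`; returns an object array of labels/None."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.full(x.shape, None, dtype=object)
    for a in aois:
        hit = (x >= a.x_min) & (x < a.x_max) & (y >= a.y_min) & (y < a.y_max)
        out[hit & (out == None)] = a.label  # noqa: E711 -- elementwise None test
    return out


def side_by_side_aois(
    image_w: float,
    image_h: float,
    gap: float = SIDE_BY_SIDE_GAP_PX,
    screen_w: float = DEFAULT_SCREEN_W,
    screen_h: float = DEFAULT_SCREEN_H,
) -> list[AOI]:
    """Two vertically centred AOIs separated by ``gap`` px between inner edges."""
    cx, cy = screen_w / 2, screen_h / 2
    half_gap = gap / 2
    y0, y1 = cy - image_h / 2, cy + image_h / 2
    return [
        AOI("left", cx - half_gap - image_w, cx - half_gap, y0, y1),
        AOI("right", cx + half_gap, cx + half_gap + image_w, y0, y1),
    ]


def quadrant_aois(
    image_w: float,
    image_h: float,
    screen_w: float = DEFAULT_SCREEN_W,
    screen_h: float = DEFAULT_SCREEN_H,
) -> list[AOI]:
    """Four AOIs centred on the quadrants of the screen."""
    out = []
    for label, qx, qy in [
        ("top_left", 0.25, 0.25),
        ("top_right", 0.75, 0.25),
        ("bottom_left", 0.25, 0.75),
        ("bottom_right", 0.75, 0.75),
    ]:
        cx, cy = qx * screen_w, qy * screen_h
        out.append(
            AOI(label, cx - image_w / 2, cx + image_w / 2, cy - image_h / 2, cy + image_h / 2)
        )
    return out
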
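"""Open-field grid scoring.

The open-field arena is a 20 cm x 30 cm box whose floor is ruled into a
grid of 2 cm x 2 cm squares (10 columns x 15 rows = 150 squares).  The
animal starts on the central 2x2 block of squares.  Activity is scored
from the front-paw trajectories as square-entry events:

* ``total``  — every time a front paw moves from one square to another;
* ``novel``  — the number of distinct squares entered by either front
  paw, excluding the four start squares (maximum 146);
* inner/outer splits — the central 6x11 block vs. the two-deep
  perimeter ring of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "OpenFieldGrid",
    "MeasureRow",
    "EntryEvent",
    "build_grid",
    "locate_square",
    "square_sequence",
    "score_measures",
    "exhaustive_sweep",
]


class EntryEvent(NamedTuple):
    """A single square-entry event: ``paw`` entered ``square`` at ``frame``."""

    frame: int
    paw: str
    square: tuple[int, int]  # (col, row), 0-based


@dataclass(frozen=True)
class OpenFieldGrid:
    """Geometry of the gridded open-field floor.

    Columns index the box width, rows the box height; squares are
    addressed as 0-based ``(col, row)`` pairs.  ``px_per_cm`` converts
    pixel-space trajectories to arena centimetres; when ``None`` the
    trajectories are assumed to already be in cm.
    """

    box_cm: tuple[float, float] = (20.0, 30.0)
    square_cm: float = 2.0
    px_per_cm: float | None = None
    n_cols: int = field(init=False)
    n_rows: int = field(init=False)

    def __post_init__(self) -> None:
        w, h = self.box_cm
        nc, nr = w / self.square_cm, h / self.square_cm
        if abs(nc - round(nc)) > 1e-9 or abs(nr - round(nr)) > 1e-9:
            raise ValueError(
                f"square size {self.square_cm} cm does not divide box {self.box_cm} cm"
            )
        object.__setattr__(self, "n_cols", int(round(nc)))
        object.__setattr__(self, "n_rows", int(round(nr)))
        if self.n_cols < 4 or self.n_rows < 4:
            raise ValueError("grid too small to define a two-deep perimeter ring")

    @property
    def n_squares(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def start_squares(self) -> frozenset[tuple[int, int]]:
        """The centred 2x2 start block where the animal is placed."""
        c0 = self.n_cols // 2 - 1
        r0 = self.n_rows // 2 - 1
        return frozenset((c0 + dc, r0 + dr) for dc in (0, 1) for dr in (0, 1))

    @property
    def inner_region(self) -> frozenset[tuple[int, int]]:
        """Central block: everything at least two squares from every wall."""
        return frozenset(
            (c, r)
            for c in range(2, self.n_cols - 2)
            for r in range(2, self.n_rows - 2)
        )

    @property
    def outer_region(self) -> frozenset[tuple[int, int]]:
        """Two-deep perimeter ring (complement of the inner block)."""
        inner = self.inner_region
        return frozenset(
            (c, r)
            for c in range(self.n_cols)
            for r in range(self.n_rows)
            if (c, r) not in inner
        )

    @property
    def max_novel(self) -> int:
        """Largest attainable Novel count (all squares minus the start block)."""
        return self.n_squares - len(self.start_squares)

    def square_center_cm(self, square: tuple[int, int]) -> tuple[float, float]:
        c, r = square
        s = self.square_cm
        return ((c + 0.5) * s, (r + 0.5) * s)


@dataclass(frozen=True)
class MeasureRow:
    """The six expert kinematic measures for one trial."""

    trial_id: str
    novel: int
    total: int
    novel_inner: int
    novel_outer: int
    total_inner: int
    total_outer: int

    def __post_init__(self) -> None:
        if self.novel != self.novel_inner + self.novel_outer:
            raise ValueError("novel must equal novel_inner + novel_outer")
        if self.total != self.total_inner + self.total_outer:
            raise ValueError("total must equal total_inner + total_outer")
        if min(
            self.novel, self.total, self.novel_inner,
            self.novel_outer, self.total_inner, self.total_outer,
        ) < 0:
            raise ValueError("measures must be non-negative")

    def as_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "novel": self.novel,
            "total": self.total,
            "novel_inner": self.novel_inner,
            "novel_outer": self.novel_outer,
            "total_inner": self.total_inner,
            "total_outer": self.total_outer,
        }


def build_grid(
    box_cm: tuple[float, float] = (20.0, 30.0),
    square_cm: float = 2.0,
    px_per_cm: float | None = None,
) -> OpenFieldGrid:
    """Construct the arena grid; raises if the square does not divide the box."""
    return OpenFieldGrid(box_cm=box_cm, square_cm=square_cm, px_per_cm=px_per_cm)


def locate_square(x: float, y: float, grid: OpenFieldGrid) -> tuple[int, int]:
    """Map an arena-cm coordinate to its 0-based (col, row) square.

    Cells are half-open, ``[x0, x0 + s) x [y0, y0 + s)``; points exactly
    on the far (right/top) arena boundary belong to the last cell.
    """
    w, h = grid.box_cm
    if not (0.0 <= x <= w and 0.0 <= y <= h):
        raise ValueError(f"point ({x}, {y}) cm lies outside the {w}x{h} cm arena")
    c = min(int(x // grid.square_cm), grid.n_cols - 1)
    r = min(int(y // grid.square_cm), grid.n_rows - 1)
    return (c, r)


def _to_cm(track: np.ndarray, grid: OpenFieldGrid) -> np.ndarray:
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 2:
        raise ValueError("paw track must have shape (n_frames, 2)")
    if grid.px_per_cm is not None:
        track = track / grid.px_per_cm
    return track


def square_sequence(
    left_paw: np.ndarray,
    right_paw: np.ndarray,
    grid: OpenFieldGrid,
    likelihood_left: np.ndarray | None = None,
    likelihood_right: np.ndarray | None = None,
    likelihood_gate: float = 0.6,
) -> list[EntryEvent]:
    """Ordered square-entry events induced by the two front-paw tracks.

    A paw generates an event at frame ``t`` when its square at ``t``
    differs from its square at the previous scored frame.  Frames with
    non-finite coordinates or likelihood below ``likelihood_gate`` are
    skipped for that paw (the last known square is carried over).
    Events from both paws are merged chronologically.
    """
    left = _to_cm(left_paw, grid)
    right = _to_cm(right_paw, grid)
    if left.shape[0] != right.shape[0]:
        raise ValueError("paw tracks must have the same number of frames")

    events: list[EntryEvent] = []
    for paw, track, lik in (
        ("left", left, likelihood_left),
        ("right", right, likelihood_right),
    ):
        prev: tuple[int, int] | None = None
        for t in range(track.shape[0]):
            if lik is not None and lik[t] < likelihood_gate:
                continue
            if not np.all(np.isfinite(track[t])):
                continue
            sq = locate_square(track[t, 0], track[t, 1], grid)
            if prev is not None and sq != prev:
                events.append(EntryEvent(frame=t, paw=paw, square=sq))
            prev = sq
    events.sort(key=lambda e: (e.frame, e.paw))
    return events


def score_measures(
    events: Sequence[EntryEvent], grid: OpenFieldGrid, trial_id: str = ""
) -> MeasureRow:
    """Reduce entry events to the six expert measures.

    ``novel`` counts distinct squares entered by either paw with the
    four start squares excluded; entries *into* start squares still
    count toward ``total`` (every square-to-square transition does).
    Events are attributed to the inner/outer region of the square being
    entered.
    """
    inner = grid.inner_region
    start = grid.start_squares
    total_inner = sum(1 for e in events if e.square in inner)
    total_outer = len(events) - total_inner
    entered = {e.square for e in events} - start
    novel_inner = sum(1 for sq in entered if sq in inner)
    novel_outer = len(entered) - novel_inner
    return MeasureRow(
        trial_id=trial_id,
        novel=len(entered),
        total=len(events),
        novel_inner=novel_inner,
        novel_outer=novel_outer,
        total_inner=total_inner,
        total_outer=total_outer,
    )


def exhaustive_sweep(grid: OpenFieldGrid) -> np.ndarray:
    """Boustrophedon trajectory (in cm) through the centre of every square.

    Starts at a start-block square so the sweep is a valid trial
    trajectory; visits all ``n_squares`` squares.
    """
    c0, r0 = min(grid.start_squares)
    path = [grid.square_center_cm((c0, r0))]
    for r in range(grid.n_rows):
        cols = range(grid.n_cols) if r % 2 == 0 else range(grid.n_cols - 1, -1, -1)
        for c in cols:
            path.append(grid.square_center_cm((c, r)))
    return np.asarray(path, dtype=float)
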
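"""Two-dimensional sensorimotor world for the hand-regard simulator.

The workspace is a bounded grid of cells on which two "hands" (controlled by
the network's motor outputs) and a number of "other" objects (moving at
random) live.  A rectangular field of view (fov) with a smaller central
region (fov_center) defines where objects are visible and where a hand must
arrive for a time step to count as a success.

Each time step the world is encoded into a fixed-length input vector with
three blocks, concatenated in this order:

* visual     -- one unit per workspace cell; a unit carries the visual value
                of the objects occupying its cell, but only for cells inside
                the fov (objects outside the fov produce no visual drive);
* proprioceptive -- for each hand, a one-hot place code of its x coordinate
                followed by a one-hot place code of its y coordinate;
* corollary discharge -- a copy of the previous motor command (efference
                copy passed through an identity forward model).

Under the default 16x11 geometry this gives 176 + 54 + 8 = 238 inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Rect",
    "Geometry",
    "StimulusValues",
    "WorldState",
    "InputLayout",
    "init_world",
    "step_hands",
    "step_others",
    "encode_inputs",
    "corollary_discharge",
    "in_fov",
    "in_fov_center",
]

N_OUTPUTS = 8
#: per-hand direction order of the motor outputs: +x, -x, +y, -y
DIRECTIONS = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle of cells with inclusive bounds."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError(f"empty rectangle: {self}")

    def contains(self, pos) -> bool:
        x, y = int(pos[0]), int(pos[1])
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    def contains_rect(self, other: "Rect") -> bool:
        return (self.x0 <= other.x0 and other.x1 <= self.x1
                and self.y0 <= other.y0 and other.y1 <= self.y1)

    @property
    def n_cells(self) -> int:
        return (self.x1 - self.x0 + 1) * (self.y1 - self.y0 + 1)

    def cells(self) -> np.ndarray:
        """All (x, y) pairs in the rectangle, row-major from the lower-left."""
        xs, ys = np.meshgrid(
            np.arange(self.x0, self.x1 + 1), np.arange(self.y0, self.y1 + 1)
        )
        return np.column_stack([xs.ravel(), ys.ravel()])

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)


def _central_rect(width: int, height: int, w: int, h: int) -> Rect:
    x0 = (width - w) // 2
    y0 = (height - h) // 2
    return Rect(x0, y0, x0 + w - 1, y0 + h - 1)


@dataclass(frozen=True)
class Geometry:
    """Workspace grid with nested field-of-view rectangles.

    Coordinates are 0-based integers, origin at the lower-left, x rightward
    and y upward.  ``fov_center`` must lie inside ``fov``, which must lie
    inside the workspace.  The reference point used by the motor-error
    teacher is the centroid of ``fov_center``.
    """

    width: int = 16
    height: int = 11
    fov: Rect = field(default_factory=lambda: _central_rect(16, 11, 8, 7))
    fov_center: Rect = field(default_factory=lambda: _central_rect(16, 11, 2, 2))

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("workspace must be at least 1x1")
        workspace = Rect(0, 0, self.width - 1, self.height - 1)
        if not workspace.contains_rect(self.fov):
            raise ValueError("fov must lie inside the workspace")
        if not self.fov.contains_rect(self.fov_center):
            raise ValueError("fov_center must lie inside the fov")

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    @property
    def reference(self) -> tuple[float, float]:
        """Center of the field of view: the target of the motor-error teacher."""
        return self.fov_center.centroid

    def cell_index(self, pos) -> int:
        """Row-major index of a cell in the visual block."""
        return int(pos[1]) * self.width + int(pos[0])

    def clamp(self, x: int, y: int) -> tuple[int, int]:
        return (min(max(x, 0), self.width - 1), min(max(y, 0), self.height - 1))

    def in_bounds(self, pos) -> bool:
        return 0 <= pos[0] < self.width and 0 <= pos[1] < self.height


@dataclass(frozen=True)
class StimulusValues:
    """Visual-stimulus values and the stimulus switches of the test cases.

    ``hand_visual`` / ``other_visual`` are the values written into the visual
    unit of a cell occupied by a hand / other.  The three booleans implement
    the test-case manipulations: turning off the hands' visual input, turning
    off the corollary discharge, and confining the others to the fov.
    """

    hand_visual: float = 0.5
    other_visual: float = 0.2
    n_others: int = 1
    hand_visual_on: bool = True
    corollary_on: bool = True
    confine_others: bool = False

    def __post_init__(self) -> None:
        for name in ("hand_visual", "other_visual"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_others < 0:
            raise ValueError("n_others must be >= 0")


@dataclass(frozen=True)
class WorldState:
    """Positions of both hands and the others at time ``t``."""

    left_hand: tuple[int, int]
    right_hand: tuple[int, int]
    others: np.ndarray  # (n_others, 2) int array
    t: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "others", np.asarray(self.others, dtype=np.int64).reshape(-1, 2)
        )


@dataclass(frozen=True)
class InputLayout:
    """Slice bookkeeping for the (visual, proprioceptive, corollary) blocks."""

    n_visual: int
    n_proprio: int
    n_corollary: int = N_OUTPUTS

    @property
    def total(self) -> int:
        return self.n_visual + self.n_proprio + self.n_corollary

    @property
    def visual(self) -> slice:
        return slice(0, self.n_visual)

    @property
    def proprio(self) -> slice:
        return slice(self.n_visual, self.n_visual + self.n_proprio)

    @property
    def corollary(self) -> slice:
        return slice(self.n_visual + self.n_proprio, self.total)

    @classmethod
    def from_geometry(cls, g: Geometry) -> "InputLayout":
        return cls(n_visual=g.n_cells, n_proprio=2 * (g.width + g.height))


def in_fov(pos, g: Geometry) -> bool:
    """True iff ``pos`` lies in the field of view."""
    return g.fov.contains(pos)


def in_fov_center(pos, g: Geometry) -> bool:
    """True iff ``pos`` lies in the center region of the field of view."""
    return g.fov_center.contains(pos)


def _random_cell(rect: Rect, rng: np.random.Generator) -> tuple[int, int]:
    return (int(rng.integers(rect.x0, rect.x1 + 1)),
            int(rng.integers(rect.y0, rect.y1 + 1)))


def init_world(geometry: Geometry, stim: StimulusValues,
               rng: np.random.Generator | int) -> WorldState:
    """Place hands and others uniformly at random.

    Hands are placed anywhere in the workspace.  Others are placed in the fov
    when ``stim.confine_others`` is set, otherwise anywhere.  Objects may
    overlap; there is no collision model.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    workspace = Rect(0, 0, geometry.width - 1, geometry.height - 1)
    region = geometry.fov if stim.confine_others else workspace
    left = _random_cell(workspace, rng)
    right = _random_cell(workspace, rng)
    others = np.array(
        [_random_cell(region, rng) for _ in range(stim.n_others)], dtype=np.int64
    ).reshape(-1, 2)
    return WorldState(left_hand=left, right_hand=right, others=others, t=0)


def _move_hand(pos, outputs4: np.ndarray, threshold: float,
               g: Geometry) -> tuple[int, int]:
    dx = dy = 0
    for k, (ddx, ddy) in enumerate(DIRECTIONS):
        if outputs4[k] > threshold:
            dx += ddx
            dy += ddy
    return g.clamp(pos[0] + dx, pos[1] + dy)


def step_hands(world: WorldState, motor_outputs: np.ndarray,
               move_threshold: float, g: Geometry) -> WorldState:
    """Move each hand according to its four direction outputs.

    Outputs 0-3 drive the left hand and 4-7 the right hand, in the direction
    order (+x, -x, +y, -y).  A direction fires iff its output strictly
    exceeds ``move_threshold``; the displacement is the vector sum of fired
    directions (one cell each, opposing directions cancel), clamped to the
    workspace.
    """
    motor_outputs = np.asarray(motor_outputs, dtype=float)
    if motor_outputs.shape != (N_OUTPUTS,):
        raise ValueError(f"expected {N_OUTPUTS} motor outputs")
    left = _move_hand(world.left_hand, motor_outputs[:4], move_threshold, g)
    right = _move_hand(world.right_hand, motor_outputs[4:], move_threshold, g)
    return replace(world, left_hand=left, right_hand=right)


def step_others(world: WorldState, rng: np.random.Generator, confine: bool,
                g: Geometry) -> WorldState:
    """Random walk of the others: each draws a step from {stay, +-x, +-y}.

    With ``confine`` a proposed move leaving the fov is rejected (the other
    stays put), so a confined other never leaves the fov.  Without
    confinement moves are clamped to the workspace.
    """
    if len(world.others) == 0:
        return world
    moves = np.array([(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)])
    choice = rng.integers(0, len(moves), size=len(world.others))
    proposed = world.others + moves[choice]
    new = world.others.copy()
    for i, (x, y) in enumerate(proposed):
        if confine:
            if g.fov.contains((x, y)):
                new[i] = (x, y)
        else:
            new[i] = g.clamp(x, y)
    return replace(world, others=new)


def corollary_discharge(prev_motor_outputs: np.ndarray) -> np.ndarray:
    """Forward model mapping the efference copy to a corollary discharge.

    The forward model is simplified to the identity: the previous motor
    outputs are fed back unchanged as the corollary block of the next input.
    """
    out = np.asarray(prev_motor_outputs, dtype=float)
    if out.shape != (N_OUTPUTS,):
        raise ValueError(f"expected {N_OUTPUTS} motor outputs")
    return out.copy()


def _one_hot(n: int, i: int) -> np.ndarray:
    v = np.zeros(n)
    v[i] = 1.0
    return v


def encode_inputs(world: WorldState, stim: StimulusValues,
                  corollary: np.ndarray, g: Geometry) -> np.ndarray:
    """Encode the world into the input vector (visual, proprio, corollary).

    Visual units tile the full workspace but only cells inside the fov can be
    driven; when several objects share a cell the unit takes the maximum of
    their visual values, keeping every input in [0, 1].
    """
    corollary = np.asarray(corollary, dtype=float)
    if corollary.shape != (N_OUTPUTS,):
        raise ValueError(f"corollary block must have length {N_OUTPUTS}")
    layout = InputLayout.from_geometry(g)

    visual = np.zeros(layout.n_visual)
    hand_value = stim.hand_visual if stim.hand_visual_on else 0.0
    for hand in (world.left_hand, world.right_hand):
        if in_fov(hand, g):
            idx = g.cell_index(hand)
            visual[idx] = max(visual[idx], hand_value)
    for other in world.others:
        if in_fov(other, g):
            idx = g.cell_index(other)
            visual[idx] = max(visual[idx], stim.other_visual)

    proprio = np.concatenate([
        _one_hot(g.width, world.left_hand[0]),
        _one_hot(g.height, world.left_hand[1]),
        _one_hot(g.width, world.right_hand[0]),
        _one_hot(g.height, world.right_hand[1]),
    ])

    cd = corollary.copy() if stim.corollary_on else np.zeros(N_OUTPUTS)
    x = np.concatenate([visual, proprio, cd])
    assert x.shape == (layout.total,)
    return x
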
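"""Experiment driver: training runs, test cases and ensembles.

A training run couples the world and the network in a closed loop.  Each
step: the world is encoded into the input vector (with the previous motor
command as corollary discharge), the network takes one forward step, the
motor outputs move the hands, the others take a random step, the
motor-command error is computed from the new hand positions, and the RTRL
increment is accumulated.  Weights are applied every ``update_interval``
steps and snapshotted every ``checkpoint_interval`` steps.

The *success rate* over a window is the fraction of steps at which at least
one hand is inside the center of the field of view.

Nine stimulus test cases probe what the trained network relies on: cases
1-6 vary the visual value and the number of "others" (confined to the fov),
cases 7-9 switch off the hands' visual input and/or the corollary discharge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import network, rtrl, world as world_mod
from .network import Architecture, ConnectivityMask
from .rtrl import LearningConfig, SensitivityTensor
from .world import Geometry, StimulusValues, WorldState

__all__ = [
    "TestCase",
    "CASES",
    "RunRecord",
    "seed_streams",
    "train",
    "success_rate",
    "success_series",
    "evaluate_checkpoint",
    "ensemble_average",
    "count_direction_reversals",
]


@dataclass(frozen=True)
class TestCase:
    """Stimulus condition of one test case."""

    id: int
    other_visual: float
    n_others: int
    hand_visual_on: bool = True
    corollary_on: bool = True
    confine_others: bool = True

    def stimulus(self, hand_visual: float = 0.5) -> StimulusValues:
        return StimulusValues(
            hand_visual=hand_visual,
            other_visual=self.other_visual,
            n_others=self.n_others,
            hand_visual_on=self.hand_visual_on,
            corollary_on=self.corollary_on,
            confine_others=self.confine_others,
        )


#: the nine test-case presets; cases 7-9 are case 1 with input blocks silenced
CASES: dict[int, TestCase] = {
    1: TestCase(1, other_visual=0.2, n_others=1),
    2: TestCase(2, other_visual=0.2, n_others=5),
    3: TestCase(3, other_visual=0.2, n_others=20),
    4: TestCase(4, other_visual=0.5, n_others=1),
    5: TestCase(5, other_visual=0.5, n_others=5),
    6: TestCase(6, other_visual=0.5, n_others=20),
    7: TestCase(7, other_visual=0.2, n_others=1,
                hand_visual_on=False, corollary_on=False),
    8: TestCase(8, other_visual=0.2, n_others=1, hand_visual_on=False),
    9: TestCase(9, other_visual=0.2, n_others=1, corollary_on=False),
}


def seed_streams(seed: int) -> dict[str, np.random.Generator]:
    """Three independent named random streams derived from one root seed.

    Separate streams for weight initialization, initial object placement and
    the others' motion mean that e.g. changing ``n_others`` does not perturb
    the initial weights.
    """
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    return {
        "weights": np.random.default_rng(kids[0]),
        "placement": np.random.default_rng(kids[1]),
        "others": np.random.default_rng(kids[2]),
    }


@dataclass
class RunRecord:
    """Everything a training run logs.

    ``update_steps`` are the steps at which weights were applied;
    ``delta_sign_index`` / ``weight_sign_index`` are the per-update sign
    indices over the hidden-hidden connections (see assembly_analysis).
    Checkpoints map step -> weight-matrix copy; step 0 holds the initial
    weights.
    """

    seed: int
    n_steps: int
    checkpoints: dict[int, np.ndarray] = field(default_factory=dict)
    update_steps: np.ndarray | None = None
    delta_sign_index: np.ndarray | None = None
    weight_sign_index: np.ndarray | None = None
    success: np.ndarray | None = None
    left_traj: np.ndarray | None = None
    right_traj: np.ndarray | None = None
    final_weights: np.ndarray | None = None


def _sign_index(values: np.ndarray) -> int:
    return int(np.count_nonzero(values > 0) - np.count_nonzero(values < 0))


def train(
    geometry: Geometry,
    stim: StimulusValues,
    learn: LearningConfig,
    seed: int,
    n_steps: int,
    checkpoint_interval: int | None = None,
    arch: Architecture | None = None,
    mask: ConnectivityMask | None = None,
    initial_weights: np.ndarray | None = None,
    learning_enabled: bool = True,
) -> RunRecord:
    """Run the closed training loop for ``n_steps`` steps.

    Returns a :class:`RunRecord` with checkpoints, per-step success flags,
    hand trajectories and the per-update hidden-hidden sign-index series.
    Fully deterministic given (arguments, seed).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if mask is not None and arch is None:
        arch = mask.arch
    if arch is None or mask is None:
        arch, mask = network.build_architecture(arch)
    layout = world_mod.InputLayout.from_geometry(geometry)
    if layout.total != arch.n_input:
        raise ValueError(
            f"input layout ({layout.total}) does not match the architecture "
            f"({arch.n_input} input units)")

    rngs = seed_streams(seed)
    w = (initial_weights.copy() if initial_weights is not None
         else network.init_weights(mask, learn.init_bound, rngs["weights"]))
    state = network.initial_state(arch)
    wstate = world_mod.init_world(geometry, stim, rngs["placement"])
    p = SensitivityTensor.zeros(mask)
    acc = np.zeros(mask.n_weights)
    hh = mask.hidden_hidden_flat()

    rec = RunRecord(seed=seed, n_steps=n_steps)
    rec.checkpoints[0] = w.copy()
    success = np.zeros(n_steps, dtype=bool)
    left = np.zeros((n_steps, 2), dtype=np.int64)
    right = np.zeros((n_steps, 2), dtype=np.int64)
    upd_steps, dsi, wsi = [], [], []

    for t in range(1, n_steps + 1):
        cd = world_mod.corollary_discharge(state.outputs(arch))
        x = world_mod.encode_inputs(wstate, stim, cd, geometry)
        state = network.forward_step(w, state, x, arch)
        if learning_enabled:
            p = rtrl.update_sensitivities(p, w, state)
        wstate = world_mod.step_hands(
            wstate, state.outputs(arch), learn.move_threshold, geometry)
        wstate = world_mod.step_others(
            wstate, rngs["others"], stim.confine_others, geometry)
        if learning_enabled:
            e = rtrl.motor_command_error(wstate, geometry, learn.alpha)
            acc += rtrl.weight_delta(e, p, learn.eta)
            if t % learn.update_interval == 0:
                dsi.append(_sign_index(acc[hh]))
                w = rtrl.apply_updates(w, acc, mask)
                wsi.append(_sign_index(w[mask.recv[hh], mask.send[hh]]))
                upd_steps.append(t)
                acc[:] = 0.0
        left[t - 1] = wstate.left_hand
        right[t - 1] = wstate.right_hand
        success[t - 1] = (
            world_mod.in_fov_center(wstate.left_hand, geometry)
            or world_mod.in_fov_center(wstate.right_hand, geometry))
        if checkpoint_interval and t % checkpoint_interval == 0:
            rec.checkpoints[t] = w.copy()

    rec.update_steps = np.asarray(upd_steps, dtype=np.int64)
    rec.delta_sign_index = np.asarray(dsi, dtype=np.int64)
    rec.weight_sign_index = np.asarray(wsi, dtype=np.int64)
    rec.success = success
    rec.left_traj = left
    rec.right_traj = right
    rec.final_weights = w
    return rec


def success_rate(states: list[WorldState], geometry: Geometry) -> float:
    """Fraction of states with at least one hand in the fov center."""
    if len(states) == 0:
        raise ValueError("empty trajectory")
    hits = sum(
        world_mod.in_fov_center(s.left_hand, geometry)
        or world_mod.in_fov_center(s.right_hand, geometry)
        for s in states
    )
    return hits / len(states)


def success_series(flags: np.ndarray, window: int) -> np.ndarray:
    """Windowed success rates: mean of the flags per consecutive window."""
    if window < 1:
        raise ValueError("window must be >= 1")
    flags = np.asarray(flags, dtype=float)
    n = (len(flags) // window) * window
    if n == 0:
        raise ValueError("window longer than the series")
    return flags[:n].reshape(-1, window).mean(axis=1)


def evaluate_checkpoint(
    weights: np.ndarray,
    case: TestCase | int,
    geometry: Geometry,
    learn: LearningConfig,
    seed: int,
    eval_steps: int = 10_000,
    hand_visual: float = 0.5,
    arch: Architecture | None = None,
    mask: ConnectivityMask | None = None,
) -> float:
    """Success rate of a frozen checkpoint under one test case.

    Runs the closed loop with learning disabled (weights are never mutated)
    for ``eval_steps`` steps and returns the overall success rate.
    """
    if isinstance(case, int):
        if case not in CASES:
            raise KeyError(f"unknown test case {case}")
        case = CASES[case]
    rec = train(
        geometry, case.stimulus(hand_visual), learn, seed, eval_steps,
        checkpoint_interval=None, arch=arch, mask=mask,
        initial_weights=weights, learning_enabled=False,
    )
    return float(rec.success.mean())


def ensemble_average(series: list[np.ndarray]) -> np.ndarray:
    """Pointwise arithmetic mean of equal-length series (one per seed)."""
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    return np.mean(np.stack([np.asarray(s, dtype=float) for s in series]), axis=0)


def replay_hidden(
    weights: np.ndarray,
    geometry: Geometry,
    stim: StimulusValues,
    learn: LearningConfig,
    seed: int,
    n_steps: int,
    arch: Architecture | None = None,
    mask: ConnectivityMask | None = None,
) -> np.ndarray:
    """Run the frozen closed loop and log hidden activations per step.

    Returns an ``(n_steps, n_hidden)`` array; used to snapshot the activity
    on which cell-assembly detection operates.
    """
    if mask is not None and arch is None:
        arch = mask.arch
    if arch is None or mask is None:
        arch, mask = network.build_architecture(arch)
    rngs = seed_streams(seed)
    state = network.initial_state(arch)
    wstate = world_mod.init_world(geometry, stim, rngs["placement"])
    log = np.zeros((n_steps, arch.n_hidden))
    for t in range(n_steps):
        cd = world_mod.corollary_discharge(state.outputs(arch))
        x = world_mod.encode_inputs(wstate, stim, cd, geometry)
        state = network.forward_step(weights, state, x, arch)
        wstate = world_mod.step_hands(
            wstate, state.outputs(arch), learn.move_threshold, geometry)
        wstate = world_mod.step_others(
            wstate, rngs["others"], stim.confine_others, geometry)
        log[t] = state.hidden(arch)
    return log


def count_direction_reversals(traj: np.ndarray) -> int:
    """Number of per-axis movement-direction reversals along a trajectory.

    A reversal on an axis is a sign change between consecutive nonzero
    displacements on that axis; the two axes are counted independently.
    Used to quantify the reciprocating motion of the hands across the fov.
    """
    traj = np.asarray(traj)
    total = 0
    for axis in range(traj.shape[1]):
        d = np.diff(traj[:, axis])
        signs = np.sign(d[d != 0])
        if len(signs) > 1:
            total += int(np.count_nonzero(signs[1:] != signs[:-1]))
    return total
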
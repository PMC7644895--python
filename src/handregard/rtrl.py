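"""Feedback-error real-time recurrent learning (RTRL).

The teacher signal is not a target output but a *motor-command error*: for
each hand, the signed displacement between its proprioceptively perceived
position and the center of the field of view, scaled by a constant and
mapped onto that hand's four direction outputs.  A positive error on an
output unit means "increase this output to move the hand toward the center".

Weight changes follow the RTRL rule

    dw_ij(t) = eta * sum_{k in O} e_k(t) * p_ij^k(t)

where the sensitivities p_ij^k = dy_k / dw_ij obey the forward recursion

    p_ij^k(t) = f'(s_k(t)) * ( delta_ik * z_j(t-1)
                               + sum_{l in H u O} w_kl * p_ij^l(t-1) )

with f'(s) = f(s)(1 - f(s)) for the logistic f.  Sensitivities are carried
for every hidden and output unit k (the recursion requires hidden k); only
the output-unit slice enters the weight change.  Increments are accumulated
and applied to the weights every ``update_interval`` steps (default 10);
sensitivities are not reset at update boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .network import ActivationState, Architecture, ConnectivityMask
from .world import Geometry, WorldState

__all__ = [
    "LearningConfig",
    "SensitivityTensor",
    "motor_command_error",
    "update_sensitivities",
    "weight_delta",
    "apply_updates",
]


@dataclass(frozen=True)
class LearningConfig:
    """Learning-rule constants.

    eta
        learning rate of the weight update.
    alpha
        scaling from cell displacement to motor-command error (error per
        cell of distance from the fov center).
    update_interval
        number of steps over which weight increments are accumulated before
        being applied (10 during training).
    move_threshold
        output level a direction unit must exceed for the hand to move.
    init_bound
        half-width of the uniform weight initialization interval.
    """

    eta: float = 0.1
    alpha: float = 0.1
    update_interval: int = 10
    move_threshold: float = 0.5
    init_bound: float = 0.1

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.update_interval < 1:
            raise ValueError("update_interval must be >= 1")
        if self.init_bound <= 0:
            raise ValueError("init_bound must be > 0")


@dataclass
class SensitivityTensor:
    """p_ij^k for every allowed weight (i, j) and every unit k in H u O.

    Stored as a dense array of shape ``(n_receivers, n_weights)``: row k
    holds the sensitivities of unit k's output to each allowed weight, in
    the flat weight order of the mask.  Initialized to zero.
    """

    p: np.ndarray
    mask: ConnectivityMask

    @classmethod
    def zeros(cls, mask: ConnectivityMask) -> "SensitivityTensor":
        return cls(p=np.zeros((mask.arch.n_receivers, mask.n_weights)), mask=mask)

    def output_slice(self) -> np.ndarray:
        """The k in O rows used by the weight change."""
        return self.p[self.mask.arch.output_rows]


def motor_command_error(world: WorldState, g: Geometry,
                        alpha: float) -> np.ndarray:
    """Per-output motor-command errors from proprioceptive hand positions.

    For each hand with position (x, y) and fov-center reference (rx, ry):

        e_{+x} = alpha * (rx - x),   e_{-x} = -e_{+x}
        e_{+y} = alpha * (ry - y),   e_{-y} = -e_{+y}

    so a positive error always drives the output whose direction points
    toward the center.  The 8-vector is ordered as the output units:
    left hand (+x, -x, +y, -y) then right hand (+x, -x, +y, -y).  A hand
    sitting exactly on the reference point has all four errors zero, and
    crossing the center flips the signs.
    """
    rx, ry = g.reference
    e = np.empty(8)
    for h, hand in enumerate((world.left_hand, world.right_hand)):
        ex = alpha * (rx - hand[0])
        ey = alpha * (ry - hand[1])
        e[4 * h:4 * h + 4] = (ex, -ex, ey, -ey)
    return e


def update_sensitivities(p: SensitivityTensor, w: np.ndarray,
                         state: ActivationState) -> SensitivityTensor:
    """Advance the sensitivity recursion by one step.

    ``state`` must be the activation state produced by the forward step for
    the current time: its ``s`` is s_k(t) and its ``z_prev`` is z(t-1).
    Masked-out weights keep sensitivity exactly zero because they have no
    flat column.
    """
    mask = p.mask
    arch = mask.arch
    if state.z_prev is None:
        raise ValueError("state lacks z_prev; run forward_step first")
    w_rec = w[:, arch.n_input:]  # weights from hidden/output senders
    prop = w_rec @ p.p
    # delta_ik term: for weight (i, j) add z_j(t-1) to row i
    prop[mask.recv, np.arange(mask.n_weights)] += state.z_prev[mask.send]
    y = expit(state.s)
    fprime = y * (1.0 - y)
    return SensitivityTensor(p=fprime[:, None] * prop, mask=mask)


def weight_delta(e: np.ndarray, p: SensitivityTensor, eta: float) -> np.ndarray:
    """Per-weight increment eta * sum_k e_k p_ij^k, flat over allowed weights."""
    e = np.asarray(e, dtype=float)
    if e.shape != (p.mask.arch.n_output,):
        raise ValueError("motor error must have one entry per output unit")
    return eta * (e @ p.output_slice())


def apply_updates(w: np.ndarray, accumulated: np.ndarray,
                  mask: ConnectivityMask) -> np.ndarray:
    """Add the accumulated flat increments to the allowed entries of ``w``.

    Returns a new weight matrix; masked-out entries stay exactly zero.
    """
    if accumulated.shape != (mask.n_weights,):
        raise ValueError("accumulator length must equal the number of weights")
    out = w.copy()
    out[mask.recv, mask.send] += accumulated
    return out
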
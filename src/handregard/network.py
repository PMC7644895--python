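"""Masked three-layer recurrent network.

The network has 238 input units, 48 hidden units and 8 output units under the
default configuration.  The hidden layer is split into two equal groups of
24: an *ownership* group that integrates visual and proprioceptive inputs
only, and an *agency* group that additionally receives the corollary
discharge.  Connectivity is defined by an explicit boolean mask:

* input -> hidden: full, except that ownership units receive no connections
  from the corollary-discharge input units;
* hidden -> hidden: recurrent connections only within each group, self-loops
  included (24^2 + 24^2 = 1,152 connections under the default sizes);
* hidden -> output: full (48 x 8 = 384);
* no other connections exist (in particular no input -> output and no
  output -> anywhere).

Unit activations follow discrete-time sigmoid dynamics: every hidden/output
unit computes a weighted sum of the previous step's unit outputs (restricted
to the mask) and passes it through the logistic function.  There are no bias
terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "Architecture",
    "ConnectivityMask",
    "ActivationState",
    "build_architecture",
    "init_weights",
    "sigmoid",
    "forward_step",
    "initial_state",
]


@dataclass(frozen=True)
class Architecture:
    """Index bookkeeping for the input, hidden and output layers.

    Units are numbered globally: inputs first, then the ownership hidden
    group, then the agency hidden group, then the outputs.  Weight matrices
    are stored dense with shape ``(n_receivers, n_units)`` where receivers
    are the hidden and output units in that order.
    """

    n_input: int = 238
    n_hidden_own: int = 24
    n_hidden_agency: int = 24
    n_output: int = 8

    @property
    def n_hidden(self) -> int:
        return self.n_hidden_own + self.n_hidden_agency

    @property
    def n_units(self) -> int:
        return self.n_input + self.n_hidden + self.n_output

    @property
    def n_receivers(self) -> int:
        return self.n_hidden + self.n_output

    # global unit index ranges
    @property
    def input_units(self) -> slice:
        return slice(0, self.n_input)

    @property
    def hidden_units(self) -> slice:
        return slice(self.n_input, self.n_input + self.n_hidden)

    @property
    def own_units(self) -> slice:
        return slice(self.n_input, self.n_input + self.n_hidden_own)

    @property
    def agency_units(self) -> slice:
        return slice(self.n_input + self.n_hidden_own,
                     self.n_input + self.n_hidden)

    @property
    def output_units(self) -> slice:
        return slice(self.n_input + self.n_hidden, self.n_units)

    # receiver (row) index ranges: hidden rows first, output rows last
    @property
    def hidden_rows(self) -> slice:
        return slice(0, self.n_hidden)

    @property
    def own_rows(self) -> slice:
        return slice(0, self.n_hidden_own)

    @property
    def agency_rows(self) -> slice:
        return slice(self.n_hidden_own, self.n_hidden)

    @property
    def output_rows(self) -> slice:
        return slice(self.n_hidden, self.n_receivers)


@dataclass(frozen=True)
class ConnectivityMask:
    """Boolean relation ``allowed[receiver_row, sender_unit]``.

    Rows index the hidden then output units; columns index every unit.  The
    flattened index arrays (receiver row, sender unit per allowed pair) are
    precomputed for the learning rule, which stores one sensitivity column
    per allowed weight.
    """

    allowed: np.ndarray
    arch: Architecture

    # flat per-weight index arrays, in C order of `allowed`
    recv: np.ndarray = field(init=False)
    send: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.allowed, dtype=bool)
        object.__setattr__(self, "allowed", a)
        r, s = np.nonzero(a)
        object.__setattr__(self, "recv", r)
        object.__setattr__(self, "send", s)

    @property
    def n_weights(self) -> int:
        return len(self.recv)

    def hidden_hidden_flat(self) -> np.ndarray:
        """Flat-weight indices of the hidden->hidden connections."""
        arch = self.arch
        hid = self.arch.hidden_units
        return np.nonzero(
            (self.recv < arch.n_hidden)
            & (self.send >= hid.start) & (self.send < hid.stop)
        )[0]


@dataclass
class ActivationState:
    """Per-unit outputs ``z`` and last net inputs ``s``.

    ``z`` has one entry per unit: the current input vector in the input
    slots and the latest hidden/output activations ``y`` in the rest.
    ``z_prev`` keeps the full unit-output vector that produced ``s`` — the
    learning rule's sensitivity recursion needs it.
    """

    z: np.ndarray
    s: np.ndarray
    z_prev: np.ndarray | None = None

    def y(self, arch: Architecture) -> np.ndarray:
        return self.z[arch.n_input:]

    def outputs(self, arch: Architecture) -> np.ndarray:
        return self.z[arch.output_units]

    def hidden(self, arch: Architecture) -> np.ndarray:
        return self.z[arch.hidden_units]


def build_architecture(
    arch: Architecture | None = None,
    corollary_input_slice: slice | None = None,
) -> tuple[Architecture, ConnectivityMask]:
    """Build the connectivity mask for a (possibly resized) architecture.

    ``corollary_input_slice`` identifies the corollary-discharge units within
    the input layer (default: the final ``n_output`` input units); ownership
    hidden units get no connections from them.
    """
    arch = arch or Architecture()
    if corollary_input_slice is None:
        corollary_input_slice = slice(arch.n_input - arch.n_output, arch.n_input)

    allowed = np.zeros((arch.n_receivers, arch.n_units), dtype=bool)
    # input -> hidden (full), minus corollary -> ownership
    allowed[arch.hidden_rows, arch.input_units] = True
    allowed[arch.own_rows, corollary_input_slice] = False
    # recurrent hidden -> hidden within each group, self-loops included
    allowed[arch.own_rows, arch.own_units] = True
    allowed[arch.agency_rows, arch.agency_units] = True
    # hidden -> output (full)
    allowed[arch.output_rows, arch.hidden_units] = True
    return arch, ConnectivityMask(allowed=allowed, arch=arch)


def init_weights(mask: ConnectivityMask, bound: float,
                 rng: np.random.Generator | int) -> np.ndarray:
    """I.i.d. uniform weights on [-bound, bound] over the allowed entries."""
    if bound <= 0:
        raise ValueError("bound must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    w = rng.uniform(-bound, bound, size=mask.allowed.shape)
    w[~mask.allowed] = 0.0
    return w


def sigmoid(s):
    """Logistic function 1 / (1 + e^-s); overflow-safe for large |s|."""
    return expit(s)


def initial_state(arch: Architecture) -> ActivationState:
    """Deterministic starting state: all hidden/output activations at 0.5.

    0.5 is the sigmoid of a zero net input, i.e. the fixed point of the
    zero-weight dynamics.
    """
    z = np.zeros(arch.n_units)
    z[arch.n_input:] = 0.5
    return ActivationState(z=z, s=np.zeros(arch.n_receivers))


def forward_step(w: np.ndarray, prev: ActivationState, x_t: np.ndarray,
                 arch: Architecture) -> ActivationState:
    """One step of the discrete-time dynamics.

    The net input of each hidden/output unit is the masked weighted sum of
    the previous step's unit outputs, with the freshly sensed input vector
    ``x_t`` in the input slots; the new activation is its sigmoid.
    """
    if x_t.shape != (arch.n_input,):
        raise ValueError(f"input vector must have length {arch.n_input}")
    z_in = prev.z.copy()
    z_in[arch.input_units] = x_t
    s = w @ z_in
    y = expit(s)
    z = z_in.copy()
    z[arch.n_input:] = y
    return ActivationState(z=z, s=s, z_prev=z_in)
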
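"""Cell-assembly detection, ablation and contribution analysis.

A *cell assembly* is operationalized as the set of hidden units whose output
activity is at or above a threshold (default 0.9) — after training these are
mutually excitatory winners of the inhibitory competition in the hidden
layer.  Ablating an assembly zeroes (a) every weight from an assembly unit
onto hidden receivers and (b) every weight onto an assembly unit from hidden
or output senders; re-testing the ablated network measures how much of the
success rate the assembly carried:

    contribution ratio = (rate before - rate after) / rate before.

Two integer sign indices track the inhibitory/excitatory balance of the
recurrent hidden-hidden connections:

* the *weight-change* sign index of one update batch,
  count(dw > 0) - count(dw < 0);
* the *weight* sign index of a weight matrix,
  count(w > 0) - count(w < 0) over the allowed hidden-hidden entries.

Exact zeros count in neither tally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM

from .network import ConnectivityMask

__all__ = [
    "detect_assembly",
    "ablate",
    "weight_change_sign_index",
    "weight_sign_index",
    "contribution_ratio",
    "contribution_series",
    "rm_anova",
]


def detect_assembly(hidden_outputs: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Hidden-unit indices with output >= threshold (boundary inclusive)."""
    hidden_outputs = np.asarray(hidden_outputs, dtype=float)
    return np.nonzero(hidden_outputs >= threshold)[0]


def ablate(w: np.ndarray, assembly: np.ndarray, mask: ConnectivityMask) -> np.ndarray:
    """Zero the assembly's recurrent coupling; return a new weight matrix.

    ``assembly`` holds hidden-unit indices (0-based within the hidden
    layer).  Two slices are zeroed:

    * weights from any assembly unit onto any hidden receiver (the
      assembly's outgoing drive within the hidden layer; there are no
      weights onto input units);
    * weights onto any assembly unit from any hidden or output sender (its
      incoming recurrent drive; input -> assembly weights are kept).

    All other entries are untouched and the input matrix is not modified.
    Ablation is idempotent and never creates nonzero entries.
    """
    arch = mask.arch
    assembly = np.asarray(assembly, dtype=np.int64).reshape(-1)
    if len(assembly) and (assembly.min() < 0 or assembly.max() >= arch.n_hidden):
        raise IndexError("assembly indices must address hidden units")
    out = w.copy()
    if len(assembly) == 0:
        return out
    unit_idx = arch.hidden_units.start + assembly  # global unit indices
    # outgoing: hidden receivers <- assembly senders
    out[np.ix_(np.arange(arch.n_hidden), unit_idx)] = 0.0
    # incoming: assembly receivers <- hidden/output senders
    out[np.ix_(assembly, np.arange(arch.hidden_units.start, arch.n_units))] = 0.0
    return out


def weight_change_sign_index(delta_batch: np.ndarray) -> int:
    """count(dw > 0) - count(dw < 0) over one update's weight changes."""
    d = np.asarray(delta_batch, dtype=float)
    return int(np.count_nonzero(d > 0) - np.count_nonzero(d < 0))


def weight_sign_index(w: np.ndarray, mask: ConnectivityMask) -> int:
    """count(w > 0) - count(w < 0) over the allowed hidden-hidden entries."""
    hh = mask.hidden_hidden_flat()
    vals = w[mask.recv[hh], mask.send[hh]]
    return int(np.count_nonzero(vals > 0) - np.count_nonzero(vals < 0))


def contribution_ratio(before: float, after: float) -> float:
    """(before - after) / before; NaN (undefined) when before is 0.

    Undefined ratios are flagged with NaN rather than raised, so they can be
    excluded from ensemble means downstream.
    """
    if before == 0:
        return float("nan")
    return (before - after) / before


def contribution_series(before: np.ndarray, after: np.ndarray) -> pd.DataFrame:
    """Per-checkpoint contribution table from paired success-rate series.

    Columns: ``before``, ``after``, ``contributed`` (= before - after) and
    ``ratio`` (NaN where before is 0).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after series must have equal length")
    contributed = before - after
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(before > 0, contributed / before, np.nan)
    return pd.DataFrame({
        "before": before, "after": after,
        "contributed": contributed, "ratio": ratio,
    })


def rm_anova(ratios: np.ndarray | pd.DataFrame) -> float:
    """One-way repeated-measures ANOVA p-value across cases.

    ``ratios`` is a (subjects x cases) table: one row per seed ensemble, one
    column per test case, each cell the mean contribution ratio of that seed
    under that case within the analysis window.  Subjects are the repeated
    factor's blocks; the factor is the case.  Delegates the F test to
    statsmodels' AnovaRM.
    """
    if isinstance(ratios, pd.DataFrame):
        table = ratios.to_numpy(dtype=float)
        case_labels = list(ratios.columns)
    else:
        table = np.asarray(ratios, dtype=float)
        case_labels = list(range(table.shape[1]))
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 cases")
    if np.isnan(table).any():
        raise ValueError("missing cells in the repeated-measures table")
    n_subj, n_case = table.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subj), n_case),
        "case": np.tile([str(c) for c in case_labels], n_subj),
        "ratio": table.ravel(),
    })
    res = AnovaRM(long, depvar="ratio", subject="subject", within=["case"]).fit()
    return float(res.anova_table["Pr > F"].iloc[0])
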
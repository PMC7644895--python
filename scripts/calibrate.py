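"""Sweep the learning rate and error-scaling constant.

Neither constant is pinned down by the training protocol, so this script
maps how they shape the early dynamics: hand reciprocation across the fov,
the dominance of negative weight changes, and the dive of the hidden-hidden
weight sign index.  Used once to fix the shipped defaults (eta = alpha =
0.1); re-run it to explore other regimes:

    python scripts/calibrate.py --steps 2000 --seeds 0 1 2
"""

from __future__ import annotations

import argparse

import numpy as np
import pandas as pd

from handregard import Geometry, LearningConfig, StimulusValues, protocol
from handregard.network import build_architecture


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--etas", type=float, nargs="+", default=[0.01, 0.1, 1.0])
    ap.add_argument("--alphas", type=float, nargs="+", default=[0.01, 0.1, 1.0])
    ap.add_argument("--steps", type=int, default=2000)
    ap.add_argument("--seeds", type=int, nargs="+", default=[0, 1, 2])
    args = ap.parse_args()

    geometry, stim = Geometry(), StimulusValues()
    arch, mask = build_architecture()
    rows = []
    for eta in args.etas:
        for alpha in args.alphas:
            learn = LearningConfig(eta=eta, alpha=alpha)
            for seed in args.seeds:
                rec = protocol.train(geometry, stim, learn, seed, args.steps,
                                     arch=arch, mask=mask)
                first = rec.delta_sign_index[rec.update_steps <= 1000]
                rows.append({
                    "eta": eta, "alpha": alpha, "seed": seed,
                    "reversals_left":
                        protocol.count_direction_reversals(rec.left_traj[:1000]),
                    "reversals_right":
                        protocol.count_direction_reversals(rec.right_traj[:1000]),
                    "neg_minus_pos_changes":
                        int((first < 0).sum() - (first > 0).sum()),
                    "min_sign_index": int(rec.weight_sign_index.min()),
                    "success_rate": float(rec.success.mean()),
                })
    table = pd.DataFrame(rows)
    summary = (table.groupby(["eta", "alpha"])
               .mean(numeric_only=True).drop(columns="seed"))
    print(summary.to_string(float_format=lambda v: f"{v:8.2f}"))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
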
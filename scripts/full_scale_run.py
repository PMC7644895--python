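"""Full-scale reproduction recipe: ensemble training + contribution ratios.

Trains the network for each seed, saves checkpoints, evaluates every
checkpoint under test cases 1-6 before and after ablating the cell
assembly, and writes contribution-ratio tables plus a repeated-measures
ANOVA (cases 1-5) per analysis window.

At full scale this is a multi-hour/cluster run:

    python scripts/full_scale_run.py --steps 50000000 \
        --checkpoint-interval 1000000 --eval-steps 10000 \
        --seeds 0 1 2 3 4 5 6 7 8 9 --out scratch/full_scale

The flags scale everything down for a desk-scale smoke run, e.g.
``--steps 50000 --checkpoint-interval 10000 --eval-steps 2000 --seeds 0 1``.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from handregard import LearningConfig, protocol
from handregard.assembly_analysis import (
    ablate,
    contribution_series,
    detect_assembly,
    rm_anova,
)
from handregard.config import load_preset, save_checkpoint
from handregard.network import build_architecture


def run_seed(seed, cfg, n_steps, ckpt_interval, eval_steps, threshold,
             arch, mask, out):
    rec = protocol.train(cfg.geometry, cfg.stimulus, cfg.learning, seed,
                         n_steps, checkpoint_interval=ckpt_interval,
                         arch=arch, mask=mask)
    rows = []
    for step in sorted(rec.checkpoints):
        if step == 0:
            continue
        w = rec.checkpoints[step]
        save_checkpoint(out / f"ckpt_seed{seed}_step{step}", w, mask, step)
        activity = protocol.replay_hidden(
            w, cfg.geometry, protocol.CASES[1].stimulus(), cfg.learning,
            seed=seed + 1_000_000, n_steps=min(eval_steps, 1000),
            arch=arch, mask=mask)
        assembly = detect_assembly(activity[-100:].mean(axis=0), threshold)
        w_ablated = ablate(w, assembly, mask)
        for case in range(1, 7):
            before = protocol.evaluate_checkpoint(
                w, case, cfg.geometry, cfg.learning, seed=seed + 2_000_000,
                eval_steps=eval_steps, arch=arch, mask=mask)
            after = protocol.evaluate_checkpoint(
                w_ablated, case, cfg.geometry, cfg.learning,
                seed=seed + 2_000_000, eval_steps=eval_steps,
                arch=arch, mask=mask)
            rows.append({"seed": seed, "step": step, "case": case,
                         "assembly_size": len(assembly),
                         "before": before, "after": after})
    return pd.DataFrame(rows)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--steps", type=int, default=50_000_000)
    ap.add_argument("--checkpoint-interval", type=int, default=1_000_000)
    ap.add_argument("--eval-steps", type=int, default=10_000)
    ap.add_argument("--seeds", type=int, nargs="+", default=list(range(10)))
    ap.add_argument("--anova-window", type=int, default=10_000_000,
                    help="window (in steps) per repeated-measures ANOVA")
    ap.add_argument("--out", type=Path, default=Path("scratch/full_scale"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = load_preset("default")
    arch, mask = cfg.build_network()
    tables = [run_seed(seed, cfg, args.steps, args.checkpoint_interval,
                       args.eval_steps, cfg.assembly_threshold, arch, mask,
                       args.out)
              for seed in args.seeds]
    table = pd.concat(tables, ignore_index=True)
    ratios = contribution_series(table["before"].to_numpy(),
                                 table["after"].to_numpy())
    table = pd.concat([table, ratios[["contributed", "ratio"]]], axis=1)
    table.to_csv(args.out / "contribution_ratios.tsv", sep="\t", index=False)

    # ensemble average per case and checkpoint (undefined ratios excluded)
    ens = (table.groupby(["case", "step"])["ratio"]
           .mean().reset_index())
    ens.to_csv(args.out / "ensemble_ratios.tsv", sep="\t", index=False)
    late = ens[ens["step"] > 4 * args.steps // 5]["ratio"]
    summary = {"mean_contribution_ratio_late": float(late.mean())
               if len(late) else None}

    # repeated-measures ANOVA over cases 1-5 per window
    anova = []
    for w0 in range(0, args.steps, args.anova_window):
        block = table[(table["step"] > w0)
                      & (table["step"] <= w0 + args.anova_window)
                      & (table["case"] <= 5)]
        cell = (block.groupby(["seed", "case"])["ratio"].mean().unstack())
        if cell.dropna().shape[0] >= 2 and cell.shape[1] == 5:
            anova.append({"window_start": w0 + 1,
                          "window_end": w0 + args.anova_window,
                          "p_value": rm_anova(cell.dropna())})
    pd.DataFrame(anova).to_csv(args.out / "anova_per_window.tsv",
                               sep="\t", index=False)
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
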
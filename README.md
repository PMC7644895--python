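# handregard

A simulator of how *hand regard* — the infant behavior of repeatedly
bringing the hands into view around 2–3 months of age — can be learned by a
recurrent neural network, and of how inhibitory weights and cell assemblies
self-organize in the process. It is aimed at computational-neuroscience and
developmental-robotics researchers who want a small, fully reproducible
testbed for feedback-error motor learning, real-time recurrent learning
(RTRL) and lesion-style assembly analysis.

## The model in brief

A 16 × 11 gridworld contains two "hands" and distractor "others"; nested
rectangles define a field of view and its center. A masked three-layer
network (238 inputs → 48 sigmoidal hidden units in two groups of 24 → 8
outputs) closes the loop: visual, proprioceptive and corollary-discharge
inputs come in, four outputs per hand fire moves in ±x/±y. One hidden group
("ownership") receives no corollary discharge; recurrent weights exist only
within each group (1,152 hidden-hidden weights, self-loops included).

Learning is RTRL driven by a feedback error measured proprioceptively:
for each hand, e_{+x} = α(rx − x), e_{−x} = −e_{+x} (likewise for y), with
(rx, ry) the fov-center reference. Sensitivities follow

    p_ij^k(t) = σ'(s_k(t)) ( δ_ik z_j(t−1) + Σ_{l∈H∪O} w_kl p_ij^l(t−1) )

and weights change by Δw_ij = η Σ_{k∈O} e_k p_ij^k, accumulated and applied
every 10 steps. Analyses include weight-sign indices over the recurrent
weights, cell-assembly detection (hidden output ≥ 0.9), assembly ablation,
the contribution ratio (rate before − rate after)/rate before, and a
repeated-measures ANOVA across stimulus cases. See `docs/methods.md` for
the full account.

## Worked example

Train for 10,000 steps under the default condition and inspect the early
dynamics:

```python
import numpy as np
from handregard import Geometry, LearningConfig, StimulusValues, protocol

rec = protocol.train(Geometry(), StimulusValues(), LearningConfig(),
                     seed=0, n_steps=10_000)
first = rec.delta_sign_index[rec.update_steps <= 1000]
print("negative-dominant updates in first 1k steps:",
      int((first < 0).sum()), "vs positive:", int((first > 0).sum()))
print("min hidden-hidden sign index:", rec.weight_sign_index.min())
print("late success rate:", rec.success[-2000:].mean())
```

prints

```
negative-dominant updates in first 1k steps: 83 vs positive: 13
min hidden-hidden sign index: -990
late success rate: 0.799
```

i.e. trial-and-error reciprocation of the hands across the field of view
makes weight changes predominantly negative, the balance of the 1,152
recurrent weights dives deep into inhibition (here −990), and by the end of
the run a hand occupies the fov center on ~80 % of steps while learning is
active. The same pipeline is scriptable from the shell:

```bash
handregard train --preset default --seed 0 --steps 10000 --out results/
handregard test  --preset case6 --checkpoint results/ckpt_seed0_step10000 --case 6
handregard ablate --checkpoint results/ckpt_seed0_step10000 --out results/
```

The full-scale experiment (10 seeds × 5×10⁷ steps, checkpoints
every 10⁶ steps, contribution ratios per case and ANOVA per 10⁷-step
window) is a multi-hour run; `scripts/full_scale_run.py` implements it with
flags to scale every dimension down.

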
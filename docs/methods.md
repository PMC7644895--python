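# Methods

## The model

`handregard` simulates the developmental learning of *hand regard* — an
infant repeatedly bringing its hands into view — as a closed sensorimotor
loop between a 2D gridworld and a masked three-layer recurrent network.

**World.** The workspace is a `width × height` grid of cells (default
16 × 11) holding a left hand, a right hand and `n_others` distractor
objects. Two nested axis-aligned rectangles define the field of view (fov,
default the central 8 × 7 block) and its center (fov_center, default the
central 2 × 2 block). A time step is a *success* when at least one hand
occupies the fov center; the *success rate* of a window is the fraction of
successful steps. Others take uniform random steps in {stay, ±x, ±y}; during
the test phase they are confined to the fov (moves that would exit are
rejected). Hands move one cell per fired direction: each hand owns four
output units (+x, −x, +y, −y), a direction fires when its output exceeds
`move_threshold` (default 0.5), opposing fired directions cancel, and
positions are clamped to the workspace.

**Input coding (238 units by default).** Three concatenated blocks:

* *visual* — one unit per workspace cell (16 × 11 = 176); a unit carries the
  visual value of objects on its cell only when the cell lies inside the
  fov (hands 0.5, others 0.2 by default; maximum when objects share a
  cell, keeping inputs in [0, 1]);
* *proprioceptive* — per hand, a one-hot place code of x (16) and of y (11),
  54 units total;
* *corollary discharge* — the previous step's 8 motor outputs, passed
  through an identity forward model.

The block sizes are fully configurable and validated at load time; the
defaults are the one integral decomposition of 238 consistent with the
three input kinds on this grid. The place-code choice for proprioception
keeps every input bounded; an analog two-unit coordinate code would work
but mixes magnitudes.

**Network.** 48 sigmoidal hidden units in two groups of 24 — an *ownership*
group that receives no corollary-discharge inputs and an *agency* group that
receives everything — project to 8 sigmoidal output units. Recurrent
hidden-hidden connections exist only within each group, self-loops included
(24² + 24² = 1,152 weights); hidden→output is full (384). There are no
biases, no input→output shortcuts and no output feedback weights. The
connectivity mask, not the generic net-input formula, is authoritative:
masked-out weights are structurally absent and stay exactly zero through
learning. Unit dynamics are synchronous:
`y_i(t+1) = σ(Σ_j w_ij z_j(t))` with `z` the concatenation of the current
input vector and the previous hidden/output activations. Hidden and output
activations start at 0.5, the fixed point of the zero-weight dynamics (the
starting activation is not prescribed by the protocol; 0.5 is the neutral
choice and is configurable).

**Learning.** Weights are initialized i.i.d. uniform on [−0.1, 0.1] over
the mask. The teacher is a feedback error computed from proprioception
alone: for a hand at (x, y) and the fov-center centroid (rx, ry),

    e_{+x} = α (rx − x),  e_{−x} = −e_{+x},   e_{±y} analogous,

so a positive error always asks the output pointing toward the center to
grow; a hand on the center has zero error, and crossing the center flips
all signs. RTRL sensitivities `p_ij^k = ∂y_k/∂w_ij` follow the forward
recursion

    p_ij^k(t) = σ'(s_k(t)) ( δ_ik z_j(t−1) + Σ_{l∈H∪O} w_kl p_ij^l(t−1) ),

carried for every hidden and output unit k (the recursion needs hidden k);
only the output rows enter the increment
`Δw_ij(t) = η Σ_{k∈O} e_k(t) p_ij^k(t)`. Increments are accumulated and
applied every `update_interval` = 10 steps; sensitivities are *not* reset at
update boundaries (continuous-recursion reading; resetting would discard
the recurrent credit assignment the rule exists for). No weight decay, no
clipping, no momentum.

**Timing convention.** Inputs sensed at t → activations computed for t+1 →
motor outputs at t+1 move the hands → others step → the error is measured at
the post-move positions → the increment uses the sensitivities of the same
forward step. The corollary discharge of the outputs at t enters the input
at t+1.

## Constants η and α

The learning rate η and the displacement-to-error scaling α are the two
constants the protocol leaves open. They were fixed once with
`scripts/calibrate.py`, which sweeps both over {0.01, 0.1, 1.0} and scores
the early dynamics. At η = α = 0.1 every probed seed shows the expected
regime within the first 1,000 steps: hands reciprocate across the fov
(tens of direction reversals), negative hidden-hidden weight changes
outnumber positive ones roughly 6:1, and the hidden-hidden sign index
(positive-count − negative-count over the 1,152 recurrent weights) dives
toward ≈ −1,000 within 10⁴ steps. Smaller values slow everything
proportionally; larger values saturate units early. The defaults ship in
the `default` preset and are ordinary config fields.

Each hand's error occupies its own four outputs, so both hands carry
nonzero error simultaneously whenever both are off-center; the error for a
direction and its opposite are exact negatives by construction, which makes
the sign convention self-checking (a test asserts that updates increase the
net drive toward the center for a hand held off-center).

## Analyses

* **Sign indices.** Per update, index 1 = count(Δw > 0) − count(Δw < 0) over
  the hidden-hidden increments; over the whole run, index 2 = count(w > 0) −
  count(w < 0) over the 1,152 hidden-hidden weights. Exact zeros count in
  neither tally. Both are logged online during training and reproducible
  offline from checkpoints.
* **Cell-assembly detection.** A cell assembly is the set of hidden units
  whose output activity is ≥ 0.9 at a checkpoint. The activity snapshot is
  the mean hidden output over the final 100 steps of a frozen-weights replay
  under case-1 stimulation (the averaging window is not prescribed; an
  instantaneous snapshot is noisier but gives the same members once units
  saturate near 1).
* **Ablation.** For assembly set A: `w_ij ← 0` for hidden receivers i and
  senders j ∈ A, and `w_ij ← 0` for receivers i ∈ A and hidden/output
  senders j. Input→assembly and assembly→output weights are deliberately
  untouched — the operation removes the assembly's recurrent coupling, per
  its defining equations. Ablation is idempotent, never creates nonzeros,
  and never mutates its input.
* **Contribution ratio.** (rate before − rate after) / rate before, per
  checkpoint and case; undefined (NaN) when the before-rate is 0, and such
  cells are excluded from ensemble means with a visible NaN count.
* **Repeated-measures ANOVA.** Per analysis window (10⁷ steps at full
  scale), a one-way repeated-measures ANOVA across cases 1–5 with the
  seed-ensembles as subjects; the F test is delegated to statsmodels'
  `AnovaRM` and cross-checked in the tests against a direct sums-of-squares
  decomposition. Strictly identical columns make F = 0/0; callers should
  expect a defined p only when there is any within-cell variance.

## Reproducibility

All randomness flows from three named streams spawned from one root seed
(weight init, initial placement, others' motion), so identical
(config, seed) pairs give bit-identical runs and changing the world's
composition does not perturb the initial weights. Checkpoints are `.npz`
array containers with a JSON manifest (architecture sizes, step counter,
SHA-256 of the array file, verified on load).

## Scales used in the shipped tests and acceptance script

Training to the full developmental horizon (10 seeds × 5×10⁷ steps, checkpoints
every 10⁶ steps) is the package's full-scale recipe
(`scripts/full_scale_run.py`); the ensemble contribution ratio settles near
a constant only after ~4×10⁷ steps, once assemblies (first appearing around
2×10⁶ steps) have reorganized repeatedly. The shipped test suite and
`scripts/acceptance.py` instead verify the early-phase claims at a desk
scale chosen as 5 seeds × 10⁴ steps: negative-change dominance in the first
1,000 steps, the sign-index dive below zero within 10⁴ steps, and hand
reciprocation. At this scale no assembly has formed yet and frozen
checkpoints hold no stored competence (the closed loop's early success is
carried by the ongoing error-driven updates), so passing tests demonstrate
the mechanism of inhibitory-weight generation, not the end-state memory
content; the latter requires the full-scale recipe.

## Known limitations

* The 238-input decomposition and the fov/fov_center sizes are a documented
  reconstruction (the protocol states only the total); all are configurable.
* The forward model is the identity; no arm kinematics, coordinate
  transformations, tactile input, ATNR asymmetry or LTD-style
  depression are modeled, so late-phase saturation of the assemblies is
  expected at full scale rather than avoided.
* The random-walk "others" have no collision model and may overlap hands.
* Success counts either hand in the fov center; a per-hand variant is a
  one-line change in `protocol.success_rate`.
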
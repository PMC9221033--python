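# Methods

## Problem and model

`condasp` assigns one of the eight DSSP secondary-structure states — G
(3₁₀ helix), H (α-helix), I (π-helix), E (β-strand), B (β-bridge), T
(β-turn), S (high-curvature loop), L (other/coil) — to every residue of a
protein sequence (Q8 prediction). Two properties of the problem shape the
architecture. First, secondary structure is strongly run-structured:
adjacent residues usually share a label, so the task resembles semantic
segmentation of a 1D signal more than independent per-position
classification. Second, every position needs its own label, so the network
never pools or strides: all convolutions are stride-1 and "same"-padded.

The model has three parts:

1. **CondGCNN encoder.** A window-1 projection takes the 42-dim residue
   features to `node_size` channels, followed by M residual blocks of two
   conditionally parameterized gated convolution layers each. A layer
   computes `V = CondConv(X) ⊗ σ(Conv_g(X))`: a gated convolution whose
   content branch uses a kernel mixed per protein from `n` experts,
   `W_cond = Σᵢ αᵢ Wᵢ`, with routing weights
   `α = σ(GlobalAveragePool(X) · R)` (the pool runs over sequence
   positions; routing is per example, per layer).
2. **bLSTM encoder.** N stacked bidirectional LSTM layers (standard cell:
   `c_t = f⊗c_{t−1} + i⊗g`, `h_t = o⊗tanh c_t`), concatenating the two
   directions to width 2H per position.
3. **ASP generation module.** The two encodings are concatenated
   (width `node_size + 2H`) and fed through four parallel length-preserving
   branches — a window-1 convolution and width-3 dilated convolutions at
   rates 2, 4, 8, each ReLU-activated — whose outputs are concatenated with
   a skip copy of the input. A dilated kernel samples taps r positions
   apart (`y[i] = Σₖ x[i + r(k−(K−1)/2)]·w[k]`), so rate r buys a 2r+1
   field of view at constant cost; rate 1 is the standard convolution. The
   output head is window-1 convolution to 100 channels, ReLU, window-1
   convolution to 8 logits (a single-stage head is available via
   `head_hidden=None`).

Training minimizes masked cross-entropy with Adam under a multi-step
schedule: initial LR 0.001, multiplied by 0.1 at each milestone epoch
(defaults 30 and 50 of 60). After every epoch the per-protein mean Q8 on
the validation split is computed; the parameters kept are those of the best
validation epoch.

Default hyper-parameters (`EnsembleConfig`/`TrainConfig`/`RunConfig`): 32
CondGCNN blocks, node size 64, 3 experts; 2 bLSTM layers, hidden 512; ASP
node size 100 at rates (2, 4, 8); window-1 conv head; dropout 0.2;
batch size 16.

## Input features

Each residue is a 42-vector: a 21-wide one-hot block over the amino-acid
alphabet `ACDEFGHIKLMNPQRSTVWY` + `X` (unknown; ambiguous codes B, Z, U, O,
J fold into `X` with a warning), concatenated with the 21 PSSM columns.
PSSM scores are consumed raw by default; an opt-in logistic transform
(`1/(1+e^{−s})`) is available since profile scores are sometimes
sigmoid-squashed before use. The alphabet order and the label order
`GHIEBTSL` (class indices 0–7) are frozen for reproducibility.

## Numeric core

No GPU tensor framework is used: the models run on the package's own
reverse-mode autodiff tape (`condasp.autograd`) over float64 NumPy arrays,
with convolutions as im2col + matmul and the LSTM input projection hoisted
out of the recurrence. Double precision makes the finite-difference
gradient checks in the test suite sharp (relative error tolerance 1e−3 at
step 1e−5; observed errors are orders of magnitude smaller). Adam uses
β=(0.9, 0.999), ε=1e−8.

Initialization: fan-in-scaled uniform for weight kernels, zeros for biases
(except LSTM forget-gate biases at 1, standard practice so early training
does not erase the cell state), zeros for routing matrices so training
starts at the symmetric routing point α = 0.5. All initialization,
shuffling, and dropout randomness derives from one root seed via
`SeedSequence` spawning; evaluation mode is bit-deterministic, and the same
seed reproduces identical loss curves.

Numerical/edge choices: softmax and the HMM forward–backward recursions run
in shifted/log space; argmax ties (uniform logits) break toward the lowest
class index, i.e. `G`; a loss mask selecting no positions, an empty
sequence, and an evaluation set without boundary residues are explicit
errors rather than silent 0/1 results; batches of variable-length proteins
weight per-protein losses by residue count, which equals pad-to-max
batching with a loss mask.

Two printed-formula ambiguities are resolved behind flags rather than
silently: the LSTM cell variant that squashes the cell update through a
sigmoid (bounding c in (0,1)) is available as `paper_literal_cell=True` but
off by default, and the offset-form dilated convolution is implemented in
centered form so outputs align with input positions (the two differ only by
an index shift, and residue-wise labeling requires alignment).

## Synthetic generator and the Bayes ceiling

Real labeled data requires PDB structures, DSSP labeling, and
database-search PSSMs. For desk-scale validation the package generates
proteins from an HMM chosen to reproduce the one structural property the
architecture targets: long same-label runs. Labels follow a first-order
Markov chain over the 8 states with constant self-transition `p_stay`
(geometric run lengths, mean `1/(1−p_stay)`); residues are drawn from
state-conditional emission distributions; the pseudo-PSSM row at position i
is the true state's log-emission profile plus i.i.d. Gaussian noise (sd
`pssm_noise_sd`), truncating log(0) at −12 in the degenerate deterministic
case.

Defaults (`default_spec`): p_stay = 0.85 (mean run ≈ 6.7 residues, the
scale of real helix/strand runs), off-diagonal transition mass proportional
to typical PDB-derived state frequencies (helix-heavy, π-helix rare),
emission rows from Dirichlet(0.3), lengths 50–200, pssm_noise_sd = 1.0,
seed 7. The `strong_signal_spec` preset used for generalization studies
gives each state a distinct modal residue at probability 0.9 and
pssm_noise_sd = 2.0 against log-emission contrasts of ≈5 — informative but
deliberately not an oracle, so per-position evidence stays ambiguous and
context matters, which is what makes boundary residues intrinsically harder
here, as they are in real data.

Because the generator is an HMM, exact smoothing posteriors are available:
`posterior_decode` (log-space forward–backward) is the Bayes-optimal
per-position decoder given the sequence alone, and `bayes_q8` is the
corresponding accuracy ceiling. A trained model is judged against this
ceiling rather than against an arbitrary threshold. Note the model also
sees the pseudo-PSSM, which carries information beyond the sequence, so
slightly exceeding the sequence-only ceiling is possible and not an error.

What the generator does *not* emulate: nonlocal β-pairing constraints,
DSSP's geometric label semantics, realistic amino-acid composition beyond
state-conditional frequencies, and database-profile correlation structure.
Passing the synthetic suites therefore demonstrates that the architecture,
optimization, and metrics are implemented correctly and can extract a
run-structured sequence→structure signal up to its information-theoretic
limit — not that the defaults reach any particular accuracy on real
proteins.

## Study sizes

Desk-scale experiments use a scaled-down ensemble (2 blocks, node 16,
1 bLSTM layer hidden 32, ASP node 32) chosen so the complete test suite and
the acceptance script each run in a couple of minutes on one CPU core:

- capacity/overfit: 20 training proteins of length 50, default schedule
  (60 epochs, LR 0.001, milestones 30/50);
- generalization: 60 strong-signal proteins (36 train / 12 valid / 12
  test), 20 epochs at LR 0.003 with one ×0.1 decay at epoch 15, three
  seeds, all evaluated on a common 200-protein held-out set (~15k
  residues, ~3.6k boundary residues).

## Known limitations

- Runtime: the NumPy tape is serial and allocation-heavy; the full-size
  default configuration (~20M parameters) is practical for inference and
  small studies, not for dataset-scale training.
- Routing makes the CondGCNN receptive field formally global (the pooled
  routing input sees the whole sequence); locality statements about the
  convolutional stack hold with routing fixed, and the locality tests pin
  the routing matrices to zero for exactly this reason.
- The boundary-Q8 statistic requires at least one boundary residue in the
  truth; single-state proteins are rejected rather than scored.
- Metrics are reported both residue-pooled and per-protein (mean ± sample
  sd, ddof = 1); published test-set tables conventionally use the
  per-protein form, and the two differ when lengths vary.
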
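# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not demonstrate.

## Architecture

### Directed message passing

Hidden states live on *directed* bonds: each chemical bond u–v yields two
directed bonds u→v and v→u with identical bond features, each holding the
index of its reverse. The message into bond v→w sums the hidden states of
directed bonds *entering* v, excluding the reverse bond w→v:

```
m_vw = ( Σ_{(k→v)} h_kv ) − h_wv
```

computed vectorized as a scatter-sum over bond targets followed by a
gather and a reverse-bond subtraction. Some presentations of this
architecture write the summand's subscripts with the bond direction
flipped; this package follows the incoming-bond convention of the directed
message-passing encoder family, which is the interpretation consistent
with "directed" message flow, and the test suite pins the semantics with a
hand-worked 3-atom fixture and a loop-based re-derivation.

Update depth: exactly `T` update steps are applied after bond
initialization (default `T = 3`), each computing
`h_vw = τ(h⁰_vw + W_m · m_vw)` with the skip from the *initial* state h⁰.
τ is ReLU throughout the encoder; the configurable activation (Beaf by
default) applies only where the architecture calls for a generic
nonlinearity (the MoleFFN and the transformer MLP). A `tau` config key
allows overriding the encoder activation for ablations.

Readout: per-atom states are `h_v = τ(W_a · cat(x_v, m_v))` with
`m_v = Σ_{(w→v)} h_wv`; the molecule vector is the *sum* over atoms
(`aggregation: mean` optional). The readout function applied on top of
the atom sum is the identity — the sum already aggregates, and any
further map can be absorbed by the following layers.

`W_i` and `W_m` carry no bias, `W_a` and the feed-forward linears do
(both flags config-exposed), matching the convention of the encoder
family this block follows.

### Batch normalization and the residual

Molecule vectors are batch-normalized per feature: train mode uses batch
mean and population variance and updates running estimates (momentum 0.1,
ε = 1e−5); eval mode uses the running estimates. Train mode requires
batch size ≥ 2 (the loop silently skips a trailing batch of one). The
residual skip carries the *pre-normalization* vector y:

```
Y_R = y ⊕ MoleFFN(BN(y)) ,   ⊕ = elementwise addition
```

so the main path is BN → FFN and the skip is y itself. The alternative
(skipping from the normalized Y_D) is a coherent design but is not what
the architecture diagram shows, and is not implemented. ⊕ is addition,
not concatenation — which is why the FFN's output width must equal the
hidden width, enforced at construction.

MoleFFN is exactly five layers: linear → activation → dropout → linear →
dropout (dropout rate 0.1 default, identity at eval).

### Two-head attention over molecules

The transformer treats each molecule's encoder vector as one token and
attends *across molecules of the processing set*. Rationale for two
heads: the token matrix has only two axes (molecules × features), and one
head per axis-halving gives each head an independent h/2-dimensional
subspace. q, k, v are formed by shared h×h maps without bias, split
column-wise in half; each head applies `softmax(q·kᵀ/√(h/2))·v` row-wise;
the concatenation is re-mixed by `W_o`, preserving the token width. Head
count is a config integer for ablation, but 2 is the architecture's
stated choice and the default.

Consequences of attention-over-molecules, handled explicitly:

- **Training** uses a fixed batch size with seeded shuffling, so the
  attention context is a random draw each step.
- **Evaluation** defaults to processing each molecule alone. With one
  token the softmax weight is exactly 1 and attention degenerates to
  `Y_DH = v·W_o`; the implementation uses this closed form, and a test
  verifies it equals looping molecules one at a time. This makes
  predictions batch-composition independent and deterministic. Batched
  context (`context="batch"`) reproduces attention mixing at evaluation
  for experiments; the two modes genuinely differ, and the overfit test
  shows the gap: a model that memorized its training batch attains RMSE
  ≈ 0.03 in its training context versus ≈ 0.25 in single-molecule
  context on the same molecules.

The block is pre-norm: `Y ⊕ DropPath(Sublayer(LN(Y)))` for both the
attention and MLP sublayers, followed by a final layer norm and the
linear head. The three layer norms carry independent (γ, β) pairs
(sharing them is a possible but non-standard reading). Layer norm is
per-row over features with ε = 1e−5. The MLP expands by a factor of 4
(config) and uses the selected activation. One block by default;
`n_blocks` stacks more.

### DropPath

Standard per-sample stochastic depth: during training each token's
residual branch is zeroed with probability `rate` (default 0.1) and
survivors are scaled by 1/(1−rate), preserving the expectation; at
evaluation it is the identity. A schedule that alternates local and
global branch dropping exists in the literature; it has no published
parameters for this architecture and is out of scope — the rate is the
only knob.

### Beaf

```
f(x) = x · tanh(softplus(x)) − c ,  softplus(x) = ln(1 + eˣ)
```

Softplus is computed as `max(x, 0) + log1p(e^{−|x|})`, exact in real
arithmetic and overflow-free to |x| = 1e4 (the naive `ln(1+eˣ)` overflows
near x ≈ 710). The shift c is a fixed hyperparameter in (0, 0.004],
default 0.002, validated at construction — it is not learned. Gradients
come from reverse-mode automatic differentiation of the smooth composite
(softplus's derivative is the logistic sigmoid); no custom derivative or
clamping is used anywhere. The tests compare values against a 50-digit
mpmath reference (max deviation ~4e−15 over [−30, 30]) and the gradient
against a finite difference of that reference.

## Numerical and infrastructure choices

- **Autodiff engine.** The package implements a small tape-based
  reverse-mode engine over float64 NumPy arrays (broadcasting arithmetic,
  matmul, reductions, row gather/scatter for the graph sums, column
  slicing, concatenation, the smooth nonlinearities). Gradients of every
  primitive are checked against central finite differences; the message
  passing relies on gather/scatter adjointness (gather's backward is
  scatter-add and vice versa).
- **Softmax stability.** Row max is subtracted as a detached constant
  before exponentiation; softmax is shift-invariant so the forward value
  and the gradient are unchanged.
- **BCE with logits** is computed as `softplus(z) − t·z`, the stable
  closed form.
- **Initialization.** Glorot-uniform for all weight matrices, zeros for
  biases, ones/zeros for normalization scales/shifts, all drawn from one
  seeded generator per model.
- **Optimizer.** Adam (β = 0.9/0.999, ε = 1e−8), constant learning rate
  1e−3, 30 epochs, batch 50 by default. These training hyperparameters
  are not dictated by the architecture; they are conventional defaults,
  fully config-exposed and logged.
- **Model selection** keeps the checkpoint (weights + batch-norm running
  stats) with the best validation metric; without a validation split the
  final parameters are kept. A non-finite loss raises immediately with
  step diagnostics rather than continuing.
- **Splits.** 8:1:1 with train = round(0.8n), valid = round(0.1n), test =
  the remainder (guaranteeing exhaustiveness on awkward n). The scaffold
  split groups molecules by canonical Bemis–Murcko scaffold
  (chirality-stripped by default, flag provided; acyclic molecules share
  the empty scaffold), sorts groups largest-first and assigns each to the
  first partition whose quota is unfilled, train first; the seed only
  shuffles the order of equal-size groups. One scaffold never spans
  partitions, so valid/test may deviate from exact 10% when groups are
  coarse.
- **Feature scheme.** Atom: one-hot element (1–100 + other), total degree
  0–5, formal charge −2…2, chiral tag, attached-H count 0–4,
  hybridization, aromaticity, mass/100 (d_atom = 133). Bond: null flag,
  type one-hot, conjugation, ring membership, stereo one-hot
  (d_bond = 14). Hydrogens are implicit. The scheme is pluggable; a
  scalar scheme (x_v = e_vw = [1]) backs the hand-worked fixtures.
- **Metrics.** RMSE; ROC-AUC as the Mann–Whitney statistic with half-tie
  credit; PRC-AUC by step-wise average-precision summation
  Σ(R_i − R_{i−1})·P_i rather than trapezoidal interpolation, which is
  optimistic for precision–recall. Multi-task metrics average over tasks,
  skipping (with a warning) tasks undefined on the evaluated labels;
  metric-per-task-type is validated (no RMSE for classification).

## Synthetic benchmark: what it shows

The generator assembles SMILES from a fixed fragment grammar (benzene,
pyridine, cyclohexane, piperidine cores; alkyl chains; halogen/alcohol/
amine/carboxyl terminals), guaranteeing chemical validity and, for n ≥ 9,
at least three distinct Murcko scaffolds (the first draws cycle through
the core list). Regression targets are 0.1·(heavy atoms) +
0.5·(aromatic rings) + Gaussian noise (σ = 0.1 default, giving roughly a
5:1 signal-to-noise ratio against a target spread of ≈ 0.5);
classification labels threshold per-task seeded linear signals at a
quantile (median by default), with independent label missingness.

Because the target is a deterministic function of graph-computable
descriptors, learnability is guaranteed in principle: a model that fails
to beat the mean predictor indicates an implementation bug, not an
impossible task. Conversely, passing these tests shows the pipeline is
*correct and trainable*, not that it matches published benchmark accuracy
on real data: the grammar spans a far narrower chemistry than curated
benchmark sets, the targets are additive in two descriptors (much easier
than lipophilicity or binding affinity), and the problem sizes (16–200
molecules, hidden width 16–64, tens of epochs) are chosen as compact
demonstrations of the properties under test. Full-scale benchmark CSVs
can be consumed through the same `read_dataset` / CLI path.

## Known limitations

- No positional information exists over molecule tokens (none is
  meaningful), and no attention masking is implemented.
- The activation-comparison harness makes no claim that orderings
  observed on the synthetic task transfer to real benchmarks.
- Single-molecule evaluation is the deterministic default; batched
  context changes predictions by design, and which convention external
  results use is generally unstated.
- 3D conformers, reaction SMILES, and protein–ligand structural inputs
  are out of scope; affinity data is consumed as SMILES + value tables.
- The NumPy engine targets clarity and exactness (float64, no GPU); it is
  suitable for datasets up to the tens of thousands of molecules, not for
  million-molecule screens.
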
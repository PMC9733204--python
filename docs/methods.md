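# Methods

## Model

The generator is a conditional VAE over tokenized SMILES. A SMILES string is
wrapped in start/end delimiters (`<` … `>`) and tokenized character-wise,
except that the two-character halogens `Cl`/`Br` and bracket atoms
(`[nH]`, `[O-]`, …) are single tokens. The condition vector
c = (molecular weight [Da], Crippen LogP, TPSA [Å²]) is computed with RDKit
and z-scored with training-corpus statistics before it enters the network;
the raw scales (hundreds of Da vs. unitless LogP) would otherwise dominate
the embeddings. The scaling statistics are stored in the checkpoint.

**Encoder.** Each of `num_layers` recurrent layers is a stack-augmented
cell: an external stack of `stack_depth` rows, each a `stack_width`-vector,
updated as a convex combination of the three discrete pushdown outcomes
(PUSH / POP / NO-OP) weighted by `softmax(A h_t)`. The pushed value is
`σ(D h_t)` (so `D` is `stack_width × hidden`; stack elements are
width-k vectors, consistent with the read matrix `P` being
`hidden × stack_width`). The hidden update reads only the stack top:
`h_t = σ(U x_t + R h_{t−1} + P s_{t−1}[0])`. The stack has fixed depth —
PUSH discards the bottom row, POP zero-fills it — which makes batching
straightforward; depth is configurable. Each layer owns its own stack;
layer *l* receives layer *l−1*'s hidden state as input. Initial hidden and
stack states are zero and reset per sequence. Within one step the hidden
state is computed from the *previous* stack, then the stack is updated from
the *new* hidden state. With `use_stack=False` the `P s` term and the stack
update are skipped, giving the plain recurrent baseline used for ablation.

The final top-layer hidden state maps linearly to the posterior mean and
log-variance. The prior is N(0, I), independent of c: generation draws
z ~ N(0, 1) unconditionally, and no conditional-prior form is imposed.

**Decoder.** A `num_layers` GRU; every step receives
[token embedding, z, c] (condition and latent are repeated at each step
rather than only initializing the hidden state — a per-step input keeps the
conditioning signal available at arbitrary depths of generation). A linear
layer plus softmax yields the next-token distribution. Training uses
teacher forcing; generation samples from the softmax (no argmax, no beam
search) until `>` or `max_len` tokens.

**Objective.** Reconstruction is summed token-wise cross-entropy; the KL
term is the closed-form Gaussian divergence from N(0, I), weight 1, no
annealing (an optional `kl_weight` knob exists, default 1). Optimizer is
Adam, default learning rate 1e-3, batch 64. Padded positions are masked out
of both the loss and the recurrences, so padding never changes a posterior.

## Reinforcement learning

The decoder is the policy; an episode draws z ~ N(0, I), samples a SMILES
under the reference drug's standardized condition vector, and receives a
terminal reward; intermediate rewards are zero. The per-step return is
G_t = R·γ^(T−1−t) over the T interior tokens (T excludes the delimiters),
i.e. the terminal reward attenuated geometrically toward earlier steps with
discount rate γ = 0.1. A flat multiplication of every step by the constant
0.1 would only rescale the learning rate, which cannot be what a discount
rate is for; the geometric form is the standard return of a terminal-reward
episode. The loss is −Σₜ log(yₜ)·G_t, where yₜ is the probability the
policy assigned to the chosen token. Sampling records those probabilities
from the full softmax (no token is excluded), so the recorded yₜ equals the
teacher-forced recomputation exactly — the gradient step re-runs the decoder
over the sampled tokens in a batched differentiable pass.

Only decoder parameters (GRU layers and output head) are updated; the
encoder is unused once z comes from the prior, and the shared token
embedding is kept frozen so the update set is exactly the decoder. There is
no baseline/variance-reduction term by default (an optional moving-average
baseline exists, default off). Episodes per epoch default to 32.

A sampled string that fails to parse — including one that emits a stray
delimiter or padding token — receives every reward component at its minimum
(total 3). This keeps the loss finite while penalizing invalidity relative
to any valid molecule that clears a threshold. An empty generation has
T = 0: its reward is recorded but contributes no gradient.

## Rewards and oracles

The three components and their thresholds (5 strict for on-target, 5.5 for
off-target, on a DeepPurpose-style predicted-affinity scale) are implemented
literally; thresholds are exposed as arguments with these defaults.
RAscore is accepted as a continuous value in [0, 1] and the synthesizability
rule applied as written (`5·RAscore + 1` for nonzero scores); a strictly
binary score is a special case. Affinities over a protein panel are
arithmetically averaged.

Real predictors are deliberately out of scope: any callable
`(smiles, protein) → affinity` / `smiles → rascore` can be registered. The
packaged mock oracles are deterministic, structure-dependent functions —
affinity = 3 + 4·(nitrogen fraction) + per-protein hash offset in
[−0.5, 0.5]; RAscore = logistic in heavy-atom count centred at 20 atoms —
chosen to be bounded, reproducible, and monotone in interpretable features
so the RL loop has a smooth signal to climb. They emulate nothing about real
binding physics; a passing directional-learning test shows the optimization
machinery works, not that the generated molecules would bind Raf kinases.

## Synthetic corpus

`generate_toy_corpus` assembles 3–7 fragments from a fixed grammar (alkyl
chains, benzene/pyridine/cyclohexane/piperidine rings, amide and ester
linkers, optional terminal halogen or heteroatom). Every fragment starts and
ends on an atom that accepts one more single bond, so any concatenation
parses — validity holds by construction, not by rejection sampling. At
n = 500, seed 7: 100 % valid, 497 distinct strings, 460 inside the
length < 100 / 150–500 Da training window. The corpus exercises rings,
branches, aromaticity and heteroatoms, but not stereochemistry, charged
species, or the property distribution of a real screening library; results
on it demonstrate the pipeline, not chemistry-scale performance.

## Problem sizes and defaults

`ModelConfig` defaults to the full architecture (3 layers, 512 hidden
units, stack 50×10, latent 128). The test suite and the worked example use
a reduced configuration — 1 layer, 32 hidden units, stack 8×5, latent 16,
learning rate 3e-3, 30 pretraining epochs on the 500-molecule toy corpus,
50 RL epochs of 32 episodes at learning rate 3e-3 — sizes at which the
directional behaviour (falling CVAE loss, rising mean reward) is already
clear and reproducible from a fixed seed. RL learning rates above ~5e-3
destabilize the toy policy; 3e-3 is the documented toy-scale choice.

## Numerical choices

* All arithmetic is float64 on a small reverse-mode autodiff engine;
  gradient correctness is enforced by finite-difference checks (≤ 1e-4
  relative error on the stack cell, ~1e-6 on primitive ops).
* Softmax/log-softmax subtract the (detached) row maximum for stability.
* With one-hot actions the soft stack update is bit-identical to the
  discrete pushdown automaton (0·x + 1·y sums exactly to y for finite
  inputs); this is asserted over seeded random traces at all depths 1–10.
* Min–max scaling for the composite score is computed over the batch being
  scored; a constant column scales to all zeros; ε = 1e-9 guards the
  reciprocal. Ties in top-k ranking break lexicographically on the SMILES
  string for run-to-run stability.
* The composite score's bindA term is implemented exactly as published,
  although as written a *higher* scaled on-target affinity *lowers* the
  score; `corrected_bind_a=True` substitutes 1 − bindA. The literal form is
  the default so reported numbers match the published formula.
* Property windows are inclusive at exactly 10 %; the corpus MW filter is
  inclusive at 150 and 500 Da; the length filter is strict (< 100).
* Uniqueness and novelty compare RDKit-canonical SMILES (structural
  identity); `canonical=False` switches to raw-string comparison.

## Known limitations

* Pure-NumPy training is practical at toy scale only; there is no GPU path,
  no multi-threaded batching, and full-size (512×3) pretraining on millions
  of molecules is out of reach of this implementation.
* The mock oracles are placeholders for real affinity/synthesizability
  predictors; conclusions about binding specificity require plugging in
  trained models through the oracle registry.
* The tokenizer does not handle `%nn` two-digit ring closures as single
  tokens (they tokenize as `%` + digits), stereo markers are plain
  characters, and training corpora are not deduplicated by structure.
* P(z|c) = N(0, I): the conditional information enters only through the
  encoder/decoder inputs, so condition control is soft, not guaranteed.
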
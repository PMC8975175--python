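# Methods

## The alignment decision process

Local alignment extension is modelled as a Markov decision process. The
state at cursor `(x, y)` is the pair of windows `S1[x:x+W]`, `S2[y:y+W]`,
encoded as a `2 × W × 5` array: channels 0–3 one-hot the bases A/C/G/T,
channel 4 marks positions past a sequence end (PAD), and the ambiguity code
N encodes as all-zeros (absence of evidence). PAD gets its own channel
rather than reusing a base channel so the policy can see sequence ends.

Three actions are available. FORWARD consumes one base from each sequence
and emits a match or mismatch column; INSERTION consumes only from the
subject (a gap in the query); DELETION consumes only from the query. The
reward of a step is the scoring-scheme value of the emitted column
(defaults `+1 / −1 / −2` for match/mismatch/gap, linear gap costs — there is
deliberately no affine gap model, since the drop rule and the reward are
defined per column). Summed rewards therefore equal the alignment score of
the emitted columns exactly; this conservation is asserted on thousands of
random episodes. N bases score as mismatches against everything, including
other Ns.

FORWARD advances both cursors by exactly one base — one decision per
alignment column. Coordinates are 0-based half-open everywhere.

## The Q-network

The action-value function is a dueling double DQN over the encoded window
pair (10 input channels × W positions):

* **trunk** — a stack of 1-D convolutions (kernel 3, 'same' padding,
  ReLU), either standard (`standard` variant) or depthwise-then-pointwise
  (`separable` variant, the default); the separable factorization has
  strictly fewer parameters and less per-step arithmetic at the same
  receptive field, which matters because the network runs once per emitted
  column. Then a dense layer to a hidden feature vector.
* **heads** — a scalar state value `V` and a 3-vector advantage `A`,
  combined as `Q = V + A − mean(A)` (the dueling aggregation).
* **training** — ε-greedy behaviour, uniform replay buffer, squared-error
  regression on the double-DQN target `r + γ·Q_target(s', a*)` with `a*`
  the argmax under the main network, Adam with global gradient-norm
  clipping at 10, and a Polyak-averaged target network
  (`θ_t ← τ·θ_m + (1−τ)·θ_t` after every step). A config flag
  (`literal_double_dqn`) instead lets the *target* network pick `a*`,
  matching a literal reading of the training procedure this design descends
  from; the standard decoupling is the default because it is the form with
  established convergence behaviour.

The stack is implemented directly in numpy with hand-written gradients.
With every random draw routed through seeded `numpy.random.Generator`
streams, training is bit-reproducible on a machine — checkpoints and output
tables from two runs with the same root seed are byte-identical, which the
test suite asserts.

Defaults: γ = 0.99, τ = 1e-3, batch 32, buffer 1e5, ε annealed 1.0 → 0.05
linearly over the first half of the inner steps. The learning rate defaults
to 1e-3: with Adam on the small desk-scale architectures below, 1e-4 needs
several times more steps to reach a stable FORWARD-dominant policy, and
1e-3 showed no instability at these scales.

## Mutation simulator

Training environments are simulated ancestor/descendant pairs. The model
has three parameters: per-base substitution probability `p_snp`
(substitutions always change the base, uniformly over the other three, so
`p_snp` is the realized divergence), per-base indel initiation probability
`p_indel` (insertion vs deletion an even coin flip — configurable), and a
Zipfian indel length law `P(l) ∝ l^{−s}` truncated at `max_indel`
(default exponent `s = 1.5`, a heavy-tailed choice consistent with indel
length surveys; the analytic formulas keep `s` symbolic).

Indel initiations are drawn independently per source position, so event
counts are exactly binomial — the χ² fidelity checks (substitution rate,
indel rate, length histogram, all at n = 1e5, α = 0.01) test the sampler
against closed-form expectations with no simulation slack. Every mutated
copy carries an event log that replays exactly from the ancestor; replay
equality is property-tested.

What the simulator does *not* emulate: transition/transversion bias, rate
heterogeneity along the sequence, GC skew, tandem repeats, and N runs.
Tests passing on simulated pairs therefore say nothing about repeat-dense
or biased-composition genomes; the fine-tuning stage exists precisely to
adapt the policy to real-sequence statistics.

## Meta-training

The environment distribution samples `p_snp ~ U[0, 0.3]`,
`p_indel ~ U[0, 0.1]`, `max_indel ~ U{1..10}` independently (all ranges
configurable). Each outer iteration: sample an environment, generate a
training pair and a held-out pair, copy the outer network, train the copy
for `N` inner steps (one ε-greedy action + one replay gradient step per
inner step; episodes hitting a sequence end restart at (0,0) on a fresh
pair from the same environment), then roll the trained copy out *greedily*
on the held-out pair and append that trajectory to the outer buffer.  The
outer network then takes `K = 50` gradient steps sampling from the outer
buffer.  The held-out pair never contributes inner-loop gradients (no
leakage), and the outer update is buffer-based — there is no
second-order/meta-gradient step; the outer loop is a trajectory-aggregation
scheme over the task distribution.

Desk scale: `M = 30` outer iterations, `N = 500` inner steps, 1 kb
sequences, window `W = 10`, channels `(8, 8)`, hidden 32 — about 90 s on
one CPU core. These sizes are the package's CPU-scale defaults for tests
and the acceptance script; larger windows (the aligner's default
`XdropParams.W` is 100) need proportionally more training.

`fine_tune` continues the identical update rule on all unordered pairs of
user-supplied sequences, cycled one episode at a time.

## Extension and the x-drop rule

`dqn_xdrop_extend` implements: while `Score > Best − X` and neither
sequence is exhausted, window → Q-values → argmax action (ties broken
FORWARD > INSERTION > DELETION) → apply, and record `Best`/best-prefix
whenever the score improves. The returned alignment is the best-scoring
prefix. When a sequence end and the drop condition could fire on the same
step, end-termination is recorded. The extender is policy-agnostic —
anything with `q_values(state)` drives it — so deterministic stub policies
(always-forward, forced-gaps-after-p) make every branch testable without
training, and a hand-traced oracle pins the exact stopping step.

The greedy baseline is the classical x-drop extension realized as a pruned
antidiagonal DP with linear gaps: per antidiagonal, cell scores are the
vectorized maximum over the three predecessors, the best cell is tracked,
cells not above `best − X` are dead, and the band shrinks to the outermost
live cells (interior dead cells are masked so they cannot propagate).
`steps` counts evaluated cells. With `X = None` (no pruning) the recursion
is exactly the full-matrix extension DP, and equality with an independently
coded brute-force oracle is asserted on hundreds of random pairs.

Upstream extension reuses the same network on reversed prefixes — no
separately trained upstream model; the decision process is
direction-agnostic, so one policy serves both directions.

## Seeding and assembly

Seeds are exact k-mer matches (default `k = 12`) from a hash of the query's
k-mers probed with the subject's, filtered by an n-hit rule: a hit survives
only if at least `n = 2` hits share its diagonal within `d = 100`
positions; surviving overlapping hits on a diagonal merge into one longer
seed. This replaces a full repeat-miner preprocessing stage with the same
intent (suppress isolated spurious hits) and is deliberately simple.
Seeds are extended longest-first; a seed mostly (≥ 50 %) covered on the
query by an accepted alignment is skipped. Identity is matches divided by
all alignment columns (gaps count); coverage is aligned residues of a
sequence divided by its length.

## Analytic evaluators

The `analysis` module evaluates the package's complexity/error formulas
numerically:

* `step_error_probability` — the Gumbel-statistics bound
  `(p_indel·K·(e^{λg} + ¼e^{λm} + ¾e^{λx}) + 2·p_snp·K·e^{λg}) · W²·e^{−λW·s̄}`
  on the probability that one windowed decision is suboptimal; computed in
  log space so large `W` underflows to 0 rather than overflowing. `K` and
  `λ` default to 0.711/1.33, the commonly tabulated ungapped-DNA values —
  user-replaceable, not calibrated constants. The average per-column score
  `s̄` defaults to `(1−p_snp)·match + p_snp·mismatch`.
* `expected_length_bound` — `X_g^s·ζ(s)/p_indel` with
  `X_g = ⌈X/|score_gap|⌉`: an indel of `X_g` gap columns unconditionally
  trips the drop rule, bounding the expected extension length. The gap
  score is negative; its magnitude is used so `X_g` is a positive count.
* `required_window` — `(s/B)·ln X − (s/B)·ln|score_gap| + α`, the window
  size that keeps the length-compounded error vanishing; `B` and `α` are
  free parameters of the bound, exposed symbolically.
* `zipf_zeta` — Riemann ζ via `scipy.special.zeta`.

The benchmark harness measures complexity with step counts (decision steps
vs DP cells), not wall-clock, because cell/step counts are
hardware-independent observables of the same quantities. Benchmark pairs
are a homologous core (mutated copy, default 10 % divergence) followed by
unrelated random tails, so extensions terminate by x-drop inside the tail;
on pairs that are homologous end-to-end neither extender's work depends on
`X` and the scaling comparison would be vacuous. On this design the greedy
DP's log-log slope of cells vs `X` sits near 2 and the policy extender's
slope near 0.3–0.5 (the `L` term still dominates at small `X`), with the
per-record ratio `steps / (L + 2X)` flat in `X` for the policy.

## Problem sizes and tolerances

Tests and the acceptance script use: 1 kb training sequences, 600 bp
evaluation pairs, 200 oracle pairs ≤ 30 bp, 500 soundness extensions,
1000 conservation episodes, n = 1e5 simulator draws, and
`X ∈ {25, 50, 100, 200, 400}` for scaling. Identity comparison demands the
trained policy reach ≥ 0.9× the greedy baseline's mean identity on 20
held-out 5 %-SNP pairs; at these scales the trained policy routinely ties
the baseline exactly (both walk the pure diagonal). χ² checks use α = 0.01;
float comparisons against high-precision oracles use 1e-12 relative
tolerance; DP-vs-oracle and replay checks are exact.

## Known limitations

* Forward strand only; no reverse-complement search, no translated
  alignment, no chaining into synteny blocks, no E-values.
* Linear gap penalties throughout (a consequence of per-column rewards).
* The seeding stage is quadratic in the worst case on highly repetitive
  sequences (every k-mer occurrence pair becomes a raw hit).
* The policy window defaults used for desk-scale training (`W = 10`) are
  small; policies for distant homology need larger windows and
  correspondingly longer training.
* Training quality is measured on the simulator's mutation model; real
  genomes need the fine-tuning stage, and no claim is made here about
  repeat-rich or strongly biased genomes.
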
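# Methods

## The design loop

`gapdesign` searches chemical space for molecules with an extremal
HOMO–LUMO-gap-like property by alternating four stages: generation
(masked-SMILES mutation of the current population), labeling (oracle
evaluation), selection (rank selection toward the objective plus
error-driven training-data admission), and surrogate retraining. The loop
state is a single integrated database of property records keyed by canonical
SMILES, tagged with the generation that produced each molecule and whether
it feeds surrogate training or only monitoring.

Two properties define a healthy run and are asserted by the acceptance
tests: under minimization the mean gap of successive accepted generations is
non-increasing, and the surrogate retrained each iteration keeps a roughly
flat error across generations while a surrogate frozen at generation 0
degrades on later ones. The second property is the reason the selection
rules exist: without admitting high-error molecules to training, the
surrogate's validity domain is left behind by the moving population.

## Molecule model

Molecules are connectivity graphs parsed from SMILES with RDKit. Hydrogens
are implicit (a per-atom count, never a node), the element set is fixed to
{C, H, N, O, F, S}, net-charged species are rejected by default (the gap
data this models are neutral closed-shell molecules), and stereochemistry is
stripped because every downstream consumer is connectivity-based. Canonical
SMILES is the molecular identity used for all deduplication; a candidate is
valid only if its canonical form survives a re-parse/re-canonicalize round
trip, mirroring the discard of structures whose connectivity changes during
geometry optimization in oracle-driven pipelines.

## Featurization

Each node is an 11-vector: atom-type one-hot over (C, N, O, F, S), atomic
number, aromatic flag, hybridization one-hot over (sp, sp2, sp3), and
hydrogen-neighbor count. The two counts enter unnormalized; an optional
z-scoring switch exists but is off by default, keeping features
interpretable and the layout stable. Each bond contributes two directed
edges carrying a one-hot over (single, double, triple, aromatic). Atoms
whose perceived hybridization falls outside sp/sp2/sp3 (e.g. some
hypervalent sulfur valence states) cannot be mapped onto the layout;
such molecules are skipped and counted rather than silently truncated.
The one-hot orderings are frozen in a versioned layout string checked when
loading checkpoints.

## Surrogate

The regressor is a PNA-style message-passing network: messages are a ReLU
linear map of (sender state, receiver state, edge feature); incoming
messages are aggregated per node with mean, min, max and std, each scaled by
identity, amplification `log(d+1)/δ` and attenuation `δ/log(d+1)` degree
scalers (δ is the mean `log(d+1)` over training nodes); the node update is a
ReLU linear map of the previous state concatenated with the twelve scaled
aggregates. Node states are mean-pooled per graph into a fully connected
ReLU head ending in one scalar.

The production configuration is six message-passing layers of hidden
dimension 55 with a 100/50/25 head, 200 epochs, AdamW at learning rate
1e-3, batch size 32, minimizing mean-squared error on a 90/5/5
train/validation/test split. Pooling operator (mean), loss (MSE), batch size
and weight decay (0.01, decoupled, weights only) are this package's choices
where the architecture family leaves them open. Targets are internally
z-scored against the training split; all reported errors are in eV.

The implementation is pure numpy with hand-derived backpropagation
(validated against central finite differences in the test suite) and is
bitwise deterministic given the seed. Min/max aggregator gradients split
across ties; the std aggregator uses `sqrt(max(var, 0) + 1e-5)` for
numerical stability. Degenerate cases handled explicitly: nodes with no
incoming edges (e.g. methane's single carbon) receive zero aggregates, and a
constant training target disables z-scoring rather than dividing by zero.

The surrogate is retrained from scratch at every iteration (warm starting
exists behind a flag but is off by default, since from-scratch retraining
makes each iteration's model a pure function of its training set). The model
used to screen generation X was trained before generation X existed; the
training-set fingerprint (SHA-256 of the sorted training SMILES) makes this
no-leakage property checkable after the fact.

## Generator

The generator is a training-free masked-mutation sampler standing in for a
pretrained masked language model: tokenize a seed SMILES (bracket atoms and
two-digit ring closures are single tokens; tokenization is lossless), mask a
contiguous span of 1–3 tokens, refill with 0–4 tokens drawn proportionally
to token frequency in the current population. Because the refill may be
longer than the mask, insertions occur and generated molecules can exceed
every seed in size, which is what lets the population escape the seed size
regime. Invalid proposals (syntax, valence, charge, unbalanced ring digits,
round-trip failures) are filtered, not repaired; duplicates against both the
seed set and the batch are dropped. Yield statistics
(proposed/parsed/valid/unique) are reported at every stage, and a proposal
budget (default 200 per requested molecule) turns pathological vocabularies
into an explicit exhaustion error instead of a hang. Property steering is
deliberately absent from the generator — ranking is the selection stage's
job, keeping the two concerns swappable independently.

## Selection

Rule 1a's admission threshold is the maximum absolute error over the
combined train+validation+test data of the screening surrogate (a single
pooled maximum, not per-split). Rule 2's size cut is strict: < 20 heavy
atoms for training admission; everything else that is novel becomes test
data, deliberately unrestricted in size so extrapolation keeps being
measured. Rank selection sorts by oracle value after evaluation (the
surrogate-ranked pre-screen is available as a budget-saving option) with
ties broken lexicographically by canonical SMILES for reproducibility.

Bookkeeping identity, asserted per iteration: the rank-selected generation
count equals new-train + new-test + duplicates + invalid, where invalid
includes oracle failures and feature-layout skips. Candidates dropped by
rank selection are reported separately and never enter the database.

## Toy oracle

`gap = g_min + (g0 − g_min)·exp(−α·Cmax) + δ·f_F` with `Cmax` the largest
connected unsaturated fragment and `f_F` the fluorine fraction of heavy
atoms; defaults g0 = 14 eV, g_min = 0.5 eV, α = 0.25, δ = 8 eV. The
constants were chosen once so that saturated molecules sit near 14 eV,
extended conjugation approaches 0.5 eV, benzene lands at ≈ 3.51 eV, and CF₄
exceeds 20 eV — reproducing the qualitative axes (conjugation lowers the
gap; saturation and fluorination raise it) of gap chemistry in this element
range, while remaining closed-form, connectivity-only and exactly
reproducible. HOMO and LUMO are not modeled separately because every
selection and analysis step consumes only their difference. External
backends plug in through a command-template adapter satisfying the same
evaluate contract; backend failures surface as status codes, never silent
drops, and results are cacheable to CSV keyed by canonical SMILES.

## Synthetic seed populations

The fixture generator assembles molecules from curated fragments (alkyl
chains, 5-/6-membered carbo- and heterocycles, carbonyl, nitrile, fluorine
substituents, and rare strained 3-/4-rings) with rejection sampling on
validity, uniqueness and a 9-heavy-atom cap — emulating the size regime and
functional-group variety of enumerated small-organic databases, not any
specific database's contents. Toy-gap spreads over a 300-molecule population
exceed 15 eV with mass both below 4 eV and above 10 eV, so both objective
directions have headroom. What passing tests on these populations shows: the
loop's selection pressure, bookkeeping and drift dynamics work as designed.
What they do not show: performance on real quantum-chemistry labels, where
oracle noise, geometry-dependent properties, and a far larger chemical space
apply.

## Problem sizes and numerical choices

The desk profile used throughout tests and the acceptance script is 3
message-passing layers, hidden dimension 16, a 32/16 head, 120 epochs, with
300-molecule seed populations, a generation target of 300, 3× oversampling
and 3 iterations — sizes at which every qualitative claim of the loop is
already measurable and a full run completes in well under a minute. The
production-scale configuration (6×55 PNA, 100/50/25 head, 200 epochs,
~10⁵-molecule generations) is retained in the defaults and config surface
but is not exercised by tests.

Master-seed fan-out: each stage of each iteration derives its seed as the
first four bytes of SHA-256 of `"{stage}:{iteration}:{master_seed}"`, modulo
2³¹, so stages are independently reproducible and no two stages share a
stream.

## Known limitations

* The toy oracle is exactly learnable from connectivity, so surrogate MAEs
  here are optimistic relative to real-label regressions; the drift
  *ordering* (frozen worse than retrained on late generations) is the
  transferable observation, not the MAE magnitudes.
* The vocabulary sampler explores less aggressively than a trained language
  model; novelty is local to the seed population's token statistics.
* Aromaticity-ratio and H/C-ratio conventions (all non-aromatic heavy atoms
  in the denominator; NaN sentinel for fully aromatic molecules) are fixed
  choices among several found in the descriptor literature.
* The 2-D chemical-space map applies principal components directly to ECFP
  bits; a learned intermediate embedding would separate clusters more
  sharply but adds a training dependency without changing any tested
  contract.
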
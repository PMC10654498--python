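"""Masked-SMILES mutation generator.

Novel candidates are produced by masking a short contiguous token span of a
seed SMILES and refilling it with tokens sampled in proportion to their
frequency in the current population — a desk-scale, training-free analog of a
masked language model over SMILES.  Because the replacement length may exceed
the masked span, the sampler is insertion-capable and the generated molecules
can be larger than any seed.

Proposals are unconstrained strings; validity (syntax, element set, valence,
neutrality, round-trip canonical stability) is enforced by the downstream
filter in :func:`generate_population`, and candidates with e.g. unbalanced
ring-closure digits are simply rejected there rather than repaired.  Property
steering is deliberately absent here: ranking by property is the selection
stage's job.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .chem import canonical_smiles, parse_smiles, round_trip_stable
from .errors import ExhaustionError, MoleculeError, TokenizeError

#: One token per: bracket atom, two-digit ring closure, atom symbol, ring
#: digit, bond/branch/misc punctuation.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|%\d{2}|[CNOSF]|[cnos]|\d|[()=#/\\\-+.@~])"
)


@dataclass
class SmilesTokenStream:
    """A lossless tokenization: joining ``tokens`` reproduces the source."""

    tokens: list[str]
    source: str

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_smiles(text: str) -> SmilesTokenStream:
    """Split a SMILES string into tokens; bracket atoms are single tokens."""
    if not text:
        raise TokenizeError("empty SMILES string")
    tokens = _TOKEN_RE.findall(text)
    if "".join(tokens) != text:
        leftover = _TOKEN_RE.sub("", text)
        raise TokenizeError(f"unknown characters {leftover!r} in {text!r}")
    return SmilesTokenStream(tokens=tokens, source=text)


def build_vocabulary(population: list[str]) -> Counter:
    """Token frequency table over a population; counts are additive by design."""
    vocab: Counter = Counter()
    for smiles in population:
        vocab.update(tokenize_smiles(smiles).tokens)
    return vocab


@dataclass
class MutationConfig:
    """Masking/refill hyperparameters of the mutation sampler."""

    mask_span_max: int = 3
    proposals_per_seed: int = 10
    replacement_len_range: tuple[int, int] = (0, 4)
    vocabulary: Counter = field(default_factory=Counter)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proposals_per_seed < 1:
            raise ValueError("proposals_per_seed must be >= 1")
        lo, hi = self.replacement_len_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid replacement_len_range")


def mutate(seed_smiles: str, cfg: MutationConfig, rng: np.random.Generator) -> list[str]:
    """Return ``cfg.proposals_per_seed`` raw mutated strings (possibly invalid).

    Each proposal masks a uniformly chosen contiguous span of 1..mask_span_max
    tokens and replaces it with 0..replacement_len_range[1] tokens drawn with
    probability proportional to vocabulary frequency.
    """
    stream = tokenize_smiles(seed_smiles)
    vocab_tokens = sorted(cfg.vocabulary)
    if not vocab_tokens:
        raise ValueError("mutation requires a nonempty vocabulary")
    weights = np.array([cfg.vocabulary[t] for t in vocab_tokens], dtype=float)
    weights /= weights.sum()

    proposals = []
    n = len(stream)
    lo, hi = cfg.replacement_len_range
    for _ in range(cfg.proposals_per_seed):
        span = int(rng.integers(1, min(cfg.mask_span_max, n) + 1))
        start = int(rng.integers(0, n - span + 1))
        fill_len = int(rng.integers(lo, hi + 1))
        fill = [str(t) for t in rng.choice(vocab_tokens, size=fill_len, p=weights)]
        proposals.append("".join(stream.tokens[:start] + fill + stream.tokens[start + span:]))
    return proposals


@dataclass
class GenerationStats:
    """Yield accounting for one generation pass."""

    n_proposed: int = 0
    n_parsed: int = 0
    n_valid: int = 0
    n_unique: int = 0

    def as_dict(self) -> dict:
        return {
            "proposed": self.n_proposed,
            "parsed": self.n_parsed,
            "valid": self.n_valid,
            "unique": self.n_unique,
        }


def generate_population(
    seeds: list[str],
    target_count: int,
    cfg: MutationConfig,
    rng: np.random.Generator,
    max_proposals: int | None = None,
) -> tuple[list[str], GenerationStats]:
    """Generate up to ``target_count`` unique valid novel canonical SMILES.

    Seeds are cycled in shuffled order; every proposal must parse, pass the
    element/valence/neutrality checks, survive the round-trip canonicalization
    filter, and be new with respect to both the seed set and the batch so far.
    Raises :class:`ExhaustionError` when the proposal budget runs out before
    half the target is reached (partial yields above that are returned as-is).
    """
    if not seeds:
        raise ValueError("seeds must be nonempty")
    if max_proposals is None:
        max_proposals = 200 * target_count
    seed_canon = {canonical_smiles(s) for s in seeds}

    stats = GenerationStats()
    out: list[str] = []
    batch_canon: set[str] = set()
    order = np.array(seeds, dtype=object)
    while len(out) < target_count and stats.n_proposed < max_proposals:
        rng.shuffle(order)
        for seed in order:
            if len(out) >= target_count or stats.n_proposed >= max_proposals:
                break
            for text in mutate(str(seed), cfg, rng):
                stats.n_proposed += 1
                if len(out) >= target_count or stats.n_proposed > max_proposals:
                    break
                try:
                    mol = parse_smiles(text)
                except MoleculeError:
                    continue
                stats.n_parsed += 1
                if not round_trip_stable(text):
                    continue
                stats.n_valid += 1
                canon = canonical_smiles(mol)
                if canon in seed_canon or canon in batch_canon:
                    continue
                stats.n_unique += 1
                batch_canon.add(canon)
                out.append(canon)

    if len(out) < max(1, target_count // 2):
        raise ExhaustionError(
            f"proposal budget {max_proposals} exhausted with only "
            f"{len(out)}/{target_count} unique valid molecules"
        )
    return out, stats
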
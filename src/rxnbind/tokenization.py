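"""Tokenization of reaction SMILES and amino-acid sequences.

Two tokenizers cooperate on one reaction record:

* SMILES are tokenized at atom/bond level with the standard regular
  expression used throughout reaction language modelling (bracket atoms,
  two-letter elements, ring-bond digits and stereo markers are single
  tokens).
* Amino-acid sequences are compressed losslessly with a Byte-Pair Encoding
  (BPE) tokenizer trained here from scratch.  Every token carries its
  half-open residue interval so that token-level predictions can be mapped
  back to residue coordinates.

:class:`ReactionEncoder` assembles the joint token sequence
``[CLS] reactants [SEP] enzyme [SEP] products [EOS]`` and records the
region lengths (r, m, p) and special-token positions that the attention
analysis relies on.  Mask planning for MLM (single tokens) and n-gram MLM
(contiguous spans) lives here too.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .reactions import AA_ALPHABET, EnzymaticReaction, EnzymeKind

__all__ = [
    "SMILES_TOKEN_PATTERN",
    "SmilesTokenizationError",
    "tokenize_smiles",
    "BPETokenizer",
    "tokenize_aa",
    "median_token_count",
    "TokenizedReaction",
    "ReactionEncoder",
    "ReactionLengthError",
    "MaskPlan",
    "plan_mlm_mask",
    "plan_ngram_mask",
    "SPECIAL_TOKENS",
]

# --------------------------------------------------------------------------
# SMILES tokenization
# --------------------------------------------------------------------------

SMILES_TOKEN_PATTERN = re.compile(
    r"(\[[^\]]+]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\.|=|#|-|\+|\\|\/|:"
    r"|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)


class SmilesTokenizationError(ValueError):
    """Raised when a SMILES string contains an unmatched character."""


def tokenize_smiles(smiles: str) -> list[str]:
    """Atom/bond-level SMILES tokens whose concatenation equals the input."""
    if not smiles:
        raise SmilesTokenizationError("empty SMILES string")
    tokens: list[str] = []
    pos = 0
    for match in SMILES_TOKEN_PATTERN.finditer(smiles):
        if match.start() != pos:
            raise SmilesTokenizationError(
                f"unmatched character {smiles[pos]!r} at position {pos} "
                f"in {smiles!r}"
            )
        tokens.append(match.group())
        pos = match.end()
    if pos != len(smiles):
        raise SmilesTokenizationError(
            f"unmatched character {smiles[pos]!r} at position {pos} in {smiles!r}"
        )
    return tokens


# --------------------------------------------------------------------------
# Byte-Pair Encoding for amino-acid sequences
# --------------------------------------------------------------------------


class BPETokenizer:
    """Lossless BPE tokenizer over the amino-acid alphabet.

    The vocabulary is seeded with every single character of the alphabet
    (so any sequence can be encoded) and grown by iteratively merging the
    most frequent adjacent token pair in the training corpus, breaking ties
    by the lexicographically smallest id pair.  ``encode`` returns token
    surface strings together with half-open residue offsets; joining the
    surfaces reproduces the input exactly.
    """

    def __init__(
        self,
        vocab: dict[str, int],
        merges: list[tuple[str, str]],
        metadata: dict | None = None,
    ) -> None:
        self.vocab = dict(vocab)
        self.merges = [tuple(m) for m in merges]
        self.metadata = dict(metadata or {})
        self.id_to_token = {i: t for t, i in self.vocab.items()}
        self._ranks = {pair: rank for rank, pair in enumerate(self.merges)}
        self._char_set = {t for t in self.vocab if len(t) == 1}

    # -- training ----------------------------------------------------------

    @classmethod
    def train(
        cls,
        corpus: Sequence[str],
        vocab_size: int,
        length_interval: tuple[int, int] | None = None,
        seed: int = 0,
        alphabet: str = AA_ALPHABET,
        max_train_sequences: int | None = None,
    ) -> "BPETokenizer":
        """Train a BPE tokenizer on sequences within ``length_interval``.

        ``max_train_sequences`` caps the corpus via a seeded subsample; the
        merge procedure itself is deterministic.
        """
        if vocab_size < len(alphabet):
            raise ValueError(
                f"vocab_size {vocab_size} smaller than alphabet ({len(alphabet)})"
            )
        if length_interval is not None:
            lo, hi = length_interval
            filtered = [s for s in corpus if lo <= len(s) <= hi]
            if not filtered:
                raise ValueError(
                    f"no training sequences with length in [{lo}, {hi}]"
                )
        else:
            filtered = list(corpus)
            if not filtered:
                raise ValueError("empty training corpus")
        rng = np.random.default_rng(seed)
        if max_train_sequences is not None and len(filtered) > max_train_sequences:
            idx = rng.choice(len(filtered), size=max_train_sequences, replace=False)
            filtered = [filtered[i] for i in sorted(idx)]

        tokens: list[str] = sorted(alphabet)
        vocab = {t: i for i, t in enumerate(tokens)}
        bad = {c for s in filtered for c in s} - set(alphabet)
        if bad:
            raise ValueError(f"training corpus has characters outside alphabet: {sorted(bad)}")

        # Corpus as one int array, sequences separated by -1 so merges never
        # cross sequence boundaries.
        sep = np.array([-1], dtype=np.int64)
        pieces: list[np.ndarray] = []
        for s in filtered:
            pieces.append(np.fromiter((vocab[c] for c in s), dtype=np.int64, count=len(s)))
            pieces.append(sep)
        arr = np.concatenate(pieces[:-1]) if pieces else np.empty(0, dtype=np.int64)

        mult = vocab_size + 1  # pair key = a * mult + b; ids stay < vocab_size
        merges: list[tuple[str, str]] = []
        while len(tokens) < vocab_size and arr.size > 1:
            a, b = arr[:-1], arr[1:]
            valid = (a >= 0) & (b >= 0)
            if not valid.any():
                break
            keys = a[valid] * mult + b[valid]
            uniq, counts = np.unique(keys, return_counts=True)
            cmax = counts.max()
            if cmax < 2:
                break
            best = int(uniq[counts == cmax].min())
            pa, pb = divmod(best, mult)
            new_id = len(tokens)
            merges.append((tokens[pa], tokens[pb]))
            tokens.append(tokens[pa] + tokens[pb])
            # Replace leftmost non-overlapping occurrences.
            pos = np.where((arr[:-1] == pa) & (arr[1:] == pb))[0]
            kept: list[int] = []
            last = -2
            for p in pos.tolist():
                if p == last + 1:
                    continue
                kept.append(p)
                last = p
            kept_arr = np.asarray(kept, dtype=np.int64)
            arr[kept_arr] = new_id
            mask = np.ones(arr.size, dtype=bool)
            mask[kept_arr + 1] = False
            arr = arr[mask]

        vocab = {t: i for i, t in enumerate(tokens)}
        metadata = {
            "vocab_size": vocab_size,
            "length_interval": list(length_interval) if length_interval else None,
            "corpus_size": len(filtered),
            "seed": seed,
            "alphabet": alphabet,
        }
        return cls(vocab, merges, metadata)

    # -- encoding ----------------------------------------------------------

    def encode(self, seq: str) -> tuple[list[str], list[tuple[int, int]]]:
        """Encode a sequence into (token surfaces, half-open residue offsets)."""
        for i, c in enumerate(seq):
            if c not in self._char_set:
                raise ValueError(f"illegal character {c!r} at position {i}")
        parts = list(seq)
        offsets = [(i, i + 1) for i in range(len(seq))]
        ranks = self._ranks
        while len(parts) > 1:
            best_rank: int | None = None
            best_pair: tuple[str, str] | None = None
            for pair in zip(parts, parts[1:]):
                r = ranks.get(pair)
                if r is not None and (best_rank is None or r < best_rank):
                    best_rank, best_pair = r, pair
            if best_pair is None:
                break
            new_parts: list[str] = []
            new_offsets: list[tuple[int, int]] = []
            i = 0
            while i < len(parts):
                if i + 1 < len(parts) and (parts[i], parts[i + 1]) == best_pair:
                    new_parts.append(parts[i] + parts[i + 1])
                    new_offsets.append((offsets[i][0], offsets[i + 1][1]))
                    i += 2
                else:
                    new_parts.append(parts[i])
                    new_offsets.append(offsets[i])
                    i += 1
            parts, offsets = new_parts, new_offsets
        return parts, offsets

    def decode(self, tokens: Iterable[str | int]) -> str:
        return "".join(
            t if isinstance(t, str) else self.id_to_token[t] for t in tokens
        )

    def token_count(self, seq: str) -> int:
        return len(self.encode(seq)[0])

    def __len__(self) -> int:
        return len(self.vocab)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "vocab": self.vocab,
            "merges": [list(m) for m in self.merges],
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "BPETokenizer":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(payload["vocab"], payload["merges"], payload.get("metadata"))


def tokenize_aa(
    tokenizer: BPETokenizer, seq: str
) -> tuple[list[str], list[tuple[int, int]]]:
    """Tokenize an AA sequence; offsets partition ``[0, len(seq))``."""
    return tokenizer.encode(seq)


def median_token_count(tokenizer: BPETokenizer, corpus: Sequence[str]) -> float:
    """Median per-sequence token count (the compression statistic)."""
    if not corpus:
        raise ValueError("empty corpus")
    return float(np.median([tokenizer.token_count(s) for s in corpus]))


# --------------------------------------------------------------------------
# Joint reaction encoding
# --------------------------------------------------------------------------

SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[EOS]", "[MASK]")
PAD_ID, UNK_ID, CLS_ID, SEP_ID, EOS_ID, MASK_ID = range(6)


class ReactionLengthError(ValueError):
    """Raised when an encoded reaction exceeds the position limit."""

    def __init__(self, attained: int, max_len: int):
        super().__init__(
            f"encoded reaction has {attained} tokens, exceeding max_len {max_len}"
        )
        self.attained = attained
        self.max_len = max_len


@dataclass(frozen=True)
class TokenizedReaction:
    """A reaction as model input: token ids plus region bookkeeping.

    The layout is ``[CLS] r reactant tokens [SEP] m enzyme tokens [SEP]
    p product tokens [EOS]`` (the enzyme block and its separator are absent
    for organic reactions, m = 0).  ``enzyme_offsets`` maps each enzyme
    token to its half-open residue interval.
    """

    tokens: tuple[int, ...]
    r: int
    m_enz: int
    p: int
    enzyme_offsets: tuple[tuple[int, int], ...]
    special_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.r + self.m_enz + self.p + len(self.special_positions) != len(
            self.tokens
        ):
            raise ValueError("region lengths do not sum to token count")
        if len(self.enzyme_offsets) != self.m_enz:
            raise ValueError("one residue interval required per enzyme token")
        prev_end = 0
        for a, b in self.enzyme_offsets:
            if a != prev_end or b <= a:
                raise ValueError("enzyme offsets must be contiguous half-open intervals")
            prev_end = b

    def _content_positions(self) -> list[int]:
        specials = set(self.special_positions)
        return [i for i in range(len(self.tokens)) if i not in specials]

    @property
    def reactant_positions(self) -> list[int]:
        return self._content_positions()[: self.r]

    @property
    def enzyme_positions(self) -> list[int]:
        return self._content_positions()[self.r : self.r + self.m_enz]

    @property
    def product_positions(self) -> list[int]:
        return self._content_positions()[self.r + self.m_enz :]

    @property
    def sequence_length(self) -> int:
        return self.enzyme_offsets[-1][1] if self.enzyme_offsets else 0

    def __len__(self) -> int:
        return len(self.tokens)


class ReactionEncoder:
    """Joint vocabulary over special, SMILES and (BPE) amino-acid tokens.

    SMILES and AA tokens live in disjoint id ranges even when their surface
    strings coincide (the SMILES atom ``C`` is not the residue ``C``).
    """

    def __init__(self, smiles_tokens: Sequence[str], aa_tokenizer: BPETokenizer):
        self.aa_tokenizer = aa_tokenizer
        self.smiles_vocab: dict[str, int] = {}
        next_id = len(SPECIAL_TOKENS)
        for tok in sorted(set(smiles_tokens)):
            self.smiles_vocab[tok] = next_id
            next_id += 1
        self.aa_offset = next_id
        self.vocab_size = next_id + len(aa_tokenizer)
        self.id_to_surface: dict[int, tuple[str, str]] = {
            i: ("SPECIAL", t) for i, t in enumerate(SPECIAL_TOKENS)
        }
        for tok, i in self.smiles_vocab.items():
            self.id_to_surface[i] = ("SMILES", tok)
        for tok, i in aa_tokenizer.vocab.items():
            self.id_to_surface[self.aa_offset + i] = ("AA", tok)

    @classmethod
    def build(
        cls, reactions: Sequence[EnzymaticReaction], aa_tokenizer: BPETokenizer
    ) -> "ReactionEncoder":
        """Collect the SMILES token inventory of a corpus into a joint vocab."""
        tokens: set[str] = {"."}
        for rxn in reactions:
            for mol in rxn.reactants + rxn.products:
                tokens.update(tokenize_smiles(mol))
        return cls(sorted(tokens), aa_tokenizer)

    def _smiles_ids(self, molecules: Sequence[str]) -> list[int]:
        ids = []
        for tok in tokenize_smiles(".".join(molecules)):
            if tok not in self.smiles_vocab:
                raise KeyError(f"SMILES token {tok!r} not in vocabulary")
            ids.append(self.smiles_vocab[tok])
        return ids

    def encode_reaction(
        self, rxn: EnzymaticReaction, max_len: int = 512
    ) -> TokenizedReaction:
        """Encode one reaction; raises :class:`ReactionLengthError` if the
        result exceeds ``max_len`` (no silent truncation — the attention
        analysis needs the entire sequence)."""
        if rxn.enzyme is not None and rxn.enzyme.kind is EnzymeKind.EC:
            raise ValueError(
                "cannot encode an EC-specified enzyme; run sequence augmentation first"
            )
        r_ids = self._smiles_ids(rxn.reactants)
        p_ids = self._smiles_ids(rxn.products)
        if rxn.enzyme is not None:
            surfaces, offsets = self.aa_tokenizer.encode(rxn.enzyme.value)
            m_ids = [self.aa_offset + self.aa_tokenizer.vocab[t] for t in surfaces]
            tokens = (
                [CLS_ID] + r_ids + [SEP_ID] + m_ids + [SEP_ID] + p_ids + [EOS_ID]
            )
            specials = (0, 1 + len(r_ids), 2 + len(r_ids) + len(m_ids), len(tokens) - 1)
        else:
            m_ids, offsets = [], []
            tokens = [CLS_ID] + r_ids + [SEP_ID] + p_ids + [EOS_ID]
            specials = (0, 1 + len(r_ids), len(tokens) - 1)
        if len(tokens) > max_len:
            raise ReactionLengthError(len(tokens), max_len)
        return TokenizedReaction(
            tokens=tuple(tokens),
            r=len(r_ids),
            m_enz=len(m_ids),
            p=len(p_ids),
            enzyme_offsets=tuple(offsets),
            special_positions=specials,
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "smiles_tokens": sorted(self.smiles_vocab),
            "aa_tokenizer": {
                "vocab": self.aa_tokenizer.vocab,
                "merges": [list(m) for m in self.aa_tokenizer.merges],
                "metadata": self.aa_tokenizer.metadata,
            },
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ReactionEncoder":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        aa = payload["aa_tokenizer"]
        return cls(
            payload["smiles_tokens"],
            BPETokenizer(aa["vocab"], aa["merges"], aa.get("metadata")),
        )


# --------------------------------------------------------------------------
# Mask planning
# --------------------------------------------------------------------------

#: mask / random / keep replacement probabilities (BERT convention).
DEFAULT_MASK_POLICY = (0.8, 0.1, 0.1)
_POLICY_NAMES = ("mask", "random", "keep")


@dataclass(frozen=True)
class MaskPlan:
    """Positions to hide plus the per-position replacement policy."""

    positions: tuple[int, ...]
    policies: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("mask positions must be unique")
        if len(self.policies) != len(self.positions):
            raise ValueError("one policy per masked position")


def _assign_policies(
    n: int, rng: np.random.Generator, policy: tuple[float, float, float]
) -> tuple[str, ...]:
    return tuple(rng.choice(_POLICY_NAMES, size=n, p=policy))


def plan_mlm_mask(
    positions: Sequence[int],
    rate: float,
    seed: int,
    policy: tuple[float, float, float] = DEFAULT_MASK_POLICY,
) -> MaskPlan:
    """Single-token MLM: exactly ``round(rate * len(positions))`` unique
    positions, uniformly sampled."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    n = int(np.floor(rate * len(positions) + 0.5))
    if n == 0:
        return MaskPlan((), (), seed)
    chosen = np.sort(rng.choice(len(positions), size=n, replace=False))
    abs_positions = tuple(int(positions[i]) for i in chosen)
    return MaskPlan(abs_positions, _assign_policies(n, rng, policy), seed)


def plan_ngram_mask(
    positions: Sequence[int],
    rate: float,
    n_range: tuple[int, int] = (2, 5),
    seed: int = 0,
    policy: tuple[float, float, float] = DEFAULT_MASK_POLICY,
) -> MaskPlan:
    """n-gram MLM: disjoint contiguous spans (lengths uniform in ``n_range``)
    placed until coverage reaches ``rate * len(positions)``, never exceeding
    it by more than ``max(n_range) - 1``.  Regions shorter than the minimum
    n fall back to single-token masking."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    n_min, n_max = n_range
    if not 1 <= n_min <= n_max:
        raise ValueError(f"invalid n_range {n_range}")
    length = len(positions)
    if length < n_min:
        return plan_mlm_mask(positions, rate, seed, policy)
    rng = np.random.default_rng(seed)
    covered = np.zeros(length, dtype=bool)
    target = rate * length
    total = 0
    while total < target - 1e-9:
        n = int(rng.integers(n_min, n_max + 1))
        placed = False
        for trial_n in range(n, 0, -1):
            free = [
                s
                for s in range(length - trial_n + 1)
                if not covered[s : s + trial_n].any()
            ]
            if free:
                s = free[int(rng.integers(len(free)))]
                covered[s : s + trial_n] = True
                total += trial_n
                placed = True
                break
        if not placed:
            break
    abs_positions = tuple(int(positions[i]) for i in np.flatnonzero(covered))
    return MaskPlan(abs_positions, _assign_policies(len(abs_positions), rng, policy), seed)
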
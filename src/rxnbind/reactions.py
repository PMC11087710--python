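"""Parsing, serialization and preparation of enzymatic-reaction corpora.

A corpus is plain UTF-8 text, one reaction per line, in the dialect

    reactants|enzyme>>products

where ``reactants`` and ``products`` are SMILES molecules joined by ``.``
and ``enzyme`` is either an Enzyme Commission (EC) number such as
``1.1.1.1`` or an amino-acid sequence over the 20-letter alphabet plus X.
Lines starting with ``#`` are comments.  Organic (enzyme-free) reactions
use the plain reaction-SMILES dialect ``reactants>>products``.

SMILES strings are treated as opaque text here: no chemistry validation is
performed, and product-group keys for splitting default to plain string
equality, with an optional chemistry-aware canonicalizer hook.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "AA_ALPHABET",
    "EnzymeKind",
    "EnzymeSpec",
    "EnzymaticReaction",
    "ReactionParseError",
    "AugmentationReport",
    "CorpusSplit",
    "parse_reaction",
    "parse_organic_reaction",
    "serialize_reaction",
    "read_reactions",
    "write_reactions",
    "read_ec_map",
    "read_fasta_sequences",
    "augment_with_sequences",
    "deduplicate_reactions",
    "product_split",
]

#: The 20 proteinogenic amino acids plus X (unknown residue).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

_EC_RE = re.compile(r"^[1-9]\d*(\.[1-9]\d*){0,3}$")
_AA_RE = re.compile(f"^[{AA_ALPHABET}]+$")


class ReactionParseError(ValueError):
    """Raised for malformed reaction lines; the message names the line."""


class EnzymeKind(str, Enum):
    EC = "EC"
    SEQUENCE = "SEQUENCE"


@dataclass(frozen=True)
class EnzymeSpec:
    """An enzyme given either by EC number or by amino-acid sequence."""

    kind: EnzymeKind
    value: str

    def __post_init__(self) -> None:
        if self.kind is EnzymeKind.EC:
            if not _EC_RE.match(self.value):
                raise ValueError(f"invalid EC number: {self.value!r}")
        elif not _AA_RE.match(self.value):
            raise ValueError(
                f"invalid amino-acid sequence (alphabet {AA_ALPHABET}): "
                f"{self.value!r}"
            )

    @property
    def ec_level(self) -> int:
        """Number of specified EC fields (1-4); 0 for sequence specs."""
        if self.kind is not EnzymeKind.EC:
            return 0
        return self.value.count(".") + 1

    @staticmethod
    def classify(text: str) -> "EnzymeSpec":
        """EC grammar match wins; anything else must be an AA sequence."""
        if _EC_RE.match(text):
            return EnzymeSpec(EnzymeKind.EC, text)
        return EnzymeSpec(EnzymeKind.SEQUENCE, text)


@dataclass(frozen=True)
class EnzymaticReaction:
    """One reaction record: reactants, optional enzyme, products.

    ``enzyme`` is None for organic (enzyme-free) reactions, which act as the
    auxiliary corpus during multi-task training.
    """

    reactants: tuple[str, ...]
    enzyme: EnzymeSpec | None
    products: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.reactants or any(not m for m in self.reactants):
            raise ValueError("reactants must contain >=1 non-empty SMILES")
        if not self.products or any(not m for m in self.products):
            raise ValueError("products must contain >=1 non-empty SMILES")
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))

    @property
    def product_key(self) -> tuple[str, ...]:
        """Canonical key of the product set (sorted, string equality)."""
        return tuple(sorted(self.products))


def parse_reaction(line: str) -> EnzymaticReaction:
    """Parse one ``reactants|enzyme>>products`` line.

    The enzyme field is classified as an EC number iff it matches the EC
    grammar, otherwise it must be a valid amino-acid sequence.
    """
    stripped = line.strip()
    if stripped.count("|") != 1:
        raise ReactionParseError(f"expected exactly one '|' in line: {line!r}")
    left, rest = stripped.split("|")
    if rest.count(">>") != 1:
        raise ReactionParseError(f"expected exactly one '>>' in line: {line!r}")
    enzyme_text, right = rest.split(">>")
    if not left or not enzyme_text or not right:
        raise ReactionParseError(f"empty field in line: {line!r}")
    try:
        enzyme = EnzymeSpec.classify(enzyme_text)
        return EnzymaticReaction(
            reactants=tuple(left.split(".")),
            enzyme=enzyme,
            products=tuple(right.split(".")),
        )
    except ValueError as exc:
        raise ReactionParseError(f"{exc} in line: {line!r}") from exc


def parse_organic_reaction(line: str) -> EnzymaticReaction:
    """Parse a plain ``reactants>>products`` line (no enzyme field)."""
    stripped = line.strip()
    if "|" in stripped:
        raise ReactionParseError(f"unexpected '|' in organic line: {line!r}")
    if stripped.count(">>") != 1:
        raise ReactionParseError(f"expected exactly one '>>' in line: {line!r}")
    left, right = stripped.split(">>")
    if not left or not right:
        raise ReactionParseError(f"empty field in line: {line!r}")
    try:
        return EnzymaticReaction(tuple(left.split(".")), None, tuple(right.split(".")))
    except ValueError as exc:
        raise ReactionParseError(f"{exc} in line: {line!r}") from exc


def serialize_reaction(rxn: EnzymaticReaction) -> str:
    """Inverse of :func:`parse_reaction` / :func:`parse_organic_reaction`."""
    left = ".".join(rxn.reactants)
    right = ".".join(rxn.products)
    if rxn.enzyme is None:
        return f"{left}>>{right}"
    return f"{left}|{rxn.enzyme.value}>>{right}"


def read_reactions(path: str | Path, organic: bool = False) -> list[EnzymaticReaction]:
    """Read a reaction file (one reaction per line, ``#`` comments ignored)."""
    parse = parse_organic_reaction if organic else parse_reaction
    out: list[EnzymaticReaction] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                out.append(parse(line))
            except ReactionParseError as exc:
                raise ReactionParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_reactions(reactions: Iterable[EnzymaticReaction], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rxn in reactions:
            fh.write(serialize_reaction(rxn) + "\n")


def read_ec_map(path: str | Path) -> dict[str, list[str]]:
    """Read a 2-column TSV (EC, sequence); repeated EC rows accumulate."""
    mapping: dict[str, list[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ValueError(f"EC map rows must have 2 columns, got {row!r}")
            ec, seq = row[0].strip(), row[1].strip()
            EnzymeSpec(EnzymeKind.EC, ec)  # validates the key
            EnzymeSpec(EnzymeKind.SEQUENCE, seq)
            mapping.setdefault(ec, []).append(seq)
    return mapping


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read amino-acid sequences from FASTA, keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class AugmentationReport:
    """Bookkeeping for EC->sequence augmentation."""

    n_input: int = 0
    n_augmented: int = 0
    n_dropped: int = 0
    dropped_ecs: Counter = field(default_factory=Counter)
    n_capped_ecs: int = 0


def augment_with_sequences(
    corpus: Sequence[EnzymaticReaction],
    ec_map: dict[str, list[str]],
    cap: int = 10_000,
    seed: int = 0,
) -> tuple[list[EnzymaticReaction], AugmentationReport]:
    """Expand EC-bearing reactions into one record per mapped AA sequence.

    Each reaction whose enzyme is an EC number is replaced by one record per
    sequence mapped to that EC, capping over-represented EC numbers at
    ``cap`` sequences via a seeded uniform sample.  Reactions whose EC is
    absent from the map are dropped and counted in the report.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    rng = np.random.default_rng(seed)
    # One capped sample per EC, drawn in sorted-key order for determinism.
    capped: dict[str, list[str]] = {}
    for ec in sorted(ec_map):
        seqs = ec_map[ec]
        if len(seqs) > cap:
            idx = rng.choice(len(seqs), size=cap, replace=False)
            capped[ec] = [seqs[i] for i in sorted(idx)]
        else:
            capped[ec] = list(seqs)

    report = AugmentationReport(n_input=len(corpus))
    report.n_capped_ecs = sum(len(ec_map[ec]) > cap for ec in ec_map)
    out: list[EnzymaticReaction] = []
    for rxn in corpus:
        if rxn.enzyme is None or rxn.enzyme.kind is not EnzymeKind.EC:
            report.n_dropped += 1
            report.dropped_ecs["<no EC>"] += 1
            continue
        ec = rxn.enzyme.value
        if ec not in capped:
            report.n_dropped += 1
            report.dropped_ecs[ec] += 1
            continue
        for seq in capped[ec]:
            out.append(
                EnzymaticReaction(
                    rxn.reactants,
                    EnzymeSpec(EnzymeKind.SEQUENCE, seq),
                    rxn.products,
                )
            )
    report.n_augmented = len(out)
    return out, report


def deduplicate_reactions(
    corpus: Sequence[EnzymaticReaction],
) -> list[EnzymaticReaction]:
    """Collapse exact duplicate reactions, keeping first-occurrence order.

    Records differing in any field (e.g. same reaction with two different
    enzyme sequences) are all retained.
    """
    seen: set[str] = set()
    out: list[EnzymaticReaction] = []
    for rxn in corpus:
        key = serialize_reaction(rxn)
        if key not in seen:
            seen.add(key)
            out.append(rxn)
    return out


@dataclass
class CorpusSplit:
    """Product-stratified train/validation/test split.

    Reactions are grouped by their canonical product key and whole groups
    are assigned to splits, so no product ever appears in two splits.
    """

    train: list[EnzymaticReaction]
    validation: list[EnzymaticReaction]
    test: list[EnzymaticReaction]
    fractions: tuple[float, float, float]
    seed: int

    def product_keys(self) -> tuple[set, set, set]:
        def keys(rxns: list[EnzymaticReaction]) -> set:
            return {r.product_key for r in rxns}

        return keys(self.train), keys(self.validation), keys(self.test)


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [f * n for f in fractions]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def product_split(
    corpus: Sequence[EnzymaticReaction],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    canonicalizer: Callable[[str], str] | None = None,
) -> CorpusSplit:
    """Split a corpus into train/validation/test by product groups.

    Groups of reactions sharing a product key (sorted product SMILES, plain
    string equality unless a ``canonicalizer`` such as
    :func:`rdkit_canonicalizer` is supplied) are shuffled with ``seed`` and
    assigned whole to splits in proportions approximating ``fractions``
    (largest-remainder rounding on group counts).
    """
    if any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")

    def key_of(rxn: EnzymaticReaction) -> tuple[str, ...]:
        if canonicalizer is None:
            return rxn.product_key
        return tuple(sorted(canonicalizer(p) for p in rxn.products))

    groups: dict[tuple[str, ...], list[EnzymaticReaction]] = {}
    for rxn in corpus:
        groups.setdefault(key_of(rxn), []).append(rxn)

    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n_train, n_val, n_test = _largest_remainder_counts(len(keys), fractions)
    splits: list[list[EnzymaticReaction]] = [[], [], []]
    for i, key in enumerate(keys):
        if i < n_train:
            splits[0].extend(groups[key])
        elif i < n_train + n_val:
            splits[1].extend(groups[key])
        else:
            splits[2].extend(groups[key])
    return CorpusSplit(splits[0], splits[1], splits[2], tuple(fractions), seed)


def rdkit_canonicalizer(smiles: str) -> str:
    """Chemistry-aware canonical SMILES (optional hook; requires rdkit)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return smiles
    return Chem.MolToSmiles(mol)
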
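"""Synthetic fixtures: decoy databases, planted homologs, evolved families.

The generators emulate the structure of a curated allergen database at desk
scale: decoy proteins of realistic amino-acid composition, entries carrying
planted 80-mer segments at exactly controlled identity to a query, planted
shared 8-mers, and homolog families evolved along a known tree with exact
substitution bookkeeping.  Everything is bit-reproducible under a fixed seed.

Planted substitutions are drawn uniformly from the 19 non-identical residues,
so a segment planted with ``k`` mismatches has window identity exactly
``100·(L−k)/L``.  Decoys are rejection-sampled so that, unless a word is
planted, no decoy shares an 8-mer with the query set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .records import AllergenEntry, ProteinRecord, save_database

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_WORD = 8
_MAX_REJECT = 200


class OversubscribedTreeError(ValueError):
    """Raised when branch substitution counts exceed the sequence length."""


@dataclass(frozen=True)
class PlantedSegment:
    """Copy query[start:start+length] into a target entry with k mismatches."""

    target: int                 # decoy index the segment is planted into
    query_start: int            # 1-based start on the query
    length: int = 80
    mismatches: int = 0
    offset: int | None = None   # 0-based position in the target; centred if None

    def __post_init__(self) -> None:
        if self.mismatches > self.length:
            raise ValueError("mismatch count exceeds segment length")


@dataclass(frozen=True)
class PlantedWord:
    """Write an exact 8-mer into a target entry at a fixed offset."""

    word: str
    target: int
    offset: int

    def __post_init__(self) -> None:
        if len(self.word) != _WORD:
            raise ValueError(f"planted word must be {_WORD} residues")


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic allergen database.

    ``alphabet_freqs`` maps residues to sampling weights (uniform over the 20
    standard amino acids when omitted); lengths are drawn uniformly from
    ``length_range``.
    """

    n_decoys: int
    length_range: tuple[int, int] = (100, 300)
    alphabet_freqs: dict[str, float] | None = None
    planted_segments: list[PlantedSegment] = field(default_factory=list)
    planted_words: list[PlantedWord] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length_range")
        if self.n_decoys < 1:
            raise ValueError("need at least one decoy")
        for seg in self.planted_segments:
            if not 0 <= seg.target < self.n_decoys:
                raise ValueError(f"planted segment target {seg.target} out of range")
        for w in self.planted_words:
            if not 0 <= w.target < self.n_decoys:
                raise ValueError(f"planted word target {w.target} out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["planted_segments"] = [
            PlantedSegment(**d) for d in raw.get("planted_segments", [])
        ]
        raw["planted_words"] = [
            PlantedWord(**d) for d in raw.get("planted_words", [])
        ]
        if "length_range" in raw:
            raw["length_range"] = tuple(raw["length_range"])
        return cls(**raw)


def _residue_sampler(spec: SyntheticSpec):
    if spec.alphabet_freqs:
        letters = sorted(spec.alphabet_freqs)
        probs = np.array([spec.alphabet_freqs[l] for l in letters], dtype=float)
        probs = probs / probs.sum()
    else:
        letters = list(STANDARD_AA)
        probs = np.full(len(letters), 1.0 / len(letters))
    letters = np.array(letters)

    def sample(rng: np.random.Generator, n: int) -> str:
        return "".join(rng.choice(letters, size=n, p=probs))

    return sample


def _words_of(seq: str, k: int = _WORD) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _clean_random_seq(rng, sample, length: int, forbidden: set[str],
                      what: str) -> str:
    """Random sequence sharing no 8-mer with ``forbidden``; rejection-sampled."""
    for _ in range(_MAX_REJECT):
        seq = sample(rng, length)
        if not (_words_of(seq) & forbidden):
            return seq
    raise RuntimeError(
        f"rejection sampling budget exceeded while generating {what}; "
        "the query set is too repetitive for a clean decoy"
    )


def mutate_segment(segment: str, k: int, rng: np.random.Generator) -> str:
    """Substitute exactly k positions, never recreating the original residue."""
    if k > len(segment):
        raise ValueError("mismatch count exceeds segment length")
    positions = rng.choice(len(segment), size=k, replace=False)
    chars = list(segment)
    for pos in sorted(positions):
        alternatives = [c for c in STANDARD_AA if c != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def gen_decoy_db(spec: SyntheticSpec,
                 queries: Sequence[ProteinRecord] = (),
                 ) -> tuple[list[AllergenEntry], dict]:
    """Generate a reproducible decoy database with optional planted structure.

    Returns the entries plus a truth dictionary recording every plant
    (positions, mismatch counts, exact expected identities).  Decoys are
    tagged "allergen" with status "putative".
    """
    rng = np.random.default_rng(spec.seed)
    sample = _residue_sampler(spec)
    forbidden: set[str] = set()
    for q in queries:
        forbidden |= _words_of(q.sequence)

    lo, hi = spec.length_range
    seqs: list[str] = []
    for i in range(spec.n_decoys):
        length = int(rng.integers(lo, hi + 1))
        seqs.append(_clean_random_seq(rng, sample, length, forbidden,
                                      f"decoy {i}"))

    truth: dict = {"seed": spec.seed, "planted_segments": [],
                   "planted_words": []}

    for seg in spec.planted_segments:
        if not queries:
            raise ValueError("planted segments require a query")
        query = queries[0]
        q0 = seg.query_start - 1
        if q0 < 0 or q0 + seg.length > query.length:
            raise ValueError(
                f"planted segment [{seg.query_start}, "
                f"{seg.query_start + seg.length - 1}] outside query bounds"
            )
        source = query.sequence[q0:q0 + seg.length]
        mutated = mutate_segment(source, seg.mismatches, rng)
        target = seqs[seg.target]
        if len(target) < seg.length:
            raise ValueError("target decoy shorter than planted segment")
        off = seg.offset
        if off is None:
            off = (len(target) - seg.length) // 2
        if off + seg.length > len(target):
            raise ValueError("planted segment offset out of bounds")
        seqs[seg.target] = target[:off] + mutated + target[off + seg.length:]
        truth["planted_segments"].append({
            "target": seg.target, "query_start": seg.query_start,
            "length": seg.length, "mismatches": seg.mismatches,
            "offset": off,
            "expected_identity": 100.0 * (seg.length - seg.mismatches) / seg.length,
        })

    for w in spec.planted_words:
        target = seqs[w.target]
        if w.offset + _WORD > len(target):
            raise ValueError("planted word offset out of bounds")
        seqs[w.target] = (target[:w.offset] + w.word
                          + target[w.offset + _WORD:])
        truth["planted_words"].append(
            {"word": w.word, "target": w.target, "offset": w.offset}
        )

    entries = [
        AllergenEntry(
            record=ProteinRecord(
                id=f"DECOY_{i:03d}", sequence=seq,
                description="synthetic decoy allergen",
                organism="synthetic",
            ),
            status="putative",
            tags=frozenset({"allergen"}),
            source_taxon="synthetic",
        )
        for i, seq in enumerate(seqs)
    ]
    return entries, truth


def plant_homolog(query: ProteinRecord, start: int, length: int = 80,
                  mismatches: int = 0, seed: int = 0,
                  flanks: tuple[int, int] = (60, 60),
                  subject_id: str = "PLANTED",
                  mask_flanks: bool = False) -> ProteinRecord:
    """A subject carrying query[start:start+length] with exactly k mismatches.

    The mutated segment is embedded between decoy flanks that share no 8-mer
    with the query.  With ``mask_flanks=True`` the flanks are unknown-residue
    (X) padding instead of random decoy residues: X never counts as an
    identity, so the planted window is then *provably* the only identity
    signal and the recovered best-window identity equals
    ``100·(length−k)/length`` exactly, for every seed — the construction used
    when an identity value must be recovered to the digit rather than with
    high probability.
    """
    q0 = start - 1
    if q0 < 0 or q0 + length > query.length:
        raise ValueError(
            f"interval [{start}, {start + length - 1}] out of query bounds"
        )
    rng = np.random.default_rng(seed)
    spec = SyntheticSpec(n_decoys=1, seed=seed)
    sample = _residue_sampler(spec)
    forbidden = _words_of(query.sequence)
    segment = mutate_segment(query.sequence[q0:q0 + length], mismatches, rng)
    if mask_flanks:
        left, right = "X" * flanks[0], "X" * flanks[1]
    else:
        left = (_clean_random_seq(rng, sample, flanks[0], forbidden,
                                  "left flank") if flanks[0] else "")
        right = (_clean_random_seq(rng, sample, flanks[1], forbidden,
                                   "right flank") if flanks[1] else "")
    return ProteinRecord(
        id=subject_id, sequence=left + segment + right,
        description=f"planted homolog ({mismatches} mismatches over {length})",
        organism="synthetic",
    )


@dataclass(frozen=True)
class BranchSpec:
    """A tree node: label, substitutions on the branch above it, children."""

    label: str
    substitutions: int = 0
    children: tuple["BranchSpec", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


def evolve_on_tree(root: ProteinRecord, tree: BranchSpec, seed: int = 0,
                   ) -> tuple[list[ProteinRecord], dict[tuple[str, str], int]]:
    """Evolve the root sequence along a tree with fixed per-branch counts.

    Substitution positions are allocated globally without replacement, so
    every position mutates on at most one branch and pairwise leaf
    differences are exactly additive along the tree.  Raises
    :class:`OversubscribedTreeError` when total counts exceed the sequence
    length.  Returns leaf records and the measured pairwise Hamming
    difference table.
    """
    rng = np.random.default_rng(seed)

    def _total(node: BranchSpec) -> int:
        return node.substitutions + sum(_total(c) for c in node.children)

    total = _total(tree)
    if total > root.length:
        raise OversubscribedTreeError(
            f"{total} substitutions oversubscribe a {root.length}-residue "
            "sequence"
        )
    pool = list(rng.permutation(root.length))
    leaves: list[ProteinRecord] = []

    def _descend(node: BranchSpec, seq: str) -> None:
        nonlocal pool
        take, pool = pool[:node.substitutions], pool[node.substitutions:]
        chars = list(seq)
        for pos in sorted(int(p) for p in take):
            alternatives = [c for c in STANDARD_AA if c != chars[pos]]
            chars[pos] = alternatives[rng.integers(len(alternatives))]
        seq = "".join(chars)
        if node.is_leaf:
            leaves.append(ProteinRecord(
                id=node.label, sequence=seq,
                description="tree-evolved synthetic homolog",
                organism="synthetic",
            ))
        else:
            for child in node.children:
                _descend(child, seq)

    _descend(tree, root.sequence)

    diffs: dict[tuple[str, str], int] = {}
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            a, b = leaves[i], leaves[j]
            d = sum(x != y for x, y in zip(a.sequence, b.sequence))
            diffs[(a.id, b.id)] = d
            diffs[(b.id, a.id)] = d
    return leaves, diffs


#: Soybean leghemoglobin c2 (UniProt P02236.2), the 145-residue query protein
#: at the centre of the screen.
LEGHB_SEQUENCE = (
    "MGAFTEKQEALVSSSFEAFKANIPQYSVVFYTSILEKAPAAKDLFSFLSNGVDPSNPKLT"
    "GHAEKLFGLVRDSAGQLKANGTVVADAALGSIHAQKAITDPQFVVVKEALLKTIKEAVGD"
    "KWSDELSSAWEVAYDELAAAIKKAF"
)


def legh_fixture() -> ProteinRecord:
    """The soybean leghemoglobin c2 sequence as a ProteinRecord."""
    return ProteinRecord(
        id="P02236.2",
        sequence=LEGHB_SEQUENCE,
        description="Leghemoglobin c2",
        organism="Glycine max",
    )


def write_fixture(spec: SyntheticSpec, out_dir: str | Path,
                  queries: Sequence[ProteinRecord] = ()) -> dict:
    """Materialize a synthetic database: FASTA + metadata TSV + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries, truth = gen_decoy_db(spec, queries=queries)
    save_database(entries, out / "db.fasta", out / "db.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
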
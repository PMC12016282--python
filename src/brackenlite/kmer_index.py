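"""Minimal Kraken-style database: canonical k-mer -> LCA taxon.

An exact hash map, no minimizers or compression: every canonical k-mer that
occurs in at least one reference genome is assigned the lowest common
ancestor of all genomes containing it. K-mers are stored 2-bit encoded as
integers (k <= 31 fits a uint64); the canonical form is the
lexicographically smaller of a k-mer and its reverse complement, which for
the A<C<G<T alphabet coincides with the numerically smaller encoding.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .taxonomy import TaxonomyTree

__all__ = [
    "GenomeRecord",
    "KmerIndex",
    "canonicalize",
    "canonical_kmers",
    "encode_kmer",
    "decode_kmer",
    "build_kmer_index",
]

MAX_K = 31  # 2 bits per base in a uint64, with headroom for the dot product

_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
_RC_TABLE = str.maketrans("ACGT", "TGCA")

_ALPHABET = frozenset("ACGTN")


def canonicalize(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    if not kmer:
        raise ValueError("empty k-mer")
    if any(c not in "ACGT" for c in kmer):
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    rc = kmer.translate(_RC_TABLE)[::-1]
    return kmer if kmer <= rc else rc


def encode_kmer(kmer: str) -> int:
    """2-bit encode an ACGT k-mer (A=0, C=1, G=2, T=3, big-endian)."""
    v = 0
    for c in kmer:
        code = "ACGT".find(c)
        if code < 0:
            raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
        v = (v << 2) | code
    return v


def decode_kmer(value: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[value & 3])
        value >>= 2
    return "".join(reversed(out))


def encode_sequence(seq: str) -> np.ndarray:
    """Per-base codes (A=0..T=3, anything else 255) as uint8."""
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Encoded canonical k-mers at every position of ``seq``.

    Returns ``(values, valid)`` arrays of length ``len(seq)-k+1``; positions
    whose k-mer overlaps a non-ACGT base are marked invalid and their value
    is meaningless.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    m = len(seq) - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = encode_sequence(seq)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    w = np.where(win < 4, win, 0).astype(np.uint64)
    fwd_weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    rev_weights = 4 ** np.arange(k, dtype=np.uint64)
    fwd = w @ fwd_weights
    rev = (np.uint64(3) - w) @ rev_weights
    return np.minimum(fwd, rev), valid


@dataclass(frozen=True)
class GenomeRecord:
    """A reference genome: a leaf taxid plus one or more contigs."""

    taxid: int
    contigs: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.taxid <= 0:
            raise ValueError(f"taxid must be positive, got {self.taxid}")
        if not self.contigs or any(not c for c in self.contigs):
            raise ValueError(f"genome {self.taxid} has an empty contig or no contigs")
        for c in self.contigs:
            bad = set(c) - _ALPHABET
            if bad:
                raise ValueError(
                    f"genome {self.taxid} contains invalid characters {sorted(bad)}"
                )

    @classmethod
    def from_sequence(cls, taxid: int, sequence: str) -> "GenomeRecord":
        return cls(taxid=taxid, contigs=(sequence,))

    @property
    def sequence(self) -> str:
        return "".join(self.contigs)

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass
class KmerIndex:
    """Map from encoded canonical k-mer to the LCA taxid of its genomes."""

    k: int
    assignments: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.assignments)

    def lookup(self, kmer: str) -> int | None:
        """Taxid assigned to a k-mer string, or None if absent."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        return self.assignments.get(encode_kmer(canonicalize(kmer)))

    def as_strings(self) -> dict[str, int]:
        """Decoded view of the assignments (for inspection and small tests)."""
        return {decode_kmer(v, self.k): t for v, t in self.assignments.items()}


def build_kmer_index(
    genomes: Sequence[GenomeRecord], k: int, tree: TaxonomyTree
) -> KmerIndex:
    """Build the exact canonical-k-mer -> LCA map over a set of genomes.

    Every genome must sit at a leaf of the taxonomy. K-mers overlapping N
    contribute nothing; contigs shorter than k contribute nothing. The
    result is independent of genome input order (LCA is associative and
    commutative).
    """
    if not genomes:
        raise ValueError("no genomes given")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    for g in genomes:
        if g.taxid not in tree:
            raise ValueError(f"genome taxid {g.taxid} not in the taxonomy")
        if not tree.is_leaf(g.taxid):
            raise ValueError(f"genome taxid {g.taxid} is not a leaf")
    if all(g.length < k for g in genomes):
        raise ValueError(f"k={k} is larger than every genome")

    assignments: dict[int, int] = {}
    lca_cache: dict[tuple[int, int], int] = {}

    def lca(a: int, b: int) -> int:
        if a == b:
            return a
        key = (a, b) if a < b else (b, a)
        got = lca_cache.get(key)
        if got is None:
            got = lca_cache[key] = tree.lca(a, b)
        return got

    for g in genomes:
        parts = []
        for contig in g.contigs:
            if len(contig) < k:
                continue
            vals, valid = canonical_kmers(contig, k)
            parts.append(vals[valid])
        if not parts:
            continue
        for v in np.unique(np.concatenate(parts)).tolist():
            cur = assignments.get(v)
            assignments[v] = g.taxid if cur is None else lca(cur, g.taxid)
    return KmerIndex(k=k, assignments=assignments)
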
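"""Self-classification of reference genomes into a k-mer distribution.

Every length-r window of every database genome is classified against the
database the genomes themselves built. Because each of a genome's k-mers is
assigned somewhere on the path from the genome's own taxid to the root, a
window's classification is simply the deepest of its k-mer assignments.
Tallying windows per node yields, for each genome Si and each ancestor node
Gj, the probability P(Gj|Si) that a read of length r from Si is classified
at Gj, and in particular the unique fraction U_Si = P(Si|Si) — the
quantities the redistribution engine consumes.

The distribution depends only on the database and r, so it is computed once
and reused across samples.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .kmer_index import GenomeRecord, KmerIndex, canonical_kmers
from .taxonomy import TaxonomyTree

__all__ = [
    "UNCLASSIFIED",
    "GenomeDistribution",
    "KmerDistribution",
    "classify_window",
    "classify_read",
    "classify_sequence",
    "compute_genome_distribution",
    "build_distribution",
]

#: Sentinel taxid for reads with no k-mer hits (Kraken's "unclassified").
UNCLASSIFIED = 0


@dataclass
class GenomeDistribution:
    """Window-classification tally for one genome.

    ``node_counts[Gj]`` is the number of the genome's length-r windows
    classified to node Gj; counts sum to ``num_windows`` (Li - r + 1 summed
    over contigs) and all keys lie on the genome's root-to-leaf path.
    Fractions are exact rationals over the fixed denominator.
    """

    taxid: int
    num_windows: int
    node_counts: dict[int, int]

    def __post_init__(self) -> None:
        if self.num_windows <= 0:
            raise ValueError(f"genome {self.taxid}: num_windows must be positive")
        if any(c < 0 for c in self.node_counts.values()):
            raise ValueError(f"genome {self.taxid}: negative window count")
        total = sum(self.node_counts.values())
        if total != self.num_windows:
            raise ValueError(
                f"genome {self.taxid}: window counts sum to {total}, "
                f"expected {self.num_windows}"
            )

    @property
    def node_fractions(self) -> dict[int, Fraction]:
        return {t: Fraction(c, self.num_windows) for t, c in self.node_counts.items()}

    @property
    def unique_fraction(self) -> Fraction:
        """Fraction of windows classified to the genome's own node (U_Si)."""
        return Fraction(self.node_counts.get(self.taxid, 0), self.num_windows)


@dataclass
class KmerDistribution:
    """Per-genome window distributions for one (database, read length) pair."""

    read_length: int
    k: int
    per_genome: dict[int, GenomeDistribution]

    def __post_init__(self) -> None:
        if self.read_length < self.k:
            raise ValueError(
                f"read length {self.read_length} must be >= k ({self.k})"
            )


def classify_window(kmer_taxids: Sequence[int], tree: TaxonomyTree) -> int:
    """Deepest taxid of a window whose k-mers all lie on one root-to-leaf path.

    Windows drawn from a database genome satisfy the single-path precondition
    by construction; violating inputs (e.g. reads with errors) must go
    through :func:`classify_read` instead.
    """
    if not kmer_taxids:
        raise ValueError("window has no k-mer taxids")
    deepest = max(kmer_taxids, key=tree.depth)
    on_path = set(tree.ancestor_path(deepest))
    if any(t not in on_path for t in kmer_taxids):
        raise ValueError("k-mer taxids do not lie on a single root-to-leaf path")
    return deepest


def classify_read(kmer_taxids: Sequence[int], tree: TaxonomyTree) -> int:
    """Kraken read classification: deepest node of the max-weight leaf path.

    Each root-to-leaf path is weighted by the number of k-mer hits on it;
    the read is classified to the deepest hit node of the heaviest path.
    Ties between paths resolve to the LCA of their deepest nodes. An empty
    hit list yields :data:`UNCLASSIFIED`.
    """
    if not kmer_taxids:
        return UNCLASSIFIED
    counts = Counter(kmer_taxids)
    if len(counts) == 1:
        return next(iter(counts))
    paths = {t: tree.ancestor_path(t) for t in counts}
    hit_set = set(counts)
    # Terminal hits: hit nodes with no hit strictly below them. The deepest
    # node of any maximal path is one of these.
    terminals = [
        t
        for t in counts
        if not any(u != t and t in paths[u] for u in hit_set)
    ]
    weights = {
        t: sum(counts[a] for a in paths[t] if a in counts) for t in terminals
    }
    best = max(weights.values())
    winners = [t for t in terminals if weights[t] == best]
    out = winners[0]
    for t in winners[1:]:
        out = tree.lca(out, t)
    return out


def classify_sequence(seq: str, index: KmerIndex, tree: TaxonomyTree) -> int:
    """Classify a raw read sequence against the index (Kraken semantics)."""
    vals, valid = canonical_kmers(seq, index.k)
    assignments = index.assignments
    hits = []
    for v, ok in zip(vals.tolist(), valid.tolist()):
        if ok:
            t = assignments.get(v)
            if t is not None:
                hits.append(t)
    return classify_read(hits, tree)


def compute_genome_distribution(
    genome: GenomeRecord, index: KmerIndex, tree: TaxonomyTree, r: int
) -> GenomeDistribution:
    """Slide all length-r windows of a genome and tally their classifications.

    Windows never span contig boundaries; contigs shorter than r contribute
    no windows. Windows in which every k-mer overlaps an N are counted at
    the root (they carry no signal but the denominator Li-r+1 counts them).
    """
    k = index.k
    if r < k:
        raise ValueError(f"read length r={r} must be >= k={k}")
    usable = [c for c in genome.contigs if len(c) >= r]
    if not usable:
        raise ValueError(
            f"read length r={r} exceeds every contig of genome {genome.taxid}"
        )

    path = tree.ancestor_path(genome.taxid)
    depth_of = {t: i for i, t in enumerate(path)}
    assignments = index.assignments
    counts = np.zeros(len(path), dtype=np.int64)
    num_windows = 0
    w = r - k + 1
    for contig in usable:
        vals, valid = canonical_kmers(contig, k)
        m = len(vals)
        depths = np.empty(m, dtype=np.int64)
        vlist = vals.tolist()
        oklist = valid.tolist()
        for i in range(m):
            if not oklist[i]:
                depths[i] = -1
                continue
            t = assignments.get(vlist[i])
            if t is None:
                raise ValueError(
                    f"k-mer of genome {genome.taxid} missing from the index; "
                    "the index must be built from the same genomes"
                )
            d = depth_of.get(t)
            if d is None:
                raise ValueError(
                    f"k-mer of genome {genome.taxid} assigned to taxid {t}, "
                    "which is off the genome's root-to-leaf path"
                )
            depths[i] = d
        win_depth = np.lib.stride_tricks.sliding_window_view(depths, w).max(axis=1)
        win_depth = np.where(win_depth < 0, 0, win_depth)
        counts += np.bincount(win_depth, minlength=len(path))
        num_windows += len(win_depth)

    node_counts = {path[i]: int(c) for i, c in enumerate(counts) if c}
    return GenomeDistribution(
        taxid=genome.taxid, num_windows=num_windows, node_counts=node_counts
    )


def build_distribution(
    genomes: Sequence[GenomeRecord],
    index: KmerIndex,
    tree: TaxonomyTree,
    r: int,
) -> KmerDistribution:
    """Self-classify every genome of the database at read length r."""
    per_genome: dict[int, GenomeDistribution] = {}
    for g in genomes:
        if g.taxid in per_genome:
            raise ValueError(f"duplicate genome taxid {g.taxid}")
        per_genome[g.taxid] = compute_genome_distribution(g, index, tree, r)
    return KmerDistribution(read_length=r, k=index.k, per_genome=per_genome)
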
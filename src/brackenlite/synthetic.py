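"""Mock communities with known truth for validating abundance estimates.

The generator emulates the two benchmark designs the method is judged on:
a mixture of many genomes at known proportions with Illumina-like
substitution errors, and a skin-like equal-mass community of nine species,
four of which share one genus and two of which are near-identical sisters.
Near-identity can be specified two ways, matching how real genomes relate:

* ``shared_fraction`` — the sisters share a verbatim block (a fraction of
  the genome) and are random elsewhere, the regime where whole regions are
  ambiguous;
* ``divergence`` — the sister is a copy of its partner with i.i.d. point
  substitutions (e.g. 0.001 for 99.9% identity), the regime of genuinely
  near-identical species pairs whose differences are scattered SNPs.

A fixed seed makes every genome, read and report byte-identical across
runs.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .core import KrakenReport
from .distribution import UNCLASSIFIED, classify_sequence
from .kmer_index import GenomeRecord, KmerIndex
from .taxonomy import TaxonNode, TaxonomyTree

__all__ = [
    "SpeciesSpec",
    "CommunitySpec",
    "Community",
    "make_community",
    "simulate_reads",
    "simulate_kraken_report",
    "skin_like_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class SpeciesSpec:
    """One species of a mock community.

    ``sister_of`` names another species in the same genus whose sequence
    this one partially copies, either as a shared prefix block
    (``shared_fraction``) or as a point-mutated whole-genome copy
    (``divergence``); the two modes are mutually exclusive.
    """

    name: str
    genus: str
    genome_length: int
    proportion: float
    sister_of: str | None = None
    shared_fraction: float = 0.0
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError(f"{self.name}: genome_length must be positive")
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"{self.name}: proportion must be in [0, 1]")
        if not 0.0 <= self.shared_fraction < 1.0:
            raise ValueError(f"{self.name}: shared_fraction must be in [0, 1)")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError(f"{self.name}: divergence must be in [0, 1)")
        if self.sister_of is None and (self.shared_fraction or self.divergence):
            raise ValueError(f"{self.name}: sharing requires sister_of")
        if self.shared_fraction and self.divergence:
            raise ValueError(
                f"{self.name}: shared_fraction and divergence are mutually exclusive"
            )


@dataclass(frozen=True)
class CommunitySpec:
    """Full design of a mock community; the seed fixes all randomness."""

    species: tuple[SpeciesSpec, ...]
    n_reads: int
    read_length: int = 75
    error_rate: float = 0.0
    seed: int = 0
    k: int = 31

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("community needs at least one species")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        total = sum(s.proportion for s in self.species)
        if not math.isclose(total, 1.0, rel_tol=1e-6, abs_tol=1e-9):
            raise ValueError(f"proportions must sum to 1, got {total}")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        by_name = {s.name: s for s in self.species}
        for s in self.species:
            if s.sister_of is None:
                continue
            base = by_name.get(s.sister_of)
            if base is None:
                raise ValueError(f"{s.name}: unknown sister {s.sister_of!r}")
            if base.sister_of is not None:
                raise ValueError(f"{s.name}: sister chains are not supported")
            if base.genus != s.genus:
                raise ValueError(f"{s.name}: sisters must share a genus")
            if s.divergence and base.genome_length != s.genome_length:
                raise ValueError(
                    f"{s.name}: divergence mode requires equal genome lengths"
                )


@dataclass
class Community:
    """A realised community: taxonomy, genomes and the implied truth."""

    spec: CommunitySpec
    tree: TaxonomyTree
    genomes: list[GenomeRecord]
    taxid_by_name: dict[str, int]
    truth: dict[int, float]  # expected reads per species taxid

    @property
    def proportions(self) -> list[float]:
        by_taxid = {self.taxid_by_name[s.name]: s.proportion for s in self.spec.species}
        return [by_taxid[g.taxid] for g in self.genomes]


def _random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def make_community(spec: CommunitySpec) -> Community:
    """Build the taxonomy, the genomes and the truth table of a community.

    Genomes are random uniform ACGT sequences; a sister either copies its
    partner's prefix block verbatim or copies the whole genome and applies
    i.i.d. substitutions. Taxa are laid out root -> genus -> species, with
    genomes at the species leaves.
    """
    rng = np.random.default_rng(spec.seed)
    for s in spec.species:
        if s.genome_length < spec.read_length:
            raise ValueError(
                f"{s.name}: genome ({s.genome_length} bp) shorter than the "
                f"read length ({spec.read_length} bp)"
            )

    genera: list[str] = []
    for s in spec.species:
        if s.genus not in genera:
            genera.append(s.genus)
    genus_taxid = {g: 10 + i for i, g in enumerate(genera)}
    species_taxid = {s.name: 100 + i for i, s in enumerate(spec.species)}

    nodes = [TaxonNode(taxid=1, parent_taxid=1, rank="root", name="root")]
    nodes += [
        TaxonNode(taxid=t, parent_taxid=1, rank="genus", name=g)
        for g, t in genus_taxid.items()
    ]
    nodes += [
        TaxonNode(
            taxid=species_taxid[s.name],
            parent_taxid=genus_taxid[s.genus],
            rank="species",
            name=s.name,
        )
        for s in spec.species
    ]
    tree = TaxonomyTree(nodes)

    # Base species first so sisters can copy them; generation order is the
    # listed order within each group, keeping the construction deterministic.
    codes_by_name: dict[str, np.ndarray] = {}
    for s in spec.species:
        if s.sister_of is None:
            codes_by_name[s.name] = _random_codes(rng, s.genome_length)
    for s in spec.species:
        if s.sister_of is None:
            continue
        base = codes_by_name[s.sister_of]
        if s.divergence:
            codes = base.copy()
            mask = rng.random(s.genome_length) < s.divergence
            n_mut = int(mask.sum())
            if n_mut:
                shift = rng.integers(1, 4, size=n_mut, dtype=np.uint8)
                codes[mask] = (codes[mask] + shift) % 4
        else:
            n_shared = int(round(s.shared_fraction * s.genome_length))
            if n_shared > len(base):
                raise ValueError(f"{s.name}: shared block longer than sister genome")
            codes = np.concatenate(
                [base[:n_shared], _random_codes(rng, s.genome_length - n_shared)]
            )
        codes_by_name[s.name] = codes

    genomes = [
        GenomeRecord.from_sequence(
            species_taxid[s.name], _codes_to_str(codes_by_name[s.name])
        )
        for s in spec.species
    ]
    truth = {species_taxid[s.name]: s.proportion * spec.n_reads for s in spec.species}
    return Community(
        spec=spec,
        tree=tree,
        genomes=genomes,
        taxid_by_name=dict(species_taxid),
        truth=truth,
    )


def simulate_reads(
    genomes: Sequence[GenomeRecord],
    proportions: Sequence[float],
    n: int,
    r: int,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, int]]:
    """Draw n single-end reads of length r with substitution errors.

    Per-genome read counts are multinomial in the proportions; start
    positions are uniform over each genome's valid windows (never spanning
    contig boundaries); each base substitutes independently to a uniformly
    random different base with probability ``error_rate``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    if len(genomes) != len(proportions):
        raise ValueError("genomes and proportions must align")
    if not math.isclose(sum(proportions), 1.0, rel_tol=1e-6, abs_tol=1e-9):
        raise ValueError("proportions must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n, proportions) if n else np.zeros(len(genomes), dtype=int)

    reads: list[tuple[str, int]] = []
    for genome, count in zip(genomes, counts):
        if count == 0:
            continue
        contigs = [c for c in genome.contigs if len(c) >= r]
        if not contigs:
            raise ValueError(f"genome {genome.taxid} has no contig of at least {r} bp")
        windows = np.array([len(c) - r + 1 for c in contigs])
        offsets = np.concatenate([[0], np.cumsum(windows)])
        starts = rng.integers(0, offsets[-1], size=count)
        for s in starts:
            ci = int(np.searchsorted(offsets, s, side="right")) - 1
            pos = int(s - offsets[ci])
            read = contigs[ci][pos : pos + r]
            if error_rate:
                mask = rng.random(r) < error_rate
                if mask.any():
                    buf = bytearray(read, "ascii")
                    for j in np.flatnonzero(mask):
                        code = _CODE_OF.get(chr(buf[j]))
                        if code is None:
                            continue
                        buf[j] = _BASES[(code + int(rng.integers(1, 4))) % 4]
                    read = buf.decode("ascii")
            reads.append((read, genome.taxid))
    return reads


def simulate_kraken_report(
    reads: Sequence[tuple[str, int]], index: KmerIndex, tree: TaxonomyTree
) -> KrakenReport:
    """Classify every read against the index and tally a valid report."""
    direct: Counter[int] = Counter()
    unclassified = 0
    for seq, _true_taxid in reads:
        taxid = classify_sequence(seq, index, tree)
        if taxid == UNCLASSIFIED:
            unclassified += 1
        else:
            direct[taxid] += 1
    return KrakenReport.from_direct_counts(direct, tree, unclassified)


def skin_like_spec(
    n_reads: int = 100_000,
    read_length: int = 75,
    error_rate: float = 0.0,
    seed: int = 0,
    genome_length: int = 100_000,
    sister_divergence: float = 0.001,
) -> CommunitySpec:
    """Nine species mixed in equal proportions, skin-community style.

    Four species share one genus (mirroring the four staphylococci of the
    mock skin community) and two of those four are a near-identical sister
    pair (99.9% identity at the default divergence); the other five genera
    hold one species each. Each species contributes ~11.1% of the reads.

    The 100 kb default genome length keeps the build desk-scale while
    giving the sister pair ~100 scattered SNPs, so each genome's unique
    fraction is a stable property of the pair's divergence (as it is for
    real near-identical bacterial genomes) rather than a small-sample
    Poisson draw.
    """
    p = 1.0 / 9.0
    species = (
        SpeciesSpec("species_a1", "genus_a", genome_length, p),
        SpeciesSpec(
            "species_a2",
            "genus_a",
            genome_length,
            p,
            sister_of="species_a1",
            divergence=sister_divergence,
        ),
        SpeciesSpec("species_a3", "genus_a", genome_length, p),
        SpeciesSpec("species_a4", "genus_a", genome_length, p),
        SpeciesSpec("species_b", "genus_b", genome_length, p),
        SpeciesSpec("species_c", "genus_c", genome_length, p),
        SpeciesSpec("species_d", "genus_d", genome_length, p),
        SpeciesSpec("species_e", "genus_e", genome_length, p),
        SpeciesSpec("species_f", "genus_f", genome_length, p),
    )
    return CommunitySpec(
        species=species,
        n_reads=n_reads,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed,
    )
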
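"""Bayesian redistribution of Kraken read counts to a single taxonomic level.

A k-mer LCA classifier strands reads at internal nodes of the taxonomy
whenever their sequence is shared among several genomes. This module pushes
those stranded reads back down: for a read classified at node Gj, the
probability that it came from genome Si below is, by Bayes' theorem,

    P(Si|Gj) = P(Gj|Si) * P(Si) / P(Gj),    with P(Gj) = 1

because the read is conditioned on having been classified at Gj.
P(Gj|Si) comes from the precomputed k-mer distribution; the prior P(Si) is
estimated from the reads Kraken assigned uniquely to Si, inflated by the
genome's unique fraction (K_Si / U_Si) and normalised over the genomes of
the distributing node's subtree. Reads classified below the target level
(strains, unranked intermediates) simply roll up to their level ancestor.

All arithmetic is exact (``fractions.Fraction``); rounding happens only when
a table is serialised. Read conservation is the governing contract: every
classified read ends up in exactly one of a level taxon's estimate or the
unallocated pool.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from fractions import Fraction

from .distribution import UNCLASSIFIED, KmerDistribution
from .taxonomy import RANK_ORDER, TaxonomyTree, UnknownTaxidError

__all__ = [
    "EstimationConfig",
    "KrakenReport",
    "SpeciesEstimate",
    "NodeAllocation",
    "AbundanceRow",
    "AbundanceTable",
    "NoSignalError",
    "detect_taxa",
    "estimate_derived_total",
    "compute_priors",
    "allocate_node_reads",
    "estimate_abundance",
    "estimate_at_level",
]


class NoSignalError(ValueError):
    """All candidate genomes under a node have a zero derived read total."""


@dataclass(frozen=True)
class EstimationConfig:
    """Target level, detection threshold and the read length of the sample.

    The threshold (default 10 reads) excludes low-count taxa as likely false
    positives before any reads are redistributed; it applies to the rolled-up
    count of a level taxon (own reads plus everything below it).
    """

    level: str = "species"
    threshold: int = 10
    read_length: int = 75

    def __post_init__(self) -> None:
        if self.level not in RANK_ORDER:
            raise ValueError(f"unknown level {self.level!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.read_length < 1:
            raise ValueError("read length must be >= 1")


class KrakenReport:
    """Per-taxon direct and clade read counts (Kraken report semantics).

    ``direct(t)`` is the number of reads assigned to exactly node t;
    ``clade(t)`` covers t and all its descendants. The clade-sum invariant
    clade(t) == direct(t) + sum(clade(children)) holds by construction when
    built through :meth:`from_direct_counts`.
    """

    def __init__(
        self,
        direct: Mapping[int, int],
        clade: Mapping[int, int],
        unclassified: int = 0,
    ):
        for d in (direct, clade):
            for t, c in d.items():
                if t == UNCLASSIFIED:
                    raise ValueError("taxid 0 is reserved for unclassified reads")
                if c < 0 or int(c) != c:
                    raise ValueError(f"counts must be non-negative integers, got {c} at {t}")
        if unclassified < 0:
            raise ValueError("unclassified count must be >= 0")
        self._direct = {t: int(c) for t, c in direct.items() if c}
        self._clade = {t: int(c) for t, c in clade.items() if c}
        self.unclassified_count = int(unclassified)

    @classmethod
    def from_direct_counts(
        cls, direct: Mapping[int, int], tree: TaxonomyTree, unclassified: int = 0
    ) -> "KrakenReport":
        clade: dict[int, int] = defaultdict(int)
        for t, c in direct.items():
            if t not in tree:
                raise UnknownTaxidError(t)
            for a in tree.ancestor_path(t):
                clade[a] += c
        return cls(direct, clade, unclassified)

    def direct(self, taxid: int) -> int:
        return self._direct.get(taxid, 0)

    def clade(self, taxid: int) -> int:
        return self._clade.get(taxid, 0)

    def direct_taxids(self) -> tuple[int, ...]:
        return tuple(self._direct)

    def taxids(self) -> tuple[int, ...]:
        """All taxids with a nonzero clade count."""
        return tuple(self._clade)

    @property
    def classified_reads(self) -> int:
        return sum(self._direct.values())

    @property
    def total_reads(self) -> int:
        return self.classified_reads + self.unclassified_count

    def validate(self, tree: TaxonomyTree) -> None:
        """Check the clade-sum invariant against the tree; raise on violation."""
        for t in self._clade:
            expect = self.direct(t) + sum(self.clade(c) for c in tree.children(t))
            if self.clade(t) != expect:
                raise ValueError(
                    f"clade count invariant violated at taxid {t}: "
                    f"{self.clade(t)} != {expect}"
                )

    def __eq__(self, other) -> bool:
        if not isinstance(other, KrakenReport):
            return NotImplemented
        return (
            self._direct == other._direct
            and self._clade == other._clade
            and self.unclassified_count == other.unclassified_count
        )

    def __repr__(self) -> str:
        return (
            f"KrakenReport({self.classified_reads} classified over "
            f"{len(self._direct)} taxa, {self.unclassified_count} unclassified)"
        )


@dataclass
class SpeciesEstimate:
    """Per-genome quantities feeding the prior: K_Si, U_Si, K_Si/U_Si, P(Si)."""

    taxid: int
    kraken_count: Fraction
    unique_fraction: Fraction
    derived_total: Fraction
    prior: Fraction | None = None


@dataclass
class NodeAllocation:
    """Outcome of distributing one node's direct reads to genomes below it.

    Empty ``allocated`` means the reads could not be placed (no detected
    candidate, or all Bayes scores zero) and were counted as unallocated.
    """

    node: int
    node_reads: int
    shares: dict[int, Fraction] = field(default_factory=dict)
    allocated: dict[int, Fraction] = field(default_factory=dict)


@dataclass
class AbundanceRow:
    """One target-level taxon of the final table (exact internal arithmetic)."""

    name: str
    taxid: int
    level: str
    kraken_assigned_reads: int
    added_reads: Fraction
    new_est_reads: Fraction
    fraction_total_reads: Fraction


@dataclass
class AbundanceTable:
    """Final abundance estimates plus the reads that could not be placed."""

    rows: list[AbundanceRow]
    level: str
    total_reads: int
    unallocated_reads: Fraction
    unclassified_reads: int
    allocations: list[NodeAllocation] = field(default_factory=list)

    def row(self, taxid: int) -> AbundanceRow:
        for r in self.rows:
            if r.taxid == taxid:
                return r
        raise KeyError(taxid)

    @property
    def estimated_reads(self) -> dict[int, Fraction]:
        """taxid -> exact estimated read count (evaluation-ready mapping)."""
        return {r.taxid: r.new_est_reads for r in self.rows}

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "name": [r.name for r in self.rows],
                "taxonomy_id": [r.taxid for r in self.rows],
                "taxonomy_lvl": [r.level for r in self.rows],
                "kraken_assigned_reads": [r.kraken_assigned_reads for r in self.rows],
                "added_reads": [float(r.added_reads) for r in self.rows],
                "new_est_reads": [float(r.new_est_reads) for r in self.rows],
                "fraction_total_reads": [float(r.fraction_total_reads) for r in self.rows],
            }
        )


def detect_taxa(
    report: KrakenReport, config: EstimationConfig, tree: TaxonomyTree
) -> set[int]:
    """Target-level taxa whose rolled-up read count reaches the threshold.

    A taxon's rolled-up count is its own direct reads plus the direct reads
    of everything below it (its clade count); thresholding happens after
    strain roll-up, so 4 species reads + 7 strain reads pass a threshold
    of 10.
    """
    candidates = set()
    for t in report.direct_taxids():
        level = tree.level_ancestor(t, config.level)
        if level is not None:
            candidates.add(level)
    return {t for t in candidates if report.clade(t) >= max(config.threshold, 1)}


def estimate_derived_total(kraken_count, unique_fraction):
    """Estimated true reads from a genome: Kraken's count over U_Si.

    If Kraken assigns K reads directly to a genome but only a fraction U of
    the genome's windows classify uniquely, roughly K/U reads of the sample
    derive from that genome (e.g. 1000 reads at U=0.25 imply 4000).
    """
    if unique_fraction <= 0:
        raise ValueError("degenerate genome: unique fraction must be positive")
    if unique_fraction > 1:
        raise ValueError("unique fraction cannot exceed 1")
    return kraken_count / unique_fraction


def compute_priors(estimates: Sequence[SpeciesEstimate]) -> Sequence[SpeciesEstimate]:
    """Fill ``prior`` with each genome's share of the summed derived totals."""
    if not estimates:
        raise ValueError("no estimates to normalise")
    total = sum((e.derived_total for e in estimates), Fraction(0))
    if total == 0:
        raise NoSignalError("all derived read totals are zero")
    for e in estimates:
        e.prior = Fraction(e.derived_total) / total
    return estimates


def allocate_node_reads(
    node: int,
    node_reads: int,
    candidates: Sequence[tuple[int, Fraction, Fraction]],
    config: EstimationConfig | None = None,
) -> NodeAllocation:
    """Split a node's direct reads across candidate genomes by Bayes scores.

    ``candidates`` holds ``(genome taxid, P(node|genome), prior)`` triples.
    Scores are renormalised over the candidates (P(node)=1 given the read is
    classified there), so the allocation conserves ``node_reads`` exactly.
    An empty result signals that the reads are unallocated.
    """
    if node_reads < 0:
        raise ValueError("node_reads must be >= 0")
    scores = {g: Fraction(p) * Fraction(prior) for g, p, prior in candidates}
    total = sum(scores.values(), Fraction(0))
    if not candidates or total == 0:
        return NodeAllocation(node=node, node_reads=node_reads)
    shares = {g: s / total for g, s in scores.items()}
    allocated = {g: sh * node_reads for g, sh in shares.items()}
    return NodeAllocation(node=node, node_reads=node_reads, shares=shares, allocated=allocated)


def _genome_estimates(
    report: KrakenReport,
    dist: KmerDistribution,
    tree: TaxonomyTree,
    detected: set[int],
    genome_level: Mapping[int, int | None],
) -> dict[int, SpeciesEstimate]:
    """K_Si, U_Si and K_Si/U_Si for every genome under a detected level taxon.

    Direct reads at non-genome nodes inside a level taxon's subtree (the
    taxon itself, unranked intermediates, strain nodes absent from the
    distribution) are split across the taxon's genomes in proportion to
    their unique window counts, falling back to an even split when no
    genome has unique windows.
    """
    members: dict[int, list[int]] = defaultdict(list)
    for g, lvl in genome_level.items():
        if lvl is not None and lvl in detected:
            members[lvl].append(g)

    estimates: dict[int, SpeciesEstimate] = {}
    for lvl in detected:
        genomes = members.get(lvl)
        if not genomes:
            warnings.warn(
                f"detected taxon {lvl} has no genome in the distribution; "
                "reads stranded above it cannot be redistributed to it",
                RuntimeWarning,
                stacklevel=3,
            )
            continue
        leaf_direct = {g: report.direct(g) for g in genomes}
        sub_reads = report.clade(lvl) - sum(leaf_direct.values())
        unique_windows = {
            g: dist.per_genome[g].node_counts.get(g, 0) for g in genomes
        }
        unique_total = sum(unique_windows.values())
        for g in genomes:
            if unique_total:
                split = Fraction(unique_windows[g], unique_total)
            else:
                split = Fraction(1, len(genomes))
            kraken_count = leaf_direct[g] + split * sub_reads
            u = dist.per_genome[g].unique_fraction
            if u == 0:
                if kraken_count:
                    warnings.warn(
                        f"genome {g} has no unique windows; using its Kraken "
                        "count as the derived total",
                        RuntimeWarning,
                        stacklevel=3,
                    )
                derived = Fraction(kraken_count)
            else:
                derived = Fraction(kraken_count) / u
            estimates[g] = SpeciesEstimate(
                taxid=g,
                kraken_count=Fraction(kraken_count),
                unique_fraction=u,
                derived_total=derived,
            )
    return estimates


def estimate_abundance(
    report: KrakenReport,
    dist: KmerDistribution,
    tree: TaxonomyTree,
    config: EstimationConfig | None = None,
) -> AbundanceTable:
    """Redistribute a Kraken report onto the target level.

    The pipeline: (1) detect level taxa above the read threshold; (2) roll
    reads classified at or below a level taxon up into it; (3) for every
    node strictly above the level with direct reads, allocate those reads to
    the detected genomes in its subtree via Bayes scores, with priors
    normalised per distributing node; (4) sum roll-ups and allocations per
    level taxon. Reads in subtrees with no detected taxon are reported as
    unallocated, never dropped or pushed sideways.
    """
    config = config or EstimationConfig()
    if dist.read_length != config.read_length:
        warnings.warn(
            f"distribution was built for r={dist.read_length} but the sample "
            f"read length is {config.read_length}; proceeding (probabilities "
            "remain usable, at slightly reduced accuracy)",
            RuntimeWarning,
            stacklevel=2,
        )
    for t in report.direct_taxids():
        if t not in tree:
            raise UnknownTaxidError(t)

    level = config.level
    total = report.total_reads
    detected = detect_taxa(report, config, tree)
    genome_level = {g: tree.level_ancestor(g, level) for g in dist.per_genome}
    for g in dist.per_genome:
        if g not in tree:
            raise UnknownTaxidError(g)
    estimates = _genome_estimates(report, dist, tree, detected, genome_level)
    genome_paths = {g: set(tree.ancestor_path(g)) for g in estimates}

    added: dict[int, Fraction] = defaultdict(lambda: Fraction(0))
    unallocated = Fraction(0)
    allocations: list[NodeAllocation] = []

    for t in sorted(report.direct_taxids()):
        reads = report.direct(t)
        level_of_t = tree.level_ancestor(t, level)
        if level_of_t is not None:
            # At or below the level boundary: rolled up (or discarded with
            # its undetected taxon).
            if level_of_t not in detected:
                unallocated += reads
            continue
        candidates = [g for g in estimates if t in genome_paths[g]]
        if not candidates:
            unallocated += reads
            allocations.append(NodeAllocation(node=t, node_reads=reads))
            continue
        subtree_estimates = [replace(estimates[g]) for g in candidates]
        try:
            compute_priors(subtree_estimates)
        except NoSignalError:
            warnings.warn(
                f"node {t}: no genome below it carries signal; "
                f"{reads} reads left unallocated",
                RuntimeWarning,
                stacklevel=2,
            )
            unallocated += reads
            allocations.append(NodeAllocation(node=t, node_reads=reads))
            continue
        triples = [
            (
                e.taxid,
                dist.per_genome[e.taxid].node_fractions.get(t, Fraction(0)),
                e.prior,
            )
            for e in subtree_estimates
        ]
        alloc = allocate_node_reads(t, reads, triples, config)
        allocations.append(alloc)
        if not alloc.allocated:
            warnings.warn(
                f"node {t}: all Bayes scores are zero; {reads} reads left "
                "unallocated",
                RuntimeWarning,
                stacklevel=2,
            )
            unallocated += reads
        else:
            for g, amount in alloc.allocated.items():
                added[genome_level[g]] += amount

    rows = []
    for lvl in detected:
        kraken_assigned = report.clade(lvl)
        extra = added.get(lvl, Fraction(0))
        new_est = kraken_assigned + extra
        rows.append(
            AbundanceRow(
                name=tree.node(lvl).name,
                taxid=lvl,
                level=level,
                kraken_assigned_reads=kraken_assigned,
                added_reads=extra,
                new_est_reads=new_est,
                fraction_total_reads=(
                    Fraction(new_est) / total if total else Fraction(0)
                ),
            )
        )
    rows.sort(key=lambda r: (-r.new_est_reads, r.taxid))
    return AbundanceTable(
        rows=rows,
        level=level,
        total_reads=total,
        unallocated_reads=unallocated,
        unclassified_reads=report.unclassified_count,
        allocations=allocations,
    )


def estimate_at_level(
    report: KrakenReport,
    dist: KmerDistribution,
    tree: TaxonomyTree,
    level: str,
    *,
    threshold: int = 10,
    read_length: int | None = None,
) -> AbundanceTable:
    """Run the estimator with the level boundary moved to ``level``.

    Reads at or below the level roll up; reads above redistribute down with
    the same Bayes machinery, priors still anchored at genome granularity.
    """
    config = EstimationConfig(
        level=level,
        threshold=threshold,
        read_length=read_length if read_length is not None else dist.read_length,
    )
    return estimate_abundance(report, dist, tree, config)
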
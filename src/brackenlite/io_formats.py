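"""Readers and writers for every file format the tool touches.

All readers reject rather than silently repair malformed input, and every
writer/reader pair round-trips losslessly; the Kraken report and the
distribution TSV round-trip byte-identically. Byte-level examples of each
format live in ``docs/formats.md``.
"""

from __future__ import annotations

import io as _io
import os
from collections.abc import Iterable, Mapping
from fractions import Fraction

from Bio import SeqIO

from .core import AbundanceTable, KrakenReport
from .distribution import GenomeDistribution, KmerDistribution
from .kmer_index import GenomeRecord
from .taxonomy import TaxonomyTree, UnknownTaxidError

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_seqid_taxid_map",
    "write_seqid_taxid_map",
    "load_genome_records",
    "read_kraken_report",
    "write_kraken_report",
    "rank_code",
    "read_distribution",
    "write_distribution",
    "write_abundance_table",
    "read_truth_table",
    "write_truth_table",
]


class FormatError(ValueError):
    """Malformed input for one of the supported file dialects."""


def _read_text(source) -> str:
    """Accept a path, an open file, raw text, or an iterable of lines.

    A plain string is taken as a filesystem path unless it contains a
    newline, in which case it is the content itself (every writer in this
    module ends its output with a newline, so written text round-trips).
    """
    if isinstance(source, os.PathLike):
        with open(source, "r", encoding="utf-8") as fh:
            return fh.read()
    if isinstance(source, str):
        if "\n" in source or not source:
            return source
        with open(source, "r", encoding="utf-8") as fh:
            return fh.read()
    if hasattr(source, "read"):
        return source.read()
    return "\n".join(line.rstrip("\n") for line in source)


# -- FASTA -------------------------------------------------------------------


def read_fasta(source) -> list[tuple[str, str]]:
    """Ordered (id, sequence) pairs; ids are the first whitespace token.

    Sequences are uppercased and U is mapped to T. An empty file and
    sequence data before the first header are rejected.
    """
    text = _read_text(source)
    stripped = text.strip()
    if not stripped:
        raise ValueError("empty FASTA input")
    if not stripped.startswith(">"):
        raise FormatError("sequence data before the first FASTA header")
    records = [
        (rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(_io.StringIO(text), "fasta")
    ]
    if not records:
        raise ValueError("FASTA input contains no records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], width: int = 70) -> str:
    out = []
    for rid, seq in records:
        out.append(f">{rid}")
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"


# -- seqid -> taxid map --------------------------------------------------------


def read_seqid_taxid_map(source) -> dict[str, int]:
    """Two-column ``seqid<TAB>taxid`` map linking FASTA records to taxa."""
    mapping: dict[str, int] = {}
    for lineno, line in enumerate(_read_text(source).splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"seqid map line {lineno}: expected 2 tab-separated fields")
        seqid, taxid = fields
        if seqid in mapping:
            raise FormatError(f"seqid map: duplicate sequence id {seqid!r}")
        mapping[seqid] = int(taxid)
    return mapping


def write_seqid_taxid_map(mapping: Mapping[str, int]) -> str:
    return "".join(f"{s}\t{t}\n" for s, t in mapping.items())


def load_genome_records(
    fasta_source, map_source, tree: TaxonomyTree
) -> list[GenomeRecord]:
    """Group FASTA contigs by taxid into GenomeRecords (multi-contig aware)."""
    seq2tax = read_seqid_taxid_map(map_source)
    by_taxid: dict[int, list[str]] = {}
    for rid, seq in read_fasta(fasta_source):
        if rid not in seq2tax:
            raise FormatError(f"sequence id {rid!r} missing from the seqid->taxid map")
        by_taxid.setdefault(seq2tax[rid], []).append(seq)
    records = []
    for taxid, contigs in by_taxid.items():
        if taxid not in tree:
            raise UnknownTaxidError(taxid)
        records.append(GenomeRecord(taxid=taxid, contigs=tuple(contigs)))
    return records


# -- Kraken report ------------------------------------------------------------

_RANK_LETTER = {
    "root": "R",
    "domain": "D",
    "kingdom": "K",
    "phylum": "P",
    "class": "C",
    "order": "O",
    "family": "F",
    "genus": "G",
    "species": "S",
}


def rank_code(tree: TaxonomyTree, taxid: int) -> str:
    """Kraken rank code: a letter, or letter+digits for intermediate depths.

    Unranked or intermediate nodes (species groups, strains, ``no rank``)
    take the code of their nearest letter-ranked ancestor suffixed with the
    number of steps to it, e.g. a species group directly under a genus is
    ``G1`` and a strain under a species is ``S1``.
    """
    node = tree.node(taxid)
    if node.rank in _RANK_LETTER:
        return _RANK_LETTER[node.rank]
    steps = 0
    cur = taxid
    while True:
        cur = tree.node(cur).parent_taxid
        steps += 1
        rank = tree.node(cur).rank
        if rank in _RANK_LETTER:
            return _RANK_LETTER[rank] + str(steps)


def read_kraken_report(source, tree: TaxonomyTree) -> KrakenReport:
    """Parse the 6-column Kraken report dialect and validate clade sums."""
    direct: dict[int, int] = {}
    file_clade: dict[int, int] = {}
    unclassified = 0
    for lineno, line in enumerate(_read_text(source).splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise FormatError(
                f"report line {lineno}: expected 6 tab-separated fields, got {len(fields)}"
            )
        _, clade_s, direct_s, _, taxid_s, _ = fields
        taxid = int(taxid_s)
        clade_n = int(clade_s)
        direct_n = int(direct_s)
        if taxid == 0:
            unclassified = direct_n
            if clade_n != direct_n:
                raise FormatError("unclassified row must have clade == direct")
            continue
        if taxid not in tree:
            raise FormatError(f"report line {lineno}: unknown taxid {taxid}")
        if taxid in file_clade:
            raise FormatError(f"report line {lineno}: duplicate taxid {taxid}")
        file_clade[taxid] = clade_n
        if direct_n:
            direct[taxid] = direct_n
    report = KrakenReport.from_direct_counts(direct, tree, unclassified)
    for taxid, clade_n in file_clade.items():
        if report.clade(taxid) != clade_n:
            raise FormatError(
                f"clade count invariant violated at taxid {taxid}: file says "
                f"{clade_n}, direct counts imply {report.clade(taxid)}"
            )
    return report


def write_kraken_report(report: KrakenReport, tree: TaxonomyTree) -> str:
    """Depth-first emission; children by descending clade count then taxid."""
    total = report.total_reads
    lines: list[str] = []

    def pct(count: int) -> str:
        return f"{100 * count / total:.2f}" if total else "0.00"

    if report.unclassified_count:
        u = report.unclassified_count
        lines.append(f"{pct(u)}\t{u}\t{u}\tU\t0\tunclassified")

    def emit(taxid: int, depth: int) -> None:
        clade = report.clade(taxid)
        if clade == 0:
            return
        name = tree.node(taxid).name
        lines.append(
            f"{pct(clade)}\t{clade}\t{report.direct(taxid)}\t"
            f"{rank_code(tree, taxid)}\t{taxid}\t{'  ' * depth}{name}"
        )
        for child in sorted(tree.children(taxid), key=lambda c: (-report.clade(c), c)):
            emit(child, depth + 1)

    emit(tree.root, 0)
    return "\n".join(lines) + "\n" if lines else ""


# -- k-mer distribution TSV ----------------------------------------------------

_DIST_COLUMNS = "genome_taxid\tnode_taxid\tnode_rank\twindow_count\ttotal_windows\tfraction"


def write_distribution(dist: KmerDistribution, tree: TaxonomyTree) -> str:
    """Serialise a distribution; counts are the source of truth, fractions
    are serialised at full precision for human inspection and verified on
    read."""
    lines = [f"# k={dist.k}\tr={dist.read_length}", _DIST_COLUMNS]
    for si in sorted(dist.per_genome):
        gd = dist.per_genome[si]
        for gj in sorted(gd.node_counts, key=tree.depth):
            count = gd.node_counts[gj]
            frac = count / gd.num_windows
            lines.append(
                f"{si}\t{gj}\t{tree.node(gj).rank}\t{count}\t{gd.num_windows}\t{frac!r}"
            )
    return "\n".join(lines) + "\n"


def read_distribution(source) -> KmerDistribution:
    lines = _read_text(source).splitlines()
    if not lines or not lines[0].startswith("#"):
        raise FormatError("distribution file is missing its '# k=.. r=..' header")
    header = lines[0][1:].replace("\t", " ").split()
    meta = dict(part.split("=", 1) for part in header if "=" in part)
    if "k" not in meta or "r" not in meta:
        raise FormatError("distribution header must carry k and r")
    k, r = int(meta["k"]), int(meta["r"])

    counts: dict[int, dict[int, int]] = {}
    totals: dict[int, int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("genome_taxid"):
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise FormatError(f"distribution line {lineno}: expected 6 fields")
        si, gj = int(fields[0]), int(fields[1])
        count, total = int(fields[3]), int(fields[4])
        if float(fields[5]) != count / total:
            raise FormatError(
                f"distribution line {lineno}: fraction {fields[5]} does not "
                f"equal {count}/{total}"
            )
        if si in totals and totals[si] != total:
            raise FormatError(
                f"distribution line {lineno}: inconsistent total_windows for genome {si}"
            )
        totals[si] = total
        genome_counts = counts.setdefault(si, {})
        if gj in genome_counts:
            raise FormatError(f"distribution line {lineno}: duplicate node {gj}")
        genome_counts[gj] = count

    per_genome = {}
    for si, node_counts in counts.items():
        try:
            per_genome[si] = GenomeDistribution(
                taxid=si, num_windows=totals[si], node_counts=node_counts
            )
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    return KmerDistribution(read_length=r, k=k, per_genome=per_genome)


# -- abundance table -----------------------------------------------------------

_TABLE_HEADER = (
    "name\ttaxonomy_id\ttaxonomy_lvl\tkraken_assigned_reads\t"
    "added_reads\tnew_est_reads\tfraction_total_reads"
)


def write_abundance_table(table: AbundanceTable) -> str:
    """Bracken-style output TSV.

    Estimated reads are rounded half-to-even to integers at this boundary
    only; ``added_reads`` is derived from the rounded estimate so that the
    per-row identity kraken + added == new_est survives rounding.
    """
    lines = [_TABLE_HEADER]
    for row in table.rows:
        est = _round_half_even(row.new_est_reads)
        added = est - row.kraken_assigned_reads
        lines.append(
            f"{row.name}\t{row.taxid}\t{row.level}\t{row.kraken_assigned_reads}\t"
            f"{added}\t{est}\t{float(row.fraction_total_reads):.5f}"
        )
    return "\n".join(lines) + "\n"


def _round_half_even(value: Fraction) -> int:
    return round(Fraction(value))


def read_abundance_table(source) -> dict[int, tuple[str, float]]:
    """taxid -> (name, estimated reads) from a written abundance table."""
    lines = _read_text(source).splitlines()
    if not lines or lines[0] != _TABLE_HEADER:
        raise FormatError("abundance table header missing or malformed")
    out: dict[int, tuple[str, float]] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise FormatError("abundance table row must have 7 fields")
        out[int(fields[1])] = (fields[0], float(fields[5]))
    return out


# -- truth table (synthetic communities) ---------------------------------------


def write_truth_table(truth: Mapping[int, float], tree: TaxonomyTree) -> str:
    lines = ["name\ttaxonomy_id\treads"]
    for taxid in sorted(truth):
        lines.append(f"{tree.node(taxid).name}\t{taxid}\t{truth[taxid]!r}")
    return "\n".join(lines) + "\n"


def read_truth_table(source) -> dict[int, float]:
    lines = _read_text(source).splitlines()
    if not lines or lines[0] != "name\ttaxonomy_id\treads":
        raise FormatError("truth table header missing or malformed")
    out: dict[int, float] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError("truth table row must have 3 fields")
        out[int(fields[1])] = float(fields[2])
    return out
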
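"""Independent brute-force re-implementations used as test oracles.

Everything here works from first principles on plain dicts and strings —
parent maps, ancestor-list intersections, window slicing — deliberately
sharing no code with the package so that agreement is meaningful.
"""

from __future__ import annotations

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def o_revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def o_canonical(s: str) -> str:
    return min(s, o_revcomp(s))


def o_path(parent: dict[int, int], t: int) -> list[int]:
    """Root-to-t path from a raw parent map."""
    out = [t]
    while parent[t] != t:
        t = parent[t]
        out.append(t)
    return list(reversed(out))


def o_depth(parent: dict[int, int], t: int) -> int:
    return len(o_path(parent, t)) - 1


def o_lca(parent: dict[int, int], a: int, b: int) -> int:
    pa, pb = o_path(parent, a), o_path(parent, b)
    out = pa[0]
    for x, y in zip(pa, pb):
        if x != y:
            break
        out = x
    return out


def o_lca_set(parent: dict[int, int], taxa) -> int:
    taxa = list(taxa)
    out = taxa[0]
    for t in taxa[1:]:
        out = o_lca(parent, out, t)
    return out


def o_kmer_index(genome_seqs: dict[int, list[str]], k: int, parent: dict[int, int]) -> dict[str, int]:
    """Canonical k-mer string -> LCA of all genomes containing it."""
    occurrences: dict[str, set[int]] = {}
    for taxid, contigs in genome_seqs.items():
        for contig in contigs:
            for i in range(len(contig) - k + 1):
                kmer = contig[i : i + k]
                if "N" in kmer:
                    continue
                occurrences.setdefault(o_canonical(kmer), set()).add(taxid)
    return {kmer: o_lca_set(parent, taxa) for kmer, taxa in occurrences.items()}


def o_genome_distribution(
    taxid: int,
    contigs: list[str],
    index: dict[str, int],
    parent: dict[int, int],
    k: int,
    r: int,
) -> tuple[int, dict[int, int]]:
    """Window-by-window tally re-derived from raw strings.

    Windows never span contigs; a window's label is the deepest k-mer
    assignment within it, or the root if every k-mer overlaps an N.
    """
    root = next(t for t, p in parent.items() if p == t)
    counts: dict[int, int] = {}
    num_windows = 0
    for contig in contigs:
        if len(contig) < r:
            continue
        for j in range(len(contig) - r + 1):
            window = contig[j : j + r]
            labels = []
            for i in range(len(window) - k + 1):
                kmer = window[i : i + k]
                if "N" in kmer:
                    continue
                labels.append(index[o_canonical(kmer)])
            if labels:
                label = max(labels, key=lambda t: o_depth(parent, t))
            else:
                label = root
            counts[label] = counts.get(label, 0) + 1
            num_windows += 1
    return num_windows, counts


def o_classify_read(hits: list[int], parent: dict[int, int]) -> int:
    """Classify by exhaustively scoring every root-to-leaf path."""
    if not hits:
        return 0
    children: dict[int, set[int]] = {t: set() for t in parent}
    for t, p in parent.items():
        if t != p:
            children[p].add(t)
    leaves = [t for t, cs in children.items() if not cs]
    best_weight = -1
    winners: list[int] = []
    for leaf in leaves:
        path = o_path(parent, leaf)
        weight = sum(1 for h in hits if h in path)
        on_path = [h for h in hits if h in path]
        if not on_path:
            continue
        deepest_hit = max(on_path, key=lambda t: o_depth(parent, t))
        if weight > best_weight:
            best_weight = weight
            winners = [deepest_hit]
        elif weight == best_weight and deepest_hit not in winners:
            winners.append(deepest_hit)
    return o_lca_set(parent, winners)
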
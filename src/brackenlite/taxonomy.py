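"""Taxonomic tree with NCBI-dialect dump parsing, LCA and rank queries.

The tree is the backbone of the whole package: the k-mer index assigns
k-mers to lowest common ancestors, the distribution builder walks
root-to-leaf paths, and the redistribution engine moves reads along them.
Ranks form a closed, totally ordered vocabulary (``RANK_ORDER``) so that
"above the species level" is a well defined notion; NCBI's ``no rank``
nodes are kept but act as pass-throughs for level queries.
"""

from __future__ import annotations

import io
import os
from collections.abc import Iterable
from dataclasses import dataclass

__all__ = [
    "RANK_ORDER",
    "NO_RANK",
    "RANKS",
    "TaxonNode",
    "TaxonomyTree",
    "TaxonomyError",
    "UnknownTaxidError",
    "normalize_rank",
    "load_taxonomy",
    "write_nodes_dmp",
    "write_names_dmp",
]

#: Ranked levels from shallowest to deepest. ``species-group`` (e.g. the
#: Mycobacterium tuberculosis complex) sits strictly between genus and
#: species; genomes are always leaves at or below species.
RANK_ORDER: tuple[str, ...] = (
    "root",
    "domain",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species-group",
    "species",
    "strain",
)

NO_RANK = "no rank"
RANKS = frozenset(RANK_ORDER) | {NO_RANK}

_RANK_ALIASES = {
    "species group": "species-group",
    "superkingdom": "domain",
    "leaf": "strain",
    "no-rank": NO_RANK,
}


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy (orphan, cycle, duplicate, no root)."""


class UnknownTaxidError(KeyError):
    """A taxid was queried that is not present in the tree."""


def normalize_rank(rank: str) -> str:
    """Map an input rank label onto the closed vocabulary.

    Unrecognised labels (NCBI has dozens of minor ranks) are treated as
    ``no rank``: they stay in the tree but are transparent to level queries.
    """
    r = rank.strip().lower()
    r = _RANK_ALIASES.get(r, r)
    return r if r in RANKS else NO_RANK


@dataclass(frozen=True)
class TaxonNode:
    """One taxon: taxid, parent taxid (root points to itself), rank, name."""

    taxid: int
    parent_taxid: int
    rank: str
    name: str

    def __post_init__(self) -> None:
        if self.taxid <= 0 or self.parent_taxid <= 0:
            raise TaxonomyError(f"taxids must be positive, got {self.taxid}->{self.parent_taxid}")
        if self.rank not in RANKS:
            raise TaxonomyError(f"unknown rank {self.rank!r} for taxid {self.taxid}")


class TaxonomyTree:
    """Rooted taxonomy supporting LCA, ancestor paths and rank queries."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[int, TaxonNode] = {}
        for n in nodes:
            if n.taxid in self._nodes:
                raise TaxonomyError(f"duplicate taxid {n.taxid}")
            self._nodes[n.taxid] = n
        if not self._nodes:
            raise TaxonomyError("taxonomy has no nodes")

        roots = [t for t, n in self._nodes.items() if n.parent_taxid == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root (parent==self), found {len(roots)}"
            )
        self._root = roots[0]

        children: dict[int, list[int]] = {t: [] for t in self._nodes}
        for t, n in self._nodes.items():
            if t == self._root:
                continue
            if n.parent_taxid not in self._nodes:
                raise TaxonomyError(f"orphan taxid {t}: parent {n.parent_taxid} missing")
            children[n.parent_taxid].append(t)
        self._children = {t: tuple(sorted(cs)) for t, cs in children.items()}

        # Reachability / cycle check by walking up with memoised depths.
        self._depth: dict[int, int] = {self._root: 0}
        for t in self._nodes:
            chain = []
            cur = t
            while cur not in self._depth:
                if cur in chain:
                    raise TaxonomyError(f"cycle detected at taxid {cur}")
                chain.append(cur)
                cur = self._nodes[cur].parent_taxid
            base = self._depth[cur]
            for i, c in enumerate(reversed(chain), start=1):
                self._depth[c] = base + i
        self._paths: dict[int, tuple[int, ...]] = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def root(self) -> int:
        return self._root

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __iter__(self):
        return iter(self._nodes)

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def children(self, taxid: int) -> tuple[int, ...]:
        self.node(taxid)
        return self._children[taxid]

    def is_leaf(self, taxid: int) -> bool:
        return not self.children(taxid)

    def leaves(self) -> list[int]:
        return [t for t in self._nodes if not self._children[t]]

    def depth(self, taxid: int) -> int:
        self.node(taxid)
        return self._depth[taxid]

    # -- path queries ------------------------------------------------------

    def ancestor_path(self, taxid: int) -> tuple[int, ...]:
        """Taxids from the root down to (and including) ``taxid``."""
        cached = self._paths.get(taxid)
        if cached is not None:
            return cached
        self.node(taxid)
        rev = []
        cur = taxid
        while cur != self._root:
            rev.append(cur)
            cur = self._nodes[cur].parent_taxid
        rev.append(self._root)
        path = tuple(reversed(rev))
        self._paths[taxid] = path
        return path

    def lca(self, a: int, b: int) -> int:
        """Lowest common ancestor by ancestor-path intersection."""
        pa = self.ancestor_path(a)
        pb = self.ancestor_path(b)
        out = self._root
        for x, y in zip(pa, pb):
            if x != y:
                break
            out = x
        return out

    def is_ancestor(self, anc: int, taxid: int) -> bool:
        """True if ``anc`` is an ancestor of or equal to ``taxid``."""
        return anc in self.ancestor_path(taxid)

    # -- rank queries ------------------------------------------------------

    def subtree(self, taxid: int):
        """Preorder iterator over the subtree rooted at ``taxid``."""
        stack = [taxid]
        self.node(taxid)
        while stack:
            t = stack.pop()
            yield t
            stack.extend(reversed(self._children[t]))

    def descendants_at_rank(self, taxid: int, rank: str) -> set[int]:
        """All nodes of ``rank`` in the subtree rooted at ``taxid`` (incl. itself)."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return {t for t in self.subtree(taxid) if self._nodes[t].rank == rank}

    def level_ancestor(self, taxid: int, rank: str) -> int | None:
        """Nearest ancestor-or-self with exactly ``rank``, or ``None``.

        ``no rank`` nodes are transparent: the level of a taxon is defined by
        ranked ancestors only.
        """
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        for t in reversed(self.ancestor_path(taxid)):
            if self._nodes[t].rank == rank:
                return t
        return None


# -- NCBI dump dialect I/O ---------------------------------------------------


def _as_lines(source) -> Iterable[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
        return
    if hasattr(source, "read"):
        yield from io.StringIO(source.read())
        return
    yield from source


def _dmp_fields(line: str) -> list[str]:
    return [f.strip(" \t") for f in line.rstrip("\n").rstrip("|\t ").split("|")]


def load_taxonomy(nodes_source, names_source=None) -> TaxonomyTree:
    """Parse pipe-delimited ``nodes.dmp`` / ``names.dmp`` sources.

    Only the first three columns of the nodes source (taxid, parent, rank)
    and "scientific name" rows of the names source are consumed. Nodes
    without a name get ``taxid:<id>``.
    """
    rows: list[tuple[int, int, str]] = []
    for line in _as_lines(nodes_source):
        if not line.strip():
            continue
        fields = _dmp_fields(line)
        if len(fields) < 3:
            raise TaxonomyError(f"nodes row has fewer than 3 fields: {line!r}")
        rows.append((int(fields[0]), int(fields[1]), normalize_rank(fields[2])))

    names: dict[int, str] = {}
    if names_source is not None:
        for line in _as_lines(names_source):
            if not line.strip():
                continue
            fields = _dmp_fields(line)
            if len(fields) < 2:
                continue
            name_class = fields[3] if len(fields) > 3 else "scientific name"
            if name_class == "scientific name":
                names[int(fields[0])] = fields[1]

    nodes = [
        TaxonNode(taxid=t, parent_taxid=p, rank=r, name=names.get(t, f"taxid:{t}"))
        for t, p, r in rows
    ]
    return TaxonomyTree(nodes)


def write_nodes_dmp(tree: TaxonomyTree) -> str:
    """Serialise the tree in the nodes.dmp dialect (taxid | parent | rank |)."""
    lines = []
    for t in sorted(tree):
        n = tree.node(t)
        lines.append(f"{n.taxid}\t|\t{n.parent_taxid}\t|\t{n.rank}\t|")
    return "\n".join(lines) + "\n"


def write_names_dmp(tree: TaxonomyTree) -> str:
    """Serialise scientific names in the names.dmp dialect."""
    lines = []
    for t in sorted(tree):
        n = tree.node(t)
        lines.append(f"{n.taxid}\t|\t{n.name}\t|\t\t|\tscientific name\t|")
    return "\n".join(lines) + "\n"
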
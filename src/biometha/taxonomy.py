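"""Rank-annotated rooted taxonomies and lowest-common-ancestor queries.

A taxonomy is stored as a flat node table (child -> parent, rank, name)
rooted at a single self-parented node, the shape produced by flattening
NCBI-style ``nodes.dmp``/``names.dmp`` dumps.  Bins are assigned a
conservative taxonomic level by taking the closest (deepest) common
ancestor of their top-scoring taxa, so the central query here is
:func:`lca`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "RANKS",
    "TaxNode",
    "TaxonomyTree",
    "ValidationReport",
    "lca",
    "validate_taxonomy",
    "read_taxonomy",
    "write_taxonomy",
    "read_ncbi_dmp",
]

#: Canonical rank vocabulary, shallowest first.  Ranks outside this list are
#: preserved verbatim on nodes but excluded from rank-level summaries.
RANKS: tuple[str, ...] = (
    "root",
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


def rank_depth(rank: str) -> int | None:
    """Position of *rank* in the canonical vocabulary, or None if unknown."""
    return _RANK_DEPTH.get(rank)


def rank_at_or_below(rank: str, reference: str) -> bool:
    """True iff *rank* is at least as deep as *reference* (both canonical)."""
    d, r = _RANK_DEPTH.get(rank), _RANK_DEPTH.get(reference)
    if d is None or r is None:
        return False
    return d >= r


@dataclass(frozen=True)
class TaxNode:
    parent: str
    rank: str
    name: str


@dataclass
class ValidationReport:
    """Structural defects found in a node table."""

    multiple_roots: list[str] = field(default_factory=list)
    missing_root: bool = False
    orphans: list[str] = field(default_factory=list)  # parent id not in table
    cycles: list[str] = field(default_factory=list)  # nodes on/under a loop

    @property
    def ok(self) -> bool:
        return not (self.multiple_roots or self.missing_root or self.orphans or self.cycles)

    def summary(self) -> str:
        if self.ok:
            return "taxonomy OK"
        parts = []
        if self.missing_root:
            parts.append("no self-parented root")
        if self.multiple_roots:
            parts.append(f"multiple roots: {sorted(self.multiple_roots)}")
        if self.orphans:
            parts.append(f"orphan nodes (unknown parent): {sorted(self.orphans)}")
        if self.cycles:
            parts.append(f"nodes in parent cycles: {sorted(self.cycles)}")
        return "; ".join(parts)


class TaxonomyTree:
    """Rooted taxonomy supporting ancestor and LCA queries.

    Parameters
    ----------
    nodes:
        Mapping node-id -> (parent-id, rank, name).  The root is its own
        parent.  Construction does not validate; call
        :func:`validate_taxonomy` (loaders do this with ``strict=True``).
    """

    def __init__(self, nodes: Mapping[str, TaxNode]):
        self.nodes: dict[str, TaxNode] = dict(nodes)
        roots = [n for n, rec in self.nodes.items() if rec.parent == n]
        self.root: str | None = roots[0] if len(roots) == 1 else None
        self._path_cache: dict[str, tuple[str, ...]] = {}

    # -- basic queries -------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def rank(self, node_id: str) -> str:
        return self.nodes[node_id].rank

    def name(self, node_id: str) -> str:
        return self.nodes[node_id].name

    def parent(self, node_id: str) -> str:
        return self.nodes[node_id].parent

    def path_to_root(self, node_id: str) -> tuple[str, ...]:
        """Node ids from *node_id* up to and including the root.

        Raises KeyError for unknown ids and ValueError if a parent loop is
        encountered (malformed trees should be caught by validation first).
        """
        cached = self._path_cache.get(node_id)
        if cached is not None:
            return cached
        if node_id not in self.nodes:
            raise KeyError(f"unknown taxonomy node: {node_id!r}")
        path = []
        seen = set()
        cur = node_id
        while True:
            if cur in seen:
                raise ValueError(f"parent cycle at node {cur!r}")
            seen.add(cur)
            path.append(cur)
            nxt = self.nodes[cur].parent
            if nxt == cur:
                break
            if nxt not in self.nodes:
                raise KeyError(f"node {cur!r} has unknown parent {nxt!r}")
            cur = nxt
        result = tuple(path)
        self._path_cache[node_id] = result
        return result

    def ancestors(self, node_id: str) -> tuple[str, ...]:
        """Ancestor-or-self set of *node_id*, ordered node -> root."""
        return self.path_to_root(node_id)

    def is_ancestor(self, anc: str, node_id: str) -> bool:
        """True iff *anc* is an ancestor-or-self of *node_id*."""
        return anc in self.path_to_root(node_id)

    def depth(self, node_id: str) -> int:
        """Edges from the root (root has depth 0)."""
        return len(self.path_to_root(node_id)) - 1

    def ancestor_at_rank(self, node_id: str, rank: str) -> str | None:
        """The ancestor-or-self of *node_id* carrying *rank*, if any."""
        for n in self.path_to_root(node_id):
            if self.nodes[n].rank == rank:
                return n
        return None

    def domain_of(self, node_id: str) -> str | None:
        return self.ancestor_at_rank(node_id, "domain")

    def children(self, node_id: str) -> list[str]:
        return [n for n, rec in self.nodes.items() if rec.parent == node_id and n != node_id]


def lca(taxa: Iterable[str], tree: TaxonomyTree) -> str:
    """Closest (deepest) common ancestor of a non-empty set of nodes.

    The result is an ancestor-or-self of every input node; for a singleton
    set it is the node itself, and for nodes spanning both domains it is
    the root.
    """
    taxa = list(dict.fromkeys(taxa))
    if not taxa:
        raise ValueError("lca() requires a non-empty taxon set")
    for t in taxa:
        if t not in tree:
            raise KeyError(f"unknown taxonomy node: {t!r}")
    # Compare root->node paths and keep the deepest shared prefix.
    paths = [tree.path_to_root(t)[::-1] for t in taxa]
    ancestor = paths[0][0]
    for level in range(min(len(p) for p in paths)):
        step = paths[0][level]
        if all(p[level] == step for p in paths):
            ancestor = step
        else:
            break
    return ancestor


def validate_taxonomy(tree: TaxonomyTree | Mapping[str, TaxNode]) -> ValidationReport:
    """Report structural defects: missing/multiple roots, orphans, cycles."""
    nodes = tree.nodes if isinstance(tree, TaxonomyTree) else dict(tree)
    report = ValidationReport()
    roots = [n for n, rec in nodes.items() if rec.parent == n]
    if not roots:
        report.missing_root = True
    elif len(roots) > 1:
        report.multiple_roots = sorted(roots)
    root_set = set(roots)
    OK, CYCLE, BROKEN = 1, 2, 3
    state: dict[str, int] = {}

    for start in nodes:
        if start in state:
            continue
        walk: list[str] = []
        on_walk: set[str] = set()
        cur = start
        while True:
            if cur in state:
                verdict = state[cur]
                break
            if cur in on_walk:
                verdict = CYCLE
                break
            walk.append(cur)
            on_walk.add(cur)
            if cur in root_set:
                verdict = OK
                break
            parent = nodes[cur].parent
            if parent not in nodes:
                report.orphans.append(cur)
                verdict = BROKEN
                break
            cur = parent
        for n in walk:
            state[n] = verdict
            if verdict == CYCLE:
                report.cycles.append(n)
    report.orphans = sorted(set(report.orphans))
    report.cycles = sorted(set(report.cycles))
    return report


# -- file formats ------------------------------------------------------


def read_taxonomy(path: str | Path, *, strict: bool = True) -> TaxonomyTree:
    """Load a 4-column TSV ``node_id  parent_id  rank  name`` (header optional)."""
    nodes: dict[str, TaxNode] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if i == 1 and row[0].lower() in {"node_id", "taxid", "id"}:
                continue
            if len(row) < 4:
                raise ValueError(f"{path}: line {i}: expected 4 columns, got {len(row)}")
            node_id, parent, rank, name = (c.strip() for c in row[:4])
            if node_id in nodes:
                raise ValueError(f"{path}: line {i}: duplicate node id {node_id!r}")
            nodes[node_id] = TaxNode(parent=parent, rank=rank, name=name)
    tree = TaxonomyTree(nodes)
    if strict:
        report = validate_taxonomy(tree)
        if not report.ok:
            raise ValueError(f"{path}: invalid taxonomy: {report.summary()}")
    return tree


def write_taxonomy(tree: TaxonomyTree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tparent_id\trank\tname\n")
        for node_id in sorted(tree.nodes):
            rec = tree.nodes[node_id]
            fh.write(f"{node_id}\t{rec.parent}\t{rec.rank}\t{rec.name}\n")


_NCBI_RANK_MAP = {"superkingdom": "domain", "no rank": "root"}


def read_ncbi_dmp(nodes_path: str | Path, names_path: str | Path, *, strict: bool = True) -> TaxonomyTree:
    """Import NCBI-style ``nodes.dmp``/``names.dmp`` dumps.

    Fields are '|'-separated with tab padding; only scientific names are
    used.  ``superkingdom`` maps onto the ``domain`` rank and taxid 1
    becomes the root.
    """
    names: dict[str, str] = {}
    with open(names_path, encoding="utf-8") as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\t|\n").split("\t|\t")]
            if len(parts) >= 4 and parts[3] == "scientific name":
                names[parts[0]] = parts[1]
            elif len(parts) >= 2 and parts[0] not in names:
                names.setdefault(parts[0], parts[1])
    nodes: dict[str, TaxNode] = {}
    with open(nodes_path, encoding="utf-8") as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\t|\n").split("\t|\t")]
            if len(parts) < 3:
                continue
            taxid, parent, rank = parts[0], parts[1], parts[2]
            rank = _NCBI_RANK_MAP.get(rank, rank)
            if taxid == parent and rank not in RANKS:
                rank = "root"
            nodes[taxid] = TaxNode(parent=parent, rank=rank, name=names.get(taxid, taxid))
    tree = TaxonomyTree(nodes)
    if strict:
        report = validate_taxonomy(tree)
        if not report.ok:
            raise ValueError(f"invalid taxonomy dump: {report.summary()}")
    return tree
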
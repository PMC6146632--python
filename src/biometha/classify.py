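"""Fragment-vote taxonomic classification of genomic bins.

Each contig of a bin is split into 1000-bp fragments; every fragment
contributes one vote, the subject taxon of its top-scoring alignment
hit.  Per-taxon scores are vote counts divided by the number of
fragments in the bin, and the bin is assigned to the closest common
ancestor of the top-scoring taxa — so a bin whose fragments split
between two sibling species lands on their genus, and one split across
domains lands at the root and is flagged as hybrid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import HitRecord
from .taxonomy import TaxonomyTree, lca

__all__ = [
    "FragmentationConfig",
    "Fragment",
    "fragment_contig",
    "top_hit",
    "TaxonScoreVector",
    "score_taxa",
    "BinAssignment",
    "classify_bin",
    "flag_hybrid",
    "classify_bins",
    "read_bin_membership",
]


@dataclass(frozen=True)
class FragmentationConfig:
    fragment_bp: int = 1000
    min_tail_bp: int = 200

    def __post_init__(self) -> None:
        if not (self.fragment_bp >= self.min_tail_bp >= 1):
            raise ValueError("require fragment_bp >= min_tail_bp >= 1")


@dataclass(frozen=True)
class Fragment:
    contig_id: str
    index: int
    start: int  # 1-based inclusive
    end: int

    @property
    def fragment_id(self) -> str:
        return f"{self.contig_id}_f{self.index}"

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def fragment_contig(
    contig_id: str,
    length_bp: int,
    cfg: FragmentationConfig | None = None,
) -> list[Fragment]:
    """Split a contig into consecutive non-overlapping windows.

    Windows are ``fragment_bp`` long; a terminal remainder shorter than
    ``min_tail_bp`` is merged into the previous window rather than kept
    as a tiny fragment (a 2100-bp contig yields [1,1000], [1001,2100]).
    """
    cfg = cfg or FragmentationConfig()
    if length_bp < 1:
        raise ValueError(f"contig {contig_id!r}: non-positive length")
    bounds: list[tuple[int, int]] = []
    pos = 1
    while pos + cfg.fragment_bp - 1 <= length_bp:
        bounds.append((pos, pos + cfg.fragment_bp - 1))
        pos += cfg.fragment_bp
    tail = length_bp - pos + 1
    if tail > 0:
        if tail >= cfg.min_tail_bp or not bounds:
            bounds.append((pos, length_bp))
        else:
            start, _ = bounds[-1]
            bounds[-1] = (start, length_bp)
    return [Fragment(contig_id=contig_id, index=i, start=s, end=e) for i, (s, e) in enumerate(bounds)]


def top_hit(hits: Sequence[HitRecord]) -> HitRecord | None:
    """The fragment's single best hit; None when the fragment has no hits.

    Maximal bit score wins; ties break by lower e-value, then
    lexicographically smaller subject id, so runs are reproducible.
    """
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    return min(hits, key=lambda h: (-h.bit_score, h.e_value, h.subject_id))


@dataclass
class TaxonScoreVector:
    """Per-taxon fragment-vote fractions for one bin.

    ``scores[t]`` is the number of fragments whose top hit maps to taxon
    *t* divided by the total number of fragments in the bin, so scores
    sum to at most 1 (no-hit fragments contribute nothing).
    """

    scores: dict[str, float]
    n_fragments: int

    def __post_init__(self) -> None:
        if self.n_fragments < 1:
            raise ValueError("a bin must contain at least one fragment")
        if any(v < 0 for v in self.scores.values()):
            raise ValueError("negative taxon score")
        if sum(self.scores.values()) > 1 + 1e-9:
            raise ValueError("taxon scores sum above 1")

    @property
    def max_score(self) -> float:
        return max(self.scores.values(), default=0.0)

    def top_scoring(self, top_frac: float = 0.8, min_score: float = 0.0) -> list[str]:
        """Taxa scoring within ``top_frac`` of the maximum (and above ``min_score``)."""
        if not self.scores:
            return []
        cutoff = top_frac * self.max_score
        return sorted(t for t, s in self.scores.items() if s >= cutoff and s > min_score)


def score_taxa(
    fragment_top_taxa: Iterable[str | None],
    n_fragments: int | None = None,
) -> TaxonScoreVector:
    """Tally per-fragment top-hit taxa into a score vector.

    *fragment_top_taxa* holds one entry per fragment: the taxon of its
    top hit or None for hitless fragments.  ``n_fragments`` defaults to
    the sequence length and must be >= 1.
    """
    taxa = list(fragment_top_taxa)
    if n_fragments is None:
        n_fragments = len(taxa)
    if n_fragments < 1:
        raise ValueError("n_fragments must be at least 1")
    counts: dict[str, int] = {}
    for t in taxa:
        if t is not None:
            counts[t] = counts.get(t, 0) + 1
    return TaxonScoreVector(
        scores={t: c / n_fragments for t, c in sorted(counts.items())},
        n_fragments=n_fragments,
    )


@dataclass
class BinAssignment:
    bin_id: str
    node: str | None  # None = unclassified
    rank: str | None
    score_max: float
    top_set: list[str] = field(default_factory=list)
    hybrid: bool = False

    @property
    def classified(self) -> bool:
        return self.node is not None


def classify_bin(
    scores: TaxonScoreVector,
    tree: TaxonomyTree,
    top_frac: float = 0.8,
    min_score: float = 0.0,
    bin_id: str = "",
) -> BinAssignment:
    """Assign a bin to the closest common ancestor of its top-scoring taxa.

    The top-scoring set is every taxon within ``top_frac`` of the best
    score (``top_frac=1.0`` recovers strict-max behaviour); an empty
    vector yields an unclassified assignment.
    """
    top = scores.top_scoring(top_frac=top_frac, min_score=min_score)
    if not top:
        return BinAssignment(bin_id=bin_id, node=None, rank=None, score_max=0.0)
    node = lca(top, tree)
    return BinAssignment(
        bin_id=bin_id,
        node=node,
        rank=tree.rank(node),
        score_max=scores.max_score,
        top_set=top,
    )


def flag_hybrid(
    assignment: BinAssignment,
    tree: TaxonomyTree,
    completeness_pct: float | None = None,
) -> bool:
    """Flag bins whose top-scoring taxa span both Bacteria and Archaea.

    True iff the assigned node sits at or above domain level and the top
    set covers more than one domain.  Such bins typically have very low
    completeness (below 20%); when a completeness value is supplied it
    is recorded on the assignment report as the suspected cause.
    """
    if not assignment.classified or not assignment.top_set:
        return False
    from .taxonomy import rank_depth

    d = rank_depth(assignment.rank) if assignment.rank else None
    at_or_above_domain = d is not None and d <= rank_depth("domain")
    domains = {tree.domain_of(t) for t in assignment.top_set}
    domains.discard(None)
    hybrid = at_or_above_domain and len(domains) > 1
    assignment.hybrid = hybrid
    return hybrid


def classify_bins(
    bin_fragments: Mapping[str, int],
    fragment_hits: Mapping[str, Sequence[HitRecord]],
    bin_of_fragment: Mapping[str, str],
    tree: TaxonomyTree,
    top_frac: float = 0.8,
    min_score: float = 0.0,
) -> dict[str, BinAssignment]:
    """End-to-end classification of many bins.

    Parameters
    ----------
    bin_fragments:
        bin id -> total number of fragments in the bin (hitless included).
    fragment_hits:
        fragment id -> hits for that fragment.
    bin_of_fragment:
        fragment id -> owning bin id.
    """
    votes: dict[str, list[str | None]] = {b: [] for b in bin_fragments}
    for frag_id, hits in fragment_hits.items():
        bin_id = bin_of_fragment.get(frag_id)
        if bin_id is None:
            raise KeyError(f"fragment {frag_id!r} belongs to no bin")
        best = top_hit(list(hits))
        if best is not None and best.subject_taxon is not None:
            votes[bin_id].append(best.subject_taxon)
    out: dict[str, BinAssignment] = {}
    for bin_id, n_frag in bin_fragments.items():
        vector = score_taxa(votes.get(bin_id, []), n_fragments=n_frag)
        assignment = classify_bin(vector, tree, top_frac=top_frac, min_score=min_score, bin_id=bin_id)
        if assignment.classified:
            flag_hybrid(assignment, tree)
        out[bin_id] = assignment
    return out


def read_bin_membership(path: str | Path) -> dict[str, list[str]]:
    """TSV ``bin_id  contig_id`` -> bin id -> ordered contig list."""
    bins: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "bin_id":
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: expected 2 columns, got {row!r}")
            bins.setdefault(row[0].strip(), []).append(row[1].strip())
    return bins
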
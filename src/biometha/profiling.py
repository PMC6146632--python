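"""EC-module functional profiling of metagenomes and metatranscriptomes.

Genes are attached to the reference collection's EC numbers (trailing
dash wildcards expand, and one gene may feed several modules), read
counts are normalized to RPKM (reads per kilobase per million mapped)
or RPM (reads per million mapped), and per-module abundances are
summarized on a log2 scale with a pseudocount so absent modules map to
zero.  Samples and modules are then ordered by deterministic
agglomerative clustering for heatmap display.

Module abundance under the RPKM scheme is

    log2( mean_{s in module sequences} RPKM(s) + eps )

with the unweighted mean taken over every reference sequence of every
EC in the module (zero-count sequences included); a per-EC-mean variant
is available.  Under the RPM scheme module counts are summed first:

    log2( 1e6 * sum(counts) / total_mapped + eps ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import CountTable
from .reference import ECNumber, ERSC, GeneRecord, MetabolicModule

__all__ = [
    "assign_genes_to_ecs",
    "rpkm",
    "module_abundance",
    "module_rpm",
    "AbundanceMatrix",
    "module_abundance_matrix",
    "annotation_coverage",
    "expression_coverage",
    "ModuleCoverageReport",
    "coverage_report",
    "ClusteringResult",
    "cluster_samples",
    "plot_heatmap",
    "top_expressed_summary",
]


def assign_genes_to_ecs(
    genes: Sequence[GeneRecord],
    ersc: ERSC,
) -> dict[str, list[GeneRecord]]:
    """Map collection EC codes to the genes that carry them.

    A gene contributes to every collection EC that any of its own EC
    annotations falls under (wildcards expand: a 3.4.21.1 peptidase
    feeds the 3.4.-.- protease entry).  Genes without a matching EC are
    excluded from the result.
    """
    out: dict[str, list[GeneRecord]] = {}
    collection = ersc.unique_ecs
    for gene in genes:
        matched: list[str] = []
        for gene_ec in gene.ec_codes:
            for ref_ec in collection:
                if ref_ec.matches(gene_ec):
                    matched.append(ref_ec.code)
        for code in dict.fromkeys(matched):
            out.setdefault(code, []).append(gene)
    return out


def rpkm(count: float, gene_length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_bp < 1:
        raise ValueError("gene length must be at least 1 bp")
    if total_mapped < 1:
        raise ValueError("total mapped reads must be at least 1")
    return count / ((gene_length_bp / 1e3) * (total_mapped / 1e6))


def module_abundance(rpkm_values: Iterable[float], pseudocount: float = 1.0) -> float | None:
    """log2(mean RPKM + pseudocount) over a module's reference sequences.

    Zero-count sequences participate in the mean; a module with no
    reference sequence at all has no defined abundance (None, flagged
    upstream).
    """
    values = list(rpkm_values)
    if not values:
        return None
    return math.log2(sum(values) / len(values) + pseudocount)


def module_rpm(
    module_count_sum: float,
    total_mapped: int,
    pseudocount: float = 1.0,
    log: bool = True,
) -> float:
    """Module reads-per-million; log2(RPM + pseudocount) by default."""
    if total_mapped < 1:
        raise ValueError("total mapped reads must be at least 1")
    rpm = 1e6 * module_count_sum / total_mapped
    return math.log2(rpm + pseudocount) if log else rpm


@dataclass
class AbundanceMatrix:
    """Module x sample matrix of log2-normalized abundances."""

    values: pd.DataFrame  # rows: module_id, columns: sample_id
    normalization: str  # log2_mean_rpkm | log2_rpm
    pseudocount: float
    per_ec_mean: bool = False
    undefined_modules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate row or column labels")
        if not np.isfinite(self.values.values).all():
            raise ValueError("non-finite abundance values")


def _module_sequence_ids(module: MetabolicModule, ersc: ERSC) -> list[tuple[str, str, int]]:
    """(ec code, sequence id, length) triples for a module, order-stable."""
    out = []
    for ec in module.ec_codes:
        for g in ersc.sequences_for(ec):
            out.append((ec.code, g.gene_id, g.length_bp))
    return out


def module_abundance_matrix(
    ersc: ERSC,
    counts: CountTable,
    normalization: str = "log2_mean_rpkm",
    pseudocount: float = 1.0,
    per_ec_mean: bool = False,
    samples: Sequence[str] | None = None,
) -> AbundanceMatrix:
    """Build the module x sample abundance matrix from raw counts.

    Count rows are keyed by reference sequence id; sequences absent from
    the table count as zero.  Modules whose ECs have no reference
    sequence get no abundance and are listed in ``undefined_modules``
    rather than silently imputed.
    """
    if normalization not in {"log2_mean_rpkm", "log2_rpm"}:
        raise ValueError(f"unknown normalization {normalization!r}")
    sample_ids = list(samples) if samples is not None else counts.samples
    rows: dict[str, list[float]] = {}
    undefined: list[str] = []
    for module in ersc.modules:
        seqs = _module_sequence_ids(module, ersc)
        if not seqs:
            undefined.append(module.module_id)
            continue
        row: list[float] = []
        for sample in sample_ids:
            total = counts.total_mapped[sample]
            col = counts.counts[sample]
            if normalization == "log2_rpm":
                count_sum = float(sum(col.get(seq_id, 0) for _, seq_id, _ in seqs))
                row.append(module_rpm(count_sum, total, pseudocount=pseudocount))
            else:
                per_seq = [
                    (ec, rpkm(float(col.get(seq_id, 0)), length, total))
                    for ec, seq_id, length in seqs
                ]
                if per_ec_mean:
                    by_ec: dict[str, list[float]] = {}
                    for ec, v in per_seq:
                        by_ec.setdefault(ec, []).append(v)
                    values = [sum(v) / len(v) for v in by_ec.values()]
                else:
                    values = [v for _, v in per_seq]
                row.append(module_abundance(values, pseudocount=pseudocount))
        rows[module.module_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    df.index.name = "module_id"
    return AbundanceMatrix(
        values=df,
        normalization=normalization,
        pseudocount=pseudocount,
        per_ec_mean=per_ec_mean,
        undefined_modules=undefined,
    )


# -- coverage ----------------------------------------------------------


def _ecs_with_genes(module: MetabolicModule, gene_ecs: Iterable[ECNumber]) -> set[str]:
    gene_ecs = list(gene_ecs)
    covered = set()
    for ref_ec in module.ec_codes:
        if any(ref_ec.matches(g) for g in gene_ecs):
            covered.add(ref_ec.code)
    return covered


def annotation_coverage(
    module: MetabolicModule,
    annotated_genes: Sequence[GeneRecord] | Sequence[ECNumber],
) -> float:
    """Percent of a module's unique ECs carried by at least one annotated gene."""
    ecs: list[ECNumber] = []
    for item in annotated_genes:
        if isinstance(item, GeneRecord):
            ecs.extend(item.ec_codes)
        else:
            ecs.append(item)
    covered = _ecs_with_genes(module, ecs)
    return 100.0 * len(covered) / module.n_ecs


def expression_coverage(
    ersc: ERSC,
    counts: CountTable,
    samples: Sequence[str] | None = None,
    ec_gene_ids: Mapping[str, Sequence[str]] | None = None,
) -> tuple[dict[str, float], tuple[int, int, float]]:
    """Per-module and global expressed-EC percentages.

    An EC is expressed iff any of its genes (by default its reference
    sequences; override with *ec_gene_ids*) has one or more reads in any
    selected sample.  Returns ({module_id: pct}, (n expressed ECs,
    n total ECs, global pct)).
    """
    sample_ids = list(samples) if samples is not None else counts.samples
    sub = counts.counts[sample_ids]
    expressed_genes = set(sub.index[(sub > 0).any(axis=1)])

    def ec_expressed(code: str) -> bool:
        if ec_gene_ids is not None:
            gene_ids = ec_gene_ids.get(code, [])
        else:
            gene_ids = [g.gene_id for g in ersc.sequences.get(code, [])]
        return any(g in expressed_genes for g in gene_ids)

    expressed_ecs = {ec.code for ec in ersc.unique_ecs if ec_expressed(ec.code)}
    per_module = {
        m.module_id: 100.0 * sum(ec.code in expressed_ecs for ec in m.ec_codes) / m.n_ecs
        for m in ersc.modules
    }
    n_total = ersc.n_unique_ecs
    n_expr = len(expressed_ecs)
    return per_module, (n_expr, n_total, 100.0 * n_expr / n_total if n_total else 0.0)


@dataclass
class ModuleCoverageReport:
    """Per-module annotation and expression coverage (the pathway-map view)."""

    table: pd.DataFrame
    # columns: category, name, n_ecs, n_ecs_with_sequence,
    # annotation_coverage_pct, n_genes_detected, expression_coverage_pct


def coverage_report(
    ersc: ERSC,
    genes: Sequence[GeneRecord],
    counts: CountTable | None = None,
    samples: Sequence[str] | None = None,
) -> ModuleCoverageReport:
    """Assemble the per-module coverage table from annotation and expression."""
    gene_map = assign_genes_to_ecs([g for g in genes if g.ec_codes], ersc)
    expr: dict[str, float] = {}
    if counts is not None:
        expr, _ = expression_coverage(ersc, counts, samples=samples)
    rows = []
    for m in ersc.modules:
        detected = {g.gene_id for ec in m.ec_codes for g in gene_map.get(ec.code, [])}
        rows.append(
            {
                "module_id": m.module_id,
                "name": m.name,
                "category": m.category,
                "n_ecs": m.n_ecs,
                "n_ecs_with_sequence": sum(bool(ersc.sequences_for(ec)) for ec in m.ec_codes),
                "annotation_coverage_pct": annotation_coverage(m, genes),
                "n_genes_detected": len(detected),
                "expression_coverage_pct": expr.get(m.module_id, float("nan")),
            }
        )
    df = pd.DataFrame(rows).set_index("module_id")
    return ModuleCoverageReport(table=df)


# -- clustering --------------------------------------------------------


@dataclass
class ClusteringResult:
    sample_linkage: np.ndarray
    module_linkage: np.ndarray | None
    sample_order: list[str]
    module_order: list[str]
    sample_newick: str
    module_newick: str | None
    ordered: pd.DataFrame  # heatmap table, rows/cols in dendrogram order


def _to_newick(linkage_matrix: np.ndarray, labels: Sequence[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage_matrix, list(labels))
    return str(tree).strip()


def cluster_samples(
    matrix: AbundanceMatrix | pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
    cluster_modules: bool = True,
) -> ClusteringResult:
    """Agglomerative clustering of samples (and modules) of an abundance matrix.

    Labels are sorted before distance computation so ties resolve
    identically regardless of input order; a constant matrix (all
    distances zero) still yields a deterministic tree.  Requires at
    least two samples.
    """
    df = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("clustering requires at least two samples")
    df = df.sort_index(axis=0).sort_index(axis=1)

    sample_z = linkage(pdist(df.T.values, metric=metric), method=method)
    sample_order = [df.columns[i] for i in leaves_list(sample_z)]
    module_z = None
    module_newick = None
    if cluster_modules and df.shape[0] >= 2:
        module_z = linkage(pdist(df.values, metric=metric), method=method)
        module_order = [df.index[i] for i in leaves_list(module_z)]
        module_newick = _to_newick(module_z, list(df.index))
    else:
        module_order = list(df.index)
    return ClusteringResult(
        sample_linkage=sample_z,
        module_linkage=module_z,
        sample_order=list(sample_order),
        module_order=list(module_order),
        sample_newick=_to_newick(sample_z, list(df.columns)),
        module_newick=module_newick,
        ordered=df.loc[module_order, sample_order],
    )


def plot_heatmap(
    matrix: AbundanceMatrix,
    path: str | Path,
    metric: str = "euclidean",
    method: str = "average",
) -> None:
    """Clustered log2-abundance heatmap (samples and modules), PNG or SVG by suffix."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import seaborn as sns

    df = matrix.values.sort_index(axis=0).sort_index(axis=1)
    n_rows = max(df.shape[0], 2)
    grid = sns.clustermap(
        df,
        metric=metric,
        method=method,
        cmap="viridis",
        figsize=(max(6, 0.6 * df.shape[1] + 3), max(4, 0.25 * n_rows + 2)),
        cbar_kws={"label": matrix.normalization},
    )
    grid.savefig(str(path), dpi=150)
    import matplotlib.pyplot as plt

    plt.close(grid.figure)


# -- top expressed transcripts ----------------------------------------


def top_expressed_summary(
    counts: CountTable,
    gene_lengths: Mapping[str, int],
    go_terms: Mapping[str, Sequence[str]] | None = None,
    n: int = 500,
    samples: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Rank transcripts by mean RPKM and tally GO terms over the top *n*.

    Ties at the rank-n boundary break by transcript id so the cut is
    reproducible; when fewer than *n* transcripts exist all are used and
    the table notes it via its length.  GO terms are counted with
    multiplicity across the selected transcripts.
    """
    sample_ids = list(samples) if samples is not None else counts.samples
    rows = []
    for gene_id in counts.gene_ids:
        length = gene_lengths.get(gene_id)
        if length is None:
            raise KeyError(f"no length for transcript {gene_id!r}")
        vals = [
            rpkm(float(counts.counts.at[gene_id, s]), length, counts.total_mapped[s])
            for s in sample_ids
        ]
        rows.append((gene_id, sum(vals) / len(vals)))
    ranked = pd.DataFrame(rows, columns=["transcript_id", "mean_rpkm"])
    ranked = ranked.sort_values(
        ["mean_rpkm", "transcript_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    top = ranked.head(n).copy()
    go_counts: dict[str, int] = {}
    if go_terms is not None:
        for gene_id in top["transcript_id"]:
            for term in go_terms.get(gene_id, []):
                go_counts[term] = go_counts.get(term, 0) + 1
    freq = pd.Series(go_counts, dtype=int).sort_values(ascending=False)
    if len(freq) > 1:
        freq = freq.sort_index().sort_values(ascending=False, kind="mergesort")
    freq.name = "n_transcripts"
    return top, freq
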
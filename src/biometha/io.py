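"""Readers and writers for the formats the toolkit consumes and emits.

FASTA goes through Biopython, tabular formats through pandas/csv.  The
one piece of scientific logic living here is :func:`merge_annotations`,
the complementation of a bacterial CDS annotation with an archaeal one
for bins of mixed taxonomic background.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import unquote

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import ECNumber, GeneRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fasta_tuples",
    "read_gff3",
    "write_gff3",
    "HitRecord",
    "read_hits",
    "CountTable",
    "read_counts",
    "write_counts",
    "reciprocal_overlap",
    "merge_annotations",
]

_IUPAC_NT = set("ACGTURYSWKMBDHVN")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA; sequences are uppercased, duplicate ids are a hard error.

    Characters outside the IUPAC nucleotide alphabet raise a warning but
    the record is kept.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        rec.seq = Seq(str(rec.seq).upper())
        bad = set(str(rec.seq)) - _IUPAC_NT
        if bad:
            warnings.warn(
                f"{path}: record {rec.id!r} contains non-IUPAC characters {sorted(bad)}",
                stacklevel=2,
            )
        records.append(rec)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description and rec.description != rec.id else ""
            fh.write(f">{rec.id}{desc}\n")
            seq = str(rec.seq)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fasta_tuples(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Convenience writer for (id, description, sequence) tuples."""
    write_fasta(
        (SeqRecord(Seq(seq), id=rid, description=desc or rid) for rid, desc, seq in records),
        path,
    )


# -- GFF3 --------------------------------------------------------------


def _parse_gff_attributes(raw: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, value = chunk.split("=", 1)
        attrs.setdefault(key.strip(), []).extend(unquote(v) for v in value.split(","))
    return attrs


def read_gff3(path: str | Path, feature_types: Sequence[str] = ("CDS",)) -> list[GeneRecord]:
    """Parse CDS features from a Prokka-style GFF3 into GeneRecords.

    EC numbers come from the ``eC_number`` attribute, gene names from
    ``gene`` (falling back to ``Name``), GO terms from ``Ontology_term``
    entries of the form GO:nnnnnnn.  Coordinates are 1-based inclusive;
    an end before the start is a hard error naming the line.
    """
    genes: list[GeneRecord] = []
    wanted = set(feature_types)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##FASTA"):
                break
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_raw = cols[:9]
            if ftype not in wanted:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if not (1 <= start <= end):
                raise ValueError(
                    f"{path}: line {lineno}: out-of-range coordinates {start_s}..{end_s}"
                )
            attrs = _parse_gff_attributes(attr_raw)
            gene_id = attrs.get("ID", [f"{seqid}:{start}-{end}"])[0]
            ecs = []
            for raw in attrs.get("eC_number", []) + attrs.get("ec_number", []):
                try:
                    ecs.append(ECNumber.parse(raw))
                except ValueError:
                    logger.warning("%s: line %d: unparseable EC %r skipped", path, lineno, raw)
            gene_name = (attrs.get("gene") or attrs.get("Name") or [None])[0]
            product = (attrs.get("product") or [None])[0]
            go_terms = [t for t in attrs.get("Ontology_term", []) if t.startswith("GO:")]
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=seqid,
                    start=start,
                    end=end,
                    strand=strand if strand in {"+", "-"} else "+",
                    ec_codes=ecs,
                    gene_name=gene_name,
                    product=product,
                    go_terms=go_terms,
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneRecord], path: str | Path, source: str = "biometha") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.gene_name:
                attrs.append(f"gene={g.gene_name}")
            for ec in g.ec_codes:
                attrs.append(f"eC_number={ec.code}")
            if g.product:
                attrs.append(f"product={g.product}")
            if g.go_terms:
                attrs.append("Ontology_term=" + ",".join(g.go_terms))
            fh.write(
                f"{g.contig_id}\t{source}\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                + ";".join(attrs)
                + "\n"
            )


# -- alignment hit tables ---------------------------------------------


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit (BLAST/DIAMOND tabular, outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    bit_score: float
    e_value: float
    subject_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.bit_score < 0 or self.e_value < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative score")
        if not (0 <= self.percent_identity <= 100):
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: identity out of [0,100]")


_TAB6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(
    path: str | Path,
    taxon_map: dict[str, str] | None = None,
) -> list[HitRecord]:
    """Read a 12-column BLAST outfmt-6 table, optionally with a 13th staxid column.

    Subject taxa are resolved from the extra column or from *taxon_map*
    (subject id -> taxonomy node); unmappable subjects keep a null taxon
    and are counted in a single warning.  Rows with the wrong column
    count or uncoercible fields are hard errors naming the line.
    """
    hits: list[HitRecord] = []
    unmapped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) not in (12, 13):
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 or 13 columns, got {len(cols)}"
                )
            try:
                pident = float(cols[2])
                length = int(cols[3])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: uncoercible field ({exc})") from exc
            subject = cols[1]
            taxon: str | None = cols[12].strip() if len(cols) == 13 and cols[12].strip() else None
            if taxon is None and taxon_map is not None:
                taxon = taxon_map.get(subject)
            if taxon is None:
                unmapped += 1
            hits.append(
                HitRecord(
                    query_id=cols[0],
                    subject_id=subject,
                    percent_identity=pident,
                    alignment_length=length,
                    bit_score=bitscore,
                    e_value=evalue,
                    subject_taxon=taxon,
                )
            )
    if unmapped:
        logger.warning("%s: %d hits with unmappable subject taxon", path, unmapped)
    return hits


# -- count tables ------------------------------------------------------


@dataclass
class CountTable:
    """Per-gene read counts across samples with per-sample mapped totals.

    ``totals_include_non_gene`` records whether ``total_mapped`` may
    exceed the column sum (totals counted over the whole reference) or
    must equal it.
    """

    counts: pd.DataFrame  # rows: gene_id, columns: sample_id, int values
    total_mapped: dict[str, int]
    totals_include_non_gene: bool = True

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        for sample in self.counts.columns:
            total = self.total_mapped.get(sample)
            if total is None:
                raise ValueError(f"no mapped total for sample {sample!r}")
            colsum = int(self.counts[sample].sum())
            if total < colsum:
                raise ValueError(
                    f"sample {sample!r}: total_mapped {total} < column sum {colsum}"
                )
            if not self.totals_include_non_gene and total != colsum:
                raise ValueError(
                    f"sample {sample!r}: total_mapped {total} != column sum {colsum}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


def read_counts(
    counts_path: str | Path,
    totals_path: str | Path | None = None,
    totals_include_non_gene: bool = True,
) -> CountTable:
    """Read a counts TSV (``gene_id`` + one column per sample) and its totals sidecar.

    Without a sidecar (TSV ``sample_id  total_mapped``) the totals default
    to the column sums.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{counts_path}: duplicate gene ids {dupes[:5]}")
    df = df.astype(int)
    if totals_path is not None:
        tot = pd.read_csv(totals_path, sep="\t", index_col=0).iloc[:, 0]
        totals = {str(k): int(v) for k, v in tot.items()}
    else:
        totals = {str(c): int(df[c].sum()) for c in df.columns}
        totals_include_non_gene = False
    return CountTable(counts=df, total_mapped=totals, totals_include_non_gene=totals_include_non_gene)


def write_counts(table: CountTable, counts_path: str | Path, totals_path: str | Path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    with open(totals_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\ttotal_mapped\n")
        for sample in table.counts.columns:
            fh.write(f"{sample}\t{table.total_mapped[sample]}\n")


# -- bacteria/archaea annotation merge --------------------------------


def reciprocal_overlap(a: GeneRecord, b: GeneRecord) -> float:
    """Fraction of the *shorter* constraint: min(overlap/len(a), overlap/len(b)).

    Both genes must lie on the same contig; comparing genes across
    contigs is a hard error.
    """
    if a.contig_id != b.contig_id:
        raise ValueError(
            f"cannot compute overlap across contigs ({a.contig_id!r} vs {b.contig_id!r})"
        )
    overlap = min(a.end, b.end) - max(a.start, b.start) + 1
    if overlap <= 0:
        return 0.0
    return min(overlap / a.length_bp, overlap / b.length_bp)


def merge_annotations(
    bacterial: Sequence[GeneRecord],
    archaeal: Sequence[GeneRecord],
    min_reciprocal_overlap: float = 0.5,
) -> list[GeneRecord]:
    """Complement a bacterial CDS annotation with annotated archaeal CDS.

    All bacterial CDS are retained, except that an unannotated bacterial
    CDS reciprocally overlapped (>``min_reciprocal_overlap`` of both
    lengths, same contig and strand) by an annotated archaeal CDS is
    replaced by that archaeal record.  Annotated archaeal CDS that
    overlap no annotated bacterial CDS are added; unannotated archaeal
    CDS are never added.  Annotated bacterial CDS are never removed.
    """
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in bacterial:
        by_contig.setdefault(g.contig_id, []).append(g)

    replaced: set[int] = set()  # identity of bacterial records displaced
    additions: list[GeneRecord] = []
    for arch in archaeal:
        if not arch.annotated:
            continue
        blocked = False
        displaced: list[GeneRecord] = []
        for bact in by_contig.get(arch.contig_id, []):
            if bact.strand != arch.strand:
                continue
            if reciprocal_overlap(arch, bact) > min_reciprocal_overlap:
                if bact.annotated:
                    blocked = True
                    break
                displaced.append(bact)
        if blocked:
            continue
        for bact in displaced:
            replaced.add(id(bact))
        additions.append(arch)

    merged = [g for g in bacterial if id(g) not in replaced]
    merged.extend(additions)
    merged.sort(key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))
    return merged
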
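"""Domain types for the EC reference sequence collection (ERSC).

The ERSC is a curated set of enzyme-commission (EC) numbers relevant to
anaerobic digestion, grouped into metabolic modules (one module per
conversion step of the pathway, e.g. methyl-CoA -> methane), together
with reference gene sequences for each EC.  EC codes may carry trailing
dash wildcards ("3.4.-.-" covers all proteases), and one EC may appear
in several modules; within one module duplicate ECs are collapsed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ECNumber",
    "MetabolicModule",
    "RefGene",
    "ERSC",
    "ErscSummary",
    "MarkerGeneSet",
    "GeneRecord",
    "GenomicBin",
    "load_ersc",
    "write_ersc",
    "read_marker_set",
]


@dataclass(frozen=True, order=True)
class ECNumber:
    """A dotted enzyme-commission identifier, possibly wildcarded.

    Four dot-separated fields, each a positive integer or "-"; a "-" may
    only be followed by further "-" fields ("3.4.-.-" is valid,
    "3.-.4.-" is not).
    """

    fields: tuple[str, str, str, str]

    @classmethod
    def parse(cls, code: str) -> "ECNumber":
        code = code.strip()
        if code.upper().startswith("EC"):
            code = code[2:].lstrip(" :")
        parts = code.split(".")
        if len(parts) != 4:
            raise ValueError(f"malformed EC code {code!r}: expected 4 dot-separated fields")
        seen_dash = False
        for p in parts:
            if p == "-":
                seen_dash = True
            else:
                if seen_dash:
                    raise ValueError(f"malformed EC code {code!r}: '-' may only be followed by '-'")
                if not p.isdigit() or int(p) <= 0:
                    raise ValueError(f"malformed EC code {code!r}: field {p!r} is not a positive integer")
        return cls(fields=tuple(parts))  # type: ignore[arg-type]

    @property
    def code(self) -> str:
        return ".".join(self.fields)

    @property
    def is_wildcard(self) -> bool:
        return "-" in self.fields

    @property
    def specified_prefix(self) -> tuple[str, ...]:
        return tuple(f for f in self.fields if f != "-")

    def matches(self, other: "ECNumber | str") -> bool:
        """True iff *other* falls under this code (wildcards expand).

        A fully specified code matches only itself; "3.4.-.-" matches any
        EC whose first two fields are 3 and 4.
        """
        if isinstance(other, str):
            other = ECNumber.parse(other)
        for mine, theirs in zip(self.fields, other.fields):
            if mine == "-":
                return True
            if theirs != mine:
                return False
        return True

    def __str__(self) -> str:
        return self.code


@dataclass
class MetabolicModule:
    """One conversion step of the anaerobic-digestion pathway map."""

    module_id: str
    name: str
    category: str
    ec_codes: list[ECNumber]

    def __post_init__(self) -> None:
        if not self.ec_codes:
            raise ValueError(f"module {self.module_id!r} has no EC codes")
        # duplicates within one module are collapsed, order preserved
        self.ec_codes = list(dict.fromkeys(self.ec_codes))

    @property
    def n_ecs(self) -> int:
        return len(self.ec_codes)


@dataclass(frozen=True)
class RefGene:
    """A reference gene sequence backing one EC number."""

    gene_id: str
    length_bp: int
    source: str = "public-db"  # public-db | assembly-derived
    sequence: str | None = None


@dataclass
class ErscSummary:
    n_unique_ecs: int
    n_modules: int
    n_sequences: int
    ecs_without_sequence: list[str]


@dataclass
class ERSC:
    """EC reference sequence collection: modules plus per-EC gene records."""

    modules: list[MetabolicModule]
    sequences: dict[str, list[RefGene]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {ec.code for m in self.modules for ec in m.ec_codes}
        for code in self.sequences:
            if code not in known:
                raise ValueError(f"sequence mapped to EC {code!r} absent from the module table")

    @property
    def unique_ecs(self) -> list[ECNumber]:
        seen: dict[str, ECNumber] = {}
        for m in self.modules:
            for ec in m.ec_codes:
                seen.setdefault(ec.code, ec)
        return list(seen.values())

    @property
    def n_unique_ecs(self) -> int:
        return len(self.unique_ecs)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module(self, module_id: str) -> MetabolicModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(f"unknown module {module_id!r}")

    def sequences_for(self, ec: ECNumber | str) -> list[RefGene]:
        code = ec.code if isinstance(ec, ECNumber) else ECNumber.parse(ec).code
        return self.sequences.get(code, [])

    def ecs_without_sequence(self) -> list[str]:
        """ECs with no known reference sequence (the pathway map's asterisks)."""
        return sorted(ec.code for ec in self.unique_ecs if not self.sequences.get(ec.code))

    def summary(self) -> ErscSummary:
        return ErscSummary(
            n_unique_ecs=self.n_unique_ecs,
            n_modules=self.n_modules,
            n_sequences=sum(len(v) for v in self.sequences.values()),
            ecs_without_sequence=self.ecs_without_sequence(),
        )

    def matching_ecs(self, gene_ec: ECNumber | str) -> list[ECNumber]:
        """All collection ECs a gene-level EC falls under (wildcards expand)."""
        if isinstance(gene_ec, str):
            gene_ec = ECNumber.parse(gene_ec)
        return [ec for ec in self.unique_ecs if ec.matches(gene_ec)]


def load_ersc(
    module_table: str | Path,
    sequences_fasta: str | Path | None = None,
    sequence_mapping: str | Path | None = None,
) -> ERSC:
    """Load an ERSC from its module table and optional sequence index.

    ``module_table`` is a UTF-8 TSV with header
    ``ec  module_id  module_name  category``; duplicate rows and duplicate
    ECs within one module collapse silently.  ``sequences_fasta`` plus
    ``sequence_mapping`` (TSV ``seq_id  ec``) attach reference gene
    records; a mapping to an EC absent from the table is a hard error,
    as is a malformed EC code (the offending row is named).
    """
    modules: dict[str, MetabolicModule] = {}
    with open(module_table, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{module_table}: empty module table")
        cols = [c.strip().lower() for c in header]
        required = {"ec", "module_id"}
        if not required.issubset(cols):
            raise ValueError(f"{module_table}: missing required columns {sorted(required - set(cols))}")
        idx = {c: cols.index(c) for c in cols}
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            try:
                ec = ECNumber.parse(row[idx["ec"]])
            except ValueError as exc:
                raise ValueError(f"{module_table}: line {lineno}: {exc}") from exc
            module_id = row[idx["module_id"]].strip()
            name = row[idx["module_name"]].strip() if "module_name" in idx and len(row) > idx["module_name"] else module_id
            category = row[idx["category"]].strip() if "category" in idx and len(row) > idx["category"] else ""
            mod = modules.get(module_id)
            if mod is None:
                modules[module_id] = MetabolicModule(module_id=module_id, name=name, category=category, ec_codes=[ec])
            elif ec not in mod.ec_codes:
                mod.ec_codes.append(ec)

    sequences: dict[str, list[RefGene]] = {}
    if sequence_mapping is not None:
        from . import io as _io  # late import: io depends on nothing here

        seq_records = {}
        if sequences_fasta is not None:
            seq_records = {r.id: r for r in _io.read_fasta(sequences_fasta)}
        with open(sequence_mapping, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            for lineno, row in enumerate(reader, start=1):
                if not row or row[0].startswith("#") or row[0].strip().lower() == "seq_id":
                    continue
                if len(row) < 2:
                    raise ValueError(f"{sequence_mapping}: line {lineno}: expected 2 columns")
                seq_id, ec_raw = row[0].strip(), row[1].strip()
                extra = [c.strip() for c in row[2:]]
                try:
                    ec = ECNumber.parse(ec_raw)
                except ValueError as exc:
                    raise ValueError(f"{sequence_mapping}: line {lineno}: {exc}") from exc
                rec = seq_records.get(seq_id)
                seq = str(rec.seq) if rec is not None else None
                length = len(seq) if seq is not None else int(extra[0]) if extra and extra[0].isdigit() else 0
                source = extra[1] if len(extra) > 1 and extra[1] else "public-db"
                sequences.setdefault(ec.code, []).append(
                    RefGene(gene_id=seq_id, length_bp=length, source=source, sequence=seq)
                )

    return ERSC(modules=list(modules.values()), sequences=sequences)


def write_ersc(
    ersc: ERSC,
    module_table: str | Path,
    sequences_fasta: str | Path | None = None,
    sequence_mapping: str | Path | None = None,
) -> None:
    """Inverse of :func:`load_ersc`; round-trips every field."""
    with open(module_table, "w", encoding="utf-8") as fh:
        fh.write("ec\tmodule_id\tmodule_name\tcategory\n")
        for m in ersc.modules:
            for ec in m.ec_codes:
                fh.write(f"{ec.code}\t{m.module_id}\t{m.name}\t{m.category}\n")
    if sequence_mapping is not None:
        with open(sequence_mapping, "w", encoding="utf-8") as fh:
            fh.write("seq_id\tec\tlength_bp\tsource\n")
            for code, genes in ersc.sequences.items():
                for g in genes:
                    fh.write(f"{g.gene_id}\t{code}\t{g.length_bp}\t{g.source}\n")
    if sequences_fasta is not None:
        from . import io as _io

        records = [
            (g.gene_id, "", g.sequence)
            for genes in ersc.sequences.values()
            for g in genes
            if g.sequence is not None
        ]
        _io.write_fasta_tuples(records, sequences_fasta)


# -- marker genes, genes, bins ----------------------------------------


@dataclass
class MarkerGeneSet:
    """A universal single-copy marker set used for completeness estimation.

    The default expectation is the 137-gene bacterial/archaeal marker
    panel; the concrete id list is data supplied by file.
    """

    marker_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.marker_ids = frozenset(self.marker_ids)
        if not self.marker_ids:
            raise ValueError("marker set is empty")

    @property
    def expected_count(self) -> int:
        return len(self.marker_ids)


def read_marker_set(path: str | Path) -> MarkerGeneSet:
    """One marker id per line; '#' comments and blanks ignored."""
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line.split("\t")[0])
    return MarkerGeneSet(marker_ids=frozenset(ids))


@dataclass
class GeneRecord:
    """A predicted CDS with optional functional annotation."""

    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    ec_codes: list[ECNumber] = field(default_factory=list)
    gene_name: str | None = None
    product: str | None = None
    go_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def annotated(self) -> bool:
        """A CDS counts as annotated when a gene name or an EC number is known."""
        return bool(self.gene_name) or bool(self.ec_codes)


@dataclass
class GenomicBin:
    """A set of contigs putatively from one taxon, with QC metadata."""

    bin_id: str
    contigs: dict[str, int]  # contig id -> length in bp
    markers_found: set[str] = field(default_factory=set)
    sample_support: dict[str, bool] = field(default_factory=dict)
    completeness_pct: float | None = None
    taxon_assignment: tuple[str, str] | None = None  # (node id, rank)
    hybrid: bool = False

    @property
    def total_length(self) -> int:
        return sum(self.contigs.values())

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def support_count(self) -> int:
        return sum(bool(v) for v in self.sample_support.values())
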
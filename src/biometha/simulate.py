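"""Synthetic anaerobic-digester communities with known ground truth.

The generator emits every input the downstream stages consume — a
rank-complete taxonomy, genomic bins with marker-gene presence and
per-sample read support, fragment-level alignment hit tables, a
synthetic EC reference collection, CDS annotations, and RNA count
tables with module-level log2 expression effects between two
conditions — together with the truth needed to score recovery.  The
same seed always produces byte-identical files.

The community shape mirrors a bacteria-dominated digester: one archaeal
phylum against several bacterial ones, full rank chains down to species,
and an EC collection spanning the anaerobic-digestion categories from
polymer hydrolysis (including wildcard protease/lipase entries) to
methanogenesis.

Generative model, in brief: marker presence per bin is Bernoulli with
the bin's target completeness; each contig fragment's top hit is the
bin's true species with probability 1 - epsilon, otherwise a random
species from another phylum; per-gene log2 expression is normal
(mu, sigma) plus the owning module's condition effect, expected reads
are proportional to rate x gene length and normalized to the sample
depth, and counts are Poisson (negative binomial available, since real
metatranscriptomes are overdispersed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as bio_io
from .binqc import completeness as _completeness_of
from .classify import BinAssignment, Fragment, FragmentationConfig, fragment_contig
from .io import CountTable, HitRecord
from .reference import (
    ECNumber,
    ERSC,
    GeneRecord,
    GenomicBin,
    MarkerGeneSet,
    MetabolicModule,
    RefGene,
)
from .taxonomy import TaxNode, TaxonomyTree, rank_at_or_below

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedCommunity",
    "synthetic_taxonomy",
    "synthetic_ersc",
    "simulate_community",
    "RecoveryReport",
    "evaluate_recovery",
]

_CATEGORIES = (
    "polymer degradation",
    "carbohydrate metabolism",
    "lipid metabolism",
    "amino acid metabolism",
    "acetogenesis",
    "methanogenesis",
    "coenzyme metabolism",
)


@dataclass
class SimulationConfig:
    """Knobs of the community generator; the seed fully determines output."""

    seed: int = 0
    n_bins: int = 50
    n_dna_samples: int = 4
    n_rna_samples_per_condition: int = 3
    # taxonomy shape: (bacterial phyla, archaeal phyla); two families per
    # order, two genera per family, two species per genus
    phyla_per_domain: tuple[int, int] = (4, 1)
    # bins
    contigs_per_bin: tuple[int, int] = (5, 10)
    contig_bp: tuple[int, int] = (2000, 8000)
    completeness_range: tuple[float, float] = (0.05, 1.0)
    hit_error_rate: float = 0.0  # epsilon: wrong-phylum top hits
    decoy_hit_rate: float = 0.3  # extra sub-optimal hits per fragment
    marker_count: int = 137
    # EC reference collection
    n_modules: int = 12
    n_unique_ecs: int = 48
    seqs_per_ec: tuple[int, int] = (1, 3)
    frac_ecs_without_sequence: float = 0.05
    # expression
    expression_mu: float = 3.0  # log2 baseline
    expression_sigma: float = 1.5
    effect_range_log2: float = 2.0  # module effects ~ U(-range, range)
    reads_per_sample: int = 1_000_000
    count_model: str = "poisson"  # poisson | nb
    nb_dispersion: float = 0.2
    annotated_frac: float = 0.7
    write_sequences: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.hit_error_rate <= 1.0):
            raise ValueError("hit_error_rate must lie in [0, 1]")
        lo, hi = self.completeness_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("completeness_range must lie in [0, 1]")
        if self.count_model not in {"poisson", "nb"}:
            raise ValueError(f"unknown count model {self.count_model!r}")


@dataclass
class SyntheticTruth:
    """Ground truth backing a simulated community."""

    bin_species: dict[str, str]
    bin_completeness_target: dict[str, float]
    bin_completeness_pct: dict[str, float]  # realized, 0.1% precision
    module_effect_log2: dict[str, float]
    sample_condition: dict[str, str]  # RNA sample -> A | B
    ec_of_sequence: dict[str, str]
    annotated_ecs: list[str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
        # trailing newline keeps the file diff-friendly
        with open(path, "a", encoding="utf-8") as fh:
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedCommunity:
    config: SimulationConfig
    tree: TaxonomyTree
    marker_set: MarkerGeneSet
    bins: list[GenomicBin]
    contig_lengths: dict[str, int]
    fragments: dict[str, list[Fragment]]  # contig -> fragments
    bin_of_contig: dict[str, str]
    hits: list[HitRecord]
    contig_mapping: dict[str, set[str]]  # DNA sample -> mapped contigs
    ersc: ERSC
    counts: CountTable
    genes: list[GeneRecord]
    go_terms: dict[str, list[str]]
    truth: SyntheticTruth

    @property
    def bin_fragment_counts(self) -> dict[str, int]:
        out: dict[str, int] = {b.bin_id: 0 for b in self.bins}
        for contig, frags in self.fragments.items():
            out[self.bin_of_contig[contig]] += len(frags)
        return out

    @property
    def fragment_bins(self) -> dict[str, str]:
        return {
            f.fragment_id: self.bin_of_contig[contig]
            for contig, frags in self.fragments.items()
            for f in frags
        }


# -- taxonomy ----------------------------------------------------------


def synthetic_taxonomy(phyla_per_domain: tuple[int, int] = (4, 1)) -> TaxonomyTree:
    """A rank-complete two-domain taxonomy (8 species per phylum)."""
    n_bac, n_arc = phyla_per_domain
    if n_bac + n_arc < 2:
        raise ValueError("need at least two phyla for a non-degenerate taxonomy")
    nodes: dict[str, TaxNode] = {"root": TaxNode("root", "root", "root")}
    for domain, n_phyla, tag in (("Bacteria", n_bac, "Bac"), ("Archaea", n_arc, "Arc")):
        if n_phyla == 0:
            continue
        nodes[domain] = TaxNode("root", "domain", domain)
        for p in range(1, n_phyla + 1):
            phylum = f"{tag}_p{p}"
            nodes[phylum] = TaxNode(domain, "phylum", phylum)
            clazz = f"{phylum}_c1"
            nodes[clazz] = TaxNode(phylum, "class", clazz)
            order = f"{clazz}_o1"
            nodes[order] = TaxNode(clazz, "order", order)
            for f in (1, 2):
                family = f"{order}_f{f}"
                nodes[family] = TaxNode(order, "family", family)
                for g in (1, 2):
                    genus = f"{family}_g{g}"
                    nodes[genus] = TaxNode(family, "genus", genus)
                    for s in (1, 2):
                        species = f"{genus}_s{s}"
                        nodes[species] = TaxNode(genus, "species", species)
    return TaxonomyTree(nodes)


# -- EC reference collection ------------------------------------------


def synthetic_ersc(
    n_modules: int = 12,
    n_unique_ecs: int = 48,
    seed: int = 0,
    seqs_per_ec: tuple[int, int] = (1, 3),
    frac_ecs_without_sequence: float = 0.05,
    cross_module_duplicates: int = 0,
    with_sequences: bool = True,
) -> ERSC:
    """Generate a synthetic EC reference collection.

    The collection mirrors the structure of a curated anaerobic-digestion
    pathway map — modules grouped into hydrolysis/metabolism/methanogenesis
    categories, wildcard protease (3.4.-.-) and lipase (3.1.1.-) entries,
    a few ECs without any known reference sequence — without reproducing
    any real curation.  Set ``n_modules=52, n_unique_ecs=235`` for a
    collection with the full-scale shape.
    """
    if n_unique_ecs < n_modules:
        raise ValueError("need at least one unique EC per module")
    rng = np.random.default_rng(seed)
    # enumerate candidate fully specified codes, then sample without replacement
    pool = [
        f"{c}.{s}.{ss}.{nn}"
        for c in range(1, 7)
        for s in range(1, 10)
        for ss in range(1, 10)
        for nn in range(1, 5)
    ]
    idx = rng.permutation(len(pool))[: n_unique_ecs - 2]
    codes = ["3.4.-.-", "3.1.1.-"] + [pool[i] for i in sorted(idx)]
    codes = list(dict.fromkeys(codes))[:n_unique_ecs]

    # random composition of module sizes (each >= 1)
    cuts = np.sort(rng.choice(np.arange(1, len(codes)), size=n_modules - 1, replace=False))
    chunks = np.split(np.arange(len(codes)), cuts)
    modules: list[MetabolicModule] = []
    for i, chunk in enumerate(chunks):
        category = _CATEGORIES[i * len(_CATEGORIES) // n_modules]
        ecs = [ECNumber.parse(codes[j]) for j in chunk]
        modules.append(
            MetabolicModule(
                module_id=f"M{i + 1:02d}",
                name=f"synthetic module {i + 1}",
                category=category,
                ec_codes=ecs,
            )
        )
    for _ in range(cross_module_duplicates):
        src, dst = rng.integers(0, n_modules, size=2)
        ec = modules[src].ec_codes[int(rng.integers(0, len(modules[src].ec_codes)))]
        if ec not in modules[dst].ec_codes:
            modules[dst].ec_codes.append(ec)

    sequences: dict[str, list[RefGene]] = {}
    n_silent = int(round(frac_ecs_without_sequence * len(codes)))
    silent = set(rng.choice(len(codes), size=n_silent, replace=False).tolist())
    for j, code in enumerate(codes):
        if j in silent:
            continue
        n_seqs = int(rng.integers(seqs_per_ec[0], seqs_per_ec[1] + 1))
        genes = []
        for k in range(n_seqs):
            length = int(rng.integers(600, 3000))
            source = "assembly-derived" if rng.random() < 0.4 else "public-db"
            seq = None
            if with_sequences:
                seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
            genes.append(
                RefGene(
                    gene_id=f"ERSC_{code.replace('.', '_')}_{k + 1}",
                    length_bp=length,
                    source=source,
                    sequence=seq,
                )
            )
        sequences[code] = genes
    return ERSC(modules=modules, sequences=sequences)


# -- community ---------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def simulate_community(
    cfg: SimulationConfig,
    out_dir: str | Path | None = None,
) -> SimulatedCommunity:
    """Generate a full synthetic community; optionally write all files.

    When *out_dir* is given, every external-interface file is emitted
    (taxonomy/bins/markers/mapping/hits/ERSC/counts/GFF3/GO tables plus
    ``truth.json``); the same config yields byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = synthetic_taxonomy(cfg.phyla_per_domain)
    species = sorted(n for n, rec in tree.nodes.items() if rec.rank == "species")
    phylum_of = {s: tree.ancestor_at_rank(s, "phylum") for s in species}

    marker_ids = [f"MK{i + 1:04d}" for i in range(cfg.marker_count)]
    marker_set = MarkerGeneSet(marker_ids=frozenset(marker_ids))

    dna_samples = [f"DNA{i + 1}" for i in range(cfg.n_dna_samples)]

    bins: list[GenomicBin] = []
    contig_lengths: dict[str, int] = {}
    fragments: dict[str, list[Fragment]] = {}
    bin_of_contig: dict[str, str] = {}
    hits: list[HitRecord] = []
    contig_mapping: dict[str, set[str]] = {s: set() for s in dna_samples}
    frag_cfg = FragmentationConfig()

    bin_species: dict[str, str] = {}
    completeness_target: dict[str, float] = {}
    completeness_realized: dict[str, float] = {}
    contig_seqs: dict[str, str] = {}

    for b in range(cfg.n_bins):
        bin_id = f"GB{b + 1:03d}"
        true_sp = species[int(rng.integers(0, len(species)))]
        bin_species[bin_id] = true_sp
        c_target = float(rng.uniform(*cfg.completeness_range))
        completeness_target[bin_id] = c_target
        present = [m for m in marker_ids if rng.random() < c_target]
        if c_target >= 1.0:
            present = list(marker_ids)

        n_contigs = int(rng.integers(cfg.contigs_per_bin[0], cfg.contigs_per_bin[1] + 1))
        contigs: dict[str, int] = {}
        for c in range(n_contigs):
            contig_id = f"{bin_id}_ctg{c + 1:02d}"
            length = int(rng.integers(cfg.contig_bp[0], cfg.contig_bp[1] + 1))
            contigs[contig_id] = length
            contig_lengths[contig_id] = length
            bin_of_contig[contig_id] = bin_id
            if cfg.write_sequences:
                contig_seqs[contig_id] = _random_seq(rng, length)
            frags = fragment_contig(contig_id, length, frag_cfg)
            fragments[contig_id] = frags
            for s in dna_samples:
                contig_mapping[s].add(contig_id)
            # per-fragment top hit (plus occasional decoys below it)
            other_phyla = [sp for sp in species if phylum_of[sp] != phylum_of[true_sp]]
            for frag in frags:
                if rng.random() < cfg.hit_error_rate and other_phyla:
                    taxon = other_phyla[int(rng.integers(0, len(other_phyla)))]
                else:
                    taxon = true_sp
                top_score = float(rng.uniform(150, 300))
                hits.append(
                    HitRecord(
                        query_id=frag.fragment_id,
                        subject_id=f"ref|{taxon}|1",
                        percent_identity=float(np.round(rng.uniform(75, 100), 1)),
                        alignment_length=int(min(frag.length_bp, rng.integers(200, 1000))),
                        bit_score=float(np.round(top_score, 1)),
                        e_value=float(np.format_float_scientific(10 ** -rng.uniform(10, 50), 2)),
                        subject_taxon=taxon,
                    )
                )
                if rng.random() < cfg.decoy_hit_rate:
                    decoy = species[int(rng.integers(0, len(species)))]
                    hits.append(
                        HitRecord(
                            query_id=frag.fragment_id,
                            subject_id=f"ref|{decoy}|2",
                            percent_identity=float(np.round(rng.uniform(60, 90), 1)),
                            alignment_length=int(min(frag.length_bp, rng.integers(100, 800))),
                            bit_score=float(np.round(top_score - rng.uniform(10, 80), 1)),
                            e_value=float(np.format_float_scientific(10 ** -rng.uniform(3, 10), 2)),
                            subject_taxon=decoy,
                        )
                    )

        gb = GenomicBin(
            bin_id=bin_id,
            contigs=contigs,
            markers_found=set(present),
            sample_support={s: True for s in dna_samples},
        )
        gb.completeness_pct = _completeness_of(gb.markers_found, marker_set) if present else 0.0
        completeness_realized[bin_id] = gb.completeness_pct
        bins.append(gb)

    # -- EC reference collection and expression ------------------------
    ersc = synthetic_ersc(
        n_modules=cfg.n_modules,
        n_unique_ecs=cfg.n_unique_ecs,
        seed=int(rng.integers(0, 2**31 - 1)),
        seqs_per_ec=cfg.seqs_per_ec,
        frac_ecs_without_sequence=cfg.frac_ecs_without_sequence,
        with_sequences=cfg.write_sequences,
    )
    module_of_ec: dict[str, str] = {}
    for m in ersc.modules:
        for ec in m.ec_codes:
            module_of_ec.setdefault(ec.code, m.module_id)

    effects = {
        m.module_id: float(np.round(rng.uniform(-cfg.effect_range_log2, cfg.effect_range_log2), 3))
        for m in ersc.modules
    }

    rna_samples = [f"RNA_A{i + 1}" for i in range(cfg.n_rna_samples_per_condition)] + [
        f"RNA_B{i + 1}" for i in range(cfg.n_rna_samples_per_condition)
    ]
    condition = {s: ("A" if s.startswith("RNA_A") else "B") for s in rna_samples}

    seq_ids: list[str] = []
    seq_len: dict[str, int] = {}
    ec_of_seq: dict[str, str] = {}
    for code, genes in ersc.sequences.items():
        for g in genes:
            seq_ids.append(g.gene_id)
            seq_len[g.gene_id] = g.length_bp
            ec_of_seq[g.gene_id] = code
    base_log2 = {g: float(rng.normal(cfg.expression_mu, cfg.expression_sigma)) for g in seq_ids}

    count_cols: dict[str, np.ndarray] = {}
    totals: dict[str, int] = {}
    for sample in rna_samples:
        cond_b = condition[sample] == "B"
        rates = np.array(
            [
                2.0 ** (base_log2[g] + (effects[module_of_ec[ec_of_seq[g]]] if cond_b else 0.0))
                * (seq_len[g] / 1000.0)
                for g in seq_ids
            ]
        )
        expected = cfg.reads_per_sample * rates / rates.sum()
        if cfg.count_model == "nb":
            # NB via gamma-Poisson mixture; dispersion d: var = mu + d*mu^2
            shape = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape, expected / shape)
            counts_vec = rng.poisson(lam)
        else:
            counts_vec = rng.poisson(expected)
        count_cols[sample] = counts_vec.astype(int)
        non_gene = int(rng.poisson(0.1 * cfg.reads_per_sample))
        totals[sample] = int(counts_vec.sum()) + non_gene

    counts_df = pd.DataFrame(count_cols, index=pd.Index(seq_ids, name="gene_id"))
    counts = CountTable(counts=counts_df, total_mapped=totals, totals_include_non_gene=True)

    # -- CDS annotation on bin contigs ---------------------------------
    genes: list[GeneRecord] = []
    annotated_ecs: set[str] = set()
    unique_codes = [ec.code for ec in ersc.unique_ecs]
    gene_counter = 0
    for gb in bins:
        for contig_id, length in gb.contigs.items():
            n_genes = max(1, length // 2500)
            pos = 1
            for _ in range(n_genes):
                glen = int(rng.integers(300, 1200))
                if pos + glen - 1 > length:
                    break
                gene_counter += 1
                gid = f"CDS_{gene_counter:05d}"
                strand = "+" if rng.random() < 0.5 else "-"
                ecs: list[ECNumber] = []
                gene_name = None
                if rng.random() < cfg.annotated_frac:
                    code = unique_codes[int(rng.integers(0, len(unique_codes)))]
                    ec = ECNumber.parse(code)
                    if ec.is_wildcard:
                        # a concrete CDS carries a fully specified EC under the wildcard
                        filled = [f if f != "-" else str(int(rng.integers(1, 30))) for f in ec.fields]
                        ec = ECNumber.parse(".".join(filled))
                    ecs = [ec]
                    annotated_ecs.add(code)
                    if rng.random() < 0.5:
                        gene_name = f"gene{gene_counter:05d}"
                genes.append(
                    GeneRecord(
                        gene_id=gid,
                        contig_id=contig_id,
                        start=pos,
                        end=pos + glen - 1,
                        strand=strand,
                        ec_codes=ecs,
                        gene_name=gene_name,
                    )
                )
                pos += glen + int(rng.integers(20, 200))

    go_pool = [f"GO:{7_000_000 + i}" for i in range(40)]
    go_terms = {
        g: sorted(
            rng.choice(go_pool, size=int(rng.integers(1, 4)), replace=False).tolist()
        )
        for g in seq_ids
    }

    truth = SyntheticTruth(
        bin_species=bin_species,
        bin_completeness_target=completeness_target,
        bin_completeness_pct=completeness_realized,
        module_effect_log2=effects,
        sample_condition=condition,
        ec_of_sequence=ec_of_seq,
        annotated_ecs=sorted(annotated_ecs),
    )
    community = SimulatedCommunity(
        config=cfg,
        tree=tree,
        marker_set=marker_set,
        bins=bins,
        contig_lengths=contig_lengths,
        fragments=fragments,
        bin_of_contig=bin_of_contig,
        hits=hits,
        contig_mapping=contig_mapping,
        ersc=ersc,
        counts=counts,
        genes=genes,
        go_terms=go_terms,
        truth=truth,
    )
    if out_dir is not None:
        _write_community(community, Path(out_dir), contig_seqs)
    return community


def _write_community(
    com: SimulatedCommunity, out_dir: Path, contig_seqs: dict[str, str]
) -> None:
    from .reference import write_ersc
    from .taxonomy import write_taxonomy

    out_dir.mkdir(parents=True, exist_ok=True)
    write_taxonomy(com.tree, out_dir / "taxonomy.tsv")
    with open(out_dir / "marker_set.txt", "w", encoding="utf-8") as fh:
        for m in sorted(com.marker_set.marker_ids):
            fh.write(m + "\n")
    with open(out_dir / "bins.tsv", "w", encoding="utf-8") as fh:
        fh.write("bin_id\tcontig_id\n")
        for gb in com.bins:
            for contig in gb.contigs:
                fh.write(f"{gb.bin_id}\t{contig}\n")
    with open(out_dir / "contig_lengths.tsv", "w", encoding="utf-8") as fh:
        fh.write("contig_id\tlength_bp\n")
        for contig, length in com.contig_lengths.items():
            fh.write(f"{contig}\t{length}\n")
    if contig_seqs:
        bio_io.write_fasta_tuples(
            [(cid, "", seq) for cid, seq in contig_seqs.items()], out_dir / "contigs.fasta"
        )
    with open(out_dir / "markers.tsv", "w", encoding="utf-8") as fh:
        fh.write("bin_id\tmarker_id\n")
        for gb in com.bins:
            for m in sorted(gb.markers_found):
                fh.write(f"{gb.bin_id}\t{m}\n")
    with open(out_dir / "mapping.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tcontig_id\n")
        for sample in sorted(com.contig_mapping):
            for contig in sorted(com.contig_mapping[sample]):
                fh.write(f"{sample}\t{contig}\n")
    with open(out_dir / "hits.tsv", "w", encoding="utf-8") as fh:
        for h in com.hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity}\t{h.alignment_length}"
                f"\t0\t0\t1\t{h.alignment_length}\t1\t{h.alignment_length}"
                f"\t{h.e_value}\t{h.bit_score}\t{h.subject_taxon}\n"
            )
    write_ersc(
        com.ersc,
        out_dir / "ersc.tsv",
        sequences_fasta=out_dir / "ersc.fasta",
        sequence_mapping=out_dir / "ersc_mapping.tsv",
    )
    bio_io.write_counts(com.counts, out_dir / "counts.tsv", out_dir / "totals.tsv")
    bio_io.write_gff3(com.genes, out_dir / "genes.gff3")
    with open(out_dir / "go.tsv", "w", encoding="utf-8") as fh:
        fh.write("transcript_id\tgo_term\n")
        for gid in sorted(com.go_terms):
            for term in com.go_terms[gid]:
                fh.write(f"{gid}\t{term}\n")
    com.truth.to_json(out_dir / "truth.json")


# -- end-to-end helpers ------------------------------------------------


def classify_community(
    com: SimulatedCommunity, top_frac: float = 0.8, min_score: float = 0.0
) -> dict[str, BinAssignment]:
    """Run fragment-vote classification over every bin of a simulated community."""
    from .classify import classify_bins

    frag_hits: dict[str, list[HitRecord]] = {}
    for h in com.hits:
        frag_hits.setdefault(h.query_id, []).append(h)
    return classify_bins(
        com.bin_fragment_counts,
        frag_hits,
        com.fragment_bins,
        com.tree,
        top_frac=top_frac,
        min_score=min_score,
    )


def module_rpm_differences(com: SimulatedCommunity) -> dict[str, float]:
    """Condition B minus A mean log2 RPM per module, from the simulated counts."""
    from .profiling import module_abundance_matrix

    matrix = module_abundance_matrix(com.ersc, com.counts, normalization="log2_rpm")
    a_cols = [s for s, c in com.truth.sample_condition.items() if c == "A"]
    b_cols = [s for s, c in com.truth.sample_condition.items() if c == "B"]
    diff = matrix.values[b_cols].mean(axis=1) - matrix.values[a_cols].mean(axis=1)
    out = {m: float(diff[m]) for m in matrix.values.index}
    # modules without any reference sequence have no estimate; report 0 difference
    for m in matrix.undefined_modules:
        out[m] = 0.0
    return out


# -- recovery scoring --------------------------------------------------


@dataclass
class RecoveryReport:
    exact_accuracy: float
    accuracy_by_rank: dict[str, float]
    genus_or_below_accuracy: float
    completeness_rmse: float | None
    module_sign_accuracy: float | None
    n_bins: int
    n_effect_modules: int = 0


def evaluate_recovery(
    truth: SyntheticTruth,
    tree: TaxonomyTree,
    assignments: Mapping[str, BinAssignment],
    completeness_estimates: Mapping[str, float] | None = None,
    module_diff_estimates: Mapping[str, float] | None = None,
    min_effect_log2: float = 0.5,
) -> RecoveryReport:
    """Score pipeline outputs against simulation truth.

    Classification accuracy at rank r counts a bin as correct when its
    assignment is at rank r or deeper and shares the true lineage's
    ancestor at r; completeness error is the plain RMSE over bins; module
    effect recovery is the sign agreement of estimated condition
    differences for modules whose simulated |effect| reaches
    *min_effect_log2*.
    """
    bin_ids = sorted(truth.bin_species)
    missing = [b for b in bin_ids if b not in assignments]
    if missing:
        raise KeyError(f"assignments missing bins: {missing[:5]}")

    exact = 0
    from .taxonomy import RANKS

    ranks = [r for r in RANKS if r not in {"root"}]
    correct_at: dict[str, int] = {r: 0 for r in ranks}
    genus_ok = 0
    for b in bin_ids:
        true_sp = truth.bin_species[b]
        a = assignments[b]
        if a.node == true_sp:
            exact += 1
        for r in ranks:
            if not a.classified or a.rank is None or not rank_at_or_below(a.rank, r):
                continue
            if tree.ancestor_at_rank(a.node, r) == tree.ancestor_at_rank(true_sp, r):
                correct_at[r] += 1
        if (
            a.classified
            and a.rank is not None
            and rank_at_or_below(a.rank, "genus")
            and tree.ancestor_at_rank(a.node, "genus") == tree.ancestor_at_rank(true_sp, "genus")
        ):
            genus_ok += 1

    n = len(bin_ids)
    rmse = None
    if completeness_estimates is not None:
        missing_c = [b for b in bin_ids if b not in completeness_estimates]
        if missing_c:
            raise KeyError(f"completeness estimates missing bins: {missing_c[:5]}")
        sq = [
            (completeness_estimates[b] - truth.bin_completeness_pct[b]) ** 2 for b in bin_ids
        ]
        rmse = math.sqrt(sum(sq) / n)

    sign_acc = None
    n_effect = 0
    if module_diff_estimates is not None:
        agree = 0
        for mod, effect in truth.module_effect_log2.items():
            if abs(effect) < min_effect_log2:
                continue
            if mod not in module_diff_estimates:
                raise KeyError(f"module difference estimate missing for {mod!r}")
            n_effect += 1
            if math.copysign(1, module_diff_estimates[mod]) == math.copysign(1, effect):
                agree += 1
        sign_acc = agree / n_effect if n_effect else None

    return RecoveryReport(
        exact_accuracy=exact / n,
        accuracy_by_rank={r: correct_at[r] / n for r in ranks},
        genus_or_below_accuracy=genus_ok / n,
        completeness_rmse=rmse,
        module_sign_accuracy=sign_acc,
        n_bins=n,
        n_effect_modules=n_effect,
    )
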
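"""RPKM/RPM normalization, module abundance, coverage, clustering, top transcripts."""

import math

import numpy as np
import pandas as pd
import pytest

from biometha.io import CountTable
from biometha.profiling import (
    annotation_coverage,
    assign_genes_to_ecs,
    cluster_samples,
    coverage_report,
    expression_coverage,
    module_abundance,
    module_abundance_matrix,
    module_rpm,
    rpkm,
    top_expressed_summary,
)
from biometha.reference import ECNumber, ERSC, GeneRecord, MetabolicModule, RefGene


def gene(gid, ecs=(), contig="c1", start=1, end=300):
    return GeneRecord(gene_id=gid, contig_id=contig, start=start, end=end, strand="+",
                      ec_codes=[ECNumber.parse(e) for e in ecs])


class TestAssignGenes:
    def test_wildcard_ec_catches_specific_protease(self, small_ersc):
        mapping = assign_genes_to_ecs([gene("g1", ["3.4.21.1"])], small_ersc)
        assert [g.gene_id for g in mapping["3.4.-.-"]] == ["g1"]

    def test_gene_without_ec_excluded(self, small_ersc):
        assert assign_genes_to_ecs([gene("g1")], small_ersc) == {}

    def test_gene_with_two_ecs_counts_once_per_module(self, small_ersc):
        g = gene("g1", ["3.2.1.4", "2.8.4.1"])
        mapping = assign_genes_to_ecs([g], small_ersc)
        assert set(mapping) == {"3.2.1.4", "2.8.4.1"}


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [
            (0, 1000, 1_000_000, 0.0),
            (10, 1000, 1_000_000, 10.0),
            (5, 500, 2_000_000, 5.0),
        ],
    )
    def test_formula(self, count, length, total, expected):
        assert rpkm(count, length, total) == pytest.approx(expected)

    def test_joint_scale_invariance(self):
        assert rpkm(10, 800, 10**6) == pytest.approx(rpkm(30, 800, 3 * 10**6))

    def test_zero_total_is_hard_error(self):
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestModuleAbundance:
    def test_all_zero_module_maps_to_zero_with_unit_pseudocount(self):
        assert module_abundance([0.0, 0.0], pseudocount=1.0) == 0.0

    def test_mean_then_pseudocount_then_log2(self):
        assert module_abundance([3.0, 5.0]) == pytest.approx(math.log2(5), abs=1e-12)
        assert module_abundance([3.0, 5.0]) == pytest.approx(2.3219, abs=5e-4)

    def test_single_sequence_rpkm_one_gives_one(self):
        assert module_abundance([1.0]) == pytest.approx(1.0)

    def test_no_sequences_gives_none(self):
        assert module_abundance([]) is None

    def test_monotone_in_every_constituent(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 50, size=8)
        lo = module_abundance(list(base))
        for i in range(len(base)):
            bumped = base.copy()
            bumped[i] += 1.0
            assert module_abundance(list(bumped)) > lo


class TestModuleRpm:
    def test_zero_counts_map_to_zero(self):
        assert module_rpm(0, 10**6) == 0.0

    def test_worked_example(self):
        assert module_rpm(500, 1_000_000) == pytest.approx(math.log2(501))
        assert module_rpm(500, 1_000_000) == pytest.approx(8.969, abs=5e-4)

    def test_scale_invariance_of_rpm(self):
        assert module_rpm(500, 10**6, log=False) == pytest.approx(
            module_rpm(1000, 2 * 10**6, log=False)
        )


class TestCoverage:
    def test_one_of_three_ecs_gives_one_third(self, small_ersc):
        trp = small_ersc.module("TRP")
        genes = [gene("g1", ["4.1.99.1"])]
        assert annotation_coverage(trp, genes) == pytest.approx(33.3, abs=0.05)

    def test_one_of_four_ecs_gives_25_percent(self):
        module = MetabolicModule(
            "MMA", "methylamine to methyl-CoA", "methanogenesis",
            [ECNumber.parse(c) for c in ("2.1.1.248", "2.1.1.249", "2.1.1.250", "1.5.98.1")],
        )
        assert annotation_coverage(module, [gene("g1", ["2.1.1.248"])]) == pytest.approx(25.0)

    def test_all_ecs_annotated_gives_100(self, small_ersc):
        trp = small_ersc.module("TRP")
        genes = [gene(f"g{i}", [c]) for i, c in enumerate(("4.1.99.1", "1.13.11.11", "2.6.1.27"))]
        assert annotation_coverage(trp, genes) == pytest.approx(100.0)

    def test_expression_coverage_counts_ecs_with_any_read(self, small_ersc):
        counts = CountTable(
            counts=pd.DataFrame(
                {"S1": [4, 0, 0, 0, 0], "S2": [0, 0, 2, 0, 0]},
                index=["seq_prot_1", "seq_prot_2", "seq_cel_1", "seq_trp_1", "seq_mcr_1"],
            ),
            total_mapped={"S1": 100, "S2": 100},
        )
        per_module, (n_expr, n_total, pct) = expression_coverage(small_ersc, counts)
        # HYD: both ECs expressed (3.4.-.- via seq_prot_1, 3.2.1.4 via seq_cel_1)
        assert per_module["HYD"] == pytest.approx(100.0)
        assert per_module["TRP"] == 0.0
        assert (n_expr, n_total) == (2, 6)
        assert pct == pytest.approx(100 * 2 / 6, abs=1e-9)

    def test_no_reads_means_zero_everywhere(self, small_ersc):
        counts = CountTable(
            counts=pd.DataFrame({"S1": [0]}, index=["seq_prot_1"]),
            total_mapped={"S1": 10},
        )
        per_module, (n_expr, _, pct) = expression_coverage(small_ersc, counts)
        assert all(v == 0.0 for v in per_module.values())
        assert n_expr == 0 and pct == 0.0

    def test_coverage_report_table(self, small_ersc):
        genes = [gene("g1", ["3.4.21.1"]), gene("g2", ["4.1.99.1"])]
        report = coverage_report(small_ersc, genes)
        t = report.table
        assert t.loc["TRP", "n_ecs"] == 3
        assert t.loc["TRP", "annotation_coverage_pct"] == pytest.approx(33.3, abs=0.05)
        assert t.loc["HYD", "n_ecs_with_sequence"] == 2
        assert t.loc["MCR", "n_genes_detected"] == 0


class TestMatrixAndOracle:
    def _fixture(self, rng, n_modules=4, n_samples=3):
        modules, sequences = [], {}
        for m in range(n_modules):
            n_ecs = int(rng.integers(1, 4))
            ecs = []
            for e in range(n_ecs):
                code = f"{m + 1}.{e + 1}.1.1"
                ecs.append(ECNumber.parse(code))
                sequences[code] = [
                    RefGene(f"s{m}_{e}_{k}", int(rng.integers(300, 2000)))
                    for k in range(int(rng.integers(1, 3)))
                ]
            modules.append(MetabolicModule(f"M{m}", f"m{m}", "x", ecs))
        ersc = ERSC(modules=modules, sequences=sequences)
        seq_ids = [g.gene_id for genes in sequences.values() for g in genes]
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(len(seq_ids), n_samples)),
            index=seq_ids,
            columns=[f"S{j}" for j in range(n_samples)],
        )
        totals = {c: int(counts[c].sum()) + int(rng.integers(0, 1000)) for c in counts.columns}
        return ersc, CountTable(counts=counts, total_mapped=totals)

    def test_matrix_matches_brute_force_recomputation(self):
        """Direct per-cell recomputation from raw counts agrees to 1e-9 rel."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            ersc, counts = self._fixture(rng)
            matrix = module_abundance_matrix(ersc, counts)
            for m in ersc.modules:
                for s in counts.samples:
                    vals = []
                    for ec in m.ec_codes:
                        for g in ersc.sequences_for(ec):
                            c = counts.counts.at[g.gene_id, s]
                            vals.append(
                                c / ((g.length_bp / 1000) * (counts.total_mapped[s] / 1e6))
                            )
                    expected = math.log2(sum(vals) / len(vals) + 1.0)
                    got = matrix.values.at[m.module_id, s]
                    assert got == pytest.approx(expected, rel=1e-9)

    def test_rpm_matrix_matches_brute_force(self):
        rng = np.random.default_rng(43)
        ersc, counts = self._fixture(rng)
        matrix = module_abundance_matrix(ersc, counts, normalization="log2_rpm")
        for m in ersc.modules:
            for s in counts.samples:
                total = sum(
                    counts.counts.at[g.gene_id, s]
                    for ec in m.ec_codes
                    for g in ersc.sequences_for(ec)
                )
                expected = math.log2(1e6 * total / counts.total_mapped[s] + 1.0)
                assert matrix.values.at[m.module_id, s] == pytest.approx(expected, rel=1e-9)

    def test_module_without_sequences_flagged_not_imputed(self):
        m1 = MetabolicModule("M1", "m", "x", [ECNumber.parse("1.1.1.1")])
        m2 = MetabolicModule("M2", "m", "x", [ECNumber.parse("2.2.2.2")])
        ersc = ERSC(modules=[m1, m2], sequences={"1.1.1.1": [RefGene("s1", 1000)]})
        counts = CountTable(counts=pd.DataFrame({"S1": [7]}, index=["s1"]), total_mapped={"S1": 100})
        matrix = module_abundance_matrix(ersc, counts)
        assert matrix.undefined_modules == ["M2"]
        assert list(matrix.values.index) == ["M1"]


class TestClustering:
    def _matrix(self):
        return pd.DataFrame(
            {
                "A": [1.0, 2.0, 3.0],
                "B": [1.0, 2.0, 3.0],
                "C": [9.0, 9.0, 9.0],
            },
            index=["M1", "M2", "M3"],
        )

    def test_identical_samples_merge_first_at_height_zero(self):
        result = cluster_samples(self._matrix())
        first_merge = result.sample_linkage[0]
        assert first_merge[2] == 0.0  # merge height
        # A and B are leaves 0 and 1 after label sorting
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert result.sample_order.index("C") in (0, 2)

    def test_permuting_sample_order_leaves_tree_unchanged(self):
        df = self._matrix()
        r1 = cluster_samples(df)
        r2 = cluster_samples(df[["C", "A", "B"]])
        assert np.allclose(r1.sample_linkage, r2.sample_linkage)
        assert r1.sample_order == r2.sample_order
        assert r1.sample_newick == r2.sample_newick

    def test_constant_matrix_is_deterministic(self):
        df = pd.DataFrame(np.ones((3, 3)), columns=list("ABC"), index=["M1", "M2", "M3"])
        r1, r2 = cluster_samples(df), cluster_samples(df)
        assert r1.sample_order == r2.sample_order
        assert (r1.sample_linkage == r2.sample_linkage).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples(self._matrix()[["A"]])

    def test_ordered_table_matches_leaf_orders(self):
        r = cluster_samples(self._matrix())
        assert list(r.ordered.columns) == r.sample_order
        assert list(r.ordered.index) == r.module_order


class TestTopExpressed:
    def _counts(self):
        df = pd.DataFrame({"S1": [100, 10, 50], "S2": [80, 10, 40]}, index=["t1", "t2", "t3"])
        return CountTable(counts=df, total_mapped={"S1": 1000, "S2": 1000})

    def test_n_larger_than_transcript_count_uses_all(self):
        top, _ = top_expressed_summary(self._counts(), {"t1": 500, "t2": 500, "t3": 500}, n=500)
        assert len(top) == 3

    def test_top_one_by_mean_rpkm(self):
        top, _ = top_expressed_summary(self._counts(), {"t1": 500, "t2": 500, "t3": 500}, n=1)
        assert list(top["transcript_id"]) == ["t1"]

    def test_length_normalization_changes_ranking(self):
        # t1 has more reads but is 10x longer, so t3 wins on RPKM
        top, _ = top_expressed_summary(self._counts(), {"t1": 5000, "t2": 500, "t3": 500}, n=1)
        assert list(top["transcript_id"]) == ["t3"]

    def test_go_terms_counted_with_multiplicity(self):
        go = {"t1": ["GO:1", "GO:2"], "t2": ["GO:1"], "t3": ["GO:1"]}
        _, freq = top_expressed_summary(self._counts(), {"t1": 500, "t2": 500, "t3": 500},
                                        go_terms=go, n=3)
        assert freq["GO:1"] == 3
        assert freq["GO:2"] == 1

    def test_rank_boundary_tie_breaks_by_label(self):
        df = pd.DataFrame({"S1": [10, 10]}, index=["b", "a"])
        counts = CountTable(counts=df, total_mapped={"S1": 100})
        top, _ = top_expressed_summary(counts, {"a": 300, "b": 300}, n=1)
        assert list(top["transcript_id"]) == ["a"]
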
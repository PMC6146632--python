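"""Synthetic community generation, determinism, and recovery scoring."""

import filecmp
import json
from pathlib import Path

import numpy as np
import pytest

from biometha.binqc import BinFilterConfig, filter_bins, read_contig_mapping, read_marker_hits
from biometha.classify import BinAssignment, classify_bins, read_bin_membership
from biometha.io import read_counts, read_gff3, read_hits
from biometha.profiling import module_abundance_matrix
from biometha.reference import read_marker_set
from biometha.simulate import (
    SimulationConfig,
    SyntheticTruth,
    classify_community,
    evaluate_recovery,
    module_rpm_differences,
    simulate_community,
    synthetic_ersc,
    synthetic_taxonomy,
)
from biometha.taxonomy import read_taxonomy, validate_taxonomy

FAST = dict(n_bins=4, write_sequences=False, reads_per_sample=100_000)


class TestGenerators:
    def test_synthetic_taxonomy_is_valid_and_rank_complete(self):
        tree = synthetic_taxonomy((4, 1))
        assert validate_taxonomy(tree).ok
        species = [n for n, rec in tree.nodes.items() if rec.rank == "species"]
        assert len(species) == 5 * 8
        for s in species[:5]:
            assert tree.ancestor_at_rank(s, "genus") is not None
            assert tree.domain_of(s) in {"Bacteria", "Archaea"}

    def test_degenerate_taxonomy_rejected(self):
        with pytest.raises(ValueError):
            synthetic_taxonomy((1, 0))

    def test_synthetic_ersc_counts_are_exact(self):
        ersc = synthetic_ersc(n_modules=12, n_unique_ecs=48, seed=9, with_sequences=False)
        assert ersc.n_modules == 12
        assert ersc.n_unique_ecs == 48
        assert any(ec.is_wildcard for ec in ersc.unique_ecs)

    def test_some_ecs_lack_sequences(self):
        ersc = synthetic_ersc(n_modules=12, n_unique_ecs=48, seed=9,
                              frac_ecs_without_sequence=0.1, with_sequences=False)
        assert len(ersc.ecs_without_sequence()) == round(0.1 * 48)


class TestSimulateCommunity:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=13, n_bins=3, reads_per_sample=50_000)
        simulate_community(cfg, out_dir=tmp_path / "a")
        simulate_community(cfg, out_dir=tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files  # emitted something
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", files, shallow=False)
        assert mismatch == [] and errors == []

    def test_noiseless_limit_every_top_hit_is_the_true_taxon(self):
        com = simulate_community(SimulationConfig(seed=2, hit_error_rate=0.0, decoy_hit_rate=0.0, **FAST))
        frag_bins = com.fragment_bins
        for h in com.hits:
            assert h.subject_taxon == com.truth.bin_species[frag_bins[h.query_id]]

    def test_full_completeness_gives_all_137_markers(self):
        cfg = SimulationConfig(seed=3, completeness_range=(1.0, 1.0), **FAST)
        com = simulate_community(cfg)
        for gb in com.bins:
            assert len(gb.markers_found) == 137
            assert gb.completeness_pct == 100.0

    def test_truth_round_trips_through_json(self, tmp_path):
        com = simulate_community(SimulationConfig(seed=4, **FAST), out_dir=tmp_path)
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back == com.truth

    def test_emitted_files_reload_through_the_io_layer(self, tmp_path):
        """End-to-end on files: simulate, then reread every interface file and
        run QC + classification + profiling from disk alone."""
        cfg = SimulationConfig(seed=8, n_bins=4, reads_per_sample=50_000)
        com = simulate_community(cfg, out_dir=tmp_path)
        tree = read_taxonomy(tmp_path / "taxonomy.tsv")
        marker_set = read_marker_set(tmp_path / "marker_set.txt")
        membership = read_bin_membership(tmp_path / "bins.tsv")
        marker_hits = read_marker_hits(tmp_path / "markers.tsv")
        mapping = read_contig_mapping(tmp_path / "mapping.tsv")
        hits = read_hits(tmp_path / "hits.tsv")
        counts = read_counts(tmp_path / "counts.tsv", tmp_path / "totals.tsv")
        genes = read_gff3(tmp_path / "genes.gff3")
        assert set(membership) == {gb.bin_id for gb in com.bins}
        assert marker_set.expected_count == 137
        assert len(hits) == len(com.hits)
        assert counts.counts.equals(com.counts.counts)
        assert len(genes) == len(com.genes)
        assert len(mapping) == cfg.n_dna_samples

        # QC from files
        from biometha.binqc import completeness, sample_support
        from biometha.reference import GenomicBin

        lengths = {}
        for line in (tmp_path / "contig_lengths.tsv").read_text().splitlines()[1:]:
            cid, n = line.split("\t")
            lengths[cid] = int(n)
        bins = []
        for bin_id, contigs in membership.items():
            gb = GenomicBin(bin_id=bin_id, contigs={c: lengths[c] for c in contigs},
                            markers_found=set(marker_hits.get(bin_id, [])))
            gb.completeness_pct = completeness(gb.markers_found, marker_set)
            sample_support(mapping, gb)
            bins.append(gb)
        retained, _ = filter_bins(bins, BinFilterConfig())
        assert {b.bin_id for b in retained} <= set(membership)

        # classification from files agrees with the in-memory route
        from biometha.classify import FragmentationConfig, fragment_contig

        bin_fragments, bin_of_fragment = {}, {}
        for bin_id, contigs in membership.items():
            n = 0
            for contig in contigs:
                frags = fragment_contig(contig, lengths[contig], FragmentationConfig())
                n += len(frags)
                for f in frags:
                    bin_of_fragment[f.fragment_id] = bin_id
            bin_fragments[bin_id] = n
        frag_hits: dict[str, list] = {}
        for h in hits:
            frag_hits.setdefault(h.query_id, []).append(h)
        from_files = classify_bins(bin_fragments, frag_hits, bin_of_fragment, tree)
        in_memory = classify_community(com)
        assert {b: a.node for b, a in from_files.items()} == {
            b: a.node for b, a in in_memory.items()
        }

        matrix = module_abundance_matrix(com.ersc, counts, normalization="log2_rpm")
        assert matrix.values.shape[1] == 2 * cfg.n_rna_samples_per_condition


class TestEvaluateRecovery:
    def _perfect(self, com):
        return {
            b: BinAssignment(bin_id=b, node=sp, rank="species", score_max=1.0, top_set=[sp])
            for b, sp in com.truth.bin_species.items()
        }

    def test_outputs_identical_to_truth_score_perfectly(self):
        com = simulate_community(SimulationConfig(seed=5, **FAST))
        report = evaluate_recovery(
            com.truth, com.tree, self._perfect(com),
            completeness_estimates=dict(com.truth.bin_completeness_pct),
            module_diff_estimates={m: e for m, e in com.truth.module_effect_log2.items()},
        )
        assert report.exact_accuracy == 1.0
        assert report.accuracy_by_rank["genus"] == 1.0
        assert report.completeness_rmse == 0.0
        assert report.module_sign_accuracy == 1.0

    def test_all_bins_assigned_root_score_zero_at_genus(self):
        com = simulate_community(SimulationConfig(seed=6, **FAST))
        at_root = {
            b: BinAssignment(bin_id=b, node="root", rank="root", score_max=1.0, top_set=["root"])
            for b in com.truth.bin_species
        }
        report = evaluate_recovery(com.truth, com.tree, at_root)
        assert report.genus_or_below_accuracy == 0.0
        assert report.exact_accuracy == 0.0

    def test_constant_completeness_offset_gives_that_rmse(self):
        com = simulate_community(SimulationConfig(seed=7, n_bins=10, write_sequences=False,
                                                  reads_per_sample=50_000))
        off = {b: v + 5.0 for b, v in com.truth.bin_completeness_pct.items()}
        report = evaluate_recovery(com.truth, com.tree, self._perfect(com),
                                   completeness_estimates=off)
        assert report.completeness_rmse == pytest.approx(5.0)

    def test_missing_bin_is_hard_error(self):
        com = simulate_community(SimulationConfig(seed=5, **FAST))
        partial = self._perfect(com)
        partial.popitem()
        with pytest.raises(KeyError):
            evaluate_recovery(com.truth, com.tree, partial)


class TestExpressionRecovery:
    def test_module_effect_signs_recovered_across_replicates(self):
        """Simulated module-level log2 effects of at least 0.5 between the
        two conditions have their sign recovered from Poisson counts in at
        least 95% of (replicate, module) cases."""
        total, agree = 0, 0
        for rep in range(100):
            cfg = SimulationConfig(seed=1000 + rep, n_bins=2, write_sequences=False,
                                   reads_per_sample=200_000, frac_ecs_without_sequence=0.0)
            com = simulate_community(cfg)
            diffs = module_rpm_differences(com)
            for mod, effect in com.truth.module_effect_log2.items():
                if abs(effect) < 0.5:
                    continue
                total += 1
                agree += (diffs[mod] > 0) == (effect > 0)
        assert total > 50
        assert agree / total >= 0.95

    def test_negative_binomial_counts_supported(self):
        cfg = SimulationConfig(seed=9, count_model="nb", nb_dispersion=0.3, **FAST)
        com = simulate_community(cfg)
        assert (com.counts.counts.values >= 0).all()
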
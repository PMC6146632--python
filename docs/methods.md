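# Methods

`biometha` implements the bespoke downstream stages of a
metagenome/metatranscriptome workflow for anaerobic-digester (biogas)
microbiomes: quality control and retention of genomic bins, fragment-vote
taxonomic classification, merging of bacterial and archaeal CDS
annotations for mixed-background bins, and functional profiling of
expression against a curated EC reference sequence collection (ERSC).
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Bin quality control

**Profile completeness.** A bin's completeness is the percentage of a
universal single-copy marker panel detected in it:
`100 × |markers found| / |panel|`. The default panel size is 137 genes
(the bacterial/archaeal single-copy panel widely used for bin
completeness); the panel itself is data supplied by file, so any marker
set can be substituted. Marker observations use presence/absence
semantics: duplicate detections of one marker never inflate the score and
are reported separately (`duplicate_marker_report`) as a contamination
hint. Scores are reported to one decimal with round-half-even so reports
are deterministic.

**Sample support.** The retention rule couples completeness with
cross-sample read support. The upstream description conflates two
readings ("coverage of at least 50% or more" vs. "mapping of at least 2
out of 4 samples"), so both are exposed: a sample supports a bin when at
least `min_contig_frac` (default 0.5) of the bin's contigs receive one or
more mapped reads from it, and a bin is retained when at least
`min_sample_support` (default 2) of `n_samples` (default 4) samples
support it. Both knobs are configurable.

**Thresholds are inclusive.** "10% or more" and "at least 2 of 4" mean a
bin at exactly 10.0% completeness with exactly 2 supporting samples is
retained; "contigs smaller than 1000 bp are discarded" means a 1000-bp
contig survives the prefilter. The boundary tests pin these semantics.

## Taxonomic classification

Contigs are split into consecutive 1000-bp fragments
(`fragment_bp=1000`). A terminal remainder shorter than `min_tail_bp`
(default 200 bp) is merged into the previous window rather than emitted
as a tiny fragment — short windows carry almost no alignment signal; the
threshold is a package choice since the reference binning tool does not
publish its rule.

Each fragment casts one vote: the subject taxon of its top-scoring hit
(maximal bit score; ties broken by lower e-value, then lexicographic
subject id, so runs are bit-for-bit reproducible). Per-taxon scores are
vote counts divided by the number of fragments in the bin — computed over
the whole bin, not per contig — so hitless fragments dilute all scores
and score vectors sum to at most 1.

**Top-scoring set.** "Top-scoring taxa" is implemented as a relative
band: every taxon scoring at least `top_frac` (default 0.8) of the
maximum. A strict maximum (`top_frac=1.0`) is available, but a strict max
degenerates the ancestor resolution to a single taxon whenever vote
counts differ by even one fragment, which defeats the purpose of a
conservative rank assignment. The bin is assigned the lowest (deepest)
common ancestor of the top set; an empty vector is unclassified.

**Hybrid bins.** A bin is flagged hybrid when its assignment sits at or
above domain rank and the top set spans both Bacteria and Archaea.
Such bins typically have very low completeness (below 20%), which the
report records as the suspected cause when completeness is supplied.

One vote per fragment is emitted even when several hits tie at the top
score (the deterministic tie-break selects one); counting all tied hits
as separate votes is a known alternative the implementation does not use.

## Annotation merging

Bins of mixed taxonomic background are annotated twice (bacterial and
archaeal gene callers). The merge keeps every bacterial CDS; an
*annotated* archaeal CDS (gene name or EC known) is added when it
overlaps no annotated bacterial CDS at the same locus, and it *replaces*
any unannotated bacterial CDS it overlaps. "Same locus" means reciprocal
overlap above `min_reciprocal_overlap` (default 0.5 — more than half of
*both* CDS lengths) on the same contig and strand; the threshold is
configurable (`--merge-overlap`) because the original merge script's rule
is unpublished. Comparing CDS across contigs is a hard error. Under this
rule an annotated bacterial CDS is never removed, and for
internally non-overlapping inputs the merged annotated count is at least
the larger of the two inputs' counts.

## EC reference collection and functional profiling

EC numbers are four dot-separated fields; trailing dash wildcards
(`3.4.-.-` for proteases, `3.1.1.-` for lipases) match any fully
specified EC sharing the specified prefix. A metabolic module is the
enzyme complement of one conversion step of the anaerobic-digestion
pathway; duplicate ECs within a module collapse on load, duplicates
across modules are preserved (a gene then counts once per module). ECs
may legitimately carry zero reference sequences ("no known sequence");
they are flagged, never imputed. Any number of reference sequences per
EC is allowed.

**Normalization.** For a gene with `c` reads, length `L` bp, and `N`
total mapped reads in the sample: `RPKM = c / ((L/1000)·(N/10^6))`;
`RPM = 10^6·c/N`. `N` is the per-sample total mapped to the reference
collection in use (supplied via the totals sidecar; defaults to the
column sum when absent).

**Module abundance.** RPKM mode:
`log2( mean over module sequences of RPKM + ε )`, the unweighted mean
over *all* reference sequences of *all* ECs in the module,
zero-count sequences included; the pseudocount is added after averaging.
A per-EC-mean variant (average within each EC first) is available and the
report records which was used. RPM mode sums counts over the module's
sequences first: `log2(10^6·Σc/N + ε)`. The pseudocount ε defaults to 1
so silent modules map exactly to 0 on the log2 scale; it is configurable
(`--pseudocount`).

**Coverage.** Annotation coverage of a module is the percentage of its
unique ECs carried by at least one annotated gene (wildcards expand);
expression coverage is the percentage with at least one mapped read in at
least one selected sample, with a global expressed-EC tally alongside.

**Clustering.** Samples and modules are clustered agglomeratively
(Euclidean distance, average linkage — the display convention for these
heatmaps; both configurable). Labels are sorted before distance
computation so ties, including fully constant matrices, resolve
identically regardless of input order; dendrograms are exported as
Newick, and leaf orders fix the heatmap layout.

**Top expressed transcripts.** Transcripts are ranked by mean RPKM over
the selected samples; ties at the rank-`n` boundary break by transcript
id. GO terms are tallied with multiplicity over the top `n` (default
500). Only frequency tallies are produced — no enrichment statistics.

## Synthetic communities

The generator emits every input the pipeline consumes, with ground truth,
so all stages are testable without downloads.

- **Taxonomy**: two domains with full rank chains; by default 4
  bacterial phyla and 1 archaeal phylum (mirroring a bacteria-dominated
  digester with a single archaeal phylum), branching ×2 at family, genus
  and species — 40 species in total, enough structure for non-trivial
  ancestor queries.
- **Markers**: each of the 137 panel genes is present in a bin with
  probability equal to the bin's target completeness. Truth records the
  *realized* completeness (present markers / 137), so with perfect
  detection the estimator's RMSE is exactly 0 by construction of the
  estimator, not by sampling luck.
- **Hits**: each fragment's top hit is the bin's true species with
  probability 1 − ε, otherwise a uniformly random species from another
  phylum; decoy hits with strictly lower bit scores are added at rate 0.3
  to exercise top-hit selection.
- **Expression**: per-gene log2 baseline ~ Normal(μ=3, σ=1.5); each
  module carries a condition effect ~ Uniform(−2, 2) log2 units applied
  in condition B; expected reads ∝ rate × gene length, normalized to the
  sample depth (10^6 by default, 3 samples per condition); counts are
  Poisson, with a gamma-Poisson (negative binomial) option since real
  metatranscriptomes are overdispersed.
- **Determinism**: one seeded generator drives everything; the same
  config yields byte-identical files.

What the generator does *not* emulate: sequence-level homology (hits are
drawn, not aligned), assembly artifacts (chimeric contigs, misbinning),
strain heterogeneity, compositional coupling beyond depth normalization,
and library-preparation biases. Passing recovery tests therefore
demonstrates the correctness of the decision rules and arithmetic, not
robustness to real-data noise sources outside this model.

**Recovery scoring.** Classification accuracy at rank r counts a bin as
correct when its assignment is at rank r or deeper and shares the true
lineage's ancestor at r. Completeness error is plain RMSE. Module-effect
recovery is the sign agreement of estimated condition differences
(mean log2 RPM in B minus A) for modules whose simulated |effect| is at
least 0.5 log2 units; smaller effects are not scored because depth
normalization makes RPM compositional and sub-0.5 shifts can be absorbed
by renormalization.

## Problem sizes and numerical notes

The bundled checks run at desk scale by design: oracle comparisons use
1000 random trees of up to 200 nodes; recovery runs use 50 bins
(noiseless) and 200 bins at ε=0.1 (noisy); normalization agreement is
checked on 100 random fixtures at 10⁻⁹ relative tolerance; expression
sign recovery uses 30 replicate communities. Headline corpus statistics
of the original full-scale study (built from ~46 Gb of raw reads on a
compute cluster) are out of reach at this scale and are not asserted;
the full-size *shape* of the EC collection (235 unique ECs in 52
modules) is emulated synthetically and its load-time counting verified.

Degenerate inputs: empty marker sets, zero-fragment bins, zero totals,
single-sample clustering, and single-node taxonomies are hard errors;
empty hit tables, empty FASTA files and empty bin lists are valid empty
results. All floating-point report values are emitted at fixed precision
with round-half-even.

## Known limitations

- The merge rule is a documented stand-in for an unpublished script; real
  mixed-background annotations may need a different overlap threshold.
- Marker multiplicity is ignored for completeness (presence/absence); a
  CheckM-style contamination estimate is out of scope.
- Redundancy collapse of transcripts (non-redundant transcriptional
  units) is out of scope; counts are reported on input units.
- The CLI `report` command renders markdown only; figures come from
  `plot_heatmap` / the `cluster --heatmap` option.
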
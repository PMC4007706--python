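# Methods

## The analysis and its assumptions

`txsnp` re-implements, as a tested library, the post-alignment half of a
pooled-sample transcriptome SNP survey. The design assumptions are
those of the study it follows: RNA-seq libraries are pooled over many
individuals per strain, so genotypes of individual animals are not
identifiable — the unit of evidence is the (strain, site, alternate
allele) observation with its read support, and no allele-frequency or
Hardy–Weinberg modelling is attempted. Variants are single-nucleotide
only; indels and MNPs in input VCFs are skipped and counted, never
analysed. Because SNP detection from RNA-seq depends on expression,
every quantitative claim is restricted to "SNP-genes" — genes whose
coverage and expression make an absence of calls interpretable.

Internally all coordinates are 0-based half-open; GTF and VCF (1-based)
and depth tables are converted exactly once, at the I/O boundary.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| `min_qual` | 40 (phred) | site-level call quality; applied to every strain |
| `min_qa` | 40 | per-strain, per-allele sum of alternate-observation qualities |
| `min_dp` | 3 reads | per-strain read depth |
| `min_ao` | 2 reads | per-strain, per-allele alternate observations |
| `min_base_depth` | 3 reads | a transcript base counts as covered at this depth |
| `min_coverage_fraction` | 0.90 | closed bound: exactly 90 % passes |
| `min_fpkm` | 15 | open bound: exactly 15 fails |
| `near_window` / `far_window` | 1 000 / 10 000 bp | NTU distance classes |
| `alpha` | 0.01 | significance level of the paired density test |

The mixed boundary semantics (coverage closed, FPKM open) follow the
inequality notation of the criteria being reproduced ("≥ 90 %",
"FPKM > 15"); the filter minima are closed ("minimum 40" admits 40).
For multi-isoform genes, "transcript length" is the genomic exon union
of all isoforms — a single number per gene, since selection is at gene
level; the alternative (longest isoform) is not offered, and the choice
is recorded in output provenance headers.

## Classification conventions

* Splice windows are the two intronic bases entering (donor) and
  leaving (acceptor) each intron in transcript orientation, matching
  canonical GT/AG dinucleotides; the window size is configurable.
  Windows are intronic by construction, so splice and exonic classes
  never compete.
* In the CDS, the rules are applied to the mutated codon in this order:
  annotated-start destruction, stop↔stop (synonymous-stop), stop loss,
  stop gain, then amino-acid comparison under the standard nuclear
  code (stops {TAA, TAG, TGA}; no mitochondrial handling). The CDS as
  modelled here includes the stop codon, which is what makes stop-codon
  classes addressable; total CDS length must be divisible by 3 or the
  transcript is flagged frame-broken and excluded from ORF calls.
* START_GAINED requires the alternate allele to complete a new ATG
  lying entirely within the 5'UTR, with no Kozak-context requirement,
  and takes precedence over plain UTR_5.
* Gene-level counting is per (gene, site, alt): isoforms of one gene
  agreeing on a class count once; disagreeing isoforms each contribute
  their class, and an ambiguity counter records how often that happened
  (the original tabulation did not state a collapse rule, so the
  convention is made explicit and observable). Non-coding transcripts
  are counted and skipped for exonic classes; their splice windows are
  still classified.
* Strain-specific means retained after filtering in exactly one strain,
  evaluated per alternate allele.

## NTU conventions

Distance is the strand-agnostic gap in bases between the NTU interval
and the nearest annotated exon (of any transcript, not collapsed gene
spans); overlap or abutment is distance 0. WITHIN means ≤ 1 000,
BEYOND means > 10 000 (matching the "> 10 000 bp away" phrasing of the
novel-gene criterion), the middle band is the remainder. A contig with
no annotation gives infinite distance: BEYOND by convention, flagged
`empty_supercontig` and reported separately. FPKM bin labels are read
as disjoint intervals [0,1), [1,10), [10,100), [100,∞) — the published
per-bin counts only sum to the published total if the bins are
disjoint — and the cumulative ("in all three strains") bin is the bin
of the maximum FPKM over strains, so the lowest cumulative bin is
exactly "below 1 in every strain".

## Statistics

The strain-pair density comparison is a two-sided Wilcoxon signed-rank
test on PS/kb paired by supercontig, restricted to supercontigs present
in both strains (≥ 10 pairs required; an all-zero difference vector
returns p = 1 by convention). A paired rank test was chosen because the
design pairs corresponding supercontigs and density distributions are
skewed; a paired sign test would be the conservative alternative. No
multiple-testing correction is applied across the three pairwise tests,
and that is noted in the output. The spatial gene-count association
uses squared Pearson correlation (an R² is what the claim states); the
density-vs-FPKM detection-bias diagnostic uses Spearman's rank
correlation because a monotone bias is the concern. The strain-level
density aggregate is Σ sites / Σ kilobases over SNP-genes, so the
weighted identity against per-gene densities holds exactly.

## The synthetic-data generator

`simulate()` produces a complete, internally consistent input bundle
with planted answers. Design choices:

* **Class-first variant planting.** An effect class is drawn from a
  target mix (dominated by synonymous and 3'UTR changes, as in real
  transcriptome data), then a gene, position and allele realizing that
  class are searched for. Truth labels therefore never depend on
  running a classifier. Variants that would fall into a second gene's
  space are only admitted where both genes agree by construction
  (planted convergent 3'UTR–3'UTR overlaps), which is also what
  exercises the count-per-gene rule.
* **Quality fields conditioned on intended outcomes.** Each planted
  site draws per-strain retention first — a mixture of single-strain,
  two-strain and all-strain membership whose default weights are solved
  so expected per-strain densities land near 5.05/9.13/9.43 PS/kb with
  the reference strain lowest, and strain-specific fractions near
  15/28/28 % — then draws QUAL/QA/DP/AO conditional on passing or
  failing, including exact boundary values (40/40/3/2) at a small rate.
  The retained set under the default filters is therefore known
  exactly. About 5 % of sites fail site-level QUAL outright, and extra
  failing calls appear in non-member strains.
* **Exact coverage control.** Per gene and strain a covered-base count
  is planted directly (a contiguous dropout block in exon space), with
  pass targets above 0.92 and fail targets in 0.50–0.88 so the cohort
  straddles the 0.90 cutoff; FPKM draws straddle 15 the same way. For
  genes overlapping at UTRs the final depth array is re-read to give
  exact truth. Intron/intergenic background depth is low Poisson noise.
* **Controlled NTU geometry.** Contig layout reserves standard
  intergenic gaps and one ~25–30 kb gap per contig; NTUs are placed at
  drawn distances straddling both window thresholds, and every third
  beyond-10 kb NTU goes to an annotation-empty contig so that feature
  is always present.
* **Scale.** Defaults are ≈ 100× below the real study: 12 gene-bearing
  supercontigs plus 2 empty ones (~0.4 Mb), ~50–70 genes, ~600–700
  sites, 30 NTUs; a run takes under a second and the full test suite
  under a minute. Sizes were chosen so every statistic still has
  working sample sizes (e.g. ≥ 10 supercontig pairs for the paired
  test).

What the generator does **not** emulate: read-level errors, alignment
artefacts, allele-specific expression, mapping bias near splice sites,
GC effects on coverage, or linkage between nearby sites. Passing tests
therefore demonstrate correctness of the accounting and classification
logic under clean inputs, not robustness to upstream artefacts.

`verify_ground_truth()` re-reads an emitted bundle and asserts the
truth is consistent with the files themselves: reference alleles match
the genome, every planted class sits in the compartment it implies,
NTU distances match an exhaustive rescan, and covered-base counts match
the depth tracks.

## Numerical and degenerate-input choices

* VCF QUAL passes through htslib as a 32-bit float; it is rounded to
  4 decimals on read so written values round-trip exactly.
* Reference-N sites are excluded with a warning; ref/genome mismatches
  are excluded and counted (the count must be 0 on simulator output).
* An empty SNP-gene set produces empty density tables rather than
  0/0 divisions; a constant count vector makes the gene-count R²
  NaN; fewer than 10 shared supercontigs makes the paired test refuse
  rather than return an unstable p-value.
* Provenance headers on every output TSV hash the analysis parameters
  (not file paths), so identical analyses produce byte-identical
  reports.

## Known limitations

* Effect classification assumes the annotated reading frame; it does
  not re-annotate starts/stops disrupted by other variants (each
  variant is classified against the reference transcript
  independently, as the original single-variant annotation did).
* The isoform-disagreement convention (one record per distinct class)
  can count one allele twice within a gene when isoforms differ; the
  ambiguity counter makes this visible but the original tabulation's
  behaviour is unknown.
* FPKM is taken as given; no re-normalisation across libraries is
  attempted, so cross-strain FPKM comparability is an input assumption.
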
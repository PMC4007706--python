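"""Effect classification: codon-level cases, splice windows, strand
symmetry, oracle equivalence and the gene-level counting rules."""

import numpy as np
import pytest

from _oracle import classify_oracle, oracle_corpus
from conftest import TOY_OFFSET, TOY_UTR5
from txsnp.effects import (
    EffectClass,
    classify_all,
    classify_variant,
    strain_specific,
    summarize_effects,
)
from txsnp.filtering import FilterCriteria, FilteredCallset, apply_quality_filters
from txsnp.models import (
    GeneModel,
    Genome,
    SupercontigSeq,
    TranscriptModel,
    revcomp,
)

STRAINS = ("LVP", "CTM", "RexD")


def _callset(entries):
    retained = {s: set() for s in STRAINS}
    for s, key in entries:
        retained[s].add(key)
    return FilteredCallset(
        FilterCriteria(), retained,
        {s: len(retained[s]) for s in STRAINS},
        {s: {} for s in STRAINS},
    )


class TestCodonCases:
    # transcript layout: 10nt UTR5 "CCCCACGCCC", CDS "ATGGAATACCATTGGTAA",
    # 10nt UTR3; offsets below are transcript coordinates
    @pytest.mark.parametrize(
        "tx_off,alt,expected",
        [
            (15, "G", EffectClass.SYNONYMOUS),        # GAA -> GAG (Glu)
            (23, "C", EffectClass.NON_SYNONYMOUS),    # CAT -> CAC? no: TGG pos
            (11, "C", EffectClass.START_LOST),        # ATG -> ACG
            (18, "A", EffectClass.STOP_GAINED),       # TAC -> TAA mid-CDS
            (25, "C", EffectClass.STOP_LOST),         # TAA -> CAA
            (27, "G", EffectClass.SYNONYMOUS_STOP),   # TAA -> TAG
            (5, "T", EffectClass.START_GAINED),       # ACG -> ATG in UTR5
            (0, "G", EffectClass.UTR_5),
            (30, "C", EffectClass.UTR_3),
        ],
    )
    def test_plus_strand_classes(self, toy, tx_off, alt, expected):
        genome, gene, tx = toy
        pos0 = TOY_OFFSET + tx_off
        ref = genome.base("chr", pos0)
        rec = classify_variant(pos0, ref, alt, tx, genome)
        assert rec.effect_class == expected

    def test_non_synonymous_third_gene_codon(self, toy):
        genome, gene, tx = toy
        # codon 5 TGG (Trp) -> TGC (Cys)
        pos0 = TOY_OFFSET + len(TOY_UTR5) + 14
        rec = classify_variant(pos0, genome.base("chr", pos0), "C", tx, genome)
        assert rec.effect_class == EffectClass.NON_SYNONYMOUS
        assert rec.aa_change == ("W", "C")

    def test_codon_change_recorded_only_for_coding(self, toy):
        genome, gene, tx = toy
        rec = classify_variant(TOY_OFFSET, "C", "G", tx, genome)
        assert rec.codon_change is None

    def test_outside_transcript_errors(self, toy):
        genome, gene, tx = toy
        with pytest.raises(ValueError, match="outside transcript"):
            classify_variant(5, genome.base("chr", 5), "T", tx, genome)


class TestSpliceWindows:
    def test_donor_and_acceptor_plus_strand(self, toy_spliced):
        genome, gene, tx = toy_spliced
        # intron is (70, 80): donor = 70,71; acceptor = 78,79
        for pos in (70, 71):
            rec = classify_variant(pos, genome.base("chr", pos), "A", tx, genome)
            assert rec.effect_class == EffectClass.SPLICE_DONOR
        for pos in (78, 79):
            rec = classify_variant(pos, genome.base("chr", pos), "A", tx, genome)
            assert rec.effect_class == EffectClass.SPLICE_ACCEPTOR

    def test_window_adjacent_exonic_bases_are_exonic(self, toy_spliced):
        genome, gene, tx = toy_spliced
        for pos in (69, 80):  # last base of exon 1, first base of exon 2
            ref = genome.base("chr", pos)
            alt = "A" if ref != "A" else "G"
            rec = classify_variant(pos, ref, alt, tx, genome)
            assert rec.effect_class not in (
                EffectClass.SPLICE_DONOR, EffectClass.SPLICE_ACCEPTOR,
            )

    def test_windows_are_intronic(self, sim):
        for g in sim.genes:
            for t in g.transcripts:
                for (s, e), _ in t.splice_windows(2):
                    for p in range(s, e):
                        assert not any(
                            xs <= p < xe for xs, xe in t.exons
                        )


class TestOracleEquivalence:
    def test_rule_based_equals_translation_oracle(self, sim):
        corpus = oracle_corpus(sim)
        assert len(corpus) >= 1500
        for pos0, ref, alt, tx in corpus:
            rec = classify_variant(pos0, ref, alt, tx, sim.genome)
            assert rec.effect_class.value == classify_oracle(
                pos0, alt, tx, sim.genome
            ), f"{tx.transcript_id}:{pos0} {ref}>{alt}"

    def test_strand_symmetry(self, sim):
        """Mirroring the genome and flipping all coordinates/strands
        leaves every classification unchanged."""
        corpus = oracle_corpus(sim)[::7][:300]
        mirrored_genomes = {}
        for pos0, ref, alt, tx in corpus:
            contig = tx.contig_id
            L = len(sim.genome[contig])
            if contig not in mirrored_genomes:
                mirrored_genomes[contig] = Genome.from_contigs(
                    [SupercontigSeq(contig, revcomp(sim.genome[contig].sequence))]
                )
            flip = lambda iv: (L - iv[1], L - iv[0])
            mtx = TranscriptModel(
                tx.transcript_id, tx.gene_id, contig,
                "-" if tx.strand == "+" else "+",
                exons=tuple(sorted(flip(iv) for iv in tx.exons)),
                cds_intervals=tuple(sorted(flip(iv) for iv in tx.cds_intervals)),
            )
            orig = classify_variant(pos0, ref, alt, tx, sim.genome)
            mirr = classify_variant(
                L - 1 - pos0, revcomp(ref), revcomp(alt),
                mtx, mirrored_genomes[contig],
            )
            assert orig.effect_class == mirr.effect_class


class TestGeneLevelCounting:
    def test_overlap_snp_counted_once_per_gene(self, sim, report):
        vt = sim.truth.variant_records
        dup = vt.groupby(["contig", "pos", "alt"]).gene_id.nunique()
        multi = dup[dup > 1]
        assert len(multi) > 0, "simulation should plant shared-UTR overlaps"
        got = {}
        for rec in report.classification.records:
            key = (rec.contig_id, rec.pos0 + 1, rec.alt_allele)
            got.setdefault(key, set()).add(rec.gene_id)
        retained_any = set().union(*sim.truth.retained.values())
        snp = sim.truth.snp_genes
        for (c, p, a), n in multi.items():
            genes = set(vt[(vt.contig == c) & (vt.pos == p) & (vt.alt == a)].gene_id)
            genes &= snp
            if (c, p - 1, a) in retained_any and len(genes) > 1:
                assert got[(c, p, a)] == genes

    def test_snp_outside_snp_genes_yields_no_record(self, toy):
        genome, gene, tx = toy
        cs = _callset([("LVP", ("chr", TOY_OFFSET + 15, "G"))])
        out = classify_all(cs, [gene], genome, snp_genes=set())
        assert out.records == []

    def test_identical_isoforms_count_once(self, toy):
        genome, gene, tx = toy
        t2 = TranscriptModel(
            "toy_t2", "toy", "chr", "+", exons=tx.exons,
            cds_intervals=tx.cds_intervals,
        )
        gene2 = GeneModel("toy", "chr", "+", (tx, t2))
        cs = _callset([("LVP", ("chr", TOY_OFFSET + 15, "G"))])
        out = classify_all(cs, [gene2], genome, snp_genes={"toy"})
        assert len(out.records) == 1
        assert out.n_isoform_ambiguous == 0


class TestStrainSpecific:
    def test_definitions(self):
        shared = ("c", 1, "G")
        only_ctm = ("c", 2, "T")
        cs = _callset(
            [(s, shared) for s in STRAINS] + [("CTM", only_ctm)]
        )
        spec = strain_specific(cs)
        assert spec == {("CTM", "c", 2, "T")}

    def test_matches_membership_scan(self, sim, report):
        cs = report.callset
        brute = set()
        for s in STRAINS:
            for key in cs.retained[s]:
                if all(key not in cs.retained[o] for o in STRAINS if o != s):
                    brute.add((s, *key))
        assert strain_specific(cs) == brute


class TestSummaries:
    def test_empty_records_all_zero(self):
        cs = _callset([])
        table = summarize_effects([], cs)
        assert (table.to_numpy() == 0).all()
        assert len(table) == len(EffectClass)

    def test_matches_group_by_oracle(self, sim, report):
        cs = report.callset
        spec = strain_specific(cs)
        table = report.effect_summary
        for s in STRAINS:
            for cls in EffectClass:
                recs = [
                    r for r in report.classification.records
                    if r.effect_class == cls
                    and (r.contig_id, r.pos0, r.alt_allele) in cs.retained[s]
                ]
                n_spec = sum(
                    1 for r in recs
                    if (s, r.contig_id, r.pos0, r.alt_allele) in spec
                )
                row = table.loc[cls.value]
                assert row[f"{s}_snps"] == len(recs)
                assert row[f"{s}_specific"] == n_spec
                assert row[f"{s}_genes"] == len({r.gene_id for r in recs})

    def test_class_totals_sum_to_occurrences(self, report):
        table = report.effect_summary
        for s in STRAINS:
            total = sum(
                1 for r in report.classification.records
                if (r.contig_id, r.pos0, r.alt_allele)
                in report.callset.retained[s]
            )
            assert table[f"{s}_snps"].sum() == total
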
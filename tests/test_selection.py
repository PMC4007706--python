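"""SNP-gene selection: coverage arithmetic, boundary semantics, Venn
consistency and planted-truth recovery."""

import numpy as np
import pytest

from txsnp.models import (
    CoverageTrack,
    GeneExpression,
    GeneModel,
    TranscriptModel,
)
from txsnp.selection import (
    SelectionCriteria,
    assign_sites_to_genes,
    gene_coverage,
    select_snp_genes,
)

STRAINS = ("LVP", "CTM", "RexD")


def single_exon_gene(gene_id="g", start=0, end=1000, contig="c"):
    tx = TranscriptModel(f"{gene_id}_t", gene_id, contig, "+",
                         exons=((start, end),))
    return GeneModel(gene_id, contig, "+", (tx,))


def track_with(depths, strain="LVP", contig="c"):
    return CoverageTrack(strain, {contig: np.asarray(depths, dtype=np.int64)})


class TestGeneCoverage:
    def test_uniform_depth_full_coverage(self):
        gene = single_exon_gene(end=1000)
        rec = gene_coverage(track_with([5] * 1000), gene)
        assert rec.coverage_fraction == 1.0

    def test_partial_coverage_fraction(self):
        depths = [5] * 890 + [0] * 110
        rec = gene_coverage(track_with(depths), single_exon_gene(end=1000))
        assert rec.coverage_fraction == pytest.approx(0.89)
        assert rec.coverage_fraction < 0.90

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            exons = []
            cur = int(rng.integers(0, 50))
            for _ in range(int(rng.integers(1, 5))):
                L = int(rng.integers(30, 200))
                exons.append((cur, cur + L))
                cur += L + int(rng.integers(10, 100))
            tx = TranscriptModel("t", "g", "c", "+", exons=tuple(exons))
            gene = GeneModel("g", "c", "+", (tx,))
            depths = rng.integers(0, 8, cur + 10)
            rec = gene_coverage(CoverageTrack("LVP", {"c": depths}), gene, 3)
            brute = sum(
                1 for s, e in exons for p in range(s, e) if depths[p] >= 3
            )
            assert rec.covered_bases == brute

    def test_multi_transcript_union_counts_bases_once(self):
        t1 = TranscriptModel("t1", "g", "c", "+", exons=((0, 100),))
        t2 = TranscriptModel("t2", "g", "c", "+", exons=((50, 150),))
        gene = GeneModel("g", "c", "+", (t1, t2))
        rec = gene_coverage(track_with([5] * 200), gene)
        assert rec.transcript_length == 150


class TestSelection:
    def _inputs(self, frac, fpkm_by_strain):
        gene = single_exon_gene(end=1000)
        n = int(round(frac * 1000))
        records = [
            gene_coverage(track_with([5] * n + [0] * (1000 - n), s), gene)
            for s in STRAINS
        ]
        expr = GeneExpression({"g": dict(zip(STRAINS, fpkm_by_strain))})
        return records, expr

    def test_fpkm_exactly_15_excluded(self):
        records, expr = self._inputs(0.95, (16.0, 15.0, 16.0))
        out = select_snp_genes(records, expr, STRAINS)
        assert out.snp_genes == set()
        assert out.per_strain["CTM"] == set()

    def test_coverage_exactly_090_included(self):
        records, expr = self._inputs(0.90, (16.0, 16.0, 16.0))
        out = select_snp_genes(records, expr, STRAINS)
        assert out.snp_genes == {"g"}

    def test_unknown_strain_errors(self):
        records, expr = self._inputs(0.95, (16, 16, 16))
        records[0].strain = "XYZ"
        with pytest.raises(ValueError, match="unknown strain"):
            select_snp_genes(records, expr, STRAINS)

    def test_raising_thresholds_shrinks_sets(self, sim, report):
        cov = [
            gene_coverage(sim.tracks[s], g, 3)
            for g in sim.genes
            for s in STRAINS
        ]
        strict = select_snp_genes(
            cov, sim.expression, STRAINS,
            SelectionCriteria(min_coverage_fraction=0.95, min_fpkm=30),
        )
        for s in STRAINS:
            assert strict.per_strain[s] <= report.snp_gene_set.per_strain[s]
        assert strict.snp_genes <= report.snp_gene_set.snp_genes

    def test_planted_truth_and_venn_identities(self, sim, report):
        out = report.snp_gene_set
        assert out.snp_genes == sim.truth.snp_genes
        per = out.per_strain
        # Venn counts equal brute-force set algebra
        for combo, n in out.venn.items():
            assert n == len(set.intersection(*(per[s] for s in combo)))
        triple = out.venn[STRAINS]
        pair_min = min(out.venn[c] for c in out.venn if len(c) == 2)
        single_min = min(out.venn[(s,)] for s in STRAINS)
        assert triple <= pair_min <= single_min
        # inclusion-exclusion for the three-set union
        union = len(per["LVP"] | per["CTM"] | per["RexD"])
        ie = (
            sum(out.venn[(s,)] for s in STRAINS)
            - sum(n for c, n in out.venn.items() if len(c) == 2)
            + triple
        )
        assert union == ie


class TestSiteAssignment:
    def test_overlap_site_assigned_to_both_genes(self):
        a = single_exon_gene("a", 0, 120)
        tx = TranscriptModel("b_t", "b", "c", "-", exons=((100, 220),))
        b = GeneModel("b", "c", "-", (tx,))
        out = assign_sites_to_genes([("c", 110)], [a, b], {"a", "b"})
        assert out["a"] == [("c", 110)] and out["b"] == [("c", 110)]

    def test_intron_site_assigned_nowhere(self):
        tx = TranscriptModel("t", "g", "c", "+", exons=((0, 50), (100, 150)))
        gene = GeneModel("g", "c", "+", (tx,))
        out = assign_sites_to_genes([("c", 75)], [gene], {"g"})
        assert out["g"] == []

    def test_matches_interval_containment_oracle(self, sim, report):
        snp = sim.truth.snp_genes
        genes = [g for g in sim.genes if g.gene_id in snp]
        assignment = report.assignment
        brute = {g.gene_id: [] for g in genes}
        for loc in sorted(report.unique_sites):
            for g in genes:
                if g.contig_id == loc[0] and any(
                    s <= loc[1] < e for s, e in g.exon_union
                ):
                    brute[g.gene_id].append(loc)
        assert assignment == brute
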
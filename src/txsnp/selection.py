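"""SNP-gene selection: per-gene coverage fractions and the three criteria.

A gene passes in one strain when read coverage reaches at least 90% of
its transcript length (bases with depth >= 3) and its FPKM exceeds 15
(strictly).  "SNP-genes" are the genes passing in every strain; they are
the universe for effect classification and density statistics.  For a
multi-transcript gene, transcript length is the length of the genomic
exon union over all its transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .models import CoverageTrack, GeneExpression, GeneModel


@dataclass(frozen=True)
class SelectionCriteria:
    min_coverage_fraction: float = 0.90
    min_base_depth: int = 3
    min_fpkm: float = 15.0


@dataclass
class GeneCoverageRecord:
    gene_id: str
    strain: str
    covered_bases: int
    transcript_length: int

    @property
    def coverage_fraction(self) -> float:
        return self.covered_bases / self.transcript_length


def gene_coverage(track: CoverageTrack, gene: GeneModel,
                  min_base_depth: int = 3) -> GeneCoverageRecord:
    """Fraction of the gene's exon-union bases with depth >= min_base_depth.

    Each genomic base counts once even when shared by several
    transcripts; depth is strand-agnostic.
    """
    arr = track.depths.get(gene.contig_id)
    if arr is None:
        raise ValueError(f"contig {gene.contig_id} absent from coverage track")
    union = gene.exon_union
    length = sum(e - s for s, e in union)
    if length == 0:
        raise ValueError(f"gene {gene.gene_id}: empty exon union")
    covered = int(sum(int((arr[s:e] >= min_base_depth).sum()) for s, e in union))
    return GeneCoverageRecord(
        gene_id=gene.gene_id,
        strain=track.strain,
        covered_bases=covered,
        transcript_length=length,
    )


@dataclass
class SNPGeneSet:
    """Per-strain passing sets, their intersection, and Venn counts."""

    criteria: SelectionCriteria
    per_strain: Dict[str, Set[str]]
    snp_genes: Set[str]
    venn: Dict[Tuple[str, ...], int]


def select_snp_genes(
    coverage: Iterable[GeneCoverageRecord],
    expression: GeneExpression,
    strains: Sequence[str],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> SNPGeneSet:
    """Apply the coverage and expression criteria per strain and intersect.

    Coverage boundary is closed (fraction exactly 0.90 passes); the FPKM
    boundary is open (exactly 15 fails).  Genes without a coverage record
    or FPKM entry for a strain read as fraction 0 / FPKM 0 there.
    """
    frac: Dict[Tuple[str, str], float] = {}
    gene_ids: Set[str] = set()
    for rec in coverage:
        if rec.strain not in strains:
            raise ValueError(f"unknown strain {rec.strain!r} in coverage records")
        frac[(rec.gene_id, rec.strain)] = rec.coverage_fraction
        gene_ids.add(rec.gene_id)
    gene_ids |= set(expression.genes())

    per_strain: Dict[str, Set[str]] = {s: set() for s in strains}
    for g in gene_ids:
        for s in strains:
            if (
                frac.get((g, s), 0.0) >= criteria.min_coverage_fraction
                and expression.get(g, s) > criteria.min_fpkm
            ):
                per_strain[s].add(g)

    snp_genes = set.intersection(*(per_strain[s] for s in strains)) if strains else set()
    venn: Dict[Tuple[str, ...], int] = {}
    for r in range(1, len(strains) + 1):
        for combo in combinations(strains, r):
            venn[combo] = len(set.intersection(*(per_strain[s] for s in combo)))
    return SNPGeneSet(
        criteria=criteria, per_strain=per_strain, snp_genes=snp_genes, venn=venn
    )


def assign_sites_to_genes(
    locations: Iterable[Tuple[str, int]],
    genes: Sequence[GeneModel],
    snp_genes: Set[str] | None = None,
) -> Dict[str, List[Tuple[str, int]]]:
    """Assign polymorphic-site locations to every gene whose exon union
    contains them.

    A site inside the overlap of two genes lands in both lists; a site
    in an intron (or outside every selected gene) is assigned to no gene
    but stays in the unique-site universe.
    """
    pool = [
        g for g in genes if snp_genes is None or g.gene_id in snp_genes
    ]
    by_contig: Dict[str, List[GeneModel]] = {}
    for g in pool:
        by_contig.setdefault(g.contig_id, []).append(g)
    out: Dict[str, List[Tuple[str, int]]] = {g.gene_id: [] for g in pool}
    for contig, pos in sorted(set(locations)):
        for g in by_contig.get(contig, ()):
            if any(s <= pos < e for s, e in g.exon_union):
                out[g.gene_id].append((contig, pos))
    return out
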
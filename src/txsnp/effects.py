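"""Classification of SNPs into eleven effect categories.

Every retained (site, alternate allele) is classified against every
transcript of every SNP-gene whose exon-or-splice space contains it,
in transcript-strand sequence space (minus-strand alleles are reverse
complemented before codon arithmetic).  The categories:

  coding        NON_SYNONYMOUS, SYNONYMOUS, SYNONYMOUS_STOP, START_LOST,
                STOP_GAINED, STOP_LOST
  splice        SPLICE_ACCEPTOR, SPLICE_DONOR (the first/last two
                intronic bases of each intron in transcript orientation)
  untranslated  UTR_5, UTR_3, START_GAINED (a 5'UTR change completing a
                new ATG entirely within the UTR)

Each (site, alt, transcript) gets exactly one class; splice windows are
intronic so they never collide with exonic classes.  Gene-level counting
is per (gene, site, alt): transcripts of one gene agreeing on a class
count once, disagreeing isoforms contribute one record per distinct
class (tracked by an ambiguity counter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .filtering import FilteredCallset
from .models import (
    STOP_CODONS,
    GeneModel,
    Genome,
    TranscriptModel,
    point_in_intervals,
    revcomp,
)

log = logging.getLogger(__name__)


class EffectClass(str, Enum):
    NON_SYNONYMOUS = "NON_SYNONYMOUS"
    SYNONYMOUS = "SYNONYMOUS"
    SYNONYMOUS_STOP = "SYNONYMOUS_STOP"
    SPLICE_ACCEPTOR = "SPLICE_ACCEPTOR"
    SPLICE_DONOR = "SPLICE_DONOR"
    START_GAINED = "START_GAINED"
    START_LOST = "START_LOST"
    STOP_GAINED = "STOP_GAINED"
    STOP_LOST = "STOP_LOST"
    UTR_3 = "UTR_3"
    UTR_5 = "UTR_5"


CODING_CLASSES = frozenset(
    {
        EffectClass.NON_SYNONYMOUS,
        EffectClass.SYNONYMOUS,
        EffectClass.SYNONYMOUS_STOP,
        EffectClass.START_LOST,
        EffectClass.STOP_GAINED,
        EffectClass.STOP_LOST,
    }
)

# standard nuclear code
CODON_TABLE: Dict[str, str] = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]


@dataclass
class EffectRecord:
    contig_id: str
    pos0: int
    ref_allele: str
    alt_allele: str
    gene_id: str
    transcript_id: str
    effect_class: EffectClass
    codon_change: Optional[Tuple[str, str]] = None
    aa_change: Optional[Tuple[str, str]] = None


def classify_variant(
    pos0: int,
    ref: str,
    alt: str,
    transcript: TranscriptModel,
    genome: Genome,
    splice_window: int = 2,
) -> EffectRecord:
    """Classify one (position, alt allele) against one transcript.

    Raises ValueError when the position lies outside the transcript's
    exon union and splice windows, or when the transcript cannot be
    classified (non-coding or broken reading frame).
    """
    # splice windows first: intronic, so no overlap with exonic space
    for (s, e), kind in transcript.splice_windows(splice_window):
        if s <= pos0 < e:
            cls = (
                EffectClass.SPLICE_DONOR if kind == "donor"
                else EffectClass.SPLICE_ACCEPTOR
            )
            return EffectRecord(
                transcript.contig_id, pos0, ref, alt,
                transcript.gene_id, transcript.transcript_id, cls,
            )
    if not point_in_intervals(pos0, transcript.exons):
        raise ValueError(
            f"position {pos0} outside transcript {transcript.transcript_id}"
        )
    if not transcript.coding or not transcript.frame_ok:
        raise ValueError(
            f"transcript {transcript.transcript_id} is non-coding or "
            "frame-broken; not classifiable"
        )

    alt_tx = alt if transcript.strand == "+" else revcomp(alt)

    if point_in_intervals(pos0, transcript.cds_intervals):
        return _classify_cds(pos0, ref, alt, alt_tx, transcript, genome)
    if point_in_intervals(pos0, transcript.utr5_intervals):
        cls = (
            EffectClass.START_GAINED
            if _creates_utr_atg(pos0, alt_tx, transcript, genome)
            else EffectClass.UTR_5
        )
        return EffectRecord(
            transcript.contig_id, pos0, ref, alt,
            transcript.gene_id, transcript.transcript_id, cls,
        )
    # remaining exonic space is the 3'UTR
    return EffectRecord(
        transcript.contig_id, pos0, ref, alt,
        transcript.gene_id, transcript.transcript_id, EffectClass.UTR_3,
    )


def _classify_cds(pos0, ref, alt, alt_tx, transcript, genome) -> EffectRecord:
    cds_pos = transcript.region_positions(transcript.cds_intervals)
    cds_seq = transcript.region_sequence(transcript.cds_intervals, genome)
    idx = cds_pos.index(pos0)
    codon_i, off = divmod(idx, 3)
    ref_codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    alt_codon = ref_codon[:off] + alt_tx + ref_codon[off + 1 :]

    n_codons = len(cds_seq) // 3
    if codon_i == 0 and alt_codon != "ATG":
        cls = EffectClass.START_LOST
    elif ref_codon in STOP_CODONS and alt_codon in STOP_CODONS:
        cls = EffectClass.SYNONYMOUS_STOP
    elif ref_codon in STOP_CODONS:
        cls = EffectClass.STOP_LOST
    elif alt_codon in STOP_CODONS:
        cls = EffectClass.STOP_GAINED
    elif CODON_TABLE[ref_codon] == CODON_TABLE[alt_codon]:
        cls = EffectClass.SYNONYMOUS
    else:
        cls = EffectClass.NON_SYNONYMOUS
    return EffectRecord(
        transcript.contig_id, pos0, ref, alt,
        transcript.gene_id, transcript.transcript_id, cls,
        codon_change=(ref_codon, alt_codon),
        aa_change=(CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]),
    )


def _creates_utr_atg(pos0, alt_tx, transcript, genome) -> bool:
    """True if the alt base completes an ATG entirely within the 5'UTR."""
    utr_pos = transcript.region_positions(transcript.utr5_intervals)
    utr_seq = transcript.region_sequence(transcript.utr5_intervals, genome)
    u = utr_pos.index(pos0)
    mut = utr_seq[:u] + alt_tx + utr_seq[u + 1 :]
    for w in range(max(0, u - 2), min(u, len(mut) - 3) + 1):
        if mut[w : w + 3] == "ATG" and utr_seq[w : w + 3] != "ATG":
            return True
    return False


# ---------------------------------------------------------------------------
# corpus-level classification and summaries
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    records: List[EffectRecord]          # gene-level: one per (gene, site, alt, class)
    n_isoform_ambiguous: int             # (gene, site, alt) with >1 class across isoforms
    n_unclassifiable_transcripts: int    # non-coding/frame-broken transcript hits skipped


def classify_all(
    callset: FilteredCallset,
    genes: Sequence[GeneModel],
    genome: Genome,
    snp_genes: Optional[Set[str]] = None,
    splice_window: int = 2,
) -> ClassificationResult:
    """Classify every retained (site, alt) against the SNP-gene set.

    Returns gene-level records: per (gene, site, alt), one record per
    distinct class over the gene's transcripts (agreeing isoforms count
    once; disagreements increment the ambiguity counter).
    """
    pool = [g for g in genes if snp_genes is None or g.gene_id in snp_genes]
    by_contig: Dict[str, List[GeneModel]] = {}
    for g in pool:
        by_contig.setdefault(g.contig_id, []).append(g)

    site_alts: Set[Tuple[str, int, str]] = set()
    for strain in callset.retained:
        site_alts |= callset.retained[strain]

    records: List[EffectRecord] = []
    n_ambig = 0
    n_skip = 0
    for contig, pos0, alt in sorted(site_alts):
        for gene in by_contig.get(contig, ()):
            per_class: Dict[EffectClass, EffectRecord] = {}
            for tx in gene.transcripts:
                if not tx.contains(pos0, splice_window):
                    continue
                if not tx.coding or not tx.frame_ok:
                    # splice windows are still classifiable on any transcript
                    in_window = any(
                        s <= pos0 < e
                        for (s, e), _ in tx.splice_windows(splice_window)
                    )
                    if not in_window:
                        n_skip += 1
                        continue
                ref = genome.base(contig, pos0)
                rec = classify_variant(pos0, ref, alt, tx, genome, splice_window)
                per_class.setdefault(rec.effect_class, rec)
            if len(per_class) > 1:
                n_ambig += 1
            records.extend(per_class.values())
    return ClassificationResult(records, n_ambig, n_skip)


def strain_specific(callset: FilteredCallset) -> Set[Tuple[str, str, int, str]]:
    """(strain, contig, pos0, alt) retained in that strain and no other."""
    out: Set[Tuple[str, str, int, str]] = set()
    strains = list(callset.retained)
    for s in strains:
        others = set().union(
            *(callset.retained[o] for o in strains if o != s)
        ) if len(strains) > 1 else set()
        for key in callset.retained[s]:
            if key not in others:
                out.add((s, *key))
    return out


def summarize_effects(
    records: Iterable[EffectRecord],
    callset: FilteredCallset,
    specific: Optional[Set[Tuple[str, str, int, str]]] = None,
):
    """Per strain x class counts: SNP occurrences, strain-specific, genes.

    The counting unit is the gene-level record (gene, site, alt, class):
    a SNP in the ORFs or UTRs of overlapping genes is counted once per
    gene.  A record contributes to a strain when its (site, alt) is
    retained there; the strain-specific column counts those retained in
    that strain alone.  Returns a table with one row per class and, per
    strain, columns ``<strain>_snps``, ``<strain>_specific``,
    ``<strain>_genes``.
    """
    import pandas as pd

    if specific is None:
        specific = strain_specific(callset)
    strains = list(callset.retained)
    counts = {
        (s, cls): {"snps": 0, "specific": 0, "genes": set()}
        for s in strains
        for cls in EffectClass
    }
    for rec in records:
        key = (rec.contig_id, rec.pos0, rec.alt_allele)
        for s in strains:
            if key in callset.retained[s]:
                cell = counts[(s, rec.effect_class)]
                cell["snps"] += 1
                cell["genes"].add(rec.gene_id)
                if (s, *key) in specific:
                    cell["specific"] += 1
    rows = []
    for cls in EffectClass:
        row: Dict[str, object] = {"effect_class": cls.value}
        for s in strains:
            cell = counts[(s, cls)]
            row[f"{s}_snps"] = cell["snps"]
            row[f"{s}_specific"] = cell["specific"]
            row[f"{s}_genes"] = len(cell["genes"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("effect_class").sort_index()


def strain_specific_percentages(summary) -> Dict[str, float]:
    """Per-strain percentage of gene-level SNP occurrences that are
    strain-specific, from a summarize_effects-shaped table."""
    out: Dict[str, float] = {}
    for col in summary.columns:
        if col.endswith("_snps"):
            s = col[: -len("_snps")]
            total = summary[col].sum()
            spec = summary[f"{s}_specific"].sum()
            out[s] = 100.0 * spec / total if total else float("nan")
    return out
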
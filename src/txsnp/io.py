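"""Readers and writers for the pipeline's external formats.

This is the single place where external coordinate conventions (GTF and
VCF are 1-based, depth tables 1-based) are converted to the internal
0-based half-open convention.  Formats handled: FASTA genome, GTF v2.2
annotation, VCF v4.x variants with per-sample ``GT:DP:AO:QA`` fields,
per-base depth TSV (contig, 1-based position, depth) and per-gene FPKM
TSV (gene_id plus one column per strain).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CoverageTrack,
    GeneExpression,
    GeneModel,
    Genome,
    StrainCall,
    SupercontigSeq,
    TranscriptModel,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def read_genome(path) -> Genome:
    """Read a FASTA genome; lowercase is normalised to uppercase."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    contigs = [
        SupercontigSeq(rec.id, str(rec.seq).upper()) for rec in records
    ]
    return Genome.from_contigs(contigs)


def write_genome(genome: Genome, path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
        for c in genome.values()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# annotation (GTF)
# ---------------------------------------------------------------------------

def read_annotation(path, genome: Optional[Genome] = None) -> List[GeneModel]:
    """Read a GTF into GeneModels; UTRs are derived as exon minus CDS.

    Transcripts whose CDS length is not divisible by 3 are kept but
    flagged frame-broken (a warning is emitted); CDS outside exons is an
    error.
    """
    exons: Dict[str, List[Tuple[int, int]]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}  # tid -> (gene, contig, strand)
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    by_gene: Dict[str, List[TranscriptModel]] = {}
    for tid, (gid, contig, strand) in meta.items():
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            contig_id=contig,
            strand=strand,
            exons=tuple(exons.get(tid, ())),
            cds_intervals=tuple(cds.get(tid, ())),
        )
        if tx.coding and not tx.frame_ok:
            warnings.warn(
                f"transcript {tid}: CDS length not divisible by 3; "
                "excluded from ORF-effect classification"
            )
        by_gene.setdefault(gid, []).append(tx)

    genes = []
    for gid, txs in by_gene.items():
        txs.sort(key=lambda t: t.transcript_id)
        genes.append(
            GeneModel(gid, txs[0].contig_id, txs[0].strand, tuple(txs))
        )
    genes.sort(key=lambda g: (g.contig_id, g.span, g.gene_id))
    if genome is not None:
        for g in genes:
            if g.contig_id not in genome:
                raise ValueError(
                    f"gene {g.gene_id}: contig {g.contig_id} absent from genome"
                )
    return genes


def write_annotation(genes: Sequence[GeneModel], path) -> None:
    """Write GeneModels as GTF (gene/transcript/exon/CDS features)."""
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.span
            fh.write(_gtf_line(g.contig_id, "gene", s, e, g.strand,
                               f'gene_id "{g.gene_id}";'))
            for t in g.transcripts:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                ts, te = t.span
                fh.write(_gtf_line(g.contig_id, "transcript", ts, te, g.strand, attrs))
                for iv in t.exons:
                    fh.write(_gtf_line(g.contig_id, "exon", *iv, strand=g.strand,
                                       attrs=attrs))
                for iv in t.cds_intervals:
                    fh.write(_gtf_line(g.contig_id, "CDS", *iv, strand=g.strand,
                                       attrs=attrs))


def _gtf_line(contig, feature, start0, end, strand=None, attrs="") -> str:
    return (
        f"{contig}\ttxsnp\t{feature}\t{start0 + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
    )


# ---------------------------------------------------------------------------
# variants (VCF)
# ---------------------------------------------------------------------------

@dataclass
class VariantReadResult:
    """Sites plus skip accounting for non-SNV records."""

    sites: List = field(default_factory=list)
    n_skipped_non_snv: int = 0

    def __iter__(self):
        return iter(self.sites)

    def __len__(self):
        return len(self.sites)


def _is_snv(ref: str, alts: Sequence[str]) -> bool:
    if len(ref) != 1:
        return False
    return all(len(a) == 1 and a in "ACGT" for a in alts)


def read_variants(path, strains: Optional[Sequence[str]] = None) -> VariantReadResult:
    """Read a multi-sample VCF into VariantSites.

    Indels/MNPs and symbolic alleles are skipped and counted.  If
    ``strains`` is given, the VCF sample names must match it exactly
    (order-insensitive).
    """
    from .models import VariantSite

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if strains is not None and set(samples) != set(strains):
        raise ValueError(
            f"{path}: VCF samples {samples} do not match strains {list(strains)}"
        )
    result = VariantReadResult()
    for rec in vf:
        alts = rec.alts or ()
        if not _is_snv(rec.ref, alts):
            result.n_skipped_non_snv += 1
            continue
        if rec.qual is None:
            raise ValueError(f"{path}: record at {rec.chrom}:{rec.pos} lacks QUAL")
        # htslib stores QUAL as a 32-bit float; undo the precision loss
        qual = round(float(rec.qual), 4)
        n_alt = len(alts)
        per_strain: Dict[str, StrainCall] = {}
        for s in samples:
            sd = rec.samples[s]
            gt = sd.get("GT")
            called = gt is not None and any(a is not None for a in gt)
            if not called:
                per_strain[s] = StrainCall(called=False)
                continue
            dp = sd.get("DP")
            ao = sd.get("AO")
            qa = sd.get("QA")
            if dp is None or ao is None or qa is None:
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} sample {s} "
                    "missing DP/AO/QA"
                )
            ao_t = tuple(int(x) for x in (ao if isinstance(ao, tuple) else (ao,)))
            qa_t = tuple(float(x) for x in (qa if isinstance(qa, tuple) else (qa,)))
            if len(ao_t) != n_alt or len(qa_t) != n_alt:
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} sample {s}: "
                    "AO/QA arity does not match ALT count"
                )
            per_strain[s] = StrainCall(called=True, dp=int(dp), ao=ao_t, qa=qa_t)
        result.sites.append(
            VariantSite(
                contig_id=rec.chrom,
                pos0=rec.pos - 1,
                ref_allele=rec.ref,
                alt_alleles=tuple(alts),
                qual=qual,
                per_strain=per_strain,
            )
        )
    if result.n_skipped_non_snv:
        log.info("%s: skipped %d non-SNV records", path, result.n_skipped_non_snv)
    return result


def write_variants(sites, strains: Sequence[str], genome: Genome, path) -> None:
    """Write VariantSites as a multi-sample VCF (FORMAT GT:DP:AO:QA)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in genome.values():
            fh.write(f"##contig=<ID={c.contig_id},length={len(c)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AO,Number=A,Type=Integer,'
                 'Description="Alternate allele observation count">\n')
        fh.write('##FORMAT=<ID=QA,Number=A,Type=Integer,'
                 'Description="Sum of quality of alternate observations">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(strains) + "\n")
        for site in sorted(sites, key=lambda s: (s.contig_id, s.pos0)):
            cols = [
                site.contig_id,
                str(site.pos0 + 1),
                ".",
                site.ref_allele,
                ",".join(site.alt_alleles),
                f"{site.qual:g}",
                ".",
                ".",
                "GT:DP:AO:QA",
            ]
            for s in strains:
                call = site.per_strain.get(s, StrainCall(called=False))
                if not call.called:
                    cols.append("./.")
                else:
                    ao = ",".join(str(a) for a in call.ao)
                    qa = ",".join(str(int(q)) for q in call.qa)
                    cols.append(f"0/1:{call.dp}:{ao}:{qa}")
            fh.write("\t".join(cols) + "\n")


def cross_check_ref(sites, genome: Genome):
    """Validate ref alleles against the genome.

    Returns ``(valid_sites, n_mismatch, n_ref_n)``.  Sites whose
    reference base is N are excluded with a warning; mismatching sites
    are excluded and counted (must be 0 on simulator output).
    """
    valid, n_mismatch, n_ref_n = [], 0, 0
    for site in sites:
        base = genome.base(site.contig_id, site.pos0)
        if base == "N":
            n_ref_n += 1
            warnings.warn(
                f"site {site.contig_id}:{site.pos0 + 1}: reference base N; excluded"
            )
        elif base != site.ref_allele:
            n_mismatch += 1
        else:
            valid.append(site)
    return valid, n_mismatch, n_ref_n


# ---------------------------------------------------------------------------
# coverage and expression
# ---------------------------------------------------------------------------

def read_coverage(path, strain: str, genome: Genome) -> CoverageTrack:
    """Read a per-base depth TSV (contig, 1-based position, depth).

    Contigs absent from the table get all-zero depth with a warning.
    """
    df = pd.read_csv(
        str(path), sep="\t", names=["contig", "pos", "depth"], dtype={"contig": str}
    )
    depths: Dict[str, np.ndarray] = {}
    for contig_id, c in genome.items():
        depths[contig_id] = np.zeros(len(c), dtype=np.int64)
    for contig_id, sub in df.groupby("contig", sort=False):
        if contig_id not in depths:
            raise ValueError(f"{path}: unknown contig {contig_id}")
        depths[contig_id][sub["pos"].to_numpy() - 1] = sub["depth"].to_numpy()
    missing = set(genome) - set(df["contig"].unique())
    for contig_id in sorted(missing):
        warnings.warn(f"{path}: contig {contig_id} absent; depth set to 0")
    return CoverageTrack(strain=strain, depths=depths)


def write_coverage(track: CoverageTrack, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "contig": contig_id,
                "pos": np.arange(1, len(arr) + 1),
                "depth": arr,
            }
        )
        for contig_id, arr in track.depths.items()
    ]
    pd.concat(frames).to_csv(path, sep="\t", header=False, index=False)


def read_expression(path, strains: Optional[Sequence[str]] = None) -> GeneExpression:
    """Read an FPKM TSV: gene_id column plus one column per strain."""
    df = pd.read_csv(str(path), sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    cols = [c for c in df.columns if c != "gene_id"]
    if strains is not None:
        missing = set(strains) - set(cols)
        if missing:
            raise ValueError(f"{path}: missing strain columns {sorted(missing)}")
        cols = list(strains)
    return GeneExpression(
        {
            row["gene_id"]: {s: float(row[s]) for s in cols}
            for _, row in df.iterrows()
        }
    )


def write_expression(expr: GeneExpression, strains: Sequence[str], path) -> None:
    rows = [
        {"gene_id": g, **{s: expr.get(g, s) for s in strains}}
        for g in expr.genes()
    ]
    pd.DataFrame(rows, columns=["gene_id", *strains]).to_csv(
        path, sep="\t", index=False
    )
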
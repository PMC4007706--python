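"""Core domain types for transcriptome polymorphism analysis.

All genomic coordinates held by these types are 0-based half-open
``(start, end)`` intervals on the forward strand of a supercontig.
1-based conventions (GTF, VCF, per-base depth tables) are converted at
the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# interval arithmetic (0-based half-open throughout)
# ---------------------------------------------------------------------------

def interval_len(iv: Interval) -> int:
    return iv[1] - iv[0]


def total_length(ivs: Iterable[Interval]) -> int:
    return sum(e - s for s, e in ivs)


def merge_intervals(ivs: Iterable[Interval]) -> List[Interval]:
    """Union of intervals as a sorted, non-overlapping list."""
    ivs = sorted(ivs)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Set difference a \\ b for sorted non-overlapping interval lists."""
    out: List[Interval] = []
    b = sorted(b)
    for s, e in sorted(a):
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
        if cur < e:
            out.append((cur, e))
    return out


def point_in_intervals(pos: int, ivs: Sequence[Interval]) -> bool:
    return any(s <= pos < e for s, e in ivs)


def interval_gap(a: Interval, b: Interval) -> int:
    """Gap in bases between two intervals; 0 when overlapping or abutting."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(a[0] - b[1], b[0] - a[1], 0)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class SupercontigSeq:
    """One assembly scaffold: an id and its nucleotide sequence."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.contig_id}: invalid bases {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class Genome(dict):
    """Mapping contig_id -> SupercontigSeq with convenience accessors."""

    @classmethod
    def from_contigs(cls, contigs: Iterable[SupercontigSeq]) -> "Genome":
        g = cls()
        for c in contigs:
            if c.contig_id in g:
                raise ValueError(f"duplicate contig id {c.contig_id!r}")
            g[c.contig_id] = c
        return g

    def base(self, contig_id: str, pos0: int) -> str:
        return self[contig_id].sequence[pos0]

    def fetch(self, contig_id: str, start: int, end: int) -> str:
        return self[contig_id].sequence[start:end]


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """A stranded multi-exon transcript with derived UTR partition.

    ``exons`` and ``cds_intervals`` are sorted 0-based half-open genomic
    intervals.  The 5'/3' UTR intervals are derived as exon-minus-CDS,
    split strand-aware around the CDS.  A transcript without CDS is
    non-coding and excluded from ORF-effect classification; a CDS whose
    total length is not divisible by 3 is kept but flagged frame-broken.
    """

    transcript_id: str
    gene_id: str
    contig_id: str
    strand: str
    exons: Tuple[Interval, ...]
    cds_intervals: Tuple[Interval, ...] = ()
    utr5_intervals: Tuple[Interval, ...] = field(init=False)
    utr3_intervals: Tuple[Interval, ...] = field(init=False)
    frame_ok: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        self.exons = tuple(sorted(self.exons))
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.cds_intervals = tuple(sorted(self.cds_intervals))
        cds_in_exons = subtract_intervals(self.cds_intervals, self.exons)
        if cds_in_exons:
            raise ValueError(
                f"{self.transcript_id}: CDS outside exons at {cds_in_exons}"
            )
        self.frame_ok = total_length(self.cds_intervals) % 3 == 0
        utr = subtract_intervals(self.exons, self.cds_intervals)
        if self.cds_intervals:
            cds_start = self.cds_intervals[0][0]
            cds_end = self.cds_intervals[-1][1]
            left = tuple(iv for iv in utr if iv[1] <= cds_start)
            right = tuple(iv for iv in utr if iv[0] >= cds_end)
            if self.strand == "+":
                self.utr5_intervals, self.utr3_intervals = left, right
            else:
                self.utr5_intervals, self.utr3_intervals = right, left
        else:
            self.utr5_intervals = ()
            self.utr3_intervals = ()

    # -- derived geometry -------------------------------------------------

    @property
    def coding(self) -> bool:
        return bool(self.cds_intervals)

    @property
    def transcript_length(self) -> int:
        return total_length(self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def exonic_positions(self) -> np.ndarray:
        """Genomic positions of all exon bases, ascending."""
        return np.concatenate(
            [np.arange(s, e) for s, e in self.exons]
        ) if self.exons else np.empty(0, dtype=int)

    def _oriented(self, ivs: Sequence[Interval]) -> List[Interval]:
        """Intervals in transcript (5'->3') order."""
        ivs = sorted(ivs)
        return ivs if self.strand == "+" else ivs[::-1]

    def region_positions(self, ivs: Sequence[Interval]) -> List[int]:
        """Genomic positions of a region in transcript orientation."""
        pos: List[int] = []
        for s, e in self._oriented(ivs):
            rng = range(s, e) if self.strand == "+" else range(e - 1, s - 1, -1)
            pos.extend(rng)
        return pos

    def region_sequence(self, ivs: Sequence[Interval], genome: Genome) -> str:
        """Sequence of a region in transcript orientation (strand-corrected)."""
        parts = []
        for s, e in self._oriented(ivs):
            chunk = genome.fetch(self.contig_id, s, e)
            parts.append(chunk if self.strand == "+" else revcomp(chunk))
        return "".join(parts)

    def splice_windows(self, size: int = 2) -> List[Tuple[Interval, str]]:
        """Intronic donor/acceptor windows, as (interval, kind) pairs.

        The donor window is the first ``size`` intronic bases after an exon
        in transcript orientation; the acceptor window the last ``size``
        before the next exon.
        """
        out: List[Tuple[Interval, str]] = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            ilen = s2 - e1
            w = min(size, ilen)
            left = (e1, e1 + w)          # intron side touching lower exon
            right = (s2 - w, s2)         # intron side touching upper exon
            if self.strand == "+":
                out.append((left, "donor"))
                out.append((right, "acceptor"))
            else:
                out.append((right, "donor"))
                out.append((left, "acceptor"))
        return out

    def contains(self, pos0: int, splice_size: int = 2) -> bool:
        """True if pos lies in the exon union or a splice window."""
        if point_in_intervals(pos0, self.exons):
            return True
        return any(s <= pos0 < e for (s, e), _ in self.splice_windows(splice_size))


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing contig and strand."""

    gene_id: str
    contig_id: str
    strand: str
    transcripts: Tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        self.transcripts = tuple(self.transcripts)
        for t in self.transcripts:
            if (t.gene_id, t.contig_id, t.strand) != (
                self.gene_id,
                self.contig_id,
                self.strand,
            ):
                raise ValueError(
                    f"transcript {t.transcript_id} inconsistent with gene "
                    f"{self.gene_id}"
                )

    @property
    def exon_union(self) -> List[Interval]:
        return merge_intervals(
            iv for t in self.transcripts for iv in t.exons
        )

    @property
    def exon_union_length(self) -> int:
        return total_length(self.exon_union)

    @property
    def span(self) -> Interval:
        u = self.exon_union
        return (u[0][0], u[-1][1])

    def contains(self, pos0: int, splice_size: int = 2) -> bool:
        return any(t.contains(pos0, splice_size) for t in self.transcripts)


# ---------------------------------------------------------------------------
# variants / coverage / expression
# ---------------------------------------------------------------------------

@dataclass
class StrainCall:
    """Per-strain genotype evidence at one site (pooled-sample semantics).

    ``ao`` and ``qa`` are per-alternate-allele tuples aligned with the
    site's ``alt_alleles``; ``dp`` is total read depth.
    """

    called: bool
    dp: int = 0
    ao: Tuple[int, ...] = ()
    qa: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.called:
            if any(a < 0 for a in self.ao) or self.dp < 0:
                raise ValueError("negative DP/AO")
            if sum(self.ao) > self.dp:
                raise ValueError(f"sum(AO)={sum(self.ao)} exceeds DP={self.dp}")


@dataclass
class VariantSite:
    """One genomic location with reference and alternate allele(s).

    ``pos0`` is 0-based; the VCF reader/writer converts.  ``qual`` is the
    site-level phred quality shared by all strains.
    """

    contig_id: str
    pos0: int
    ref_allele: str
    alt_alleles: Tuple[str, ...]
    qual: float
    per_strain: Dict[str, StrainCall]

    def __post_init__(self) -> None:
        self.alt_alleles = tuple(self.alt_alleles)
        if not self.alt_alleles:
            raise ValueError("alt_alleles empty")
        if len(set(self.alt_alleles)) != len(self.alt_alleles):
            raise ValueError("duplicate alt alleles")
        if self.ref_allele in self.alt_alleles:
            raise ValueError("alt equals ref")

    def check_ref(self, genome: Genome) -> bool:
        return genome.base(self.contig_id, self.pos0) == self.ref_allele


@dataclass
class CoverageTrack:
    """Per-base read depth for one strain: contig -> int array."""

    strain: str
    depths: Dict[str, np.ndarray]

    def depth_at(self, contig_id: str, pos0: int) -> int:
        arr = self.depths.get(contig_id)
        return int(arr[pos0]) if arr is not None else 0


class GeneExpression:
    """FPKM per gene per strain; missing genes read as 0."""

    def __init__(self, fpkm: Mapping[str, Mapping[str, float]]):
        self._fpkm: Dict[str, Dict[str, float]] = {
            g: dict(sv) for g, sv in fpkm.items()
        }
        for g, sv in self._fpkm.items():
            for s, v in sv.items():
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"FPKM for {g}/{s} invalid: {v}")

    def get(self, gene_id: str, strain: str) -> float:
        return self._fpkm.get(gene_id, {}).get(strain, 0.0)

    def genes(self) -> List[str]:
        return list(self._fpkm)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._fpkm

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneExpression) and self._fpkm == other._fpkm
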
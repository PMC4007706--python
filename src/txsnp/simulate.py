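"""Ground-truthed synthetic data for the whole pipeline.

The generator emits a complete input bundle — multi-contig genome,
stranded multi-exon annotation with UTRs, a three-strain pooled VCF,
per-base depth tracks, per-gene FPKM, and candidate NTU intervals —
together with the planted truth for every downstream question: the
effect class of each variant per gene, per-strain retention under the
default quality filters, per-gene coverage fractions and SNP-gene
labels, and NTU distances/window classes/FPKM bins.

Variants are planted class-first: an effect class is drawn, then a
position and allele realizing it are chosen, so truth labels never
depend on running a classifier.  Gene pairs overlapping at their 3'UTRs
are planted to exercise per-gene double counting; quality fields are
drawn conditional on an intended pass/fail outcome per strain, so the
retained set is known exactly; NTUs are placed at controlled distances
straddling the 1 kb and 10 kb windows, including some on supercontigs
with no annotation at all.

Default scale is roughly a hundredfold reduction of the study: ~50
genes over a few hundred kb, ~500 variant sites, ~30 NTUs; a run takes
seconds.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .effects import CODON_TABLE
from .models import (
    STOP_CODONS,
    CoverageTrack,
    GeneExpression,
    GeneModel,
    Genome,
    Interval,
    StrainCall,
    SupercontigSeq,
    TranscriptModel,
    VariantSite,
    point_in_intervals,
    revcomp,
)
from .ntu import FpkmBin, WindowClass, fpkm_bin, window_class

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_NONSTOP_CODONS = [c for c in CODON_TABLE if c not in STOP_CODONS]


@dataclass(frozen=True)
class SimulationConfig:
    """All dials of the generator; defaults emulate the study regime."""

    seed: int = 0
    strains: Tuple[str, ...] = ("LVP", "CTM", "RexD")
    # genome layout
    n_gene_contigs: int = 12
    n_empty_contigs: int = 2
    empty_contig_length: int = 15_000
    genes_per_contig: Tuple[int, int] = (4, 7)
    exons_per_transcript: Tuple[int, int] = (1, 4)
    utr5_range: Tuple[int, int] = (40, 150)
    utr3_range: Tuple[int, int] = (90, 250)
    n_codons_range: Tuple[int, int] = (80, 300)
    intron_range: Tuple[int, int] = (80, 1_500)
    gap_range: Tuple[int, int] = (2_600, 4_000)
    big_gap_range: Tuple[int, int] = (24_000, 30_000)
    overlap_fraction: float = 0.15
    second_isoform_fraction: float = 0.15
    # variants: the unique-site density over the exon union and the
    # strain-membership mixture.  The defaults are solved so the expected
    # per-strain densities land near 5.05/9.13/9.43 PS/kb with the
    # reference strain (LVP) carrying fewest sites, and the per-strain
    # strain-specific fractions near 15/28/28% — the regime the analysis
    # is meant for.
    union_density_per_kb: float = 13.0
    fraction_single: float = 0.458
    single_weights: Tuple[float, float, float] = (0.129, 0.428, 0.443)
    fraction_pair: float = 0.274
    pair_weights: Tuple[float, float, float] = (0.080, 0.139, 0.781)  # LC, LR, CR
    class_proportions: Tuple[Tuple[str, float], ...] = (
        ("SYNONYMOUS", 0.40),
        ("NON_SYNONYMOUS", 0.20),
        ("UTR_3", 0.20),
        ("UTR_5", 0.10),
        ("SPLICE_ACCEPTOR", 0.02),
        ("SPLICE_DONOR", 0.02),
        ("START_GAINED", 0.02),
        ("START_LOST", 0.005),
        ("STOP_GAINED", 0.015),
        ("STOP_LOST", 0.01),
        ("SYNONYMOUS_STOP", 0.01),
    )
    fraction_multiallelic_of_utr3: float = 0.4
    qual_fail_fraction: float = 0.05
    extra_fail_call_rate: float = 0.15
    boundary_value_rate: float = 0.05
    depth_mean: float = 20.0
    # gene selection regime
    p_snp_gene: float = 0.6
    # NTUs
    n_ntus: int = 30
    ntu_window_proportions: Tuple[float, float, float] = (0.275, 0.485, 0.24)
    ntu_len_range: Tuple[int, int] = (200, 800)
    ntu_same_bin_fraction: float = 0.8
    ntu_bin_weights: Tuple[float, float, float, float] = (0.65, 0.20, 0.10, 0.05)

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_single,
            self.fraction_pair,
            self.overlap_fraction,
            self.qual_fail_fraction,
            self.p_snp_gene,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.union_density_per_kb <= 0:
            raise ValueError("density must be positive")
        if self.fraction_single + self.fraction_pair > 1:
            raise ValueError("single+pair membership fractions exceed 1")


@dataclass
class GroundTruth:
    """Planted answers, internally consistent with the emitted files."""

    variant_records: pd.DataFrame   # per (site, alt, gene): effect class
    site_truth: pd.DataFrame        # per (site, alt): membership and retention
    gene_truth: pd.DataFrame        # per gene x strain: coverage, fpkm, labels
    ntu_truth: pd.DataFrame         # per NTU: distance, window, bins
    retained: Dict[str, Set[Tuple[str, int, str]]]
    snp_genes: Set[str]


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: Genome
    genes: List[GeneModel]
    sites: List[VariantSite]
    tracks: Dict[str, CoverageTrack]
    expression: GeneExpression
    ntus: List[Tuple[str, str, Interval]]
    ntu_fpkm: Dict[str, Dict[str, float]]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _tx_to_genomic(exons: Sequence[Interval], strand: str,
                   t_start: int, t_end: int) -> List[Interval]:
    """Map a transcript-coordinate range onto genomic intervals."""
    orient = list(exons) if strand == "+" else list(exons)[::-1]
    out: List[Interval] = []
    acc = 0
    for s, e in orient:
        length = e - s
        o1, o2 = max(t_start - acc, 0), min(t_end - acc, length)
        if o1 < o2:
            out.append((s + o1, s + o2) if strand == "+" else (e - o2, e - o1))
        acc += length
    return sorted(out)


@dataclass
class _GeneSpec:
    gene_id: str
    contig: str
    strand: str
    exons: List[Interval]
    cds: List[Interval]
    utr5_len: int
    cds_len: int
    utr3_len: int
    mrna: str
    isoforms: int = 1


def _split_exons(rng, total: int, n_ex: int, tail_min: int) -> List[int]:
    """Transcript exon lengths; the 3'-terminal exon keeps >= tail_min."""
    if n_ex == 1:
        return [total]
    for _ in range(30):
        cuts = np.sort(rng.integers(40, total - tail_min, n_ex - 1))
        lens = np.diff(np.concatenate(([0], cuts, [total])))
        if (lens[:-1] >= 40).all() and lens[-1] >= tail_min:
            return [int(x) for x in lens]
    return [total]


def _make_gene(rng, cfg: SimulationConfig, gene_id: str, contig: str,
               strand: str, start: int) -> _GeneSpec:
    u5 = int(rng.integers(*cfg.utr5_range))
    u3 = int(rng.integers(*cfg.utr3_range))
    ncod = int(rng.integers(*cfg.n_codons_range))
    cds_len = 3 * ncod
    total = u5 + cds_len + u3
    lo, hi = cfg.exons_per_transcript
    n_ex = int(rng.integers(lo, hi + 1))
    tx_lens = _split_exons(rng, total, n_ex, tail_min=u3 + 10)
    introns = [int(rng.integers(*cfg.intron_range)) for _ in tx_lens[:-1]]
    # genomic order: transcript order for +, reversed for -
    g_lens = tx_lens if strand == "+" else tx_lens[::-1]
    g_introns = introns if strand == "+" else introns[::-1]
    exons: List[Interval] = []
    cur = start
    for i, L in enumerate(g_lens):
        exons.append((cur, cur + L))
        cur += L
        if i < len(g_introns):
            cur += g_introns[i]
    middle = "".join(
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), ncod - 2)
    )
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    mrna = _random_seq(rng, u5) + "ATG" + middle + stop + _random_seq(rng, u3)
    cds = _tx_to_genomic(exons, strand, u5, u5 + cds_len)
    return _GeneSpec(gene_id, contig, strand, exons, cds, u5, cds_len, u3, mrna)


def _stamp(arr: np.ndarray, spec: _GeneSpec) -> None:
    orient = spec.exons if spec.strand == "+" else spec.exons[::-1]
    acc = 0
    for s, e in orient:
        chunk = spec.mrna[acc : acc + (e - s)]
        if spec.strand == "-":
            chunk = revcomp(chunk)
        arr[s:e] = np.frombuffer(chunk.encode(), dtype="S1").astype("U1")
        acc += e - s


# ---------------------------------------------------------------------------
# class-first variant realization
# ---------------------------------------------------------------------------

class _TxGeom:
    """Cached transcript geometry read back from the final genome."""

    def __init__(self, tx: TranscriptModel, genome: Genome):
        self.tx = tx
        self.cds_pos = tx.region_positions(tx.cds_intervals)
        self.cds_seq = tx.region_sequence(tx.cds_intervals, genome)
        self.utr5_pos = tx.region_positions(tx.utr5_intervals)
        self.utr5_seq = tx.region_sequence(tx.utr5_intervals, genome)
        self.utr3_pos = tx.region_positions(tx.utr3_intervals)
        self.windows = tx.splice_windows(2)

    def genomic_alt(self, alt_tx: str) -> str:
        return alt_tx if self.tx.strand == "+" else revcomp(alt_tx)


def _new_atg(seq: str, u: int, alt: str) -> bool:
    mut = seq[:u] + alt + seq[u + 1 :]
    for w in range(max(0, u - 2), min(u, len(mut) - 3) + 1):
        if mut[w : w + 3] == "ATG" and seq[w : w + 3] != "ATG":
            return True
    return False


def _realize(rng, geom: _TxGeom, cls: str, used: Set[Tuple[str, int]]
             ) -> Optional[Tuple[int, str]]:
    """Find (genomic pos0, genomic alt) producing the requested class on
    this transcript, avoiding used positions.  None when infeasible."""
    contig = geom.tx.contig_id
    bases = "ACGT"
    n_cod = len(geom.cds_seq) // 3

    def cds_candidate(codon_range, cond):
        order = list(codon_range)
        rng.shuffle(order)
        for ci in order[:60]:
            ref_codon = geom.cds_seq[3 * ci : 3 * ci + 3]
            offs = [0, 1, 2]
            rng.shuffle(offs)
            for off in offs:
                pos = geom.cds_pos[3 * ci + off]
                if (contig, pos) in used:
                    continue
                alts = [b for b in bases if b != ref_codon[off]]
                rng.shuffle(alts)
                for a in alts:
                    alt_codon = ref_codon[:off] + a + ref_codon[off + 1 :]
                    if cond(ci, ref_codon, alt_codon):
                        return pos, geom.genomic_alt(a)
        return None

    if cls == "SYNONYMOUS":
        return cds_candidate(
            range(1, n_cod - 1),
            lambda ci, rc, ac: ac not in STOP_CODONS
            and CODON_TABLE[rc] == CODON_TABLE[ac],
        )
    if cls == "NON_SYNONYMOUS":
        return cds_candidate(
            range(1, n_cod - 1),
            lambda ci, rc, ac: ac not in STOP_CODONS
            and CODON_TABLE[rc] != CODON_TABLE[ac],
        )
    if cls == "STOP_GAINED":
        return cds_candidate(
            range(1, n_cod - 1), lambda ci, rc, ac: ac in STOP_CODONS
        )
    if cls == "STOP_LOST":
        return cds_candidate(
            [n_cod - 1], lambda ci, rc, ac: ac not in STOP_CODONS
        )
    if cls == "SYNONYMOUS_STOP":
        return cds_candidate([n_cod - 1], lambda ci, rc, ac: ac in STOP_CODONS)
    if cls == "START_LOST":
        return cds_candidate([0], lambda ci, rc, ac: ac != "ATG")
    if cls in ("UTR_5", "START_GAINED"):
        idx = list(range(len(geom.utr5_pos)))
        rng.shuffle(idx)
        want_atg = cls == "START_GAINED"
        for u in idx[:80]:
            pos = geom.utr5_pos[u]
            if (contig, pos) in used:
                continue
            alts = [b for b in bases if b != geom.utr5_seq[u]]
            rng.shuffle(alts)
            for a in alts:
                if _new_atg(geom.utr5_seq, u, a) == want_atg:
                    return pos, geom.genomic_alt(a)
        return None
    if cls == "UTR_3":
        idx = list(range(len(geom.utr3_pos)))
        rng.shuffle(idx)
        for u in idx[:80]:
            pos = geom.utr3_pos[u]
            if (contig, pos) in used:
                continue
            a = bases[rng.integers(0, 4)]
            return pos, a  # fixed up by caller against the genome base
        return None
    if cls in ("SPLICE_DONOR", "SPLICE_ACCEPTOR"):
        kind = "donor" if cls == "SPLICE_DONOR" else "acceptor"
        wins = [(iv, k) for iv, k in geom.windows if k == kind]
        rng.shuffle(wins)
        for (s, e), _ in wins:
            for pos in range(s, e):
                if (contig, pos) not in used:
                    a = bases[rng.integers(0, 4)]
                    return pos, a  # fixed up by caller
        return None
    raise ValueError(f"unknown class {cls}")


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, outdir=None) -> SimulationResult:
    """Run the generator; optionally write the full file bundle."""
    rng = np.random.default_rng(config.seed)
    strains = list(config.strains)

    # ---- layout and sequences -------------------------------------------
    specs: List[_GeneSpec] = []
    gaps: Dict[str, List[Interval]] = {}
    contig_arrays: Dict[str, np.ndarray] = {}
    gid = 0
    for ci in range(config.n_gene_contigs):
        contig = f"sc_{ci + 1}"
        contig_specs: List[_GeneSpec] = []
        contig_gaps: List[Interval] = []
        n_genes = int(rng.integers(*config.genes_per_contig))
        big_gap_after = int(rng.integers(0, n_genes))
        big_done = False
        cursor = int(rng.integers(500, 1500))
        prev_end = 0
        gi = 0
        while gi < n_genes:
            overlap_pair = (
                gi + 1 < n_genes and rng.random() < config.overlap_fraction
            )
            strand = "+" if overlap_pair else ("+", "-")[rng.integers(0, 2)]
            gid += 1
            spec = _make_gene(rng, config, f"gene_{gid:03d}", contig, strand, cursor)
            contig_specs.append(spec)
            if cursor > prev_end:
                contig_gaps.append((prev_end, cursor))
            end = spec.exons[-1][1]
            gi += 1
            if overlap_pair:
                # convergent partner overlapping this gene's 3'UTR
                for _ in range(20):
                    gid2 = gid + 1
                    partner = _make_gene(
                        rng, config, f"gene_{gid2:03d}", contig, "-", 0
                    )
                    k_max = min(spec.utr3_len, partner.utr3_len) - 12
                    if k_max > 15:
                        break
                else:
                    partner = None
                if partner is not None:
                    gid += 1
                    k = int(rng.integers(15, k_max))
                    shift = end - k
                    partner.exons = [(s + shift, e + shift) for s, e in partner.exons]
                    partner.cds = [(s + shift, e + shift) for s, e in partner.cds]
                    contig_specs.append(partner)
                    end = partner.exons[-1][1]
                    gi += 1
            if not big_done and gi - 1 >= big_gap_after:
                gap = int(rng.integers(*config.big_gap_range))
                big_done = True
            else:
                gap = int(rng.integers(*config.gap_range))
            prev_end = end
            cursor = end + gap
        contig_gaps.append((prev_end, cursor))
        length = cursor
        arr = _BASES[rng.integers(0, 4, length)]
        for spec in contig_specs:
            _stamp(arr, spec)
        contig_arrays[contig] = arr
        gaps[contig] = contig_gaps
        specs.extend(contig_specs)
    for ci in range(config.n_empty_contigs):
        contig = f"sc_empty_{ci + 1}"
        contig_arrays[contig] = _BASES[
            rng.integers(0, 4, config.empty_contig_length)
        ]
        gaps[contig] = [(0, config.empty_contig_length)]

    genome = Genome.from_contigs(
        SupercontigSeq(c, "".join(arr)) for c, arr in contig_arrays.items()
    )

    # ---- gene models ----------------------------------------------------
    genes: List[GeneModel] = []
    for spec in specs:
        txs = [
            TranscriptModel(
                transcript_id=f"{spec.gene_id}_t1",
                gene_id=spec.gene_id,
                contig_id=spec.contig,
                strand=spec.strand,
                exons=tuple(spec.exons),
                cds_intervals=tuple(spec.cds),
            )
        ]
        if rng.random() < config.second_isoform_fraction:
            txs.append(
                TranscriptModel(
                    transcript_id=f"{spec.gene_id}_t2",
                    gene_id=spec.gene_id,
                    contig_id=spec.contig,
                    strand=spec.strand,
                    exons=tuple(spec.exons),
                    cds_intervals=tuple(spec.cds),
                )
            )
            spec.isoforms = 2
        genes.append(GeneModel(spec.gene_id, spec.contig, spec.strand, tuple(txs)))
    gene_by_id = {g.gene_id: g for g in genes}
    genes_by_contig: Dict[str, List[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig_id, []).append(g)

    geoms = {g.gene_id: _TxGeom(g.transcripts[0], genome) for g in genes}

    # ---- variants -------------------------------------------------------
    exon_union_len = {g.gene_id: g.exon_union_length for g in genes}
    total_kb = sum(exon_union_len.values()) / 1000.0
    n_sites = int(round(config.union_density_per_kb * total_kb))
    class_names = [c for c, _ in config.class_proportions]
    class_p = np.array([p for _, p in config.class_proportions])
    class_p = class_p / class_p.sum()
    gene_ids = [g.gene_id for g in genes]
    gene_w = np.array([exon_union_len[g] for g in gene_ids], dtype=float)
    gene_w /= gene_w.sum()

    used: Set[Tuple[str, int]] = set()
    sites: List[VariantSite] = []
    var_rows: List[dict] = []
    site_rows: List[dict] = []
    retained: Dict[str, Set[Tuple[str, int, str]]] = {s: set() for s in strains}

    def covering_transcripts(contig: str, pos: int):
        hits = []
        for g in genes_by_contig.get(contig, ()):
            for tx in g.transcripts:
                if tx.contains(pos, 2):
                    hits.append(tx)
                    break
        return hits

    def membership() -> Tuple[str, ...]:
        r = rng.random()
        if r < config.fraction_single:
            i = rng.choice(3, p=np.array(config.single_weights) /
                           sum(config.single_weights))
            return (strains[i],)
        if r < config.fraction_single + config.fraction_pair:
            pairs = [
                (strains[0], strains[1]),
                (strains[0], strains[2]),
                (strains[1], strains[2]),
            ]
            i = rng.choice(3, p=np.array(config.pair_weights) /
                           sum(config.pair_weights))
            return pairs[i]
        return tuple(strains)

    planted = 0
    attempts = 0
    while planted < n_sites:
        attempts += 1
        if attempts > 50 * n_sites:
            raise RuntimeError(
                "variant planting stalled: no eligible position for the "
                "requested effect-class mix at this density"
            )
        cls = class_names[rng.choice(len(class_names), p=class_p)]
        gene_id = gene_ids[rng.choice(len(gene_ids), p=gene_w)]
        geom = geoms[gene_id]
        if cls in ("SPLICE_DONOR", "SPLICE_ACCEPTOR") and not geom.windows:
            continue
        got = _realize(rng, geom, cls, used)
        if got is None:
            continue
        pos, alt = got
        contig = geom.tx.contig_id
        ref = genome.base(contig, pos)
        if alt == ref:  # UTR_3/splice candidates return an unchecked base
            alt = "ACGT"[(("ACGT".index(ref)) + 1 + rng.integers(0, 3)) % 4]
        # eligibility against other genes: only shared 3'UTRs are allowed
        covering = covering_transcripts(contig, pos)
        other = [t for t in covering if t.gene_id != gene_id]
        if other:
            ok = cls == "UTR_3" and all(
                point_in_intervals(pos, t.utr3_intervals) for t in other
            )
            if not ok:
                continue
        used.add((contig, pos))
        planted += 1

        alts = [alt]
        if cls == "UTR_3" and rng.random() < config.fraction_multiallelic_of_utr3:
            extra = [b for b in "ACGT" if b not in (ref, alt)]
            alts.append(extra[rng.integers(0, len(extra))])

        qual_fail = rng.random() < config.qual_fail_fraction
        if qual_fail:
            qual = round(float(rng.uniform(1, 39.9)), 1)
        elif rng.random() < config.boundary_value_rate:
            qual = 40.0
        else:
            qual = round(float(rng.uniform(40, 2000)), 1)

        member: Dict[str, Tuple[str, ...]] = {a: membership() for a in alts}
        intended: Dict[str, Set[str]] = {
            a: set() if qual_fail else set(member[a]) for a in alts
        }
        called: Set[str] = set()
        for a in alts:
            called |= set(member[a])
        for s in strains:
            if s not in called and rng.random() < config.extra_fail_call_rate:
                called.add(s)

        per_strain: Dict[str, StrainCall] = {}
        for s in strains:
            if s not in called:
                per_strain[s] = StrainCall(called=False)
                continue
            passing = [a for a in alts if s in intended[a]]
            if passing:
                boundary = len(alts) == 1 and rng.random() < config.boundary_value_rate
                dp = 3 if boundary else 3 + int(rng.poisson(config.depth_mean))
                ao, qa = [], []
                for a in alts:
                    if s in intended[a]:
                        if boundary:
                            ao_i, qa_i = 2, 40
                        else:
                            ao_i = int(rng.integers(2, max(3, dp // 2 + 1)))
                            qa_i = max(40, ao_i * int(rng.integers(20, 39)))
                    elif rng.random() < 0.5:
                        ao_i = int(rng.integers(0, 2))
                        qa_i = ao_i * 30
                    else:
                        ao_i, qa_i = 2, int(rng.integers(0, 40))
                    ao.append(ao_i)
                    qa.append(qa_i)
                dp = max(dp, sum(ao))
                per_strain[s] = StrainCall(True, dp, tuple(ao), tuple(qa))
            else:
                mode = int(rng.integers(0, 3))
                if mode == 0:  # depth failure
                    dp = int(rng.integers(0, 3))
                    ao = [0] * len(alts)
                    qa = [0] * len(alts)
                elif mode == 1:  # observation-count failure
                    dp = 3 + int(rng.poisson(5))
                    ao = [int(rng.integers(0, 2)) for _ in alts]
                    qa = [a_i * 30 for a_i in ao]
                else:  # quality-sum failure
                    ao = [2] * len(alts)
                    qa = [int(rng.integers(0, 40)) for _ in alts]
                    dp = max(3 + int(rng.poisson(5)), sum(ao))
                per_strain[s] = StrainCall(True, dp, tuple(ao), tuple(qa))

        site = VariantSite(contig, pos, ref, tuple(alts), qual, per_strain)
        sites.append(site)
        for a in alts:
            for s in intended[a]:
                retained[s].add((contig, pos, a))
            site_rows.append(
                {
                    "contig": contig,
                    "pos": pos + 1,
                    "ref": ref,
                    "alt": a,
                    "qual": qual,
                    "called_strains": ",".join(sorted(s for s in strains
                                                      if per_strain[s].called)),
                    "retained_strains": ",".join(sorted(intended[a])),
                }
            )
            target_genes = [gene_id] + [t.gene_id for t in other]
            for g in target_genes:
                var_rows.append(
                    {
                        "contig": contig,
                        "pos": pos + 1,
                        "ref": ref,
                        "alt": a,
                        "gene_id": g,
                        "effect_class": cls,
                    }
                )

    # ---- coverage and expression ---------------------------------------
    tracks: Dict[str, CoverageTrack] = {}
    for s in strains:
        tracks[s] = CoverageTrack(
            strain=s,
            depths={
                c: rng.poisson(0.6, len(genome[c])).astype(np.int64)
                for c in genome
            },
        )
    fpkm: Dict[str, Dict[str, float]] = {}
    gene_rows: List[dict] = []
    snp_genes: Set[str] = set()
    gene_positions: Dict[str, np.ndarray] = {}
    for g in genes:
        positions = np.concatenate([np.arange(s, e) for s, e in g.exon_union])
        gene_positions[g.gene_id] = positions
        L = len(positions)
        is_snp_gene = rng.random() < config.p_snp_gene
        fail_plan: Dict[str, Tuple[bool, bool]] = {}
        if not is_snp_gene:
            n_fail = int(rng.integers(1, 4))
            fail_strains = list(rng.choice(strains, n_fail, replace=False))
            for s in strains:
                if s in fail_strains:
                    mode = int(rng.integers(0, 3))
                    fail_plan[s] = (mode != 1, mode != 0)  # (cov_fail, fpkm_fail)
                else:
                    fail_plan[s] = (False, False)
        fpkm[g.gene_id] = {}
        for s in strains:
            cov_fail, fpkm_fail = fail_plan.get(s, (False, False))
            target = (
                float(rng.uniform(0.50, 0.88)) if cov_fail
                else float(rng.uniform(0.92, 1.0))
            )
            k = int(round(target * L))
            arr = tracks[s].depths[g.contig_id]
            start = int(rng.integers(0, L)) if k < L else 0
            drop = np.zeros(L, dtype=bool)
            if k < L:
                idx = (np.arange(L - k) + start) % L
                drop[idx] = True
            arr[positions[~drop]] = 3 + rng.poisson(config.depth_mean, int(L - drop.sum()))
            arr[positions[drop]] = rng.integers(0, 3, int(drop.sum()))
            value = (
                round(float(rng.uniform(0.3, 14.5)), 3) if fpkm_fail
                else round(float(np.exp(rng.uniform(np.log(16), np.log(300)))), 3)
            )
            fpkm[g.gene_id][s] = value
    # truth from the final arrays: overlapping genes perturb each other's
    # stamps, so per-gene coverage is re-derived only after all stamping
    for g in genes:
        positions = gene_positions[g.gene_id]
        L = len(positions)
        all_pass = True
        for s in strains:
            arr = tracks[s].depths[g.contig_id]
            covered = int((arr[positions] >= 3).sum())
            frac = covered / L
            passed = frac >= 0.90 and fpkm[g.gene_id][s] > 15.0
            all_pass = all_pass and passed
            gene_rows.append(
                {
                    "gene_id": g.gene_id,
                    "strain": s,
                    "covered_bases": covered,
                    "transcript_length": L,
                    "coverage_fraction": frac,
                    "fpkm": fpkm[g.gene_id][s],
                    "passes": passed,
                }
            )
        if all_pass:
            snp_genes.add(g.gene_id)
    for row in gene_rows:
        row["snp_gene"] = row["gene_id"] in snp_genes
    expression = GeneExpression(fpkm)

    # ---- NTUs -----------------------------------------------------------
    ntus: List[Tuple[str, str, Interval]] = []
    ntu_fpkm: Dict[str, Dict[str, float]] = {}
    ntu_rows: List[dict] = []
    free_gaps = [
        (c, s, e) for c, lst in gaps.items() for s, e in lst
        if c in genes_by_contig
    ]
    rng.shuffle(free_gaps)
    gap_claims: Dict[Tuple[str, int, int], List[Interval]] = {}
    empty_contigs = [c for c in genome if c not in genes_by_contig]
    win_p = np.array(config.ntu_window_proportions)
    win_p = win_p / win_p.sum()
    bin_lims = {
        FpkmBin.LT1: (0.01, 0.99),
        FpkmBin.GE1_LT10: (1.0, 9.99),
        FpkmBin.GE10_LT100: (10.0, 99.9),
        FpkmBin.GE100: (100.0, 500.0),
    }
    n_beyond = 0
    for ni in range(config.n_ntus):
        ntu_id = f"NTU_{ni + 1:03d}"
        wcls = [WindowClass.WITHIN_1KB, WindowClass.BETWEEN_1KB_10KB,
                WindowClass.BEYOND_10KB][rng.choice(3, p=win_p)]
        length = int(rng.integers(*config.ntu_len_range))
        placed = None
        if wcls is WindowClass.BEYOND_10KB:
            n_beyond += 1
        # every third beyond-window NTU goes to an annotation-empty contig
        if wcls is WindowClass.BEYOND_10KB and empty_contigs and n_beyond % 3 == 1:
            c = empty_contigs[rng.integers(0, len(empty_contigs))]
            clen = len(genome[c])
            s0 = int(rng.integers(0, clen - length))
            placed = (c, (s0, s0 + length), math.inf, True)
        else:
            for _ in range(12):
                if wcls is WindowClass.WITHIN_1KB:
                    d = int(rng.integers(0, 1001))
                elif wcls is WindowClass.BETWEEN_1KB_10KB:
                    d = int(rng.integers(1001, 10001))
                else:
                    d = int(rng.integers(10001, 12000))
                for c, gs, ge in free_gaps:
                    # interior gaps need clearance on both sides; terminal
                    # gaps (contig start/end) only on the annotated side
                    left_exon = gs > 0
                    right_exon = ge < len(genome[c])
                    if not (left_exon or right_exon):
                        continue
                    if left_exon:
                        s0 = gs + d
                        fits = s0 + length <= ge - (d if right_exon else 0)
                    else:
                        s0 = ge - d - length
                        fits = s0 >= gs
                    iv = (s0, s0 + length)
                    taken = gap_claims.get((c, gs, ge), [])
                    if fits and s0 >= gs and all(
                        iv[1] <= t0 or t1 <= iv[0] for t0, t1 in taken
                    ):
                        placed = (c, iv, float(d), False)
                        gap_claims.setdefault((c, gs, ge), []).append(iv)
                        break
                if placed is not None:
                    break
        if placed is None:
            continue  # no eligible gap for this class; generate fewer
        c, iv, d, empty = placed
        ntus.append((ntu_id, c, iv))
        same_bin = rng.random() < config.ntu_same_bin_fraction
        vals: Dict[str, float] = {}
        if same_bin:
            b = list(FpkmBin)[rng.choice(4, p=np.array(config.ntu_bin_weights))]
            for s in strains:
                vals[s] = round(float(rng.uniform(*bin_lims[b])), 3)
        else:
            for s in strains:
                b = list(FpkmBin)[rng.choice(4, p=np.array(config.ntu_bin_weights))]
                vals[s] = round(float(rng.uniform(*bin_lims[b])), 3)
        ntu_fpkm[ntu_id] = vals
        ntu_rows.append(
            {
                "ntu_id": ntu_id,
                "contig": c,
                "start0": iv[0],
                "end": iv[1],
                "min_distance": d,
                "window": window_class(d).value,
                "empty_supercontig": empty,
                **{f"fpkm_{s}": vals[s] for s in strains},
                "cumulative_bin": fpkm_bin(max(vals.values())).value,
            }
        )

    truth = GroundTruth(
        variant_records=pd.DataFrame(var_rows),
        site_truth=pd.DataFrame(site_rows),
        gene_truth=pd.DataFrame(gene_rows),
        ntu_truth=pd.DataFrame(ntu_rows),
        retained=retained,
        snp_genes=snp_genes,
    )
    result = SimulationResult(
        config=config,
        genome=genome,
        genes=genes,
        sites=sites,
        tracks=tracks,
        expression=expression,
        ntus=ntus,
        ntu_fpkm=ntu_fpkm,
        truth=truth,
    )
    if outdir is not None:
        write_bundle(result, outdir)
    return result


# ---------------------------------------------------------------------------
# emission and verification
# ---------------------------------------------------------------------------

def write_bundle(result: SimulationResult, outdir) -> Dict[str, Path]:
    """Write the full input bundle plus ground-truth TSVs."""
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    strains = list(result.config.strains)
    paths: Dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fasta"
    tio.write_genome(result.genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gtf"
    tio.write_annotation(result.genes, paths["annotation"])
    paths["variants"] = outdir / "variants.vcf"
    tio.write_variants(result.sites, strains, result.genome, paths["variants"])
    for s in strains:
        p = outdir / f"depth_{s}.tsv"
        tio.write_coverage(result.tracks[s], p)
        paths[f"depth_{s}"] = p
    paths["fpkm"] = outdir / "fpkm.tsv"
    tio.write_expression(result.expression, strains, paths["fpkm"])

    paths["ntus"] = outdir / "ntus.gtf"
    with open(paths["ntus"], "w") as fh:
        for ntu_id, c, (s0, e) in result.ntus:
            attrs = f'gene_id "{ntu_id}"; transcript_id "{ntu_id}";'
            fh.write(f"{c}\ttxsnp\ttranscript\t{s0 + 1}\t{e}\t.\t+\t.\t{attrs}\n")
            fh.write(f"{c}\ttxsnp\texon\t{s0 + 1}\t{e}\t.\t+\t.\t{attrs}\n")
    paths["ntu_fpkm"] = outdir / "ntu_fpkm.tsv"
    rows = [
        {"gene_id": ntu_id, **{s: result.ntu_fpkm[ntu_id][s] for s in strains}}
        for ntu_id, _, _ in result.ntus
    ]
    pd.DataFrame(rows, columns=["gene_id", *strains]).to_csv(
        paths["ntu_fpkm"], sep="\t", index=False
    )

    t = result.truth
    for name, df in [
        ("truth_variants", t.variant_records),
        ("truth_sites", t.site_truth),
        ("truth_genes", t.gene_truth),
        ("truth_ntus", t.ntu_truth),
    ]:
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)
    return paths


def verify_ground_truth(outdir, strains: Sequence[str] = ("LVP", "CTM", "RexD")
                        ) -> List[str]:
    """Re-read an emitted bundle and cross-check it against its truth.

    Returns a list of inconsistency descriptions (empty when clean):
    reference alleles must match the genome, planted effect positions
    must lie in the compartments their class implies, NTU distances must
    match an exhaustive rescan, and per-gene covered-base counts must
    match the depth tracks.
    """
    from . import io as tio
    from .models import point_in_intervals

    outdir = Path(outdir)
    problems: List[str] = []
    genome = tio.read_genome(outdir / "genome.fasta")
    genes = tio.read_annotation(outdir / "annotation.gtf", genome)
    gene_by_id = {g.gene_id: g for g in genes}
    by_contig: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)

    vt = pd.read_csv(outdir / "truth_variants.tsv", sep="\t")
    for _, row in vt.iterrows():
        pos0 = int(row["pos"]) - 1
        base = genome.base(row["contig"], pos0)
        if base != row["ref"]:
            problems.append(
                f"{row['contig']}:{row['pos']}: truth ref {row['ref']} != "
                f"genome {base}"
            )
            continue
        gene = gene_by_id.get(row["gene_id"])
        if gene is None:
            problems.append(f"unknown gene {row['gene_id']}")
            continue
        tx = gene.transcripts[0]
        cls = row["effect_class"]
        if cls in ("SYNONYMOUS", "NON_SYNONYMOUS", "SYNONYMOUS_STOP",
                   "START_LOST", "STOP_GAINED", "STOP_LOST"):
            ok = point_in_intervals(pos0, tx.cds_intervals)
        elif cls in ("UTR_5", "START_GAINED"):
            ok = point_in_intervals(pos0, tx.utr5_intervals)
        elif cls == "UTR_3":
            ok = point_in_intervals(pos0, tx.utr3_intervals)
        else:
            kind = "donor" if cls == "SPLICE_DONOR" else "acceptor"
            ok = any(
                s <= pos0 < e for (s, e), k in tx.splice_windows(2) if k == kind
            )
        if not ok:
            problems.append(
                f"{row['contig']}:{row['pos']}: class {cls} outside its "
                f"compartment in {gene.gene_id}"
            )

    nt = pd.read_csv(outdir / "truth_ntus.tsv", sep="\t")
    for _, row in nt.iterrows():
        iv = (int(row["start0"]), int(row["end"]))
        best = math.inf
        for g in by_contig.get(row["contig"], ()):
            for s, e in g.exon_union:
                if iv[0] < e and s < iv[1]:
                    best = 0.0
                else:
                    best = min(best, max(s - iv[1], iv[0] - e, 0))
        if not (
            best == float(row["min_distance"])
            or (math.isinf(best) and math.isinf(float(row["min_distance"])))
        ):
            problems.append(
                f"{row['ntu_id']}: truth distance {row['min_distance']} != "
                f"rescan {best}"
            )

    gt = pd.read_csv(outdir / "truth_genes.tsv", sep="\t")
    tracks = {
        s: tio.read_coverage(outdir / f"depth_{s}.tsv", s, genome)
        for s in strains
    }
    for _, row in gt.iterrows():
        gene = gene_by_id[row["gene_id"]]
        arr = tracks[row["strain"]].depths[gene.contig_id]
        pos = np.concatenate([np.arange(s, e) for s, e in gene.exon_union])
        covered = int((arr[pos] >= 3).sum())
        if covered != int(row["covered_bases"]):
            problems.append(
                f"{row['gene_id']}/{row['strain']}: truth covered "
                f"{row['covered_bases']} != depth-track {covered}"
            )
    return problems
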
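"""Novel transcriptional unit (NTU) classification.

Candidate NTUs — assembled transcript intervals absent from the
reference annotation — are classified by the minimum gap in bases to any
annotated exon on the same supercontig, then bucketed into three
windows: within 1 kb, between 1 kb and 10 kb, and beyond 10 kb (the
novel-gene candidate set).  NTUs on supercontigs with no annotated gene
have infinite distance and land in the beyond class with an
``empty_supercontig`` flag.  Expression is bucketed into the FPKM bins
[0,1), [1,10), [10,100), [100,inf) per strain, and cumulatively by the
maximum FPKM over strains (so "FPKM < 1 in all three strains" is the
lowest cumulative bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .models import GeneModel, Interval, interval_gap


class WindowClass(str, Enum):
    WITHIN_1KB = "WITHIN_1KB"
    BETWEEN_1KB_10KB = "BETWEEN_1KB_10KB"
    BEYOND_10KB = "BEYOND_10KB"


class FpkmBin(str, Enum):
    LT1 = "LT1"
    GE1_LT10 = "GE1_LT10"
    GE10_LT100 = "GE10_LT100"
    GE100 = "GE100"


FPKM_EDGES = (1.0, 10.0, 100.0)


def fpkm_bin(value: float) -> FpkmBin:
    """Disjoint bins; FPKM exactly 100 falls in the top bin."""
    if value < 1.0:
        return FpkmBin.LT1
    if value < 10.0:
        return FpkmBin.GE1_LT10
    if value < 100.0:
        return FpkmBin.GE10_LT100
    return FpkmBin.GE100


@dataclass(frozen=True)
class WindowThresholds:
    near: int = 1_000
    far: int = 10_000


def window_class(min_distance: float, thresholds: WindowThresholds = WindowThresholds()
                 ) -> WindowClass:
    """WITHIN when distance <= near; BEYOND when distance > far."""
    if min_distance <= thresholds.near:
        return WindowClass.WITHIN_1KB
    if min_distance > thresholds.far:
        return WindowClass.BEYOND_10KB
    return WindowClass.BETWEEN_1KB_10KB


@dataclass
class NTURecord:
    ntu_id: str
    contig_id: str
    interval: Interval
    fpkm: Dict[str, float]
    min_distance: float
    window: WindowClass
    empty_supercontig: bool

    @property
    def cumulative_bin(self) -> FpkmBin:
        return fpkm_bin(max(self.fpkm.values()))


def distance_to_annotation(
    interval: Interval,
    genes: Sequence[GeneModel],
    contig_length: Optional[int] = None,
) -> float:
    """Minimum gap in bases between the interval and any annotated exon
    on the same contig; 0 on overlap or adjacency; inf when the contig
    has no genes.

    ``genes`` must already be restricted to the NTU's contig.
    """
    if contig_length is not None and not (
        0 <= interval[0] < interval[1] <= contig_length
    ):
        raise ValueError(f"interval {interval} outside contig bounds")
    best = math.inf
    for g in genes:
        for exon in g.exon_union:
            best = min(best, interval_gap(interval, exon))
            if best == 0:
                return 0.0
    return best


def classify_ntus(
    ntus: Iterable[Tuple[str, str, Interval]],
    genes: Sequence[GeneModel],
    expression: Mapping[str, Mapping[str, float]],
    thresholds: WindowThresholds = WindowThresholds(),
) -> List[NTURecord]:
    """Classify (ntu_id, contig, interval) triples.

    ``expression`` maps ntu_id -> strain -> FPKM.
    """
    by_contig: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    records = []
    for ntu_id, contig, iv in ntus:
        contig_genes = by_contig.get(contig, [])
        d = distance_to_annotation(iv, contig_genes)
        records.append(
            NTURecord(
                ntu_id=ntu_id,
                contig_id=contig,
                interval=iv,
                fpkm=dict(expression.get(ntu_id, {})),
                min_distance=d,
                window=window_class(d, thresholds),
                empty_supercontig=not contig_genes,
            )
        )
    return records


def window_histogram(records: Sequence[NTURecord]) -> pd.DataFrame:
    """Counts and percentages per distance window (classes partition the
    NTU set, so counts sum to the total)."""
    total = len(records)
    rows = []
    for w in WindowClass:
        n = sum(1 for r in records if r.window == w)
        rows.append(
            {
                "window": w.value,
                "count": n,
                "percent": 100.0 * n / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("window")


def outside_window_percentage(n_outside: int, n_total: int) -> float:
    """Percentage of NTUs falling outside a distance window."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * n_outside / n_total


def bin_by_fpkm(records: Sequence[NTURecord], strains: Sequence[str]) -> pd.DataFrame:
    """FPKM-bin counts per strain plus the cumulative (max-over-strains)
    grouping; one row per bin."""
    rows = []
    for b in FpkmBin:
        row: Dict[str, object] = {"fpkm_bin": b.value}
        for s in strains:
            row[s] = sum(
                1 for r in records if fpkm_bin(r.fpkm.get(s, 0.0)) == b
            )
        row["cumulative"] = sum(1 for r in records if r.cumulative_bin == b)
        rows.append(row)
    return pd.DataFrame(rows).set_index("fpkm_bin")


def read_ntu_gtf(path) -> List[Tuple[str, str, Interval]]:
    """Read candidate NTU intervals from a GTF (transcript features; the
    interval is the transcript span) or BED-like rows."""
    import gffutils

    spans: Dict[str, Tuple[str, int, int]] = {}
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype not in ("transcript", "exon"):
            continue
        tid = feat.attributes["transcript_id"][0]
        s, e = feat.start - 1, feat.end
        if tid in spans:
            c, s0, e0 = spans[tid]
            spans[tid] = (c, min(s0, s), max(e0, e))
        else:
            spans[tid] = (feat.seqid, s, e)
    return [(tid, c, (s, e)) for tid, (c, s, e) in sorted(spans.items())]
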
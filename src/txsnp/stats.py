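"""Polymorphism-density and association statistics.

Densities are polymorphic sites per kilobase (PS/kb) of analyzed exon
sequence, computed per gene, per supercontig and per strain; paired
strain comparisons use a two-sided Wilcoxon signed-rank test on
per-supercontig densities (the pairing is by supercontig); the
annotated-gene vs SNP-gene spatial association uses squared Pearson
correlation, and the density-vs-FPKM detection-bias diagnostic uses
Spearman rank correlation.  No multiple-testing correction is applied
across the three pairwise strain tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class DensityRecord:
    scope: str      # "gene" | "supercontig" | "strain"
    unit_id: str
    strain: str
    n_ps: int
    length_kb: float

    @property
    def ps_per_kb(self) -> float:
        return self.n_ps / self.length_kb


def ps_density(
    site_locations: Mapping[str, Set[Tuple[str, int]]],
    unit_lengths: Mapping[str, int],
    unit_of_location: Mapping[Tuple[str, int], Sequence[str]],
    strain_scope: bool = True,
    scope: str = "gene",
) -> List[DensityRecord]:
    """Per-unit and per-strain PS/kb.

    ``site_locations``: strain -> set of (contig, pos) retained there;
    ``unit_lengths``: unit id -> analyzed exon length in bases;
    ``unit_of_location``: (contig, pos) -> unit ids containing the site
    (a site shared by overlapping genes counts in each).  The strain
    aggregate is total assigned sites / total kb, so the weighted
    identity  aggregate = sum(n_ps) / sum(length_kb)  holds exactly.
    """
    records: List[DensityRecord] = []
    for strain, locs in site_locations.items():
        per_unit: Dict[str, int] = {u: 0 for u in unit_lengths}
        for loc in locs:
            for u in unit_of_location.get(loc, ()):
                per_unit[u] += 1
        for u, n in per_unit.items():
            if unit_lengths[u] <= 0:
                raise ValueError(f"unit {u}: non-positive length")
            records.append(
                DensityRecord(scope, u, strain, n, unit_lengths[u] / 1000.0)
            )
        if strain_scope and sum(unit_lengths.values()) > 0:
            records.append(
                DensityRecord(
                    "strain",
                    strain,
                    strain,
                    sum(per_unit.values()),
                    sum(unit_lengths.values()) / 1000.0,
                )
            )
    return records


def density_table(records: Sequence[DensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scope": r.scope,
                "unit_id": r.unit_id,
                "strain": r.strain,
                "n_ps": r.n_ps,
                "length_kb": r.length_kb,
                "ps_per_kb": r.ps_per_kb,
            }
            for r in records
        ]
    )


def density_fold(densities: Mapping[str, float], reference: str) -> float:
    """Mean density of the non-reference strains over the reference
    strain's density."""
    others = [v for k, v in densities.items() if k != reference]
    if not others:
        raise ValueError("need at least one non-reference strain")
    return float(np.mean(others) / densities[reference])


@dataclass
class StrainComparisonResult:
    strain_a: str
    strain_b: str
    statistic: float
    p_value: float
    n_pairs: int
    significant: bool
    alpha: float
    test_name: str = "wilcoxon_signed_rank"


def compare_density_distributions(
    dens_a: Mapping[str, float],
    dens_b: Mapping[str, float],
    strain_a: str = "A",
    strain_b: str = "B",
    alpha: float = 0.01,
    min_pairs: int = 10,
) -> StrainComparisonResult:
    """Two-sided Wilcoxon signed-rank test on supercontig-paired PS/kb.

    Restricted to supercontigs present in both mappings; an all-zero
    difference vector returns p = 1 by convention.
    """
    shared = sorted(set(dens_a) & set(dens_b))
    if len(shared) < min_pairs:
        raise ValueError(
            f"only {len(shared)} shared supercontigs; need >= {min_pairs} "
            "for a meaningful paired comparison"
        )
    a = np.array([dens_a[k] for k in shared])
    b = np.array([dens_b[k] for k in shared])
    d = a - b
    if np.all(d == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.wilcoxon(a, b, alternative="two-sided")
    return StrainComparisonResult(
        strain_a, strain_b, float(stat), float(p), len(shared), p < alpha, alpha
    )


def gene_count_correlation(
    annotated_counts: Mapping[str, int],
    snp_gene_counts: Mapping[str, int],
) -> float:
    """Squared Pearson correlation of per-supercontig annotated-gene vs
    SNP-gene counts, over supercontigs with >= 1 annotated gene.

    Returns NaN when either count vector is constant (undefined R^2).
    """
    keys = [k for k, v in annotated_counts.items() if v >= 1]
    if len(keys) < 3:
        raise ValueError("need >= 3 supercontigs with annotated genes")
    x = np.array([annotated_counts[k] for k in keys], dtype=float)
    y = np.array([snp_gene_counts.get(k, 0) for k in keys], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


def density_fpkm_association(
    gene_density: Mapping[str, float],
    gene_fpkm: Mapping[str, float],
) -> Tuple[float, float]:
    """Spearman rho and p-value of per-gene PS/kb vs FPKM — the
    detection-bias diagnostic (a null result supports unbiased SNP
    detection across expression levels)."""
    keys = sorted(set(gene_density) & set(gene_fpkm))
    if len(keys) < 3:
        raise ValueError("need >= 3 genes for a rank correlation")
    x = np.array([gene_density[k] for k in keys])
    y = np.array([gene_fpkm[k] for k in keys])
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def zero_polymorphism_genes(
    snp_genes: Iterable[str],
    assignment: Mapping[str, Sequence],
) -> List[str]:
    """SNP-genes with no assigned polymorphic site in any strain."""
    return sorted(g for g in snp_genes if not assignment.get(g))
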
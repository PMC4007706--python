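"""Quality filtering of pooled-strain variant calls.

A (strain, site, alt allele) is retained iff the strain is called at the
site and QUAL >= min_qual, QA >= min_qa, DP >= min_dp and AO >= min_ao
("minimum X" reads as a closed bound: the boundary value passes).  QUAL
is a site-level quantity applied to every strain; QA/DP/AO are
per-strain, and QA/AO per alternate allele, so at a multi-allelic site
each allele is filtered on its own evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

SiteAllele = Tuple[str, int, str]  # (contig, pos0, alt)


@dataclass(frozen=True)
class FilterCriteria:
    """The four post-call thresholds (defaults are the study's values)."""

    min_qual: float = 40.0
    min_qa: float = 40.0
    min_dp: int = 3
    min_ao: int = 2

    def __post_init__(self) -> None:
        if min(self.min_qual, self.min_qa, self.min_dp, self.min_ao) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FilteredCallset:
    """Per-strain retained (contig, pos0, alt) sets plus provenance."""

    criteria: FilterCriteria
    retained: Dict[str, Set[SiteAllele]]
    n_input: Dict[str, int]
    n_removed: Dict[str, Dict[str, int]]  # strain -> reason -> count

    def strains(self) -> List[str]:
        return list(self.retained)

    def n_retained(self, strain: str) -> int:
        return len(self.retained[strain])

    def retained_locations(self, strain: str) -> Set[Tuple[str, int]]:
        return {(c, p) for c, p, _ in self.retained[strain]}


def apply_quality_filters(sites, criteria: FilterCriteria,
                          strains: Sequence[str] | None = None) -> FilteredCallset:
    """Filter VariantSites into per-strain retained allele sets.

    Filtering is per strain: a site may survive in one strain and not
    another.  The provenance counters use the first failing criterion in
    the order QUAL, DP, AO, QA.
    """
    if strains is None:
        seen: List[str] = []
        for site in sites:
            for s in site.per_strain:
                if s not in seen:
                    seen.append(s)
        strains = seen
    retained: Dict[str, Set[SiteAllele]] = {s: set() for s in strains}
    n_input = {s: 0 for s in strains}
    n_removed: Dict[str, Dict[str, int]] = {s: {} for s in strains}

    def _drop(strain: str, reason: str) -> None:
        n_removed[strain][reason] = n_removed[strain].get(reason, 0) + 1

    for site in sites:
        for strain in strains:
            call = site.per_strain.get(strain)
            if call is None or not call.called:
                continue
            for i, alt in enumerate(site.alt_alleles):
                n_input[strain] += 1
                if site.qual < criteria.min_qual:
                    _drop(strain, "QUAL")
                elif call.dp < criteria.min_dp:
                    _drop(strain, "DP")
                elif call.ao[i] < criteria.min_ao:
                    _drop(strain, "AO")
                elif call.qa[i] < criteria.min_qa:
                    _drop(strain, "QA")
                else:
                    retained[strain].add((site.contig_id, site.pos0, alt))
    return FilteredCallset(
        criteria=criteria, retained=retained, n_input=n_input, n_removed=n_removed
    )


def unique_polymorphic_sites(callset: FilteredCallset) -> Set[Tuple[str, int]]:
    """Locations with a retained alternate allele in at least one strain.

    Multi-allelic locations and locations retained in several strains
    count once.
    """
    out: Set[Tuple[str, int]] = set()
    for strain in callset.retained:
        out |= callset.retained_locations(strain)
    return out
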
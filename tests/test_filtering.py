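"""Quality-filter semantics: boundary behaviour, brute-force
equivalence, and the monotonicity/idempotence/conservation properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txsnp.filtering import (
    FilterCriteria,
    apply_quality_filters,
    unique_polymorphic_sites,
)
from txsnp.models import StrainCall, VariantSite

STRAINS = ("LVP", "CTM", "RexD")


def make_site(pos0, qual, calls, ref="A", alts=("G",)):
    per_strain = {}
    for s in STRAINS:
        if s in calls:
            dp, ao, qa = calls[s]
            n = len(alts)
            ao = ao if isinstance(ao, tuple) else (ao,) * n
            qa = qa if isinstance(qa, tuple) else (qa,) * n
            per_strain[s] = StrainCall(True, dp, ao, qa)
        else:
            per_strain[s] = StrainCall(False)
    return VariantSite("c", pos0, ref, alts, qual, per_strain)


def random_sites(rng, n):
    sites = []
    for i in range(n):
        calls = {}
        for s in STRAINS:
            if rng.random() < 0.8:
                dp = int(rng.integers(0, 10))
                ao = int(rng.integers(0, dp + 1))
                qa = int(rng.integers(0, 120))
                calls[s] = (dp, ao, qa)
        sites.append(make_site(i, float(rng.integers(0, 120)), calls))
    return sites


def brute_force(sites, crit):
    out = {s: set() for s in STRAINS}
    for site in sites:
        for s in STRAINS:
            call = site.per_strain[s]
            if not call.called:
                continue
            for i, alt in enumerate(site.alt_alleles):
                if (
                    site.qual >= crit.min_qual
                    and call.qa[i] >= crit.min_qa
                    and call.dp >= crit.min_dp
                    and call.ao[i] >= crit.min_ao
                ):
                    out[s].add((site.contig_id, site.pos0, alt))
    return out


class TestBoundaries:
    def test_exact_minimums_pass(self):
        site = make_site(1, 40.0, {"LVP": (3, 2, 40)})
        cs = apply_quality_filters([site], FilterCriteria())
        assert cs.retained["LVP"] == {("c", 1, "G")}

    @pytest.mark.parametrize(
        "qual,dp,ao,qa",
        [(39.9, 3, 2, 40), (40, 2, 2, 40), (40, 3, 1, 40), (40, 3, 2, 39)],
    )
    def test_one_below_any_minimum_fails(self, qual, dp, ao, qa):
        site = make_site(1, qual, {"LVP": (dp, ao, qa)})
        cs = apply_quality_filters([site], FilterCriteria())
        assert cs.retained["LVP"] == set()

    def test_per_strain_independence(self):
        site = make_site(1, 50.0, {"LVP": (3, 2, 40), "CTM": (3, 1, 40)})
        cs = apply_quality_filters([site], FilterCriteria())
        assert cs.retained["LVP"] and not cs.retained["CTM"]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            FilterCriteria(min_dp=-1)

    def test_per_allele_filtering_at_multiallelic_site(self):
        site = make_site(
            1, 50.0, {"LVP": (10, (3, 1), (90, 90))}, alts=("G", "T")
        )
        cs = apply_quality_filters([site], FilterCriteria())
        assert cs.retained["LVP"] == {("c", 1, "G")}


class TestOracle:
    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        sites = random_sites(rng, 1000)
        crit = FilterCriteria(min_qual=60, min_qa=50, min_dp=4, min_ao=2)
        cs = apply_quality_filters(sites, crit, STRAINS)
        assert cs.retained == brute_force(sites, crit)

    def test_conservation(self):
        rng = np.random.default_rng(12)
        sites = random_sites(rng, 500)
        cs = apply_quality_filters(sites, FilterCriteria(), STRAINS)
        for s in STRAINS:
            removed = sum(cs.n_removed[s].values())
            assert cs.n_retained(s) + removed == cs.n_input[s]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    dq=st.floats(0, 30),
    ddp=st.integers(0, 4),
)
def test_raising_thresholds_is_monotone(seed, dq, ddp):
    rng = np.random.default_rng(seed)
    sites = random_sites(rng, 120)
    base = FilterCriteria()
    stricter = FilterCriteria(
        min_qual=base.min_qual + dq,
        min_qa=base.min_qa + dq,
        min_dp=base.min_dp + ddp,
        min_ao=base.min_ao + ddp,
    )
    loose = apply_quality_filters(sites, base, STRAINS)
    tight = apply_quality_filters(sites, stricter, STRAINS)
    for s in STRAINS:
        assert tight.retained[s] <= loose.retained[s]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_idempotence(seed):
    """Re-filtering only the surviving evidence changes nothing."""
    rng = np.random.default_rng(seed)
    sites = random_sites(rng, 120)
    crit = FilterCriteria()
    first = apply_quality_filters(sites, crit, STRAINS)
    survivors = []
    for site in sites:
        kept = {
            s: site.per_strain[s]
            for s in STRAINS
            if site.per_strain[s].called
            and any(
                (site.contig_id, site.pos0, a) in first.retained[s]
                for a in site.alt_alleles
            )
        }
        if kept:
            per_strain = {
                s: kept.get(s, StrainCall(False)) for s in STRAINS
            }
            survivors.append(
                VariantSite(
                    site.contig_id, site.pos0, site.ref_allele,
                    site.alt_alleles, site.qual, per_strain,
                )
            )
    second = apply_quality_filters(survivors, crit, STRAINS)
    assert second.retained == first.retained


class TestUniqueSites:
    def test_location_level_uniqueness(self):
        sites = [
            make_site(1, 50.0, {s: (9, 4, 90) for s in STRAINS}),
            make_site(2, 50.0, {"LVP": (9, 4, 90)}, alts=("G",)),
            make_site(2, 50.0, {"CTM": (9, 4, 90)}, alts=("T",)),
        ]
        cs = apply_quality_filters(sites, FilterCriteria(), STRAINS)
        assert unique_polymorphic_sites(cs) == {("c", 1), ("c", 2)}

    def test_matches_union_cardinality(self):
        rng = np.random.default_rng(13)
        sites = random_sites(rng, 800)
        cs = apply_quality_filters(sites, FilterCriteria(), STRAINS)
        brute = set()
        for s in STRAINS:
            brute |= {(c, p) for c, p, _ in brute_force(sites, FilterCriteria())[s]}
        assert unique_polymorphic_sites(cs) == brute

    def test_simulator_truth(self, sim):
        cs = apply_quality_filters(
            sim.sites, FilterCriteria(), sim.config.strains
        )
        assert cs.retained == sim.truth.retained
        truth_unique = set()
        for s in sim.truth.retained:
            truth_unique |= {(c, p) for c, p, _ in sim.truth.retained[s]}
        assert unique_polymorphic_sites(cs) == truth_unique
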
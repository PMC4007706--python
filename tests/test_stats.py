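"""Density statistics: arithmetic identities, paired-test behaviour,
correlations and the zero-polymorphism report."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from txsnp import stats as tstats

STRAINS = ("LVP", "CTM", "RexD")


class TestDensity:
    def test_sites_per_kb_arithmetic(self):
        recs = tstats.ps_density(
            {"LVP": {("c", i) for i in range(10)}},
            {"g": 2000},
            {("c", i): ["g"] for i in range(10)},
        )
        gene = next(r for r in recs if r.scope == "gene")
        assert gene.ps_per_kb == 5.0

    def test_aggregate_weighted_identity(self, report):
        df = report.density
        for s in STRAINS:
            genes = df[(df.scope == "gene") & (df.strain == s)]
            agg = df[(df.scope == "strain") & (df.strain == s)].iloc[0]
            assert agg.n_ps == genes.n_ps.sum()
            assert agg.ps_per_kb == pytest.approx(
                genes.n_ps.sum() / genes.length_kb.sum()
            )

    def test_matches_brute_force_counts(self):
        rng = np.random.default_rng(4)
        lengths = {f"g{i}": int(rng.integers(500, 3000)) for i in range(20)}
        loc_map = {}
        locs = set()
        for i in range(300):
            loc = ("c", i)
            owners = list(
                rng.choice(list(lengths), int(rng.integers(1, 3)), replace=False)
            )
            loc_map[loc] = owners
            if rng.random() < 0.7:
                locs.add(loc)
        recs = tstats.ps_density({"LVP": locs}, lengths, loc_map)
        for r in recs:
            if r.scope == "gene":
                brute = sum(1 for loc in locs if r.unit_id in loc_map[loc])
                assert r.n_ps == brute
                assert r.ps_per_kb == brute / (lengths[r.unit_id] / 1000)

    def test_density_fold_from_reported_values(self):
        fold = tstats.density_fold(
            {"LVP": 5.05, "CTM": 9.13, "RexD": 9.43}, "LVP"
        )
        assert round(fold, 1) == 1.8


class TestPairedComparison:
    def test_identical_vectors_null_by_convention(self):
        d = {f"sc{i}": float(i) for i in range(20)}
        res = tstats.compare_density_distributions(d, dict(d))
        assert res.p_value == 1.0
        assert not res.significant

    def test_too_few_pairs_errors(self):
        d = {f"sc{i}": 1.0 for i in range(5)}
        with pytest.raises(ValueError, match="shared supercontigs"):
            tstats.compare_density_distributions(d, d)

    def test_restricted_to_shared_supercontigs(self):
        rng = np.random.default_rng(0)
        a = {f"sc{i}": float(rng.gamma(4, 2)) for i in range(30)}
        b = {f"sc{i}": float(rng.gamma(4, 2)) for i in range(15, 45)}
        res = tstats.compare_density_distributions(a, b)
        assert res.n_pairs == 15

    def test_symmetry_preserves_p_value(self):
        rng = np.random.default_rng(1)
        a = {f"sc{i}": float(rng.gamma(4, 2)) for i in range(40)}
        b = {f"sc{i}": float(rng.gamma(4, 2)) for i in range(40)}
        r1 = tstats.compare_density_distributions(a, b, "A", "B")
        r2 = tstats.compare_density_distributions(b, a, "B", "A")
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = {f"sc{i}": float(rng.gamma(4, 2)) for i in range(100)}
            b = {k: v + 2.0 for k, v in a.items()}
            res = tstats.compare_density_distributions(a, b, alpha=0.01)
            assert res.significant


class TestCorrelations:
    def test_perfect_linearity_r2_one(self):
        ann = {f"sc{i}": 2 * i + 2 for i in range(10)}
        snp = {f"sc{i}": i + 1 for i in range(10)}
        assert tstats.gene_count_correlation(ann, snp) == pytest.approx(1.0)

    def test_constant_counts_undefined(self):
        ann = {f"sc{i}": i + 1 for i in range(10)}
        snp = {f"sc{i}": 3 for i in range(10)}
        assert math.isnan(tstats.gene_count_correlation(ann, snp))

    def test_matches_pearson_squared_oracle(self):
        rng = np.random.default_rng(3)
        ann = {f"sc{i}": int(rng.integers(1, 40)) for i in range(50)}
        snp = {f"sc{i}": int(rng.integers(0, 30)) for i in range(50)}
        x = np.array([ann[k] for k in ann], dtype=float)
        y = np.array([snp[k] for k in ann], dtype=float)
        r = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum())
            * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert tstats.gene_count_correlation(ann, snp) == pytest.approx(r * r)

    def test_fpkm_association_null_and_planted(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(200)]
        fpkm = {g: float(rng.uniform(1, 300)) for g in genes}
        dens_null = {g: float(rng.gamma(4, 2)) for g in genes}
        rho0, _ = tstats.density_fpkm_association(dens_null, fpkm)
        assert abs(rho0) < 0.2
        dens_dep = {g: fpkm[g] / 20 + float(rng.gamma(2, 0.5)) for g in genes}
        rho1, p1 = tstats.density_fpkm_association(dens_dep, fpkm)
        assert rho1 > 0.5 and p1 < 0.01

    def test_single_gene_errors(self):
        with pytest.raises(ValueError):
            tstats.density_fpkm_association({"g": 1.0}, {"g": 2.0})


class TestZeroPolymorphism:
    def test_definitions(self):
        out = tstats.zero_polymorphism_genes(
            ["a", "b", "c"], {"a": [("c", 1)], "b": []}
        )
        assert out == ["b", "c"]

    def test_matches_planted_truth(self, sim, report):
        truth_with_sites = set()
        retained_any = set().union(*sim.truth.retained.values())
        for _, row in sim.truth.variant_records.iterrows():
            if (row.contig, row.pos - 1, row.alt) in retained_any:
                truth_with_sites.add(row.gene_id)
        expected = sorted(sim.truth.snp_genes - truth_with_sites)
        assert report.zero_polymorphism == expected
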
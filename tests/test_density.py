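"""Density arithmetic and cross-sample set algebra."""

import numpy as np
import pytest

from halomet import (
    cluster_density,
    compare_samples,
    function_density,
    screen,
    shared_taxa,
)
from halomet.density import DensityError
from halomet.screening import SampleProfile, ScreeningError

from conftest import make_table


def _profile(catalog, counts, size_bp=1_000_000, sample_id="S1"):
    ec_lists = [[ec] for ec, n in counts.items() for _ in range(n)]
    return screen(make_table(ec_lists, sample_id=sample_id, size_bp=size_bp), catalog)


class TestFunctionDensity:
    def test_simple_ratio(self, catalog):
        profile = _profile(catalog, {"3.8.1.5": 10}, size_bp=5_000_000)
        (rec,) = function_density(profile)
        assert rec.density == 2.0 and rec.n_genes == 10

    def test_empty_profile_sparse_vs_dense(self, catalog):
        profile = _profile(catalog, {})
        assert function_density(profile) == []
        dense = function_density(profile, catalog, dense=True)
        assert len(dense) == len(catalog)
        assert all(r.density == 0.0 for r in dense)

    def test_densities_match_division_oracle(self, catalog):
        rng = np.random.default_rng(5)
        ecs = ["3.8.1.5", "3.8.1.2", "1.14.19.9", "2.5.1.18", "1.3.1.103",
               "1.21.99.5", "1.8.5.7"]
        counts = {ec: int(rng.integers(1, 40)) for ec in ecs}
        profile = _profile(catalog, counts, size_bp=3_200_000)
        for rec in function_density(profile):
            assert rec.density == counts[rec.key] / 3.2

    def test_display_rounding_configurable(self, catalog):
        profile = _profile(catalog, {"3.8.1.5": 1}, size_bp=3_000_000)
        assert function_density(profile, decimals=2)[0].density_display == 0.33
        assert function_density(profile, decimals=4)[0].density_display == 0.3333

    def test_zero_density_iff_zero_genes(self, catalog):
        profile = _profile(catalog, {"3.8.1.5": 3})
        for rec in function_density(profile, catalog, dense=True):
            assert (rec.density == 0.0) == (rec.n_genes == 0)

    def test_non_positive_size_rejected(self, catalog):
        profile = SampleProfile("bad", "metagenome", 0.0, {},
                                catalog_checksum=catalog.checksum)
        with pytest.raises(DensityError):
            function_density(profile)


class TestClusterDensity:
    def test_cluster_count_sums_members(self, catalog):
        # D7 (chloroacrylate) members include 1.3.1.103 and 3.8.1.2
        profile = _profile(catalog, {"1.3.1.103": 3, "3.8.1.2": 2}, size_bp=1_000_000)
        by_key = {r.key: r for r in cluster_density(profile, catalog)}
        assert by_key["D7"].density == 5.0

    def test_shared_ec_contributes_to_every_cluster(self, catalog):
        profile = _profile(catalog, {"3.8.1.2": 4})
        by_key = {r.key: r for r in cluster_density(profile, catalog)}
        for cid in catalog.get("3.8.1.2").cluster_ids:
            assert by_key[cid].n_genes == 4

    def test_all_clusters_emitted_even_when_zero(self, catalog):
        profile = _profile(catalog, {})
        records = cluster_density(profile, catalog)
        assert len(records) == 32
        assert all(r.density == 0.0 for r in records)

    def test_additivity_over_member_functions(self, catalog):
        rng = np.random.default_rng(17)
        counts = {ec: int(rng.integers(0, 25)) for ec in sorted(catalog.ecs)
                  if not ec.startswith("8.")}
        profile = _profile(catalog, {k: v for k, v in counts.items() if v},
                           size_bp=7_300_000)
        func = {r.key: r.density for r in function_density(profile, catalog, dense=True)}
        for rec in cluster_density(profile, catalog):
            member_sum = sum(func[ec] for ec in catalog.cluster(rec.key).member_ecs)
            assert rec.density == pytest.approx(member_sum, rel=1e-12)

    def test_doubling_size_halves_density_exactly(self, catalog):
        counts = {"3.8.1.5": 6, "1.14.19.9": 3}
        p1 = _profile(catalog, counts, size_bp=2_000_000)
        p2 = _profile(catalog, counts, size_bp=4_000_000)
        d1 = {r.key: r.density for r in function_density(p1)}
        d2 = {r.key: r.density for r in function_density(p2)}
        assert all(d2[k] == d1[k] / 2 for k in d1)


def _brute_force_sets(sets):
    inter = set(sets[0])
    union = set()
    for s in sets:
        inter &= set(s)
        union |= set(s)
    return inter, union


class TestCompareSamples:
    def test_worked_three_sample_case(self, catalog):
        a, b, c, d = "3.8.1.5", "3.8.1.2", "1.14.19.9", "2.5.1.18"
        profiles = [
            _profile(catalog, {a: 1, b: 1, c: 1}, sample_id="S1"),
            _profile(catalog, {b: 1, c: 1, d: 1}, sample_id="S2"),
            _profile(catalog, {b: 2, c: 3}, sample_id="S3"),
        ]
        report = compare_samples(profiles)
        assert len(report.intersection) == 2
        assert len(report.union) == 4
        assert report.shared_fraction == 0.5
        assert report.pairwise_shared[("S1", "S2")] == {b, c}

    def test_identical_and_disjoint_extremes(self, catalog):
        same = [_profile(catalog, {"3.8.1.5": 1}, sample_id=s) for s in ("A", "B")]
        assert compare_samples(same).shared_fraction == 1.0
        disjoint = [
            _profile(catalog, {"3.8.1.5": 1}, sample_id="A"),
            _profile(catalog, {"1.14.19.9": 1}, sample_id="B"),
        ]
        assert compare_samples(disjoint).shared_fraction == 0.0

    def test_matches_brute_force_on_random_triples(self, catalog):
        rng = np.random.default_rng(23)
        pool = sorted(catalog.ecs)
        for _ in range(100):
            sets = [
                set(rng.choice(pool, size=rng.integers(0, 12), replace=False))
                for _ in range(3)
            ]
            profiles = [
                _profile(catalog, {ec: 1 for ec in s}, sample_id=f"S{i}")
                for i, s in enumerate(sets)
            ]
            report = compare_samples(profiles)
            inter, union = _brute_force_sets(sets)
            assert report.intersection == inter
            assert report.union == union

    def test_cluster_level_presence(self, catalog):
        profiles = [
            _profile(catalog, {"1.3.1.103": 1}, sample_id="A"),  # D7 member
            _profile(catalog, {"3.8.1.9": 2}, sample_id="B"),  # D7 member too
        ]
        report = compare_samples(profiles, level="cluster", catalog=catalog)
        assert "D7" in report.intersection

    def test_mixed_catalogs_rejected(self, catalog):
        p1 = _profile(catalog, {"3.8.1.5": 1}, sample_id="A")
        p2 = _profile(catalog, {"3.8.1.5": 1}, sample_id="B")
        p2.catalog_checksum = "other"
        with pytest.raises(ScreeningError):
            compare_samples([p1, p2])

    def test_needs_two_profiles(self, catalog):
        with pytest.raises(DensityError):
            compare_samples([_profile(catalog, {})])


class TestSharedTaxa:
    def test_phylum_example(self):
        report, table = shared_taxa(
            {"A": ["P1", "P2"], "B": ["P2", "P3"], "C": ["P2"]}
        )
        assert report.intersection == {"p2"}
        assert len(report.union) == 3
        mask = table.set_index(["sample", "taxon"])["shared_with_mask"]
        assert mask[("A", "p2")] == "A|B|C"

    def test_empty_sample_warns_and_counts_as_empty(self):
        with pytest.warns(UserWarning, match="no taxon labels"):
            report, _ = shared_taxa({"A": ["P1"], "B": []})
        assert report.intersection == set()
        assert report.union == {"p1"}

    def test_three_identical_nine_phylum_sets(self):
        phyla = [f"Phylum{i}" for i in range(9)]
        report, _ = shared_taxa({s: list(phyla) for s in ("A", "B", "C")})
        assert len(report.intersection) == 9
        assert report.shared_fraction == 1.0

    def test_labels_normalised_before_comparison(self):
        report, _ = shared_taxa({"A": ["  Proteobacteria "], "B": ["proteobacteria"]})
        assert report.shared_fraction == 1.0
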
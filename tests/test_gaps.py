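"""Barcode-gap reports, target-specific gap test and distance-matrix PCA."""

import numpy as np
import pandas as pd
import pytest

import cladegap as cg
from cladegap.distances import DistanceMatrix
from cladegap.gaps import (
    closest_relatives,
    gap_report,
    pca_scatter,
    pcoa_scatter,
    target_gap,
)
from cladegap import SpeciesMap


def block_matrix(ids, species, within=0.01, between=0.10):
    """Distance matrix where conspecific pairs sit at ``within`` and
    heterospecific pairs at ``between``."""
    n = len(ids)
    vals = np.full((n, n), between)
    for i in range(n):
        for j in range(n):
            if species[ids[i]] == species[ids[j]]:
                vals[i, j] = within
        vals[i, i] = 0.0
    return DistanceMatrix(ids, vals)


@pytest.fixture
def two_species():
    ids = ["a1", "a2", "b1", "b2"]
    species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    sp_map = SpeciesMap({i: (species[i], "c1") for i in ids})
    return ids, species, sp_map


class TestGapReport:
    def test_clean_gap_has_zero_overlap(self, two_species):
        ids, species, sp_map = two_species
        dm = block_matrix(ids, species)
        rep = gap_report(dm, sp_map)
        assert rep.overlap_fraction == 0.0
        assert len(rep.intra) == 2 and len(rep.inter) == 4

    def test_pair_count_conservation(self, small_library):
        lib, _ = small_library
        dm = cg.distance_matrix(lib.combined())
        rep = gap_report(dm, lib.species_map)
        n = len(lib.species_map.ingroup_individuals)
        assert len(rep.intra) + len(rep.inter) == n * (n - 1) // 2

    def test_overlapping_pair_detected(self, two_species):
        ids, species, sp_map = two_species
        dm = block_matrix(ids, species)
        vals = dm.values.copy()
        vals[0, 2] = vals[2, 0] = 0.005  # one inter pair below max intra
        rep = gap_report(DistanceMatrix(ids, vals), sp_map)
        assert rep.overlap_fraction == pytest.approx(0.25)

    def test_hand_enumerated_classification(self):
        ids = ["a1", "a2", "b1", "c1"]
        sp_map = SpeciesMap(
            {"a1": ("A", "c1"), "a2": ("A", "c1"), "b1": ("B", "c1"), "c1": ("C", "c2")}
        )
        vals = np.array(
            [
                [0.00, 0.01, 0.05, 0.20],
                [0.01, 0.00, 0.06, 0.21],
                [0.05, 0.06, 0.00, 0.22],
                [0.20, 0.21, 0.22, 0.00],
            ]
        )
        rep = gap_report(DistanceMatrix(ids, vals), sp_map)
        assert rep.intra == [("A", 0.01)]
        assert sorted(d for *_, d in rep.inter) == [0.05, 0.06, 0.20, 0.21, 0.22]

    def test_all_singletons_overlap_undefined(self):
        ids = ["a1", "b1", "c1"]
        sp_map = SpeciesMap({i: (i[0].upper(), "c1") for i in ids})
        vals = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        rep = gap_report(DistanceMatrix(ids, vals), sp_map)
        assert rep.intra == []
        assert np.isnan(rep.overlap_fraction)


class TestTargetGap:
    def test_gap_present(self, two_species):
        ids, species, sp_map = two_species
        dm = block_matrix(ids, species, within=0.004, between=0.020)
        rep = target_gap(dm, sp_map, "A", relatives=["B"])
        assert rep.max_intra == pytest.approx(0.004)
        assert rep.min_inter == pytest.approx(0.020)
        assert rep.gap_exists is True

    def test_only_target_to_relative_distances_count(self, two_species):
        # a tight pair *within the relative* must not close the gap; only a
        # target-to-relative distance below the target's own spread does
        ids, species, sp_map = two_species
        dm = block_matrix(ids, species, within=0.004, between=0.020)
        vals = dm.values.copy()
        vals[2, 3] = vals[3, 2] = 0.001  # within relative B: irrelevant
        assert target_gap(DistanceMatrix(ids, vals), sp_map, "A", relatives=["B"]).gap_exists
        vals[0, 2] = vals[2, 0] = 0.003  # target-to-relative below max intra
        rep = target_gap(DistanceMatrix(ids, vals), sp_map, "A", relatives=["B"])
        assert rep.gap_exists is False

    def test_scale_invariance(self, two_species):
        ids, species, sp_map = two_species
        dm = block_matrix(ids, species, within=0.004, between=0.020)
        for c in (0.1, 1.0, 37.0):
            scaled = DistanceMatrix(ids, dm.values * c)
            assert target_gap(scaled, sp_map, "A", relatives=["B"]).gap_exists is True

    def test_singleton_target_advisory(self):
        ids = ["a1", "b1", "b2"]
        sp_map = SpeciesMap({"a1": ("A", "c1"), "b1": ("B", "c1"), "b2": ("B", "c1")})
        vals = np.array([[0, 0.02, 0.02], [0.02, 0, 0.004], [0.02, 0.004, 0]])
        rep = target_gap(DistanceMatrix(ids, vals), sp_map, "A", relatives=["B"])
        assert np.isnan(rep.max_intra)
        assert rep.gap_exists is None
        assert rep.advisory is not None

    def test_histogram_counts_sum_to_pair_counts(self, two_species):
        ids, species, sp_map = two_species
        dm = block_matrix(ids, species)
        rep = target_gap(dm, sp_map, "A", relatives=["B"])
        assert rep.histogram["count_intra"].sum() == 1  # one within-target pair
        assert rep.histogram["count_inter"].sum() == 4

    def test_auto_relatives_recovers_simulated_sisters(self, small_library):
        lib, _ = small_library
        sp_map = lib.species_map
        dm = cg.distance_matrix(lib.combined())
        target = "sp_c1_1"
        rels = closest_relatives(dm, sp_map, target, k=2)
        # the two closest relatives must be the other members of clade 1
        assert set(rels) <= {"sp_c1_2", "sp_c1_3"}
        assert len(rels) == 2

    def test_auto_mode_used_by_target_gap(self, small_library):
        lib, _ = small_library
        dm = cg.distance_matrix(lib.combined())
        rep = target_gap(dm, lib.species_map, "sp_c1_1", relatives="auto")
        assert set(rep.relatives) == {"sp_c1_2", "sp_c1_3"}


class TestPca:
    def test_identical_profiles_identical_coordinates(self):
        ids = ["a", "b", "c", "d"]
        vals = np.array(
            [
                [0.0, 0.0, 0.3, 0.3],
                [0.0, 0.0, 0.3, 0.3],
                [0.3, 0.3, 0.0, 0.1],
                [0.3, 0.3, 0.1, 0.0],
            ]
        )
        res = pca_scatter(DistanceMatrix(ids, vals))
        assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["b"])

    def test_eigenvalues_sorted_and_sum_to_total_variance(self, small_library):
        lib, _ = small_library
        dm = cg.distance_matrix(lib.combined())
        res = pca_scatter(dm)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        total_var = dm.values.var(axis=0, ddof=1).sum()
        assert res.eigenvalues.sum() == pytest.approx(total_var)

    def test_three_clusters_separate_on_leading_components(self):
        rng = np.random.default_rng(8)
        ids, species = [], {}
        for c, lab in enumerate("ABC"):
            for k in range(4):
                i = f"{lab}{k}"
                ids.append(i)
                species[i] = lab
        base = {"A": 0.0, "B": 0.4, "C": 0.8}
        n = len(ids)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                si, sj = species[ids[i]], species[ids[j]]
                d = abs(base[si] - base[sj]) + rng.uniform(0.001, 0.01)
                vals[i, j] = vals[j, i] = d
        res = pca_scatter(DistanceMatrix(ids, vals))
        pts = res.coordinates[["PC1", "PC2"]].to_numpy()
        within, between = [], []
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(pts[i] - pts[j])
                (within if species[ids[i]] == species[ids[j]] else between).append(d)
        assert max(within) < min(between)

    def test_constant_matrix_collapses_to_origin(self):
        ids = ["a", "b", "c"]
        res = pca_scatter(DistanceMatrix(ids, np.zeros((3, 3))))
        assert np.allclose(res.coordinates.to_numpy(), 0)
        assert np.allclose(res.eigenvalues, 0)

    def test_pcoa_is_a_different_ordination(self, small_library):
        lib, _ = small_library
        dm = cg.distance_matrix(lib.combined())
        a = pca_scatter(dm).coordinates.iloc[:, 0].to_numpy()
        b = pcoa_scatter(dm).coordinates.iloc[:, 0].to_numpy()
        # same individuals, different method: coordinates differ beyond sign
        assert not np.allclose(np.abs(a), np.abs(b), atol=1e-6)
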
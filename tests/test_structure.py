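"""AMOVA, Nei distance, clustering and Mantel tests."""

import math

import numpy as np
import pytest

from genecapture.errors import UndefinedStatisticError
from genecapture.io import AlleleFrequencyTable, MISSING, Role
from genecapture.structure import (
    DistanceMatrix,
    amova,
    amova_permutation_test,
    geographic_distance_matrix,
    hierarchical_clustering,
    mantel_test,
    nei_distance_matrix,
    pairwise_mismatch_distances,
)

from conftest import make_dataset


def amova_oracle(d: np.ndarray, labels: list[str]):
    """Definitional sums-of-squares decomposition, written independently:
    explicit loops over pairs, no shared code with the implementation."""
    n = len(labels)
    d2 = d**2
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d2[i, j]
    ss_total /= n
    groups = sorted(set(labels))
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        sub = 0.0
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                sub += d2[i, j]
        ss_within += sub / len(idx)
    ss_among = ss_total - ss_within
    df_a = len(groups) - 1
    df_w = n - len(groups)
    ms_a = ss_among / df_a
    ms_w = ss_within / df_w
    sizes = [labels.count(g) for g in groups]
    n0 = (n - sum(s**2 for s in sizes) / n) / df_a
    s2_w = ms_w
    s2_a = max(0.0, (ms_a - ms_w) / n0)
    phi = s2_a / (s2_a + s2_w)
    return ss_among, ss_within, s2_a, s2_w, phi


class TestMismatchDistance:
    def test_locus_scores(self):
        rows = [
            ("s1", "p", Role.POPULATION, None, {"L1": (1, 2), "L2": (1, 1), "L3": (1, 2)}),
            ("s2", "p", Role.POPULATION, None, {"L1": (2, 1), "L2": (3, 3), "L3": (1, 3)}),
        ]
        ds = make_dataset(rows, ["L1", "L2", "L3"])
        d = pairwise_mismatch_distances(ds.samples, ds.loci)
        # identical (0) + disjoint (2) + one shared (1) = 3
        assert d[0, 1] == pytest.approx(3.0)

    def test_missing_loci_rescaled(self):
        rows = [
            ("s1", "p", Role.POPULATION, None, {"L1": (1, 1), "L2": (MISSING, MISSING)}),
            ("s2", "p", Role.POPULATION, None, {"L1": (2, 2), "L2": (1, 1)}),
        ]
        ds = make_dataset(rows, ["L1", "L2"])
        d = pairwise_mismatch_distances(ds.samples, ds.loci)
        assert d[0, 1] == pytest.approx(2 * 2 / 1)  # d=2 over 1 locus, x L/L_comp
        d_raw = pairwise_mismatch_distances(ds.samples, ds.loci,
                                            rescale_missing=False)
        assert d_raw[0, 1] == pytest.approx(2.0)


class TestAmova:
    def _clonal_two_pop(self):
        rows = [
            ("a1", "A", Role.POPULATION, None, {"L1": (1, 1), "L2": (1, 1)}),
            ("a2", "A", Role.POPULATION, None, {"L1": (1, 1), "L2": (1, 1)}),
            ("a3", "A", Role.POPULATION, None, {"L1": (1, 1), "L2": (1, 1)}),
            ("b1", "B", Role.POPULATION, None, {"L1": (2, 2), "L2": (2, 2)}),
            ("b2", "B", Role.POPULATION, None, {"L1": (2, 2), "L2": (2, 2)}),
            ("b3", "B", Role.POPULATION, None, {"L1": (2, 2), "L2": (2, 2)}),
        ]
        return make_dataset(rows, ["L1", "L2"])

    def test_clonal_populations_full_structure(self):
        res = amova(self._clonal_two_pop())
        assert res.phi == pytest.approx(1.0)
        assert res.percent_within == pytest.approx(0.0)

    def test_duplicated_population_no_structure(self):
        rows = []
        calls = [{"L1": (1, 1)}, {"L1": (1, 2)}, {"L1": (2, 2)}, {"L1": (1, 2)}]
        for pop in ("A", "B"):
            for i, c in enumerate(calls):
                rows.append((f"{pop}{i}", pop, Role.POPULATION, None, dict(c)))
        res = amova(make_dataset(rows, ["L1"]))
        assert res.phi == pytest.approx(0.0, abs=1e-9)
        assert res.percent_within == pytest.approx(100.0, abs=1e-6)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(15):
            n_per = [int(rng.integers(2, 5)) for _ in range(3)]
            rows = []
            for p, n in zip("ABC", n_per):
                for i in range(n):
                    calls = {
                        f"L{j}": tuple(sorted(rng.integers(1, 4, size=2)))
                        for j in range(4)
                    }
                    rows.append((f"{p}{i}", p, Role.POPULATION, None, calls))
            ds = make_dataset(rows, [f"L{j}" for j in range(4)])
            d = pairwise_mismatch_distances(ds.samples, ds.loci)
            labels = [s.population for s in ds.samples]
            try:
                res = amova(ds)
            except UndefinedStatisticError:
                continue
            ss_a, ss_w, s2_a, s2_w, phi = amova_oracle(d, labels)
            assert res.ss_among == pytest.approx(ss_a, abs=1e-9)
            assert res.ss_within == pytest.approx(ss_w, abs=1e-9)
            assert res.sigma2_among == pytest.approx(s2_a, abs=1e-9)
            assert res.sigma2_within == pytest.approx(s2_w, abs=1e-9)
            assert res.phi == pytest.approx(phi, abs=1e-9)

    def test_identical_samples_undefined(self):
        rows = [(f"s{i}", "AB"[i % 2], Role.POPULATION, None, {"L1": (1, 1)})
                for i in range(4)]
        with pytest.raises(UndefinedStatisticError):
            amova(make_dataset(rows, ["L1"]))

    def test_single_sample_population_rejected(self):
        rows = [
            ("a1", "A", Role.POPULATION, None, {"L1": (1, 1)}),
            ("a2", "A", Role.POPULATION, None, {"L1": (1, 2)}),
            ("b1", "B", Role.POPULATION, None, {"L1": (2, 2)}),
        ]
        with pytest.raises(ValueError, match="single sample"):
            amova(make_dataset(rows, ["L1"]))

    def test_permutation_p_for_maximal_structure(self):
        res = amova_permutation_test(self._clonal_two_pop(),
                                     n_permutations=99, rng_seed=0)
        # phi_obs = 1; permutations can only tie when they reproduce the
        # exact partition: p is small but never zero
        assert res.p_value <= 0.11
        assert res.p_value >= 1 / 100

    def test_p_never_zero(self):
        res = amova_permutation_test(self._clonal_two_pop(),
                                     n_permutations=19, rng_seed=1)
        assert res.p_value > 0


class TestNeiDistance:
    def _tables(self, fx, fy):
        return [
            AlleleFrequencyTable("X", {"L1": fx}, {"L1": 10}),
            AlleleFrequencyTable("Y", {"L1": fy}, {"L1": 10}),
        ]

    def test_identical_tables_zero(self):
        dm = nei_distance_matrix(self._tables({1: 0.5, 2: 0.5}, {1: 0.5, 2: 0.5}))
        assert dm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        dm = nei_distance_matrix(self._tables({1: 0.5, 2: 0.5}, {1: 1.0}))
        assert dm.matrix[0, 1] == pytest.approx(0.346574, abs=1e-6)

    def test_disjoint_alleles_infinite_flagged(self):
        dm = nei_distance_matrix(self._tables({1: 1.0}, {2: 1.0}))
        assert math.isinf(dm.matrix[0, 1])
        assert dm.has_infinite

    def test_symmetry_and_relabelling_invariance(self):
        ta = AlleleFrequencyTable("X", {"L1": {1: 0.3, 2: 0.7}}, {"L1": 20})
        tb = AlleleFrequencyTable("Y", {"L1": {1: 0.6, 2: 0.4}}, {"L1": 20})
        d1 = nei_distance_matrix([ta, tb]).matrix[0, 1]
        # relabel alleles 1<->2 in both tables
        ta2 = AlleleFrequencyTable("X", {"L1": {2: 0.3, 1: 0.7}}, {"L1": 20})
        tb2 = AlleleFrequencyTable("Y", {"L1": {2: 0.6, 1: 0.4}}, {"L1": 20})
        d2 = nei_distance_matrix([ta2, tb2]).matrix[0, 1]
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestClustering:
    def _dmat(self, labels, entries):
        n = len(labels)
        m = np.zeros((n, n))
        for (i, j), v in entries.items():
            m[i, j] = m[j, i] = v
        return DistanceMatrix(labels=tuple(labels), matrix=m, metric="test")

    def test_hand_agglomeration(self):
        dm = self._dmat("ABC", {(0, 1): 1.0, (0, 2): 5.0, (1, 2): 5.0})
        dendro = hierarchical_clustering(dm)
        heights = sorted(dendro.merge_heights())
        assert heights == pytest.approx([1.0, 5.0])
        nwk = dendro.to_newick()
        assert nwk.endswith(";") and "A" in nwk and "C" in nwk

    def test_ultrametric_heights_reproduced(self):
        dm = self._dmat("ABCD", {(0, 1): 2.0, (2, 3): 2.0, (0, 2): 6.0,
                                 (0, 3): 6.0, (1, 2): 6.0, (1, 3): 6.0})
        dendro = hierarchical_clustering(dm)
        assert sorted(dendro.merge_heights()) == pytest.approx([2.0, 2.0, 6.0])

    def test_label_permutation_leaves_heights(self):
        dm1 = self._dmat("ABC", {(0, 1): 1.0, (0, 2): 4.0, (1, 2): 3.0})
        dm2 = self._dmat("CBA", {(2, 1): 1.0, (2, 0): 4.0, (1, 0): 3.0})
        h1 = sorted(hierarchical_clustering(dm1).merge_heights())
        h2 = sorted(hierarchical_clustering(dm2).merge_heights())
        assert h1 == pytest.approx(h2)

    def test_infinite_entries_refused(self):
        dm = self._dmat("AB", {(0, 1): math.inf})
        with pytest.raises(ValueError, match="infinite"):
            hierarchical_clustering(dm)

    def test_newick_parses_with_dendropy(self):
        import dendropy

        dm = self._dmat("ABCD", {(0, 1): 1.0, (2, 3): 2.0, (0, 2): 6.0,
                                 (0, 3): 6.0, (1, 2): 6.0, (1, 3): 6.0})
        nwk = hierarchical_clustering(dm).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set("ABCD")


class TestMantel:
    def _mat(self, labels, m):
        return DistanceMatrix(labels=tuple(labels), matrix=np.asarray(m, float),
                              metric="test")

    def test_affine_relation_r_one(self):
        a = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        b = 2 * a + 3
        np.fill_diagonal(b, 0)
        res = mantel_test(self._mat("ABC", a), self._mat("ABC", b),
                          n_permutations=99, rng_seed=0)
        assert res.r == pytest.approx(1.0)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(2)
        n = 5
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.random((n, n))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        labels = tuple("ABCDE")
        r1 = mantel_test(self._mat(labels, a), self._mat(labels, b),
                         n_permutations=9, rng_seed=0).r
        perm = [3, 1, 4, 0, 2]
        a2 = a[np.ix_(perm, perm)]
        b2 = b[np.ix_(perm, perm)]
        labels2 = tuple(labels[i] for i in perm)
        r2 = mantel_test(self._mat(labels2, a2), self._mat(labels2, b2),
                         n_permutations=9, rng_seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_r_agrees_with_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel

        rng = np.random.default_rng(4)
        n = 6
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = a + rng.normal(0, 0.1, (n, n))
        b = np.abs((b + b.T) / 2)
        np.fill_diagonal(b, 0)
        labels = tuple("ABCDEF")
        mine = mantel_test(self._mat(labels, a), self._mat(labels, b),
                           n_permutations=99, rng_seed=0)
        r_ref, _, _ = mantel(SkbioDM(a), SkbioDM(b), method="pearson",
                             permutations=0)
        assert mine.r == pytest.approx(float(r_ref), abs=1e-9)

    def test_detects_simulated_isolation_by_distance(self):
        from genecapture.io import allele_frequencies, group_samples, pool
        from genecapture.simulate import SimulationConfig, simulate_dataset

        hits = 0
        n_rep = 12
        for seed in range(n_rep):
            config = SimulationConfig(
                n_loci=12, alleles_per_locus=6, regional_alpha=0.8,
                n_populations=6, theta=0.35, n_adults_per_pop=12,
                seeds_per_bunch=2, spatial_gradient=True, rng_seed=seed,
            )
            ds, _ = simulate_dataset(config)
            pops = pool(ds, Role.POPULATION)
            gen = nei_distance_matrix(allele_frequencies(pops, "population"))
            coords = {
                label: (members[0].latitude, members[0].longitude)
                for label, members in group_samples(pops, "population").items()
            }
            geo = geographic_distance_matrix(gen.labels, coords)
            res = mantel_test(geo, gen, n_permutations=199, rng_seed=seed)
            hits += res.p <= 0.05
        assert hits >= int(0.7 * n_rep)

    def test_label_mismatch_rejected(self):
        a = self._mat("ABC", np.zeros((3, 3)))
        b = self._mat("ABD", np.zeros((3, 3)))
        with pytest.raises(ValueError):
            mantel_test(a, b)
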
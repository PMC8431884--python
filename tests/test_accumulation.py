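"""Incidence matrices, richness extrapolation, accumulation curves."""

import itertools

import numpy as np
import pytest

from genecapture.accumulation import (
    AccumulationCurve,
    IncidenceMatrix,
    RichnessEstimate,
    accumulation_curve,
    allele_membership,
    build_incidence,
    extrapolate_total_richness,
    incidences_per_bunch,
    units_to_threshold,
)
from genecapture.errors import EmptyDatasetError
from genecapture.io import Role

from conftest import make_dataset


def incidence_from_sets(unit_sets: dict[str, set]) -> IncidenceMatrix:
    alleles = sorted(set().union(*unit_sets.values()))
    presence = np.array(
        [[a in s for a in alleles] for s in unit_sets.values()], dtype=bool
    )
    return IncidenceMatrix(
        units=tuple(unit_sets),
        alleles=tuple(("L1", a) for a in alleles),
        presence=presence,
    )


def enumerate_mean_curve(inc: IncidenceMatrix) -> np.ndarray:
    """Oracle: average cumulative distinct alleles over ALL n! orderings."""
    n = inc.n_units
    acc = np.zeros(n)
    count = 0
    for order in itertools.permutations(range(n)):
        cum = np.logical_or.accumulate(inc.presence[list(order)], axis=0)
        acc += cum.sum(axis=1)
        count += 1
    return acc / count


class TestBuildIncidence:
    def test_counting(self):
        rows = [
            ("u1", "A", Role.POPULATION, None, {"L1": (1, 2)}),
            ("u2", "B", Role.POPULATION, None, {"L1": (2, 3)}),
        ]
        inc = build_incidence(make_dataset(rows, ["L1"]), "population")
        assert inc.s_obs == 3
        p = inc.incidence_counts() / inc.n_units
        assert sorted(p) == [0.5, 0.5, 1.0]

    def test_bunch_units_need_seeds(self):
        rows = [("u1", "A", Role.POPULATION, None, {"L1": (1, 2)})]
        with pytest.raises(EmptyDatasetError):
            build_incidence(make_dataset(rows, ["L1"]), "bunch")

    def test_presence_semantics_ignore_duplicates(self, two_pop_dataset):
        inc1 = build_incidence(two_pop_dataset, "population")
        dup = make_dataset(
            [
                (s.sample_id + ("x" if i else ""), s.population, s.role,
                 s.bunch_id, dict(s.calls))
                for s in two_pop_dataset.samples if s.role is Role.POPULATION
                for i in range(2)
            ],
            two_pop_dataset.loci,
        )
        inc2 = build_incidence(dup, "population")
        assert inc1.alleles == inc2.alleles
        assert np.array_equal(inc1.presence, inc2.presence)

    def test_per_bunch_seed_incidences(self, two_pop_dataset):
        incs = incidences_per_bunch(two_pop_dataset)
        assert set(incs) == {"bunchA", "bunchB"}
        assert incs["bunchA"].n_units == 2  # two seeds


class TestExtrapolators:
    def test_nothing_unseen(self):
        inc = incidence_from_sets({"u1": {1, 2}, "u2": {1, 2}, "u3": {1, 2}})
        for est in ("bootstrap", "chao2", "jackknife1"):
            assert extrapolate_total_richness(inc, est).s_hat == pytest.approx(2.0)

    def test_bootstrap_closed_form(self):
        # 5 units; one allele in exactly 1 unit, the rest in all 5
        sets = {f"u{i}": {1, 2, 3} for i in range(5)}
        sets["u0"] = {1, 2, 3, 4}
        inc = incidence_from_sets(sets)
        est = extrapolate_total_richness(inc, "bootstrap")
        assert est.s_hat == pytest.approx(4 + 0.8**5)

    def test_chao2_closed_form(self):
        # S_obs=5, q1=2 (alleles 4 and 5), q2=1 (allele 2) -> 5 + 4/2 = 7
        sets = {
            "u1": {1, 2, 3, 4},
            "u2": {1, 2, 3, 5},
            "u3": {1, 3},
        }
        inc = incidence_from_sets(sets)
        est = extrapolate_total_richness(inc, "chao2")
        assert (est.q1, est.q2) == (2, 1)
        assert est.s_hat == pytest.approx(7.0)
        assert est.se is not None and est.se > 0

    def test_chao2_bias_corrected_when_no_doubletons(self):
        sets = {"u1": {1, 2}, "u2": {1, 3}, "u3": {1}}
        inc = incidence_from_sets(sets)  # q1=2, q2=0 (allele 1 is in all 3)
        est = extrapolate_total_richness(inc, "chao2")
        assert est.s_hat == pytest.approx(3 + 2 * 1 / 2)

    def test_jackknife_closed_form(self):
        sets = {"u1": {1, 2}, "u2": {1, 3}, "u3": {1}}
        inc = incidence_from_sets(sets)  # q1 = 2, n = 3
        est = extrapolate_total_richness(inc, "jackknife1")
        assert est.s_hat == pytest.approx(3 + 2 * 2 / 3)

    def test_estimators_never_below_observed(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n_units = int(rng.integers(2, 7))
            n_alleles = int(rng.integers(2, 12))
            presence = rng.random((n_units, n_alleles)) < 0.5
            presence[0, ~presence.any(axis=0)] = True  # every allele somewhere
            inc = IncidenceMatrix(
                units=tuple(f"u{i}" for i in range(n_units)),
                alleles=tuple(("L1", a) for a in range(n_alleles)),
                presence=presence,
            )
            for est in ("bootstrap", "chao2", "jackknife1"):
                assert extrapolate_total_richness(inc, est).s_hat >= inc.s_obs - 1e-12

    def test_unknown_estimator(self):
        inc = incidence_from_sets({"u1": {1}, "u2": {1}})
        with pytest.raises(ValueError, match="unknown estimator"):
            extrapolate_total_richness(inc, "chao3")


class TestAccumulationCurve:
    def test_identical_units_flat_curve(self):
        inc = incidence_from_sets({f"u{i}": {1, 2, 3} for i in range(4)})
        curve = accumulation_curve(inc, n_resamples=50, rng_seed=0)
        assert np.allclose(curve.mean, 3.0)
        assert np.allclose(curve.sd, 0.0)

    def test_exact_two_unit_example(self):
        inc = incidence_from_sets({"u1": {1, 2}, "u2": {2, 3}})
        curve = accumulation_curve(inc, method="exact")
        assert curve.mean[0] == pytest.approx(2.0)
        assert curve.mean[1] == pytest.approx(3.0)

    def test_exact_equals_full_enumeration(self):
        rng = np.random.default_rng(11)
        for n_units in (2, 3, 4, 5, 6):
            presence = rng.random((n_units, 8)) < 0.5
            presence[0, ~presence.any(axis=0)] = True
            inc = IncidenceMatrix(
                units=tuple(f"u{i}" for i in range(n_units)),
                alleles=tuple(("L1", a) for a in range(8)),
                presence=presence,
            )
            exact = accumulation_curve(inc, method="exact")
            oracle = enumerate_mean_curve(inc)
            assert np.allclose(exact.mean, oracle, atol=1e-9)

    def test_random_matches_exact_within_3se(self):
        rng = np.random.default_rng(5)
        presence = rng.random((4, 10)) < 0.4
        presence[0, ~presence.any(axis=0)] = True
        inc = IncidenceMatrix(
            units=tuple(f"u{i}" for i in range(4)),
            alleles=tuple(("L1", a) for a in range(10)),
            presence=presence,
        )
        exact = accumulation_curve(inc, method="exact")
        rand = accumulation_curve(inc, method="random", n_resamples=999, rng_seed=1)
        se = rand.sd / np.sqrt(rand.n_resamples)
        # final step is deterministic (union of all units)
        assert rand.sd[-1] == pytest.approx(0.0)
        inner = slice(0, 3)
        assert np.all(np.abs(rand.mean[inner] - exact.mean[inner])
                      <= 3 * se[inner] + 1e-12)

    def test_normalisation_bounded_by_observed_fraction(self):
        inc = incidence_from_sets({"u1": {1, 2}, "u2": {3, 4}, "u3": {5}})
        curve = accumulation_curve(inc, method="exact", estimator="chao2")
        bound = 100.0 * curve.s_obs / curve.richness.s_hat
        assert np.all(curve.normalized <= bound + 1e-9)

    def test_resample_count_validated(self):
        inc = incidence_from_sets({"u1": {1}, "u2": {1}})
        with pytest.raises(ValueError):
            accumulation_curve(inc, n_resamples=0)


class TestThresholds:
    def _disjoint_curve(self):
        sets = {f"u{i}": {2 * i, 2 * i + 1} for i in range(5)}
        inc = incidence_from_sets(sets)
        richness = RichnessEstimate(s_hat=10.0, s_obs=10, estimator="fixed",
                                    q1=10, q2=0)
        return accumulation_curve(inc, method="exact", richness=richness)

    def test_disjoint_units_need_four_for_seventy(self):
        curve = self._disjoint_curve()
        res = units_to_threshold(curve, targets=(70.0,))
        assert res[70.0].k == 4 and res[70.0].reached

    def test_unobserved_alleles_block_full_capture(self):
        sets = {f"u{i}": {2 * i, 2 * i + 1} for i in range(5)}
        inc = incidence_from_sets(sets)
        curve = accumulation_curve(inc, method="exact")  # bootstrap s_hat > 10
        res = units_to_threshold(curve, targets=(100.0,), extrapolate=False)
        assert not res[100.0].reached and res[100.0].k is None

    def test_extrapolated_target_is_flagged(self):
        sets = {f"u{i}": {2 * i, 2 * i + 1, 100} for i in range(5)}
        inc = incidence_from_sets(sets)
        richness = RichnessEstimate(s_hat=14.0, s_obs=11, estimator="fixed",
                                    q1=0, q2=0)
        curve = accumulation_curve(inc, method="exact", richness=richness)
        res = units_to_threshold(curve, targets=(90.0,))
        assert not res[90.0].reached
        if res[90.0].k is not None:
            assert res[90.0].extrapolated
            assert res[90.0].k > 5

    def test_threshold_monotonicity(self):
        curve = self._disjoint_curve()
        res = units_to_threshold(curve, targets=(20.0, 50.0, 70.0, 90.0))
        ks = [res[t].k for t in (20.0, 50.0, 70.0, 90.0)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))

    def test_invalid_target_rejected(self):
        curve = self._disjoint_curve()
        with pytest.raises(ValueError):
            units_to_threshold(curve, targets=(120.0,))


class TestMembership:
    def test_shared_and_unique(self, two_pop_dataset):
        groups = {
            "A": [s for s in two_pop_dataset.samples if s.population == "A"],
            "B": [s for s in two_pop_dataset.samples if s.population == "B"],
        }
        res = allele_membership(groups, two_pop_dataset.loci)
        # L1: A={101,103}, B={101,105}; L2: A={201,203}, B={201,205}
        assert res.shared_by_all == 2
        assert res.unique == {"A": 2, "B": 2}
        assert res.pairwise_shared.loc["A", "B"] == 2

    def test_nested_group_has_no_unique_alleles(self):
        rows = [
            ("s1", "A", Role.POPULATION, None, {"L1": (1, 2)}),
            ("s2", "B", Role.POPULATION, None, {"L1": (1, 2)}),
            ("s3", "B", Role.POPULATION, None, {"L1": (3, 3)}),
        ]
        ds = make_dataset(rows, ["L1"])
        groups = {
            "inner": [ds.samples[0]],
            "outer": ds.samples[1:],
        }
        res = allele_membership(groups, ds.loci)
        assert res.unique["inner"] == 0

    def test_three_group_hand_enumeration(self):
        rows = [
            ("s1", "A", Role.POPULATION, None, {"L1": (1, 2)}),
            ("s2", "B", Role.POPULATION, None, {"L1": (2, 3)}),
            ("s3", "C", Role.POPULATION, None, {"L1": (3, 1)}),
        ]
        ds = make_dataset(rows, ["L1"])
        groups = {p: [s] for p, s in zip("ABC", ds.samples)}
        res = allele_membership(groups, ds.loci)
        assert res.shared_by_all == 0
        assert res.unique == {"A": 0, "B": 0, "C": 0}
        table = res.table
        assert table.loc[("L1", 1)].tolist() == [True, False, True]
        assert table.loc[("L1", 2)].tolist() == [True, True, False]
        assert table.loc[("L1", 3)].tolist() == [False, True, True]
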
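"""Pair enumeration (against a brute-force oracle), correlation
estimation, the log-linear transmissibility fit, and cohort trends."""

import numpy as np
import pandas as pd
import pytest

import kinconfound as kc
from kinconfound.errors import EstimationError, FitError

from conftest import clustered_pair_table


# ----------------------------------------------------------------------
# independent oracle: exhaustive ancestor-path enumeration
# ----------------------------------------------------------------------

def oracle_closest_relationships(df):
    """Brute-force closest-relationship map {frozenset(a,b): (n, dmin, dmax)}
    computed by exhaustive recursion over ancestor paths."""
    parents = {
        row.id: [p for p in (row.father_id, row.mother_id) if p is not None]
        for row in df.itertuples()
    }

    def ancestors(i, depth=0, acc=None):
        if acc is None:
            acc = {}
        for p in parents[i]:
            if depth + 1 < acc.get(p, 99):
                acc[p] = depth + 1
            ancestors(p, depth + 1, acc)
        return acc

    anc = {i: ancestors(i) for i in parents}
    out = {}
    ids = list(parents)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            x, y = ids[i], ids[j]
            best = None
            if y in anc[x]:
                best = (anc[x][y], 0, anc[x][y])
            if x in anc[y]:
                cand = (anc[y][x], 0, anc[y][x])
                best = min(best, cand) if best else cand
            for a in set(anc[x]) & set(anc[y]):
                dx, dy = anc[x][a], anc[y][a]
                cand = (dx + dy - 1, min(dx, dy), max(dx, dy))
                best = min(best, cand) if best else cand
            if best:
                out[frozenset((x, y))] = best
    return out


class TestEnumeration:
    def test_nuclear_family_has_all_sibling_pairs(self, nuclear_family):
        pairs = kc.enumerate_relative_pairs(nuclear_family)
        sibs = pairs[pairs["relationship"] == "siblings"]
        assert len(sibs) == 6  # C(4, 2)
        po = pairs[pairs["relationship"] == "parent-offspring"]
        assert len(po) == 8  # 2 parents x 4 children

    def test_toy_pedigree_matches_bruteforce_oracle(self, toy_pedigree):
        pairs = kc.enumerate_relative_pairs(toy_pedigree)
        oracle = oracle_closest_relationships(toy_pedigree.individuals)
        got = {
            frozenset((r.id_a, r.id_b)): int(r.n)
            for r in pairs.itertuples()
        }
        assert set(got) == set(oracle)
        for key, (n, _, _) in oracle.items():
            assert got[key] == n, key
        # the four grandchildren form first-cousin pairs across couples
        fc = pairs[pairs["relationship"] == "first-cousins"]
        assert len(fc) == 4
        assert set(map(frozenset, zip(fc["id_a"], fc["id_b"]))) == {
            frozenset(p) for p in
            [("g1", "g3"), ("g1", "g4"), ("g2", "g3"), ("g2", "g4")]
        }

    def test_simulated_pedigree_sample_matches_oracle(self):
        ped = kc.simulate_pedigree(
            kc.TransmissionParams(), n_founder_couples=6,
            n_generations=4, seed=23,
        )
        pairs = kc.enumerate_relative_pairs(ped)
        oracle = oracle_closest_relationships(ped.individuals)
        got = {
            frozenset((r.id_a, r.id_b)): int(r.n) for r in pairs.itertuples()
        }
        assert got == {k: v[0] for k, v in oracle.items()}

    def test_unrelated_lineages_yield_no_cousin_pairs(self):
        from conftest import build_pedigree

        rows = [
            ("X1", None, None, "M", 1700, "X", 0, 0.0),
            ("X2", None, None, "F", 1700, "X", 0, 0.0),
            ("Y1", None, None, "M", 1700, "Y", 0, 0.0),
            ("Y2", None, None, "F", 1700, "Y", 0, 0.0),
            ("x", "X1", "X2", "M", 1730, "X", 1, 0.0),
            ("y", "Y1", "Y2", "F", 1730, "Y", 1, 0.0),
        ]
        ped = build_pedigree(rows, generations=2)
        pairs = kc.enumerate_relative_pairs(ped)
        assert not pairs["relationship"].str.contains("cousins").any()

    def test_pair_table_deterministic(self, medium_pedigree):
        a = kc.enumerate_relative_pairs(
            medium_pedigree, relationships=["first-cousins"]
        )
        b = kc.enumerate_relative_pairs(
            medium_pedigree, relationships=["first-cousins"]
        )
        pd.testing.assert_frame_equal(a, b)

    def test_surname_is_closest_common_patriline(self, toy_pedigree):
        pairs = kc.enumerate_relative_pairs(toy_pedigree)
        sibs = pairs[pairs["relationship"] == "siblings"]
        by_pair = {
            frozenset((r.id_a, r.id_b)): r.surname for r in sibs.itertuples()
        }
        assert by_pair[frozenset(("a1", "a2"))] == "A"
        assert by_pair[frozenset(("b1", "b2"))] == "B"


class TestEstimateKinCorrelation:
    def test_identical_values_give_degenerate_unit_correlation(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        tab = pd.DataFrame(
            {
                "id_a": [f"a{i}" for i in range(40)],
                "id_b": [f"b{i}" for i in range(40)],
                "relationship": "siblings",
                "surname": [f"S{i}" for i in range(40)],
                "values_a": v, "values_b": v, "cohort": 0,
            }
        )
        for method in ("naive", "one_per_surname_bootstrap"):
            est = kc.estimate_kin_correlation(tab, method=method, seed=0)
            assert est.r == pytest.approx(1.0)
            assert est.ci_low == pytest.approx(1.0)
            assert est.ci_high == pytest.approx(1.0)

    def test_dual_sample_size_reporting_exposes_pseudoreplication(self):
        rng = np.random.default_rng(1)
        tab = clustered_pair_table(rng, n_clusters=20, cluster_size=10, rho=0.4)
        est = kc.estimate_kin_correlation(tab, seed=1)
        assert est.n_pairs == 20 * 45
        assert est.n_unique == 200
        assert est.n_unique <= 2 * est.n_pairs

    def test_corrected_ci_wider_under_heavy_pair_sharing(self):
        rng = np.random.default_rng(2)
        big = clustered_pair_table(rng, n_clusters=1, cluster_size=50, rho=0.4)
        small = clustered_pair_table(rng, n_clusters=20, cluster_size=2, rho=0.4)
        small["surname"] = [f"T{i}" for i in range(len(small))]
        tab = pd.concat([big, small], ignore_index=True)
        naive = kc.estimate_kin_correlation(tab, method="naive")
        boot = kc.estimate_kin_correlation(
            tab, method="one_per_surname_bootstrap", n_boot=500, seed=2
        )
        assert (boot.ci_high - boot.ci_low) > (naive.ci_high - naive.ci_low)

    def test_methods_agree_when_pairs_are_independent(self):
        rng = np.random.default_rng(3)
        tab = clustered_pair_table(rng, n_clusters=400, cluster_size=2, rho=0.3)
        naive = kc.estimate_kin_correlation(tab, method="naive")
        boot = kc.estimate_kin_correlation(
            tab, method="one_per_surname_bootstrap", n_boot=500, seed=3
        )
        assert boot.r == pytest.approx(naive.r, abs=3 * (boot.se or 0.05))

    def test_row_order_and_id_relabelling_irrelevant(self):
        rng = np.random.default_rng(4)
        tab = clustered_pair_table(rng, n_clusters=30, cluster_size=4, rho=0.4)
        shuffled = tab.sample(frac=1.0, random_state=5).reset_index(drop=True)
        relabelled = tab.assign(
            id_a="z" + tab["id_a"], id_b="z" + tab["id_b"]
        )
        r0 = kc.estimate_kin_correlation(tab, method="naive").r
        # invariant up to floating-point summation order
        assert kc.estimate_kin_correlation(shuffled, method="naive").r == (
            pytest.approx(r0, abs=1e-12)
        )
        assert kc.estimate_kin_correlation(relabelled, method="naive").r == r0

    def test_too_few_clusters_is_an_error(self):
        rng = np.random.default_rng(5)
        tab = clustered_pair_table(rng, n_clusters=5, cluster_size=4, rho=0.4)
        with pytest.raises(EstimationError, match="surname"):
            kc.estimate_kin_correlation(tab, seed=5)


class TestFitTransmissionModel:
    @staticmethod
    def _noise_free_estimates(t2, b, ns):
        return [
            kc.KinCorrEstimate(
                relationship=f"rel{n}", r=t2 * b**n, ci_low=0, ci_high=1,
                n_pairs=1000, n_unique=2000, method="naive", se=0.01,
            )
            for n in ns
        ]

    def test_exact_recovery_from_noise_free_profile(self):
        ests = self._noise_free_estimates(0.5, 0.8, range(1, 6))
        mapping = {f"rel{n}": n for n in range(1, 6)}
        fit = kc.fit_transmission_model(ests, mapping=mapping, n_boot=50, seed=0)
        assert fit.t2_hat == pytest.approx(0.5, abs=1e-10)
        assert fit.b_hat == pytest.approx(0.8, abs=1e-10)
        assert fit.m_hat == pytest.approx(0.6, abs=1e-9)

    def test_parameter_recovery_from_simulation(self):
        params = kc.TransmissionParams(t2=0.6, m=0.4)
        ped = kc.simulate_pedigree(
            params, n_founder_couples=5000, n_generations=4, seed=24
        )
        pairs = kc.enumerate_relative_pairs(ped)
        ests = kc.estimate_by_relationship(pairs, method="naive")
        fit = kc.fit_transmission_model(ests, n_boot=200, seed=24)
        assert fit.t2_hat == pytest.approx(0.6, abs=0.05)
        assert fit.b_hat == pytest.approx(0.7, abs=0.05)

    def test_nonpositive_estimates_excluded_and_counted(self):
        ests = self._noise_free_estimates(0.5, 0.8, range(1, 5))
        ests.append(
            kc.KinCorrEstimate(
                relationship="rel9", r=-0.02, ci_low=-1, ci_high=1,
                n_pairs=100, n_unique=200, method="naive", se=0.05,
            )
        )
        mapping = {f"rel{n}": n for n in list(range(1, 5)) + [9]}
        fit = kc.fit_transmission_model(ests, mapping=mapping, n_boot=50, seed=1)
        assert fit.n_excluded == 1
        assert fit.n_relationships == 4

    def test_too_few_distinct_distances_is_an_error(self):
        ests = self._noise_free_estimates(0.5, 0.8, [1, 2])
        mapping = {"rel1": 1, "rel2": 2}
        with pytest.raises(FitError):
            kc.fit_transmission_model(ests, mapping=mapping)

    def test_pure_cultural_fit_reads_as_heritability_in_genetic_mode(self):
        # h2_share=0: nothing genetic is transmitted, yet the genetic-mode
        # report labels the fitted transmissibility as h2 ~ 0.5
        params = kc.TransmissionParams(t2=0.5, m=0.6, h2_share=0.0)
        ped = kc.simulate_pedigree(
            params, n_founder_couples=3000, n_generations=4, seed=25
        )
        pairs = kc.enumerate_relative_pairs(ped)
        ests = kc.estimate_by_relationship(pairs, method="naive")
        fit = kc.fit_transmission_model(ests, n_boot=100, seed=25)
        report = kc.reinterpret_fit(fit, "genetic")
        true_h2 = params.t2 * params.h2_share
        assert true_h2 == 0.0
        assert report["h2"] == pytest.approx(0.5, abs=0.07)


class TestCohortTrend:
    def _pairs_with_cohorts(self, rng, rhos):
        frames = []
        for c, rho in enumerate(rhos):
            tab = clustered_pair_table(rng, n_clusters=150, cluster_size=2, rho=rho)
            tab["cohort"] = c
            tab["surname"] = tab["surname"] + f"_c{c}"
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)

    def test_constant_correlation_trend_covers_zero(self):
        rng = np.random.default_rng(6)
        pairs = self._pairs_with_cohorts(rng, [0.4, 0.4, 0.4, 0.4])
        res = kc.cohort_trend(pairs, n_boot=400, seed=6)
        assert res.diff_ci_low <= 0.0 <= res.diff_ci_high

    def test_declining_correlation_detected(self):
        rng = np.random.default_rng(7)
        pairs = self._pairs_with_cohorts(rng, [0.6, 0.5, 0.4, 0.2])
        res = kc.cohort_trend(pairs, n_boot=400, seed=7)
        assert res.diff < 0
        assert res.diff_ci_high < 0
        rank = kc.cohort_trend(pairs, use_ranks=True, n_boot=400, seed=7)
        assert np.sign(rank.diff) == np.sign(res.diff)

    def test_empty_cohort_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        pairs = self._pairs_with_cohorts(rng, [0.4, 0.4])
        with pytest.warns(UserWarning, match="empty"):
            res = kc.cohort_trend(pairs, cohorts=[0, 1, 99], n_boot=200, seed=8)
        assert res.cohorts == [0, 1]
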
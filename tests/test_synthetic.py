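"""Generator ground truth: stationarity, assortment, conservation,
reproducibility, and the auxiliary generators (wealth, questionnaire,
correlation sets)."""

import numpy as np
import pandas as pd
import pytest

import kinconfound as kc
from kinconfound.errors import (
    ConfigurationError,
    ExtinctionError,
    ParameterError,
)


class TestTransmissionParams:
    def test_persistence_rate_derived_exactly(self):
        assert kc.TransmissionParams(m=0.6).b == pytest.approx(0.8)
        assert kc.TransmissionParams(m=0.0).b == 0.5

    @pytest.mark.parametrize(
        "kwargs", [dict(t2=1.2), dict(t2=-0.1), dict(m=1.0), dict(m=-0.2),
                   dict(h2_share=1.5)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            kc.TransmissionParams(**kwargs)


def _couples(df):
    """(father T, mother T) arrays over distinct couples."""
    kids = df[df["father_id"].notna()]
    fam = kids.drop_duplicates(subset=["father_id", "mother_id"])
    byid = df.set_index("id")
    return (
        byid.loc[fam["father_id"], "T"].to_numpy(),
        byid.loc[fam["mother_id"], "T"].to_numpy(),
    )


class TestPedigreeSimulation:
    def test_structural_invariants(self):
        ped = kc.simulate_pedigree(
            kc.TransmissionParams(), n_founder_couples=200,
            n_generations=4, seed=1,
        )
        ped.validate()

    def test_random_mating_gives_zero_spousal_correlation(self):
        ped = kc.simulate_pedigree(
            kc.TransmissionParams(t2=0.5, m=0.0),
            n_founder_couples=10000, n_generations=2, seed=2,
        )
        tm, tf = _couples(ped.individuals)
        assert abs(np.corrcoef(tm, tf)[0, 1]) < 0.03

    @pytest.mark.parametrize("m", [0.3, 0.6])
    def test_assortment_hits_target_spousal_correlation(self, m):
        ped = kc.simulate_pedigree(
            kc.TransmissionParams(t2=0.6, m=m),
            n_founder_couples=6000, n_generations=3, seed=3,
        )
        df = ped.individuals
        tm, tf = _couples(df)
        assert np.corrcoef(tm, tf)[0, 1] == pytest.approx(m, abs=0.03)

    def test_stationary_variance_across_generations(self):
        t2 = 0.6
        ped = kc.simulate_pedigree(
            kc.TransmissionParams(t2=t2, m=0.4),
            n_founder_couples=5000, n_generations=5, seed=4,
        )
        for _, grp in ped.individuals.groupby("generation"):
            n = len(grp)
            se = t2 * np.sqrt(2.0 / n)  # var-of-variance for normal data
            assert grp["T"].var() == pytest.approx(t2, abs=3 * se)

    def test_components_conserved_and_split_stationary(self):
        params = kc.TransmissionParams(t2=0.6, m=0.4, h2_share=0.3)
        ped = kc.simulate_pedigree(
            params, n_founder_couples=5000, n_generations=5, seed=5
        )
        df = ped.individuals
        np.testing.assert_allclose(
            df["T"], df["G"] + df["C"], atol=1e-10
        )
        for _, grp in df.groupby("generation"):
            share = grp["G"].var() / grp["T"].var()
            se = np.sqrt(2.0 / len(grp))
            assert share == pytest.approx(params.h2_share, abs=3 * se)

    def test_parent_offspring_correlation_matches_closed_form(self):
        # t2 * b with t2=0.6, m=0.4 -> 0.42
        params = kc.TransmissionParams(t2=0.6, m=0.4)
        ped = kc.simulate_pedigree(
            params, n_founder_couples=5000, n_generations=4, seed=6
        )
        pairs = kc.enumerate_relative_pairs(
            ped, relationships=["parent-offspring"]
        )
        r = np.corrcoef(pairs["values_a"], pairs["values_b"])[0, 1]
        se = kc.cluster_bootstrap_se(pairs, n_boot=100, seed=6)
        assert r == pytest.approx(0.42, abs=3 * se)

    def test_phenotypes_invariant_to_latent_split(self):
        # h2_share relabels G/C only; observables must be bit-identical
        kw = dict(n_founder_couples=300, n_generations=4, seed=7)
        a = kc.simulate_pedigree(kc.TransmissionParams(h2_share=1.0), **kw)
        b = kc.simulate_pedigree(kc.TransmissionParams(h2_share=0.0), **kw)
        pd.testing.assert_frame_equal(
            a.individuals.drop(columns=["G", "C"]),
            b.individuals.drop(columns=["G", "C"]),
        )
        assert not np.allclose(a.individuals["G"], b.individuals["G"])

    def test_bit_reproducible_given_seed(self):
        kw = dict(n_founder_couples=150, n_generations=3, seed=11)
        a = kc.simulate_pedigree(kc.TransmissionParams(), **kw)
        b = kc.simulate_pedigree(kc.TransmissionParams(), **kw)
        pd.testing.assert_frame_equal(a.individuals, b.individuals)

    def test_subcritical_offspring_distribution_goes_extinct(self):
        with pytest.raises(ExtinctionError) as err:
            kc.simulate_pedigree(
                kc.TransmissionParams(), n_founder_couples=5,
                n_generations=12, offspring_dist=("poisson", 0.4), seed=8,
            )
        assert err.value.generation >= 1

    def test_declining_t2_schedule_reduces_variance(self):
        sched = (0.6, 0.45, 0.3)
        ped = kc.simulate_pedigree(
            kc.TransmissionParams(t2=0.6, m=0.4),
            n_founder_couples=4000, n_generations=3, seed=9,
            t2_schedule=sched,
        )
        var_by_gen = ped.individuals.groupby("generation")["T"].var()
        for g, target in enumerate(sched):
            assert var_by_gen[g] == pytest.approx(target, abs=0.03)


class TestWealth:
    def test_zero_loading_decorrelates_wealth_from_status(self):
        ped = kc.simulate_pedigree(
            kc.TransmissionParams(), n_founder_couples=5000,
            n_generations=2, seed=10,
        )
        ped = kc.simulate_wealth(ped, status_loading=0.0, seed=10)
        df = ped.individuals
        sub = df[df["probated"]]
        r = np.corrcoef(sub["status"], sub["wealth"])[0, 1]
        assert abs(r) < 0.03

    def test_no_censoring_when_minimum_is_tiny(self):
        ped = kc.simulate_pedigree(
            kc.TransmissionParams(), n_founder_couples=100,
            n_generations=3, seed=11,
        )
        ped = kc.simulate_wealth(
            ped, probate_minimums=[(1600, 2100, 1e-12)], seed=11
        )
        assert ped.individuals["probated"].all()

    def test_strong_loading_brackets_reported_individual_correlation(self):
        # offspring status vs father's wealth lands in [0.5, 0.8]
        ped = kc.simulate_pedigree(
            kc.TransmissionParams(t2=0.6, m=0.6),
            n_founder_couples=5000, n_generations=3, seed=12,
        )
        ped = kc.simulate_wealth(ped, status_loading=0.9, seed=12)
        df = ped.individuals
        centred = kc.preprocess_wealth(kc.wealth_records(ped))
        kids = df[df["father_id"].notna()]
        fw = centred[kids["father_id"]].to_numpy()
        r = np.corrcoef(kids["status"], fw)[0, 1]
        assert 0.5 <= r <= 0.8

    def test_missing_period_coverage_is_an_error(self):
        ped = kc.simulate_pedigree(
            kc.TransmissionParams(), n_founder_couples=50,
            n_generations=3, seed=13,
        )
        with pytest.raises(ConfigurationError):
            kc.simulate_wealth(ped, probate_minimums=[(1700, 1709, 100.0)])


class TestQuestionnaire:
    def test_zero_rates_classify_nobody(self):
        q = kc.simulate_questionnaire(
            5000, strata_spec=((0, 12, 0.0), (13, None, 0.0)), seed=14
        )
        assert kc.classify(q).sum() == 0

    def test_default_strata_rates_recovered(self):
        q = kc.simulate_questionnaire(50000, seed=15)
        flags = kc.classify(q)
        age = q["age_first_sex"]
        for lo, hi, rate in kc.synthetic.DEFAULT_STRATA_SPEC:
            sel = (age >= lo) & (age <= (np.inf if hi is None else hi))
            n = int(sel.sum())
            if n == 0:
                continue
            se = np.sqrt(rate * (1 - rate) / n)
            assert flags[sel].mean() == pytest.approx(rate, abs=max(3 * se, 0.02))

    def test_single_stratum_binomial_mean(self):
        q = kc.simulate_questionnaire(
            1000, strata_spec=((0, None, 0.5),), seed=16, missing_rate=0.0
        )
        k = int(kc.classify(q).sum())
        assert abs(k - 500) <= 3 * np.sqrt(1000 * 0.25)

    def test_overlapping_strata_rejected(self):
        with pytest.raises(ConfigurationError):
            kc.simulate_questionnaire(
                100, strata_spec=((0, 12, 0.1), (10, None, 0.2)), seed=17
            )


class TestRgSet:
    def test_rank_one_entries_exact_without_noise(self):
        s = kc.simulate_rg_set(
            ["A", "B", "C"], [0.5, 0.4, 0.6], noise_sd=0.0,
            n_effective=100, seed=18,
        )
        assert s.r("A", "B") == pytest.approx(0.2, abs=1e-12)
        assert s.r("A", "C") == pytest.approx(0.3, abs=1e-12)

    def test_zero_loadings_give_identity(self):
        s = kc.simulate_rg_set(
            ["A", "B", "C"], [0.0, 0.0, 0.0], noise_sd=0.0,
            n_effective=100, seed=19,
        )
        np.testing.assert_allclose(s.R, np.eye(3), atol=1e-12)

    def test_noisy_matrix_projected_to_valid_correlation(self):
        s = kc.simulate_rg_set(
            [f"X{i}" for i in range(12)], np.full(12, 0.9),
            noise_sd=0.3, n_effective=100, seed=20,
        )
        w = np.linalg.eigvalsh(s.R)
        assert w.min() >= -1e-8
        np.testing.assert_allclose(np.diag(s.R), 1.0, atol=1e-12)

    def test_sampling_variance_scales_inversely_with_n(self):
        a = kc.simulate_rg_set(["A", "B"], [0.5, 0.5], 0.0, 100, seed=21)
        b = kc.simulate_rg_set(["A", "B"], [0.5, 0.5], 0.0, 400, seed=21)
        assert a.V[0, 0] == pytest.approx(4.0 * b.V[0, 0])

    def test_loadings_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError):
            kc.simulate_rg_set(["A", "B"], [1.0, 0.5], seed=22)
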
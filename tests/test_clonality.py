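"""Heterozygous-site conservation statistic and clonal-group calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalpop import (MISSING, ClonalityConfig, GroupSpec, SimulationConfig,
                       apply_genotyping_noise, calibrate_threshold,
                       call_clonal_groups, conservation_percent,
                       count_pairwise_conservation,
                       expected_clonal_conservation,
                       pairwise_conservation_table, simulate_cohort,
                       simulate_individual)
from clonalpop.clonality import round_percent

from conftest import make_matrix


def brute_force_conservation(a, b):
    """Independent site-by-site enumeration of the pair statistic."""
    n_var = n_cons = 0
    for ga, gb in zip(a, b):
        if ga == MISSING or gb == MISSING:
            continue
        alleles_a = {0: "rr", 1: "ra", 2: "aa"}[ga]
        alleles_b = {0: "rr", 1: "ra", 2: "aa"}[gb]
        if alleles_a == alleles_b and ga != 1:
            continue  # all four alleles identical -> monomorphic for the pair
        n_var += 1
        if ga == 1 and gb == 1:
            n_cons += 1
    return n_var, n_cons


def test_worked_example_five_sites():
    m = make_matrix([[1, 1, 0, 2, 0], [1, 2, 0, 2, 2]])
    pc = count_pairwise_conservation(m, "s1", "s2")
    assert (pc.n_variable, pc.n_conserved_het) == (3, 1)
    assert pc.percent_display == 33.3
    assert brute_force_conservation([1, 1, 0, 2, 0], [1, 2, 0, 2, 2]) == (3, 1)


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.integers(-1, 2), st.integers(-1, 2)),
                min_size=1, max_size=40))
def test_counts_match_brute_force_and_are_symmetric(pairs):
    a = [x for x, _ in pairs]
    b = [y for _, y in pairs]
    m = make_matrix([a, b])
    pc = count_pairwise_conservation(m, "s1", "s2")
    assert (pc.n_variable, pc.n_conserved_het) == brute_force_conservation(a, b)
    rev = count_pairwise_conservation(m, "s2", "s1")
    assert (rev.n_variable, rev.n_conserved_het) == (pc.n_variable,
                                                    pc.n_conserved_het)


def test_sites_missing_in_either_sample_are_ignored():
    base = make_matrix([[1, 1, 0], [1, 2, 0]])
    padded = make_matrix([[1, 1, 0, MISSING, 2], [1, 2, 0, 1, MISSING]])
    pc1 = count_pairwise_conservation(base, "s1", "s2")
    pc2 = count_pairwise_conservation(padded, "s1", "s2")
    assert (pc1.n_variable, pc1.n_conserved_het) == (pc2.n_variable,
                                                     pc2.n_conserved_het)


def test_identical_clones_conserve_100_percent():
    m = make_matrix([[1, 0, 2, 1], [1, 0, 2, 1]])
    assert count_pairwise_conservation(m, "s1", "s2").percent == 100.0


def test_no_variable_sites_is_inconclusive_not_zero():
    m = make_matrix([[0, 2], [0, 2]])
    pc = count_pairwise_conservation(m, "s1", "s2")
    assert pc.inconclusive
    assert np.isnan(pc.percent)
    with pytest.raises(ValueError):
        conservation_percent(0, 0)


@pytest.mark.parametrize(
    "n_variable,n_conserved,expected",
    [
        (15116, 6166, 40.8),
        (9726, 5065, 52.1),
        (16321, 7997, 49.0),
        (14445, 6882, 47.6),
        (100, 0, 0.0),
    ],
)
def test_tabular_percent_one_decimal_half_up(n_variable, n_conserved, expected):
    assert conservation_percent(n_variable, n_conserved) == expected


def test_truncation_mode_available():
    # 2810/6160 = 45.616...: half-up 45.6 either way; 5574/12344 = 45.155...
    assert round_percent(45.1555, mode="half-up") == 45.2
    assert round_percent(45.1555, mode="truncate") == 45.1


class TestExpectedConservation:
    def test_closed_form_values(self):
        assert expected_clonal_conservation(0.0) == 100.0
        assert expected_clonal_conservation(0.35) == pytest.approx(45.0, abs=0.1)

    def test_monte_carlo_matches_closed_form(self):
        rng = np.random.default_rng(12)
        founder = np.ones(50000, dtype=np.int8)  # 50k het sites
        a = apply_genotyping_noise(founder, 0.2, 0.0, rng)
        b = apply_genotyping_noise(founder, 0.2, 0.0, rng)
        m = make_matrix([a, b])
        pc = count_pairwise_conservation(m, "s1", "s2")
        assert pc.percent == pytest.approx(expected_clonal_conservation(0.2),
                                           abs=0.5)

    def test_monotone_decreasing_in_dropout(self):
        vals = [expected_clonal_conservation(d) for d in (0, 0.1, 0.2, 0.35)]
        assert vals == sorted(vals, reverse=True)

    def test_domain(self):
        with pytest.raises(ValueError):
            expected_clonal_conservation(1.0)


def test_unrelated_outbred_pair_expectation():
    # p = 0.5, HWE: expected percent = 100*(2pq)^2/(1-p^4-q^4) = 28.6
    rng = np.random.default_rng(21)
    freqs = np.full((1, 30000), 0.5)
    a = simulate_individual(np.array([1.0]), freqs, rng)
    b = simulate_individual(np.array([1.0]), freqs, rng)
    m = make_matrix([a, b])
    pc = count_pairwise_conservation(m, "s1", "s2")
    assert pc.percent == pytest.approx(
        100 * (2 * 0.5 * 0.5) ** 2 / (1 - 2 * 0.5**4), abs=1.0)


class TestCalibration:
    def test_replicates_near_forty(self):
        cfg = calibrate_threshold([49.0, 47.6, 43.9], margin=4.0)
        assert cfg.threshold_percent == pytest.approx(40.0, abs=0.1)

    def test_no_replicates_falls_back_to_default(self):
        assert calibrate_threshold([]).threshold_percent == 40.0

    def test_noise_free_replicates(self):
        assert calibrate_threshold([100.0, 100.0]).threshold_percent == 96.0


class TestClonalGroupCalling:
    def test_simulated_trio_recovered(self):
        cfg = SimulationConfig(
            n_sites=2000, K=1, drift=(0.1,),
            group_specs=(GroupSpec("L", 3, "clonal", population=0),
                         GroupSpec("O", 5, "outbred", population=0)),
            dropout_d=0.3, seed=3)
        m, _ = simulate_cohort(cfg)
        table = pairwise_conservation_table(m)
        part = call_clonal_groups(table, ClonalityConfig(threshold_percent=40))
        assert part.groups == [{"L_01", "L_02", "L_03"}]
        assert part.singletons == {f"O_{i:02d}" for i in range(1, 6)}

    def test_all_below_threshold_yields_no_groups(self):
        table = pd.DataFrame(
            [{"sample_a": "x", "sample_b": "y",
              "n_variable": 1000, "n_conserved_het": 100}]
        )
        part = call_clonal_groups(table, ClonalityConfig(threshold_percent=40))
        assert part.groups == []
        assert part.singletons == {"x", "y"}

    def test_transitive_closure_with_one_borderline_pair(self):
        # chain: a-b and b-c pass; a-c sits just below 40 (39.6) and is
        # annotated borderline, yet the component still covers all three
        rows = [
            ("a", "b", 10000, 4070), ("b", "c", 10000, 4970),
            ("a", "c", 10000, 3960),
        ]
        table = pd.DataFrame(rows, columns=["sample_a", "sample_b",
                                            "n_variable", "n_conserved_het"])
        part = call_clonal_groups(
            table, ClonalityConfig(threshold_percent=40, borderline_band=4))
        assert part.groups == [{"a", "b", "c"}]
        assert part.borderline_pairs == [("a", "c", 39.6)]

    def test_inconclusive_pairs_listed_not_linked(self):
        table = pd.DataFrame(
            [("a", "b", 10, 9), ("a", "c", 10000, 5000)],
            columns=["sample_a", "sample_b", "n_variable", "n_conserved_het"])
        part = call_clonal_groups(
            table, ClonalityConfig(threshold_percent=40, min_variable_sites=50))
        assert part.inconclusive_pairs == [("a", "b")]
        assert part.groups == [{"a", "c"}]


def test_verdict_column_in_table(small_matrix):
    table = pairwise_conservation_table(
        small_matrix, cfg=ClonalityConfig(min_variable_sites=1))
    assert set(table.columns) >= {"sample_a", "sample_b", "n_variable",
                                  "n_conserved_het", "percent", "verdict"}
    assert len(table) == 6  # all unordered pairs of 4 samples
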
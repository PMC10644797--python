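import io
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import TreeNode

from ecoassembly import (
    PROCESSES,
    OTUTable,
    assembly_analysis,
    beta_nti,
    classify,
    classify_pair,
    patristic_matrix,
    process_fractions,
    raup_crick_bray,
    rc_score,
)
from ecoassembly.nullmodels import _null_community, _pair_substream
from tests.conftest import random_table


def exhaustive_beta_nti(table, tree, weighted=True):
    """Oracle: exact null over all tip-label permutations (tiny trees only)."""
    from tests.test_phylo import brute_force_beta_mntd

    dm = patristic_matrix(tree)
    D = dm.filter(table.taxon_ids).data
    counts = table.values()
    obs = brute_force_beta_mntd(counts, D, weighted)
    n = D.shape[0]
    nulls = [
        brute_force_beta_mntd(counts, D[np.ix_(p, p)], weighted)
        for p in itertools.permutations(range(n))
    ]
    nulls = np.array(nulls)
    # the enumeration is the full population of permutations -> ddof=0
    mean, sd = nulls.mean(axis=0), nulls.std(axis=0, ddof=0)
    return obs, mean, sd, (obs - mean) / np.where(sd == 0, np.nan, sd)


class TestBetaNTI:
    def test_monte_carlo_matches_exhaustive_null_three_tips(self, toy_tree):
        # two single-taxon samples; exact null = all 3! tip permutations
        table = OTUTable(
            pd.DataFrame({"X": [5, 0, 0], "Y": [0, 0, 5]}, index=["A", "B", "C"])
        )
        obs, mean, sd, exact = exhaustive_beta_nti(table, toy_tree)
        got = beta_nti(table, toy_tree, reps=10000, seed=0)
        assert abs(got.loc["X", "Y"] - exact[0, 1]) < 0.05

    def test_identical_samples_nonpositive(self, toy_tree):
        table = OTUTable(
            pd.DataFrame({"X": [2, 3, 1], "Y": [2, 3, 1]}, index=["A", "B", "C"])
        )
        nti = beta_nti(table, toy_tree, reps=99, seed=1)
        assert nti.loc["X", "Y"] <= 0

    def test_relabeling_invariance_statistical(self, rng):
        from ecoassembly import simulate_tree

        tree = simulate_tree(6, rng)
        table = random_table(rng, 6, 3, depth=60)
        table = OTUTable(
            table.counts.set_axis(sorted(t.name for t in tree.tips()), axis=0)
        )
        relabel = {name: f"T{i}" for i, name in enumerate(table.taxon_ids)}
        table2 = OTUTable(table.counts.rename(index=relabel))
        tree2 = tree.copy()
        for tip in tree2.tips():
            tip.name = relabel[tip.name]
        a = beta_nti(table, tree, reps=4000, seed=3)
        b = beta_nti(table2, tree2, reps=4000, seed=3)
        np.testing.assert_allclose(a.values, b.values, atol=0.15)

    def test_degenerate_pair_single_shared_taxon_is_zero(self, toy_tree):
        # both samples hold only taxon A: every permutation gives betaMNTD 0
        table = OTUTable(
            pd.DataFrame({"X": [4, 0, 0], "Y": [9, 0, 0]}, index=["A", "B", "C"])
        )
        nti = beta_nti(table, toy_tree, reps=99, seed=0)
        assert nti.loc["X", "Y"] == 0.0

    def test_reps_below_two_rejected(self, toy_tree, toy_table):
        with pytest.raises(ValueError, match="reps"):
            beta_nti(toy_table, toy_tree, reps=1, seed=0)


class TestRaupCrick:
    def test_rc_score_two_point_rescaling(self):
        # reps=1: null below obs -> +1, null above obs -> -1, tie -> 0
        assert rc_score(1, 0, 1) == 1.0
        assert rc_score(0, 0, 1) == -1.0
        assert rc_score(0, 1, 1) == 0.0

    def test_obs_exceeding_all_nulls_gives_plus_one(self):
        assert rc_score(999, 0, 999) == 1.0

    def test_identical_full_communities_nonpositive_and_near_minus_one(self):
        # identical communities containing every metacommunity taxon:
        # obs BC = 0, no null can fall below it -> RC <= 0; with many taxa
        # exact null ties (null BC == 0) are vanishingly rare -> RC -> -1
        rng = np.random.default_rng(0)
        counts = rng.integers(5, 50, size=30)
        table = OTUTable(
            pd.DataFrame(
                {"X": counts, "Y": counts, "Z": rng.integers(5, 50, size=30)},
                index=[f"T{i}" for i in range(30)],
            )
        )
        rc = raup_crick_bray(table, reps=199, seed=1)
        assert rc.loc["X", "Y"] <= 0
        assert rc.loc["X", "Y"] == -1.0

    def test_two_taxon_toy_matches_enumeration(self):
        # identical 2-taxon communities: obs BC = 0, so RC = P(tie) - 1 where
        # a tie is two identical null communities; P computed by enumeration
        # over the binomial fill distribution.
        depth, reps = 8, 4000
        table = OTUTable(
            pd.DataFrame({"X": [5, 3], "Y": [5, 3]}, index=["A", "B"])
        )
        rc = raup_crick_bray(table, reps=reps, seed=7)
        # null community: both taxa seeded once, 6 remaining ~ Bin(6, pA)
        from scipy.stats import binom

        p_a = 10 / 16  # metacommunity relative abundance of taxon A
        pmf = binom.pmf(np.arange(7), 6, p_a)
        p_tie = float((pmf**2).sum())  # both null draws identical
        assert rc.loc["X", "Y"] == pytest.approx(p_tie - 1, abs=0.05)

    def test_rc_within_bounds_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            table = random_table(rng, 12, 4, depth=80)
            rc = raup_crick_bray(table, reps=49, seed=11)
            vals = rc.values[np.triu_indices(4, 1)]
            assert np.all(vals >= -1) and np.all(vals <= 1)

    def test_uniform_under_self_null(self):
        # when the observed pair is itself one more draw of the null assembly
        # process (same occupancy/abundance statistics), its Bray-Curtis rank
        # is exchangeable with the null draws, so RC ~ uniform on [-1, 1];
        # the mean over 500 replicates has sd ~ 0.026 under exact uniformity
        rng = np.random.default_rng(10)
        base = random_table(rng, 40, 6, depth=300)
        X = base.values().astype(np.int64)
        occupancy = (X > 0).sum(axis=1) / X.shape[1]
        active = np.flatnonzero(occupancy > 0)
        log_occ = np.log(occupancy[active])
        p_ab = X.sum(axis=1) / X.sum()
        richness, totals = int((X[:, 0] > 0).sum()), int(X[:, 0].sum())

        def bc(x, y):
            return np.abs(x - y).sum() / (x + y).sum()

        def draw():
            return _null_community(rng, richness, totals, log_occ, active, p_ab)

        reps = 99
        rcs = []
        for _ in range(500):
            obs = bc(draw(), draw())
            nulls = np.array([bc(draw(), draw()) for _ in range(reps)])
            less = int((nulls < obs - 1e-12).sum())
            ties = int(np.isclose(nulls, obs, rtol=1e-12, atol=1e-12).sum())
            rcs.append(rc_score(less, ties, reps))
        assert abs(np.mean(rcs)) < 0.05

    def test_non_integer_counts_rejected(self):
        table = OTUTable(
            pd.DataFrame({"X": [1.5, 2.0], "Y": [1.0, 1.0]}, index=["A", "B"])
        )
        with pytest.raises(ValueError, match="integer"):
            raup_crick_bray(table, reps=9, seed=0)

    def test_pair_substream_order_independent(self):
        a = _pair_substream(3, "S1", "S2").integers(0, 1 << 30, 4)
        b = _pair_substream(3, "S2", "S1").integers(0, 1 << 30, 4)
        np.testing.assert_array_equal(a, b)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "nti,rc,expected",
        [
            (-2.5, 0.0, "homogeneous_selection"),
            (-2.5, 0.99, "homogeneous_selection"),  # rc irrelevant under selection
            (2.5, -0.99, "heterogeneous_selection"),
            (0.5, 0.97, "dispersal_limitation"),
            (0.5, -0.97, "homogenizing_dispersal"),
            (0.5, 0.5, "drift"),
            (2.0, 0.0, "drift"),  # |betaNTI| <= 2 boundary is non-selection
            (-2.0, 0.96, "dispersal_limitation"),
            (1.0, 0.95, "drift"),  # |RC| <= 0.95 boundary is drift
            (1.0, -0.95, "drift"),
        ],
    )
    def test_threshold_rules(self, nti, rc, expected):
        assert classify_pair(nti, rc) == expected

    def test_custom_thresholds(self):
        assert classify_pair(1.5, 0.0, t_nti=1.0) == "heterogeneous_selection"
        assert classify_pair(0.0, 0.9, t_rc=0.8) == "dispersal_limitation"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(np.nan, 0.0)
        with pytest.raises(ValueError):
            classify_pair(0.0, np.inf)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        nti=st.floats(-10, 10, allow_nan=False),
        rc=st.floats(-1, 1, allow_nan=False),
    )
    def test_exactly_one_label_for_every_point(self, nti, rc):
        label = classify_pair(nti, rc)
        assert label in PROCESSES
        assert classify(np.array([nti]), np.array([rc]))[0] == label


class TestProcessFractions:
    def _pairs(self, labels, ntis, group="g1"):
        return pd.DataFrame(
            {
                "sample_a": [f"a{i}" for i in range(len(labels))],
                "sample_b": [f"b{i}" for i in range(len(labels))],
                "group": group,
                "beta_nti": ntis,
                "process": labels,
            }
        )

    def test_counting_example(self):
        pairs = self._pairs(
            ["homogeneous_selection", "homogeneous_selection", "drift",
             "dispersal_limitation"],
            [-3.0, -2.5, 0.1, 1.0],
        )
        out = process_fractions(pairs)
        row = out.loc["g1"]
        assert row["homogeneous_selection"] == 0.5
        assert row["drift"] == 0.25
        assert row["dispersal_limitation"] == 0.25
        assert row["heterogeneous_selection"] == 0.0
        assert row[list(PROCESSES)].sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_strong_selection(self):
        pairs = self._pairs(["homogeneous_selection"] * 4, [-3.0] * 4)
        row = process_fractions(pairs).loc["g1"]
        assert row["deterministic_fraction"] == 1.0
        assert row["median_beta_nti"] == -3.0

    def test_group_without_pairs_flagged(self):
        pairs = self._pairs(["drift"], [0.0])
        grouping = {"a0": "g1", "b0": "g1", "solo": "g2"}
        out = process_fractions(pairs, grouping=grouping)
        assert out.loc["g2", "n_pairs"] == 0
        assert np.isnan(out.loc["g2", "drift"])

    def test_all_pairs_scope_pools_everything(self):
        pairs = self._pairs(["drift", "homogenizing_dispersal"], [0.0, -1.0])
        out = process_fractions(pairs, scope="all_pairs")
        assert list(out.index) == ["all_pairs"]
        assert out.loc["all_pairs", "n_pairs"] == 2


class TestPipeline:
    def test_deterministic_given_seed(self, rng):
        from ecoassembly import RegimeConfig, simulate_dataset

        ds = simulate_dataset(
            RegimeConfig(regime="drift", n_taxa=30, n_samples=4, depth=300, seed=5)
        )
        run1 = assembly_analysis(
            ds.table, ds.tree, ds.metadata, reps=29, seed=7
        )
        run2 = assembly_analysis(
            ds.table, ds.tree, ds.metadata, reps=29, seed=7
        )
        pd.testing.assert_frame_equal(run1[0], run2[0])
        pd.testing.assert_frame_equal(run1[1], run2[1])
        assert set(run1[0]["process"]).issubset(set(PROCESSES))

    def test_pair_results_consistent_with_classifier(self, rng):
        from ecoassembly import RegimeConfig, simulate_dataset

        ds = simulate_dataset(
            RegimeConfig(regime="drift", n_taxa=30, n_samples=4, depth=300, seed=6)
        )
        pairs, fractions = assembly_analysis(
            ds.table, ds.tree, ds.metadata, reps=29, seed=3
        )
        for _, row in pairs.iterrows():
            assert row["process"] == classify_pair(row["beta_nti"], row["rc"])
        assert fractions.loc["10", "n_pairs"] == len(pairs)
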
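"""Group construction, similarity assignment and the 2G statistic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from tdt2g.fixtures import random_trios, worked_example_dataset
from tdt2g.haplotype_core import count_transmissions, phase_dataset
from tdt2g.tdt_tests import tdt_single
from tdt2g.two_groups import (
    GroupModel,
    MaxTest,
    MhetTest,
    TwoByTwoCounts,
    TwoGroupsTest,
    assign_group,
    build_groups,
    cross_sample_test,
    holdout_split,
    holdout_wrap,
    length_similarity,
    statistic_2g,
    two_group_counts,
)
from tdt2g.two_groups import test_2g as run_2g

AB, Ab, aB, ab = ("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")


class TestHoldoutSplit:
    def test_even_split_168(self):
        ds = random_trios(168, 2, seed=0)
        train, test = holdout_split(ds, 0.5, seed=1)
        assert len(train) == len(test) == 84

    def test_odd_count_rounds_half_up_to_training(self):
        ds = random_trios(5, 1, seed=0)
        train, test = holdout_split(ds, 0.5, seed=1)
        assert (len(train), len(test)) == (3, 2)

    def test_deterministic_and_seed_sensitive(self):
        ds = random_trios(60, 1, seed=0)
        a1, _ = holdout_split(ds, 0.5, seed=5)
        a2, _ = holdout_split(ds, 0.5, seed=5)
        b1, _ = holdout_split(ds, 0.5, seed=6)
        ids = lambda d: [t.family_id for t in d]
        assert ids(a1) == ids(a2)
        assert ids(a1) != ids(b1)

    def test_too_few_trios_raises(self):
        with pytest.raises(ValueError):
            holdout_split(random_trios(1, 1, seed=0), 0.5, seed=0)

    def test_families_stay_intact(self):
        ds = random_trios(30, 1, seed=0)
        train, test = holdout_split(ds, 0.5, seed=2)
        assert not ({t.family_id for t in train} & {t.family_id for t in test})


class TestBuildGroups:
    def test_worked_example_groups(self, worked_example):
        train, _ = worked_example
        txs, _ = phase_dataset(train, (0, 2))
        model = build_groups(count_transmissions(txs))
        assert model.g1 == frozenset({Ab, aB})
        assert model.g2 == frozenset({AB})
        assert ab not in model.g1 | model.g2  # tied 15/15: unassigned

    def test_all_tied_table_gives_empty_model(self):
        from tdt2g.haplotype_core import ParentalTransmission

        txs = [
            ParentalTransmission(AB, ab, "f1", "father"),
            ParentalTransmission(ab, AB, "f1", "mother"),
        ]
        model = build_groups(count_transmissions(txs))
        assert model.empty

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_groups_partition_distinct_haplotypes(self, seed):
        ds = random_trios(40, 3, seed=seed)
        txs, _ = phase_dataset(ds, (0, 3))
        table = count_transmissions(txs)
        model = build_groups(table)
        for h in table.haplotypes:
            memberships = (h in model.g1) + (h in model.g2)
            assert memberships <= 1
            expected = (
                1 if table.t(h) != table.u(h) else 0
            )
            assert memberships == expected


class TestLengthSimilarity:
    def test_two_marker_alphabet_exhaustive(self):
        """All 2-marker pairs against a direct run-scan oracle."""

        def oracle(h1, h2):
            best = run = 0
            for a, b in zip(h1, h2):
                run = run + 1 if a == b else 0
                best = max(best, run)
            return best

        for h1, h2 in itertools.product([AB, Ab, aB, ab], repeat=2):
            assert length_similarity(h1, h2) == oracle(h1, h2)
        assert length_similarity(AB, ab) == 0
        assert length_similarity(ab, Ab) == 1
        assert length_similarity(ab, aB) == 1

    def test_identical_haplotypes_score_full_length(self):
        h = ("A", "b", "A", "B")
        assert length_similarity(h, h) == 4

    @given(st.integers(1, 6), st.data())
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_bounds(self, l, data):
        hap = st.tuples(*[st.sampled_from("Aa") for _ in range(l)])
        h1, h2 = data.draw(hap), data.draw(hap)
        s = length_similarity(h1, h2)
        assert s == length_similarity(h2, h1)
        assert 0 <= s <= l

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            length_similarity(AB, ("A",))


class TestAssignGroup:
    def test_similarity_assignment_of_unseen_haplotype(self):
        model = GroupModel(frozenset({Ab, aB}), frozenset({AB}), 2)
        assert assign_group(ab, model) == "g1"  # best similarity 1 vs 0

    def test_membership_short_circuits_similarity(self):
        # AB is more similar to g1's members than to itself? irrelevant:
        model = GroupModel(frozenset({ab}), frozenset({AB}), 2)
        assert assign_group(ab, model) == "g1"
        assert assign_group(AB, model) == "g2"

    def test_equidistant_three_marker_haplotype_unassigned(self):
        """Cross-checked by enumerating every similarity explicitly."""
        g1 = frozenset({("A", "B", "C")})
        g2 = frozenset({("a", "B", "c")})
        model = GroupModel(g1, g2, 3)
        h = ("A", "B", "c")  # run of 2 against both members
        sims1 = [length_similarity(h, m) for m in g1]
        sims2 = [length_similarity(h, m) for m in g2]
        assert max(sims1) == max(sims2) == 2
        assert assign_group(h, model) is None

    def test_empty_model_assigns_nothing(self):
        model = GroupModel(frozenset(), frozenset(), 2)
        assert assign_group(AB, model) is None


class TestTwoGroupCounts:
    def test_worked_example_counts(self, worked_example):
        train, test = worked_example
        txs, _ = phase_dataset(train, (0, 2))
        model = build_groups(count_transmissions(txs))
        test_txs, _ = phase_dataset(test, (0, 2))
        counts = two_group_counts(test_txs, model)
        assert (counts.n_t, counts.n_u) == (51, 34)
        assert counts.n_used == 85

    def test_empty_g2_yields_no_counts(self, worked_example):
        _, test = worked_example
        model = GroupModel(frozenset({AB, Ab, aB, ab}), frozenset(), 2)
        test_txs, _ = phase_dataset(test, (0, 2))
        counts = two_group_counts(test_txs, model)
        assert (counts.n_t, counts.n_u) == (0, 0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_counts_match_independent_tally(self, seed):
        ds = random_trios(60, 2, seed=seed)
        train, test = holdout_split(ds, 0.5, seed=seed)
        txs, _ = phase_dataset(train, (0, 2))
        model = build_groups(count_transmissions(txs))
        test_txs, _ = phase_dataset(test, (0, 2))
        counts = two_group_counts(test_txs, model)
        tally = 0
        for tx in test_txs:
            if not tx.heterozygous:
                continue
            gt = assign_group(tx.transmitted, model)
            gu = assign_group(tx.nontransmitted, model)
            tally += gt is not None and gu is not None and gt != gu
        assert counts.n_used == tally


class TestStatistic2G:
    def test_worked_example_statistic(self):
        res = statistic_2g(TwoByTwoCounts(51, 34))
        assert res.statistic == pytest.approx((51 - 34) ** 2 / 85)
        assert res.statistic == pytest.approx(3.4)
        assert res.p_value == pytest.approx(float(chi2.sf(3.4, 1)), rel=1e-12)
        assert res.p_value == pytest.approx(0.0652, abs=5e-4)

    @pytest.mark.parametrize("k", [1, 7, 30])
    def test_balanced_counts_give_zero(self, k):
        res = statistic_2g(TwoByTwoCounts(k, k))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("m", [1, 5, 12])
    def test_one_sided_counts_give_m(self, m):
        assert statistic_2g(TwoByTwoCounts(m, 0)).statistic == pytest.approx(m)

    def test_no_informative_genotypes_flagged(self):
        res = statistic_2g(TwoByTwoCounts(0, 0))
        assert res.p_value == 1.0
        assert "no informative genotypes" in res.flags

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoCounts(-1, 3)


class TestPipeline:
    def test_holdout_wrap_with_2g_base_equals_test_2g(self):
        ds = random_trios(80, 2, seed=4)
        a = holdout_wrap(TwoGroupsTest(), ds, (0, 2), 0.5, seed=9)
        b = run_2g(ds, (0, 2), seed=9)
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_allele_relabeling_invariance(self):
        """Consistently renaming the alleles at any marker leaves the
        statistic unchanged (groups and similarities relabel along)."""
        from tdt2g.datasets import TrioDataset, trio_from_phases

        ds = random_trios(100, 3, seed=5)
        relabel = {"1": "x", "2": "y"}

        def rl(h):  # rename alleles at marker 1 only
            return tuple(relabel[a] if i == 1 else a for i, a in enumerate(h))

        renamed = []
        for t in ds:
            renamed.append(
                trio_from_phases(
                    t.family_id,
                    (rl(t.father_phase[0]), rl(t.father_phase[1])),
                    (rl(t.mother_phase[0]), rl(t.mother_phase[1])),
                )
            )
        ds2 = TrioDataset(renamed, 3)
        r1 = run_2g(ds, (0, 3), seed=11)
        r2 = run_2g(ds2, (0, 3), seed=11)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.n_informative == r2.n_informative

    def test_max_holdout_matches_hand_computation_on_small_fixture(self):
        """10-trio fixture: the training argmax haplotype and the one-vs-rest
        test counts are enumerated by hand."""
        from tdt2g.datasets import TrioDataset, trio_from_phases

        # training: Ab overtransmitted (4:1), others balanced
        train_pairs = [(Ab, AB)] * 4 + [(AB, Ab)] + [(aB, ab), (ab, aB)] * 2
        test_pairs = [(Ab, AB)] * 3 + [(AB, Ab)] * 2 + [(aB, ab)] * 3 + [(ab, aB)] * 2
        mk = lambda pairs, pre: TrioDataset(
            [
                trio_from_phases(f"{pre}{i}", pairs[2 * i], pairs[2 * i + 1])
                for i in range(len(pairs) // 2)
            ],
            2,
        )
        train, test = mk(train_pairs, "tr"), mk(test_pairs, "te")
        res = cross_sample_test(MaxTest(), train, test, (0, 2))
        # argmax on training is Ab (one-vs-rest (4,1) -> 1.8; aB/ab: 0)
        # test one-vs-rest for Ab: transmitted 3, nontransmitted 2;
        # aB->g2, ab->g2, AB->g2: cross-group genotypes are the Ab/AB ones
        assert res.n_informative == 5
        assert res.statistic == pytest.approx((3 - 2) ** 2 / 5)
        assert res.df == 1

    def test_mhet_holdout_df_equals_training_haplotypes_minus_one(self):
        ds = random_trios(120, 2, seed=6)
        train, test = holdout_split(ds, 0.5, seed=3)
        txs, _ = phase_dataset(train, (0, 2))
        H = count_transmissions(txs).n_distinct
        res = cross_sample_test(MhetTest(), train, test, (0, 2))
        assert res.df == H - 1


class TestWorkedExampleEndToEnd:
    def test_full_pipeline_reproduces_published_numbers(self, worked_example):
        train, test = worked_example
        res = cross_sample_test(TwoGroupsTest(), train, test, (0, 2))
        assert res.statistic == pytest.approx(3.4)
        assert res.n_informative == 85

    def test_fixture_is_bit_reproducible(self):
        a = worked_example_dataset()
        b = worked_example_dataset()
        assert a[0].trios == b[0].trios and a[1].trios == b[1].trios
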
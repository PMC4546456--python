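"""Activation calls, group summaries, triplet coverage, menu selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sims.combinations import (
    build_activation_matrix,
    classify_activation,
    enumerate_triplets,
    group_summary,
    pair_counts,
    percent_of,
    round_half_away,
    select_menu,
    shared_gene_pairs,
)
from sims.errors import DataError
from sims.registry import DEFAULT_ALIASES, MergedNodeAlias

from conftest import random_scores


def bool_matrix(data, labels, patients=None):
    data = np.asarray(data, dtype=bool)
    patients = patients or [f"P{i:03d}" for i in range(data.shape[0])]
    return pd.DataFrame(data, index=patients, columns=labels)


def oracle_triplet_counts(matrix):
    """Independent recount via per-label patient-set intersections."""
    sets = {
        lab: frozenset(matrix.index[matrix[lab]]) for lab in matrix.columns
    }
    return {
        combo: len(sets[combo[0]] & sets[combo[1]] & sets[combo[2]])
        for combo in itertools.combinations(sorted(matrix.columns), 3)
    }


class TestClassification:
    @pytest.mark.parametrize(
        "score,category",
        [(10, "high"), (9, "high"), (8, "high"),
         (7, "medium"), (6, "medium"),
         (5, "none"), (1, "none")],
    )
    def test_categories(self, score, category):
        assert classify_activation(score) == category

    @pytest.mark.parametrize("bad", [0, 11, -3])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(DataError, match="range"):
            classify_activation(bad)

    def test_non_integer_rejected(self):
        with pytest.raises(DataError):
            classify_activation(6.5)


class TestActivationMatrix:
    def test_all_max_scores_give_all_true(self):
        scores = pd.DataFrame(10, index=["mTOR", "PI3K", "HER"], columns=["P1", "P2"])
        matrix = build_activation_matrix(scores)
        assert matrix.to_numpy().all()
        assert "mTOR/PI3K" in matrix.columns

    def test_alias_union_counts(self, rng):
        # 30 mTOR-activated, 28 PI3K-activated, overlap 16 -> union 42
        n = 121
        mtor = np.zeros(n, bool)
        pi3k = np.zeros(n, bool)
        mtor[:30] = True
        pi3k[14:42] = True  # 16 overlap with the first 30
        scores = pd.DataFrame(
            np.where(np.vstack([mtor, pi3k]), 10, 1),
            index=["mTOR", "PI3K"],
            columns=[f"P{i:03d}" for i in range(n)],
        )
        matrix = build_activation_matrix(scores)
        assert int(matrix["mTOR"].sum()) == 30
        assert int(matrix["PI3K"].sum()) == 28
        assert int(matrix["mTOR/PI3K"].sum()) == 42

    def test_alias_union_bounds(self, rng):
        scores = random_scores(rng, names=["mTOR", "PI3K"], n_patients=60)
        matrix = build_activation_matrix(scores)
        union = int(matrix["mTOR/PI3K"].sum())
        members = [int(matrix["mTOR"].sum()), int(matrix["PI3K"].sum())]
        assert max(members) <= union <= sum(members)

    def test_threshold_monotonicity(self, rng):
        scores = random_scores(rng, n_nodes=5, n_patients=40)
        strict = build_activation_matrix(scores, aliases=(), activated_min=8)
        loose = build_activation_matrix(scores, aliases=(), activated_min=6)
        assert (strict.to_numpy() <= loose.to_numpy()).all()

    def test_alias_with_unknown_member_rejected(self, rng):
        scores = random_scores(rng, names=["A", "B", "C"])
        bad = (MergedNodeAlias("x", ("A", "NOPE")),)
        with pytest.raises(DataError, match="unknown"):
            build_activation_matrix(scores, aliases=bad)


class TestRounding:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (63, 121, 52), (58, 121, 48), (36, 121, 30),
            (88, 121, 73), (23, 121, 19), (34, 121, 28),
            (87, 121, 72), (60, 121, 50),
        ],
    )
    def test_published_percentages_reproduced(self, count, total, expected):
        assert percent_of(count, total) == expected

    def test_half_rounds_away_from_zero(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(2.5) == 3
        assert round_half_away(-0.5) == -1


class TestGroupSummary:
    @staticmethod
    def matrix_121():
        rng = np.random.default_rng(7)
        n = 121
        pdl1 = np.zeros(n, bool)
        pdl1[:63] = True
        ctla4 = np.zeros(n, bool)
        ctla4[27:85] = True  # 58 activated, overlap 36 with PDL1
        mek = rng.random(n) < 0.4
        return bool_matrix(np.column_stack([pdl1, ctla4, mek]),
                           ["PDL1", "CTLA4", "MEK"])

    def test_group_sizes_and_cohort_percentages(self):
        m = self.matrix_121()
        g1 = group_summary(m, "PDL1")
        assert (g1.size, g1.cohort_size, g1.percent_of_cohort) == (63, 121, 52)
        g2 = group_summary(m, "CTLA4")
        assert (g2.size, g2.percent_of_cohort) == (58, 48)
        neither = group_summary(m, lambda x: ~(x["PDL1"] | x["CTLA4"]), name="neither")
        assert (neither.size, neither.percent_of_cohort) == (36, 30)

    def test_within_group_percentages(self):
        m = self.matrix_121()
        g = group_summary(m, "PDL1")
        assert g.table.at["PDL1", "count"] == 63
        assert g.table.at["PDL1", "percent"] == 100
        mek_count = int((m["PDL1"] & m["MEK"]).sum())
        assert g.table.at["MEK", "count"] == mek_count
        assert g.table.at["MEK", "percent"] == percent_of(mek_count, 63)

    def test_empty_group_all_zero(self):
        m = self.matrix_121()
        g = group_summary(m, lambda x: pd.Series(False, index=x.index), name="none")
        assert g.size == 0
        assert (g.table["count"] == 0).all()
        assert (g.table["percent"] == 0).all()

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError, match="unknown group"):
            group_summary(self.matrix_121(), "NOPE")


class TestEnumerateTriplets:
    def test_four_labels_all_active(self):
        m = bool_matrix(np.ones((4, 4)), list("ABCD"))
        triplets = enumerate_triplets(m)
        assert len(triplets) == 4  # C(4,3)
        assert all(t.count == 4 and t.percent == 100 for t in triplets)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            n_pat = int(rng.integers(5, 201))
            n_lab = int(rng.integers(3, 25))
            m = bool_matrix(
                rng.random((n_pat, n_lab)) < rng.uniform(0.2, 0.8),
                [f"L{i:02d}" for i in range(n_lab)],
            )
            expected = oracle_triplet_counts(m)
            got = {t.labels: t.count for t in enumerate_triplets(m)}
            assert got == expected
            for t in enumerate_triplets(m):
                assert t.percent == percent_of(t.count, n_pat)

    def test_sorted_by_count_then_lexicographic(self, rng):
        m = bool_matrix(rng.random((50, 6)) < 0.5, list("ABCDEF"))
        triplets = enumerate_triplets(m)
        keys = [(-t.count, t.labels) for t in triplets]
        assert keys == sorted(keys)

    def test_must_include_constraint(self, rng):
        m = bool_matrix(rng.random((20, 5)) < 0.5, list("ABCDE"))
        for t in enumerate_triplets(m, must_include=["A"]):
            assert "A" in t.labels
        assert len(enumerate_triplets(m, must_include=["A"])) == 6  # C(4,2)

    def test_excluded_pairs_constraint(self, rng):
        m = bool_matrix(rng.random((20, 4)) < 0.5, list("ABCD"))
        out = enumerate_triplets(m, excluded_pairs=[("A", "B")])
        assert all(not {"A", "B"} <= set(t.labels) for t in out)
        assert len(out) == 2  # ACD, BCD

    def test_overconstrained_returns_empty_with_warning(self, rng, caplog):
        m = bool_matrix(rng.random((5, 3)) < 0.5, list("ABC"))
        with caplog.at_level("WARNING"):
            out = enumerate_triplets(m, excluded_pairs=[("A", "B")])
        assert out == []
        assert "eliminated" in caplog.text

    def test_threshold_antimonotone_in_counts(self, rng):
        scores = random_scores(rng, n_nodes=6, n_patients=80)
        loose = {
            t.labels: t.count
            for t in enumerate_triplets(
                build_activation_matrix(scores, (), activated_min=6)
            )
        }
        strict = {
            t.labels: t.count
            for t in enumerate_triplets(
                build_activation_matrix(scores, (), activated_min=8)
            )
        }
        assert all(strict[k] <= loose[k] for k in loose)

    def test_fewer_than_three_labels_rejected(self, rng):
        with pytest.raises(DataError, match="at least 3"):
            enumerate_triplets(bool_matrix(np.ones((3, 2)), ["A", "B"]))


class TestMenuSelection:
    @staticmethod
    def planted_matrix():
        """9 labels forming three designed triplets: A covers patients 0-4,
        B covers 3-7, C covers 8."""
        patients = 9
        labels = ["a1", "a2", "a3", "b1", "b2", "b3", "c1", "c2", "c3"]
        m = np.zeros((patients, 9), bool)
        m[0:5, 0:3] = True
        m[3:8, 3:6] = True
        m[8, 6:9] = True
        return bool_matrix(m, labels)

    def test_k1_returns_max_count_triplet(self):
        m = self.planted_matrix()
        menu = select_menu(m, k=1)
        assert menu.entries[0].triplet.count == 5
        assert menu.entries[0].triplet.labels == ("a1", "a2", "a3")

    def test_greedy_two_step_coverage(self):
        m = self.planted_matrix()
        menu = select_menu(m, k=2)
        chosen = [e.triplet.labels for e in menu.entries]
        assert chosen[0] == ("a1", "a2", "a3")
        assert chosen[1] == ("b1", "b2", "b3")
        assert menu.coverage == 8
        # exhaustive 2-menu search agrees
        exhaustive = select_menu(m, k=2, method="exhaustive")
        assert exhaustive.coverage == 8

    def test_cumulative_coverage_nondecreasing(self, rng):
        m = bool_matrix(rng.random((60, 8)) < 0.4, [f"L{i}" for i in range(8)])
        menu = select_menu(m, k=6)
        coverage = [e.cumulative_coverage for e in menu.entries]
        assert coverage == sorted(coverage)
        assert all(e.new_patients >= 0 for e in menu.entries)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_greedy_vs_exhaustive_on_small_instances(self, k):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n_lab = int(rng.integers(4, 7))
            m = bool_matrix(
                rng.random((25, n_lab)) < 0.45,
                [f"L{i}" for i in range(n_lab)],
            )
            greedy = select_menu(m, k=k, method="greedy")
            optimal = select_menu(m, k=k, method="exhaustive")
            auto = select_menu(m, k=k)  # <= 8 labels: auto picks exhaustive
            assert optimal.coverage >= greedy.coverage
            assert greedy.coverage >= (1 - 1 / np.e) * optimal.coverage
            assert auto.coverage == optimal.coverage

    def test_menu_shorter_than_k_when_triplets_scarce(self, rng, caplog):
        m = bool_matrix(rng.random((10, 3)) < 0.5, list("ABC"))
        with caplog.at_level("WARNING"):
            menu = select_menu(m, k=5)
        assert len(menu.entries) == 1

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(DataError, match="k must be"):
            select_menu(bool_matrix(np.ones((3, 3)), list("ABC")), k=0)


class TestIndependenceDefaults:
    def test_shared_gene_pairs(self, registry):
        pairs = {frozenset(p) for p in shared_gene_pairs(registry)}
        assert frozenset({"PARP", "DNA Repair"}) in pairs  # BRCA1 shared
        assert frozenset({"MEK", "Ras/Raf"}) not in pairs  # disjoint gene sets
        # an alias shares genes with each of its members
        assert frozenset({"mTOR/PI3K", "mTOR"}) in pairs
        assert frozenset({"mTOR/PI3K", "PI3K"}) in pairs


class TestPairCounts:
    def test_explicit_pair_counts(self, rng):
        m = bool_matrix(rng.random((40, 4)) < 0.5, list("ABCD"))
        table = pair_counts(m).set_index(["label1", "label2"])
        for a, b in itertools.combinations(sorted(m.columns), 2):
            assert table.at[(a, b), "count"] == int((m[a] & m[b]).sum())
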
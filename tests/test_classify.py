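import itertools

import numpy as np
import pytest

from spcregress import (
    SpectralCountMatrix,
    apply_rules,
    fit_two_node_tree,
    logistic_rank,
    roc_threshold,
)


def presence_matrix(znf_detected_reg, pld_detected_reg, n_per_group=10):
    """Offset (+1) presence matrix mimicking printed detection patterns:
    detected regression samples get offset count 2, everything else 1."""
    samples = [f"r{i}" for i in range(n_per_group)] + [
        f"p{i}" for i in range(n_per_group)
    ]
    znf = [2 if i < znf_detected_reg else 1 for i in range(n_per_group)] + [1] * n_per_group
    pld = [2 if i < pld_detected_reg else 1 for i in range(n_per_group)] + [1] * n_per_group
    return SpectralCountMatrix(
        counts=np.array([znf, pld]),
        protein_ids=["ZNF441", "PLD6"],
        sample_ids=samples,
        group_of={s: ("regression" if s.startswith("r") else "persistence")
                  for s in samples},
        offset_applied=True,
    )


class TestROCThreshold:
    def test_detection_pattern_gives_le1_vs_gt1_rule(self):
        m = presence_matrix(10, 7)
        y = m.y()
        rule = roc_threshold(m.counts[0], y, "ZNF441")
        # equivalent to "<= 1 vs > 1": high side predicts regression
        assert 1.0 < rule.threshold < 2.0
        assert rule.direction == "gt_is_regression"
        assert rule.youden_j == pytest.approx(1.0)
        assert np.array_equal(rule.predict(m.counts[0]), y)

    def test_constant_values_flagged_uninformative(self):
        y = np.array([0.0] * 5 + [1.0] * 5)
        rule = roc_threshold(np.ones(10), y)
        assert rule.uninformative and rule.youden_j == pytest.approx(0.0)

    def test_matches_exhaustive_youden_search(self):
        def oracle_j(v, y):
            best = 0.0
            for thr in np.concatenate([np.unique(v) - 1e-9, np.unique(v) + 1e-9]):
                gt = v > thr
                n1, n0 = (y == 1).sum(), (y == 0).sum()
                j = abs((gt & (y == 1)).sum() / n1 - (gt & (y == 0)).sum() / n0)
                best = max(best, j)
            return best

        rng = np.random.default_rng(31)
        y = np.array([0.0] * 10 + [1.0] * 10)
        for _ in range(10):
            v = np.round(rng.normal(size=20) + y, 1)
            rule = roc_threshold(v, y)
            assert rule.youden_j == pytest.approx(oracle_j(v, y), abs=1e-9)

    @pytest.mark.parametrize("transform", [lambda v: 2 * v + 1, np.exp,
                                           lambda v: v**3])
    def test_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(32)
        y = np.array([0.0] * 8 + [1.0] * 8)
        v = rng.normal(size=16) + 1.5 * y
        base = roc_threshold(v, y)
        trans = roc_threshold(transform(v), y)
        assert trans.youden_j == pytest.approx(base.youden_j, abs=1e-9)
        assert np.array_equal(base.predict(v), trans.predict(transform(v)))


class TestApplyRules:
    def test_learning_pattern_classified_perfectly(self):
        m = presence_matrix(10, 7)
        rule = roc_threshold(m.counts[0], m.y(), "ZNF441")
        _, summary = apply_rules(rule, m)
        assert summary["n_correct"] == 20
        assert summary["correct_by_group"] == {"regression": 10, "persistence": 10}

    def test_validation_pattern_19_of_20(self):
        m = presence_matrix(9, 5)
        rule = roc_threshold(presence_matrix(10, 7).counts[0],
                             presence_matrix(10, 7).y(), "ZNF441")
        _, summary = apply_rules(rule, m)
        assert summary["correct_by_group"] == {"regression": 9, "persistence": 10}
        assert summary["n_correct"] == 19

    def test_all_absent_predicts_persistence(self):
        m = presence_matrix(0, 0)
        rule = roc_threshold(presence_matrix(10, 7).counts[0],
                             presence_matrix(10, 7).y(), "ZNF441")
        pred, _ = apply_rules(rule, m)
        assert (pred == 1).all()

    def test_confusion_counts_sum_to_n(self):
        m = presence_matrix(6, 3)
        rule = roc_threshold(m.counts[0], m.y(), "ZNF441")
        _, summary = apply_rules(rule, m)
        assert sum(summary["confusion"].values()) == 20

    def test_missing_accession_named(self):
        m = presence_matrix(10, 7)
        rule = roc_threshold(m.counts[0], m.y(), "NOPE")
        with pytest.raises(KeyError, match="NOPE"):
            apply_rules(rule, m)


def random_count_matrix(rng, n_proteins, n_samples):
    y = np.array([0.0] * (n_samples // 2) + [1.0] * (n_samples - n_samples // 2))
    counts = rng.integers(0, 6, size=(n_proteins, n_samples))
    samples = [f"s{j}" for j in range(n_samples)]
    m = SpectralCountMatrix(
        counts=counts,
        protein_ids=[f"P{i}" for i in range(n_proteins)],
        sample_ids=samples,
        group_of={s: ("persistence" if y[j] else "regression")
                  for j, s in enumerate(samples)},
    )
    return m, y


class TestTwoNodeTree:
    def gini_oracle(self, m, y):
        """Exhaustive search over every protein and every threshold."""
        def gini(sub):
            if sub.size == 0:
                return 0.0
            p = sub.mean()
            return 2 * p * (1 - p)

        best = (0.0, None, None)
        parent = gini(y)
        for i, acc in enumerate(m.protein_ids):
            v = m.counts[i].astype(float)
            for thr in np.unique(v)[:-1] + 0.5:
                gt = v > thr
                dec = parent - gt.mean() * gini(y[gt]) - (~gt).mean() * gini(y[~gt])
                if dec > best[0] + 1e-12:
                    best = (dec, acc, thr)
        return best

    def test_root_matches_exhaustive_search(self):
        rng = np.random.default_rng(41)
        for _ in range(15):
            m, y = random_count_matrix(rng, rng.integers(2, 9), 20)
            tree = fit_two_node_tree(m, y)
            dec, acc, _ = self.gini_oracle(m, y)
            if tree.degenerate:
                assert dec <= 1e-12
            else:
                got_dec = dict(tree.competitor_ranking)[tree.root.accession]
                assert got_dec == pytest.approx(dec, abs=1e-12)

    def test_perfect_root_and_partial_competitor(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        perfect = np.array([3] * 10 + [0] * 10)
        partial = np.array([3] * 7 + [0] * 13)
        noise = np.array([1, 2] * 10)
        m = SpectralCountMatrix(
            counts=np.vstack([noise, partial, perfect]),
            protein_ids=["C_noise", "B_partial", "A_perfect"],
            sample_ids=[f"s{j}" for j in range(20)],
            group_of={f"s{j}": ("persistence" if j >= 10 else "regression")
                      for j in range(20)},
        )
        tree = fit_two_node_tree(m, y)
        assert tree.root.accession == "A_perfect"
        assert tree.child is None  # both branches pure
        assert [a for a, _ in tree.competitor_ranking[:2]] == ["A_perfect", "B_partial"]

    def test_child_refines_impure_branch(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        # root separates 7 regression; the remaining mixed branch is fixed by P2
        p1 = np.array([5] * 7 + [0] * 13)
        p2 = np.array([0] * 7 + [4, 4, 4] + [0] * 10)
        m = SpectralCountMatrix(
            counts=np.vstack([p1, p2]),
            protein_ids=["P1", "P2"],
            sample_ids=[f"s{j}" for j in range(20)],
            group_of={f"s{j}": ("persistence" if j >= 10 else "regression")
                      for j in range(20)},
        )
        tree = fit_two_node_tree(m, y)
        assert tree.root.accession == "P1"
        assert tree.child is not None and tree.child.accession == "P2"
        pred = tree.predict({a: m.counts[i].astype(float)
                             for i, a in enumerate(m.protein_ids)})
        assert (pred == y).all()

    def test_pure_input_degenerate(self):
        rng = np.random.default_rng(42)
        m, _ = random_count_matrix(rng, 3, 10)
        tree = fit_two_node_tree(m, np.zeros(10))
        assert tree.degenerate and tree.root is None

    def test_identical_separators_tie_broken_by_accession(self):
        y = np.array([0.0] * 5 + [1.0] * 5)
        sep = np.array([4] * 5 + [0] * 5)
        m = SpectralCountMatrix(
            counts=np.vstack([sep, sep]),
            protein_ids=["B", "A"],
            sample_ids=[f"s{j}" for j in range(10)],
            group_of={f"s{j}": ("persistence" if j >= 5 else "regression")
                      for j in range(10)},
        )
        assert fit_two_node_tree(m, y).root.accession == "A"


class TestLogisticRank:
    def test_perfect_separator_flagged_and_top(self):
        rng = np.random.default_rng(51)
        m, y = random_count_matrix(rng, 4, 20)
        m.counts[2] = np.where(y == 1, 9, 0)
        entries = logistic_rank(m, y)
        assert entries[0].accession == "P2"
        assert entries[0].separated and np.isinf(entries[0].lr_stat)

    def test_constant_protein_scores_zero(self):
        rng = np.random.default_rng(52)
        m, y = random_count_matrix(rng, 3, 20)
        m.counts[1] = 4
        entry = {e.accession: e for e in logistic_rank(m, y)}["P1"]
        assert entry.lr_stat == pytest.approx(0.0)

    def test_planted_beats_permuted_null(self):
        """Planted discriminator outranks its label-permuted copy in >=95/100."""
        rng = np.random.default_rng(53)
        y = np.array([0.0] * 10 + [1.0] * 10)
        wins = 0
        for _ in range(100):
            planted = rng.poisson(3, size=20) + 3 * y  # group-shifted counts
            null = rng.permutation(planted)
            m = SpectralCountMatrix(
                counts=np.vstack([planted, null]).astype(int),
                protein_ids=["planted", "null"],
                sample_ids=[f"s{j}" for j in range(20)],
                group_of={f"s{j}": ("persistence" if j >= 10 else "regression")
                          for j in range(20)},
            )
            entries = {e.accession: e for e in logistic_rank(m, y)}
            lr_p = entries["planted"].lr_stat
            lr_n = entries["null"].lr_stat
            wins += int(lr_n < lr_p or (np.isinf(lr_p) and not np.isinf(lr_n)))
        assert wins >= 95
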
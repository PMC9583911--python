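"""Gini impurity, tree construction and donor identification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from skinprint.identity import (
    UNLABELED,
    build_tree,
    evaluate_identifier,
    gini,
    gini_index,
    identify,
    tree_from_json,
    tree_to_json,
)


def enumerate_gini_oracle(labels):
    """Definition-level oracle: 1 - sum over classes of p^2."""
    n = len(labels)
    return 1 - sum((labels.count(c) / n) ** 2 for c in set(labels))


class TestGini:
    def test_pure_set_is_zero(self):
        assert gini(["A", "A", "A"]) == 0.0

    def test_even_two_class_split_is_half(self):
        assert gini(["A"] * 3 + ["B"] * 3) == pytest.approx(0.5)

    def test_uniform_k_classes(self):
        for k in (2, 3, 4, 5):
            labels = [f"C{i}" for i in range(k)]
            assert gini(labels) == pytest.approx(1 - 1 / k)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gini([])

    def test_matches_enumeration_oracle_on_all_small_multisets(self):
        """Exhaustive: every label multiset of size <= 6 over 3 classes."""
        for size in range(1, 7):
            for combo in itertools.combinations_with_replacement("ABC", size):
                assert gini(list(combo)) == pytest.approx(
                    enumerate_gini_oracle(list(combo))
                )


def _lookup(values):
    """sample -> {individual: rpkm} from a dict of per-sample values."""
    return {sid: dict(v) for sid, v in values.items()}


class TestGiniIndex:
    def test_perfect_split_is_zero(self):
        labels = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        lookup = _lookup({f"s{i}": {"A": 5.0 if i < 4 else 0.0} for i in range(8)})
        assert gini_index(labels, ("A", 1.0), lookup) == 0.0

    def test_split_separating_nothing_equals_parent_gini(self):
        labels = {f"s{i}": ("A" if i % 2 else "B") for i in range(6)}
        lookup = _lookup({f"s{i}": {"A": 0.0} for i in range(6)})
        assert gini_index(labels, ("A", 1.0), lookup) == pytest.approx(
            gini(list(labels.values()))
        )

    def test_matches_exhaustive_enumeration(self):
        """Weighted-branch oracle over all small assignments."""
        for n_above in range(0, 5):
            labels = {f"s{i}": "ABC"[i % 3] for i in range(4)}
            lookup = _lookup(
                {f"s{i}": {"X": 9.0 if i < n_above else 0.0} for i in range(4)}
            )
            above = [labels[f"s{i}"] for i in range(n_above)]
            below = [labels[f"s{i}"] for i in range(n_above, 4)]
            expected = sum(
                len(b) / 4 * enumerate_gini_oracle(b) for b in (above, below) if b
            )
            assert gini_index(labels, ("X", 1.0), lookup) == pytest.approx(expected)

    def test_missing_rpkm_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            gini_index({"s": "A"}, ("A", 1.0), {"s": {}})


def separable_setup(n_per=3):
    """Three individuals whose fingerprints perfectly separate training data."""
    inds = ["HV01", "HV02", "HV03"]
    samples = [f"{ind}_s{i}" for ind in inds for i in range(n_per)]
    rpkm = pd.DataFrame(0.0, index=inds, columns=samples)
    for ind in inds:
        for sid in samples:
            if sid.startswith(ind):
                rpkm.at[ind, sid] = 50.0
    thresholds = {ind: 10.0 for ind in inds}
    labels = {sid: sid.split("_")[0] for sid in samples}
    return rpkm, thresholds, labels


class TestBuildTree:
    def test_separable_training_data_routes_perfectly(self):
        rpkm, thresholds, labels = separable_setup()
        tree = build_tree(rpkm, thresholds, labels)
        report = evaluate_identifier(tree, rpkm, labels)
        assert report.accuracy == 1.0

    def test_tree_is_deterministic(self):
        rpkm, thresholds, labels = separable_setup()
        a = tree_to_json(build_tree(rpkm, thresholds, labels))
        b = tree_to_json(build_tree(rpkm, thresholds, labels))
        assert a == b

    def test_silent_fingerprints_sink_to_the_bottom(self):
        """Individuals whose fingerprint never fires are decided last."""
        rpkm, thresholds, labels = separable_setup()
        rpkm.loc["HV01"] = 0.0  # HV01's fingerprint exceeds no threshold
        tree = build_tree(rpkm, thresholds, labels)
        order = []
        node = tree
        while node.kind == "decision":
            order.append(node.individual_id)
            node = node.below
        assert order[-1] == "HV01"
        assert node.individual_id == UNLABELED

    def test_every_individual_keeps_a_leaf_even_with_empty_branches(self):
        rpkm, thresholds, labels = separable_setup()
        tree = build_tree(rpkm, thresholds, labels)
        seen = set()
        stack = [tree]
        while stack:
            n = stack.pop()
            if n.kind == "leaf":
                seen.add(n.individual_id)
            else:
                stack.extend([n.above, n.below])
        assert seen == {"HV01", "HV02", "HV03", UNLABELED}

    def test_unlabeled_leaf_is_unique(self):
        rpkm, thresholds, labels = separable_setup()
        tree = build_tree(rpkm, thresholds, labels)
        count = 0
        stack = [tree]
        while stack:
            n = stack.pop()
            if n.kind == "leaf" and n.individual_id == UNLABELED:
                count += 1
            elif n.kind == "decision":
                stack.extend([n.above, n.below])
        assert count == 1

    def test_json_roundtrip_preserves_decisions(self, tmp_path):
        rpkm, thresholds, labels = separable_setup()
        tree = build_tree(rpkm, thresholds, labels)
        tree_to_json(tree, tmp_path / "t.json")
        back = tree_from_json(tmp_path / "t.json")
        assert tree_to_json(back) == tree_to_json(tree)


class TestIdentify:
    def _tree(self):
        rpkm, thresholds, labels = separable_setup()
        return build_tree(rpkm, thresholds, labels)

    def test_sample_above_root_threshold_gets_that_label(self):
        tree = self._tree()
        root = tree.individual_id
        abund = {ind: 0.0 for ind in ["HV01", "HV02", "HV03"]}
        abund[root] = 99.0
        assert identify(tree, abund) == root

    def test_all_zero_abundances_fall_to_unlabeled(self):
        assert identify(self._tree(), {i: 0.0 for i in ["HV01", "HV02", "HV03"]}) == UNLABELED

    def test_small_subthreshold_signal_stays_unlabeled(self):
        # e.g. an out-of-cohort sample with RPKM 2.2 against threshold 10
        abund = {"HV01": 2.2, "HV02": 0.0, "HV03": 0.0}
        assert identify(self._tree(), abund) == UNLABELED

    def test_missing_abundance_is_named(self):
        with pytest.raises(ValueError, match="HV"):
            identify(self._tree(), {"HV01": 0.0})

    def test_identification_is_invariant_to_dict_order(self):
        tree = self._tree()
        abund = {"HV03": 99.0, "HV01": 0.0, "HV02": 0.0}
        flipped = dict(reversed(list(abund.items())))
        assert identify(tree, abund) == identify(tree, flipped)


class TestEvaluate:
    def test_all_correct_metrics(self):
        rpkm, thresholds, labels = separable_setup()
        tree = build_tree(rpkm, thresholds, labels)
        report = evaluate_identifier(tree, rpkm, labels)
        assert report.accuracy == 1.0
        assert all(v == 1.0 for v in report.precision.values())
        assert all(v == 1.0 for v in report.recall.values())

    def test_unlabeled_in_cohort_sample_counts_as_error(self):
        rpkm, thresholds, labels = separable_setup(n_per=1)
        tree = build_tree(rpkm, thresholds, labels)
        test = rpkm.copy()
        test["HV01_s0"] = 0.0  # silence one sample entirely
        report = evaluate_identifier(tree, test, labels)
        assert report.accuracy == pytest.approx(2 / 3)
        assert report.confusion.at[UNLABELED, "HV01"] == 1

    def test_confusion_matrix_rows_are_predictions(self):
        rpkm, thresholds, labels = separable_setup(n_per=2)
        tree = build_tree(rpkm, thresholds, labels)
        report = evaluate_identifier(tree, rpkm, labels)
        for ind in ["HV01", "HV02", "HV03"]:
            assert report.confusion.at[ind, ind] == 2
        assert report.confusion.to_numpy().sum() == 6
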
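"""ASS scoring, specific-k-mer detection, CV and stability evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from skinprint.cohort import load_sample_reads
from skinprint.kmers import build_matrix, count_canonical_kmers
from skinprint.specificity import (
    ABSENCE,
    PRESENCE,
    SpecificityConfig,
    crossvalidate_specific_kmers,
    detect_specific_kmers,
    evaluate_on_grouping,
    records_from_tsv,
    records_to_tsv,
    rescore_records,
    score_kmer,
)


def brute_force_ass(row, labels):
    """Oracle: best-direction ASS from explicit confusion matrices."""
    best = None
    for direction in (PRESENCE, ABSENCE):
        tp = fn = tn = fp = 0
        for present, positive in zip(row, labels):
            predicted_pos = present if direction == PRESENCE else not present
            if positive and predicted_pos:
                tp += 1
            elif positive:
                fn += 1
            elif predicted_pos:
                fp += 1
            else:
                tn += 1
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        ass = (sens + spec) / 2
        if best is None or ass > best[0]:
            best = (ass, direction)
    return best


class TestScoreKmer:
    def test_hand_confusion_matrix(self):
        # present in 4/5 positives and 1/5 negatives
        row = [1, 1, 1, 1, 0, 1, 0, 0, 0, 0]
        labels = [True] * 5 + [False] * 5
        rec = score_kmer(row, labels)
        assert rec.direction == PRESENCE
        assert rec.sensitivity == pytest.approx(0.8)
        assert rec.specificity == pytest.approx(0.8)
        assert rec.ass == pytest.approx(0.8)

    def test_perfect_presence_separator(self):
        rec = score_kmer([1, 1, 1, 0, 0], [True, True, True, False, False])
        assert rec.ass == 1.0 and rec.direction == PRESENCE

    def test_absence_direction_perfect_separator(self):
        rec = score_kmer([0, 0, 1, 1, 1], [True, True, False, False, False])
        assert rec.ass == 1.0 and rec.direction == ABSENCE

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            score_kmer([1, 0], [True, True])

    @given(st.integers(2, 12), st.integers(0, 2**30))
    def test_matches_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, bool)
        labels[: max(1, n // 2)] = True
        rng.shuffle(labels)
        if labels.all() or not labels.any():
            return
        row = rng.integers(0, 2, n).astype(bool)
        rec = score_kmer(row, labels)
        ass, _direction = brute_force_ass(row.tolist(), labels.tolist())
        assert rec.ass == pytest.approx(ass)

    def test_label_swap_preserves_ass_and_flips_direction(self):
        rng = np.random.default_rng(1)
        row = rng.integers(0, 2, 20).astype(bool)
        labels = np.array([True] * 8 + [False] * 12)
        a = score_kmer(row, labels)
        b = score_kmer(row, ~labels)
        assert a.ass == pytest.approx(b.ass)
        if a.sensitivity != a.specificity:
            assert a.direction != b.direction


def matrix_from_patterns(patterns, n_pos, n_neg):
    """Build a matrix whose rows follow given presence patterns."""
    k = 5
    kmer_pool = ["AACGT", "ACCGT", "AGCGT", "ATCGT", "CACGT", "CCCGT"]
    tables = []
    labels = {}
    for j in range(n_pos + n_neg):
        seqs = [kmer_pool[i] for i, pat in enumerate(patterns) if pat[j]]
        tables.append(
            count_canonical_kmers(seqs or ["GGGGG"], k=k, min_count=1, sample_id=f"s{j}")
        )
        labels[f"s{j}"] = "positive" if j < n_pos else "negative"
    return build_matrix(tables, labels)


class TestDetection:
    def test_threshold_is_inclusive(self):
        # ASS exactly 0.8: present in 4/5 positives, 1/5 negatives
        pattern = [1, 1, 1, 1, 0, 1, 0, 0, 0, 0]
        m = matrix_from_patterns([pattern], 5, 5)
        recs = detect_specific_kmers(m, SpecificityConfig(ass_threshold=0.8))
        assert any(r.ass == pytest.approx(0.8) for r in recs)

    def test_above_threshold_kmer_excluded(self):
        pattern = [1, 1, 1, 1, 0, 0, 1, 0, 0, 0]  # ASS 0.85
        m = matrix_from_patterns([pattern], 5, 5)
        assert detect_specific_kmers(m, SpecificityConfig(ass_threshold=0.9)) == []

    def test_raising_threshold_yields_subset(self):
        rng = np.random.default_rng(0)
        patterns = [rng.integers(0, 2, 12).tolist() for _ in range(6)]
        m = matrix_from_patterns(patterns, 6, 6)
        low = {r.kmer for r in detect_specific_kmers(m, SpecificityConfig(ass_threshold=0.6))}
        high = {r.kmer for r in detect_specific_kmers(m, SpecificityConfig(ass_threshold=0.75))}
        assert high <= low

    def test_records_sorted_by_ass_then_kmer(self):
        rng = np.random.default_rng(3)
        patterns = [rng.integers(0, 2, 12).tolist() for _ in range(6)]
        m = matrix_from_patterns(patterns, 6, 6)
        recs = detect_specific_kmers(m, SpecificityConfig(ass_threshold=0.5))
        keys = [(-r.ass, r.kmer) for r in recs]
        assert keys == sorted(keys)

    def test_planted_variants_score_perfect_ass(self, tiny_cohort):
        """Every truth k-mer of an individual is detected with ASS 1.0."""
        tables = []
        labels = {}
        for s in tiny_cohort.manifest.samples:
            reads = [seq for _, seq in load_sample_reads(s)]
            tables.append(count_canonical_kmers(reads, 31, 3, s.sample_id))
            labels[s.sample_id] = (
                "positive" if s.individual_id == "HV01" else "negative"
            )
        m = build_matrix(tables, labels)
        recs = detect_specific_kmers(m, SpecificityConfig(ass_threshold=0.8))
        perfect = {r.kmer for r in recs if r.ass == 1.0 and r.direction == PRESENCE}
        assert tiny_cohort.truth.kmers["HV01"] <= perfect

    def test_permuted_labels_yield_no_specific_kmers(self):
        """Under a permutation null, a strict threshold detects ~nothing."""
        rng = np.random.default_rng(11)
        patterns = [rng.integers(0, 2, 30).tolist() for _ in range(40)]
        m = matrix_from_patterns_big(patterns, rng)
        recs = detect_specific_kmers(m, SpecificityConfig(ass_threshold=0.9))
        assert len(recs) <= 1

    def test_roundtrip_records_tsv(self, tmp_path):
        pattern = [1, 1, 1, 1, 0, 1, 0, 0, 0, 0]
        m = matrix_from_patterns([pattern], 5, 5)
        recs = detect_specific_kmers(m, SpecificityConfig(ass_threshold=0.8))
        records_to_tsv(recs, tmp_path / "r.tsv")
        back = records_from_tsv(tmp_path / "r.tsv")
        assert [(r.kmer, r.direction, r.ass) for r in back] == [
            (r.kmer, r.direction, r.ass) for r in recs
        ]


def matrix_from_patterns_big(patterns, rng):
    """Random 31-mer rows with random labels (permutation null)."""
    from skinprint.seqcodes import canonical

    n = len(patterns[0])
    kmers = []
    while len(kmers) < len(patterns):
        km = "".join(rng.choice(list("ACGT"), 31))
        if canonical(km) == km:
            kmers.append(km)
    tables = []
    labels = {}
    order = rng.permutation(n)
    for j in range(n):
        seqs = [kmers[i] for i, pat in enumerate(patterns) if pat[j]]
        tables.append(
            count_canonical_kmers(seqs or ["G" * 31], 31, 1, sample_id=f"s{j}")
        )
        labels[f"s{j}"] = "positive" if order[j] < n // 3 else "negative"
    return build_matrix(tables, labels)


class TestCrossValidation:
    def _tables_labels(self, tiny_cohort, target="HV01"):
        tables = {}
        labels = {}
        for s in tiny_cohort.manifest.samples:
            reads = [seq for _, seq in load_sample_reads(s)]
            tables[s.sample_id] = count_canonical_kmers(reads, 31, 3, s.sample_id)
            labels[s.sample_id] = s.individual_id == target
        return tables, labels

    def test_separable_cohort_validates_perfectly(self, tiny_cohort):
        tables, labels = self._tables_labels(tiny_cohort)
        results = crossvalidate_specific_kmers(
            tables, labels, SpecificityConfig(cv_folds=2, seed=0)
        )
        assert len(results) == 2
        for fold in results:
            assert fold.n_detected > 0
            truth = tiny_cohort.truth.kmers["HV01"]
            perfect = {
                r.kmer for r in fold.records if r.ass_validation == 1.0
            }
            assert truth <= perfect

    def test_same_seed_reproduces_folds(self, tiny_cohort):
        tables, labels = self._tables_labels(tiny_cohort)
        cfg = SpecificityConfig(cv_folds=2, seed=5)
        a = crossvalidate_specific_kmers(tables, labels, cfg)
        b = crossvalidate_specific_kmers(tables, labels, cfg)
        assert [f.n_detected for f in a] == [f.n_detected for f in b]
        assert [f.fraction_validated for f in a] == [f.fraction_validated for f in b]

    def test_too_few_positives_rejected(self, tiny_cohort):
        tables, labels = self._tables_labels(tiny_cohort)
        with pytest.raises(ValueError, match="positive"):
            crossvalidate_specific_kmers(
                tables, labels, SpecificityConfig(cv_folds=10)
            )


class TestGroupingEvaluation:
    def test_rescoring_on_training_partition_reproduces_ass(self, tiny_cohort):
        tables = {}
        labels = {}
        for s in tiny_cohort.manifest.samples:
            reads = [seq for _, seq in load_sample_reads(s)]
            tables[s.sample_id] = count_canonical_kmers(reads, 31, 3, s.sample_id)
            labels[s.sample_id] = s.individual_id == "HV02"
        m = build_matrix(
            [tables[s] for s in sorted(tables)],
            {s: ("positive" if labels[s] else "negative") for s in sorted(tables)},
        )
        recs = detect_specific_kmers(m, SpecificityConfig(ass_threshold=0.8))[:50]
        ass = rescore_records(recs, tables, labels)
        assert np.allclose(ass, [r.ass for r in recs])

    def test_stable_variants_hold_up_on_heldout_timepoint(self, tiny_cohort):
        tables = {}
        labels = {}
        by_tp = {}
        for s in tiny_cohort.manifest.samples:
            reads = [seq for _, seq in load_sample_reads(s)]
            tables[s.sample_id] = count_canonical_kmers(reads, 31, 3, s.sample_id)
            labels[s.sample_id] = s.individual_id == "HV01"
            by_tp.setdefault(s.timepoint, []).append(s.sample_id)
        m = build_matrix(
            [tables[s] for s in by_tp["T1"]],
            {s: ("positive" if labels[s] else "negative") for s in by_tp["T1"]},
        )
        recs = detect_specific_kmers(m, SpecificityConfig(ass_threshold=0.9))
        # presence-direction records are the ones carried into assembly;
        # absence-direction calls on a 2-positive partition are dominated by
        # Poisson coverage dropout and are not expected to be stable
        recs = [r for r in recs if r.direction == PRESENCE]
        assert recs
        out = evaluate_on_grouping(recs, tables, labels, {"T2": by_tp["T2"]})
        assert out["T2"].fraction_ge_08 == 1.0

    def test_partition_without_positives_is_skipped(self, tiny_cohort):
        tables = {}
        labels = {}
        ids = []
        for s in tiny_cohort.manifest.samples:
            reads = [seq for _, seq in load_sample_reads(s)]
            tables[s.sample_id] = count_canonical_kmers(reads, 31, 3, s.sample_id)
            labels[s.sample_id] = s.individual_id == "HV01"
            if s.individual_id != "HV01":
                ids.append(s.sample_id)
        m = build_matrix(
            [tables[s] for s in sorted(tables)],
            {s: ("positive" if labels[s] else "negative") for s in sorted(tables)},
        )
        recs = detect_specific_kmers(m, SpecificityConfig())[:5]
        with pytest.warns(UserWarning, match="skipped"):
            out = evaluate_on_grouping(recs, tables, labels, {"neg_only": ids})
        assert out == {}
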
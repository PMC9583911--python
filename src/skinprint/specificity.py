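"""Individual-specific k-mer detection by single-feature logical predictors.

Every retained k-mer is treated as a one-feature classifier: either its
presence predicts "this individual" (presence direction) or its absence does
(absence direction).  Each direction is scored by ASS — the average of
sensitivity and specificity — and the better direction is kept.  K-mers whose
ASS reaches the threshold θ1 (default 0.80) are called individual-specific.
Cross-validation re-scores fold-detected k-mers on held-out folds, and
``evaluate_on_grouping`` re-scores fixed records on alternative partitions
(timepoints, body-site strata) to probe temporal and spatial stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kmers import KmerCountTable, KmerMatrix, POSITIVE, build_matrix, filter_sparse
from .seqcodes import kmer_to_code

PRESENCE = "presence"
ABSENCE = "absence"


@dataclass
class SpecificKmerRecord:
    kmer: str
    direction: str  # PRESENCE: presence => positive; ABSENCE: absence => positive
    sensitivity: float
    specificity: float
    ass: float
    ass_validation: float | None = None

    def __post_init__(self) -> None:
        if abs(self.ass - (self.sensitivity + self.specificity) / 2) > 1e-12:
            raise ValueError("ass must equal (sensitivity+specificity)/2")


@dataclass
class SpecificityConfig:
    ass_threshold: float = 0.80
    validation_ass_threshold: float = 0.80
    cv_folds: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.ass_threshold <= 1:
            raise ValueError(f"ass_threshold must be in [0.5, 1]; got {self.ass_threshold}")


def _direction_scores(logical: np.ndarray, positive: np.ndarray):
    """Vectorised sens/spec/ASS for both predictor directions.

    ``logical`` is (n_kmers, n_samples) presence; returns arrays of shape
    (n_kmers,) for the chosen direction with ties broken toward presence.
    """
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both groups must be non-empty")
    pres_pos = logical[:, positive].sum(axis=1)
    pres_neg = logical[:, ~positive].sum(axis=1)
    # presence => positive
    sens_p = pres_pos / n_pos
    spec_p = 1 - pres_neg / n_neg
    ass_p = (sens_p + spec_p) / 2
    # absence => positive
    sens_a = 1 - sens_p
    spec_a = pres_neg / n_neg
    ass_a = (sens_a + spec_a) / 2
    use_presence = ass_p >= ass_a  # tie -> presence
    sens = np.where(use_presence, sens_p, sens_a)
    spec = np.where(use_presence, spec_p, spec_a)
    ass = np.where(use_presence, ass_p, ass_a)
    return use_presence, sens, spec, ass


def score_kmer(logical_row: Sequence[int], labels: Sequence[bool]) -> SpecificKmerRecord:
    """Score one presence/absence row against group labels (True = positive)."""
    row = np.asarray(logical_row, bool).reshape(1, -1)
    positive = np.asarray(labels, bool)
    use_presence, sens, spec, ass = _direction_scores(row, positive)
    return SpecificKmerRecord(
        kmer="",
        direction=PRESENCE if use_presence[0] else ABSENCE,
        sensitivity=float(sens[0]),
        specificity=float(spec[0]),
        ass=float(ass[0]),
    )


def detect_specific_kmers(
    matrix: KmerMatrix, config: SpecificityConfig | None = None
) -> list[SpecificKmerRecord]:
    """All k-mers with ASS >= θ1, sorted by ASS descending then k-mer ascending."""
    config = config or SpecificityConfig()
    if matrix.n_kmers == 0:
        warnings.warn("empty k-mer matrix; no specific k-mers")
        return []
    use_presence, sens, spec, ass = _direction_scores(matrix.logical, matrix.positive)
    hit = ass >= config.ass_threshold - 1e-12
    idx = np.nonzero(hit)[0]
    # sort by ASS descending, then code (== lexicographic k-mer) ascending
    order = np.lexsort((matrix.codes[idx], -ass[idx]))
    idx = idx[order]
    kmers = matrix.kmer_strings()
    return [
        SpecificKmerRecord(
            kmer=kmers[i],
            direction=PRESENCE if use_presence[i] else ABSENCE,
            sensitivity=float(sens[i]),
            specificity=float(spec[i]),
            ass=float(ass[i]),
        )
        for i in idx
    ]


def presence_matrix_for_records(
    records: Sequence[SpecificKmerRecord],
    tables: Mapping[str, KmerCountTable],
    sample_ids: Sequence[str],
) -> np.ndarray:
    """(n_records, n_samples) presence of each record's k-mer per sample."""
    codes = np.asarray([kmer_to_code(r.kmer) for r in records], np.uint64)
    out = np.zeros((len(records), len(sample_ids)), bool)
    for j, sid in enumerate(sample_ids):
        out[:, j] = tables[sid].contains_codes(codes)
    return out


def rescore_records(
    records: Sequence[SpecificKmerRecord],
    tables: Mapping[str, KmerCountTable],
    labels: Mapping[str, bool],
) -> np.ndarray:
    """ASS of each record's FIXED direction on a new sample set.

    Returns an array of ASS values aligned with ``records``.
    """
    sample_ids = list(labels)
    positive = np.asarray([labels[s] for s in sample_ids], bool)
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("rescoring needs both groups present")
    logical = presence_matrix_for_records(records, tables, sample_ids)
    pres_pos = logical[:, positive].sum(axis=1)
    pres_neg = logical[:, ~positive].sum(axis=1)
    sens_p = pres_pos / n_pos
    spec_p = 1 - pres_neg / n_neg
    is_presence = np.asarray([r.direction == PRESENCE for r in records])
    sens = np.where(is_presence, sens_p, 1 - sens_p)
    spec = np.where(is_presence, spec_p, 1 - spec_p)
    return (sens + spec) / 2


def stratified_folds(
    pos_ids: Sequence[str], neg_ids: Sequence[str], n_folds: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    """Deterministic stratified folds: list of (validation pos, validation neg)."""
    rng = np.random.default_rng(seed)
    pos = [pos_ids[i] for i in rng.permutation(len(pos_ids))]
    neg = [neg_ids[i] for i in rng.permutation(len(neg_ids))]
    return [(pos[f::n_folds], neg[f::n_folds]) for f in range(n_folds)]


@dataclass
class FoldResult:
    fold: int
    n_detected: int
    fraction_validated: float
    validation_ass: np.ndarray
    records: list[SpecificKmerRecord] = field(repr=False, default_factory=list)


def crossvalidate_specific_kmers(
    tables: Mapping[str, KmerCountTable],
    labels: Mapping[str, bool],
    config: SpecificityConfig | None = None,
    min_count_presence: int = 1,
    max_absent_fraction: float = 0.8,
) -> list[FoldResult]:
    """K-fold CV: detect on fold-train samples, re-score on the held-out fold.

    ``tables``/``labels`` cover the (undersampled) training set; for each fold
    the detected records carry ``ass_validation`` and the fold reports the
    fraction reaching the secondary validation threshold.
    """
    config = config or SpecificityConfig()
    pos_ids = sorted(s for s, lab in labels.items() if lab)
    neg_ids = sorted(s for s, lab in labels.items() if not lab)
    if len(pos_ids) < config.cv_folds:
        raise ValueError(
            f"need >= {config.cv_folds} positive samples; got {len(pos_ids)}"
        )
    folds = stratified_folds(pos_ids, neg_ids, config.cv_folds, config.seed)
    results = []
    for f, (val_pos, val_neg) in enumerate(folds):
        if not val_pos or not val_neg:
            raise ValueError(f"fold {f} lacks positives or negatives")
        val = set(val_pos) | set(val_neg)
        train_ids = [s for s in list(labels) if s not in val]
        mat = build_matrix(
            [tables[s] for s in train_ids],
            {s: (POSITIVE if labels[s] else "negative") for s in train_ids},
        )
        mat = filter_sparse(mat, max_absent_fraction)
        records = detect_specific_kmers(mat, config)
        if records:
            val_ass = rescore_records(
                records, tables, {s: labels[s] for s in sorted(val)}
            )
            for r, a in zip(records, val_ass):
                r.ass_validation = float(a)
            frac = float(
                (val_ass >= config.validation_ass_threshold - 1e-12).mean()
            )
        else:
            val_ass = np.empty(0)
            frac = float("nan")
        results.append(FoldResult(f, len(records), frac, val_ass, records))
    return results


@dataclass
class GroupingEval:
    partition: str
    ass: np.ndarray
    fraction_ge_08: float
    fraction_ge_09: float


def evaluate_on_grouping(
    records: Sequence[SpecificKmerRecord],
    tables: Mapping[str, KmerCountTable],
    labels: Mapping[str, bool],
    partitions: Mapping[str, Sequence[str]],
) -> dict[str, GroupingEval]:
    """Re-score fixed records on each partition of samples.

    ``partitions`` maps a partition key (e.g. a timepoint or site stratum) to
    its sample ids; partitions missing one of the groups are skipped with a
    warning.  Reports the fraction of records at ASS >= 0.8 and >= 0.9.
    """
    out: dict[str, GroupingEval] = {}
    for key, ids in partitions.items():
        part_labels = {s: labels[s] for s in ids}
        n_pos = sum(part_labels.values())
        if n_pos == 0 or n_pos == len(part_labels):
            warnings.warn(f"partition {key!r} lacks positives or negatives; skipped")
            continue
        ass = rescore_records(records, tables, part_labels)
        out[key] = GroupingEval(
            partition=key,
            ass=ass,
            fraction_ge_08=float((ass >= 0.8 - 1e-12).mean()),
            fraction_ge_09=float((ass >= 0.9 - 1e-12).mean()),
        )
    return out


def records_to_tsv(records: Sequence[SpecificKmerRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "kmer": r.kmer,
                "direction": r.direction,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "ass": r.ass,
                "ass_validation": r.ass_validation,
            }
            for r in records
        ],
        columns=["kmer", "direction", "sensitivity", "specificity", "ass", "ass_validation"],
    ).to_csv(path, sep="\t", index=False)


def records_from_tsv(path: str | Path) -> list[SpecificKmerRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SpecificKmerRecord(
            kmer=row.kmer,
            direction=row.direction,
            sensitivity=float(row.sensitivity),
            specificity=float(row.specificity),
            ass=float(row.ass),
            ass_validation=None if pd.isna(row.ass_validation) else float(row.ass_validation),
        )
        for row in df.itertuples()
    ]
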
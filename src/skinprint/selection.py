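"""Fingerprint contig selection and RPKM decision-threshold calibration.

Candidate contigs with mean RPKM above 0.01 across the individual's training
samples are ranked by cross-validated AUC of their RPKM as a one-feature
classifier; the winner becomes the individual's fingerprint.  Its decision
threshold is read off the ROC curve — scanned on a 0.001-step grid — as the
point closest to perfect performance (sensitivity, 1-specificity) = (1, 0),
averaged over the folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .abundance import AbundanceTable
from .assembly import Contig
from .specificity import stratified_folds

logger = logging.getLogger(__name__)


@dataclass
class FingerprintMarker:
    """One contig per individual with its calibrated RPKM threshold."""

    individual_id: str
    contig: Contig
    rpkm_threshold: float
    cv_auc_mean: float
    fold_thresholds: list[float]
    fold_aucs: list[float]


def filter_contigs_by_abundance(
    table: AbundanceTable,
    individual_id: str,
    sample_ids: Sequence[str],
    min_rpkm: float = 0.01,
) -> list[str]:
    """Contig ids whose mean RPKM over the individual's training samples is
    strictly greater than ``min_rpkm``."""
    missing = [s for s in sample_ids if s not in table.rpkm.columns]
    if missing:
        raise ValueError(f"samples missing from abundance table: {missing}")
    mean_rpkm = table.rpkm[list(sample_ids)].mean(axis=1)
    kept = mean_rpkm.index[mean_rpkm > min_rpkm].tolist()
    if not kept:
        raise ValueError(f"no abundant contig for individual {individual_id!r}")
    return kept


def auc_of_contig(pos: Sequence[float], neg: Sequence[float]) -> float:
    """AUC = P(positive RPKM > negative) + 0.5 P(tie), via midranks."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def optimal_threshold(pos: Sequence[float], neg: Sequence[float], step: float = 0.001) -> float:
    """Grid-scan ROC threshold closest to (sensitivity, 1-specificity) = (1, 0).

    Thresholds run from 0 to the maximum observed value in steps of ``step``;
    a sample is classified positive when its value >= threshold.  Ties in the
    distance go to the smallest threshold.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0; got {step}")
    pos = np.sort(np.asarray(pos, float))
    neg = np.sort(np.asarray(neg, float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    hi = float(max(pos.max(), neg.max()))
    # sens/FPR are step functions changing only at observed values, so the
    # full grid scan reduces to the smallest grid point of each inter-value
    # interval; this is exactly equivalent to scanning every grid threshold.
    vals = np.unique(np.concatenate([pos, neg]))
    idx = np.floor(vals / step).astype(np.int64)
    cand = np.unique(np.concatenate([[0], idx, idx + 1, idx + 2]))
    grid = cand[cand >= 0].astype(float) * step
    grid = grid[grid <= hi + step]
    # value >= t  <=>  index past searchsorted-left
    sens = 1 - np.searchsorted(pos, grid, side="left") / pos.size
    fpr = 1 - np.searchsorted(neg, grid, side="left") / neg.size
    dist2 = (1 - sens) ** 2 + fpr**2
    best = int(np.argmin(dist2))  # first minimum == smallest threshold
    if pos.max() <= neg.min() and pos.max() < neg.max():
        logger.warning("degenerate ROC: all positives at/below all negatives")
    return float(grid[best])


def select_fingerprint(
    candidates: Sequence[Contig],
    table: AbundanceTable,
    pos_ids: Sequence[str],
    neg_ids: Sequence[str],
    individual_id: str,
    cv_folds: int = 6,
    seed: int = 0,
    roc_step: float = 0.001,
) -> FingerprintMarker:
    """Pick the contig with the largest mean validation AUC over CV folds.

    AUC ties are broken by longer contig, then contig_id.  The returned
    threshold is the mean of the per-fold ROC-optimal thresholds (computed on
    each fold's training portion) for the selected contig.
    """
    if not candidates:
        raise ValueError(f"no candidate contigs for {individual_id!r}")
    by_id = {c.contig_id: c for c in candidates}
    folds = stratified_folds(list(pos_ids), list(neg_ids), cv_folds, seed)
    fold_train: list[tuple[list[str], list[str]]] = []
    fold_val: list[tuple[list[str], list[str]]] = []
    for val_pos, val_neg in folds:
        if not val_pos or not val_neg:
            raise ValueError("a fold lacks positives or negatives; reduce cv_folds")
        fold_train.append(
            (
                [s for s in pos_ids if s not in set(val_pos)],
                [s for s in neg_ids if s not in set(val_neg)],
            )
        )
        fold_val.append((list(val_pos), list(val_neg)))
    rpkm = table.rpkm
    mean_auc: dict[str, float] = {}
    for cid in sorted(by_id):
        aucs = [
            auc_of_contig(rpkm.loc[cid, vp].to_numpy(), rpkm.loc[cid, vn].to_numpy())
            for vp, vn in fold_val
        ]
        mean_auc[cid] = float(np.mean(aucs))
    winner = min(
        sorted(by_id),
        key=lambda cid: (-mean_auc[cid], -by_id[cid].length, cid),
    )
    fold_aucs = [
        auc_of_contig(rpkm.loc[winner, vp].to_numpy(), rpkm.loc[winner, vn].to_numpy())
        for vp, vn in fold_val
    ]
    fold_thresholds = [
        optimal_threshold(
            rpkm.loc[winner, tp].to_numpy(), rpkm.loc[winner, tn].to_numpy(), roc_step
        )
        for tp, tn in fold_train
    ]
    return FingerprintMarker(
        individual_id=individual_id,
        contig=by_id[winner],
        rpkm_threshold=float(np.mean(fold_thresholds)),
        cv_auc_mean=float(np.mean(fold_aucs)),
        fold_thresholds=[float(t) for t in fold_thresholds],
        fold_aucs=[float(a) for a in fold_aucs],
    )


def markers_to_tsv(markers: Sequence[FingerprintMarker], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": m.individual_id,
                "contig_id": m.contig.contig_id,
                "length": m.contig.length,
                "rpkm_threshold": m.rpkm_threshold,
                "cv_auc_mean": m.cv_auc_mean,
            }
            for m in markers
        ]
    ).to_csv(path, sep="\t", index=False)
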
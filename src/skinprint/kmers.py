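"""Canonical k-mer counting and the per-individual frequency union matrix.

Each sample's reads are reduced to a table of canonical k-mer occurrence
counts (both strands counted as one key); low-count keys — below ``min_count``,
default 3, i.e. "seen more than twice" — are dropped as likely sequencing
error.  Tables from the positive (one individual) and negative (everyone else)
training samples are merged into a union matrix holding, per k-mer and sample,
the normalised frequency n_i(j) = f_i(j) / total retained occurrences, and its
logicalised presence/absence value.  K-mers absent from more than
``max_absent_fraction`` of BOTH groups are discarded as uninformative.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqcodes import code_to_kmer, codes_to_kmers, kmer_to_code, reads_to_codes

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class KmerCountTable:
    """Occurrence counts of canonical k-mers in one sample.

    ``codes`` is sorted ascending (== lexicographic k-mer order);
    ``total_retained`` is the sum of the surviving counts and is the
    normalisation denominator for frequencies.
    """

    sample_id: str
    k: int
    codes: np.ndarray   # uint64, sorted
    counts: np.ndarray  # int64
    total_retained: int

    def __len__(self) -> int:
        return int(self.codes.shape[0])

    def get(self, kmer: str) -> int:
        """Count of a canonical k-mer string (0 when absent)."""
        code = np.uint64(kmer_to_code(kmer))
        i = int(np.searchsorted(self.codes, code))
        if i < len(self.codes) and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def contains_codes(self, query: np.ndarray) -> np.ndarray:
        """Boolean presence of each query code in this table."""
        idx = np.searchsorted(self.codes, query)
        idx_c = np.minimum(idx, len(self.codes) - 1) if len(self.codes) else idx
        if len(self.codes) == 0:
            return np.zeros(query.shape, bool)
        return self.codes[idx_c] == query

    def as_dict(self) -> dict[str, int]:
        return {
            code_to_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    def to_tsv(self, path: str | Path) -> None:
        """Write as sorted two-column text (kmer TAB count); .gz honoured."""
        path = Path(path)
        if path.suffix == ".gz":
            opener = lambda p, m: gzip.open(p, m, compresslevel=1)  # noqa: E731
        else:
            opener = open
        kmers = codes_to_kmers(self.codes, self.k)
        body = "".join(f"{km}\t{int(n)}\n" for km, n in zip(kmers, self.counts))
        with opener(path, "wt") as fh:
            fh.write(f"#sample_id={self.sample_id}\tk={self.k}\ttotal={self.total_retained}\n")
            fh.write(body)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerCountTable":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            header = fh.readline().strip()
            meta = dict(kv.split("=", 1) for kv in header.lstrip("#").split("\t"))
            kmers, counts = [], []
            for line in fh:
                kmer, n = line.rstrip("\n").split("\t")
                kmers.append(kmer)
                counts.append(int(n))
        k = int(meta["k"])
        if kmers:
            from .seqcodes import encode_bases

            mat = encode_bases("".join(kmers)).reshape(len(kmers), k).astype(np.uint64)
            codes = np.zeros(len(kmers), np.uint64)
            two = np.uint64(2)
            for j in range(k):
                codes <<= two
                codes |= mat[:, j]
        else:
            codes = np.empty(0, np.uint64)
        return cls(
            sample_id=meta["sample_id"],
            k=k,
            codes=codes,
            counts=np.asarray(counts, np.int64),
            total_retained=int(meta["total"]),
        )


def count_canonical_kmers(
    reads: Iterable[str],
    k: int = 31,
    min_count: int = 3,
    sample_id: str = "",
) -> KmerCountTable:
    """Count canonical k-mers over a stream of reads.

    Every length-k window free of N contributes one count to its canonical
    form; keys with fewer than ``min_count`` occurrences are dropped.
    """
    seqs = reads if isinstance(reads, (list, tuple)) else list(reads)
    rc = reads_to_codes(seqs, k)
    return _table_from_codes(rc.valid_codes(), k, min_count, sample_id)


def table_from_read_codes(rc, min_count: int = 3, sample_id: str = "") -> KmerCountTable:
    """Build a count table from precomputed :class:`ReadCodes`."""
    return _table_from_codes(rc.valid_codes(), rc.k, min_count, sample_id)


def _table_from_codes(codes: np.ndarray, k: int, min_count: int, sample_id: str) -> KmerCountTable:
    if codes.shape[0] == 0:
        warnings.warn(f"sample {sample_id!r}: no length-{k} windows; empty k-mer table")
        return KmerCountTable(sample_id, k, np.empty(0, np.uint64), np.empty(0, np.int64), 0)
    uniq, counts = np.unique(codes, return_counts=True)
    keep = counts >= min_count
    uniq, counts = uniq[keep], counts[keep].astype(np.int64)
    return KmerCountTable(sample_id, k, uniq, counts, int(counts.sum()))


@dataclass
class KmerMatrix:
    """Union frequency matrix over positive and negative training samples.

    Rows are canonical k-mers (codes, ascending), columns samples.  ``freq``
    holds n_i(j) in [0, 1]; ``logical`` holds the presence indicator
    (1 iff the count, hence the frequency, is nonzero).
    """

    k: int
    codes: np.ndarray        # uint64, rows
    sample_ids: list[str]
    freq: np.ndarray         # float64 (n_kmers, n_samples)
    logical: np.ndarray      # bool     (n_kmers, n_samples)
    positive: np.ndarray     # bool     (n_samples,) group membership
    group_labels: dict[str, str] = field(default_factory=dict)

    @property
    def n_kmers(self) -> int:
        return int(self.codes.shape[0])

    def kmer_strings(self) -> list[str]:
        return codes_to_kmers(self.codes, self.k)


def build_matrix(
    tables: Sequence[KmerCountTable],
    labels: Mapping[str, str],
) -> KmerMatrix:
    """Merge per-sample tables into the union frequency matrix.

    ``labels`` maps sample_id to "positive"/"negative".  Frequencies are the
    per-sample counts divided by that sample's total retained occurrences;
    k-mers absent from a sample get 0.
    """
    if not tables:
        raise ValueError("no tables to merge")
    k = tables[0].k
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id in tables: {dup}")
    for t in tables:
        if t.k != k:
            raise ValueError(f"mixed k: {t.sample_id} has k={t.k}, expected {k}")
        if t.sample_id not in labels:
            raise ValueError(f"sample {t.sample_id!r} missing from labels")
    union = np.unique(np.concatenate([t.codes for t in tables if len(t)]))
    freq = np.zeros((union.shape[0], len(tables)))
    for j, t in enumerate(tables):
        if len(t) == 0 or t.total_retained == 0:
            continue
        rows = np.searchsorted(union, t.codes)
        freq[rows, j] = t.counts / t.total_retained
    positive = np.array([labels[i] == POSITIVE for i in ids])
    return KmerMatrix(
        k=k,
        codes=union,
        sample_ids=list(ids),
        freq=freq,
        logical=freq > 0,
        positive=positive,
        group_labels={i: labels[i] for i in ids},
    )


def filter_sparse(matrix: KmerMatrix, max_absent_fraction: float = 0.8) -> KmerMatrix:
    """Drop k-mers absent from more than the threshold fraction of BOTH groups.

    A row is removed only when its absence fraction exceeds
    ``max_absent_fraction`` among positives AND among negatives; row order is
    preserved and surviving entries are untouched.
    """
    pos, neg = matrix.positive, ~matrix.positive
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("both groups must be non-empty for the sparsity filter")
    absent = ~matrix.logical
    absent_pos = absent[:, pos].mean(axis=1)
    absent_neg = absent[:, neg].mean(axis=1)
    drop = (absent_pos > max_absent_fraction) & (absent_neg > max_absent_fraction)
    keep = ~drop
    logger.info(
        "sparsity filter: %d of %d k-mers removed", int(drop.sum()), matrix.n_kmers
    )
    return KmerMatrix(
        k=matrix.k,
        codes=matrix.codes[keep],
        sample_ids=list(matrix.sample_ids),
        freq=matrix.freq[keep],
        logical=matrix.logical[keep],
        positive=matrix.positive.copy(),
        group_labels=dict(matrix.group_labels),
    )
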
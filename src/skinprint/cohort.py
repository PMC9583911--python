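"""Cohort manifests, sample-level QC, balanced splits and undersampling.

A cohort is described by a TSV manifest mapping each sample to its donor
individual, body site and timepoint, plus one or two FASTQ paths.  Data
preparation removes samples with extremely low sequencing depth (below a
fraction of the cohort median and/or an absolute read floor) and samples from
excluded body sites, then partitions the remainder 70/30 into training and
testing sets stratified by individual.  Because one individual's positives are
vastly outnumbered by everyone else's samples, the negative class is randomly
undersampled, round-robin across the other individuals.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import math
import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["sample_id", "individual_id", "body_site", "timepoint", "fastq_1"]


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    individual_id: str
    body_site: str
    timepoint: str
    read_paths: tuple[str, ...]
    n_reads: int | None = None


@dataclass
class CohortManifest:
    samples: list[SampleRecord]
    excluded_sites: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dups = sorted({i for i in ids if ids.count(i) > 1})
        if dups:
            raise ValueError(f"duplicate sample_id: {dups}")

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CohortManifest)
            and self.samples == other.samples
            and self.excluded_sites == other.excluded_sites
        )

    def get(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def individuals(self) -> list[str]:
        return sorted({s.individual_id for s in self.samples})

    def by_individual(self) -> dict[str, list[SampleRecord]]:
        out: dict[str, list[SampleRecord]] = {}
        for s in self.samples:
            out.setdefault(s.individual_id, []).append(s)
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for s in self.samples:
            row = {
                "sample_id": s.sample_id,
                "individual_id": s.individual_id,
                "body_site": s.body_site,
                "timepoint": s.timepoint,
                "fastq_1": s.read_paths[0],
            }
            if len(s.read_paths) > 1:
                row["fastq_2"] = s.read_paths[1]
            if s.n_reads is not None:
                row["n_reads"] = s.n_reads
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a TSV manifest.

    Required columns: sample_id, individual_id, body_site, timepoint, fastq_1;
    optional fastq_2 and a cached n_reads.  Errors name the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing column(s) {missing}")
    dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dups:
        raise ValueError(f"manifest {path}: duplicate sample_id {sorted(set(dups))}")
    samples = []
    for _, row in df.iterrows():
        paths = [row["fastq_1"]]
        if "fastq_2" in df.columns and isinstance(row.get("fastq_2"), str) and row["fastq_2"]:
            paths.append(row["fastq_2"])
        n_reads = None
        if "n_reads" in df.columns and not pd.isna(row.get("n_reads")):
            n_reads = int(row["n_reads"])
        for col in MANIFEST_COLUMNS[:4]:
            if pd.isna(row[col]) or row[col] == "":
                raise ValueError(
                    f"manifest {path}: sample {row['sample_id']!r} has empty {col}"
                )
        samples.append(
            SampleRecord(
                sample_id=row["sample_id"],
                individual_id=row["individual_id"],
                body_site=row["body_site"],
                timepoint=row["timepoint"],
                read_paths=tuple(paths),
                n_reads=n_reads,
            )
        )
    return CohortManifest(samples=samples)


_FASTQ_BASES = frozenset("ACGTNacgtn")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file (plain or gzip) into (read_id, sequence) pairs.

    Sequences containing characters outside ACGTN are rejected.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            if not _FASTQ_BASES.issuperset(seq):
                bad = sorted(set(seq) - _FASTQ_BASES)
                raise ValueError(f"{path}: read {title.split()[0]!r} has non-ACGTN characters {bad}")
            out.append((title.split()[0], seq.upper()))
    return out


def load_sample_reads(record: SampleRecord) -> list[tuple[str, str]]:
    """All reads of a sample (both mates concatenated for paired data)."""
    reads: list[tuple[str, str]] = []
    for p in record.read_paths:
        reads.extend(read_fastq(p))
    return reads


def count_reads(record: SampleRecord) -> int:
    """Number of reads across the sample's FASTQ file(s), validating pairing."""
    counts = []
    for p in record.read_paths:
        path = Path(p)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            n_lines = sum(1 for _ in fh)
        if n_lines % 4:
            raise ValueError(f"{p}: truncated FASTQ ({n_lines} lines)")
        counts.append(n_lines // 4)
    if len(counts) == 2 and counts[0] != counts[1]:
        raise ValueError(
            f"sample {record.sample_id}: paired files have unequal read counts {counts}"
        )
    return sum(counts)


def ensure_read_counts(manifest: CohortManifest) -> CohortManifest:
    """Return a manifest with n_reads populated for every sample."""
    samples = [
        s if s.n_reads is not None else replace(s, n_reads=count_reads(s))
        for s in manifest.samples
    ]
    return CohortManifest(samples=samples, excluded_sites=set(manifest.excluded_sites))


def qc_filter(
    manifest: CohortManifest,
    min_read_fraction_of_median: float = 0.1,
    absolute_min_reads: int = 0,
    excluded_sites: Iterable[str] = (),
) -> tuple[CohortManifest, pd.DataFrame]:
    """Remove low-depth samples and samples from excluded body sites.

    A sample is dropped when its read count is strictly below
    ``max(median * fraction, absolute_min_reads)`` — the median taken over all
    samples — or when its body site is excluded.  Returns the filtered
    manifest and a removal report (sample_id, reason).
    """
    manifest = ensure_read_counts(manifest)
    excluded = set(excluded_sites)
    median = float(np.median([s.n_reads for s in manifest.samples]))
    cutoff = max(median * min_read_fraction_of_median, float(absolute_min_reads))
    kept, removed = [], []
    for s in manifest.samples:
        if s.body_site in excluded:
            removed.append({"sample_id": s.sample_id, "reason": f"excluded_site:{s.body_site}"})
        elif s.n_reads < cutoff:
            removed.append(
                {"sample_id": s.sample_id, "reason": f"low_depth:{s.n_reads}<{cutoff:g}"}
            )
        else:
            kept.append(s)
    if not kept:
        raise ValueError("empty cohort after QC")
    report = pd.DataFrame(removed, columns=["sample_id", "reason"])
    return CohortManifest(samples=kept, excluded_sites=excluded), report


@dataclass
class SplitPlan:
    """A 70/30-style train/test partition, stratified by individual."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fractions: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def split_cohort(
    manifest: CohortManifest, train_fraction: float = 0.7, seed: int = 0
) -> SplitPlan:
    """Stratified random train/test split, rounding ties toward train."""
    if not 0 < train_fraction <= 1:
        raise ValueError(f"train_fraction must be in (0, 1]; got {train_fraction}")
    rng = np.random.default_rng(seed)
    train, test, fractions = [], [], {}
    for ind in manifest.individuals():
        ids = sorted(s.sample_id for s in manifest.samples if s.individual_id == ind)
        if len(ids) == 1:
            warnings.warn(f"individual {ind!r} has a single sample; assigned to train")
            train.extend(ids)
            fractions[ind] = 1.0
            continue
        perm = rng.permutation(len(ids))
        n_train = min(len(ids), math.ceil(train_fraction * len(ids) - 1e-9))
        chosen = [ids[i] for i in perm]
        train.extend(sorted(chosen[:n_train]))
        test.extend(sorted(chosen[n_train:]))
        fractions[ind] = n_train / len(ids)
    return SplitPlan(tuple(train), tuple(test), fractions, seed)


def undersample_negatives(
    manifest: CohortManifest,
    plan: SplitPlan,
    target_individual: str,
    ratio: float = 2.0,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Positives and round-robin undersampled negatives from the training set.

    Negatives are drawn without replacement from the other individuals'
    training samples, cycling across individuals so none dominates;
    ``round(ratio * n_positives)`` are requested, capped at availability.
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be positive; got {ratio}")
    train = set(plan.train_ids)
    by_ind = manifest.by_individual()
    if target_individual not in by_ind:
        raise ValueError(f"unknown individual {target_individual!r}")
    pos = sorted(
        s.sample_id for s in by_ind[target_individual] if s.sample_id in train
    )
    if not pos:
        raise ValueError(f"individual {target_individual!r} has no training samples")
    rng = np.random.default_rng(seed)
    pools = {}
    for ind in sorted(by_ind):
        if ind == target_individual:
            continue
        ids = sorted(s.sample_id for s in by_ind[ind] if s.sample_id in train)
        if ids:
            pools[ind] = [ids[i] for i in rng.permutation(len(ids))]
    available = sum(len(v) for v in pools.values())
    n_neg = min(int(round(ratio * len(pos))), available)
    if n_neg < int(round(ratio * len(pos))):
        warnings.warn(
            f"only {available} negatives available; requested {round(ratio * len(pos))}"
        )
    neg: list[str] = []
    order = sorted(pools)
    depth = 0
    while len(neg) < n_neg:
        took = False
        for ind in order:
            if len(neg) >= n_neg:
                break
            if depth < len(pools[ind]):
                neg.append(pools[ind][depth])
                took = True
        if not took:
            break
        depth += 1
    return pos, neg
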
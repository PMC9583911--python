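"""Read-to-contig mapping, RPKM quantification and per-base coverage.

Mapping is exact canonical k-mer containment, emulating mismatch-free
end-to-end alignment: by default (``min_shared_kmers=None``) a read maps to a
contig only when EVERY length-k window of the read occurs exactly in the
contig (either strand) — the k-mer analogue of an alignment with zero
mismatches over the full read.  Passing an integer relaxes this to "at least
that many distinct shared k-mers".  A read mapping to several contigs is
assigned to the one sharing most k-mers (ties to the lexicographically first
contig_id).

RPKM = mapped reads / (contig length in kb × library size in millions), the
library size being the total number of reads in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import Contig
from .seqcodes import ReadCodes, reads_to_codes, window_codes, encode_bases


@dataclass
class MappingResult:
    """Per-sample mapping of reads onto a contig panel."""

    sample_id: str
    library_size: int
    mapped_read_count: dict[str, int]           # contig_id -> reads
    depth: dict[str, np.ndarray]                # contig_id -> per-base raw depth
    contig_lengths: dict[str, int]

    @property
    def total_mapped(self) -> int:
        return sum(self.mapped_read_count.values())


class ContigIndex:
    """Canonical k-mer index over a contig panel (code -> contig, position)."""

    def __init__(self, contigs: Sequence[Contig], k: int = 31):
        if not contigs:
            raise ValueError("empty contig panel")
        self.k = k
        self.contigs = sorted(contigs, key=lambda c: c.contig_id)
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig_id in panel")
        self.lengths = {c.contig_id: c.length for c in self.contigs}
        self.positions: dict[int, list[tuple[int, int]]] = {}
        for ci, c in enumerate(self.contigs):
            codes, valid = window_codes(encode_bases(c.sequence), k)
            for pos in np.nonzero(valid)[0]:
                code = int(codes[pos])
                # duplicate k-mers within the panel keep all locations
                self.positions.setdefault(code, []).append((ci, int(pos)))
        self.sorted_codes = np.asarray(sorted(self.positions), np.uint64)

    def window_hits(self, rc: ReadCodes) -> np.ndarray:
        hit = np.zeros(rc.codes.shape[0], bool)
        if rc.codes.shape[0] and self.sorted_codes.shape[0]:
            idx = np.searchsorted(self.sorted_codes, rc.codes)
            idx_c = np.minimum(idx, len(self.sorted_codes) - 1)
            hit = (self.sorted_codes[idx_c] == rc.codes) & rc.valid
        return hit


def map_reads(
    contigs: Sequence[Contig] | ContigIndex,
    reads: Sequence[str] | ReadCodes,
    min_shared_kmers: int | None = None,
    k: int = 31,
    sample_id: str = "",
) -> MappingResult:
    """Assign each read to at most one contig by exact k-mer containment.

    ``min_shared_kmers=None`` (default) requires every window of the read to
    occur in the assigned contig — full-length mismatch-free containment.
    Depth is incremented over the span between the first and last matched
    k-mer position (plus k) in the assigned contig.
    """
    index = contigs if isinstance(contigs, ContigIndex) else ContigIndex(contigs, k)
    rc = reads if isinstance(reads, ReadCodes) else reads_to_codes(list(reads), k)
    if min_shared_kmers is not None and min_shared_kmers < 1:
        raise ValueError("min_shared_kmers must be >= 1")
    hit = index.window_hits(rc)
    per_read = rc.per_read_counts(hit)
    n_windows = rc.ends - rc.starts
    if min_shared_kmers is None:
        candidates = np.nonzero((per_read == n_windows) & (n_windows > 0))[0]
    else:
        candidates = np.nonzero(per_read >= min_shared_kmers)[0]
    counts = {c.contig_id: 0 for c in index.contigs}
    depth = {c.contig_id: np.zeros(c.length, np.int64) for c in index.contigs}
    ids = [c.contig_id for c in index.contigs]
    for i in candidates:
        s, e = rc.starts[i], rc.ends[i]
        matched = rc.codes[s:e][hit[s:e]]
        shared: dict[int, set[int]] = {}
        span: dict[int, list[int]] = {}
        for code in np.unique(matched):
            for ci, pos in index.positions[int(code)]:
                shared.setdefault(ci, set()).add(int(code))
                span.setdefault(ci, []).append(pos)
        # full mode: every distinct window k-mer of the read must be in the contig
        required = (
            len(np.unique(matched)) if min_shared_kmers is None else min_shared_kmers
        )
        best = None
        for ci in sorted(shared):  # sorted contig order == lexicographic id
            n = len(shared[ci])
            if n >= required and (best is None or n > len(shared[best])):
                best = ci
        if best is None:
            continue
        cid = ids[best]
        counts[cid] += 1
        lo = min(span[best])
        hi = min(max(span[best]) + index.k, index.lengths[cid])
        depth[cid][lo:hi] += 1
    return MappingResult(
        sample_id=sample_id,
        library_size=rc.n_reads,
        mapped_read_count=counts,
        depth=depth,
        contig_lengths=dict(index.lengths),
    )


@dataclass
class AbundanceTable:
    """Contig × sample read counts and RPKM."""

    counts: pd.DataFrame          # contigs × samples, int
    rpkm: pd.DataFrame            # contigs × samples, float
    contig_lengths: pd.Series
    library_sizes: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        self.rpkm.to_csv(path, sep="\t", index_label="contig_id")


def compute_rpkm(
    assignments: Sequence[MappingResult],
    library_sizes: Mapping[str, int] | None = None,
) -> AbundanceTable:
    """RPKM = reads / (length_kb × library_millions) for every contig × sample."""
    if not assignments:
        raise ValueError("no mapping results")
    lengths = dict(assignments[0].contig_lengths)
    for cid, ln in lengths.items():
        if ln == 0:
            raise ValueError(f"contig {cid} has length 0")
    sample_ids = [a.sample_id for a in assignments]
    libs = {
        a.sample_id: (library_sizes[a.sample_id] if library_sizes else a.library_size)
        for a in assignments
    }
    for sid, n in libs.items():
        if n <= 0:
            raise ValueError(f"library size of {sid} must be > 0")
    contig_ids = sorted(lengths)
    counts = pd.DataFrame(
        {a.sample_id: [a.mapped_read_count.get(c, 0) for c in contig_ids] for a in assignments},
        index=contig_ids,
    )
    len_kb = pd.Series({c: lengths[c] / 1000 for c in contig_ids})
    lib_m = pd.Series({s: libs[s] / 1e6 for s in sample_ids})
    rpkm = counts.div(len_kb, axis=0).div(lib_m, axis=1)
    return AbundanceTable(
        counts=counts,
        rpkm=rpkm,
        contig_lengths=pd.Series(lengths),
        library_sizes=pd.Series(libs),
    )


@dataclass
class CoverageProfile:
    """Per-base read depth of one contig in one sample, per million reads."""

    contig_id: str
    sample_id: str
    depth: np.ndarray  # float, normalised per million library reads

    @classmethod
    def from_mapping(cls, result: MappingResult, contig_id: str) -> "CoverageProfile":
        raw = result.depth[contig_id]
        return cls(
            contig_id=contig_id,
            sample_id=result.sample_id,
            depth=raw / (result.library_size / 1e6),
        )


def export_coverage_heatmap_matrix(
    profiles: Sequence[CoverageProfile],
    path: str | Path | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Samples × contig-positions matrix, optionally log10(coverage + 1)."""
    cids = {p.contig_id for p in profiles}
    if len(cids) != 1:
        raise ValueError(f"profiles must share one contig; got {sorted(cids)}")
    mat = pd.DataFrame(
        {p.sample_id: p.depth for p in profiles}
    ).T
    mat.columns = [f"pos_{i}" for i in range(mat.shape[1])]
    if log_transform:
        mat = np.log10(mat + 1)
    if path is not None:
        mat.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")
    return mat


def load_coverage_heatmap_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
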
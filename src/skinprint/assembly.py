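"""Read recruitment by specific k-mers and unitig assembly of marker contigs.

Reads exactly containing at least ``min_hits`` distinct individual-specific
canonical k-mers (default 3, "more than two") are recruited, then assembled
with a single-k canonical de Bruijn unitig assembler: k-mers below a coverage
floor are discarded as sequencing error, and maximal non-branching paths are
compressed into contigs.  Recruited sets are small (reads clustered around
private-variant loci), so non-branching paths suffice to span each locus; an
external assembler's FASTA can be substituted via :func:`load_contigs_fasta`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqcodes import canonical, kmer_to_code, reads_to_codes, revcomp


@dataclass
class RecruitedReadSet:
    individual_id: str
    reads: list[tuple[str, str]]           # (read_id, sequence)
    hits_per_read: dict[str, int]          # distinct specific k-mers contained


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    source_individual: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def recruit_reads(
    specific_kmers: Sequence[str],
    reads: Sequence[tuple[str, str]],
    min_hits: int = 3,
    k: int | None = None,
    individual_id: str = "",
    read_codes=None,
) -> RecruitedReadSet:
    """Collect reads exactly matched by >= min_hits distinct specific k-mers.

    Matching is canonical (either strand), mismatch-free, over every length-k
    window of the read; distinct k-mers are counted, not windows.  Precomputed
    :class:`~skinprint.seqcodes.ReadCodes` for the reads may be passed to skip
    re-encoding.
    """
    if not specific_kmers:
        raise ValueError("no specific k-mers to recruit with")
    k = k or len(specific_kmers[0])
    targets = np.unique(
        np.asarray([kmer_to_code(canonical(s)) for s in specific_kmers], np.uint64)
    )
    rc = read_codes if read_codes is not None else reads_to_codes(
        [seq for _, seq in reads], k
    )
    hit = np.zeros(rc.codes.shape[0], bool)
    if rc.codes.shape[0]:
        idx = np.searchsorted(targets, rc.codes)
        idx_c = np.minimum(idx, len(targets) - 1)
        hit = (targets[idx_c] == rc.codes) & rc.valid
    window_hits = rc.per_read_counts(hit)
    kept: list[tuple[str, str]] = []
    hits_per_read: dict[str, int] = {}
    for i in np.nonzero(window_hits >= min_hits)[0]:
        s, e = rc.starts[i], rc.ends[i]
        matched = rc.codes[s:e][hit[s:e]]
        distinct = int(np.unique(matched).shape[0])
        if distinct >= min_hits:
            rid, seq = reads[i]
            kept.append((rid, seq))
            hits_per_read[rid] = distinct
    if not kept:
        warnings.warn(f"no reads recruited for {individual_id!r}")
    return RecruitedReadSet(individual_id=individual_id, reads=kept, hits_per_read=hits_per_read)


def _kmer_coverage(seqs: Iterable[str], k: int) -> dict[str, int]:
    cov: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            c = canonical(w)
            cov[c] = cov.get(c, 0) + 1
    return cov


def _succs(node: str, present: set[str]) -> list[str]:
    k = len(node)
    return [node[1:] + b for b in "ACGT" if canonical(node[1:] + b) in present]


def _preds(node: str, present: set[str]) -> list[str]:
    return [b + node[:-1] for b in "ACGT" if canonical(b + node[:-1]) in present]


def _extend_right(start: str, present: set[str], in_path: set[str]) -> list[str]:
    """Walk right through the bidirected graph along the unique-extension chain."""
    path: list[str] = []
    cur = start
    while True:
        nxt = _succs(cur, present)
        if len(nxt) != 1:
            break
        t = nxt[0]
        if len(_preds(t, present)) != 1:
            break
        ct = canonical(t)
        if ct in in_path:
            break  # cycle or hairpin
        path.append(t)
        in_path.add(ct)
        cur = t
    return path


def assemble_unitigs(
    reads: RecruitedReadSet | Sequence[str],
    k_asm: int = 31,
    min_contig_len: int = 100,
    coverage_floor: int = 2,
    source_individual: str | None = None,
) -> list[Contig]:
    """Compact the canonical de Bruijn graph of the reads into unitigs.

    K-mers with coverage below ``coverage_floor`` are removed first; unitigs
    shorter than ``min_contig_len`` are suppressed.  Output is deterministic:
    longest first, then lexicographic; each sequence is emitted in its
    canonical orientation (min of itself and its reverse complement).
    """
    if isinstance(reads, RecruitedReadSet):
        seqs = [seq for _, seq in reads.reads]
        source = source_individual or reads.individual_id
    else:
        seqs = list(reads)
        source = source_individual or ""
    if k_asm % 2 == 0:
        raise ValueError("k_asm must be odd")
    cov = _kmer_coverage(seqs, k_asm)
    present = {km for km, c in cov.items() if c >= coverage_floor}
    if not present:
        warnings.warn("no k-mers above the coverage floor; empty assembly")
        return []
    visited: set[str] = set()
    unitigs: list[str] = []
    for km in sorted(present):
        if km in visited:
            continue
        in_path = {km}
        right = _extend_right(km, present, in_path)
        left_rc = _extend_right(revcomp(km), present, in_path)
        # left extensions, re-oriented forward
        left = [revcomp(x) for x in reversed(left_rc)]
        chain = left + [km] + right
        seq = chain[0] + "".join(node[-1] for node in chain[1:])
        visited.update(canonical(node) for node in chain)
        unitigs.append(min(seq, revcomp(seq)))
    unitigs = [u for u in unitigs if len(u) >= min_contig_len]
    unitigs.sort(key=lambda s: (-len(s), s))
    return [
        Contig(contig_id=f"{source or 'asm'}_c{i+1:03d}", sequence=u, source_individual=source)
        for i, u in enumerate(unitigs)
    ]


def contigs_to_fasta(contigs: Sequence[Contig], path: str | Path) -> None:
    """Write contigs as FASTA with headers ``individual|contig_id|length``."""
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.source_individual}|{c.contig_id}|{c.length}\n{c.sequence}\n")


def load_contigs_fasta(path: str | Path, source_individual: str | None = None) -> list[Contig]:
    """Load contigs from FASTA (hook for substituting an external assembler)."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) >= 2:
            ind, cid = parts[0], parts[1]
        else:
            ind, cid = source_individual or "", rec.id
        out.append(
            Contig(contig_id=cid, sequence=str(rec.seq).upper(), source_individual=ind)
        )
    return out
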
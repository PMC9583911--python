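"""Two-bit packed canonical k-mer codes.

Nucleotides are encoded A=0, C=1, G=2, T=3, so the numeric order of packed
k-mer codes equals the lexicographic order of the k-mer strings.  A k-mer and
its reverse complement are collapsed onto the canonical form — the
lexicographically (numerically) smaller of the two — which makes counting
strand-symmetric.  k must be odd so no k-mer is its own reverse complement.

Everything here is vectorised over a whole batch of reads: the reads are
concatenated with a sentinel base between them and a rolling 62-bit code is
computed for every window, with windows containing a sentinel or an N marked
invalid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

MAX_K = 31  # 2*31 = 62 bits fits in uint64

_ENCODE = bytes.maketrans(b"ACGTacgt", bytes([0, 1, 2, 3, 0, 1, 2, 3]))
# anything not ACGT (N, sentinel, ...) encodes to 4 and invalidates its windows
_ENCODE_FULL = bytes(
    _ENCODE[i] if chr(i) in "ACGTacgt" else 4 for i in range(256)
)
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC_TABLE = bytes.maketrans(b"ACGTacgtNn", b"TGCATGCANN")


def encode_bases(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A0 C1 G2 T3, other 4)."""
    return np.frombuffer(seq.encode("ascii").translate(_ENCODE_FULL), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


def canonical(seq: str) -> str:
    """Canonical form: lexicographic min of the k-mer and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def kmer_to_code(kmer: str) -> int:
    arr = encode_bases(kmer)
    if (arr > 3).any():
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
    code = 0
    for b in arr:
        code = (code << 2) | int(b)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = _DECODE[code & 3]
        code >>= 2
    return out.decode("ascii")


def codes_to_kmers(codes: Iterable[int], k: int) -> list[str]:
    """Vectorised decoding of many packed codes to k-mer strings."""
    arr = np.asarray(list(codes) if not isinstance(codes, np.ndarray) else codes,
                     np.uint64)
    n = arr.shape[0]
    if n == 0:
        return []
    out = np.empty((n, k), np.uint8)
    c = arr.copy()
    three, two = np.uint64(3), np.uint64(2)
    for i in range(k - 1, -1, -1):
        out[:, i] = _DECODE[(c & three).astype(np.intp)]
        c >>= two
    flat = out.tobytes().decode("ascii")
    return [flat[i * k : (i + 1) * k] for i in range(n)]


def window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes of every length-k window of an encoded base array.

    Returns (codes, valid): ``codes[i]`` is the canonical packed code of
    ``arr[i:i+k]``; ``valid[i]`` is False when the window contains a non-ACGT
    base (its code is then meaningless).
    """
    if k % 2 == 0 or k < 3 or k > MAX_K:
        raise ValueError(f"k must be odd, 3 <= k <= {MAX_K}; got {k}")
    n = arr.shape[0]
    m = n - k + 1
    if m <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    a = arr.astype(np.uint64)
    comp = a ^ np.uint64(3)
    fwd = np.zeros(m, np.uint64)
    rev = np.zeros(m, np.uint64)
    two = np.uint64(2)
    for j in range(k):
        fwd <<= two
        fwd |= a[j : j + m]
        jr = k - 1 - j
        rev <<= two
        rev |= comp[jr : jr + m]
    # mask garbage bits contributed by sentinel code 4 (3 bits wide)
    mask = np.uint64((1 << (2 * k)) - 1)
    fwd &= mask
    rev &= mask
    bad = (arr > 3).astype(np.int32)
    c = np.concatenate([[0], np.cumsum(bad)])
    valid = (c[k:] - c[:-k]) == 0
    return np.minimum(fwd, rev), valid


@dataclass
class ReadCodes:
    """Canonical window codes for a batch of reads, with per-read extents.

    ``codes``/``valid`` cover the concatenation of all reads (sentinel-
    separated); read ``i`` owns window positions ``starts[i] .. ends[i]-1``.
    """

    k: int
    codes: np.ndarray        # uint64, all windows of the concatenation
    valid: np.ndarray        # bool, same length
    starts: np.ndarray       # int64, per-read first window index
    ends: np.ndarray         # int64, per-read one-past-last window index
    read_lengths: np.ndarray # int64
    n_reads: int

    def valid_codes(self) -> np.ndarray:
        """All valid canonical codes across the batch (one per window)."""
        return self.codes[self.valid]

    def read_codes(self, i: int) -> np.ndarray:
        """Valid canonical codes of read ``i``."""
        s, e = self.starts[i], self.ends[i]
        c = self.codes[s:e]
        return c[self.valid[s:e]]

    def per_read_counts(self, window_mask: np.ndarray) -> np.ndarray:
        """Number of True windows per read for a boolean mask over all windows."""
        if self.n_reads == 0:
            return np.zeros(0, np.int64)
        csum = np.concatenate([[0], np.cumsum(window_mask.astype(np.int64))])
        return csum[self.ends] - csum[self.starts]


def reads_to_codes(seqs: Sequence[str], k: int) -> ReadCodes:
    """Compute canonical window codes for every read in one vectorised pass."""
    n_reads = len(seqs)
    lengths = np.fromiter((len(s) for s in seqs), np.int64, count=n_reads)
    if n_reads == 0:
        z = np.zeros(0, np.int64)
        return ReadCodes(k, np.empty(0, np.uint64), np.empty(0, bool), z, z, lengths, 0)
    concat = "N".join(seqs)
    arr = encode_bases(concat)
    codes, valid = window_codes(arr, k)
    m = codes.shape[0]
    # read i occupies concat[o_i : o_i + L_i]; its windows are o_i .. o_i+L_i-k
    offsets = np.concatenate([[0], np.cumsum(lengths[:-1] + 1)])
    starts = np.minimum(offsets, m)
    ends = np.minimum(offsets + np.maximum(lengths - k + 1, 0), m)
    ends = np.maximum(ends, starts)
    return ReadCodes(k, codes, valid, starts, ends, lengths, n_reads)
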
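"""Low-level canonical k-mer primitives.

A k-mer and its reverse complement are treated as the same object; the
canonical form is the lexicographically smaller of the two.  With the base
encoding A=0 < C=1 < G=2 < T=3 the integer code of the canonical string is
the minimum of the forward and reverse-complement codes, so string-space
and code-space canonicalization agree.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")

# 256-entry base-to-code lookup; non-ACGT maps to 255 (invalid).
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Largest k for which a k-mer code fits in a signed 64-bit integer.
MAX_PACKED_K = 31


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A<->T, C<->G, N kept)."""
    return seq.translate(_COMP_TABLE)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence to uint8 codes (A=0,C=1,G=2,T=3, other=255)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` for valid codes only."""
    return _DECODE[codes].tobytes().decode("ascii")


def kmer_code(kmer: str) -> int:
    """Pack an ACGT string into its integer code (2 bits per base)."""
    code = 0
    for ch in kmer:
        v = "ACGT".index(ch)
        code = (code << 2) | v
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range((k - 1) * 2, -1, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def canonical_window_codes(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical integer codes of every valid length-``k`` window.

    Parameters
    ----------
    values
        uint8 base codes from :func:`encode_sequence`; 255 marks an
        invalid base (any window covering one is dropped).
    k
        Window length; must satisfy ``k <= MAX_PACKED_K``.

    Returns
    -------
    codes, starts
        ``codes[i]`` is the canonical code of the window beginning at
        position ``starts[i]``.  Windows shorter than ``k`` (sequence end)
        or containing a non-ACGT base produce no entry.
    """
    if k > MAX_PACKED_K:
        raise ValueError(f"k={k} exceeds packed-integer limit {MAX_PACKED_K}")
    n = values.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    invalid = (values >= 4).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(invalid)])
    window_ok = (csum[k:] - csum[:-k]) == 0
    v = (values & 3).astype(np.int64)
    fwd = np.zeros(m, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | v[j : j + m]
    rc = np.zeros(m, dtype=np.int64)
    for j in range(k - 1, -1, -1):
        rc = (rc << 2) | (3 - v[j : j + m])
    canon = np.minimum(fwd, rc)
    starts = np.nonzero(window_ok)[0]
    return canon[starts], starts


def canonical_windows(seq: str, k: int) -> set[str]:
    """Set of canonical k-mers present in ``seq`` (non-ACGT windows skipped)."""
    n = len(seq)
    if n < k or k < 1:
        return set()
    values = encode_sequence(seq)
    invalid = (values >= 4).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(invalid)])
    starts = np.nonzero((csum[k:] - csum[:-k]) == 0)[0]
    return {canonical(seq[i : i + k]) for i in starts}
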
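"""Low-level sequence utilities shared across the package.

Sequences are plain upper-case ``str`` over the DNA alphabet ``ACGT``.
Hot paths (k-mer scans over whole libraries) work on 2-bit numpy
encodings instead.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np

DNA = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# byte value -> 2-bit code (A=0, C=1, G=2, T=3)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


class Read(NamedTuple):
    """A named read: ``id`` and its sequence (5'->3' as sequenced)."""

    id: str
    sequence: str


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq``."""
    return seq.translate(_COMP)[::-1]


def gc_at_fraction(seq: str) -> float:
    """A+T fraction of ``seq``."""
    if not seq:
        raise ValueError("empty sequence")
    at = seq.count("A") + seq.count("T")
    return at / len(seq)


def encode(seq: str) -> np.ndarray:
    """2-bit encode a DNA string (A=0, C=1, G=2, T=3)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[codes].tobytes().decode()


def rotations(seq: str) -> Iterable[str]:
    doubled = seq + seq
    n = len(seq)
    for i in range(n):
        yield doubled[i : i + n]


def canonical_rotation(seq: str) -> str:
    """Canonical monomer frame: lexicographically minimal rotation over
    the sequence and its reverse complement.

    Monomers mined from different array phases or strands reduce to the
    same canonical string, so families compare equal regardless of how
    they were first assembled.
    """
    if not seq:
        raise ValueError("empty sequence")
    best = min(rotations(seq))
    best_rc = min(rotations(revcomp(seq)))
    return min(best, best_rc)


def kmer_codes(seqs: "list[str] | np.ndarray", k: int) -> np.ndarray:
    """Canonical k-mer codes for every window of every fixed-length sequence.

    Parameters
    ----------
    seqs
        Either a list of equal-length DNA strings or an already 2-bit
        encoded ``(n, L)`` uint8 matrix.
    k
        Word size; must satisfy ``2*k <= 63``.

    Returns
    -------
    ``(n, L - k + 1)`` int64 matrix of canonical (strand-min) k-mer codes.
    """
    if 2 * k > 63:
        raise ValueError("k too large for 64-bit packing")
    if isinstance(seqs, np.ndarray):
        mat = seqs
    else:
        mat = np.vstack([encode(s) for s in seqs])
    n, length = mat.shape
    if length < k:
        return np.empty((n, 0), dtype=np.int64)
    w = length - k + 1
    weights_f = (4 ** np.arange(k - 1, -1, -1, dtype=np.int64))
    # forward codes via strided windows
    windows = np.lib.stride_tricks.sliding_window_view(mat, k, axis=1)
    fwd = (windows.astype(np.int64) * weights_f).sum(axis=2)
    # reverse complement: complement base = 3 - code, reversed order
    weights_r = (4 ** np.arange(k, dtype=np.int64))
    rev = ((3 - windows.astype(np.int64)) * weights_r).sum(axis=2)
    return np.minimum(fwd, rev)


def seq_kmers(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of one (variable-length) sequence."""
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    arr = encode(seq)[None, :]
    return np.unique(kmer_codes(arr, k))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


_PURINES = frozenset("AG")


def classify_substitution(a: str, b: str) -> str:
    """'ts' for a transition (A<->G, C<->T), 'tv' for a transversion.

    ``a`` and ``b`` must be distinct bases.
    """
    if a == b:
        raise ValueError("not a substitution")
    return "ts" if ((a in _PURINES) == (b in _PURINES)) else "tv"
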
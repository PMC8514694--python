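"""Read-vs-consensus alignment engine.

Consensus monomers are tiled head-to-tail into a target long enough
that any read position, including monomer junctions, can align in one
piece. Candidate (read, family) pairs are found with a shared canonical
k-mer screen; candidates are then aligned locally (affine gaps) and the
best hit per read is kept. Mismatches inside aligned blocks are split
into transitions and transversions so Kimura 2-parameter distances can
be computed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np
from Bio import Align

from ._seq import Read, encode, kmer_codes, revcomp, seq_kmers

PREFILTER_K = 11  # screen word size; small enough to tolerate ~25% divergence


@dataclass
class AlignedReadHit:
    """One read aligned to one family's tiled consensus.

    ``blocks`` are gap-free aligned segments as ``(t0, t1, q0, q1)`` in
    tiled-target / oriented-read coordinates; ``aligned_columns`` counts
    non-gap columns only. ``k2p`` is filled in by the quantification
    layer (NaN until then; ``saturated`` marks hits whose mismatch load
    puts them outside the K2P domain).
    """

    read_id: str
    family_id: str
    strand: str  # '+' or '-'
    aligned_columns: int
    matches: int
    transitions: int
    transversions: int
    identity: float
    gap_columns: int
    blocks: tuple[tuple[int, int, int, int], ...]
    read_seq: str  # oriented to the target strand
    rul: int
    k2p: float = math.nan
    saturated: bool = False

    @property
    def mismatches(self) -> int:
        return self.transitions + self.transversions


def tiled_target(consensus: str, read_length: int) -> str:
    """Consensus repeated enough times that a read starting anywhere in
    the first monomer still fits entirely inside the target."""
    rul = len(consensus)
    n = max(3, math.ceil(read_length / rul) + 2)
    return consensus * n


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


_PURINE = np.zeros(256, dtype=bool)
_PURINE[ord("A")] = _PURINE[ord("G")] = True


def _score_alignment(alignment, target: str, query: str):
    """matches / transitions / transversions / gap columns from one
    Biopython local alignment."""
    t_blocks, q_blocks = alignment.aligned
    matches = ts = tv = 0
    blocks = []
    nongap = 0
    gaps = 0
    prev_t = prev_q = None
    tb = np.frombuffer(target.encode(), dtype=np.uint8)
    qb = np.frombuffer(query.encode(), dtype=np.uint8)
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            gaps += (t0 - prev_t) + (q0 - prev_q)
        a = tb[t0:t1]
        b = qb[q0:q1]
        eq = a == b
        matches += int(eq.sum())
        diff = ~eq
        if diff.any():
            same_class = _PURINE[a[diff]] == _PURINE[b[diff]]
            ts += int(same_class.sum())
            tv += int((~same_class).sum())
        nongap += t1 - t0
        blocks.append((int(t0), int(t1), int(q0), int(q1)))
        prev_t, prev_q = t1, q1
    return matches, ts, tv, nongap, gaps, tuple(blocks)


class ConsensusIndex:
    """Tiled targets plus a canonical k-mer screen for a consensus set."""

    def __init__(
        self,
        consensuses: Mapping[str, str],
        read_length: int = 150,
        k: int = PREFILTER_K,
    ):
        self.k = k
        self.family_ids = sorted(consensuses)
        self.consensuses = {fid: consensuses[fid] for fid in self.family_ids}
        self.targets = {
            fid: tiled_target(seq, read_length) for fid, seq in self.consensuses.items()
        }
        kmer_to_fams: dict[int, list[int]] = {}
        for i, fid in enumerate(self.family_ids):
            for code in seq_kmers(self.targets[fid], k):
                kmer_to_fams.setdefault(int(code), []).append(i)
        self._kmers = np.array(sorted(kmer_to_fams), dtype=np.int64)
        self._fam_lists = [tuple(kmer_to_fams[int(c)]) for c in self._kmers]

    def candidates(self, reads: Sequence[Read]) -> dict[int, set[int]]:
        """read index -> set of candidate family indices (shared k-mers)."""
        out: dict[int, set[int]] = {}
        if self._kmers.size == 0:
            return out
        by_len: dict[int, list[int]] = {}
        for i, r in enumerate(reads):
            by_len.setdefault(len(r.sequence), []).append(i)
        for length, idxs in by_len.items():
            if length < self.k:
                continue
            block = 20_000
            for lo in range(0, len(idxs), block):
                sub = idxs[lo : lo + block]
                mat = np.vstack([encode(reads[i].sequence) for i in sub])
                codes = kmer_codes(mat, self.k)
                pos = np.searchsorted(self._kmers, codes)
                pos[pos == self._kmers.size] = 0
                hitmask = self._kmers[pos] == codes
                rows, cols = np.nonzero(hitmask)
                for r_row, c in zip(rows, cols):
                    fams = self._fam_lists[int(pos[r_row, c])]
                    s = out.setdefault(sub[r_row], set())
                    s.update(fams)
        return out


def scan_reads(
    reads: Sequence[Read],
    consensuses: Mapping[str, str],
    min_identity: float = 0.7,
    min_aligned: "int | Mapping[str, int] | None" = None,
    min_score: int = 25,
    k: int = PREFILTER_K,
    index: Optional[ConsensusIndex] = None,
) -> list[AlignedReadHit]:
    """Best hit per read over a set of consensus monomers.

    A read is reported at most once, assigned to its best family
    (highest identity, ties broken by longer alignment, then by family
    id). ``min_aligned`` defaults to ``max(25, min(rul, read_len // 2))``
    per family. ``min_score`` (matches - mismatches - gap columns) is a
    noise floor against short spurious local alignments from random
    sequence, in the spirit of repeat-masking minimum-score cutoffs.
    """
    if not consensuses:
        raise ValueError("empty consensus set")
    max_read_len = max((len(r.sequence) for r in reads), default=0)
    if index is None:
        index = ConsensusIndex(consensuses, read_length=max_read_len, k=k)
    aligner = make_aligner()
    hits: list[AlignedReadHit] = []
    cand = index.candidates(reads)
    for ridx in sorted(cand):
        read = reads[ridx]
        best: Optional[AlignedReadHit] = None
        for fidx in sorted(cand[ridx]):
            fid = index.family_ids[fidx]
            target = index.targets[fid]
            rul = len(index.consensuses[fid])
            if isinstance(min_aligned, Mapping):
                need = min_aligned[fid]
            elif min_aligned is None:
                need = max(25, min(rul, len(read.sequence) // 2))
            else:
                need = min_aligned
            # strand pick with a cheap semi-global edit distance
            ed_f = edlib.align(read.sequence, target, mode="HW", task="distance")[
                "editDistance"
            ]
            rc = revcomp(read.sequence)
            ed_r = edlib.align(rc, target, mode="HW", task="distance")["editDistance"]
            if ed_r < ed_f:
                oriented, strand = rc, "-"
            else:
                oriented, strand = read.sequence, "+"
            alignments = aligner.align(target, oriented)
            if len(alignments) == 0:
                continue
            aln = alignments[0]
            matches, ts, tv, nongap, gaps, blocks = _score_alignment(
                aln, target, oriented
            )
            columns = nongap + gaps
            if columns == 0:
                continue
            identity = matches / columns
            score = matches - (ts + tv) - gaps
            if identity < min_identity or nongap < need or score < min_score:
                continue
            hit = AlignedReadHit(
                read_id=read.id,
                family_id=fid,
                strand=strand,
                aligned_columns=nongap,
                matches=matches,
                transitions=ts,
                transversions=tv,
                identity=identity,
                gap_columns=gaps,
                blocks=blocks,
                read_seq=oriented,
                rul=rul,
            )
            if best is None or (
                hit.identity,
                hit.aligned_columns,
            ) > (best.identity, best.aligned_columns) or (
                (hit.identity, hit.aligned_columns)
                == (best.identity, best.aligned_columns)
                and hit.family_id < best.family_id
            ):
                best = hit
        if best is not None:
            hits.append(best)
    return hits
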
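"""Minimum-spanning-tree haplotype networks of satellite monomers.

Full-length monomers are cut out of mapped reads at consensus-period
boundaries, aligned into a fixed-length consensus-anchored alignment,
collapsed into unique haplotypes with per-source occurrence counts, and
joined by a minimum spanning tree weighted by pairwise differences —
the classic way to display how satellite copies radiate within and
between libraries, sexes or species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np

from ._align import AlignedReadHit
from ._rng import rng_for

__all__ = [
    "Haplotype",
    "HaplotypeNetwork",
    "extract_monomers",
    "align_monomers",
    "collapse_haplotypes",
    "pairwise_differences",
    "build_mst",
    "subsample_monomers",
]


def extract_monomers(
    hits: Sequence[AlignedReadHit], consensus: str
) -> list[str]:
    """Full-length monomers cut from hits at consensus-period boundaries.

    Each hit's aligned blocks are walked in tiled-target coordinates;
    every complete period [m*rul, (m+1)*rul) covered without indels
    yields one monomer. Reads shorter than the repeat unit yield none.
    """
    rul = len(consensus)
    monomers: list[str] = []
    for h in hits:
        for t0, t1, q0, q1 in h.blocks:
            first = -(-t0 // rul)  # first full period starting inside block
            while (first + 1) * rul <= t1:
                s = first * rul
                monomers.append(h.read_seq[q0 + (s - t0) : q0 + (s - t0) + rul])
                first += 1
    return monomers


def align_monomers(monomers: Sequence[str], consensus: str) -> list[str]:
    """Consensus-anchored fixed-length alignment of monomers.

    Each monomer is globally aligned to the consensus; read deletions
    appear as '-' and insertions relative to the consensus are dropped
    (equivalently: columns gapped in the majority of rows never enter
    the alignment). All returned rows share the consensus length.
    """
    rows: list[str] = []
    for m in monomers:
        if len(m) == len(consensus):  # substitution-only: already in frame
            rows.append(m)
            continue
        res = edlib.align(m, consensus, mode="NW", task="path")
        row: list[str] = []
        qi = 0
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "=X":
                row.append(m[qi : qi + n])
                qi += n
            elif ch == "D":  # consensus columns missing from the monomer
                row.append("-" * n)
            elif ch == "I":  # insertion in the monomer: off-frame, dropped
                qi += n
        rows.append("".join(row))
    return rows


@dataclass
class Haplotype:
    """A unique aligned monomer sequence with per-source counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def collapse_haplotypes(
    aligned: Sequence[tuple[str, str]]
) -> list[Haplotype]:
    """Merge identical aligned rows, accumulating per-source counts.

    Input is (sequence, source_label) pairs; output order is
    deterministic: total count descending, then sequence lexicographic.
    """
    lengths = {len(s) for s, _ in aligned}
    if len(lengths) > 1:
        raise ValueError("aligned monomers must share one row length")
    by_seq: dict[str, dict[str, int]] = {}
    for seq, source in aligned:
        counts = by_seq.setdefault(seq, {})
        counts[source] = counts.get(source, 0) + 1
    haps = [Haplotype(sequence=s, counts=c) for s, c in by_seq.items()]
    haps.sort(key=lambda h: (-h.total, h.sequence))
    return haps


def pairwise_differences(haplotypes: Sequence[Haplotype]) -> np.ndarray:
    """Symmetric difference-count matrix; a gap against a base counts as
    one difference, gap against gap as none."""
    if not haplotypes:
        return np.zeros((0, 0), dtype=np.int64)
    mat = np.vstack(
        [np.frombuffer(h.sequence.encode(), dtype=np.uint8) for h in haplotypes]
    )
    gap = ord("-")
    n = mat.shape[0]
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        diff = mat != mat[i]
        both_gap = (mat == gap) & (mat[i] == gap)
        d[i] = (diff & ~both_gap).sum(axis=1)
    return d


@dataclass
class HaplotypeNetwork:
    """Haplotypes joined by a minimum spanning tree.

    ``edges`` hold (node_a, node_b, weight) with node indices into
    ``nodes``; ties during construction break by ascending
    (weight, node_a, node_b), so the tree is reproducible.
    """

    nodes: list[Haplotype]
    edges: list[tuple[int, int, int]]

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)

    def degree(self, i: int) -> int:
        return sum(1 for a, b, _ in self.edges if i in (a, b))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[max(ra, rb)] = min(ra, rb)
        return True


def build_mst(haplotypes: Sequence[Haplotype]) -> HaplotypeNetwork:
    """Kruskal minimum spanning tree over the complete pairwise
    difference graph; deterministic tie-breaking by node index."""
    if not haplotypes:
        raise ValueError("at least one haplotype required")
    d = pairwise_differences(haplotypes)
    n = len(haplotypes)
    order = sorted(
        ((int(d[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
    )
    uf = _UnionFind(n)
    edges: list[tuple[int, int, int]] = []
    for w, i, j in order:
        if uf.union(i, j):
            edges.append((i, j, w))
            if len(edges) == n - 1:
                break
    return HaplotypeNetwork(nodes=list(haplotypes), edges=edges)


def subsample_monomers(
    monomers: Sequence[str], cap: int = 500, seed: int = 0, label: str = ""
) -> list[str]:
    """Seeded subsample keeping at most ``cap`` monomers per source, so
    all-pairs distances stay at desk scale."""
    if len(monomers) <= cap:
        return list(monomers)
    rng = rng_for(seed, "monomers", label)
    idx = np.sort(rng.choice(len(monomers), size=cap, replace=False))
    return [monomers[i] for i in idx]
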
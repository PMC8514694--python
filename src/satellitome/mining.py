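"""Satellite DNA discovery from unassembled reads.

Mining proceeds in rounds: draw a read sample, connect reads that share
canonical k-mers into clusters, keep dense clusters whose members show
tandem periodicity, fold the reads at the detected period into a
consensus monomer, then strip reads matching the new consensuses from
the library and repeat with a doubled sample. Rounds stop when nothing
new turns up.

Satellite clusters are near-cliques (every read carries the same
monomer k-mers) whereas clusters arising from mere read overlap on
unique sequence form sparse chains; the density threshold plus the
periodicity requirement separates the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._rng import rng_for
from ._seq import Read, canonical_rotation, decode, encode, gc_at_fraction, kmer_codes, revcomp
from ._align import scan_reads
from .classification import ConsensusRecord, pairwise_identity

__all__ = [
    "ReadCluster",
    "MiningRound",
    "EmptyLibraryError",
    "sample_reads",
    "cluster_reads",
    "detect_tandem_period",
    "build_consensus",
    "filter_matched_reads",
    "match_known_library",
    "run_mining_rounds",
]


class EmptyLibraryError(ValueError):
    pass


@dataclass
class ReadCluster:
    """A connected component of the read-similarity graph."""

    cluster_id: str
    member_read_ids: list[str]
    member_indices: list[int]
    graph_density: float
    tandem_flag: bool = False
    periodicity: Optional[int] = None

    @property
    def size(self) -> int:
        return len(self.member_read_ids)


@dataclass
class MiningRound:
    round_index: int
    sample_size: int
    new_consensuses: list[str]
    remaining_library_size: int


def sample_reads(library: Sequence[Read], n: int, seed: int) -> list[Read]:
    """Uniform sample without replacement of ``min(n, |library|)`` reads."""
    if not library:
        raise EmptyLibraryError("cannot sample from an empty library")
    if n < 1:
        raise ValueError("sample size must be >= 1")
    n = min(n, len(library))
    rng = rng_for(seed, "sample")
    idx = np.sort(rng.choice(len(library), size=n, replace=False))
    return [library[i] for i in idx]


def _kmer_occurrences(reads: Sequence[Read], k: int) -> tuple[np.ndarray, np.ndarray]:
    """(read_index, canonical_kmer) pairs, one per distinct k-mer per read."""
    ridx_parts, code_parts = [], []
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r.sequence), []).append(i)
    for length, idxs in by_len.items():
        if length < k:
            continue
        block = 20_000
        for lo in range(0, len(idxs), block):
            sub = idxs[lo : lo + block]
            mat = np.vstack([encode(reads[i].sequence) for i in sub])
            codes = kmer_codes(mat, k)
            for row, i in enumerate(sub):
                u = np.unique(codes[row])
                ridx_parts.append(np.full(u.size, i, dtype=np.int64))
                code_parts.append(u)
    if not code_parts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(ridx_parts), np.concatenate(code_parts)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_reads(
    reads: Sequence[Read],
    k: int = 13,
    min_shared_kmers: int = 3,
    min_kmer_count: int = 2,
    pair_cap: int = 20_000_000,
) -> list[ReadCluster]:
    """Single-linkage clusters of reads sharing canonical k-mers.

    An edge joins two reads sharing at least ``min_shared_kmers``
    distinct canonical k-mers; connected components of size >= 2 are
    returned with their graph density. Only k-mers occurring in at
    least ``min_kmer_count`` reads contribute (values above 2 act as a
    repetitiveness filter that suppresses plain read-overlap edges in
    high-coverage samples).
    """
    if k < 9:
        raise ValueError("k must be >= 9")
    if not reads:
        raise EmptyLibraryError("no reads to cluster")
    ridx, codes = _kmer_occurrences(reads, k)
    if codes.size == 0:
        return []
    order = np.argsort(codes, kind="stable")
    codes, ridx = codes[order], ridx[order]
    uniq, starts, counts = np.unique(codes, return_index=True, return_counts=True)
    pair_counts: dict[tuple[int, int], int] = {}
    budget = pair_cap
    for s, c in zip(starts, counts):
        if c < max(2, min_kmer_count):
            continue
        members = np.sort(ridx[s : s + c])
        m = members.size
        budget -= m * (m - 1) // 2
        if budget < 0:
            raise MemoryError(
                "k-mer sharing graph too dense; raise min_kmer_count"
            )
        for i in range(m):
            a = int(members[i])
            for j in range(i + 1, m):
                key = (a, int(members[j]))
                pair_counts[key] = pair_counts.get(key, 0) + 1
    edges = [p for p, n in pair_counts.items() if n >= min_shared_kmers]
    if not edges:
        return []
    uf = _UnionFind(len(reads))
    for a, b in edges:
        uf.union(a, b)
    comp_members: dict[int, list[int]] = {}
    involved = {i for e in edges for i in e}
    for i in sorted(involved):
        comp_members.setdefault(uf.find(i), []).append(i)
    comp_edges: dict[int, int] = {}
    for a, b in edges:
        comp_edges[uf.find(a)] = comp_edges.get(uf.find(a), 0) + 1
    clusters = []
    roots = sorted(comp_members, key=lambda r: (-len(comp_members[r]), r))
    for n, root in enumerate(roots, start=1):
        members = comp_members[root]
        sz = len(members)
        density = comp_edges.get(root, 0) / (sz * (sz - 1) / 2)
        clusters.append(
            ReadCluster(
                cluster_id=f"CL{n}",
                member_read_ids=[reads[i].id for i in members],
                member_indices=members,
                graph_density=density,
            )
        )
    return clusters


def detect_tandem_period(
    sequence: str, min_period: int = 5, min_identity: float = 0.8
) -> Optional[int]:
    """Smallest period p (scanning p = min_period .. len/2) at which the
    sequence matches itself shifted by p with >= ``min_identity``
    identity over the overlap; None when no period qualifies."""
    if len(sequence) < 10:
        raise ValueError("sequence shorter than 10 bp")
    codes = encode(sequence)
    n = codes.size
    for p in range(min_period, n // 2 + 1):
        a, b = codes[:-p], codes[p:]
        if float((a == b).mean()) >= min_identity:
            return p
    return None


def _fold_counts(codes: np.ndarray, p: int) -> np.ndarray:
    """(p, 4) base-count matrix from folding a code array at period p."""
    counts = np.zeros((p, 4), dtype=np.int64)
    pos = np.arange(codes.size) % p
    np.add.at(counts, (pos, codes), 1)
    return counts


def _majority(counts: np.ndarray) -> np.ndarray:
    return counts.argmax(axis=1).astype(np.uint8)


def greedy_assemble(
    reads: Sequence[Read], seed_len: int = 25, max_len: int = 700
) -> str:
    """Greedy right-extension assembly for clusters whose monomer is too
    long to show two copies inside a single read.

    Seeds contig extension with exact ``seed_len``-mers; good enough for
    the tandem case where overlapping reads are genomically identical up
    to sequencing error.
    """
    if not reads:
        raise EmptyLibraryError("no reads to assemble")
    seqs = [r.sequence for r in reads]
    seqs += [revcomp(s) for s in seqs]
    seed_map: dict[str, list[tuple[int, int]]] = {}
    for si, s in enumerate(seqs):
        for off in range(0, len(s) - seed_len + 1):
            seed_map.setdefault(s[off : off + seed_len], []).append((si, off))
    contig = max(seqs[: len(reads)], key=len)
    used = {contig}
    while len(contig) < max_len:
        tail = contig[-seed_len:]
        best_ext = ""
        for si, off in seed_map.get(tail, []):
            ext = seqs[si][off + seed_len :]
            if len(ext) > len(best_ext) and seqs[si] not in used:
                best_ext, best_seq = ext, seqs[si]
        if not best_ext:
            break
        used.add(best_seq)
        contig += best_ext
    return contig


def build_consensus(
    reads: Sequence[Read],
    periodicity: Optional[int] = None,
    record_id: str = "consensus",
    max_reads: int = 150,
    period_identity: float = 0.7,
) -> Optional[ConsensusRecord]:
    """Fold cluster reads at the tandem period and take the majority
    base per column; the result is reported in the canonical monomer
    frame (minimal rotation over both strands).

    Each read is folded at the period and phased against a reference
    fold by exhaustive rotation / strand search before votes are
    accumulated. When no read exhibits the period internally (monomer
    longer than half the read), a greedy assembly of the cluster is
    folded instead. Returns None when no tandem period is found.

    ``period_identity`` is deliberately looser than the 0.8 default of
    :func:`detect_tandem_period`: neighbouring array copies at consensus
    divergence d agree at only ~(1-d)^2 + d^2/3 of sites, so 0.7 keeps
    families minable up to d ~ 0.15 while random sequence (~25%
    self-identity under shift) stays far below the bar.
    """
    all_reads = list(reads)
    reads = all_reads[:max_reads]
    if not reads:
        return None
    p = periodicity
    if p is None:
        votes: dict[int, int] = {}
        n_polled = 0
        for r in reads[:40]:
            if len(r.sequence) < 10:
                continue
            n_polled += 1
            got = detect_tandem_period(r.sequence, min_identity=period_identity)
            if got is not None:
                votes[got] = votes.get(got, 0) + 1
        if votes:
            period, n_votes = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            # demand a clear plurality; one stray self-similar read must
            # not outvote a long-monomer cluster into a bogus period
            if n_votes >= max(3, n_polled // 4):
                p = period
    if p is None:
        contig = greedy_assemble(all_reads[:1000])
        if len(contig) >= 10:
            p = detect_tandem_period(contig, min_identity=period_identity)
        if p is None:
            return None
        counts = _fold_counts(encode(contig), p)
        seq = canonical_rotation(decode(_majority(counts)))
        return ConsensusRecord.from_sequence(record_id, seq, canonical=True)

    ref = None
    total = np.zeros((p, 4), dtype=np.int64)
    for r in reads:
        if len(r.sequence) < p:
            continue
        fwd = _fold_counts(encode(r.sequence), p)
        rev = _fold_counts(encode(revcomp(r.sequence)), p)
        if ref is None:
            ref = _majority(fwd)
            total += fwd
            continue
        best = None
        for counts in (fwd, rev):
            mono = _majority(counts)
            doubled = np.concatenate([mono, mono])
            for rot in range(p):
                score = int((doubled[rot : rot + p] == ref).sum())
                if best is None or score > best[0]:
                    best = (score, counts, rot)
        score, counts, rot = best
        if score / p < 0.5:
            continue  # does not phase onto the reference; skip
        total += np.roll(counts, -rot, axis=0)
    if ref is None:
        return None
    seq = canonical_rotation(decode(_majority(total)))
    return ConsensusRecord.from_sequence(record_id, seq, canonical=True)


def default_min_aligned(rul: int, read_length: int) -> int:
    return max(25, min(rul, read_length // 2))


def filter_matched_reads(
    library: Sequence[Read],
    consensuses: Sequence[ConsensusRecord],
    min_identity: float = 0.7,
    min_aligned: Optional[int] = None,
) -> list[Read]:
    """Remove reads whose best local alignment to any consensus (tiled
    head-to-tail) reaches ``min_identity`` over ``min_aligned`` columns."""
    if not consensuses:
        raise ValueError("empty consensus set")
    if not library:
        return []
    read_len = max(len(r.sequence) for r in library)
    cons = {c.record_id: c.sequence for c in consensuses}
    if min_aligned is None:
        need = {c.record_id: default_min_aligned(c.rul, read_len) for c in consensuses}
    else:
        need = min_aligned
    hits = scan_reads(library, cons, min_identity=min_identity, min_aligned=need)
    matched = {h.read_id for h in hits}
    return [r for r in library if r.id not in matched]


def match_known_library(
    consensus: "ConsensusRecord | str",
    priors: Sequence["ConsensusRecord | str"],
    min_identity: float = 0.8,
) -> Optional[tuple["ConsensusRecord | str", float]]:
    """Best rotation/strand-invariant match of a consensus against a
    prior consensus library; None below ``min_identity``."""
    best = None
    for prior in priors:
        ident = pairwise_identity(consensus, prior)
        if ident >= min_identity and (best is None or ident > best[1]):
            best = (prior, ident)
    return best


def _auto_kmer_count_threshold(reads: Sequence[Read], k: int) -> int:
    """Repetitiveness cutoff for clustering: k-mers must occur clearly
    above the typical (coverage-driven) multiplicity to contribute."""
    _, codes = _kmer_occurrences(reads, k)
    if codes.size == 0:
        return 3
    _, counts = np.unique(codes, return_counts=True)
    multi = counts[counts >= 2]
    if multi.size == 0:
        return 3
    return max(3, int(math.ceil(3.0 * float(np.median(multi)))))


def run_mining_rounds(
    library: Sequence[Read],
    base_sample: int = 10_000,
    max_rounds: int = 8,
    seed: int = 0,
    k: int = 13,
    min_shared_kmers: int = 3,
    min_density: float = 0.2,
    min_cluster_size: int = 5,
    filter_identity: float = 0.7,
    dedup_identity: float = 0.8,
    priors: Sequence[ConsensusRecord] = (),
) -> tuple[list[ConsensusRecord], list[MiningRound]]:
    """Iterative mining: sample -> cluster -> tandem check -> consensus
    -> filter, doubling the sample every round.

    Stops when a round yields no consensus that is new relative to
    ``priors`` and earlier rounds (at ``dedup_identity``), or after
    ``max_rounds``. Deterministic for a given seed.
    """
    if base_sample < 1:
        raise ValueError("base_sample must be >= 1")
    remaining = list(library)
    found: list[ConsensusRecord] = []
    known: list[ConsensusRecord] = list(priors)
    rounds: list[MiningRound] = []
    for r in range(1, max_rounds + 1):
        if not remaining:
            break
        n = base_sample * 2 ** (r - 1)
        sample = sample_reads(remaining, n, int(rng_for(seed, "round", r).integers(2**31 - 1)))
        thr = _auto_kmer_count_threshold(sample, k)
        clusters = cluster_reads(
            sample, k=k, min_shared_kmers=min_shared_kmers, min_kmer_count=thr
        )
        new: list[ConsensusRecord] = []
        for cl in clusters:
            if cl.size < min_cluster_size or cl.graph_density < min_density:
                continue
            members = [sample[i] for i in cl.member_indices]
            rec = build_consensus(
                members, record_id=f"R{r}{cl.cluster_id}"
            )
            if rec is None:
                continue
            cl.tandem_flag = True
            cl.periodicity = rec.rul
            if match_known_library(rec, known + new, dedup_identity) is not None:
                continue
            new.append(rec)
        if not new:
            rounds.append(
                MiningRound(r, len(sample), [], len(remaining))
            )
            break
        remaining = filter_matched_reads(
            remaining, new, min_identity=filter_identity
        )
        found.extend(new)
        known.extend(new)
        rounds.append(
            MiningRound(r, len(sample), [c.record_id for c in new], len(remaining))
        )
    return found, rounds
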
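"""Grouping of consensus monomers into variants, families and
superfamilies, and abundance-ranked naming.

Homology between two monomers is scored as the best global identity
over every rotation frame and both strands (computed by aligning the
shorter sequence into a doubled copy of the longer one). Single-linkage
components at three nested identity thresholds define the tiers:
variants (near-identical monomers), families (clearly homologous
monomers) and superfamilies (families sharing partial homology).

Family names follow the <Prefix>Sat<NN>-<RUL> convention, numbered in
order of decreasing abundance in the female genome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, Union

import edlib

import numpy as np

from ._seq import canonical_rotation, gc_at_fraction, revcomp, seq_kmers

ANCHOR_K = 10  # exact-word seed required before two monomers count as homologous

__all__ = [
    "ConsensusRecord",
    "SatFamily",
    "pairwise_identity",
    "group_satellites",
    "name_families",
    "family_stats",
]


@dataclass(frozen=True)
class ConsensusRecord:
    """A mined consensus monomer in its canonical rotation frame."""

    record_id: str
    sequence: str
    rul: int
    at_fraction: float

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.record_id}: sequence must be non-empty ACGT")
        if self.rul != len(self.sequence):
            raise ValueError(f"{self.record_id}: rul != sequence length")
        if self.sequence != canonical_rotation(self.sequence):
            raise ValueError(f"{self.record_id}: sequence not in canonical rotation")

    @classmethod
    def from_sequence(
        cls, record_id: str, sequence: str, canonical: bool = False
    ) -> "ConsensusRecord":
        seq = sequence if canonical else canonical_rotation(sequence)
        return cls(
            record_id=record_id,
            sequence=seq,
            rul=len(seq),
            at_fraction=gc_at_fraction(seq),
        )


@dataclass(frozen=True)
class SatFamily:
    """One satellite family: a set of variant consensus records.

    ``variant_ids`` lists all member record ids; ``n_variants`` counts
    the variant-threshold subgroups among them. ``name`` is assigned by
    :func:`name_families`.
    """

    family_id: str
    variant_ids: tuple[str, ...]
    representative: ConsensusRecord
    n_variant_groups: int
    superfamily_id: Optional[str] = None
    name: Optional[str] = None

    @property
    def n_variants(self) -> int:
        """Every member consensus counts as one variant of the family."""
        return len(self.variant_ids)


def _cigar_identity(query: str, target: str) -> float:
    """Identity of the best semi-global placement of ``query`` inside
    ``target`` (matches / alignment columns, gaps counted as columns)."""
    res = edlib.align(query, target, mode="HW", task="path")
    cigar = res["cigar"]
    if cigar is None:
        return 0.0
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        columns += n
        if ch == "=":
            matches += n
    return matches / columns if columns else 0.0


def pairwise_identity(
    a: Union[ConsensusRecord, str], b: Union[ConsensusRecord, str]
) -> float:
    """Best global identity between two monomers over all rotation
    frames of either strand.

    The shorter monomer is aligned into a doubled copy of the longer
    one, which scans every rotation in a single alignment; the reverse
    complement is tried as well and the maximum identity returned.

    Unrelated random monomers still reach 55-65% "identity" under such
    an alignment, so homology is gated on an exact shared word of
    ``ANCHOR_K`` bases (rotation- and strand-insensitive): pairs without
    one score 0.0, mirroring how alignment-seeded homology searches
    simply report no hit.
    """
    sa = a.sequence if isinstance(a, ConsensusRecord) else a
    sb = b.sequence if isinstance(b, ConsensusRecord) else b
    if not sa or not sb:
        raise ValueError("empty sequence")
    if min(len(sa), len(sb)) >= ANCHOR_K:
        ka = seq_kmers(sa + sa, ANCHOR_K)
        kb = seq_kmers(sb + sb, ANCHOR_K)
        if not np.intersect1d(ka, kb, assume_unique=True).size:
            return 0.0
    query, longer = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
    target = longer + longer
    return max(
        _cigar_identity(query, target), _cigar_identity(revcomp(query), target)
    )


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


def _components(n: int, edges: Sequence[tuple[int, int]]) -> list[list[int]]:
    uf = _UnionFind(n)
    for a, b in edges:
        uf.union(a, b)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def group_satellites(
    consensuses: Sequence[ConsensusRecord],
    variant_thr: float = 0.95,
    family_thr: float = 0.80,
    superfamily_thr: float = 0.60,
) -> list[SatFamily]:
    """Partition consensus records into families via single-linkage
    components of the pairwise-identity graph.

    Components at ``family_thr`` define families; within each family,
    components at ``variant_thr`` count its variants; components at
    ``superfamily_thr`` joining two or more families define
    superfamilies (SF1, SF2, ... in deterministic order). Input order
    does not matter: records are processed sorted by sequence.
    """
    if not 0.0 < superfamily_thr < family_thr < variant_thr <= 1.0:
        raise ValueError(
            "thresholds must satisfy 0 < superfamily < family < variant <= 1"
        )
    records = sorted(consensuses, key=lambda r: (r.sequence, r.record_id))
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    ident = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            ident[i][j] = ident[j][i] = pairwise_identity(records[i], records[j])

    def edges_at(thr: float) -> list[tuple[int, int]]:
        return [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if ident[i][j] >= thr
        ]

    fam_comps = _components(n, edges_at(family_thr))
    sf_comps = _components(n, edges_at(superfamily_thr))

    # superfamily id per record index, only for components spanning >1 family
    fam_of_idx: dict[int, int] = {}
    for fi, comp in enumerate(fam_comps):
        for i in comp:
            fam_of_idx[i] = fi
    sf_of_fam: dict[int, str] = {}
    sf_n = 0
    for comp in sf_comps:
        fams = sorted({fam_of_idx[i] for i in comp})
        if len(fams) > 1:
            sf_n += 1
            for fi in fams:
                sf_of_fam[fi] = f"SF{sf_n}"

    families: list[SatFamily] = []
    for fi, comp in enumerate(fam_comps):
        sub = [records[i] for i in comp]
        # variants: single-linkage inside the family at variant_thr
        local = {i: li for li, i in enumerate(comp)}
        var_edges = [
            (local[i], local[j])
            for i in comp
            for j in comp
            if i < j and ident[i][j] >= variant_thr
        ]
        n_variant_groups = len(_components(len(comp), var_edges))
        # representative: medoid (max summed identity), tie -> sequence
        rep_idx = min(
            range(len(comp)),
            key=lambda li: (
                -sum(ident[comp[li]][j] for j in comp),
                sub[li].sequence,
            ),
        )
        rep = sub[rep_idx]
        families.append(
            SatFamily(
                family_id=f"F{fi + 1:03d}",
                variant_ids=tuple(r.record_id for r in sub),
                representative=rep,
                n_variant_groups=n_variant_groups,
                superfamily_id=sf_of_fam.get(fi),
            )
        )
    return families


def name_families(
    families: Sequence[SatFamily],
    female_abundances: Mapping[str, float],
    prefix: str = "Mel",
) -> list[SatFamily]:
    """Assign <Prefix>Sat<NN>-<RUL> names ranked by decreasing female
    abundance (ties broken by smaller RUL, then representative
    sequence); returns families in rank order."""
    ids = [f.family_id for f in families]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate family ids")
    missing = [i for i in ids if i not in female_abundances]
    if missing:
        raise ValueError(f"families without female abundance: {missing}")
    ranked = sorted(
        families,
        key=lambda f: (
            -female_abundances[f.family_id],
            f.representative.rul,
            f.representative.sequence,
        ),
    )
    width = max(2, len(str(len(ranked))))
    out = []
    for rank, fam in enumerate(ranked, start=1):
        name = f"{prefix}Sat{rank:0{width}d}-{fam.representative.rul}"
        out.append(replace(fam, name=name))
    return out


def family_stats(family: SatFamily) -> dict:
    """Descriptors of one family: representative RUL, A+T fraction and
    variant count."""
    return {
        "family_id": family.family_id,
        "name": family.name,
        "rul": family.representative.rul,
        "at_fraction": family.representative.at_fraction,
        "n_variants": family.n_variants,
        "n_records": len(family.variant_ids),
        "superfamily_id": family.superfamily_id,
    }
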
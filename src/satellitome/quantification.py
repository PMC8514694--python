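"""Abundance, divergence and sex-bias quantification.

Reads are mapped to family consensus monomers; genomic abundance of a
family is the number of read nucleotides aligned to its consensus
divided by library size in bp. Per-hit divergence uses the Kimura
2-parameter correction K = -1/2 ln[(1-2P-Q) sqrt(1-2Q)], with P and Q
the transition and transversion proportions over non-gap columns.
Landscapes histogram hit nucleotides in 1% K2P bins; the subtractive
landscape (female minus male) and the per-family F/M abundance ratio
summarize the differences between the sexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._align import AlignedReadHit, ConsensusIndex, scan_reads
from ._seq import Read

__all__ = [
    "AlignedReadHit",
    "AbundanceRecord",
    "RepeatLandscape",
    "k2p_distance",
    "k2p_from_counts",
    "map_reads",
    "assign_reads",
    "family_abundance",
    "build_landscape",
    "subtract_landscapes",
    "sex_bias_table",
    "library_totals",
    "library_size_bp",
]

N_BINS = 50  # landscape x-axis: 1% K2P bins, capped at 50%

BIAS_CLASSES = (
    "female-biased",
    "male-biased",
    "female-exclusive",
    "male-exclusive",
    "balanced",
)


def k2p_distance(p, q):
    """Kimura 2-parameter distance from transition proportion ``p`` and
    transversion proportion ``q`` (array-friendly).

    Returns NaN where the distance saturates (1-2P-Q <= 0 or 1-2Q <= 0).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(
            (a > 0) & (b > 0),
            -0.5 * np.log(np.where(a > 0, a, 1.0) * np.sqrt(np.where(b > 0, b, 1.0))),
            np.nan,
        )
    if k.ndim == 0:
        return float(k)
    return k


def k2p_from_counts(transitions: int, transversions: int, aligned_columns: int) -> float:
    """K2P distance from raw transition/transversion counts."""
    if min(transitions, transversions, aligned_columns) < 0:
        raise ValueError("negative counts")
    if aligned_columns == 0:
        raise ValueError("no aligned columns")
    return k2p_distance(transitions / aligned_columns, transversions / aligned_columns)


def _fill_k2p(hits: Sequence[AlignedReadHit]) -> None:
    for h in hits:
        if h.aligned_columns == 0:
            h.k2p, h.saturated = math.nan, True
            continue
        k = k2p_from_counts(h.transitions, h.transversions, h.aligned_columns)
        if math.isnan(k):
            h.k2p, h.saturated = math.nan, True
        else:
            h.k2p, h.saturated = k, False


def map_reads(
    library: Sequence[Read],
    consensus: str,
    min_identity: float = 0.7,
    min_aligned: Optional[int] = None,
    min_score: int = 25,
    family_id: str = "family",
) -> list[AlignedReadHit]:
    """Map every read of ``library`` against one consensus monomer.

    The consensus is tiled head-to-tail so reads spanning monomer
    junctions still produce one full-length hit. Hits carry transition /
    transversion counts and the K2P distance (non-gap columns only).
    """
    hits = scan_reads(
        library,
        {family_id: consensus},
        min_identity=min_identity,
        min_aligned=min_aligned,
        min_score=min_score,
    )
    _fill_k2p(hits)
    return hits


def assign_reads(
    library: Sequence[Read],
    consensuses: Mapping[str, str],
    min_identity: float = 0.7,
    min_aligned: "int | Mapping[str, int] | None" = None,
    min_score: int = 25,
    index: Optional[ConsensusIndex] = None,
) -> dict[str, list[AlignedReadHit]]:
    """Map a library against a whole consensus set, assigning each read
    to its single best family (avoids double-counting nucleotides across
    homologous families). Returns hits grouped by family id."""
    hits = scan_reads(
        library,
        consensuses,
        min_identity=min_identity,
        min_aligned=min_aligned,
        min_score=min_score,
        index=index,
    )
    _fill_k2p(hits)
    grouped: dict[str, list[AlignedReadHit]] = {fid: [] for fid in consensuses}
    for h in hits:
        grouped[h.family_id].append(h)
    return grouped


@dataclass(frozen=True)
class AbundanceRecord:
    """Per family x library abundance summary.

    ``abundance`` is aligned nucleotides / library size (fraction of the
    library); ``mean_divergence`` is the nucleotide-weighted mean K2P in
    percent, or None when the family has no (unsaturated) hits.
    """

    family_id: str
    library_id: str
    abundance: float
    mean_divergence: Optional[float]
    aligned_nt: int
    n_hits: int
    n_saturated: int = 0


def library_size_bp(library: Sequence[Read]) -> int:
    """Total nucleotides actually present in the library."""
    return sum(len(r.sequence) for r in library)


def family_abundance(
    hits: Sequence[AlignedReadHit],
    library_size_bp: int,
    family_id: str = "family",
    library_id: str = "library",
) -> AbundanceRecord:
    if library_size_bp <= 0:
        raise ValueError("library size must be positive")
    aligned = sum(h.aligned_columns for h in hits)
    good = [h for h in hits if not h.saturated]
    if good:
        w = np.array([h.aligned_columns for h in good], dtype=float)
        k = np.array([h.k2p for h in good])
        mean_div = float((w * k).sum() / w.sum()) * 100.0
    else:
        mean_div = None
    return AbundanceRecord(
        family_id=family_id,
        library_id=library_id,
        abundance=aligned / library_size_bp,
        mean_divergence=mean_div,
        aligned_nt=aligned,
        n_hits=len(hits),
        n_saturated=len(hits) - len(good),
    )


@dataclass
class RepeatLandscape:
    """1%-binned abundance-by-divergence histogram.

    ``bins[i]`` holds the abundance (aligned nt / library bp) of hit
    nucleotides with K2P in [i%, (i+1)%); divergences beyond 49% pool
    into the last bin. Subtractive landscapes may hold negative bins.
    """

    family_id: str
    library_id: str
    bins: np.ndarray

    def total(self) -> float:
        return float(self.bins.sum())


def build_landscape(
    hits: Sequence[AlignedReadHit],
    library_size_bp: int,
    family_id: str = "family",
    library_id: str = "library",
) -> RepeatLandscape:
    """Landscape of one family in one library. Saturated hits are
    excluded; bins sum to the abundance of the remaining hits exactly."""
    if library_size_bp <= 0:
        raise ValueError("library size must be positive")
    nt = np.zeros(N_BINS, dtype=np.int64)
    for h in hits:
        if h.saturated:
            continue
        b = min(int(h.k2p * 100), N_BINS - 1)
        nt[b] += h.aligned_columns
    return RepeatLandscape(
        family_id=family_id, library_id=library_id, bins=nt / library_size_bp
    )


def subtract_landscapes(
    female: RepeatLandscape, male: RepeatLandscape
) -> RepeatLandscape:
    """Bin-wise female minus male landscape (positive bins = female
    excess, negative = male excess)."""
    if female.family_id != male.family_id:
        raise ValueError("landscapes describe different families")
    if female.bins.shape != male.bins.shape:
        raise ValueError("mismatched bin structure")
    return RepeatLandscape(
        family_id=female.family_id,
        library_id=f"{female.library_id}-{male.library_id}",
        bins=female.bins - male.bins,
    )


def _classify_bias(f: float, m: float) -> tuple[float, str]:
    if m == 0 and f > 0:
        return math.inf, "female-exclusive"
    if f == 0 and m > 0:
        return 0.0, "male-exclusive"
    if f == 0 and m == 0:
        return math.nan, "balanced"
    r = f / m
    if r > 1:
        return r, "female-biased"
    if r < 1:
        return r, "male-biased"
    return r, "balanced"


def sex_bias_table(
    female_records: Sequence[AbundanceRecord],
    male_records: Sequence[AbundanceRecord],
) -> pd.DataFrame:
    """Per-family F/M abundance quotient and bias class.

    Families with ratio > 1 count as female-biased; a family with hits
    in only one sex is classified exclusive to that sex (the F/M ratio
    carries an infinity sentinel for female-exclusive families).
    Families absent from both record sets are dropped with a warning
    column left to the caller's logging.
    """
    f_by = {r.family_id: r for r in female_records}
    m_by = {r.family_id: r for r in male_records}
    rows = []
    for fid in sorted(set(f_by) | set(m_by)):
        f = f_by[fid].abundance if fid in f_by else 0.0
        m = m_by[fid].abundance if fid in m_by else 0.0
        if f == 0 and m == 0:
            continue
        ratio, bias = _classify_bias(f, m)
        rows.append(
            {
                "family_id": fid,
                "female_abundance": f,
                "male_abundance": m,
                "fm_ratio": ratio,
                "bias_class": bias,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "female_abundance",
            "male_abundance",
            "fm_ratio",
            "bias_class",
        ],
    )


@dataclass(frozen=True)
class LibraryTotals:
    """Total satellite fraction per library plus female enrichment."""

    totals: dict[str, float]
    enrichment_percent: Optional[float]
    enrichment_percent_rounded: Optional[int]


def library_totals(
    records_by_library: Mapping[str, Sequence[AbundanceRecord]],
    female: str = "female",
    male: str = "male",
) -> LibraryTotals:
    """Sum family abundances per library and report the female-vs-male
    enrichment 100 * (F_total / M_total - 1)."""
    totals = {
        lib: float(sum(r.abundance for r in recs))
        for lib, recs in records_by_library.items()
    }
    enrich = rounded = None
    if female in totals and male in totals:
        if totals[male] == 0:
            enrich = rounded = None  # undefined, flagged by None
        else:
            enrich = 100.0 * (totals[female] / totals[male] - 1.0)
            rounded = int(round(enrich))
    return LibraryTotals(
        totals=totals, enrichment_percent=enrich, enrichment_percent_rounded=rounded
    )
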
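"""Per-position variant profiles of a satellite family.

A profile is a pileup of mapped read bases over the consensus monomer
frame: hits against the tiled consensus are folded modulo the repeat
unit length, giving per-position coverage, base composition, the major
base and the variant fraction (1 - major/coverage). Comparing the
female and male profiles of one family flags positions where the two
libraries disagree — candidate sex-specific sequence signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._align import AlignedReadHit

__all__ = [
    "PositionProfile",
    "SignaturePosition",
    "ProfileComparison",
    "build_position_profile",
    "compare_profiles",
]

BASE_ORDER = "ACGT-"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass
class PositionProfile:
    """Pileup over consensus positions (monomer frame).

    ``counts`` has shape (rul, 5) with columns A, C, G, T, gap;
    positions are 0-based internally, 1-based in reports.
    """

    family_id: str
    library_id: str
    consensus: str
    counts: np.ndarray

    @property
    def rul(self) -> int:
        return len(self.consensus)

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def major_base(self) -> np.ndarray:
        """Most frequent state per position ('.' where coverage is 0)."""
        idx = self.counts.argmax(axis=1)
        out = np.array([BASE_ORDER[i] for i in idx])
        out[self.coverage == 0] = "."
        return out

    @property
    def variant_fraction(self) -> np.ndarray:
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            vf = 1.0 - np.where(cov > 0, self.counts.max(axis=1), 0) / np.where(
                cov > 0, cov, 1
            )
        return vf


def build_position_profile(
    hits: Sequence[AlignedReadHit],
    consensus: str,
    family_id: str = "family",
    library_id: str = "library",
) -> PositionProfile:
    """Pileup of hit bases over the consensus monomer.

    Hits carry gap-free aligned blocks in tiled-target coordinates;
    target positions fold modulo the repeat unit length. Deletions in
    the read relative to the consensus count into a fifth gap state, so
    coordinates stay frame-stable. An empty hit list yields an all-zero
    profile.
    """
    rul = len(consensus)
    counts = np.zeros((rul, 5), dtype=np.int64)
    for h in hits:
        prev_t = prev_q = None
        for t0, t1, q0, q1 in h.blocks:
            if prev_t is not None and t0 > prev_t and q0 == prev_q:
                # deletion in the read: consensus columns with no base
                pos = np.arange(prev_t, t0) % rul
                np.add.at(counts, (pos, 4), 1)
            pos = np.arange(t0, t1) % rul
            base_idx = np.fromiter(
                (_BASE_INDEX[b] for b in h.read_seq[q0:q1]), dtype=np.int64, count=q1 - q0
            )
            np.add.at(counts, (pos, base_idx), 1)
            prev_t, prev_q = t1, q1
    return PositionProfile(
        family_id=family_id, library_id=library_id, consensus=consensus, counts=counts
    )


@dataclass(frozen=True)
class SignaturePosition:
    """One flagged consensus position (1-based)."""

    position: int
    major_female: str
    major_male: str
    variant_fraction_female: float
    variant_fraction_male: float
    coverage_female: int
    coverage_male: int


@dataclass
class ProfileComparison:
    """Outcome of a female-vs-male profile comparison."""

    family_id: str
    signatures: list[SignaturePosition]
    insufficient_coverage: dict[str, bool]


def compare_profiles(
    profile_f: PositionProfile,
    profile_m: PositionProfile,
    min_coverage: int = 20,
    delta: float = 0.30,
) -> ProfileComparison:
    """Flag positions where the sexes disagree.

    A position is a signature when both libraries reach ``min_coverage``
    there and either the major base differs or the variant fractions
    differ by at least ``delta``. When one library never reaches
    ``min_coverage`` (the family is absent or too divergent in that
    sex), no positions are flagged and the library is reported as
    having an incomplete profile instead.
    """
    if profile_f.consensus != profile_m.consensus:
        raise ValueError("profiles are not in the same consensus frame")
    if profile_f.family_id != profile_m.family_id:
        raise ValueError("profiles describe different families")
    cov_f, cov_m = profile_f.coverage, profile_m.coverage
    ok = (cov_f >= min_coverage) & (cov_m >= min_coverage)
    maj_f, maj_m = profile_f.major_base, profile_m.major_base
    vf_f, vf_m = profile_f.variant_fraction, profile_m.variant_fraction
    flagged = ok & ((maj_f != maj_m) | (np.abs(vf_f - vf_m) >= delta))
    signatures = [
        SignaturePosition(
            position=i + 1,
            major_female=maj_f[i],
            major_male=maj_m[i],
            variant_fraction_female=float(vf_f[i]),
            variant_fraction_male=float(vf_m[i]),
            coverage_female=int(cov_f[i]),
            coverage_male=int(cov_m[i]),
        )
        for i in np.nonzero(flagged)[0]
    ]
    insufficient = {
        profile_f.library_id: bool((cov_f < min_coverage).all()),
        profile_m.library_id: bool((cov_m < min_coverage).all()),
    }
    return ProfileComparison(
        family_id=profile_f.family_id,
        signatures=signatures,
        insufficient_coverage=insufficient,
    )
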
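"""Synthetic genomes and sex-paired read libraries with planted satDNA.

The generator builds random genomic backgrounds, inserts tandem arrays
of independently mutated satellite monomers for each planted family,
and simulates uniform-coverage short-read libraries from the result.
Every planted locus and every per-family genome proportion is recorded
in a :class:`TruthTable`, so downstream mining / quantification results
can be scored against exact ground truth.

The built-in two-sex scenario (:func:`two_sex_scenario`) emulates a
fish satellitome with a heteromorphic, satellite-enriched W chromosome
in the female: ~30 families spanning four orders of magnitude in genome
proportion, a handful of strongly female-amplified families, one
female-exclusive family, and a female genome whose total satellite
content exceeds the male's by roughly 14%.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._rng import rng_for
from ._seq import Read, decode, encode, revcomp
from .quantification import k2p_distance

__all__ = [
    "FamilySpec",
    "LibrarySpec",
    "TruthTable",
    "ScenarioResult",
    "make_consensus",
    "mutate_copy",
    "substitution_rates",
    "plant_genome",
    "simulate_library",
    "two_sex_family_specs",
    "two_sex_scenario",
]

# Desk-scale guard: refuse to simulate libraries above this many bases
# unless explicitly overridden.
MAX_LIBRARY_BP = 1_000_000_000


class SpecError(ValueError):
    """An invalid family / library specification."""


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one planted satellite family.

    ``divergence_target`` is the expected Kimura 2-parameter distance of
    each monomer copy to the family consensus; ``ts_tv_ratio`` is the
    expected transition/transversion count ratio of those substitutions.
    Copy counts and locus counts are per haploid genome and per sex.
    """

    family_id: str
    rul: int
    at_fraction: float = 0.6
    consensus: Optional[str] = None
    divergence_target: float = 0.05
    ts_tv_ratio: float = 2.0
    copies_female: int = 0
    copies_male: int = 0
    n_loci_female: int = 1
    n_loci_male: int = 1

    def __post_init__(self) -> None:
        if self.rul < 5:
            raise SpecError(f"{self.family_id}: repeat unit length must be >= 5")
        if not 0.0 <= self.at_fraction <= 1.0:
            raise SpecError(f"{self.family_id}: at_fraction outside [0, 1]")
        if self.divergence_target < 0:
            raise SpecError(f"{self.family_id}: negative divergence target")
        if self.divergence_target >= 1:
            raise SpecError(f"{self.family_id}: K2P target saturates at >= 1")
        if self.ts_tv_ratio < 0:
            raise SpecError(f"{self.family_id}: negative ts/tv ratio")
        if min(self.copies_female, self.copies_male) < 0:
            raise SpecError(f"{self.family_id}: negative copy count")
        for sex in ("female", "male"):
            if self.copies(sex) > 0 and self.n_loci(sex) < 1:
                raise SpecError(
                    f"{self.family_id}: copies planted for {sex} but no loci"
                )
        if self.consensus is not None and len(self.consensus) != self.rul:
            raise SpecError(f"{self.family_id}: consensus length != rul")

    def copies(self, sex: str) -> int:
        return {"female": self.copies_female, "male": self.copies_male}[sex]

    def n_loci(self, sex: str) -> int:
        return {"female": self.n_loci_female, "male": self.n_loci_male}[sex]


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one simulated read library."""

    library_id: str
    read_length: int = 100
    n_reads: int = 100_000
    paired: bool = False
    insert_mean: int = 300
    insert_sd: int = 30
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 30:
            raise SpecError("read_length must be >= 30")
        if self.n_reads < 1:
            raise SpecError("n_reads must be >= 1")
        if not 0.0 <= self.error_rate < 0.1:
            raise SpecError("error_rate must be in [0, 0.1)")
        if self.paired and self.n_reads % 2:
            raise SpecError("paired libraries need an even n_reads")


LOCUS_COLUMNS = ["genome_id", "start", "end", "family_id", "n_monomers"]
PROPORTION_COLUMNS = ["family_id", "genome_id", "proportion"]


@dataclass
class TruthTable:
    """Ground truth for planted satellite content.

    ``loci`` holds one row per planted array with 0-based half-open
    coordinates on the finished genome (BED-compatible column order);
    ``proportions`` holds, per family x genome, the exact fraction of
    genome base pairs lying inside that family's arrays.
    """

    loci: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=LOCUS_COLUMNS)
    )
    proportions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=PROPORTION_COLUMNS)
    )

    def validate(self) -> None:
        for genome_id, sub in self.loci.groupby("genome_id"):
            ordered = sub.sort_values("start")
            if (ordered["start"] >= ordered["end"]).any():
                raise ValueError(f"{genome_id}: empty or inverted locus")
            if (ordered["end"].values[:-1] > ordered["start"].values[1:]).any():
                raise ValueError(f"{genome_id}: overlapping loci")
        for genome_id, sub in self.proportions.groupby("genome_id"):
            p = sub["proportion"]
            if (p < 0).any() or p.sum() > 1 + 1e-12:
                raise ValueError(f"{genome_id}: bad proportions")

    def proportion(self, family_id: str, genome_id: str) -> float:
        sub = self.proportions
        hit = sub[(sub.family_id == family_id) & (sub.genome_id == genome_id)]
        if hit.empty:
            raise KeyError((family_id, genome_id))
        return float(hit["proportion"].iloc[0])

    def total_proportion(self, genome_id: str) -> float:
        sub = self.proportions[self.proportions.genome_id == genome_id]
        return float(sub["proportion"].sum())

    @staticmethod
    def concat(tables: Sequence["TruthTable"]) -> "TruthTable":
        return TruthTable(
            loci=pd.concat([t.loci for t in tables], ignore_index=True),
            proportions=pd.concat(
                [t.proportions for t in tables], ignore_index=True
            ),
        )

    def loci_tsv(self) -> str:
        buf = _stdio.StringIO()
        buf.write("#" + "\t".join(LOCUS_COLUMNS) + "\n")
        self.loci.to_csv(buf, sep="\t", header=False, index=False)
        return buf.getvalue()

    def proportions_tsv(self) -> str:
        buf = _stdio.StringIO()
        self.proportions.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()


def make_consensus(rul: int, at_fraction: float, seed: int) -> str:
    """Random consensus monomer with expected A+T content ``at_fraction``."""
    if rul < 5:
        raise SpecError("repeat unit length must be >= 5")
    if not 0.0 <= at_fraction <= 1.0:
        raise SpecError("at_fraction outside [0, 1]")
    rng = rng_for(seed, "consensus")
    p = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    )
    return decode(rng.choice(4, size=rul, p=p).astype(np.uint8))


def substitution_rates(divergence_target: float, ts_tv_ratio: float) -> tuple[float, float]:
    """Per-site transition and transversion probabilities whose expected
    K2P distance equals ``divergence_target``.

    With observed transition proportion P and transversion proportion Q,
    K = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]. The total substitution probability
    s is split as P = s*r/(1+r), Q = s/(1+r) for ratio r, and s is solved
    numerically so that K(s) equals the target.
    """
    if divergence_target < 0:
        raise SpecError("negative divergence target")
    if divergence_target >= 1:
        raise SpecError("K2P target >= 1 saturates the distance")
    if divergence_target == 0:
        return 0.0, 0.0
    r = ts_tv_ratio

    def k_of(s: float) -> float:
        p = s * r / (1 + r)
        q = s / (1 + r)
        return k2p_distance_scalar(p, q)

    upper = min((1 + r) / (2 * r + 1), (1 + r) / 2) - 1e-9
    s = brentq(lambda x: k_of(x) - divergence_target, 1e-12, upper)
    return s * r / (1 + r), s / (1 + r)


def k2p_distance_scalar(p: float, q: float) -> float:
    # thin scalar wrapper; the array version lives in quantification
    return float(k2p_distance(p, q))


def mutate_copy(
    consensus: str,
    divergence_target: float,
    ts_tv_ratio: float,
    seed: "int | np.random.Generator",
    indel_rate: float = 0.0,
) -> str:
    """One monomer copy mutated away from ``consensus``.

    Substitutions are drawn per site under a two-rate transition /
    transversion scheme calibrated so the expected K2P distance of the
    copy to the consensus equals ``divergence_target``. Indels are off by
    default (monomers are treated as fixed-length units); a small
    ``indel_rate`` inserts/deletes single bases at that per-site rate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "mutate")
    p_ts, p_tv = substitution_rates(divergence_target, ts_tv_ratio)
    codes = encode(consensus)
    u = rng.random(codes.size)
    out = codes.copy()
    ts_mask = u < p_ts
    tv_mask = (u >= p_ts) & (u < p_ts + p_tv)
    out[ts_mask] ^= 2  # A<->G, C<->T
    if tv_mask.any():
        flips = rng.choice(np.array([1, 3], dtype=np.uint8), size=int(tv_mask.sum()))
        out[tv_mask] ^= flips
    seq = decode(out)
    if indel_rate > 0:
        v = rng.random(len(seq))
        pieces = []
        for i, ch in enumerate(seq):
            if v[i] < indel_rate / 2:
                continue  # deletion
            pieces.append(ch)
            if indel_rate / 2 <= v[i] < indel_rate:
                pieces.append("ACGT"[rng.integers(4)])
        seq = "".join(pieces)
    return seq


def _random_background(length: int, at_fraction: float, rng: np.random.Generator) -> str:
    p = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    )
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def _family_consensus(spec: FamilySpec, seed: int) -> str:
    if spec.consensus is not None:
        return spec.consensus
    return make_consensus(spec.rul, spec.at_fraction, rng_for(seed, "cons", spec.family_id).integers(2**31 - 1))


def _mutated_array(
    consensus: str,
    n_copies: int,
    divergence: float,
    ts_tv_ratio: float,
    rng: np.random.Generator,
) -> str:
    """Head-to-tail tandem of independently mutated monomers."""
    p_ts, p_tv = substitution_rates(divergence, ts_tv_ratio)
    codes = np.tile(encode(consensus), n_copies)
    u = rng.random(codes.size)
    ts_mask = u < p_ts
    tv_mask = (u >= p_ts) & (u < p_ts + p_tv)
    codes[ts_mask] ^= 2
    if tv_mask.any():
        codes[tv_mask] ^= rng.choice(np.array([1, 3], dtype=np.uint8), size=int(tv_mask.sum()))
    return decode(codes)


def plant_genome(
    family_specs: Sequence[FamilySpec],
    background_length: int,
    sex: str,
    seed: int,
    background_at: float = 0.6,
    genome_id: Optional[str] = None,
) -> tuple[str, TruthTable]:
    """Random background with tandem satellite arrays spliced in.

    For each family, ``n_loci`` arrays are inserted at uniform random
    positions, each a perfect head-to-tail tandem of independently
    mutated monomers; array orientation is chosen uniformly per locus.
    The returned truth table records every locus (0-based half-open on
    the finished genome) and each family's exact genome proportion.
    """
    if sex not in ("female", "male"):
        raise SpecError(f"unknown sex {sex!r}")
    genome_id = genome_id or sex
    ids = [s.family_id for s in family_specs]
    if len(set(ids)) != len(ids):
        raise SpecError("duplicate family ids")

    arrays: list[tuple[str, str, int]] = []  # (family_id, sequence, n_monomers)
    for spec in family_specs:
        copies = spec.copies(sex)
        if copies == 0:
            continue
        consensus = _family_consensus(spec, seed)
        n_loci = min(spec.n_loci(sex), copies)
        per_locus = [copies // n_loci] * n_loci
        for i in range(copies % n_loci):
            per_locus[i] += 1
        rng = rng_for(seed, "plant", genome_id, spec.family_id)
        for n in per_locus:
            arr = _mutated_array(
                consensus, n, spec.divergence_target, spec.ts_tv_ratio, rng
            )
            if rng.random() < 0.5:
                arr = revcomp(arr)
            arrays.append((spec.family_id, arr, n))

    total_sat = sum(len(a[1]) for a in arrays)
    if total_sat >= background_length:
        raise SpecError(
            f"planted arrays ({total_sat} bp) exceed background ({background_length} bp)"
        )

    # background keyed by seed only: two sexes planted with one seed share
    # the same (autosomal) background and differ only in satellite content
    bg_rng = rng_for(seed, "background")
    background = _random_background(background_length, background_at, bg_rng)

    place_rng = rng_for(seed, "place", genome_id)
    offsets = np.sort(
        place_rng.choice(background_length + 1, size=len(arrays), replace=False)
    )
    order = place_rng.permutation(len(arrays))

    pieces = []
    loci_rows = []
    prev = 0
    shift = 0
    for off, idx in zip(offsets, order):
        family_id, arr, n_mono = arrays[idx]
        pieces.append(background[prev:off])
        start = off + shift
        pieces.append(arr)
        loci_rows.append((genome_id, start, start + len(arr), family_id, n_mono))
        shift += len(arr)
        prev = off
    pieces.append(background[prev:])
    genome = "".join(pieces)

    loci = pd.DataFrame(loci_rows, columns=LOCUS_COLUMNS)
    planted = loci.groupby("family_id")["end"].sum() - loci.groupby("family_id")["start"].sum()
    prop_rows = []
    for spec in family_specs:
        bp = int(planted.get(spec.family_id, 0))
        prop_rows.append((spec.family_id, genome_id, bp / len(genome)))
    proportions = pd.DataFrame(prop_rows, columns=PROPORTION_COLUMNS)
    truth = TruthTable(loci=loci, proportions=proportions)
    truth.validate()
    return genome, truth


def simulate_library(
    genome: str, library_spec: LibrarySpec, allow_large: bool = False
) -> list[Read]:
    """Uniform-coverage read simulation.

    Fragments are drawn uniformly over the genome, strands uniformly at
    random; per-base substitution errors are applied at ``error_rate``.
    Deterministic for a given ``library_spec.seed``; the read count is
    exactly ``n_reads`` (counting both mates in paired mode).
    """
    spec = library_spec
    if spec.n_reads * spec.read_length > MAX_LIBRARY_BP and not allow_large:
        raise SpecError(
            "library exceeds the desk-scale guard of "
            f"{MAX_LIBRARY_BP} bp; pass allow_large=True to override"
        )
    L = len(genome)
    if L < spec.read_length:
        raise SpecError("genome shorter than read length")
    rng = rng_for(spec.seed, "library", spec.library_id)
    reads: list[Read] = []
    if spec.paired:
        if L <= spec.insert_mean + 4 * spec.insert_sd:
            raise SpecError("genome too short for the insert distribution")
        n_pairs = spec.n_reads // 2
        inserts = np.clip(
            np.rint(rng.normal(spec.insert_mean, spec.insert_sd, n_pairs)).astype(int),
            spec.read_length,
            L,
        )
        starts = rng.integers(0, L - inserts + 1)
        for i in range(n_pairs):
            frag = genome[starts[i] : starts[i] + inserts[i]]
            r1, r2 = frag[: spec.read_length], revcomp(frag[-spec.read_length :])
            reads.append(Read(f"{spec.library_id}_p{i}/1", r1))
            reads.append(Read(f"{spec.library_id}_p{i}/2", r2))
    else:
        starts = rng.integers(0, L - spec.read_length + 1, spec.n_reads)
        minus = rng.random(spec.n_reads) < 0.5
        for i in range(spec.n_reads):
            seq = genome[starts[i] : starts[i] + spec.read_length]
            if minus[i]:
                seq = revcomp(seq)
            reads.append(Read(f"{spec.library_id}_r{i}", seq))
    if spec.error_rate > 0:
        reads = _apply_errors(reads, spec.error_rate, rng)
    return reads


def _apply_errors(
    reads: list[Read], error_rate: float, rng: np.random.Generator
) -> list[Read]:
    out: list[Read] = []
    block = 50_000
    for lo in range(0, len(reads), block):
        chunk = reads[lo : lo + block]
        mat = np.vstack([encode(r.sequence) for r in chunk])
        mask = rng.random(mat.shape) < error_rate
        n_err = int(mask.sum())
        if n_err:
            mat[mask] = (mat[mask] + rng.integers(1, 4, n_err).astype(np.uint8)) % 4
        for r, row in zip(chunk, mat):
            out.append(Read(r.id, decode(row)))
    return out


# ---------------------------------------------------------------------------
# Built-in two-sex scenario
# ---------------------------------------------------------------------------

# Per family: (rul, female genome proportion in %, female/male amplification
# factor (None = female-exclusive), K2P divergence target, A+T fraction).
# Abundant families are kept at low divergence and rare families at high
# divergence, the pattern real satellitomes show; totals come to ~5.1% of
# the female and ~4.5% of the male genome (F/M ~ 1.14).
_SCENARIO_TABLE = [
    (36, 0.484, 3.05, 0.05, 0.62),
    (26, 0.413, 3.05, 0.10, 0.66),
    (177, 0.338, 3.25, 0.08, 0.55),
    (36, 0.280, 1.02, 0.06, 0.60),
    (21, 0.260, 0.91, 0.04, 0.70),
    (44, 0.250, 0.96, 0.07, 0.52),
    (38, 0.240, 1.12, 0.09, 0.64),
    (48, 0.230, 0.91, 0.05, 0.48),
    (31, 0.220, 0.93, 0.12, 0.58),
    (46, 0.210, 1.07, 0.03, 0.60),
    (28, 0.200, 0.89, 0.08, 0.72),
    (45, 0.190, 0.96, 0.10, 0.44),
    (24, 0.180, 0.91, 0.06, 0.66),
    (34, 0.175, 0.94, 0.11, 0.56),
    (35, 0.170, 0.91, 0.05, 0.62),
    (22, 0.165, 1.02, 0.07, 0.58),
    (19, 0.160, 0.86, 0.09, 0.74),
    (27, 0.155, 0.91, 0.12, 0.50),
    (23, 0.150, 0.96, 0.06, 0.60),
    (33, 0.150, 0.91, 0.08, 0.64),
    (25, 0.150, 0.93, 0.10, 0.54),
    (42, 0.150, 0.89, 0.07, 0.68),
    (30, 0.150, 0.96, 0.09, 0.58),
    (41, 0.030, 0.81, 0.15, 0.46),
    (29, 0.020, 0.71, 0.20, 0.62),
    (245, 0.010, 0.81, 0.18, 0.38),
    (20, 0.005, 0.61, 0.25, 0.66),
    (15, 0.002, 0.71, 0.30, 0.80),
    (11, 0.001, 0.91, 0.28, 0.31),
    (39, 0.010, None, 0.10, 0.60),  # female-exclusive family
]

SCENARIO_BACKGROUND_LENGTH = 3_000_000
SCENARIO_READS_PER_SEX = 200_000
SCENARIO_READ_LENGTH = 100
SCENARIO_ERROR_RATE = 0.002


def two_sex_family_specs(background_length: int = SCENARIO_BACKGROUND_LENGTH) -> list[FamilySpec]:
    """Family table of the built-in scenario, copy counts resolved for a
    given background length."""
    f_total = sum(r[1] for r in _SCENARIO_TABLE) / 100
    m_total = sum(r[1] / 100 / r[2] for r in _SCENARIO_TABLE if r[2])
    g_female = background_length / (1 - f_total)
    g_male = background_length / (1 - m_total)
    specs = []
    for i, (rul, f_pct, amp, div, at) in enumerate(_SCENARIO_TABLE, start=1):
        copies_f = max(1, round(f_pct / 100 * g_female / rul))
        if amp is None:
            copies_m = 0
        else:
            copies_m = max(1, round(f_pct / 100 / amp * g_male / rul))
        big_f = copies_f * rul >= 5000
        specs.append(
            FamilySpec(
                family_id=f"fam{i:02d}",
                rul=rul,
                at_fraction=at,
                divergence_target=div,
                ts_tv_ratio=2.0,
                copies_female=copies_f,
                copies_male=copies_m,
                n_loci_female=3 if big_f else (2 if copies_f * rul >= 1000 else 1),
                n_loci_male=2 if copies_m * rul >= 5000 else 1,
            )
        )
    return specs


@dataclass
class ScenarioResult:
    """Everything the built-in scenario produced."""

    family_specs: list[FamilySpec]
    female_genome: str
    male_genome: str
    truth: TruthTable
    female_reads: list[Read]
    male_reads: list[Read]
    consensuses: dict[str, str]  # family_id -> planted consensus


def two_sex_scenario(
    seed: int,
    background_length: int = SCENARIO_BACKGROUND_LENGTH,
    n_reads: int = SCENARIO_READS_PER_SEX,
    read_length: int = SCENARIO_READ_LENGTH,
    error_rate: float = SCENARIO_ERROR_RATE,
) -> ScenarioResult:
    """Two-sex satellitome fixture with exact ground truth.

    Both sexes share the same genomic background (the autosomal
    complement); they differ only in planted satellite copy numbers.
    """
    specs = two_sex_family_specs(background_length)
    female_genome, truth_f = plant_genome(
        specs, background_length, "female", seed, genome_id="female"
    )
    male_genome, truth_m = plant_genome(
        specs, background_length, "male", seed, genome_id="male"
    )
    truth = TruthTable.concat([truth_f, truth_m])
    female_reads = simulate_library(
        female_genome,
        LibrarySpec(
            library_id="female",
            read_length=read_length,
            n_reads=n_reads,
            error_rate=error_rate,
            seed=int(rng_for(seed, "lib", "female").integers(2**31 - 1)),
        ),
    )
    male_reads = simulate_library(
        male_genome,
        LibrarySpec(
            library_id="male",
            read_length=read_length,
            n_reads=n_reads,
            error_rate=error_rate,
            seed=int(rng_for(seed, "lib", "male").integers(2**31 - 1)),
        ),
    )
    consensuses = {s.family_id: _family_consensus(s, seed) for s in specs}
    return ScenarioResult(
        family_specs=specs,
        female_genome=female_genome,
        male_genome=male_genome,
        truth=truth,
        female_reads=female_reads,
        male_reads=male_reads,
        consensuses=consensuses,
    )
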
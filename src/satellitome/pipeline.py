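"""End-to-end pipeline: simulate/load -> mine -> classify -> quantify
-> profile -> network -> report.

A :class:`RunConfig` (built directly or loaded from YAML) names the
input libraries with their sex labels and carries per-stage parameters;
:func:`run_pipeline` executes the chain and writes the full report set.
Identical config + seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from ._seq import Read
from .classification import (
    ConsensusRecord,
    SatFamily,
    group_satellites,
    name_families,
)
from .mining import run_mining_rounds
from .networks import (
    HaplotypeNetwork,
    align_monomers,
    build_mst,
    collapse_haplotypes,
    extract_monomers,
    subsample_monomers,
)
from .profiles import ProfileComparison, build_position_profile, compare_profiles
from .quantification import (
    AbundanceRecord,
    LibraryTotals,
    RepeatLandscape,
    assign_reads,
    build_landscape,
    family_abundance,
    library_size_bp,
    library_totals,
    sex_bias_table,
    subtract_landscapes,
)
from .synthetic_data import TruthTable, two_sex_scenario

__all__ = ["LibraryInput", "RunConfig", "PipelineResult", "run_pipeline"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class LibraryInput:
    library_id: str
    sex: str  # 'female' | 'male' | 'unknown'
    path: Optional[str] = None


@dataclass
class RunConfig:
    """Run configuration; field defaults mirror the per-stage defaults."""

    seed: Optional[int] = None
    outdir: str = "satellitome_out"
    prefix: str = "Mel"
    libraries: list[LibraryInput] = field(default_factory=list)
    simulate: Optional[dict] = None  # two_sex_scenario overrides
    # mining
    base_sample: int = 10_000
    max_rounds: int = 8
    cluster_k: int = 13
    min_shared_kmers: int = 3
    min_density: float = 0.2
    min_cluster_size: int = 5
    # classification
    variant_thr: float = 0.95
    family_thr: float = 0.80
    superfamily_thr: float = 0.60
    # quantification
    min_identity: float = 0.7
    # profiles
    profile_min_coverage: int = 20
    profile_delta: float = 0.30
    profile_top_n: int = 22
    # networks
    network_top_n: int = 2
    monomer_cap: int = 500

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        libs = [LibraryInput(**entry) for entry in raw.pop("libraries", [])]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(libraries=libs, **raw)

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory (mining and simulation are stochastic)")
        ids = [l.library_id for l in self.libraries]
        if len(set(ids)) != len(ids):
            raise ConfigError("library ids must be unique")
        if self.simulate is None:
            if not self.libraries:
                raise ConfigError("no libraries configured and simulate not set")
            for lib in self.libraries:
                if not lib.path:
                    raise ConfigError(f"{lib.library_id}: missing path")
                if not Path(lib.path).exists():
                    raise ConfigError(f"{lib.library_id}: path {lib.path} not found")

    def echo(self) -> dict:
        """Config as written to the run manifest; the output location is
        dropped so identical runs into different directories produce
        byte-identical artifact sets."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return d


@dataclass
class PipelineResult:
    library_ids: list[str]
    sex_of: dict[str, str]
    consensus_records: list[ConsensusRecord]
    named_families: list[SatFamily]
    abundances: dict[str, dict[str, AbundanceRecord]]  # lib -> family -> record
    sex_bias: pd.DataFrame
    totals: LibraryTotals
    landscapes: list[RepeatLandscape]
    subtractive_landscapes: list[RepeatLandscape]
    profile_comparisons: list[ProfileComparison]
    networks: dict[str, HaplotypeNetwork]
    truth: Optional[TruthTable]
    seed: int
    config_echo: dict
    log: list[str]


def _acquire_libraries(
    config: RunConfig,
) -> tuple[dict[str, list[Read]], dict[str, str], Optional[TruthTable], list[str]]:
    from .io import read_sequences, write_fastq

    log: list[str] = []
    if config.simulate is not None:
        params = dict(config.simulate)
        scenario = two_sex_scenario(config.seed, **params)
        reads = {"female": scenario.female_reads, "male": scenario.male_reads}
        sex_of = {"female": "female", "male": "male"}
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib, rs in reads.items():
            write_fastq(rs, outdir / f"reads_{lib}.fastq.gz")
        log.append(
            f"simulated scenario: {len(scenario.family_specs)} families, "
            f"{len(scenario.female_reads)} + {len(scenario.male_reads)} reads"
        )
        return reads, sex_of, scenario.truth, log
    reads = {}
    sex_of = {}
    for lib in config.libraries:
        reads[lib.library_id] = read_sequences(lib.path)
        sex_of[lib.library_id] = lib.sex
        log.append(f"loaded {lib.library_id}: {len(reads[lib.library_id])} reads")
    return reads, sex_of, None, log


def _mine_all(
    config: RunConfig, reads: dict[str, list[Read]], sex_of: dict[str, str], log: list[str]
) -> list[ConsensusRecord]:
    # female library first, mirroring abundance-first discovery
    order = sorted(reads, key=lambda lib: (sex_of.get(lib) != "female", lib))
    records: list[ConsensusRecord] = []
    for lib in order:
        found, rounds = run_mining_rounds(
            reads[lib],
            base_sample=config.base_sample,
            max_rounds=config.max_rounds,
            seed=config.seed,
            k=config.cluster_k,
            min_shared_kmers=config.min_shared_kmers,
            min_density=config.min_density,
            min_cluster_size=config.min_cluster_size,
            filter_identity=config.min_identity,
            priors=records,
        )
        renamed = [
            replace(rec, record_id=f"{lib}:{rec.record_id}") for rec in found
        ]
        records.extend(renamed)
        log.append(
            f"mined {lib}: {len(renamed)} new consensuses over {len(rounds)} rounds"
        )
    return records


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis chain and write the report set."""
    from .io import write_reports

    config.validate()
    seed = int(config.seed)
    reads, sex_of, truth, log = _acquire_libraries(config)
    library_ids = sorted(reads, key=lambda lib: (sex_of.get(lib) != "female", lib))

    records = _mine_all(config, reads, sex_of, log)
    families = group_satellites(
        records,
        variant_thr=config.variant_thr,
        family_thr=config.family_thr,
        superfamily_thr=config.superfamily_thr,
    )
    log.append(f"classified {len(records)} consensuses into {len(families)} families")

    rep_seqs = {f.family_id: f.representative.sequence for f in families}
    abundances: dict[str, dict[str, AbundanceRecord]] = {}
    hits_by_lib: dict[str, dict[str, list]] = {}
    lib_bp: dict[str, int] = {}
    for lib in library_ids:
        lib_bp[lib] = library_size_bp(reads[lib])
        if rep_seqs:
            grouped = assign_reads(reads[lib], rep_seqs, min_identity=config.min_identity)
        else:
            grouped = {}
        hits_by_lib[lib] = grouped
        abundances[lib] = {
            fid: family_abundance(grouped.get(fid, []), lib_bp[lib], fid, lib)
            for fid in rep_seqs
        }
        n_sat = sum(len(h) for h in grouped.values())
        sat_nt = sum(r.aligned_nt for r in abundances[lib].values())
        n_bad = sum(r.n_saturated for r in abundances[lib].values())
        log.append(
            f"quantified {lib}: {n_sat} satellite hits, {sat_nt} aligned nt, "
            f"{n_bad} saturated hits dropped from landscapes"
        )

    female_lib = next((l for l in library_ids if sex_of.get(l) == "female"), library_ids[0])
    male_lib = next((l for l in library_ids if sex_of.get(l) == "male"), None)

    female_ab = {fid: rec.abundance for fid, rec in abundances[female_lib].items()}
    named = name_families(families, female_ab, prefix=config.prefix)
    log.append(
        f"named {len(named)} families by decreasing {female_lib} abundance"
    )

    landscapes: list[RepeatLandscape] = []
    per_key: dict[tuple[str, str], RepeatLandscape] = {}
    for lib in library_ids:
        for fam in named:
            ls = build_landscape(
                hits_by_lib[lib].get(fam.family_id, []), lib_bp[lib], fam.family_id, lib
            )
            landscapes.append(ls)
            per_key[(fam.family_id, lib)] = ls
        all_hits = [h for hs in hits_by_lib[lib].values() for h in hs]
        landscapes.append(build_landscape(all_hits, lib_bp[lib], "ALL", lib))
        per_key[("ALL", lib)] = landscapes[-1]

    subtractive: list[RepeatLandscape] = []
    if male_lib is not None:
        for fam in named:
            subtractive.append(
                subtract_landscapes(
                    per_key[(fam.family_id, female_lib)], per_key[(fam.family_id, male_lib)]
                )
            )
        subtractive.append(
            subtract_landscapes(per_key[("ALL", female_lib)], per_key[("ALL", male_lib)])
        )

    if male_lib is not None:
        bias = sex_bias_table(
            list(abundances[female_lib].values()), list(abundances[male_lib].values())
        )
    else:
        bias = pd.DataFrame(
            columns=["family_id", "female_abundance", "male_abundance", "fm_ratio", "bias_class"]
        )
    totals = library_totals(
        {lib: list(abundances[lib].values()) for lib in library_ids},
        female=female_lib,
        male=male_lib if male_lib is not None else "male",
    )

    comparisons: list[ProfileComparison] = []
    if male_lib is not None and len(bias):
        ranked = bias.sort_values(
            ["fm_ratio", "family_id"], ascending=[False, True]
        )["family_id"].tolist()
        n = config.profile_top_n
        selected = list(dict.fromkeys(ranked[:n] + ranked[-n:]))
        for fid in selected:
            fam = next(f for f in named if f.family_id == fid)
            cons = fam.representative.sequence
            prof_f = build_position_profile(
                hits_by_lib[female_lib].get(fid, []), cons, fid, female_lib
            )
            prof_m = build_position_profile(
                hits_by_lib[male_lib].get(fid, []), cons, fid, male_lib
            )
            comparisons.append(
                compare_profiles(
                    prof_f,
                    prof_m,
                    min_coverage=config.profile_min_coverage,
                    delta=config.profile_delta,
                )
            )
        log.append(f"profiled {len(selected)} most sex-biased families")

    networks: dict[str, HaplotypeNetwork] = {}
    top_by_female = sorted(
        named, key=lambda f: -female_ab.get(f.family_id, 0.0)
    )[: config.network_top_n]
    for fam in top_by_female:
        cons = fam.representative.sequence
        labelled: list[tuple[str, str]] = []
        for lib in library_ids:
            monomers = extract_monomers(hits_by_lib[lib].get(fam.family_id, []), cons)
            monomers = subsample_monomers(
                monomers, cap=config.monomer_cap, seed=seed, label=f"{fam.family_id}:{lib}"
            )
            labelled.extend((row, lib) for row in align_monomers(monomers, cons))
        if not labelled:
            continue
        haps = collapse_haplotypes(labelled)
        networks[fam.family_id] = build_mst(haps)
        log.append(
            f"network {fam.name}: {len(haps)} haplotypes from {len(labelled)} monomers"
        )

    result = PipelineResult(
        library_ids=library_ids,
        sex_of=sex_of,
        consensus_records=records,
        named_families=named,
        abundances=abundances,
        sex_bias=bias,
        totals=totals,
        landscapes=landscapes,
        subtractive_landscapes=subtractive,
        profile_comparisons=comparisons,
        networks=networks,
        truth=truth,
        seed=seed,
        config_echo=config.echo(),
        log=log,
    )
    write_reports(result, config.outdir)
    return result
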
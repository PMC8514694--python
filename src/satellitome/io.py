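"""Standard-format I/O and report tables.

FASTA/FASTQ (plain or gzip) go through Biopython; all report tables are
TSV with '.' marking missing values (so absence stays distinguishable
from a true zero), interval outputs use 0-based half-open coordinates
(BED convention) and profile positions are 1-based (pileup convention).
Gzip output is written with a zeroed mtime so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from ._seq import Read
from .quantification import AbundanceRecord, RepeatLandscape, N_BINS

__all__ = [
    "ParseError",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "write_reports",
]

MISSING = "."
DEFAULT_QUALITY_CHAR = "F"  # Phred 37, offset 33


class ParseError(ValueError):
    pass


def _open_text(path: "str | Path", mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed header fields -> byte-identical reruns
            return gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
        return gzip.open(path, mode)
    return open(path, mode)


def _guess_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if not suffixes:
        raise ParseError(f"{path}: cannot guess sequence format from name")
    ext = suffixes[-1]
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    if ext in (".fq", ".fastq"):
        return "fastq"
    raise ParseError(f"{path}: unknown sequence format {ext!r}")


def read_sequences(path: "str | Path", format: Optional[str] = None) -> list[Read]:
    """Read FASTA/FASTQ records (gzip transparent) as :class:`Read`s.

    Malformed records raise :class:`ParseError` naming the file and the
    offending record index.
    """
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ParseError(f"unsupported format {fmt!r}")
    reads: list[Read] = []
    try:
        with _open_text(path) as fh:
            for i, rec in enumerate(SeqIO.parse(fh, fmt)):
                reads.append(Read(rec.id, str(rec.seq).upper()))
    except (ValueError, OSError) as exc:
        raise ParseError(
            f"{path}: malformed {fmt} near record {len(reads) + 1}: {exc}"
        ) from exc
    return reads


def write_fasta(records: Mapping[str, str], path: "str | Path") -> None:
    """Write an id -> sequence mapping as FASTA (60-column wrap)."""
    with _open_text(path, "wt") as fh:
        out = fh
        for name in records:
            seq = records[name]
            _write_text(out, f">{name}\n")
            for i in range(0, len(seq), 60):
                _write_text(out, seq[i : i + 60] + "\n")


def write_fastq(
    reads: Iterable[Read], path: "str | Path", quality_char: str = DEFAULT_QUALITY_CHAR
) -> None:
    """Write reads as FASTQ with constant quality (Phred+33)."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            _write_text(fh, f"@{r.id}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")


def _write_text(fh, text: str) -> None:
    if isinstance(fh, gzip.GzipFile):
        fh.write(text.encode())
    else:
        fh.write(text)


def _fmt(x, nd: int = 8) -> str:
    if x is None:
        return MISSING
    if isinstance(x, float):
        if x != x:  # NaN
            return MISSING
        if x == float("inf"):
            return "inf"
        return f"{x:.{nd}g}"
    return str(x)


def sha256_of(path: "str | Path") -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_reports(results: "PipelineResult", outdir: "str | Path") -> list[Path]:
    """Write the full TSV/FASTA report set plus a checksummed manifest.

    Files: families.tsv (name, RUL, A+T, per-library abundance and mean
    divergence, F/M ratio, bias class, plus one TOTAL row per library's
    abundance column), landscapes.tsv, subtractive_landscapes.tsv,
    signatures.tsv, network_nodes.tsv, network_edges.tsv,
    consensuses.fasta and run_manifest.json.
    """
    from .pipeline import PipelineResult  # local import to avoid a cycle

    assert isinstance(results, PipelineResult)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    libs = list(results.library_ids)
    fam_rows = []
    for fam in results.named_families:
        row = {
            "name": fam.name,
            "family_id": fam.family_id,
            "rul": fam.representative.rul,
            "at_fraction": _fmt(fam.representative.at_fraction, 4),
            "n_variants": fam.n_variants,
            "superfamily_id": fam.superfamily_id or MISSING,
        }
        for lib in libs:
            rec = results.abundances[lib].get(fam.family_id)
            row[f"abundance_{lib}"] = _fmt(rec.abundance if rec else 0.0)
            row[f"mean_divergence_{lib}"] = _fmt(rec.mean_divergence if rec else None, 4)
        bias = results.sex_bias.set_index("family_id") if len(results.sex_bias) else None
        if bias is not None and fam.family_id in bias.index:
            row["fm_ratio"] = _fmt(float(bias.loc[fam.family_id, "fm_ratio"]), 6)
            row["bias_class"] = bias.loc[fam.family_id, "bias_class"]
        else:
            row["fm_ratio"] = MISSING
            row["bias_class"] = MISSING
        fam_rows.append(row)
    total_row = {
        "name": "TOTAL",
        "family_id": MISSING,
        "rul": MISSING,
        "at_fraction": MISSING,
        "n_variants": MISSING,
        "superfamily_id": MISSING,
        "fm_ratio": MISSING,
        "bias_class": MISSING,
    }
    for lib in libs:
        total_row[f"abundance_{lib}"] = _fmt(results.totals.totals.get(lib, 0.0))
        total_row[f"mean_divergence_{lib}"] = MISSING
    fam_rows.append(total_row)
    fam_path = outdir / "families.tsv"
    pd.DataFrame(fam_rows).to_csv(fam_path, sep="\t", index=False)
    written.append(fam_path)

    def landscape_rows(landscapes: Sequence[RepeatLandscape]):
        for ls in landscapes:
            for b in range(N_BINS):
                yield {
                    "family_id": ls.family_id,
                    "library_id": ls.library_id,
                    "k2p_bin_low_pct": b,
                    "abundance": _fmt(float(ls.bins[b]), 10),
                }

    ls_path = outdir / "landscapes.tsv"
    pd.DataFrame(landscape_rows(results.landscapes)).to_csv(ls_path, sep="\t", index=False)
    written.append(ls_path)

    sub_path = outdir / "subtractive_landscapes.tsv"
    pd.DataFrame(landscape_rows(results.subtractive_landscapes)).to_csv(
        sub_path, sep="\t", index=False
    )
    written.append(sub_path)

    sig_rows = []
    for comp in results.profile_comparisons:
        for s in comp.signatures:
            sig_rows.append(
                {
                    "family_id": comp.family_id,
                    "position_1based": s.position,
                    "major_female": s.major_female,
                    "major_male": s.major_male,
                    "variant_fraction_female": _fmt(s.variant_fraction_female, 4),
                    "variant_fraction_male": _fmt(s.variant_fraction_male, 4),
                    "coverage_female": s.coverage_female,
                    "coverage_male": s.coverage_male,
                }
            )
        for lib, flag in comp.insufficient_coverage.items():
            if flag:
                sig_rows.append(
                    {
                        "family_id": comp.family_id,
                        "position_1based": MISSING,
                        "major_female": MISSING,
                        "major_male": MISSING,
                        "variant_fraction_female": MISSING,
                        "variant_fraction_male": MISSING,
                        "coverage_female": MISSING,
                        "coverage_male": f"insufficient coverage in {lib}",
                    }
                )
    sig_path = outdir / "signatures.tsv"
    pd.DataFrame(
        sig_rows,
        columns=[
            "family_id",
            "position_1based",
            "major_female",
            "major_male",
            "variant_fraction_female",
            "variant_fraction_male",
            "coverage_female",
            "coverage_male",
        ],
    ).to_csv(sig_path, sep="\t", index=False)
    written.append(sig_path)

    node_rows, edge_rows = [], []
    for fid, net in results.networks.items():
        for i, hap in enumerate(net.nodes):
            row = {"family_id": fid, "node": i, "sequence": hap.sequence, "total": hap.total}
            for lib in libs:
                row[f"count_{lib}"] = hap.counts.get(lib, 0)
            node_rows.append(row)
        for a, b, w in net.edges:
            edge_rows.append({"family_id": fid, "node_a": a, "node_b": b, "weight": w})
    nodes_path = outdir / "network_nodes.tsv"
    cols = ["family_id", "node", "sequence", "total"] + [f"count_{lib}" for lib in libs]
    pd.DataFrame(node_rows, columns=cols).to_csv(nodes_path, sep="\t", index=False)
    written.append(nodes_path)
    edges_path = outdir / "network_edges.tsv"
    pd.DataFrame(edge_rows, columns=["family_id", "node_a", "node_b", "weight"]).to_csv(
        edges_path, sep="\t", index=False
    )
    written.append(edges_path)

    cons_path = outdir / "consensuses.fasta"
    cons = {}
    for fam in results.named_families:
        cons[f"{fam.name} {fam.family_id}"] = fam.representative.sequence
    write_fasta(cons, cons_path)
    written.append(cons_path)

    if results.truth is not None:
        truth_path = outdir / "truth_loci.tsv"
        truth_path.write_text(results.truth.loci_tsv())
        written.append(truth_path)
        prop_path = outdir / "truth_proportions.tsv"
        prop_path.write_text(results.truth.proportions_tsv())
        written.append(prop_path)

    manifest = {
        "package": "satellitome",
        "config": results.config_echo,
        "seed": results.seed,
        "files": [
            {"path": p.name, "sha256": sha256_of(p)} for p in sorted(written)
        ],
        "log": results.log,
    }
    man_path = outdir / "run_manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(man_path)
    return written
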
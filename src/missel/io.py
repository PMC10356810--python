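"""File formats: mutation tables, transcript FASTA, spectra, residue sets,
∆∆G tables, catalogues, dN/dS tables, results.

All tabular formats are tab-separated with a header row; lines starting with
``#`` are provenance/comment lines and are skipped on read. Transcripts
travel as FASTA with ``key=value`` tags in the description encoding gene and
flanks, optionally cross-checked against an annotation table.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalogue import SnvCatalogue
from .errors import FormatError
from .spectrum import MutationRecord, Transcript, TrinucleotideSpectrum
from .stats import SelectionTestResult
from .structure import DdgTable, ResidueSet

__all__ = [
    "read_mutation_table",
    "write_mutation_table",
    "read_transcripts_fasta",
    "write_transcripts_fasta",
    "read_spectrum",
    "write_spectrum",
    "read_residue_sets",
    "write_residue_sets",
    "load_bundled_residue_sets",
    "read_dnds_table",
    "write_ddg_table",
    "read_ddg_table",
    "export_catalogue",
    "write_results",
    "provenance_header",
    "file_checksum",
]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return frame


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def provenance_header(seed: int | None = None,
                      inputs: Mapping[str, str | Path] | None = None,
                      extra: Mapping[str, str] | None = None) -> str:
    """Comment lines recording package version, seed and input checksums."""
    from . import __version__

    lines = [f"# missel {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for name, path in (inputs or {}).items():
        lines.append(f"# input {name}: {Path(path).name} sha256:{file_checksum(path)}")
    for key, value in (extra or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Mutations

def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """TSV with header gene, cds_pos, ref, alt, count (optional aa_change)."""
    frame = _read_tsv(path, ["gene", "cds_pos", "ref", "alt"])
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            records.append(
                MutationRecord(
                    gene_id=row.gene,
                    cds_position=int(row.cds_pos),
                    ref=row.ref,
                    alt=row.alt,
                    count=int(getattr(row, "count", 1) or 1)
                    if "count" in frame.columns else 1,
                    aa_change=getattr(row, "aa_change", None)
                    if "aa_change" in frame.columns else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{Path(path).name}: {exc}", line=i) from exc
    return records


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path,
                         header: str | None = None) -> None:
    frame = pd.DataFrame(
        [
            (m.gene_id, m.cds_position, m.ref, m.alt, m.count, m.aa_change or "")
            for m in records
        ],
        columns=["gene", "cds_pos", "ref", "alt", "count", "aa_change"],
    )
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)


# --------------------------------------------------------------------------
# Transcripts

def read_transcripts_fasta(
    fasta_path: str | Path, annotation_path: str | Path | None = None
) -> list[Transcript]:
    """FASTA records ``>transcript_id gene=G upstream=X downstream=Y``.

    The record sequence is the spliced CDS. If an annotation table
    (gene_id, transcript_id, cds_length) is given, lengths and gene
    assignments are cross-checked.
    """
    transcripts = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        tags = dict(
            part.split("=", 1) for part in record.description.split()[1:]
            if "=" in part
        )
        for key in ("gene", "upstream", "downstream"):
            if key not in tags:
                raise FormatError(
                    f"{fasta_path}: record {record.id} missing tag {key}="
                )
        transcripts.append(
            Transcript(
                gene_id=tags["gene"],
                transcript_id=record.id,
                cds_sequence=str(record.seq).upper(),
                upstream_flank=tags["upstream"].upper(),
                downstream_flank=tags["downstream"].upper(),
            )
        )
    if annotation_path is not None:
        ann = _read_tsv(annotation_path, ["gene_id", "transcript_id", "cds_length"])
        lengths = {r.transcript_id: int(r.cds_length) for r in ann.itertuples()}
        genes = {r.transcript_id: r.gene_id for r in ann.itertuples()}
        for t in transcripts:
            if t.transcript_id in lengths and lengths[t.transcript_id] != t.length:
                raise FormatError(
                    f"{t.transcript_id}: annotation length "
                    f"{lengths[t.transcript_id]} != sequence length {t.length}"
                )
            if t.transcript_id in genes and genes[t.transcript_id] != t.gene_id:
                raise FormatError(
                    f"{t.transcript_id}: annotation gene {genes[t.transcript_id]} "
                    f"!= FASTA gene {t.gene_id}"
                )
    return transcripts


def write_transcripts_fasta(transcripts: Iterable[Transcript],
                            fasta_path: str | Path,
                            annotation_path: str | Path | None = None) -> None:
    records = [
        SeqRecord(
            Seq(t.cds_sequence),
            id=t.transcript_id,
            description=(
                f"gene={t.gene_id} upstream={t.upstream_flank} "
                f"downstream={t.downstream_flank}"
            ),
        )
        for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if annotation_path is not None:
        pd.DataFrame(
            [(t.gene_id, t.transcript_id, t.length) for t in transcripts],
            columns=["gene_id", "transcript_id", "cds_length"],
        ).to_csv(annotation_path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Spectrum

def write_spectrum(spectrum: TrinucleotideSpectrum, path: str | Path,
                   header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        spectrum.to_frame().to_csv(fh, sep="\t", index=False)


def read_spectrum(path: str | Path) -> TrinucleotideSpectrum:
    frame = _read_tsv(path, ["ctx5", "ref", "ctx3", "alt",
                             "context_count", "mutation_count", "rate"])
    for col in ("context_count", "mutation_count", "rate"):
        frame[col] = frame[col].astype(float)
    return TrinucleotideSpectrum.from_frame(frame)


# --------------------------------------------------------------------------
# Residue sets

def read_residue_sets(path: str | Path) -> dict[str, ResidueSet]:
    """YAML mapping name -> {residues: [...], provenance: str}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: expected a mapping of residue sets")
    sets = {}
    for name, spec in raw.items():
        if not isinstance(spec, dict) or "residues" not in spec:
            raise FormatError(f"{path}: set {name!r} lacks a residues list")
        sets[name] = ResidueSet(
            name=name,
            residues=frozenset(int(r) for r in spec["residues"]),
            provenance=str(spec.get("provenance", "")),
        )
    return sets


def write_residue_sets(sets: Mapping[str, ResidueSet], path: str | Path) -> None:
    raw = {
        name: {"provenance": rs.provenance, "residues": sorted(rs.residues)}
        for name, rs in sets.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def load_bundled_residue_sets() -> dict[str, ResidueSet]:
    """The NOTCH1/NOTCH2 EGF11-12 interface and calcium-binding sets."""
    from importlib.resources import files

    text = files("missel.data").joinpath("residue_sets.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: ResidueSet(
            name=name,
            residues=frozenset(int(r) for r in spec["residues"]),
            provenance=str(spec.get("provenance", "")),
        )
        for name, spec in raw.items()
    }


# --------------------------------------------------------------------------
# dN/dS and ∆∆G tables

def read_dnds_table(path: str | Path) -> dict[str, float]:
    """TSV with header gene, dnds (truncating dN/dS per gene)."""
    frame = _read_tsv(path, ["gene", "dnds"])
    out = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            out[row.gene] = float(row.dnds)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{Path(path).name}: bad dnds {row.dnds!r}",
                              line=i) from exc
    return out


def write_ddg_table(table: DdgTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_ddg_table(path: str | Path, source_structure: str = "") -> DdgTable:
    frame = _read_tsv(path, ["chain", "residue", "aa_ref", "aa_alt", "ddg"])
    values = {
        (r.chain, int(r.residue), r.aa_ref, r.aa_alt): float(r.ddg)
        for r in frame.itertuples(index=False)
    }
    return DdgTable(values=values, source_structure=source_structure)


# --------------------------------------------------------------------------
# Catalogue and results

def export_catalogue(catalogue: SnvCatalogue, path: str | Path,
                     header: str | None = None) -> None:
    cols = ["cds_pos", "ref", "alt", "residue", "aa_ref", "aa_alt",
            "consequence", "prob"] + catalogue.feature_columns()
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        catalogue.entries[cols].to_csv(fh, sep="\t", index=False)


def import_catalogue(path: str | Path, region_id: str = "region",
                     class_filter: Iterable[str] = ("missense",)) -> SnvCatalogue:
    frame = _read_tsv(path, ["cds_pos", "ref", "alt", "residue", "aa_ref",
                             "aa_alt", "consequence", "prob"])
    frame["cds_pos"] = frame["cds_pos"].astype(int)
    frame["residue"] = frame["residue"].astype(int)
    frame["prob"] = frame["prob"].astype(float)
    core = {"cds_pos", "ref", "alt", "residue", "aa_ref", "aa_alt",
            "consequence", "prob"}
    for col in frame.columns:
        if col in core:
            continue
        lowered = frame[col].str.lower()
        if set(lowered.dropna().unique()) <= {"true", "false"}:
            frame[col] = lowered == "true"
        else:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    # contexts are not exported; fill placeholders so the schema matches
    if "ctx5" not in frame.columns:
        frame["ctx5"] = "N"
        frame["ctx3"] = "N"
    return SnvCatalogue(region_id=region_id, entries=frame,
                        class_filter=frozenset(class_filter))


def write_results(results: Sequence[SelectionTestResult], tsv_path: str | Path,
                  json_path: str | Path | None = None,
                  header: str | None = None) -> None:
    """TSV + JSON mirror of selection-test results."""
    rows = [r.to_dict() for r in results]
    frame = pd.DataFrame(rows)
    with open(tsv_path, "w") as fh:
        if header:
            fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
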
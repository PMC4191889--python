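"""Readers and writers for the pipeline's text formats.

FASTA (reference/decoy databases), the PSM TSV schema, validated-PSM output,
per-locus quantification tables, census tables, and a flat key=value config.
All tables are tab-separated; scores are written with 4 decimals and NSAF
with 6, so a write-read cycle is lossless after the first write.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .census import CensusTable
from .records import (
    AMINO_ACIDS,
    DECOY_PREFIX,
    Mod,
    ProteinRecord,
    PSMRecord,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_psm_table",
    "write_psm_table",
    "read_validated_psms",
    "write_validation_results",
    "write_quant_table",
    "write_census",
    "read_census",
    "read_config",
    "write_config",
]

PathLike = Union[str, Path]

PSM_COLUMNS = (
    "spectrum_id", "sample", "peptide", "protein_ids", "charge_class",
    "tryptic_status", "xcorr", "deltacn", "delta_mass_ppm", "mods", "truth",
)


def _parse_header(description: str) -> dict:
    fields = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, value = token.split("=", 1)
            fields[key] = value
    return fields


def read_fasta(path) -> list[ProteinRecord]:
    """Parse a FASTA file into protein records.

    The id is the first whitespace-delimited header token; a ``Reverse_``
    prefix marks decoys. Optional ``family=``/``species=`` header tokens are
    honoured. Malformed records (empty sequence, illegal characters) raise
    with the offending line number. Leading ';' comment lines are ignored.
    """
    path = Path(path) if not hasattr(path, "open") else path
    with open(path) if isinstance(path, Path) else path.open() as fh:
        lines = fh.read().splitlines()
    # track line numbers for error messages
    seq_start_line: dict[str, int] = {}
    cleaned = []
    current_id = None
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(";"):
            continue
        if line.startswith(">"):
            current_id = line[1:].split()[0] if len(line) > 1 else ""
            if not current_id:
                raise ValueError(f"line {lineno}: empty FASTA header")
            seq_start_line[current_id] = lineno
        cleaned.append(line)
    records = []
    for rec in SeqIO.parse(_io.StringIO("\n".join(cleaned) + "\n"), "fasta"):
        lineno = seq_start_line.get(rec.id, 0)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"line {lineno}: record {rec.id!r} has empty sequence")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"line {lineno}: record {rec.id!r} contains illegal "
                f"character(s) {sorted(bad)}"
            )
        meta = _parse_header(rec.description)
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                sequence=seq,
                species=meta.get("species", "synthetic"),
                family=meta.get("family", "other"),
                is_decoy=rec.id.startswith(DECOY_PREFIX),
            )
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f">{rec.protein_id} family={rec.family} species={rec.species}\n"
            )
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def _format_mods(mods: Sequence[Mod]) -> str:
    return ";".join(f"{m.offset}:{m.delta:.6f}" for m in mods)


def _parse_mods(text: str, row: int) -> tuple[Mod, ...]:
    if not text:
        return ()
    mods = []
    for part in text.split(";"):
        try:
            offset, delta = part.split(":")
            mods.append(Mod(offset=int(offset), delta=float(delta)))
        except ValueError as exc:
            raise ValueError(f"row {row}: bad mod syntax {part!r}") from exc
    return tuple(mods)


def _format_truth(truth: Optional[bool]) -> str:
    return "" if truth is None else ("true" if truth else "false")


def _parse_truth(text: str, row: int) -> Optional[bool]:
    if text == "":
        return None
    if text in ("true", "false"):
        return text == "true"
    raise ValueError(f"row {row}: bad truth value {text!r}")


def write_psm_table(psms: Iterable[PSMRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PSM_COLUMNS) + "\n")
        for p in psms:
            fh.write(
                "\t".join(
                    (
                        p.spectrum_id,
                        p.sample,
                        p.peptide,
                        ",".join(p.protein_ids),
                        p.charge_class,
                        p.tryptic_status,
                        f"{p.xcorr:.4f}",
                        f"{p.deltacn:.4f}",
                        f"{p.delta_mass_ppm:.4f}",
                        _format_mods(p.mods),
                        _format_truth(p.truth),
                    )
                )
                + "\n"
            )


def read_psm_table(path: PathLike) -> list[PSMRecord]:
    """Parse the PSM TSV schema; errors name the offending row."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PSM_COLUMNS:
            unknown = set(header) - set(PSM_COLUMNS)
            missing = set(PSM_COLUMNS) - set(header)
            raise ValueError(
                f"PSM table header mismatch: unknown={sorted(unknown)} "
                f"missing={sorted(missing)}"
            )
        psms = []
        for rownum, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(PSM_COLUMNS):
                raise ValueError(
                    f"row {rownum}: expected {len(PSM_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(PSM_COLUMNS, fields))
            try:
                psm = PSMRecord(
                    spectrum_id=row["spectrum_id"],
                    sample=row["sample"],
                    peptide=row["peptide"],
                    protein_ids=tuple(
                        pid for pid in row["protein_ids"].split(",") if pid
                    ),
                    charge_class=row["charge_class"],
                    tryptic_status=row["tryptic_status"],
                    xcorr=float(row["xcorr"]),
                    deltacn=float(row["deltacn"]),
                    delta_mass_ppm=float(row["delta_mass_ppm"]),
                    mods=_parse_mods(row["mods"], rownum),
                    truth=_parse_truth(row["truth"], rownum),
                )
            except ValueError as exc:
                raise ValueError(f"row {rownum}: {exc}") from exc
            psms.append(psm)
    return psms


def write_validation_results(results, path: PathLike) -> None:
    """Validated-PSM table: PSM columns plus probability, passed, fail_reason."""
    with open(path, "w") as fh:
        fh.write(
            "\t".join(PSM_COLUMNS + ("probability", "passed", "fail_reason"))
            + "\n"
        )
        for r in results:
            p = r.psm
            fh.write(
                "\t".join(
                    (
                        p.spectrum_id, p.sample, p.peptide,
                        ",".join(p.protein_ids), p.charge_class,
                        p.tryptic_status, f"{p.xcorr:.4f}", f"{p.deltacn:.4f}",
                        f"{p.delta_mass_ppm:.4f}", _format_mods(p.mods),
                        _format_truth(p.truth), f"{r.probability:.4f}",
                        "true" if r.passed else "false", r.fail_reason,
                    )
                )
                + "\n"
            )


def read_validated_psms(
    path: PathLike, passing_only: bool = True
) -> list[PSMRecord]:
    """Read a validated-PSM table back into records.

    With ``passing_only`` (the default) only rows with passed=true are
    returned; the probability/passed/fail_reason columns are dropped.
    """
    import csv

    psms = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rownum, row in enumerate(reader, start=2):
            if passing_only and row["passed"] != "true":
                continue
            psms.append(
                PSMRecord(
                    spectrum_id=row["spectrum_id"],
                    sample=row["sample"],
                    peptide=row["peptide"],
                    protein_ids=tuple(
                        pid for pid in row["protein_ids"].split(",") if pid
                    ),
                    charge_class=row["charge_class"],
                    tryptic_status=row["tryptic_status"],
                    xcorr=float(row["xcorr"]),
                    deltacn=float(row["deltacn"]),
                    delta_mass_ppm=float(row["delta_mass_ppm"]),
                    mods=_parse_mods(row["mods"], rownum),
                    truth=_parse_truth(row["truth"], rownum),
                )
            )
    return psms


def write_quant_table(frame: pd.DataFrame, path: PathLike) -> None:
    out = frame.copy()
    out["spectral_count"] = out["spectral_count"].map(lambda v: f"{v:.4f}")
    out["coverage"] = out["coverage"].map(lambda v: f"{v:.4f}")
    out["nsaf"] = out["nsaf"].map(lambda v: f"{v:.6f}")
    out["empai"] = out["empai"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def write_census(census: CensusTable, path: PathLike,
                 flagged_path: Optional[PathLike] = None) -> None:
    census.to_frame().to_csv(path, sep="\t", index=False)
    if flagged_path is not None:
        flagged = pd.DataFrame(
            census.flagged_excluded,
            columns=["locus", "site", "ptm_or_reason", "sample", "count"],
        )
        flagged.to_csv(flagged_path, sep="\t", index=False)


def read_census(path: PathLike) -> CensusTable:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    frame["occurrences"] = frame["occurrences"].astype(int)
    return CensusTable.from_frame(frame)


def read_config(path: PathLike) -> dict[str, str]:
    """Flat key=value config; '#' starts a comment, blank lines ignored."""
    config: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key=value")
            key, value = line.split("=", 1)
            config[key.strip()] = value.strip()
    return config


def write_config(config: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        for key, value in config.items():
            fh.write(f"{key}={value}\n")
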
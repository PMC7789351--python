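"""Readers and writers for the external formats the pipeline touches.

Formats: BED3/BED6 for peaks and fragments, FASTA for genome sequence,
JASPAR-style text for PWMs, tab-separated tables (with header) for gene
models, expression flags and all results, and a flat YAML file for the run
configuration.  All coordinates become 0-based half-open at this boundary.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Type, TypeVar

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CELL_TYPES,
    AnalysisConfig,
    ExpressionTable,
    GeneModel,
    Peak,
    PeakSet,
    PWM,
    pwm_from_counts,
)


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# BED

_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path, cell_type: str | None = None) -> PeakSet:
    """Read a BED3/BED6 file into a sorted :class:`PeakSet`.

    Missing names are auto-generated as "<chrom>:<start>-<end>"; missing
    scores default to 0.  track/browser/comment lines are skipped.
    """
    path = Path(path)
    label = cell_type if cell_type is not None else path.stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else ""
            score = 0.0
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                peaks.append(Peak(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(label, peaks)


def write_bed(peakset: PeakSet | Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED6 (score formatted with %g)."""
    with open(path, "w") as fh:
        for p in peakset:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t{p.strand}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: Mapping[str, object], path: str | Path) -> None:
    """Write {name: sequence} to FASTA; accepts str/bytes/bytearray values."""
    records = []
    for name, seq in genome.items():
        if isinstance(seq, (bytes, bytearray)):
            seq = seq.decode("ascii")
        records.append(SeqRecord(Seq(str(seq)), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene models

_GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tts", "exons"]


def _format_exons(exons: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in exons) or "."


def _parse_exons(text: str) -> tuple[tuple[int, int], ...]:
    if text in (".", "", "nan"):
        return ()
    out = []
    for token in text.split(","):
        s, _, e = token.partition("-")
        out.append((int(s), int(e)))
    return tuple(out)


def read_gene_table(path: str | Path, one_based: bool = False) -> list[GeneModel]:
    """Read a tab-separated gene-model table.

    Columns: gene_id, chrom, strand, tss, tts, exons ("start-end,..." or ".").
    With one_based=True (tables exported from genome browsers) positions are
    converted to the internal 0-based convention at this boundary.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing gene-table columns {sorted(missing)}")
    shift = 1 if one_based else 0
    genes = []
    for _, row in df.iterrows():
        exons = tuple(
            (s - shift, e - shift) for s, e in _parse_exons(str(row["exons"]))
        )
        genes.append(
            GeneModel(
                gene_id=row["gene_id"],
                chrom=row["chrom"],
                strand=row["strand"],
                tss=int(row["tss"]) - shift,
                tts=int(row["tts"]) - shift,
                exons=exons,
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "tts": g.tts,
            "exons": _format_exons(g.exons),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression table


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a TSV with a gene_id column and one 0/1 column per cell type."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionTable(df.astype(int).astype(bool))


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    out = table.frame.astype(int)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# JASPAR-style PWMs

_BASE_ORDER = "ACGT"


def read_pwm_jaspar(path: str | Path, pseudocount: float = 1.0) -> list[PWM]:
    """Read JASPAR-style PWM records.

    Each record is a ">ID [NAME]" header followed by four rows labelled
    A/C/G/T (bracketed or bare numbers) of equal length.  Counts get a
    per-cell pseudocount before column normalization, so every column sums
    to 1 and no probability is exactly zero.
    """
    path = Path(path)
    pwms: list[PWM] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def flush(lineno: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != set(_BASE_ORDER):
            raise ParseError(f"{path}:{lineno}: record {header} missing base rows")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ParseError(f"{path}:{lineno}: record {header} has unequal row lengths")
        counts = np.array([rows[b] for b in _BASE_ORDER])
        if (counts < 0).any():
            raise ParseError(f"{path}:{lineno}: negative counts in {header}")
        pwms.append(pwm_from_counts(header, counts, pseudocount=pseudocount))
        header, rows = None, {}

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].split()[0]
                continue
            token = line.replace("[", " ").replace("]", " ").split()
            if not token:
                continue
            base = token[0].upper()
            if base not in _BASE_ORDER:
                raise ParseError(f"{path}:{lineno}: expected a base row, got {base!r}")
            try:
                rows[base] = [float(x) for x in token[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric count") from exc
    flush(lineno + 1)
    return pwms


def write_pwm_jaspar(pwms: Iterable[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs in JASPAR text form (probabilities scaled to pseudo-counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for i, base in enumerate(_BASE_ORDER):
                vals = " ".join(f"{v * scale:.4f}" for v in pwm.matrix[i])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Run configuration


def read_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "hist_window" in raw:
        raw["hist_window"] = tuple(raw["hist_window"])
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**raw)


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    data["hist_window"] = list(data["hist_window"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Generic results tables

T = TypeVar("T")

_JSON_TYPES = (list, tuple, dict)


def _encode_cell(value):
    if isinstance(value, _JSON_TYPES):
        return json.dumps(value)
    if isinstance(value, np.generic):
        return value.item()
    return value


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Flatten a homogeneous list of dataclass records into a DataFrame.

    Compound fields (lists/tuples/dicts) are JSON-encoded so the table
    round-trips losslessly through :func:`read_results_table`.
    """
    if not records:
        raise ValueError("records_to_frame needs the record type; use write_results_table")
    rows = [
        {k: _encode_cell(v) for k, v in dataclasses.asdict(r).items()}
        for r in records
    ]
    return pd.DataFrame(rows)


def write_results_table(
    records: Sequence, path: str | Path, record_type: Type | None = None
) -> None:
    """Write dataclass records as a header-ed TSV (header-only if empty)."""
    if records:
        frame = records_to_frame(records)
    else:
        if record_type is None:
            raise ValueError("empty records require record_type for the header")
        frame = pd.DataFrame(columns=[f.name for f in dataclasses.fields(record_type)])
    frame.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path, record_type: Type[T]) -> list[T]:
    """Read a TSV written by :func:`write_results_table` back into records."""
    frame = pd.read_csv(path, sep="\t")
    fields = {f.name: f for f in dataclasses.fields(record_type)}
    out: list[T] = []
    for _, row in frame.iterrows():
        kwargs = {}
        for name in fields:
            value = row[name]
            if isinstance(value, str) and value[:1] in ("[", "{"):
                value = json.loads(value)
                if isinstance(value, list):
                    value = _maybe_tupleize(value, fields[name].type)
            elif isinstance(value, float) and np.isnan(value):
                value = None
            kwargs[name] = value
        out.append(record_type(**kwargs))
    return out


def _maybe_tupleize(value: list, type_hint) -> list | tuple:
    hint = str(type_hint)
    if "tuple" in hint or "Tuple" in hint:
        return tuple(
            tuple(v) if isinstance(v, list) else v for v in value
        )
    return value


__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_expression_table",
    "write_expression_table",
    "read_pwm_jaspar",
    "write_pwm_jaspar",
    "read_config",
    "write_config",
    "write_results_table",
    "read_results_table",
    "records_to_frame",
    "CELL_TYPES",
]
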
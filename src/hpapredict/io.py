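"""Reading and writing the external file formats.

Marker matrices and trait tables travel as TSV; sRNA genome mappings as BED
(0-based half-open); annotation as GFF3 (1-based closed on disk, converted
to 0-based half-open in memory); run metadata as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationTrack,
    DataType,
    FormatError,
    MappingRecord,
    MarkerMatrix,
    MatingDesign,
    TraitTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_marker_matrix",
    "write_marker_matrix",
    "read_trait_table",
    "write_trait_table",
    "read_design",
    "write_design",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "write_json",
    "read_json",
]


def read_marker_matrix(path: str | Path, data_type: DataType | str) -> MarkerMatrix:
    """Read a lines x markers TSV (header row = marker ids, first column = line ids)."""
    data_type = DataType.coerce(data_type)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate marker identifiers")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = None
    df.columns.name = None
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate line identifiers")
    if df.isna().to_numpy().any() and data_type is not DataType.SNP:
        raise FormatError(f"{path}: non-rectangular table (missing cells)")
    if data_type is not DataType.SNP:
        try:
            df = df.astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    matrix = MarkerMatrix(data_type, df)
    logger.info(
        "read %s marker matrix %s: %d lines x %d markers",
        data_type.value, path, matrix.n_lines, matrix.n_markers,
    )
    return matrix


def write_marker_matrix(matrix: MarkerMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="line")


def read_design(path: str | Path) -> MatingDesign:
    """Read a mating design TSV with columns flint_parent, dent_parent."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("flint_parent", "dent_parent"), path)
    flint = tuple(dict.fromkeys(df["flint_parent"]))
    dent = tuple(dict.fromkeys(df["dent_parent"]))
    hybrids = tuple(zip(df["flint_parent"], df["dent_parent"]))
    return MatingDesign(flint, dent, hybrids)


def write_design(design: MatingDesign, path: str | Path) -> None:
    pd.DataFrame(design.hybrids, columns=["flint_parent", "dent_parent"]).to_csv(
        path, sep="\t", index=False
    )


def read_trait_table(
    path: str | Path, design: MatingDesign, trait_name: str = "GY"
) -> TraitTable:
    """Read hybrid trait values; every referenced parent must exist in the design."""
    df = pd.read_csv(path, sep="\t", dtype={"flint_parent": str, "dent_parent": str})
    _require_columns(df, ("flint_parent", "dent_parent", "value"), path)
    flint, dent = set(design.flint_lines), set(design.dent_lines)
    for col, allowed, group in (
        ("flint_parent", flint, "Flint"),
        ("dent_parent", dent, "Dent"),
    ):
        unknown = set(df[col]) - allowed
        if unknown:
            raise ValidationError(
                f"{path}: {sorted(unknown)} not {group} lines of the design"
            )
    pairs = list(zip(df["flint_parent"], df["dent_parent"]))
    if len(set(pairs)) != len(pairs):
        raise ValidationError(f"{path}: hybrid listed more than once")
    known = set(design.hybrids)
    for pair in pairs:
        if pair not in known:
            raise ValidationError(f"{path}: hybrid {pair} not in the mating design")
    idx = pd.MultiIndex.from_tuples(pairs, names=["flint", "dent"])
    table = TraitTable(trait_name, pd.Series(df["value"].to_numpy(float), index=idx))
    logger.info("read trait table %s: %d hybrids", path, len(table))
    return table


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    df = table.values.rename("value").reset_index()
    df.columns = ["flint_parent", "dent_parent", "value"]
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[MappingRecord]:
    """Read sRNA mapping positions from BED (>=4 columns; 0-based half-open)."""
    records: list[MappingRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs >=4 columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                record = MappingRecord(name, chrom, int(start), int(end), strand)
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(record)
    logger.info("read %d BED records from %s", len(records), path)
    return records


def write_bed(records: Iterable[MappingRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.srna_id}\t0\t{r.strand}\n")


#: GFF3 feature types assigned to each annotation category
_GFF_CATEGORY_TYPES = {
    "gene": {"gene"},
    "repeat": {"repeat_region", "transposable_element", "repeat"},
}


def read_gff3(path: str | Path) -> dict[str, AnnotationTrack]:
    """Read gene and repeat annotation from GFF3.

    GFF3 stores 1-based closed coordinates; they are converted to the
    internal 0-based half-open convention (start-1, end).
    """
    intervals: dict[str, list[tuple[str, int, int]]] = {"gene": [], "repeat": []}
    n_converted = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: GFF3 needs >=8 columns")
            chrom, _source, ftype, start1, end1 = fields[:5]
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty interval after conversion"
                )
            n_converted += 1
            for category, types in _GFF_CATEGORY_TYPES.items():
                if ftype in types:
                    intervals[category].append((chrom, start, end))
    logger.info(
        "read %s: converted %d GFF3 features to 0-based half-open", path, n_converted
    )
    return {cat: AnnotationTrack(cat, ivs) for cat, ivs in intervals.items()}


def write_gff3(tracks: dict[str, AnnotationTrack], path: str | Path) -> None:
    type_for = {"gene": "gene", "repeat": "repeat_region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cat, track in tracks.items():
            for i, (chrom, start, end) in enumerate(track.intervals):
                fh.write(
                    f"{chrom}\thpapredict\t{type_for[cat]}\t{start + 1}\t{end}"
                    f"\t.\t.\t.\tID={cat}{i}\n"
                )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
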
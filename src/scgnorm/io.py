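"""Readers and writers for the tab-delimited formats used throughout.

All formats are plain UTF-8 TSV (Unix or Windows newlines). Abundance tables
are KO-by-sample matrices with KO ids in the first column and sample ids in
the header row; an optional ``#stage=`` sidecar comment line records the
processing stage. Readers validate and reject malformed input rather than
silently coercing it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AbundanceTable,
    GenomeContentMatrix,
    MarkerRole,
    MarkerSet,
    OTUProfileSet,
    PathwayMap,
    Stage,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_marker_set",
    "write_marker_set",
    "read_genome_content",
    "write_genome_content",
    "read_series",
    "write_series",
    "read_pathway_map",
    "write_pathway_map",
    "read_property_table",
    "write_property_table",
    "read_otu_profiles",
    "write_otu_profiles",
]

_STAGE_PREFIX = "#stage="


def _read_matrix(path, empty_as_zero: bool, what: str) -> tuple[pd.DataFrame, Stage | None]:
    """Parse a TSV matrix with row-id first column; returns (df, sidecar stage)."""
    path = Path(path)
    stage: Stage | None = None
    lines: list[str] = []
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for line in fh:
            if line.startswith(_STAGE_PREFIX):
                stage = Stage(line[len(_STAGE_PREFIX):].strip())
                continue
            if line.startswith("#"):
                continue
            lines.append(line)
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\r\n").split("\t")
    if len(header) < 1 or header[1:] and any(c == "" for c in header[1:]):
        raise ValueError(f"{path}: malformed header (empty sample id)")
    sample_ids = header[1:]
    row_ids: list[str] = []
    rows: list[list[float]] = []
    n_empty = 0
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\r\n").split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise ValueError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, got {len(fields)}"
            )
        rid = fields[0]
        if rid == "":
            raise ValueError(f"{path}:{lineno}: empty row identifier")
        vals = []
        for col, cell in enumerate(fields[1:]):
            if cell == "":
                if empty_as_zero:
                    n_empty += 1
                    vals.append(0.0)
                    continue
                raise ValueError(
                    f"{path}:{lineno}: empty cell in column {sample_ids[col]!r} "
                    "(pass empty_as_zero=True to treat as 0)"
                )
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} "
                    f"in column {sample_ids[col]!r}"
                ) from None
        row_ids.append(rid)
        rows.append(vals)
    if n_empty:
        logger.warning("%s: treated %d empty cells as zeros", path, n_empty)
    index = pd.Index(row_ids, name="id")
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"{path}: duplicate {what} id {dup!r}")
    if pd.Index(sample_ids).has_duplicates:
        dup = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()][0]
        raise ValueError(f"{path}: duplicate column id {dup!r}")
    df = pd.DataFrame(np.asarray(rows, dtype=float).reshape(len(row_ids), len(sample_ids)),
                      index=index, columns=sample_ids)
    return df, stage


def read_abundance_table(
    path,
    stage: Stage | str | None = None,
    *,
    empty_as_zero: bool = False,
    transpose: bool = False,
) -> AbundanceTable:
    """Read a KO-by-sample abundance table.

    Parameters
    ----------
    path
        Tab-delimited file; first column KO ids, header row sample ids.
    stage
        Stage tag to assign. When ``None`` the ``#stage=`` sidecar line is
        used if present, otherwise ``counts``.
    empty_as_zero
        Treat empty cells as explicit zeros (logged with a count).
    transpose
        Interpret the file as sample-by-KO and transpose on read.
    """
    df, sidecar = _read_matrix(path, empty_as_zero, "KO")
    if transpose:
        df = df.T
    if stage is None:
        stage = sidecar if sidecar is not None else Stage.counts
    try:
        return AbundanceTable(data=df, stage=Stage(stage))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write a table as TSV with a ``#stage=`` sidecar line.

    Values are serialized with 15 significant digits so a read/write round
    trip is numerically the identity (max abs error < 1e-10).
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{_STAGE_PREFIX}{table.stage.value}\n")
        samples = [str(s) for s in table.sample_ids]
        fh.write("\t".join(["KO", *samples]) + "\n")
        for ko, row in zip(table.ko_ids, table.values):
            fh.write("\t".join([str(ko), *(format(v, ".15g") for v in row)]) + "\n")


def read_marker_set(path, role: MarkerRole | str = MarkerRole.usicg) -> MarkerSet:
    """Read a marker list: one KO id per line, ``#`` comment lines allowed.

    Duplicate lines are deduplicated (first occurrence wins, order kept).
    """
    path = Path(path)
    seen: dict[str, None] = {}
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seen.setdefault(line, None)
    if not seen:
        raise ValueError(f"{path}: no marker ids found")
    return MarkerSet(ko_ids=tuple(seen), role=MarkerRole(role))


def write_marker_set(markers: MarkerSet, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#role={markers.role.value}\n")
        for ko in markers:
            fh.write(ko + "\n")


def read_genome_content(path, *, ko_length=None, genome_length=None) -> GenomeContentMatrix:
    """Read a genome-by-KO copy-number matrix (genomes as rows)."""
    df, _ = _read_matrix(path, False, "genome")
    return GenomeContentMatrix(
        copies=df,
        ko_length=read_series(ko_length) if isinstance(ko_length, (str, Path)) else ko_length,
        genome_length=(
            read_series(genome_length)
            if isinstance(genome_length, (str, Path))
            else genome_length
        ),
    )


def write_genome_content(content: GenomeContentMatrix, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("genome\t" + "\t".join(str(k) for k in content.ko_ids) + "\n")
        for gid, row in zip(content.genome_ids, content.copies.to_numpy()):
            fh.write(str(gid) + "\t" + "\t".join(format(int(v), "d") for v in row) + "\n")


def read_series(path, value_type=float) -> pd.Series:
    """Read a two-column TSV (id, value) into a Series; ``#`` comments allowed."""
    path = Path(path)
    ids, vals = [], []
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                vals.append(value_type(fields[1]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value {fields[1]!r}") from None
            ids.append(fields[0])
    if not ids:
        raise ValueError(f"{path}: empty file")
    index = pd.Index(ids)
    if index.has_duplicates:
        raise ValueError(f"{path}: duplicate id {index[index.duplicated()][0]!r}")
    return pd.Series(vals, index=index)


def write_series(series: pd.Series, path, *, fmt: str = ".15g") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for k, v in series.items():
            fh.write(f"{k}\t{format(v, fmt)}\n")


def read_pathway_map(path) -> PathwayMap:
    """Read a two-column TSV mapping pathway id -> member KO id."""
    path = Path(path)
    membership: dict[str, set] = {}
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            membership.setdefault(fields[0], set()).add(fields[1])
    if not membership:
        raise ValueError(f"{path}: empty pathway map")
    return PathwayMap(membership=membership)


def write_pathway_map(pathways: PathwayMap, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pid in pathways.pathway_ids:
            for ko in sorted(pathways[pid]):
                fh.write(f"{pid}\t{ko}\n")


def read_property_table(path):
    """Read a KO-by-property TSV of gene-specific covariates (values may be
    negative; empty cells are treated as zeros)."""
    from .bias import GenePropertyTable

    df, _ = _read_matrix(path, True, "KO")
    return GenePropertyTable(values=df)


def write_property_table(properties, path) -> None:
    path = Path(path)
    df = properties.values
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("KO\t" + "\t".join(str(c) for c in df.columns) + "\n")
        for ko, row in zip(df.index, df.to_numpy(dtype=float)):
            fh.write(str(ko) + "\t" + "\t".join(format(v, ".15g") for v in row) + "\n")


def read_otu_profiles(abundance_path, copies_path, nsti_path, ko_length_path=None) -> OTUProfileSet:
    """Assemble an OTU profile bundle from its component TSV files."""
    abund, _ = _read_matrix(abundance_path, False, "OTU")
    copies, _ = _read_matrix(copies_path, False, "OTU")
    nsti = read_series(nsti_path)
    ko_length = read_series(ko_length_path) if ko_length_path is not None else None
    return OTUProfileSet(
        otu_rel_abundance=abund, otu_ko_copies=copies, nsti=nsti, ko_length=ko_length
    )


def write_otu_profiles(profiles: OTUProfileSet, abundance_path, copies_path, nsti_path,
                       ko_length_path=None) -> None:
    write_abundance_table(
        AbundanceTable(profiles.otu_rel_abundance, Stage.compositional), abundance_path
    )
    # copy matrix is integer-valued but stored through the generic writer
    path = Path(copies_path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("OTU\t" + "\t".join(str(k) for k in profiles.ko_ids) + "\n")
        for oid, row in zip(profiles.otu_ko_copies.index, profiles.otu_ko_copies.to_numpy()):
            fh.write(str(oid) + "\t" + "\t".join(format(v, ".15g") for v in row) + "\n")
    write_series(profiles.nsti, nsti_path)
    if ko_length_path is not None and profiles.ko_length is not None:
        write_series(profiles.ko_length, ko_length_path)
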
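"""Core in-memory containers for functional metagenomic profiles.

All tabular data is carried in :class:`pandas.DataFrame` / :class:`pandas.Series`
objects; the classes here add the domain invariants (non-negativity, unique
identifiers, column sums for compositional data) and a processing-stage tag so
that operations can check they are being fed the quantity they expect.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "MarkerRole",
    "AbundanceTable",
    "MarkerSet",
    "GenomeContentMatrix",
    "PathwayMap",
    "OTUProfileSet",
]

_COLSUM_TOL = 1e-9


class Stage(str, enum.Enum):
    """Processing stage of an abundance table.

    ``counts``            raw read counts per KO.
    ``length_normalized`` counts divided by average gene length (per-bp abundance).
    ``compositional``     relative abundances; every sample column sums to 1.
    ``marker_normalized`` divided by the median abundance of the universal
                          single-copy markers -- interpretable as average
                          genomic copy numbers.
    ``bias_corrected``    marker-normalized values after gene-specific bias
                          correction.
    ``genome_size_corrected`` relative abundances rescaled by an estimated
                          average genome size (the alternative schemes).
    """

    counts = "counts"
    length_normalized = "length_normalized"
    compositional = "compositional"
    marker_normalized = "marker_normalized"
    bias_corrected = "bias_corrected"
    genome_size_corrected = "genome_size_corrected"


class MarkerRole(str, enum.Enum):
    """Role of a marker list: strict universal single-copy, or the relaxed band."""

    usicg = "usicg"
    semi_usicg = "semi_usicg"


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass(frozen=True)
class AbundanceTable:
    """A KO-by-sample matrix of non-negative abundances with a stage tag.

    Rows are KO (gene-family) identifiers, columns are sample identifiers.
    Absences are explicit zeros; missing cells are rejected.
    """

    data: pd.DataFrame
    stage: Stage = Stage.counts

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (KO x sample)")
        _check_unique(df.index, "KO ids")
        _check_unique(df.columns, "sample ids")
        values = df.to_numpy(dtype=float, copy=False)
        if np.isnan(values).any():
            ko, s = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at KO {df.index[ko]!r}, sample {df.columns[s]!r}"
            )
        if (values < 0).any():
            ko, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at KO {df.index[ko]!r}, sample {df.columns[s]!r}"
            )
        stage = Stage(self.stage)
        object.__setattr__(self, "stage", stage)
        if stage is Stage.compositional and df.shape[0] > 0 and df.shape[1] > 0:
            colsums = values.sum(axis=0)
            bad = np.abs(colsums - 1.0) > _COLSUM_TOL
            if bad.any():
                s = int(np.argmax(bad))
                raise ValueError(
                    "compositional table column does not sum to 1: "
                    f"sample {df.columns[s]!r} sums to {colsums[s]!r}"
                )

    @property
    def ko_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, stage: Stage) -> "AbundanceTable":
        return AbundanceTable(data=data, stage=stage)


@dataclass(frozen=True)
class MarkerSet:
    """An ordered list of marker KO identifiers with a role label."""

    ko_ids: tuple[str, ...]
    role: MarkerRole = MarkerRole.usicg

    def __post_init__(self) -> None:
        ids = tuple(str(k) for k in self.ko_ids)
        if len(ids) == 0:
            raise ValueError("marker set is empty")
        if len(set(ids)) != len(ids):
            raise ValueError("marker set contains duplicate KO ids")
        object.__setattr__(self, "ko_ids", ids)
        object.__setattr__(self, "role", MarkerRole(self.role))

    def __len__(self) -> int:
        return len(self.ko_ids)

    def __iter__(self):
        return iter(self.ko_ids)


@dataclass(frozen=True)
class GenomeContentMatrix:
    """Genome-by-KO copy-number matrix (non-negative integers).

    Optionally carries per-genome lengths (bp) and per-KO average gene
    lengths (bp).
    """

    copies: pd.DataFrame
    genome_length: pd.Series | None = None
    ko_length: pd.Series | None = None

    def __post_init__(self) -> None:
        df = self.copies
        _check_unique(df.index, "genome ids")
        _check_unique(df.columns, "KO ids")
        values = df.to_numpy()
        if np.isnan(np.asarray(values, dtype=float)).any():
            raise ValueError("copy-number matrix has missing values")
        if (np.asarray(values, dtype=float) < 0).any():
            raise ValueError("copy numbers must be non-negative")
        if not np.allclose(values, np.round(np.asarray(values, dtype=float))):
            raise ValueError("copy numbers must be integer-valued")
        if self.genome_length is not None:
            gl = self.genome_length.reindex(df.index)
            if gl.isna().any() or (gl <= 0).any():
                raise ValueError("genome_length must be positive for every genome")
            object.__setattr__(self, "genome_length", gl)
        if self.ko_length is not None:
            kl = self.ko_length
            if (kl.dropna() <= 0).any():
                raise ValueError("ko_length must be positive")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.copies.index)

    @property
    def ko_ids(self) -> list[str]:
        return list(self.copies.columns)

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean genome-by-KO presence matrix (copy >= 1)."""
        return self.copies >= 1


@dataclass(frozen=True)
class PathwayMap:
    """Mapping from pathway id to its member KO set."""

    membership: dict

    def __post_init__(self) -> None:
        cleaned = {}
        for pid, kos in self.membership.items():
            members = frozenset(str(k) for k in kos)
            if not members:
                raise ValueError(f"pathway {pid!r} has an empty member set")
            cleaned[str(pid)] = members
        object.__setattr__(self, "membership", cleaned)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.membership)

    def __getitem__(self, pid: str) -> frozenset:
        return self.membership[pid]

    def __len__(self) -> int:
        return len(self.membership)

    def __iter__(self):
        return iter(self.membership)


@dataclass(frozen=True)
class OTUProfileSet:
    """Per-sample OTU relative abundances plus predicted per-OTU gene content.

    ``otu_rel_abundance``  OTU x sample, columns sum to 1.
    ``otu_ko_copies``      OTU x KO predicted copy numbers.
    ``nsti``               per-OTU nearest-sequenced-taxon index in [0, 1].
    ``ko_length``          per-KO average gene length (bp), optional.
    """

    otu_rel_abundance: pd.DataFrame
    otu_ko_copies: pd.DataFrame
    nsti: pd.Series
    ko_length: pd.Series | None = None

    def __post_init__(self) -> None:
        ra = self.otu_rel_abundance
        _check_unique(ra.index, "OTU ids")
        _check_unique(ra.columns, "sample ids")
        vals = ra.to_numpy(dtype=float)
        if (vals < 0).any() or np.isnan(vals).any():
            raise ValueError("OTU relative abundances must be non-negative and complete")
        colsums = vals.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _COLSUM_TOL):
            s = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"OTU abundance column {ra.columns[s]!r} sums to {colsums[s]!r}, not 1"
            )
        missing = ra.index.difference(self.otu_ko_copies.index)
        if len(missing) > 0:
            raise ValueError(f"OTUs lacking predicted KO content: {list(missing)[:5]}")
        nsti = self.nsti
        known = nsti.dropna()
        if ((known < 0) | (known > 1)).any():
            raise ValueError("NSTI values must lie in [0, 1]")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.otu_rel_abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.otu_rel_abundance.columns)

    @property
    def ko_ids(self) -> list[str]:
        return list(self.otu_ko_copies.columns)
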
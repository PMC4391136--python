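"""Inter-sample normalization schemes for KO abundance tables.

The central operation is :func:`marker_normalize`: dividing each sample's
length-normalized gene abundances by the median abundance of a set of
universal single-copy marker genes in that sample. Because every genome
carries each marker exactly once, the marker median is a per-sample proxy
for "abundance of one genomic copy", so the normalized values estimate the
average genomic copy number of each gene across the cells of the community.
By construction the marker median equals 1 in every normalized sample and
the result is invariant to any per-sample rescaling of the input (sequencing
depth, compositional closure).

Also provided: plain length and compositional normalization, and two
genome-size-based alternatives -- the closed-form effective genome size
(EGS) from marker-gene read density,

    EGS = (a + b * L^-c) / x,     a=21.2, b=4230, c=0.733,

with L the read length and x the marker density, and the per-marker
estimate G = (g + L - 2m) / f averaged over a small panel of universal
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AbundanceTable, MarkerSet, Stage

logger = logging.getLogger(__name__)

__all__ = [
    "EGSParams",
    "MarkerEGSParams",
    "length_normalize",
    "compositional_normalize",
    "marker_normalize",
    "raes_egs",
    "marker_density",
    "marker_density_from_counts",
    "marker_egs_normalize",
    "genome_size_normalize",
    "MIN_MARKERS_DETECTED",
]

#: Default minimum number of markers with nonzero abundance per sample.
MIN_MARKERS_DETECTED = 10


@dataclass(frozen=True)
class EGSParams:
    """Parameters of the closed-form effective-genome-size formula."""

    a: float = 21.2
    b: float = 4230.0
    c: float = 0.733
    read_length: int = 101

    def __post_init__(self) -> None:
        if self.b <= 0 or self.c <= 0 or self.read_length <= 0:
            raise ValueError("EGS parameters require b > 0, c > 0, read_length > 0")


@dataclass(frozen=True)
class MarkerEGSParams:
    """Parameters of the per-marker genome-size estimate G = (g + L - 2m)/f."""

    marker_ko_ids: tuple[str, ...]
    marker_lengths: dict  # KO id -> gene length g (bp)
    read_length: int = 75
    min_overlap: int = 90

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.min_overlap < 0:
            raise ValueError("min_overlap must be non-negative")
        missing = [k for k in self.marker_ko_ids if k not in self.marker_lengths]
        if missing:
            raise ValueError(f"marker lengths missing for: {missing}")


def length_normalize(counts: AbundanceTable, ko_length: pd.Series) -> AbundanceTable:
    """Divide read counts by average gene length (bp) to per-bp abundances.

    Every KO with a nonzero count must have a length; KOs whose counts are
    zero everywhere pass through as zeros even without one.
    """
    if counts.stage is not Stage.counts:
        raise ValueError(f"expected a counts-stage table, got {counts.stage.value}")
    lengths = ko_length.reindex(counts.data.index)
    nonzero = counts.data.sum(axis=1) > 0
    bad = lengths.isna() | (lengths <= 0)
    offending = counts.data.index[nonzero & bad]
    if len(offending) > 0:
        raise ValueError(
            f"no (positive) gene length for KOs with nonzero counts: {list(offending)[:10]}"
        )
    divisor = lengths.fillna(1.0).to_numpy(dtype=float)
    data = counts.data.div(divisor, axis=0)
    return AbundanceTable(data=data, stage=Stage.length_normalized)


def compositional_normalize(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its total so columns sum to 1."""
    sums = table.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero) > 0:
        raise ValueError(f"sample(s) with zero total abundance: {list(zero.index)[:5]}")
    return AbundanceTable(data=table.data.div(sums, axis=1), stage=Stage.compositional)


def marker_normalize(
    table: AbundanceTable,
    markers: MarkerSet,
    min_detected: int = MIN_MARKERS_DETECTED,
    on_low: str = "error",
) -> AbundanceTable:
    """Divide each sample by the median abundance of the marker genes.

    The median is taken over *all* markers in the set; markers missing from
    the table or undetected contribute zeros (with many markers the median
    is robust to a few dropouts). Samples with fewer than ``min_detected``
    nonzero markers are rejected, or dropped with a warning when
    ``on_low="drop"``. Output values are average genomic copy numbers; the
    marker median is 1 in every sample.
    """
    if table.stage not in (Stage.length_normalized, Stage.counts, Stage.compositional):
        raise ValueError(
            f"cannot marker-normalize a table at stage {table.stage.value}"
        )
    if table.stage is not Stage.length_normalized:
        logger.warning(
            "marker normalization expects length-normalized abundances; "
            "got stage %s",
            table.stage.value,
        )
    if on_low not in ("error", "drop"):
        raise ValueError("on_low must be 'error' or 'drop'")
    marker_rows = table.data.reindex(list(markers)).fillna(0.0)
    detected = (marker_rows > 0).sum(axis=0)
    medians = marker_rows.median(axis=0)
    low = detected[(detected < min_detected) | (medians <= 0)]
    if len(low) > 0:
        msg = (
            f"{len(low)} sample(s) with fewer than {min_detected} detected markers "
            f"or zero marker median: "
            + ", ".join(f"{s} ({int(c)} detected)" for s, c in list(low.items())[:5])
        )
        if on_low == "error":
            raise ValueError(msg)
        logger.warning("%s -- dropping", msg)
    keep = [s for s in table.sample_ids if s not in set(low.index)]
    data = table.data[keep].div(medians[keep], axis=1)
    return AbundanceTable(data=data, stage=Stage.marker_normalized)


def raes_egs(x, params: EGSParams = EGSParams()):
    """Closed-form effective genome size (bp) from marker-gene density x.

    EGS = (a + b * L^-c) / x; strictly decreasing in x, increasing in L.
    Accepts a scalar or an array/Series of densities.
    """
    arr = np.asarray(x, dtype=float)
    if (arr <= 0).any():
        raise ValueError("marker density must be positive")
    numer = params.a + params.b * float(params.read_length) ** (-params.c)
    out = numer / arr
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index)
    return out


def marker_density(hits, marker_lengths, total_bases: float) -> float:
    """Marker-gene density of one sample from origin-tracked read hits.

    ``hits`` is an iterable of ``(marker_ko, matched_bases)`` pairs, one per
    read that matched a marker gene. The density is the sum of
    matched_bases / gene_length over those reads, divided by the total
    number of bases sequenced in the sample (making it independent of
    sequencing depth).
    """
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    total = 0.0
    n = 0
    for ko, matched in hits:
        try:
            length = float(marker_lengths[ko])
        except KeyError:
            raise ValueError(f"no length for marker {ko!r}") from None
        total += matched / length
        n += 1
    if n == 0:
        raise ValueError("no marker hits: density is zero and EGS is undefined")
    return total / total_bases


def marker_density_from_counts(
    marker_read_counts: pd.Series,
    read_length: int,
    marker_lengths: pd.Series,
    total_bases: float,
) -> float:
    """Marker density when every matching read contributes ``read_length`` bases.

    Equivalent to :func:`marker_density` with per-read hits of constant
    matched length, but computed from per-marker read counts.
    """
    counts = marker_read_counts[marker_read_counts > 0]
    lengths = marker_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"no length for marker(s) {missing[:5]}")
    if counts.sum() == 0:
        raise ValueError("no marker hits: density is zero and EGS is undefined")
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    return float((counts * read_length / lengths).sum() / total_bases)


def marker_egs_normalize(
    table: AbundanceTable, params: MarkerEGSParams
) -> AbundanceTable:
    """Rescale relative abundances by a marker-panel genome-size estimate.

    Per sample, each panel marker with relative abundance f > 0 yields
    G = (g + L - 2m) / f; the estimates are averaged into the sample's EGS
    and every gene's relative abundance is multiplied by it. Markers with
    f = 0 are skipped (logged); a sample where the whole panel is absent is
    an error.
    """
    if table.stage is not Stage.compositional:
        raise ValueError("marker-panel EGS normalization expects a compositional table")
    offset = params.read_length - 2 * params.min_overlap
    egs = {}
    for sample in table.sample_ids:
        col = table.data[sample]
        estimates = []
        skipped = 0
        for ko in params.marker_ko_ids:
            f = float(col.get(ko, 0.0))
            if f <= 0:
                skipped += 1
                continue
            g = float(params.marker_lengths[ko])
            estimates.append((g + offset) / f)
        if not estimates:
            raise ValueError(f"sample {sample!r}: all panel markers have zero abundance")
        if skipped:
            logger.info("sample %s: skipped %d absent panel markers", sample, skipped)
        egs[sample] = float(np.mean(estimates))
    scaled = table.data.mul(pd.Series(egs), axis=1)
    return AbundanceTable(data=scaled, stage=Stage.genome_size_corrected)


def genome_size_normalize(table: AbundanceTable, egs: pd.Series) -> AbundanceTable:
    """Multiply each sample's relative abundances by an estimated genome size."""
    if table.stage is not Stage.compositional:
        raise ValueError("genome-size normalization expects a compositional table")
    sizes = egs.reindex(table.data.columns)
    if sizes.isna().any() or (sizes <= 0).any():
        raise ValueError("positive genome-size estimate required for every sample")
    return AbundanceTable(
        data=table.data.mul(sizes, axis=1), stage=Stage.genome_size_corrected
    )
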
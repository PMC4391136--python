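"""Selection of universal single-copy marker genes and gene co-occurrence.

Universal single-copy genes (USiCGs) are KOs present in nearly every
prokaryotic genome at (essentially) one copy. They are selected from a
genome-by-KO copy-number matrix by a prevalence band plus a conditional
mean-copy cutoff:

* prevalence = fraction of genomes carrying the KO (copy >= 1), required to
  fall in ``[prevalence_min, prevalence_max)`` -- closed below, open above,
  so the strict and relaxed ("semi") bands are disjoint by construction;
* mean copy number, computed only over the genomes in which the KO appears,
  required to be strictly below ``mean_copy_max``.

The default bands are prevalence >= 0.915 for the strict universal set and
[0.85, 0.915) for the semi-universal set, both with mean copy < 1.1.

Co-occurrence analysis compares KO presence/absence patterns across genomes
(copy number ignored) by Jaccard similarity; highly co-occurring pairs
(similarity > 0.95 by default) form a graph whose maximal cliques of at
least five genes are reported as clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np

from .types import GenomeContentMatrix, MarkerRole, MarkerSet

logger = logging.getLogger(__name__)

__all__ = [
    "USICG_PREVALENCE_MIN",
    "SEMI_PREVALENCE_MIN",
    "MEAN_COPY_MAX",
    "JACCARD_THRESHOLD",
    "MIN_CLUSTER_SIZE",
    "CooccurrenceResult",
    "select_markers",
    "jaccard_cooccurrence",
    "load_default_markers",
]

#: Minimum genome prevalence for the strict universal single-copy band.
USICG_PREVALENCE_MIN = 0.915
#: Minimum genome prevalence for the relaxed (semi-universal) band; its upper
#: bound is the strict band's minimum.
SEMI_PREVALENCE_MIN = 0.85
#: Maximum mean copy number over genomes where the KO is present (strict <).
MEAN_COPY_MAX = 1.1
#: Jaccard similarity threshold for co-occurring gene pairs (strict >).
JACCARD_THRESHOLD = 0.95
#: Minimum clique size reported as a co-occurrence cluster.
MIN_CLUSTER_SIZE = 5


@dataclass(frozen=True)
class CooccurrenceResult:
    """Co-occurring KO pairs and maximal cliques above a Jaccard threshold."""

    pairs: tuple  # of (ko_a, ko_b, jaccard)
    clusters: tuple  # of frozenset of KO ids
    threshold: float
    min_cluster_size: int


def select_markers(
    content: GenomeContentMatrix,
    prevalence_min: float = USICG_PREVALENCE_MIN,
    prevalence_max: float | None = None,
    mean_copy_max: float = MEAN_COPY_MAX,
    role: MarkerRole | str = MarkerRole.usicg,
) -> MarkerSet:
    """Select marker KOs from a genome-by-KO copy-number matrix.

    A KO is selected when its prevalence lies in
    ``[prevalence_min, prevalence_max)`` (upper bound +inf when ``None``)
    and its mean copy number over the genomes where it is present is
    strictly below ``mean_copy_max``.
    """
    copies = content.copies
    if copies.shape[0] == 0 or copies.shape[1] == 0:
        raise ValueError("genome content matrix is empty")
    if not (0 < prevalence_min <= 1):
        raise ValueError("prevalence_min must be in (0, 1]")
    if prevalence_max is not None and prevalence_max <= prevalence_min:
        raise ValueError("prevalence_max must exceed prevalence_min")

    mat = copies.to_numpy(dtype=float)
    present = mat >= 1
    n_present = present.sum(axis=0)
    prevalence = n_present / mat.shape[0]
    with np.errstate(invalid="ignore"):
        mean_copy = np.where(
            n_present > 0, (mat * present).sum(axis=0) / np.maximum(n_present, 1), np.inf
        )
    keep = (prevalence >= prevalence_min) & (mean_copy < mean_copy_max)
    if prevalence_max is not None:
        keep &= prevalence < prevalence_max
    selected = [ko for ko, k in zip(copies.columns, keep) if k]
    if not selected:
        raise ValueError(
            "no KO satisfies the selection band "
            f"[{prevalence_min}, {prevalence_max}) with mean copy < {mean_copy_max}"
        )
    return MarkerSet(ko_ids=tuple(selected), role=MarkerRole(role))


def jaccard_cooccurrence(
    content: GenomeContentMatrix,
    threshold: float = JACCARD_THRESHOLD,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
) -> CooccurrenceResult:
    """All KO pairs with presence/absence Jaccard similarity > ``threshold``
    and the maximal cliques (size >= ``min_cluster_size``) they form.

    KOs absent from every genome have an undefined Jaccard similarity and
    are excluded (logged). Copy number is ignored; only presence counts.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    presence = content.presence.to_numpy()
    ko_ids = np.asarray(content.ko_ids)
    nonzero = presence.any(axis=0)
    if (~nonzero).any():
        logger.info(
            "excluding %d KOs absent from every genome from co-occurrence analysis",
            int((~nonzero).sum()),
        )
    presence = presence[:, nonzero].astype(np.int64)
    ko_ids = ko_ids[nonzero]
    n = presence.shape[1]
    inter = presence.T @ presence
    sizes = presence.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = inter / union
    iu = np.triu_indices(n, k=1)
    mask = jac[iu] > threshold
    pairs = tuple(
        (str(ko_ids[i]), str(ko_ids[j]), float(jac[i, j]))
        for i, j, m in zip(iu[0], iu[1], mask)
        if m
    )
    graph = nx.Graph()
    graph.add_nodes_from(str(k) for k in ko_ids)
    graph.add_edges_from((a, b) for a, b, _ in pairs)
    clusters = tuple(
        frozenset(c) for c in nx.find_cliques(graph) if len(c) >= min_cluster_size
    )
    return CooccurrenceResult(
        pairs=pairs,
        clusters=clusters,
        threshold=threshold,
        min_cluster_size=min_cluster_size,
    )


def load_default_markers(role: MarkerRole | str = MarkerRole.usicg) -> MarkerSet:
    """Load a packaged default marker list.

    The packaged lists are synthetic stand-ins: curated sets of
    well-characterized universal (76 KOs) and semi-universal (72 KOs)
    single-copy orthologs, shipped so the normalization and the simulator
    work out of the box.
    """
    from .io import read_marker_set  # local import to avoid a cycle

    role = MarkerRole(role)
    fname = {
        MarkerRole.usicg: "usicg_default_synthetic.txt",
        MarkerRole.semi_usicg: "semi_usicg_default_synthetic.txt",
    }[role]
    ref = resources.files("scgnorm.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return read_marker_set(path, role=role)
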
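"""Mock-community shotgun simulator with known average copy numbers.

The simulator builds a pool of synthetic genomes over a shared KO universe,
draws random communities from it, and generates origin-tracked shotgun
reads, yielding KO count tables together with the exact per-sample true
average copy number of every KO. It reproduces, at a configurable scale,
the benchmark design used to validate marker-based normalization:

* a pool of 21 genomes, each carrying every universal single-copy marker
  at exactly one copy and a designated *invariant pathway* at identical
  copy numbers, so the pathway's true abundance is constant across samples
  by construction;
* per-sample communities of 10 genomes with relative abundances spanning
  up to 100-fold;
* 500,000 reads of 101 bp per sample by default, assigned to genomes with
  probability proportional to (relative abundance x genome length) -- the
  length weighting is what makes average genome size a confounder for
  compositional normalization -- and within a genome to a KO (or to
  unannotated padding) proportionally to copy number x gene length.

Annotation error is emulated at the KO level with per-KO recall and a
uniform misassignment ("precision noise") probability; sequences themselves
are never generated. All randomness flows from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import load_default_markers
from .types import (
    AbundanceTable,
    GenomeContentMatrix,
    MarkerSet,
    OTUProfileSet,
    PathwayMap,
    Stage,
)
from .bias import GenePropertyTable

logger = logging.getLogger(__name__)

__all__ = [
    "MockGenome",
    "SimulatedSample",
    "SimulatedDataset",
    "synth_ko_lengths",
    "build_genome_pool",
    "sample_community",
    "simulate_reads",
    "true_average_copy_number",
    "simulate_dataset",
    "synth_property_table",
    "synth_otu_profiles",
    "pool_content_matrix",
    "DEFAULT_N_GENOMES",
    "DEFAULT_N_READS",
    "DEFAULT_READ_LENGTH",
    "DEFAULT_GENOMES_PER_SAMPLE",
    "DEFAULT_MAX_FOLD",
]

DEFAULT_N_GENOMES = 21
DEFAULT_N_READS = 500_000
DEFAULT_READ_LENGTH = 101
DEFAULT_GENOMES_PER_SAMPLE = 10
DEFAULT_MAX_FOLD = 100.0
DEFAULT_PADDING_FRACTION = 0.10
#: Size of the synthetic invariant pathway (flagellar-assembly-like module).
DEFAULT_PATHWAY_SIZE = 35
#: Total KO universe: markers + invariant pathway + accessory genes.
DEFAULT_N_KOS = 600
#: Per-genome accessory presence probabilities span this range so annotated
#: genome lengths span >= 3-fold across the pool.
ACCESSORY_PRESENCE_RANGE = (0.10, 0.95)


@dataclass(frozen=True)
class MockGenome:
    """A synthetic genome: per-KO copy numbers plus annotated/total length."""

    genome_id: str
    ko_copies: pd.Series  # full KO universe, non-negative ints
    annotated_length: float  # bp, sum of copies * gene length
    genome_length: float  # bp, annotated * (1 + padding_fraction)


@dataclass(frozen=True)
class SimulatedSample:
    """One simulated metagenomic sample with origin-tracked ground truth.

    ``ko_counts`` are the post-annotation counts (after recall/precision
    noise); ``origin_counts`` are the true per-KO read origins before
    annotation; ``true_avg_copy`` is the abundance-weighted true average
    copy number of every KO.
    """

    sample_id: str
    genome_ids: tuple[str, ...]
    rel_abundance: pd.Series
    ko_counts: pd.Series
    origin_counts: pd.Series
    unassigned: int
    true_avg_copy: pd.Series
    n_reads: int
    read_length: int
    seed: int


@dataclass(frozen=True)
class SimulatedDataset:
    """A full simulated study: pool, samples, tables and ground truth."""

    pool: tuple
    samples: tuple
    counts: AbundanceTable  # KO x sample read counts
    truth: pd.DataFrame  # KO x sample true average copy numbers
    ko_length: pd.Series
    markers: MarkerSet
    pathway: PathwayMap
    seed: int

    @property
    def pathway_id(self) -> str:
        return next(iter(self.pathway))


def synth_ko_lengths(ko_ids, seed: int = 0, mean_bp: float = 900.0) -> pd.Series:
    """Log-normal average gene lengths (bp), clipped to [150, 5000]."""
    rng = np.random.default_rng(seed)
    sigma = 0.35
    mu = np.log(mean_bp) - sigma**2 / 2
    lengths = np.exp(rng.normal(mu, sigma, size=len(list(ko_ids))))
    return pd.Series(np.clip(np.round(lengths), 150, 5000), index=list(ko_ids))


def build_genome_pool(
    n_genomes: int = DEFAULT_N_GENOMES,
    n_kos: int = DEFAULT_N_KOS,
    markers: MarkerSet | None = None,
    invariant_pathway: tuple[str, tuple] | None = None,
    ko_length: pd.Series | None = None,
    padding_fraction: float = DEFAULT_PADDING_FRACTION,
    seed: int = 0,
    accessory_presence=ACCESSORY_PRESENCE_RANGE,
    pathway_copies: int = 1,
) -> tuple[list, pd.Series, MarkerSet, PathwayMap]:
    """Build a pool of mock genomes sharing markers and an invariant pathway.

    Every genome carries each marker KO at copy exactly 1 and each
    invariant-pathway KO at the same fixed copy number; the remaining
    (accessory) KOs are present per genome with a seeded Bernoulli draw
    whose probability varies across genomes (so genome sizes differ), at
    copies 1 + Poisson(0.3).

    Returns ``(pool, ko_length, markers, pathway_map)``.
    """
    rng = np.random.default_rng(seed)
    if markers is None:
        markers = load_default_markers("usicg")
    if invariant_pathway is None:
        pathway_kos = tuple(f"KP{i:05d}" for i in range(DEFAULT_PATHWAY_SIZE))
        pathway = ("invariant_pathway", pathway_kos)
    else:
        pathway = (invariant_pathway[0], tuple(invariant_pathway[1]))
    marker_ids = tuple(markers)
    if n_kos < len(marker_ids) + len(pathway[1]):
        raise ValueError("n_kos must be at least |markers| + |pathway|")
    n_acc = n_kos - len(marker_ids) - len(pathway[1])
    accessory = tuple(f"KA{i:05d}" for i in range(n_acc))
    ko_ids = list(marker_ids) + list(pathway[1]) + list(accessory)
    if len(set(ko_ids)) != len(ko_ids):
        raise ValueError("marker, pathway and accessory KO ids overlap")
    if ko_length is None:
        ko_length = synth_ko_lengths(ko_ids, seed=int(rng.integers(2**31)))
    else:
        ko_length = ko_length.reindex(ko_ids)
        if ko_length.isna().any():
            raise ValueError("ko_length must cover every KO in the universe")

    lo, hi = accessory_presence
    presence_prob = np.linspace(lo, hi, n_genomes)
    rng.shuffle(presence_prob)
    pool = []
    lengths = ko_length.to_numpy(dtype=float)
    for g in range(n_genomes):
        copies = np.zeros(len(ko_ids), dtype=np.int64)
        copies[: len(marker_ids)] = 1
        copies[len(marker_ids): len(marker_ids) + len(pathway[1])] = pathway_copies
        if n_acc:
            present = rng.random(n_acc) < presence_prob[g]
            acc_copies = (1 + rng.poisson(0.3, size=n_acc)) * present
            copies[len(marker_ids) + len(pathway[1]):] = acc_copies
        annotated = float(copies @ lengths)
        pool.append(
            MockGenome(
                genome_id=f"G{g:03d}",
                ko_copies=pd.Series(copies, index=ko_ids),
                annotated_length=annotated,
                genome_length=annotated * (1.0 + padding_fraction),
            )
        )
    pathway_map = PathwayMap({pathway[0]: set(pathway[1])})
    _attach_lengths(pool, ko_length)
    return pool, ko_length, markers, pathway_map


def pool_content_matrix(pool, ko_length: pd.Series | None = None) -> GenomeContentMatrix:
    """The pool's genome-by-KO copy matrix as a :class:`GenomeContentMatrix`."""
    copies = pd.DataFrame({g.genome_id: g.ko_copies for g in pool}).T
    lengths = pd.Series({g.genome_id: g.genome_length for g in pool})
    return GenomeContentMatrix(copies=copies, genome_length=lengths, ko_length=ko_length)


def sample_community(
    pool,
    genomes_per_sample: int = DEFAULT_GENOMES_PER_SAMPLE,
    max_fold: float = DEFAULT_MAX_FOLD,
    seed: int = 0,
) -> tuple[tuple[str, ...], pd.Series]:
    """Draw a random community: a uniform genome subset with log-uniform
    relative abundances spanning at most ``max_fold``.
    """
    if genomes_per_sample > len(pool):
        raise ValueError("genomes_per_sample exceeds the pool size")
    if max_fold < 1:
        raise ValueError("max_fold must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=genomes_per_sample, replace=False)
    genome_ids = tuple(pool[i].genome_id for i in idx)
    raw = np.exp(rng.uniform(0.0, np.log(max_fold), size=genomes_per_sample))
    abund = pd.Series(raw / raw.sum(), index=list(genome_ids))
    return genome_ids, abund


def true_average_copy_number(community: pd.Series, pool) -> pd.Series:
    """Abundance-weighted true average copy number of every KO.

    ``community`` maps genome id -> relative abundance (summing to 1).
    """
    total = float(community.sum())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("community abundances must sum to 1")
    by_id = {g.genome_id: g for g in pool}
    out = None
    for gid, a in community.items():
        contrib = by_id[gid].ko_copies * float(a)
        out = contrib if out is None else out + contrib
    # normalize by the (float) total so a uniformly single-copy gene is
    # exactly 1 regardless of rounding in the abundance sum
    return out / total


def simulate_reads(
    community: pd.Series,
    pool,
    n_reads: int = DEFAULT_N_READS,
    read_length: int = DEFAULT_READ_LENGTH,
    annotation_recall=1.0,
    annotation_precision_noise: float = 0.0,
    seed: int = 0,
    sample_id: str = "S0",
    ko_length: pd.Series | None = None,
) -> SimulatedSample:
    """Generate one sample's origin-tracked reads and KO counts.

    Reads land on genomes multinomially with probability proportional to
    relative abundance times genome length, then within a genome on a KO
    (or intergenic padding) proportionally to copies x gene length. A
    KO-origin read is counted for its KO with probability
    ``annotation_recall`` (scalar or per-KO Series), miscounted to a
    uniformly random other KO with probability
    ``annotation_precision_noise``, and left unassigned otherwise.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    by_id = {g.genome_id: g for g in pool}
    genomes = [by_id[g] for g in community.index]
    ko_ids = genomes[0].ko_copies.index
    # per-KO expected DNA weight: sum_g a_g * copies_gk * len_k
    weights = np.zeros(len(ko_ids), dtype=float)
    padding_weight = 0.0
    for g, a in zip(genomes, community.to_numpy(dtype=float)):
        weights += a * g.ko_copies.to_numpy(dtype=float)
        padding_weight += a * (g.genome_length - g.annotated_length)
    ko_len = ko_length if ko_length is not None else _ko_lengths_from_pool(pool)
    weights = weights * ko_len.reindex(ko_ids).to_numpy(dtype=float)
    probs = np.append(weights, padding_weight)
    probs = probs / probs.sum()
    draws = rng.multinomial(n_reads, probs)
    origin = draws[:-1]
    unassigned = int(draws[-1])

    recall = (
        np.full(len(ko_ids), float(annotation_recall))
        if np.isscalar(annotation_recall)
        else annotation_recall.reindex(ko_ids).fillna(1.0).to_numpy(dtype=float)
    )
    noise = float(annotation_precision_noise)
    if np.any(recall < 0) or np.any(recall > 1) or not (0 <= noise <= 1):
        raise ValueError("recall and precision noise must lie in [0, 1]")
    if np.any(recall + noise > 1):
        raise ValueError("annotation_recall + annotation_precision_noise must be <= 1")

    if np.all(recall == 1.0) and noise == 0.0:
        return SimulatedSample(
            sample_id=sample_id,
            genome_ids=tuple(community.index),
            rel_abundance=community,
            ko_counts=pd.Series(origin.copy(), index=ko_ids),
            origin_counts=pd.Series(origin, index=ko_ids),
            unassigned=unassigned,
            true_avg_copy=true_average_copy_number(community, pool),
            n_reads=n_reads,
            read_length=read_length,
            seed=seed,
        )

    counts = np.zeros(len(ko_ids), dtype=np.int64)
    mis_total = 0
    for k in np.flatnonzero(origin):
        n_k = int(origin[k])
        kept, mis, lost = rng.multinomial(n_k, [recall[k], noise, 1.0 - recall[k] - noise])
        counts[k] += kept
        mis_total_k = int(mis)
        if mis_total_k:
            others = np.ones(len(ko_ids))
            others[k] = 0.0
            others /= others.sum()
            counts += rng.multinomial(mis_total_k, others)
        unassigned += int(lost)
        mis_total += mis_total_k
    if mis_total:
        logger.debug("sample %s: %d reads misassigned", sample_id, mis_total)

    return SimulatedSample(
        sample_id=sample_id,
        genome_ids=tuple(community.index),
        rel_abundance=community,
        ko_counts=pd.Series(counts, index=ko_ids),
        origin_counts=pd.Series(origin, index=ko_ids),
        unassigned=unassigned,
        true_avg_copy=true_average_copy_number(community, pool),
        n_reads=n_reads,
        read_length=read_length,
        seed=seed,
    )


def _ko_lengths_from_pool(pool) -> pd.Series:
    lengths = getattr(pool[0], "_ko_length_cache", None)
    if lengths is not None:
        return lengths
    raise RuntimeError(
        "pool lacks attached KO lengths; pass ko_length= to simulate_reads"
    )


def simulate_dataset(
    n_samples: int = 20,
    n_reads: int = DEFAULT_N_READS,
    read_length: int = DEFAULT_READ_LENGTH,
    genomes_per_sample: int = DEFAULT_GENOMES_PER_SAMPLE,
    max_fold: float = DEFAULT_MAX_FOLD,
    n_genomes: int = DEFAULT_N_GENOMES,
    n_kos: int = DEFAULT_N_KOS,
    annotation_recall=1.0,
    annotation_precision_noise: float = 0.0,
    padding_fraction: float = DEFAULT_PADDING_FRACTION,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate a full study: genome pool, communities, reads, truth tables.

    All randomness derives from ``seed``; identical seeds reproduce
    identical outputs.
    """
    root = np.random.SeedSequence(seed)
    pool_seed, *sample_seeds = root.spawn(1 + n_samples)
    pool, ko_length, markers, pathway = build_genome_pool(
        n_genomes=n_genomes,
        n_kos=n_kos,
        padding_fraction=padding_fraction,
        seed=int(pool_seed.generate_state(1)[0] % (2**31)),
    )
    _attach_lengths(pool, ko_length)
    samples = []
    counts = {}
    truth = {}
    for i, ss in enumerate(sample_seeds):
        s_int = int(ss.generate_state(1)[0] % (2**31))
        _, community = sample_community(
            pool, genomes_per_sample=genomes_per_sample, max_fold=max_fold, seed=s_int
        )
        sample = simulate_reads(
            community,
            pool,
            n_reads=n_reads,
            read_length=read_length,
            annotation_recall=annotation_recall,
            annotation_precision_noise=annotation_precision_noise,
            seed=s_int + 1,
            sample_id=f"S{i:03d}",
        )
        samples.append(sample)
        counts[sample.sample_id] = sample.ko_counts
        truth[sample.sample_id] = sample.true_avg_copy
    counts_df = pd.DataFrame(counts).astype(float)
    return SimulatedDataset(
        pool=tuple(pool),
        samples=tuple(samples),
        counts=AbundanceTable(data=counts_df, stage=Stage.counts),
        truth=pd.DataFrame(truth),
        ko_length=ko_length,
        markers=markers,
        pathway=pathway,
        seed=seed,
    )


def _attach_lengths(pool, ko_length: pd.Series) -> None:
    for g in pool:
        object.__setattr__(g, "_ko_length_cache", ko_length)


def synth_property_table(
    markers,
    other_kos=(),
    n_properties: int = 35,
    true_weights: dict | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[GenePropertyTable, pd.Series]:
    """Synthesize a gene-property table and the true fold-changes it implies.

    Properties are standard-normal draws named ``prop00`` ...; the true
    fold-change of KO k is ``1 + sum_j w_j z_j(k) + Normal(0, noise_sd)``,
    floored at 0.05. ``true_weights`` maps property name -> weight (all
    other weights are 0). Returns (table, per-KO true fold-change) so fits
    can be scored against the generating truth.
    """
    rng = np.random.default_rng(seed)
    ko_ids = list(markers) + list(other_kos)
    prop_names = [f"prop{j:02d}" for j in range(n_properties)]
    true_weights = dict(true_weights or {})
    unknown = set(true_weights) - set(prop_names)
    if unknown:
        raise ValueError(f"true_weights name unknown properties: {sorted(unknown)}")
    z = rng.standard_normal((len(ko_ids), n_properties))
    w = np.array([true_weights.get(p, 0.0) for p in prop_names])
    fold = 1.0 + z @ w + rng.normal(0.0, noise_sd, size=len(ko_ids))
    fold = np.maximum(fold, 0.05)
    table = GenePropertyTable(pd.DataFrame(z, index=ko_ids, columns=prop_names))
    return table, pd.Series(fold, index=ko_ids)


def synth_otu_profiles(
    n_samples: int,
    n_otus: int,
    n_kos: int = 200,
    seed: int = 0,
    nsti_max: float = 0.5,
) -> OTUProfileSet:
    """Synthetic OTU profile bundle emulating 16S-predicted gene content.

    OTU relative abundances are Dirichlet draws (columns sum to 1), KO
    copies are sparse small integers, NSTI is uniform on [0, nsti_max].
    """
    rng = np.random.default_rng(seed)
    otu_ids = [f"OTU{i:04d}" for i in range(n_otus)]
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    ko_ids = [f"K{i:05d}" for i in range(n_kos)]
    # each OTU occupies ~70% of samples, so richness varies across samples
    abund = rng.dirichlet(np.full(n_otus, 0.5), size=n_samples).T
    if n_otus > 1:
        present = rng.random((n_otus, n_samples)) < 0.7
        empty = ~present.any(axis=0)
        present[rng.integers(0, n_otus, size=int(empty.sum())), np.flatnonzero(empty)] = True
        abund = abund * present
        abund = abund / abund.sum(axis=0, keepdims=True)
    present = rng.random((n_otus, n_kos)) < 0.3
    copies = present * (1 + rng.poisson(0.2, size=(n_otus, n_kos)))
    nsti = rng.uniform(0.0, nsti_max, size=n_otus)
    ko_length = synth_ko_lengths(ko_ids, seed=int(rng.integers(2**31)))
    return OTUProfileSet(
        otu_rel_abundance=pd.DataFrame(abund, index=otu_ids, columns=sample_ids),
        otu_ko_copies=pd.DataFrame(copies, index=otu_ids, columns=ko_ids),
        nsti=pd.Series(nsti, index=otu_ids),
        ko_length=ko_length,
    )
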
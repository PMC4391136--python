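"""Sample-specific properties implicated in spurious inter-sample variation.

Three per-sample quantities are estimated from OTU profile bundles
(per-sample OTU relative abundances, per-OTU predicted KO copy numbers, and
per-OTU NSTI values):

* **average genome size** -- each OTU's effective genome size (sum of KO
  copies times average KO length) weighted by its relative abundance;
* **species richness** -- the number of OTUs detected in the sample;
* **mappability** -- the abundance-weighted average of (1 - NSTI), i.e. how
  close the community is, on average, to sequenced reference genomes.

Also provided is the correlation machinery used to dissect the individual
contributions of these inter-correlated properties: partial correlation
(residualizing both variables on a set of controls) and correlation against
the residuals of a robust linear fit.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .types import OTUProfileSet

logger = logging.getLogger(__name__)

__all__ = [
    "otu_genome_size",
    "average_genome_size",
    "species_richness",
    "mappability",
    "sample_properties",
    "partial_correlation",
    "residual_correlation",
]

#: Tuning constant of the bisquare M-estimator (conventional 95% efficiency).
BISQUARE_C = 4.685


def otu_genome_size(otu_ko_copies: pd.Series, ko_length: pd.Series) -> float:
    """Effective genome size (bp) of one OTU: sum of copy * gene length."""
    nonzero = otu_ko_copies[otu_ko_copies > 0]
    lengths = ko_length.reindex(nonzero.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"no length for KO(s) with nonzero copies: {missing[:5]}")
    size = float((nonzero * lengths).sum())
    if size == 0:
        logger.warning("OTU with zero copies everywhere: genome size 0 (degenerate)")
    return size


def _otu_sizes(profiles: OTUProfileSet) -> pd.Series:
    if profiles.ko_length is None:
        raise ValueError("OTU profile set carries no KO lengths")
    copies = profiles.otu_ko_copies
    lengths = profiles.ko_length.reindex(copies.columns)
    used = copies.loc[:, (copies > 0).any(axis=0)]
    if lengths.reindex(used.columns).isna().any():
        missing = list(used.columns[lengths.reindex(used.columns).isna()])
        raise ValueError(f"no length for KO(s): {missing[:5]}")
    return (copies * lengths.fillna(0.0)).sum(axis=1)


def average_genome_size(profiles: OTUProfileSet) -> pd.Series:
    """Per-sample abundance-weighted average genome size (bp)."""
    sizes = _otu_sizes(profiles)
    weights = profiles.otu_rel_abundance
    if (weights.sum(axis=0) <= 0).any():
        raise ValueError("sample with zero total OTU abundance")
    return weights.mul(sizes, axis=0).sum(axis=0)


def species_richness(profiles: OTUProfileSet, detection_threshold: float = 0.0) -> pd.Series:
    """Per-sample count of OTUs with relative abundance above threshold."""
    if detection_threshold < 0:
        raise ValueError("detection_threshold must be >= 0")
    return (profiles.otu_rel_abundance > detection_threshold).sum(axis=0).astype(int)


def mappability(profiles: OTUProfileSet) -> pd.Series:
    """Per-sample abundance-weighted average of (1 - NSTI), in [0, 1].

    NSTI values of absent OTUs are ignored. When present OTUs lack NSTI,
    they are dropped and the weights renormalized over the retained OTUs
    (the dropped abundance mass is logged).
    """
    nsti = profiles.nsti.reindex(profiles.otu_rel_abundance.index)
    out = {}
    for sample in profiles.sample_ids:
        w = profiles.otu_rel_abundance[sample]
        present = w > 0
        known = present & nsti.notna()
        dropped = float(w[present & nsti.isna()].sum())
        if dropped > 0:
            logger.warning(
                "sample %s: dropping %.3g abundance mass with unknown NSTI; "
                "weights renormalized",
                sample, dropped,
            )
        if not known.any():
            raise ValueError(f"sample {sample!r}: no present OTU has an NSTI value")
        wk = w[known] / w[known].sum()
        out[sample] = float((wk * (1.0 - nsti[known])).sum())
    return pd.Series(out)


def sample_properties(profiles: OTUProfileSet, detection_threshold: float = 0.0) -> pd.DataFrame:
    """The three sample-specific properties as a per-sample DataFrame."""
    return pd.DataFrame(
        {
            "avg_genome_size": average_genome_size(profiles),
            "richness": species_richness(profiles, detection_threshold),
            "mappability": mappability(profiles),
        }
    )


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(design, v, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient control matrix")
    return v - design @ coef


def partial_correlation(x, y, controls=None) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out ``controls``.

    With no controls this reduces to the ordinary Pearson correlation. The
    two-sided p-value uses a t distribution with n - 2 - k degrees of
    freedom (k = number of controls). A zero-variance residual yields
    (0.0, 1.0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if controls is None or (hasattr(controls, "size") and np.size(controls) == 0):
        k = 0
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    c = np.asarray(controls, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    k = c.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} observations for {k} controls")
    design = np.column_stack([np.ones(n), c])
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    # residual variance at the level of float roundoff => exact linear fit
    if np.var(rx) <= 1e-24 * max(1.0, np.var(x)) or np.var(ry) <= 1e-24 * max(1.0, np.var(y)):
        warnings.warn("zero-variance residual in partial correlation; returning r = 0")
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clip = min(max(r, -0.999999999999), 0.999999999999)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def residual_correlation(response, regressor, probe) -> tuple[float, float]:
    """Correlate a probe with the residuals of a robust linear fit.

    ``response`` is robustly regressed on ``regressor`` (iteratively
    reweighted least squares with bisquare weights, tuning constant 4.685);
    the Pearson correlation (and two-sided p) between the residuals and
    ``probe`` is returned. Zero-variance residuals yield (0.0, 1.0) with a
    warning.
    """
    response = np.asarray(response, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    probe = np.asarray(probe, dtype=float)
    if len(response) < 4:
        raise ValueError("need at least 4 observations")
    if np.var(regressor) == 0:
        raise ValueError("constant regressor")
    design = sm.add_constant(regressor)
    fit = sm.RLM(response, design, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C)).fit()
    resid = np.asarray(fit.resid, dtype=float)
    if np.var(resid) <= 1e-24 * max(1.0, np.var(response)) or np.var(probe) == 0:
        warnings.warn("zero-variance residuals or probe; returning r = 0")
        return 0.0, 1.0
    r, p = stats.pearsonr(resid, probe)
    return float(r), float(p)
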
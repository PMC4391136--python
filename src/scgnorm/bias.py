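"""Gene-specific bias correction via an elastic-net model on gene properties.

Even after marker normalization, the measured abundances of universal
single-copy genes vary *within* a sample although every genome carries each
of them exactly once. That residual variation is systematic and traceable
to gene-specific properties (GC content, length variability, annotation
recall, conservation, ...). This module learns a regularized linear model

    fold_change(gene) ~ intercept + sum_j w_j * z_j(gene)

on the markers of a sample -- where the fold-change response is the marker's
abundance divided by the mean marker abundance, and z_j are standardized
gene properties -- and applies it to divide every gene's abundance by its
predicted fold-change. A gene whose measured abundance is fully explained
by its properties is thereby mapped back to its unbiased value.

Model selection uses nested cross-validation with folds grouped by marker
KO: the outer folds give an honest held-out R-squared, the inner folds (on
the outer training markers only) choose the penalty, and the reported model
is refit on all markers with the median selected penalty. The elastic-net
machinery is scikit-learn's.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.metrics import r2_score

from .types import AbundanceTable, MarkerSet, Stage

logger = logging.getLogger(__name__)

__all__ = [
    "GenePropertyTable",
    "BiasModel",
    "marker_response",
    "fit_bias_model",
    "fit_shared_bias_model",
    "apply_bias_correction",
    "save_bias_model",
    "load_bias_model",
    "PREDICTION_FLOOR",
]

#: Lower clamp on predicted fold-changes; prevents sign flips/explosions for
#: genes far outside the marker property range.
PREDICTION_FLOOR = 0.01

_DEGENERATE_VAR = 1e-12


@dataclass(frozen=True)
class GenePropertyTable:
    """KO-by-property real matrix of gene-specific covariates."""

    values: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise ValueError("duplicate KO ids in property table")
        if df.columns.has_duplicates:
            raise ValueError("duplicate property names in property table")

    @property
    def ko_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def property_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class BiasModel:
    """Fitted intercept + per-property weights with standardization state.

    ``prop_means`` / ``prop_sds`` are the training-set standardization
    parameters; ``prop_medians`` impute missing property values at
    application time. ``heldout_r2`` is the mean held-out R-squared over the
    outer cross-validation folds; ``scope`` records whether the model was
    fit on one sample or pooled across samples.
    """

    intercept: float
    weights: pd.Series
    prop_means: pd.Series
    prop_sds: pd.Series
    prop_medians: pd.Series
    alpha: float
    l1_ratio: float
    heldout_r2: float
    scope: str = "per_sample"

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights.to_numpy(dtype=float)).all():
            raise ValueError("model weights must be finite")
        if self.heldout_r2 > 1:
            raise ValueError("held-out R^2 cannot exceed 1")

    def predict(self, properties: GenePropertyTable, clamp: float = PREDICTION_FLOOR) -> pd.Series:
        """Predicted fold-change per KO, clamped below at ``clamp``."""
        z = _standardize_apply(properties.values, self.prop_means, self.prop_sds,
                               self.prop_medians, list(self.weights.index))
        pred = self.intercept + z.to_numpy() @ self.weights.to_numpy()
        n_clamped = int((pred < clamp).sum())
        if n_clamped:
            logger.warning("clamped %d predicted fold-changes at %g", n_clamped, clamp)
        return pd.Series(np.maximum(pred, clamp), index=properties.values.index)


def marker_response(sample_abundances: pd.Series, markers: MarkerSet) -> pd.Series:
    """Per-marker fold-change: abundance over the mean marker abundance.

    Markers missing from the series contribute zeros. The responses always
    average to 1.
    """
    vals = sample_abundances.reindex(list(markers)).fillna(0.0)
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("mean marker abundance is zero")
    return vals / mean


def _marker_folds(marker_ids, n_folds: int, rng: np.random.Generator):
    """Seeded partition of marker ids into ``n_folds`` disjoint groups."""
    ids = np.asarray(list(marker_ids))
    perm = rng.permutation(len(ids))
    return [set(ids[perm[i::n_folds]]) for i in range(n_folds)]


def _standardize_fit(df: pd.DataFrame):
    medians = df.median(axis=0)
    filled = df.fillna(medians)
    means = filled.mean(axis=0)
    sds = filled.std(axis=0, ddof=0)
    sds = sds.where(sds > 0, 1.0)  # constant properties stay at z = 0
    return (filled - means) / sds, means, sds, medians


def _standardize_apply(df, means, sds, medians, columns):
    out = df.reindex(columns=columns)
    out = out.fillna(medians.reindex(columns))
    return (out - means.reindex(columns)) / sds.reindex(columns)


def _splits_from_folds(index: pd.Index, groups: pd.Series, folds):
    """(train, test) positional splits from marker-id fold sets."""
    splits = []
    pos = np.arange(len(index))
    for fold in folds:
        test = np.asarray([g in fold for g in groups], dtype=bool)
        if test.all() or not test.any():
            continue
        splits.append((pos[~test], pos[test]))
    return splits


def _fit_once(X: np.ndarray, y: np.ndarray, inner_splits, l1_ratio: float):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet = ElasticNetCV(l1_ratio=l1_ratio, cv=inner_splits, alphas=60, max_iter=5000)
        enet.fit(X, y)
    return enet


def _nested_fit(
    responses: pd.Series,
    properties: pd.DataFrame,
    groups: pd.Series,
    folds: int,
    seed: int,
    l1_ratio: float,
    scope: str,
) -> BiasModel:
    y_all = responses.to_numpy(dtype=float)
    if float(np.var(y_all)) < _DEGENERATE_VAR:
        logger.warning("zero-variance response: returning the trivial (zero-weight) model")
        zeros = pd.Series(0.0, index=properties.columns)
        _, means, sds, medians = _standardize_fit(properties)
        return BiasModel(
            intercept=float(np.mean(y_all)), weights=zeros, prop_means=means,
            prop_sds=sds, prop_medians=medians, alpha=0.0, l1_ratio=l1_ratio,
            heldout_r2=0.0, scope=scope,
        )

    rng = np.random.default_rng(seed)
    unique_markers = pd.unique(groups)
    outer = _marker_folds(unique_markers, folds, rng)
    r2s, alphas = [], []
    for fold in outer:
        test_mask = groups.isin(fold).to_numpy()
        if test_mask.all() or not test_mask.any():
            continue
        train_props = properties.loc[~test_mask]
        z_train, means, sds, medians = _standardize_fit(train_props)
        y_train = y_all[~test_mask]
        train_markers = pd.unique(groups[~test_mask])
        inner = _marker_folds(train_markers, min(folds, max(2, len(train_markers) // 2)), rng)
        inner_splits = _splits_from_folds(train_props.index, groups[~test_mask], inner)
        enet = _fit_once(z_train.to_numpy(), y_train, inner_splits, l1_ratio)
        z_test = _standardize_apply(properties.loc[test_mask], means, sds, medians,
                                    list(properties.columns))
        pred = enet.predict(z_test.to_numpy())
        r2s.append(r2_score(y_all[test_mask], pred))
        alphas.append(float(enet.alpha_))

    heldout_r2 = float(np.mean(r2s)) if r2s else 0.0
    alpha = float(np.median(alphas)) if alphas else 1e-3
    z_full, means, sds, medians = _standardize_fit(properties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=10000)
        final.fit(z_full.to_numpy(), y_all)
    return BiasModel(
        intercept=float(final.intercept_),
        weights=pd.Series(final.coef_, index=properties.columns),
        prop_means=means,
        prop_sds=sds,
        prop_medians=medians,
        alpha=alpha,
        l1_ratio=l1_ratio,
        heldout_r2=heldout_r2,
        scope=scope,
    )


def fit_bias_model(
    responses: pd.Series,
    properties: GenePropertyTable,
    folds: int = 5,
    seed: int = 0,
    l1_ratio: float = 0.5,
) -> BiasModel:
    """Fit the bias model for one sample from per-marker fold-changes.

    ``responses`` is indexed by marker KO id; ``properties`` must cover the
    same KOs. Nested cross-validation (see module docstring) yields
    ``heldout_r2``; the reported model is refit on all markers with the
    median penalty selected across outer folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(responses) < 2 * folds:
        raise ValueError(f"need at least {2 * folds} markers with responses")
    props = properties.values.reindex(responses.index)
    if props.isna().all(axis=1).any():
        missing = list(props.index[props.isna().all(axis=1)])
        raise ValueError(f"no properties for markers: {missing[:5]}")
    groups = pd.Series(responses.index, index=responses.index)
    return _nested_fit(responses, props, groups, folds, seed, l1_ratio, scope="per_sample")


def fit_shared_bias_model(
    table: AbundanceTable,
    markers: MarkerSet,
    properties: GenePropertyTable,
    folds: int = 5,
    seed: int = 0,
    l1_ratio: float = 0.5,
) -> BiasModel:
    """Fit one generic bias model pooled over all samples of a table.

    Per-sample (marker, fold-change) observations are stacked and fit as in
    :func:`fit_bias_model`; cross-validation folds are grouped by marker KO
    so a marker never appears in both train and test.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples to fit a shared model")
    if table.stage is not Stage.marker_normalized:
        logger.warning(
            "shared model expects marker-normalized abundances; got stage %s",
            table.stage.value,
        )
    rows, resp = [], []
    for sample in table.sample_ids:
        r = marker_response(table.data[sample], markers)
        rows.extend(r.index)
        resp.extend(r.to_numpy())
    groups = pd.Series(rows)
    responses = pd.Series(resp, index=pd.RangeIndex(len(resp)))
    props = properties.values.reindex(rows)
    props.index = responses.index
    groups.index = responses.index
    if props.isna().all(axis=1).any():
        raise ValueError("properties missing for some markers")
    model = _nested_fit(responses, props, groups, folds, seed, l1_ratio, scope="generic")
    return model


def apply_bias_correction(
    table: AbundanceTable,
    model: BiasModel,
    properties: GenePropertyTable,
    clamp: float = PREDICTION_FLOOR,
) -> AbundanceTable:
    """Divide every gene's abundance by its predicted fold-change.

    KOs without any property values pass through uncorrected (their count
    is logged). Zeros remain zero; the correction is multiplicative per
    gene, hence per-sample scale free.
    """
    if table.stage is not Stage.marker_normalized:
        logger.warning(
            "bias correction expects marker-normalized abundances; got stage %s",
            table.stage.value,
        )
    props = properties.values.reindex(table.data.index)
    has_props = ~props.isna().all(axis=1)
    n_missing = int((~has_props).sum())
    if n_missing:
        logger.info("%d KOs lack properties and pass through uncorrected", n_missing)
    covered = GenePropertyTable(props.loc[has_props])
    pred = model.predict(covered, clamp=clamp)
    divisor = pd.Series(1.0, index=table.data.index)
    divisor.loc[pred.index] = pred
    data = table.data.div(divisor, axis=0)
    return AbundanceTable(data=data, stage=Stage.bias_corrected)


def save_bias_model(model: BiasModel, path) -> None:
    """Serialize a model as flat, diffable key-value text."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#scgnorm-bias-model\n")
        fh.write(f"intercept\t{model.intercept:.15g}\n")
        fh.write(f"alpha\t{model.alpha:.15g}\n")
        fh.write(f"l1_ratio\t{model.l1_ratio:.15g}\n")
        fh.write(f"heldout_r2\t{model.heldout_r2:.15g}\n")
        fh.write(f"scope\t{model.scope}\n")
        fh.write("#property\tweight\tmean\tsd\tmedian\n")
        for prop in model.weights.index:
            fh.write(
                f"{prop}\t{model.weights[prop]:.15g}\t{model.prop_means[prop]:.15g}"
                f"\t{model.prop_sds[prop]:.15g}\t{model.prop_medians[prop]:.15g}\n"
            )


def load_bias_model(path) -> BiasModel:
    scalars: dict[str, str] = {}
    props, w, m, s, med = [], [], [], [], []
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                scalars[fields[0]] = fields[1]
            elif len(fields) == 5:
                props.append(fields[0])
                w.append(float(fields[1]))
                m.append(float(fields[2]))
                s.append(float(fields[3]))
                med.append(float(fields[4]))
            else:
                raise ValueError(f"malformed model line: {line!r}")
    idx = pd.Index(props)
    return BiasModel(
        intercept=float(scalars["intercept"]),
        weights=pd.Series(w, index=idx),
        prop_means=pd.Series(m, index=idx),
        prop_sds=pd.Series(s, index=idx),
        prop_medians=pd.Series(med, index=idx),
        alpha=float(scalars["alpha"]),
        l1_ratio=float(scalars["l1_ratio"]),
        heldout_r2=float(scalars["heldout_r2"]),
        scope=scalars.get("scope", "per_sample"),
    )
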
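"""Differential expression channel.

Per-dataset normalization, fixed-prior moderated two-group t-statistics,
Benjamini-Hochberg adjustment, up-regulated DEG calling and the union
indicator across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataFormatError

log = logging.getLogger(__name__)

GROUPS = ("normal", "tumor")

#: If the data maximum exceeds this the matrix is assumed linear-scale
#: and log2(x + 1) is applied before centering.
LINEAR_SCALE_MAX = 50.0


@dataclass
class ExpressionMatrix:
    """A log2-scale genes x samples matrix with two-group sample labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
    groups
        Series mapping each sample identifier to ``"normal"`` or ``"tumor"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise DataFormatError(f"duplicate gene identifiers: {list(dupes)[:5]}")
        if list(self.groups.index) != list(self.values.columns):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise DataFormatError(f"samples without group label: {missing[:5]}")
        bad = sorted(set(self.groups) - set(GROUPS))
        if bad:
            raise DataFormatError(f"unknown group labels: {bad}")
        for g in GROUPS:
            if (self.groups == g).sum() < 2:
                raise ConfigError(
                    f"group {g!r} has fewer than 2 samples; variance undefined"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> pd.DataFrame:
        return self.values.loc[:, self.groups[self.groups == group].index]


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-center every sample column to the global median.

    Linear-scale input (max > 50) is log2(x+1) transformed first. Gene
    order is preserved; the planted/biological group-mean difference is
    invariant to this per-column shift.
    """
    values = matrix.values.astype(float)
    if not np.isfinite(values.to_numpy()).all():
        bad = values.columns[~np.isfinite(values.to_numpy()).all(axis=0)]
        raise DataFormatError(f"non-finite values in samples: {list(bad)}")
    if values.to_numpy().max() > LINEAR_SCALE_MAX:
        if (values.to_numpy() < 0).any():
            raise DataFormatError("linear-scale data contain negative values")
        values = np.log2(values + 1.0)
    global_median = float(np.median(values.to_numpy()))
    centered = values - values.median(axis=0) + global_median
    arr = centered.to_numpy()
    if not np.isfinite(arr).all():
        bad = centered.columns[~np.isfinite(arr).all(axis=0)]
        raise DataFormatError(f"non-finite values after normalization in samples: {list(bad)}")
    return ExpressionMatrix(values=centered, groups=matrix.groups.copy())


def moderated_t(
    matrix: ExpressionMatrix,
    prior_df: float = 4.0,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Fixed-prior moderated two-sample t-statistics, tumor vs normal.

    Per gene, the pooled residual variance ``s2`` with ``d = n1 + n2 - 2``
    degrees of freedom is shrunk toward a prior::

        s2_tilde = (d0 * s0 + d * s2) / (d0 + d)
        t = logFC / sqrt(s2_tilde * (1/n1 + 1/n2))

    with a two-sided p-value from a t distribution on ``d0 + d`` degrees
    of freedom. ``prior_var`` defaults to the median of the per-gene
    pooled variances; ``prior_df = 0`` reduces exactly to the ordinary
    pooled t-test.

    Returns a DataFrame indexed by gene with columns
    ``logFC, t, df, p, s2, s2_shrunk``.
    """
    if prior_df < 0:
        raise ConfigError(f"prior_df must be >= 0, got {prior_df}")
    normal = matrix.samples_in("normal").to_numpy()
    tumor = matrix.samples_in("tumor").to_numpy()
    n1, n2 = normal.shape[1], tumor.shape[1]
    d = n1 + n2 - 2

    logfc = tumor.mean(axis=1) - normal.mean(axis=1)
    ss = normal.var(axis=1, ddof=1) * (n1 - 1) + tumor.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d
    if prior_var is None:
        prior_var = float(np.median(s2))
    if prior_var < 0:
        raise ConfigError(f"prior_var must be >= 0, got {prior_var}")

    s2_shrunk = (prior_df * prior_var + d * s2) / (prior_df + d)
    scale = np.sqrt(s2_shrunk * (1.0 / n1 + 1.0 / n2))
    df_total = prior_df + d

    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / scale
    p = np.empty_like(t)
    degenerate = scale == 0.0
    if degenerate.any():
        n_flag = int((degenerate & (logfc != 0)).sum())
        if n_flag:
            log.warning(
                "%d genes with zero shrunken variance and nonzero logFC; "
                "p set to minimum representable",
                n_flag,
            )
        t[degenerate] = np.where(logfc[degenerate] != 0, np.sign(logfc[degenerate]) * np.inf, 0.0)
        p[degenerate] = np.where(logfc[degenerate] != 0, np.finfo(float).tiny, 1.0)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total)

    return pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "df": df_total,
            "p": p,
            "s2": s2,
            "s2_shrunk": s2_shrunk,
        },
        index=matrix.gene_ids,
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adj_p(i) = min_{rank(j) >= rank(i)} min(1, m * p(j) / rank(j)).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ConfigError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        bad = p[~np.isfinite(p) | (p < 0) | (p > 1)]
        raise ConfigError(f"p-values outside [0, 1]: {bad[:5]}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_up_degs(
    result: pd.DataFrame,
    adj_p_max: float = 0.05,
    logfc_min: float = 2.0,
    absolute_logfc: bool = False,
) -> set[str]:
    """Genes with adj_p strictly below the cutoff and logFC strictly above it.

    Up-regulated only by default; ``absolute_logfc`` switches to |logFC|.
    Ties at exactly the cutoffs are excluded and logged.
    """
    required = {"adj_p", "logFC"}
    if not required <= set(result.columns):
        raise ConfigError(f"result lacks columns {sorted(required - set(result.columns))}")
    fc = result["logFC"].abs() if absolute_logfc else result["logFC"]
    mask = (result["adj_p"] < adj_p_max) & (fc > logfc_min)
    ties = ((result["adj_p"] == adj_p_max) & (fc > logfc_min)) | (
        (result["adj_p"] < adj_p_max) & (fc == logfc_min)
    )
    if ties.any():
        log.warning("%d genes at exact cutoff excluded (strict inequalities)", int(ties.sum()))
    return set(result.index[mask])


def differential_expression(
    matrix: ExpressionMatrix,
    adj_p_max: float = 0.05,
    logfc_min: float = 2.0,
    prior_df: float = 4.0,
    prior_var: float | None = None,
    absolute_logfc: bool = False,
) -> pd.DataFrame:
    """Normalize, test, adjust and flag one dataset; returns the full table."""
    table = moderated_t(normalize(matrix), prior_df=prior_df, prior_var=prior_var)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    up = call_up_degs(table, adj_p_max=adj_p_max, logfc_min=logfc_min, absolute_logfc=absolute_logfc)
    table["up_flag"] = table.index.isin(sorted(up))
    return table


def geo_channel_indicator(
    per_dataset_deg_sets: Iterable[set[str]], universe: Sequence[str]
) -> pd.Series:
    """Union rule: 1 iff the gene is an up-DEG in at least one dataset."""
    sets = list(per_dataset_deg_sets)
    if not sets:
        raise ConfigError("at least one dataset DEG set is required")
    union = set().union(*sets)
    idx = pd.Index(universe, name="gene")
    return pd.Series(idx.isin(union).astype(np.int8), index=idx, name="geo")
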
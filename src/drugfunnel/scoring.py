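"""Five-channel gene scoring.

Aggregates the binary channel indicators into the 0-5 score, applies the
score >= 2 risk rule, and produces diagnostics: channel correlations,
exclusive/intersection (Venn) counts and the sorted top-gene table.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

log = logging.getLogger(__name__)

CHANNELS = ("kegg", "bp", "ko", "glad4u", "geo")
DEFAULT_SCORE_MIN = 2


def aggregate_scores(
    indicators: Mapping[str, pd.Series],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Build the per-gene indicator table with score and risk flag.

    ``indicators`` maps each channel name in :data:`CHANNELS` to a binary
    Series indexed by gene; all five must cover the universe. The result
    has one row per universe gene, columns for the five channels plus
    ``score`` (row sum) and ``risk_flag`` (score >= 2), sorted by score
    descending then gene symbol ascending.
    """
    missing_channels = sorted(set(CHANNELS) - set(indicators))
    if missing_channels:
        raise ConfigError(f"missing channels: {missing_channels}")
    idx = pd.Index(universe, name="gene")
    if idx.has_duplicates:
        raise ConfigError("universe contains duplicate genes")
    table = pd.DataFrame(index=idx)
    for channel in CHANNELS:
        vec = indicators[channel].reindex(idx)
        if vec.isna().any():
            absent = sorted(idx[vec.isna()])
            raise ConfigError(
                f"channel {channel!r} does not cover the universe; "
                f"missing genes: {absent[:10]}"
            )
        values = vec.astype(int)
        if not values.isin((0, 1)).all():
            raise ConfigError(f"channel {channel!r} indicator is not binary")
        table[channel] = values.astype(np.int8)
    table["score"] = table[list(CHANNELS)].sum(axis=1).astype(np.int8)
    table["risk_flag"] = table["score"] >= DEFAULT_SCORE_MIN
    out = table.reset_index()
    out = out.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return out.set_index("gene")


def select_risk_genes(table: pd.DataFrame, score_min: int = DEFAULT_SCORE_MIN) -> set[str]:
    """Genes whose aggregate score is at least ``score_min``."""
    if "score" not in table.columns:
        raise ConfigError("table lacks a 'score' column")
    return set(table.index[table["score"] >= score_min])


def channel_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson (phi) correlation between the five binary channel vectors.

    Constant channels yield NaN rows/columns with a warning; the diagonal
    is 1 for non-constant channels.
    """
    if len(table) < 2:
        raise ConfigError("correlation requires at least 2 genes")
    data = table[list(CHANNELS)].astype(float)
    constant = [c for c in CHANNELS if data[c].nunique() <= 1]
    if constant:
        log.warning("constant channels, correlation undefined: %s", constant)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = data.corr(method="pearson")
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


def venn_counts(table: pd.DataFrame) -> dict:
    """Exclusive per-channel counts and the all-five intersection count.

    ``exclusive[c]`` counts genes whose only positive indicator is
    channel ``c`` (score exactly 1); ``all_five`` counts genes positive
    in every channel (score 5).
    """
    data = table[list(CHANNELS)]
    score = data.sum(axis=1)
    exclusive = {
        c: int(((data[c] == 1) & (score == 1)).sum()) for c in CHANNELS
    }
    return {"exclusive": exclusive, "all_five": int((score == len(CHANNELS)).sum())}


def top_table(table: pd.DataFrame, n: int = 30) -> pd.DataFrame:
    """The first ``n`` rows of the sorted indicator table (display helper)."""
    return table.head(n)
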
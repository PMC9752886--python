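"""Over-representation analysis for the annotation channels.

Hypergeometric set-level tests against a channel-specific annotation
universe, Benjamini-Hochberg FDR within the channel, and the per-gene
channel indicator (membership in at least one significant set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_adjust
from .errors import ConfigError

log = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "set_name",
    "set_size",
    "overlap",
    "query_size",
    "universe_size",
    "p",
    "fdr",
    "significant",
)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets of one annotation channel.

    ``annotation_universe`` is the channel's reference pool (all genes
    annotatable in the channel); every set must be contained in it. When
    built from a bare GMT file it defaults to the union of the sets.
    """

    channel_name: str
    sets: Mapping[str, frozenset[str]]
    annotation_universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        sets = {name: frozenset(members) for name, members in self.sets.items()}
        object.__setattr__(self, "sets", sets)
        universe = self.annotation_universe
        if not universe:
            universe = frozenset().union(*sets.values()) if sets else frozenset()
            object.__setattr__(self, "annotation_universe", universe)
        for name, members in sets.items():
            if not members <= universe:
                stray = sorted(members - universe)
                raise ConfigError(
                    f"set {name!r} in channel {self.channel_name!r} contains genes "
                    f"outside the annotation universe: {stray[:5]}"
                )

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_upper_tail(x: int, K: int, M: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(M, K, n), computed via scipy.

    ``M`` population size, ``K`` marked genes (set size), ``n`` draws
    (query size), ``x`` observed overlap.
    """
    if not (0 <= K <= M and 0 <= n <= M):
        raise ConfigError(f"invalid hypergeometric bounds: K={K}, M={M}, n={n}")
    if not 0 <= x <= min(K, n):
        raise ConfigError(f"overlap x={x} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(x - 1, M, K, n))


def enrich_collection(
    query: Iterable[str],
    collection: GeneSetCollection,
    min_set_size: int = 5,
    max_set_size: int = 2000,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Test every admissible set of one channel against the query.

    Sets outside the size window are excluded before testing; the
    hypergeometric universe is the channel's annotation universe and the
    effective query is its intersection with that universe. BH adjustment
    is done across the tested sets of this channel only.
    """
    if min_set_size > max_set_size:
        raise ConfigError(f"min_set_size {min_set_size} > max_set_size {max_set_size}")
    universe = collection.annotation_universe
    effective_query = frozenset(query) & universe
    n = len(effective_query)
    M = len(universe)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        if not min_set_size <= K <= max_set_size:
            continue
        x = len(members & effective_query)
        rows.append((name, K, x, n, M))
    if n == 0:
        log.warning(
            "channel %s: query has no overlap with annotation universe; empty result",
            collection.channel_name,
        )
        rows = []
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS).astype(
            {"p": float, "fdr": float, "significant": bool}, errors="ignore"
        )
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "query_size", "universe_size"])
    out["p"] = [
        hypergeom_upper_tail(x, K, M, n)
        for _, K, x, n, M in out.itertuples(index=False)
    ]
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_max
    return out


def channel_indicator(
    query: Iterable[str],
    result: pd.DataFrame,
    collection: GeneSetCollection,
) -> pd.Series:
    """1 iff the query gene belongs to at least one significant set."""
    query_genes = pd.Index(sorted(set(query)), name="gene")
    if result.empty:
        hits: frozenset[str] = frozenset()
    else:
        significant = result.loc[result["significant"], "set_name"]
        hits = frozenset().union(
            *(collection.sets[name] for name in significant)
        ) if len(significant) else frozenset()
    values = query_genes.isin(hits).astype(np.int8)
    return pd.Series(values, index=query_genes, name=collection.channel_name.lower())
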
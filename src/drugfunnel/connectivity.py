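"""Connectivity scoring of compound rank profiles against a reference.

A two-tailed signature is taken from the extremes of the reference
compound's ranking; each compound's profile is scored by an unweighted
Kolmogorov-Smirnov running-sum enrichment for the up and down sets, the
two are combined into ``w`` (zero when concordant), and ``w`` is
percentile-normalized against a background panel of compound scores to
the tau scale [-100, 100]. Candidates keep w > 0 and tau above the
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, StageError

log = logging.getLogger(__name__)

DEFAULT_SIGNATURE_SIZE = 150
DEFAULT_TAU_MIN = 80.0
REFERENCE_CELL_LINES = ("A549", "MCF7", "PC3")


@dataclass(frozen=True)
class RankProfile:
    """A complete ranking of the profiled gene space for one compound.

    ``ranking`` maps gene -> rank, a bijection onto 1..N with rank 1 the
    most up-regulated gene.
    """

    compound: str
    cell_line: str
    ranking: pd.Series

    def __post_init__(self) -> None:
        ranks = self.ranking.to_numpy()
        n = len(ranks)
        if n == 0:
            raise ConfigError(f"profile {self.compound}:{self.cell_line} is empty")
        if self.ranking.index.has_duplicates:
            raise ConfigError(f"profile {self.compound}:{self.cell_line} has duplicate genes")
        if not np.array_equal(np.sort(ranks), np.arange(1, n + 1)):
            raise ConfigError(
                f"profile {self.compound}:{self.cell_line} ranking is not a "
                f"bijection onto 1..{n}"
            )

    def __len__(self) -> int:
        return len(self.ranking)

    def genes_at_ranks(self, ranks: Iterable[int]) -> frozenset[str]:
        wanted = set(ranks)
        return frozenset(self.ranking.index[self.ranking.isin(wanted)])


@dataclass(frozen=True)
class Signature:
    """Paired up/down gene sets from the extremes of a reference ranking."""

    up_set: frozenset[str]
    down_set: frozenset[str]
    q: int

    def __post_init__(self) -> None:
        if self.up_set & self.down_set:
            raise ConfigError("up_set and down_set overlap")
        if len(self.up_set) != self.q or len(self.down_set) != self.q:
            raise ConfigError("signature sets must both have size q")


def build_signature(reference: RankProfile, q: int = DEFAULT_SIGNATURE_SIZE) -> Signature:
    """Top q ranks as the up set, bottom q ranks as the down set."""
    n = len(reference)
    if q < 1:
        raise ConfigError(f"signature size q must be >= 1, got {q}")
    if n < 2 * q:
        raise ConfigError(
            f"profile length {n} < 2q = {2 * q}; use a smaller signature size q"
        )
    up = reference.genes_at_ranks(range(1, q + 1))
    down = reference.genes_at_ranks(range(n - q + 1, n + 1))
    return Signature(up_set=up, down_set=down, q=q)


def ks_enrichment(gene_set: Iterable[str], profile: RankProfile) -> float:
    """Unweighted KS running-sum enrichment of a gene set in a profile.

    With r_1 < ... < r_n the sorted ranks of the set members and N the
    profile length:

        a = max_j (j/n - r_j/N),  b = max_j (r_j/N - (j-1)/n)
        es = a if a > b else -b
    """
    members = set(gene_set)
    if not members:
        raise ConfigError("gene_set is empty")
    missing = members - set(profile.ranking.index)
    if missing:
        raise ConfigError(
            f"genes absent from profile {profile.compound}:{profile.cell_line}: "
            f"{sorted(missing)[:5]}"
        )
    n_total = len(profile)
    ranks = np.sort(profile.ranking.loc[sorted(members)].to_numpy())
    n = ranks.size
    if n == n_total:
        log.warning("gene_set covers the whole profile; es degenerates to -1/N")
    j = np.arange(1, n + 1)
    a = float(np.max(j / n - ranks / n_total))
    b = float(np.max(ranks / n_total - (j - 1) / n))
    return a if a > b else -b


def combined_score(es_up: float, es_down: float) -> float:
    """Two-tailed combination: (es_up - es_down)/2 when discordant, else 0.

    A zero enrichment score is treated as discordant with any nonzero one
    so pure one-tailed signal is retained; two zeros give 0.
    """
    for name, value in (("es_up", es_up), ("es_down", es_down)):
        if not -1.0 <= value <= 1.0:
            raise ConfigError(f"{name} outside [-1, 1]: {value}")
    if es_up == 0.0 and es_down == 0.0:
        return 0.0
    if es_up * es_down > 0.0:
        return 0.0
    if es_up == 0.0 or es_down == 0.0:
        log.debug("zero-sign combination triggered (es_up=%g, es_down=%g)", es_up, es_down)
    return (es_up - es_down) / 2.0


def tau_normalize(w: float, background: Sequence[float]) -> float:
    """Signed percentile of |w| against the background |w| values.

    tau = sign(w) * 100 * #{b in background : |b| < |w|} / len(background).
    """
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ConfigError("tau background is empty")
    if w == 0.0:
        return 0.0
    frac = float(np.count_nonzero(np.abs(bg) < abs(w))) / bg.size
    return float(np.sign(w)) * 100.0 * frac


def score_compounds(
    profiles: Iterable[RankProfile],
    reference: str,
    cell_line: str = "MCF7",
    q: int = DEFAULT_SIGNATURE_SIZE,
    background_compounds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score every non-reference compound of one cell line against the
    reference compound's signature.

    ``background_compounds`` names the touchstone panel whose w values
    form the tau background (the scored compound is left out of its own
    background when it is a panel member); by default the background is
    all scored compounds, leave-one-out.

    Returns a DataFrame with columns ``compound, cell_line, es_up,
    es_down, w, tau`` sorted by tau descending, compound ascending.
    """
    pool = [p for p in profiles if p.cell_line == cell_line]
    names = [p.compound for p in pool]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigError(f"duplicate compound profiles in cell line {cell_line}: {dupes}")
    by_name: Mapping[str, RankProfile] = {p.compound: p for p in pool}
    if reference not in by_name:
        raise StageError(f"reference compound {reference!r} has no profile in {cell_line}")
    signature = build_signature(by_name[reference], q=q)

    scored = {}
    for name, profile in by_name.items():
        if name == reference:
            continue
        es_up = ks_enrichment(signature.up_set, profile)
        es_down = ks_enrichment(signature.down_set, profile)
        scored[name] = (es_up, es_down, combined_score(es_up, es_down))
    if not scored:
        return pd.DataFrame(columns=["compound", "cell_line", "es_up", "es_down", "w", "tau"])

    if background_compounds is None:
        bg_names = sorted(scored)
    else:
        bg_names = [str(c) for c in background_compounds]
        missing = sorted(set(bg_names) - set(scored))
        if missing:
            raise ConfigError(f"background compounds without scores: {missing[:5]}")
    bg_w = {name: scored[name][2] for name in bg_names}

    rows = []
    for name in sorted(scored):
        es_up, es_down, w = scored[name]
        background = [v for other, v in bg_w.items() if other != name]
        if not background:
            raise ConfigError("tau background is empty after leave-one-out")
        rows.append((name, cell_line, es_up, es_down, w, tau_normalize(w, background)))
    out = pd.DataFrame(rows, columns=["compound", "cell_line", "es_up", "es_down", "w", "tau"])
    return out.sort_values(["tau", "compound"], ascending=[False, True], kind="mergesort").reset_index(drop=True)


def rank_and_filter(
    results: pd.DataFrame,
    threshold: float = DEFAULT_TAU_MIN,
    strict: bool = True,
) -> pd.DataFrame:
    """Positivity filter then the tau cutoff, sorted for reporting.

    Keeps rows with w > 0 first, then tau strictly above ``threshold``
    (or >= when ``strict`` is False); sorts by tau descending with ties
    broken by compound name.
    """
    required = {"compound", "w", "tau"}
    if not required <= set(results.columns):
        raise ConfigError(f"results lack columns {sorted(required - set(results.columns))}")
    positive = results.loc[results["w"] > 0]
    if strict:
        kept = positive.loc[positive["tau"] > threshold]
    else:
        kept = positive.loc[positive["tau"] >= threshold]
    return kept.sort_values(
        ["tau", "compound"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
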
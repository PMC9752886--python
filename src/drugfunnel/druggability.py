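"""Drug-target intersection: risk genes -> druggable genes and drug pool."""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .errors import DataFormatError

log = logging.getLogger(__name__)

STATUSES = frozenset({"approved", "clinical", "experimental", "withdrawn"})
DEFAULT_ALLOWED = frozenset({"approved", "clinical", "experimental"})
MAP_COLUMNS = ("drug", "target", "status", "action")


def validate_drug_target_map(table: pd.DataFrame) -> pd.DataFrame:
    """Check column layout, status vocabulary and (drug, target) uniqueness.

    Drug names are whitespace-normalized and matched case-insensitively
    for deduplication; the original casing is kept for display.
    """
    missing = sorted(set(MAP_COLUMNS) - set(table.columns))
    if missing:
        raise DataFormatError(f"drug-target map lacks columns {missing}")
    table = table.loc[:, list(MAP_COLUMNS)].copy()
    table["drug"] = table["drug"].astype(str).str.strip().str.replace(r"\s+", " ", regex=True)
    table["target"] = table["target"].astype(str).str.strip()
    if (table["drug"] == "").any() or (table["target"] == "").any():
        bad = table.index[(table["drug"] == "") | (table["target"] == "")]
        raise DataFormatError(f"empty drug or target name at rows {list(bad)[:5]}")
    unknown = table.loc[~table["status"].isin(STATUSES)]
    if not unknown.empty:
        rec = unknown.iloc[0]
        raise DataFormatError(
            f"unknown status {rec['status']!r} for record "
            f"({rec['drug']!r}, {rec['target']!r})"
        )
    key = table["drug"].str.casefold() + "\t" + table["target"]
    if key.duplicated().any():
        rec = table.loc[key.duplicated()].iloc[0]
        raise DataFormatError(
            f"duplicate (drug, target) pair: ({rec['drug']!r}, {rec['target']!r})"
        )
    return table


def filter_drug_status(
    table: pd.DataFrame, allowed_statuses: Iterable[str] = DEFAULT_ALLOWED
) -> pd.DataFrame:
    """Keep records whose status is allowed (withdrawn excluded by default)."""
    table = validate_drug_target_map(table)
    allowed = frozenset(allowed_statuses)
    bad = sorted(allowed - STATUSES)
    if bad:
        raise DataFormatError(f"unknown status tokens in allowed_statuses: {bad}")
    return table.loc[table["status"].isin(allowed)].reset_index(drop=True)


def map_risk_to_drugs(
    risk_genes: Iterable[str], table: pd.DataFrame
) -> tuple[set[str], pd.DataFrame]:
    """Intersect risk genes with the (already filtered) drug-target map.

    Returns the druggable gene set (risk genes that are a recorded target)
    and a one-row-per-drug table with the drug's full in-risk target list.
    """
    table = validate_drug_target_map(table)
    risk = set(risk_genes)
    if not risk:
        log.warning("empty risk gene set; no druggable genes or candidate drugs")
        return set(), pd.DataFrame(columns=["drug", "targets"])
    hits = table.loc[table["target"].isin(risk)]
    druggable = set(hits["target"])
    if hits.empty:
        return druggable, pd.DataFrame(columns=["drug", "targets"])
    grouped = (
        hits.groupby("drug", sort=True)["target"]
        .apply(lambda s: tuple(sorted(set(s))))
        .reset_index()
        .rename(columns={"target": "targets"})
    )
    return druggable, grouped
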
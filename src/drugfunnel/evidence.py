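"""Evidence triage and the final candidate report.

Each candidate drug is classified into exactly one evidence class:
``Phase k`` (highest trial phase on record), ``preclinical``
(publications only) or ``none``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataFormatError, StageError

TRIAL = "trial"
PUBLICATION = "publication"
VALID_PHASES = (1, 2, 3, 4)
EVIDENCE_CLASSES = ("clinical", "preclinical", "none")


@dataclass(frozen=True)
class EvidenceRecord:
    """One registry entry: a trial (with phase) or a publication."""

    kind: str
    identifier: str
    phase: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (TRIAL, PUBLICATION):
            raise DataFormatError(f"unknown evidence kind {self.kind!r}")
        if not self.identifier:
            raise DataFormatError("evidence identifier must be nonempty")
        if self.kind == TRIAL:
            if self.phase not in VALID_PHASES:
                raise DataFormatError(f"invalid trial phase {self.phase!r}")
        elif self.phase is not None:
            raise DataFormatError("publication records carry no phase")


@dataclass
class EvidenceRegistry:
    """Drug -> evidence records; drugs may be registered with none."""

    records: dict[str, list[EvidenceRecord]] = field(default_factory=dict)

    def add(self, drug: str, record: EvidenceRecord) -> None:
        self.records.setdefault(drug, []).append(record)

    def register(self, drug: str) -> None:
        self.records.setdefault(drug, [])

    def get(self, drug: str) -> list[EvidenceRecord]:
        return self.records.get(drug, [])

    def drugs(self) -> list[str]:
        return sorted(self.records)


def classify_evidence(drug: str, registry: EvidenceRegistry) -> tuple[str, tuple[str, ...]]:
    """Evidence level and supporting identifiers for one drug.

    Trials take precedence over publications: any trial record yields
    ``"Phase k"`` with k the maximum phase and all trial IDs; otherwise
    publications yield ``"preclinical"`` with the literature IDs; an
    empty record list yields ``("none", ())``.
    """
    try:
        records = registry.get(drug)
    except DataFormatError as exc:  # pragma: no cover - defensive
        raise DataFormatError(f"malformed evidence record for {drug!r}: {exc}") from exc
    trials = [r for r in records if r.kind == TRIAL]
    if trials:
        top = max(r.phase for r in trials)  # type: ignore[type-var]
        return f"Phase {top}", tuple(r.identifier for r in trials)
    publications = [r for r in records if r.kind == PUBLICATION]
    if publications:
        return "preclinical", tuple(r.identifier for r in publications)
    return "none", ()


def evidence_class(level: str) -> str:
    """Collapse a level label to clinical / preclinical / none."""
    if level.startswith("Phase"):
        return "clinical"
    if level in ("preclinical", "none"):
        return level
    raise DataFormatError(f"unknown evidence level {level!r}")


@dataclass
class CandidateReport:
    """The final report table plus summary counts and the drug-target edges."""

    table: pd.DataFrame
    summary: dict[str, int]
    edges: pd.DataFrame


def build_candidate_report(
    candidates: pd.DataFrame,
    drug_targets: Mapping[str, Sequence[str]],
    registry: EvidenceRegistry,
    indications: Mapping[str, str] | None = None,
) -> CandidateReport:
    """Assemble the per-candidate report, evidence summary and edge list.

    ``candidates`` must carry ``compound`` and ``tau`` columns (the
    output of the ranking filter); every candidate must appear in
    ``drug_targets``. One row per drug sorted by tau descending; the edge
    list has one (target, drug, evidence class) row per drug-target link.
    """
    required = {"compound", "tau"}
    if not required <= set(candidates.columns):
        raise StageError(f"candidates lack columns {sorted(required - set(candidates.columns))}")
    missing = sorted(set(candidates["compound"]) - set(drug_targets))
    if missing:
        raise StageError(f"candidate drugs missing from the drug-target input: {missing}")
    indications = indications or {}

    rows = []
    edge_rows = []
    counts: Counter[str] = Counter({c: 0 for c in EVIDENCE_CLASSES})
    ordered = candidates.sort_values(
        ["tau", "compound"], ascending=[False, True], kind="mergesort"
    )
    for rec in ordered.itertuples(index=False):
        drug = rec.compound
        level, ids = classify_evidence(drug, registry)
        cls = evidence_class(level)
        counts[cls] += 1
        targets = tuple(drug_targets[drug])
        rows.append(
            {
                "drug": drug,
                "original_indication": indications.get(drug, ""),
                "tau": rec.tau,
                "targets": ";".join(targets),
                "evidence_level": level,
                "evidence_ids": ";".join(ids),
            }
        )
        for target in targets:
            edge_rows.append({"target": target, "drug": drug, "evidence_class": cls})

    table = pd.DataFrame(rows, columns=[
        "drug", "original_indication", "tau", "targets", "evidence_level", "evidence_ids",
    ])
    edges = pd.DataFrame(edge_rows, columns=["target", "drug", "evidence_class"])
    return CandidateReport(table=table, summary=dict(counts), edges=edges)
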
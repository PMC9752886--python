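"""Readers and writers for the plain-text exchange formats.

Formats: gene list (one symbol per line), GMT (tab-separated set name,
description, members), expression TSV with a sidecar label file,
drug-target TSV, rank-profile TSV (one integer-rank column per
compound:cell-line), evidence TSV and the report CSV. All files are
UTF-8; gene symbols are whitespace-trimmed on read. write(read(x)) is
the identity on the canonical in-memory form.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import RankProfile
from .deg import ExpressionMatrix
from .druggability import MAP_COLUMNS, validate_drug_target_map
from .errors import DataFormatError
from .evidence import EvidenceRecord, EvidenceRegistry
from .ora import GeneSetCollection

PROFILE_SEPARATOR = ":"


# -- gene lists -------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    genes = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        symbol = line.strip()
        if not symbol:
            continue
        if "\t" in symbol:
            raise DataFormatError(f"{path}:{lineno}: gene list line contains a tab: {line!r}")
        genes.append(symbol)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


# -- GMT --------------------------------------------------------------------

def read_gmt(path: str | Path, channel_name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file; the annotation universe defaults to the set union."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataFormatError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated columns, got "
                f"{len(fields)}: {line!r}"
            )
        name = fields[0].strip()
        if not name:
            raise DataFormatError(f"{path}:{lineno}: empty set name: {line!r}")
        if name in sets:
            raise DataFormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = [f.strip() for f in fields[2:] if f.strip()]
        if not members:
            raise DataFormatError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = frozenset(members)
    return GeneSetCollection(
        channel_name=channel_name or Path(path).stem,
        sets=sets,
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in sorted(collection.sets):
        members = sorted(collection.sets[name])
        lines.append("\t".join([name, collection.channel_name, *members]))
    Path(path).write_text("".join(f"{line}\n" for line in lines), encoding="utf-8")


# -- expression matrices ----------------------------------------------------

def _labels_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".labels.tsv")


def read_expression(
    path: str | Path, labels_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read an expression TSV (first column = gene) plus its label sidecar."""
    path = Path(path)
    labels_path = Path(labels_path) if labels_path else _labels_path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    values = pd.DataFrame(index=raw.index.rename("gene"), columns=raw.columns, dtype=float)
    for column in raw.columns:
        converted = pd.to_numeric(raw[column], errors="coerce")
        bad = converted.isna() & raw[column].notna()
        if bad.any():
            gene = raw.index[bad][0]
            raise DataFormatError(
                f"{path}: non-numeric value {raw.loc[gene, column]!r} "
                f"at gene {gene!r}, sample {column!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna()][0]
            raise DataFormatError(f"{path}: missing value at gene {gene!r}, sample {column!r}")
        values[column] = converted
    labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0].astype(str)
    return ExpressionMatrix(values=values, groups=labels.rename("group"))


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, labels_path: str | Path | None = None
) -> None:
    path = Path(path)
    labels_path = Path(labels_path) if labels_path else _labels_path(path)
    matrix.values.rename_axis("gene").to_csv(path, sep="\t")
    matrix.groups.rename_axis("sample").rename("group").to_csv(labels_path, sep="\t")


# -- drug-target maps -------------------------------------------------------

def read_drug_target_map(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = sorted(set(MAP_COLUMNS) - set(table.columns))
    if missing:
        raise DataFormatError(f"{path}: drug-target table lacks columns {missing}")
    try:
        return validate_drug_target_map(table)
    except DataFormatError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_drug_target_map(table: pd.DataFrame, path: str | Path) -> None:
    validate_drug_target_map(table).to_csv(path, sep="\t", index=False)


# -- rank profiles ----------------------------------------------------------

def read_rank_profiles(path: str | Path) -> list[RankProfile]:
    """Read a GCT-like TSV: gene column plus one ``compound:cell`` column each."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str).str.strip()
    profiles = []
    for column in table.columns:
        if PROFILE_SEPARATOR not in column:
            raise DataFormatError(
                f"{path}: column {column!r} is not of the form 'compound:cell_line'"
            )
        compound, cell_line = column.rsplit(PROFILE_SEPARATOR, 1)
        ranks = table[column]
        if not np.issubdtype(ranks.dtype, np.number) or (ranks != ranks.astype(int)).any():
            raise DataFormatError(f"{path}: column {column!r} contains non-integer ranks")
        profiles.append(
            RankProfile(
                compound=compound.strip(),
                cell_line=cell_line.strip(),
                ranking=ranks.astype(np.int64).rename(None),
            )
        )
    return profiles


def write_rank_profiles(profiles: Sequence[RankProfile], path: str | Path) -> None:
    if not profiles:
        raise DataFormatError("cannot write an empty profile set")
    genes = profiles[0].ranking.index
    columns = {}
    for profile in profiles:
        if not profile.ranking.index.equals(genes):
            raise DataFormatError(
                f"profile {profile.compound}:{profile.cell_line} has a different gene space"
            )
        key = f"{profile.compound}{PROFILE_SEPARATOR}{profile.cell_line}"
        if key in columns:
            raise DataFormatError(f"duplicate profile column {key!r}")
        columns[key] = profile.ranking.to_numpy()
    frame = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    frame.to_csv(path, sep="\t")


# -- evidence registries ----------------------------------------------------

def read_evidence(path: str | Path) -> EvidenceRegistry:
    """Read an evidence TSV (drug, kind, phase, identifier).

    ``kind`` is ``trial``, ``publication`` or ``none`` (registers the
    drug with an empty record list).
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"drug", "kind", "phase", "identifier"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise DataFormatError(f"{path}: evidence table lacks columns {missing}")
    registry = EvidenceRegistry()
    for lineno, rec in enumerate(table.itertuples(index=False), start=2):
        drug = rec.drug.strip()
        if not drug:
            raise DataFormatError(f"{path}:{lineno}: empty drug name")
        kind = rec.kind.strip()
        if kind == "none":
            registry.register(drug)
            continue
        phase = None
        if kind == "trial":
            try:
                phase = int(rec.phase)
            except ValueError:
                raise DataFormatError(
                    f"{path}:{lineno}: invalid trial phase {rec.phase!r} for {drug!r}"
                ) from None
        try:
            registry.add(drug, EvidenceRecord(kind=kind, phase=phase, identifier=rec.identifier.strip()))
        except DataFormatError as exc:
            raise DataFormatError(f"{path}:{lineno}: {exc}") from exc
    return registry


def write_evidence(registry: EvidenceRegistry, path: str | Path) -> None:
    rows = []
    for drug in registry.drugs():
        records = registry.get(drug)
        if not records:
            rows.append({"drug": drug, "kind": "none", "phase": "", "identifier": ""})
        for record in records:
            rows.append(
                {
                    "drug": drug,
                    "kind": record.kind,
                    "phase": "" if record.phase is None else record.phase,
                    "identifier": record.identifier,
                }
            )
    pd.DataFrame(rows, columns=["drug", "kind", "phase", "identifier"]).to_csv(
        path, sep="\t", index=False
    )
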
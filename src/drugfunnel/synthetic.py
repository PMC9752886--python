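"""Synthetic input generators and the packaged worked-example fixture.

All pipeline inputs can be simulated with the statistical structure the
analysis assumes: a gene universe with a planted risk subset, gene-set
channels enriched for the planted genes, two-group expression with
planted up-regulation, a drug-target map covering a fraction of the risk
genes, compound rank profiles correlated with a designated reference
compound, and an evidence registry.

Every generator is a pure function of (config, seed): identical inputs
give byte-identical serialized outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import RankProfile
from .deg import ExpressionMatrix
from .errors import ConfigError, DataFormatError
from .evidence import EvidenceRecord, EvidenceRegistry
from .ora import GeneSetCollection

#: ORA channel display names, in indicator order (GEO is the fifth channel).
ORA_CHANNELS = ("KEGG", "BP", "KO", "GLAD4U")

DEFAULT_REFERENCE = "gemcitabine"
REFERENCE_CELL_LINES = ("A549", "MCF7", "PC3")

_STAGE_UNIVERSE = 0
_STAGE_SETS = 1
_STAGE_EXPR = 2
_STAGE_DRUGS = 3
_STAGE_PROFILES = 4
_STAGE_EVIDENCE = 5
_STAGE_UP_GENES = 6


@dataclass(frozen=True)
class SimConfig:
    """Generative knobs for all synthetic inputs.

    ``sample_sizes`` holds one (n_normal, n_tumor) pair per expression
    dataset; defaults mirror the four public microarray series used as
    the expression channel (61/69, 42/36, 16/36, 7/15).
    """

    seed: int = 1
    n_genes: int = 895
    n_true_risk: int = 318
    n_sets_per_channel: int = 50
    n_enriched_per_channel: int = 8
    set_size_range: tuple[int, int] = (20, 120)
    enrichment_strength: float = 0.9
    background_multiplier: int = 10
    sample_sizes: tuple[tuple[int, int], ...] = ((61, 69), (42, 36), (16, 36), (7, 15))
    effect_size: float = 4.0
    noise_sd: float = 0.5
    up_fraction: float = 0.4
    druggable_fraction: float = 0.24
    n_compounds: int = 216
    n_profiled_genes: int = 1000
    correlated_compounds: int = 13
    max_transpositions: int = 150
    transposition_window: int | None = None
    n_touchstone: int = 100
    trial_fraction: float = 0.6
    publication_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")
        if not 0 <= self.n_true_risk <= self.n_genes:
            raise ConfigError(
                f"n_true_risk ({self.n_true_risk}) must lie in [0, n_genes={self.n_genes}]"
            )
        for name in (
            "enrichment_strength",
            "up_fraction",
            "druggable_fraction",
            "trial_fraction",
            "publication_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be a fraction in [0, 1], got {value}")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ConfigError(f"invalid set_size_range {self.set_size_range}")
        if self.n_enriched_per_channel > self.n_sets_per_channel:
            raise ConfigError("n_enriched_per_channel exceeds n_sets_per_channel")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_profiled_genes < 2:
            raise ConfigError("n_profiled_genes must be >= 2")
        if not 0 <= self.correlated_compounds <= self.n_compounds:
            raise ConfigError("correlated_compounds must lie in [0, n_compounds]")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {unknown}")
        kwargs = dict(raw)
        if "set_size_range" in kwargs:
            kwargs["set_size_range"] = tuple(kwargs["set_size_range"])
        if "sample_sizes" in kwargs:
            kwargs["sample_sizes"] = tuple(tuple(p) for p in kwargs["sample_sizes"])
        return cls(**kwargs)


def _rng(cfg: SimConfig, *stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *stage])


def _gene_names(prefix: str, count: int, width: int) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(1, count + 1)]


def gen_gene_universe(cfg: SimConfig) -> tuple[list[str], set[str]]:
    """Synthetic gene universe plus the hidden planted risk-gene labels."""
    genes = _gene_names("G", cfg.n_genes, max(4, len(str(cfg.n_genes))))
    rng = _rng(cfg, _STAGE_UNIVERSE)
    risk = set(rng.choice(genes, size=cfg.n_true_risk, replace=False))
    return genes, risk


def background_genes(cfg: SimConfig) -> list[str]:
    """Annotation-only genes: present in gene sets but never in the universe."""
    count = cfg.background_multiplier * cfg.n_genes
    return _gene_names("B", count, max(6, len(str(count))))


def gen_geneset_collections(
    cfg: SimConfig,
    universe: Sequence[str],
    risk_genes: Iterable[str],
) -> dict[str, GeneSetCollection]:
    """Four annotation channels with planted-enrichment structure.

    Enriched sets (names ``<CH>_E...``) draw an ``enrichment_strength``
    fraction of their members from the planted risk pool and the rest
    from the background pool; null sets (``<CH>_S...``) are uniform draws
    from the whole annotation universe, so with no planting the
    hypergeometric null holds exactly.
    """
    risk = sorted(set(risk_genes))
    if not set(risk) <= set(universe):
        raise ConfigError("risk genes must be a subset of the universe")
    background = background_genes(cfg)
    annotation_universe = sorted(set(universe) | set(background))
    lo, hi = cfg.set_size_range
    if hi > len(annotation_universe):
        raise ConfigError(
            f"set_size_range upper bound {hi} exceeds annotation universe size "
            f"{len(annotation_universe)}"
        )
    risk_arr = np.array(risk, dtype=object)
    background_arr = np.array(background, dtype=object)
    pool_arr = np.array(annotation_universe, dtype=object)

    collections: dict[str, GeneSetCollection] = {}
    for channel_index, channel in enumerate(ORA_CHANNELS):
        rng = _rng(cfg, _STAGE_SETS, channel_index)
        sets: dict[str, frozenset[str]] = {}
        for i in range(cfg.n_sets_per_channel):
            size = int(rng.integers(lo, hi + 1))
            if i < cfg.n_enriched_per_channel and len(risk_arr) > 0:
                n_risk = min(int(round(cfg.enrichment_strength * size)), len(risk_arr))
                members = set(rng.choice(risk_arr, size=n_risk, replace=False))
                n_fill = min(size - n_risk, len(background_arr))
                if n_fill > 0:
                    members |= set(rng.choice(background_arr, size=n_fill, replace=False))
                name = f"{channel}_E{i + 1:03d}"
            else:
                members = set(rng.choice(pool_arr, size=size, replace=False))
                name = f"{channel}_S{i + 1:03d}"
            sets[name] = frozenset(members)
        collections[channel] = GeneSetCollection(
            channel_name=channel,
            sets=sets,
            annotation_universe=frozenset(annotation_universe),
        )
    return collections


def choose_up_genes(cfg: SimConfig, risk_genes: Iterable[str]) -> set[str]:
    """The planted up-regulated subset of the risk genes (expression channel)."""
    risk = sorted(set(risk_genes))
    rng = _rng(cfg, _STAGE_UP_GENES)
    count = int(round(cfg.up_fraction * len(risk)))
    return set(rng.choice(np.array(risk, dtype=object), size=count, replace=False))


def gen_expression_dataset(
    cfg: SimConfig,
    universe: Sequence[str],
    up_genes: Iterable[str],
    n_normal: int,
    n_tumor: int,
    dataset_index: int = 0,
) -> ExpressionMatrix:
    """Two-group log2 expression with a planted tumor-side mean shift."""
    up = set(up_genes)
    if not up <= set(universe):
        raise ConfigError("up_genes must be a subset of the universe")
    if n_normal < 2 or n_tumor < 2:
        raise ConfigError(
            f"need >= 2 samples per group (got normal={n_normal}, tumor={n_tumor})"
        )
    rng = _rng(cfg, _STAGE_EXPR, dataset_index)
    n_genes = len(universe)
    baseline = rng.normal(7.0, 1.0, size=n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(n_genes, n_normal + n_tumor)
    )
    up_mask = np.fromiter((g in up for g in universe), dtype=bool, count=n_genes)
    values[np.ix_(up_mask, np.arange(n_normal, n_normal + n_tumor))] += cfg.effect_size
    samples = [f"DS{dataset_index}_N{j:03d}" for j in range(1, n_normal + 1)] + [
        f"DS{dataset_index}_T{j:03d}" for j in range(1, n_tumor + 1)
    ]
    frame = pd.DataFrame(values, index=pd.Index(universe, name="gene"), columns=samples)
    groups = pd.Series(
        ["normal"] * n_normal + ["tumor"] * n_tumor, index=frame.columns, name="group"
    )
    return ExpressionMatrix(values=frame, groups=groups)


def gen_expression_datasets(
    cfg: SimConfig, universe: Sequence[str], up_genes: Iterable[str]
) -> list[ExpressionMatrix]:
    """One dataset per configured (n_normal, n_tumor) pair."""
    return [
        gen_expression_dataset(cfg, universe, up_genes, n_normal, n_tumor, dataset_index=i)
        for i, (n_normal, n_tumor) in enumerate(cfg.sample_sizes)
    ]


def drug_names(cfg: SimConfig) -> list[str]:
    return [f"D{i:04d}" for i in range(1, cfg.n_compounds + 1)]


def gen_drug_target_map(
    cfg: SimConfig, universe: Sequence[str], risk_genes: Iterable[str]
) -> pd.DataFrame:
    """Long-format drug-target table (drug, target, status, action).

    A ``druggable_fraction`` of risk genes is marked druggable and
    assigned to drugs round-robin so every druggable gene has at least
    one drug; the first ``correlated_compounds`` drugs are approved (so
    the planted connectivity compounds survive the status filter) and a
    minority of drugs get an extra off-risk target.
    """
    risk = sorted(set(risk_genes))
    rng = _rng(cfg, _STAGE_DRUGS)
    drugs = drug_names(cfg)
    n_druggable = int(round(cfg.druggable_fraction * len(risk)))
    druggable = sorted(rng.choice(np.array(risk, dtype=object), size=n_druggable, replace=False)) if n_druggable else []
    non_risk = sorted(set(universe) - set(risk))
    if not non_risk:
        non_risk = _gene_names("X", 10, 4)
    non_risk_arr = np.array(non_risk, dtype=object)
    actions = np.array(["inhibitor", "agonist", "antagonist", "modulator"], dtype=object)
    status_pool = np.array(["approved", "clinical", "experimental", "withdrawn"], dtype=object)
    status_p = np.array([0.55, 0.2, 0.15, 0.1])

    records: list[tuple[str, str]] = []
    if druggable:
        for i, drug in enumerate(drugs):
            records.append((drug, druggable[i % len(druggable)]))
        # cover druggable genes left over when there are fewer drugs than genes
        for j in range(len(drugs), len(druggable)):
            records.append((drugs[int(rng.integers(0, len(drugs)))], druggable[j]))
    else:
        for drug in drugs:
            records.append((drug, str(rng.choice(non_risk_arr))))
    extra_mask = rng.random(len(drugs)) < 0.2
    for drug, extra in zip(drugs, extra_mask):
        if extra:
            records.append((drug, str(rng.choice(non_risk_arr))))

    statuses = {}
    for i, drug in enumerate(drugs):
        if i < cfg.correlated_compounds:
            statuses[drug] = "approved"
        else:
            statuses[drug] = str(rng.choice(status_pool, p=status_p))

    table = pd.DataFrame(records, columns=["drug", "target"]).drop_duplicates()
    table["status"] = table["drug"].map(statuses)
    table["action"] = [str(a) for a in rng.choice(actions, size=len(table))]
    return table.sort_values(["drug", "target"], kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class RankProfileSet:
    """Generated compound profiles plus the panel/truth bookkeeping."""

    profiles: tuple[RankProfile, ...]
    reference_name: str
    touchstone_names: tuple[str, ...]
    correlated_names: tuple[str, ...]


def _order_to_profile(
    compound: str, cell_line: str, genes: Sequence[str], order: np.ndarray
) -> RankProfile:
    ranks = np.empty(len(genes), dtype=np.int64)
    ranks[order] = np.arange(1, len(genes) + 1)
    return RankProfile(
        compound=compound,
        cell_line=cell_line,
        ranking=pd.Series(ranks, index=pd.Index(genes, name="gene")),
    )


def _perturb_order(order: np.ndarray, k: int, window: int, rng: np.random.Generator) -> np.ndarray:
    """k random transpositions of positions at most ``window`` apart."""
    out = order.copy()
    n = len(out)
    if k <= 0 or n < 2:
        return out
    window = max(1, min(window, n - 1))
    distances = rng.integers(1, window + 1, size=k)
    starts = rng.integers(0, n - distances)
    for i, d in zip(starts, distances):
        out[i], out[i + d] = out[i + d], out[i]
    return out


def gen_rank_profiles(
    cfg: SimConfig,
    reference_name: str = DEFAULT_REFERENCE,
    compounds: Sequence[str] | None = None,
) -> RankProfileSet:
    """Compound rank profiles with planted reference-correlated structure.

    The reference compound is profiled in the A549, MCF7 and PC3 cell
    lines (MCF7 exactly on the canonical ranking). The first
    ``correlated_compounds`` compounds are bounded-transposition
    perturbations of the reference ranking (0 transpositions for the
    first, growing linearly to ``max_transpositions``); the remainder are
    independent uniform permutations. A graded touchstone panel
    (``TS...``) spanning similarity from null to near-identical provides
    the tau-normalization background.
    """
    if compounds is None:
        compounds = drug_names(cfg)
    compounds = list(compounds)
    touchstone = [f"TS{i:03d}" for i in range(1, cfg.n_touchstone + 1)]
    all_names = [reference_name, *compounds, *touchstone]
    if len(set(all_names)) != len(all_names):
        dupes = sorted({n for n in all_names if all_names.count(n) > 1})
        raise ConfigError(f"duplicate compound names: {dupes}")

    n = cfg.n_profiled_genes
    genes = _gene_names("L", n, max(5, len(str(n))))
    rng = _rng(cfg, _STAGE_PROFILES)
    window = cfg.transposition_window if cfg.transposition_window is not None else max(1, n // 10)

    ref_order = rng.permutation(n)
    ref_positions = np.empty(n)
    ref_positions[ref_order] = np.arange(n)

    profiles: list[RankProfile] = []
    for cell_line in REFERENCE_CELL_LINES:
        if cell_line == "MCF7":
            order = ref_order
        else:
            order = _perturb_order(ref_order, cfg.max_transpositions, window, rng)
        profiles.append(_order_to_profile(reference_name, cell_line, genes, order))

    n_corr = cfg.correlated_compounds
    correlated = tuple(compounds[:n_corr])
    for i, compound in enumerate(compounds):
        if i < n_corr:
            k = 0 if n_corr == 1 else int(round(i * cfg.max_transpositions / (n_corr - 1)))
            order = _perturb_order(ref_order, k, window, rng)
        else:
            order = rng.permutation(n)
        profiles.append(_order_to_profile(compound, "MCF7", genes, order))

    for i, name in enumerate(touchstone):
        similarity = i / max(1, cfg.n_touchstone)
        random_positions = rng.permutation(n).astype(float)
        mixed = similarity * ref_positions + (1.0 - similarity) * random_positions
        order = np.argsort(mixed, kind="mergesort")
        profiles.append(_order_to_profile(name, "MCF7", genes, order))

    return RankProfileSet(
        profiles=tuple(profiles),
        reference_name=reference_name,
        touchstone_names=tuple(touchstone),
        correlated_names=correlated,
    )


def gen_evidence_registry(cfg: SimConfig, drugs: Sequence[str]) -> EvidenceRegistry:
    """Random trial/publication records with configurable proportions."""
    if not drugs:
        raise ConfigError("drugs must be nonempty")
    rng = _rng(cfg, _STAGE_EVIDENCE)
    registry = EvidenceRegistry()
    for drug in drugs:
        registry.register(drug)
        if rng.random() < cfg.trial_fraction:
            phase = int(rng.integers(1, 5))
            registry.add(
                drug,
                EvidenceRecord(kind="trial", phase=phase, identifier=f"NCT{int(rng.integers(0, 10**8)):08d}"),
            )
        if rng.random() < cfg.publication_fraction:
            registry.add(
                drug,
                EvidenceRecord(kind="publication", identifier=f"PMID:{int(rng.integers(10**7, 10**8))}"),
            )
    return registry


# ---------------------------------------------------------------------------
# Packaged worked-example fixture
# ---------------------------------------------------------------------------

#: Non-top-score targets in the fixture candidate table get exactly these
#: two channels, making them risk genes (score 2) without a maximal score.
_FIXTURE_TARGET_CHANNELS = ("kegg", "glad4u")

FIXTURE_THRESHOLDS = {"fdr": 0.05, "logfc_min": 2.0, "score_min": 2, "tau_min": 80.0}


@dataclass(frozen=True)
class ReferenceFixture:
    """Deterministic worked-example inputs packaged with the artifact.

    ``candidate_table`` is the published candidate-drug table (13 rows:
    drug, original indication, connectivity score, target gene, evidence
    level, evidence IDs); ``top_genes`` the 12 gene symbols reported with
    the maximum five-channel score; ``thresholds`` the pipeline cutoffs.
    """

    candidate_table: pd.DataFrame
    top_genes: tuple[str, ...]
    thresholds: dict = field(default_factory=lambda: dict(FIXTURE_THRESHOLDS))

    def __post_init__(self) -> None:
        if len(self.candidate_table) != 13:
            raise DataFormatError(
                f"fixture candidate table must have 13 rows, got {len(self.candidate_table)}"
            )
        if len(self.top_genes) != 12:
            raise DataFormatError(f"fixture must list 12 top genes, got {len(self.top_genes)}")
        scores = self.candidate_table["score"]
        if not ((scores > -100) & (scores <= 100)).all():
            raise DataFormatError("fixture scores must lie in (-100, 100]")

    def indications(self) -> dict[str, str]:
        return dict(zip(self.candidate_table["drug"], self.candidate_table["original_indication"]))

    def connectivity_results(self) -> pd.DataFrame:
        """Connectivity-result table on the tau scale (w = tau / 100)."""
        out = pd.DataFrame(
            {
                "compound": self.candidate_table["drug"],
                "cell_line": "MCF7",
                "w": self.candidate_table["score"] / 100.0,
                "tau": self.candidate_table["score"],
            }
        )
        return out.reset_index(drop=True)

    def drug_target_map(self) -> pd.DataFrame:
        table = pd.DataFrame(
            {
                "drug": self.candidate_table["drug"],
                "target": self.candidate_table["target"],
                "status": "approved",
                "action": "target",
            }
        )
        return table.reset_index(drop=True)

    def evidence_registry(self) -> EvidenceRegistry:
        registry = EvidenceRegistry()
        for rec in self.candidate_table.itertuples(index=False):
            registry.register(rec.drug)
            ids = [] if rec.evidence_ids in ("", "-") else rec.evidence_ids.split(";")
            if rec.evidence_level.startswith("Phase"):
                phase = int(rec.evidence_level.split()[1])
                for identifier in ids or [f"UNREGISTERED:{rec.drug}"]:
                    registry.add(rec.drug, EvidenceRecord(kind="trial", phase=phase, identifier=identifier))
            else:
                for identifier in ids:
                    registry.add(rec.drug, EvidenceRecord(kind="publication", identifier=identifier))
        return registry

    def channel_indicators(self) -> tuple[list[str], dict[str, pd.Series]]:
        """A 30-gene fixture universe with hand-set channel indicators.

        The 12 top genes carry all five indicators; the remaining
        candidate targets carry two; a few well-known symbols carry one;
        filler genes carry none.
        """
        from .scoring import CHANNELS

        other_targets = sorted(set(self.candidate_table["target"]) - set(self.top_genes))
        single = {"KRAS": "kegg", "TP53": "bp", "SMAD4": "ko", "RRM1": "geo"}
        fillers = [f"NRG{i:02d}" for i in range(1, 8)]
        universe = list(self.top_genes) + other_targets + sorted(single) + fillers
        indicators = {}
        for channel in CHANNELS:
            values = []
            for gene in universe:
                if gene in self.top_genes:
                    values.append(1)
                elif gene in other_targets:
                    values.append(1 if channel in _FIXTURE_TARGET_CHANNELS else 0)
                elif gene in single:
                    values.append(1 if single[gene] == channel else 0)
                else:
                    values.append(0)
            indicators[channel] = pd.Series(
                values, index=pd.Index(universe, name="gene"), dtype=np.int8, name=channel
            )
        return universe, indicators


def load_reference_fixture() -> ReferenceFixture:
    """Load the packaged candidate-drug table and top-gene list."""
    data = resources.files("drugfunnel.data")
    with resources.as_file(data / "candidate_drugs.tsv") as path:
        table = pd.read_csv(path, sep="\t", dtype={"score": float})
    with resources.as_file(data / "top_scoring_genes.txt") as path:
        genes = tuple(
            line.strip() for line in path.read_text(encoding="utf-8").splitlines() if line.strip()
        )
    required = {"drug", "original_indication", "score", "target", "evidence_level", "evidence_ids"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise DataFormatError(f"fixture table lacks columns {missing}")
    return ReferenceFixture(candidate_table=table, top_genes=genes)
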
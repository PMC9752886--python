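"""End-to-end orchestration.

Runs the stage chain simulate -> differential expression -> ORA ->
scoring -> drug mapping -> connectivity -> evidence report, writes every
intermediate table plus a hash MANIFEST, and returns the funnel summary.
Identical config and seed produce byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path
from types import SimpleNamespace
from typing import Mapping

import pandas as pd
import yaml

from . import connectivity, deg, druggability, evidence, io, ora, scoring, synthetic
from .errors import ConfigError, StageError

log = logging.getLogger(__name__)

MODES = ("synthetic", "fixture", "files")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage thresholds plus the simulation knobs and run mode."""

    mode: str = "synthetic"
    seed: int = 1
    fdr_max: float = 0.05
    logfc_min: float = 2.0
    absolute_logfc: bool = False
    score_min: int = 2
    tau_min: float = 80.0
    strict_tau: bool = True
    q: int = 150
    cell_line: str = "MCF7"
    prior_df: float = 4.0
    min_set_size: int = 5
    max_set_size: int = 2000
    allowed_statuses: tuple[str, ...] = tuple(sorted(druggability.DEFAULT_ALLOWED))
    indir: str | None = None
    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 < self.fdr_max < 1:
            raise ConfigError(f"fdr_max must be in (0, 1), got {self.fdr_max}")
        if not 0 <= self.score_min <= 6:
            raise ConfigError(f"score_min must be in [0, 6], got {self.score_min}")
        if not -100 <= self.tau_min <= 100:
            raise ConfigError(f"tau_min must be in [-100, 100], got {self.tau_min}")
        if self.q < 1:
            raise ConfigError(f"q must be >= 1, got {self.q}")
        if self.mode == "files" and not self.indir:
            raise ConfigError("mode 'files' requires indir")
        if self.seed != self.sim.seed:
            object.__setattr__(self, "sim", self.sim.with_seed(self.seed))

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = synthetic.SimConfig.from_dict(kwargs["sim"])
        if "allowed_statuses" in kwargs:
            kwargs["allowed_statuses"] = tuple(kwargs["allowed_statuses"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)


@dataclass
class FunnelSummary:
    """Stage-by-stage counts from gene universe down to final candidates."""

    universe_genes: int
    risk_genes: int
    druggable_genes: int
    pooled_drugs: int
    positive_drugs: int
    candidates: int
    channel_hit_pct: dict[str, float]
    evidence_summary: dict[str, int]

    def validate(self) -> None:
        if not self.universe_genes >= self.risk_genes >= self.druggable_genes:
            raise StageError(
                "funnel gene counts not monotone: "
                f"{self.universe_genes} >= {self.risk_genes} >= {self.druggable_genes} fails"
            )
        if not self.pooled_drugs >= self.positive_drugs >= self.candidates:
            raise StageError(
                "funnel drug counts not monotone: "
                f"{self.pooled_drugs} >= {self.positive_drugs} >= {self.candidates} fails"
            )


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _write_manifest(outdir: Path, complete: bool, failed_stage: str | None = None) -> None:
    lines = []
    status = "COMPLETE" if complete else f"INCOMPLETE stage={failed_stage}"
    for path in sorted(outdir.rglob("*")):
        if path.is_dir() or path.name == "MANIFEST.txt":
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        lines.append(f"{digest}  {path.relative_to(outdir).as_posix()}")
    text = f"# status: {status}\n" + "".join(f"{line}\n" for line in lines)
    (outdir / "MANIFEST.txt").write_text(text, encoding="utf-8")


def verify_manifest(outdir: str | Path) -> bool:
    """Re-hash every artifact listed in the MANIFEST; True when all match."""
    outdir = Path(outdir)
    lines = (outdir / "MANIFEST.txt").read_text(encoding="utf-8").splitlines()
    for line in lines:
        if line.startswith("#") or not line.strip():
            continue
        digest, rel = line.split(None, 1)
        if hashlib.sha256((outdir / rel).read_bytes()).hexdigest() != digest:
            return False
    return True


def simulate_inputs(config: PipelineConfig, outdir: str | Path) -> dict:
    """Generate and serialize every synthetic pipeline input."""
    cfg = config.sim
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    universe, risk = synthetic.gen_gene_universe(cfg)
    collections = synthetic.gen_geneset_collections(cfg, universe, risk)
    up_genes = synthetic.choose_up_genes(cfg, risk)
    datasets = synthetic.gen_expression_datasets(cfg, universe, up_genes)
    drug_map = synthetic.gen_drug_target_map(cfg, universe, risk)
    profile_set = synthetic.gen_rank_profiles(cfg)
    registry = synthetic.gen_evidence_registry(cfg, synthetic.drug_names(cfg))

    io.write_gene_list(universe, outdir / "universe.txt")
    io.write_gene_list(sorted(risk), outdir / "truth_risk_genes.txt")
    io.write_gene_list(sorted(up_genes), outdir / "truth_up_genes.txt")
    for channel, collection in collections.items():
        io.write_gmt(collection, outdir / f"genesets_{channel}.gmt")
        io.write_gene_list(
            sorted(collection.annotation_universe), outdir / f"annotation_universe_{channel}.txt"
        )
    for i, dataset in enumerate(datasets):
        io.write_expression(dataset, outdir / f"expression_{i}.tsv")
    io.write_drug_target_map(drug_map, outdir / "drug_targets.tsv")
    io.write_rank_profiles(profile_set.profiles, outdir / "rank_profiles.tsv")
    io.write_gene_list(profile_set.touchstone_names, outdir / "touchstone_compounds.txt")
    io.write_evidence(registry, outdir / "evidence.tsv")
    return {
        "universe": universe,
        "collections": collections,
        "datasets": datasets,
        "drug_map": drug_map,
        "profile_set": profile_set,
        "registry": registry,
        "reference": profile_set.reference_name,
        "touchstone": list(profile_set.touchstone_names),
    }


def _load_inputs(config: PipelineConfig) -> dict:
    indir = Path(config.indir)  # type: ignore[arg-type]
    if not indir.is_dir():
        raise ConfigError(f"input directory not found: {indir}")
    universe = io.read_gene_list(indir / "universe.txt")
    collections = {}
    for gmt in sorted(indir.glob("genesets_*.gmt")):
        channel = gmt.stem.removeprefix("genesets_")
        collection = io.read_gmt(gmt, channel_name=channel)
        universe_file = indir / f"annotation_universe_{channel}.txt"
        if universe_file.exists():
            collection = ora.GeneSetCollection(
                channel_name=channel,
                sets=collection.sets,
                annotation_universe=frozenset(io.read_gene_list(universe_file)),
            )
        collections[channel] = collection
    datasets = [io.read_expression(p) for p in sorted(indir.glob("expression_*.tsv"))
                if not p.name.endswith(".labels.tsv")]
    drug_map = io.read_drug_target_map(indir / "drug_targets.tsv")
    profiles = io.read_rank_profiles(indir / "rank_profiles.tsv")
    registry = io.read_evidence(indir / "evidence.tsv")
    touchstone_file = indir / "touchstone_compounds.txt"
    touchstone = io.read_gene_list(touchstone_file) if touchstone_file.exists() else None
    return {
        "universe": universe,
        "collections": collections,
        "datasets": datasets,
        "drug_map": drug_map,
        "profile_set": SimpleNamespace(profiles=tuple(profiles)),
        "registry": registry,
        "reference": synthetic.DEFAULT_REFERENCE,
        "touchstone": touchstone,
    }


class _StageTracker:
    def __init__(self) -> None:
        self.current = "setup"

    @contextmanager
    def __call__(self, name: str):
        self.current = name
        log.info("stage %s", name)
        yield
        self.current = f"{name} (done)"


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> FunnelSummary:
    """Execute all stages, write every artifact and the MANIFEST.

    On stage failure the partial outputs are retained, the MANIFEST marks
    the run incomplete and a :class:`StageError` is raised naming the
    stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracker = _StageTracker()
    try:
        if config.mode == "fixture":
            summary = _run_fixture(config, outdir, tracker)
        else:
            summary = _run_analytic(config, outdir, tracker)
        summary.validate()
        _write_json(asdict(summary), outdir / "funnel.json")
        _write_manifest(outdir, complete=True)
        return summary
    except StageError:
        _write_manifest(outdir, complete=False, failed_stage=tracker.current)
        raise
    except Exception as exc:
        _write_manifest(outdir, complete=False, failed_stage=tracker.current)
        raise StageError(f"stage {tracker.current!r} failed: {exc}") from exc


def _run_analytic(config: PipelineConfig, outdir: Path, stage: _StageTracker) -> FunnelSummary:
    with stage("simulate" if config.mode == "synthetic" else "load-inputs"):
        if config.mode == "synthetic":
            inputs = simulate_inputs(config, outdir / "inputs")
        else:
            inputs = _load_inputs(config)
    universe = inputs["universe"]
    collections = inputs["collections"]

    with stage("deg"):
        (outdir / "deg").mkdir(exist_ok=True)
        deg_sets = []
        for i, dataset in enumerate(inputs["datasets"]):
            table = deg.differential_expression(
                dataset,
                adj_p_max=config.fdr_max,
                logfc_min=config.logfc_min,
                prior_df=config.prior_df,
                absolute_logfc=config.absolute_logfc,
            )
            table.to_csv(outdir / "deg" / f"deg_{i}.tsv", sep="\t")
            up = set(table.index[table["up_flag"]])
            deg_sets.append(up)
            log.info("dataset %d: %d up-regulated DEGs", i, len(up))
        geo_vec = deg.geo_channel_indicator(deg_sets, universe)

    with stage("ora"):
        (outdir / "ora").mkdir(exist_ok=True)
        indicators = {"geo": geo_vec}
        channel_keys = {"KEGG": "kegg", "BP": "bp", "KO": "ko", "GLAD4U": "glad4u"}
        for channel, collection in collections.items():
            key = channel_keys.get(channel.upper(), channel.lower())
            result = ora.enrich_collection(
                universe,
                collection,
                min_set_size=config.min_set_size,
                max_set_size=config.max_set_size,
                fdr_max=config.fdr_max,
            )
            result.to_csv(outdir / "ora" / f"enrichment_{key}.tsv", sep="\t", index=False)
            indicators[key] = ora.channel_indicator(universe, result, collection).rename(key)
            log.info(
                "channel %s: %d significant sets",
                channel,
                int(result["significant"].sum()) if len(result) else 0,
            )
        missing = sorted(set(scoring.CHANNELS) - set(indicators))
        if missing:
            raise StageError(f"annotation channels missing from inputs: {missing}")

    with stage("scoring"):
        (outdir / "scores").mkdir(exist_ok=True)
        table = scoring.aggregate_scores(indicators, universe)
        table.to_csv(outdir / "scores" / "indicator_table.tsv", sep="\t")
        scoring.channel_correlation(table).to_csv(
            outdir / "scores" / "channel_correlation.tsv", sep="\t"
        )
        _write_json(scoring.venn_counts(table), outdir / "scores" / "venn_counts.json")
        scoring.top_table(table).to_csv(outdir / "scores" / "top30.tsv", sep="\t")
        risk = scoring.select_risk_genes(table, score_min=config.score_min)
        io.write_gene_list(sorted(risk), outdir / "scores" / "risk_genes.txt")
        log.info("risk genes at score >= %d: %d of %d", config.score_min, len(risk), len(universe))

    with stage("druggability"):
        (outdir / "drugs").mkdir(exist_ok=True)
        filtered = druggability.filter_drug_status(inputs["drug_map"], config.allowed_statuses)
        druggable, candidates = druggability.map_risk_to_drugs(risk, filtered)
        io.write_gene_list(sorted(druggable), outdir / "drugs" / "druggable_genes.txt")
        candidates_out = candidates.copy()
        if len(candidates_out):
            candidates_out["targets"] = candidates_out["targets"].map(lambda t: ";".join(t))
        candidates_out.to_csv(outdir / "drugs" / "candidate_pool.tsv", sep="\t", index=False)
        pool = list(candidates["drug"]) if len(candidates) else []
        log.info("druggable genes: %d; pooled drugs: %d", len(druggable), len(pool))

    with stage("connectivity"):
        (outdir / "connectivity").mkdir(exist_ok=True)
        profiles = list(inputs["profile_set"].profiles)
        results = connectivity.score_compounds(
            profiles,
            inputs["reference"],
            cell_line=config.cell_line,
            q=config.q,
            background_compounds=inputs["touchstone"],
        )
        pool_results = results.loc[results["compound"].isin(pool)].reset_index(drop=True)
        pool_results.to_csv(outdir / "connectivity" / "scores.tsv", sep="\t", index=False)
        positive = pool_results.loc[pool_results["w"] > 0]
        final = connectivity.rank_and_filter(
            pool_results, threshold=config.tau_min, strict=config.strict_tau
        )
        final.to_csv(outdir / "connectivity" / "candidates.tsv", sep="\t", index=False)
        log.info(
            "connectivity: %d scored, %d positive, %d above tau %s %g",
            len(pool_results), len(positive), len(final),
            ">" if config.strict_tau else ">=", config.tau_min,
        )

    with stage("evidence-report"):
        (outdir / "report").mkdir(exist_ok=True)
        drug_targets = dict(zip(candidates["drug"], candidates["targets"])) if len(candidates) else {}
        report = evidence.build_candidate_report(final, drug_targets, inputs["registry"])
        report.table.to_csv(outdir / "report" / "report.csv", index=False)
        _write_json(report.summary, outdir / "report" / "summary.json")
        report.edges.to_csv(outdir / "report" / "edges.tsv", sep="\t", index=False)

    channel_pct = {
        c: round(100.0 * float(table[c].mean()), 2) for c in scoring.CHANNELS
    }
    return FunnelSummary(
        universe_genes=len(universe),
        risk_genes=len(risk),
        druggable_genes=len(druggable),
        pooled_drugs=len(pool),
        positive_drugs=int(len(positive)),
        candidates=int(len(final)),
        channel_hit_pct=channel_pct,
        evidence_summary=report.summary,
    )


def _run_fixture(config: PipelineConfig, outdir: Path, stage: _StageTracker) -> FunnelSummary:
    """Ranking, filtering and evidence stages on the packaged fixture."""
    with stage("load-fixture"):
        fixture = synthetic.load_reference_fixture()
        universe, indicators = fixture.channel_indicators()

    with stage("scoring"):
        (outdir / "scores").mkdir(exist_ok=True)
        table = scoring.aggregate_scores(indicators, universe)
        table.to_csv(outdir / "scores" / "indicator_table.tsv", sep="\t")
        _write_json(scoring.venn_counts(table), outdir / "scores" / "venn_counts.json")
        risk = scoring.select_risk_genes(table, score_min=config.score_min)
        io.write_gene_list(sorted(risk), outdir / "scores" / "risk_genes.txt")

    with stage("druggability"):
        (outdir / "drugs").mkdir(exist_ok=True)
        filtered = druggability.filter_drug_status(fixture.drug_target_map(), config.allowed_statuses)
        druggable, candidates = druggability.map_risk_to_drugs(risk, filtered)
        io.write_gene_list(sorted(druggable), outdir / "drugs" / "druggable_genes.txt")

    with stage("connectivity"):
        (outdir / "connectivity").mkdir(exist_ok=True)
        results = fixture.connectivity_results()
        pool = list(candidates["drug"]) if len(candidates) else []
        pool_results = results.loc[results["compound"].isin(pool)].reset_index(drop=True)
        positive = pool_results.loc[pool_results["w"] > 0]
        final = connectivity.rank_and_filter(
            pool_results, threshold=config.tau_min, strict=config.strict_tau
        )
        final.to_csv(outdir / "connectivity" / "candidates.tsv", sep="\t", index=False)

    with stage("evidence-report"):
        (outdir / "report").mkdir(exist_ok=True)
        drug_targets = dict(zip(candidates["drug"], candidates["targets"])) if len(candidates) else {}
        report = evidence.build_candidate_report(
            final, drug_targets, fixture.evidence_registry(), indications=fixture.indications()
        )
        report.table.to_csv(outdir / "report" / "report.csv", index=False)
        _write_json(report.summary, outdir / "report" / "summary.json")
        report.edges.to_csv(outdir / "report" / "edges.tsv", sep="\t", index=False)

    channel_pct = {c: round(100.0 * float(table[c].mean()), 2) for c in scoring.CHANNELS}
    return FunnelSummary(
        universe_genes=len(universe),
        risk_genes=len(risk),
        druggable_genes=len(druggable),
        pooled_drugs=len(pool),
        positive_drugs=int(len(positive)),
        candidates=int(len(final)),
        channel_hit_pct=channel_pct,
        evidence_summary=report.summary,
    )
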
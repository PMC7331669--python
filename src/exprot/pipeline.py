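"""End-to-end orchestration of the exercise-proteome analysis.

One configuration drives: (optional) synthetic-data generation ->
per-intensity differential testing -> cross-intensity partition,
concordance and dependence classification -> gene-set enrichment of
up-regulated proteins -> tissue-source inference with platform
comparison -> pQTL/GWAS trait simulation -> a machine-readable run
report. Every stage writes its outputs as TSV/JSON under the output
directory; a fixed seed makes the whole run bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

import exprot
from exprot import io as eio
from exprot.differential import run_differential
from exprot.enrichment import GeneSetCatalog, map_proteins_to_genes, run_enrichment
from exprot.intensity import (
    check_concordance,
    classify_intensity_dependence,
    partition_by_intensity,
    volcano_table,
)
from exprot.simulate import (
    DEFAULT_BENEFIT_ORIENTATION,
    SimulationParams,
    generate_all,
)
from exprot.tissues import (
    TissueExpressionMatrix,
    aggregate_tissue_profile,
    platform_relative_enrichment,
)
from exprot.traits import run_trait_simulation

__all__ = ["PipelineConfig", "RunReport", "StageError", "run_pipeline"]

logger = logging.getLogger("exprot.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    With ``simulate=True`` (default) the inputs are generated from
    ``sim_params`` and written alongside the results; otherwise the
    ``*_path`` entries must point at existing files.
    """

    out_dir: str = "exprot_run"
    simulate: bool = True
    seed: int = 0
    sim_params: SimulationParams | None = None
    # input paths (used when simulate is False)
    abundance_path: str | None = None
    sample_sheet_path: str | None = None
    proteins_path: str | None = None
    expression_gct_path: str | None = None
    organ_map_path: str | None = None
    gmt_path: str | None = None
    pqtl_path: str | None = None
    gwas_path: str | None = None
    # analysis knobs
    alpha: float = 0.05
    gwas_threshold: float = 5e-8
    moderation: str = "eb"
    benefit_orientation: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BENEFIT_ORIENTATION)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.gwas_threshold <= 0:
            raise ValueError("gwas_threshold must be positive")
        if self.moderation not in ("eb", "none"):
            raise ValueError("moderation must be 'eb' or 'none'")
        if self.sim_params is None:
            self.sim_params = SimulationParams(seed=self.seed)
        else:
            self.sim_params = dataclasses.replace(self.sim_params, seed=self.seed)
        if not self.simulate:
            for name in (
                "abundance_path",
                "sample_sheet_path",
                "expression_gct_path",
                "organ_map_path",
                "gmt_path",
                "pqtl_path",
                "gwas_path",
            ):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} missing or unreadable: {p!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("sim_params", None)
        if isinstance(sim, Mapping):
            for key in ("dependence_mix", "dependence_ratios", "set_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "trait_plan" in sim:
                sim["trait_plan"] = {
                    k: tuple(v) for k, v in sim["trait_plan"].items()
                }
            raw["sim_params"] = SimulationParams(**sim)
        return cls(**raw)

    def echo(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim_params"]["trait_plan"] = {
            k: list(v) for k, v in d["sim_params"]["trait_plan"].items()
        }
        return d


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    version: str
    seed: int
    config: dict[str, Any]
    n_proteins: int
    n_subjects: int
    n_significant_moderate: int
    n_significant_high: int
    partition: dict[str, int]
    n_discordant: int
    dependence_counts: dict[str, int]
    enrichment_hits: dict[str, int]
    tissue_summary: dict[str, Any]
    pqtl_summary: dict[str, Any]
    trait_concordance: dict[str, list[int]]
    stage_seconds: dict[str, float]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (np.bool_,)):
                return bool(o)
            raise TypeError(f"cannot serialize {type(o)}")

        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_default)
        if path is not None:
            Path(path).write_text(text)
        return text


def _stage(name: str, timings: dict[str, float]):
    class _Timer:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            timings[name] = round(dt, 3)
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            raise StageError(name, exc) from exc

    return _Timer()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and return the run report.

    Outputs land under ``config.out_dir``. On a stage failure the partial
    outputs are retained, a ``FAILED`` marker naming the stage is
    written, and :class:`StageError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)

    try:
        return _run(config, out, timings)
    except StageError as err:
        (out / "FAILED").write_text(f"{err.stage}: {err.cause}\n")
        raise


def _run(config: PipelineConfig, out: Path, timings: dict[str, float]) -> RunReport:
    with _stage("inputs", timings):
        if config.simulate:
            params = config.sim_params
            (
                study,
                truth,
                expression,
                organ_map_df,
                platform_map,
                gene_sets,
                pqtl,
                gwas,
            ) = generate_all(params)
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            eio.write_study(study, inputs)
            eio.write_gct(expression, inputs / "expression.gct")
            organ_map_df.to_csv(inputs / "organ_map.tsv", sep="\t", index=False)
            eio.write_gmt(gene_sets, inputs / "gene_sets.gmt")
            pqtl.to_csv(inputs / "pqtl.tsv", sep="\t", index=False)
            gwas.to_csv(inputs / "gwas.tsv", sep="\t", index=False)
            eio.write_truth(truth, inputs / "truth.json")
        else:
            study = eio.read_study(
                config.abundance_path, config.sample_sheet_path, config.proteins_path
            )
            platform_map = study.proteins
            expression = eio.read_gct(config.expression_gct_path)
            organ_map_df = pd.read_csv(config.organ_map_path, sep="\t")
            gene_sets = eio.read_gmt(config.gmt_path)
            pqtl = pd.read_csv(config.pqtl_path, sep="\t")
            gwas = pd.read_csv(config.gwas_path, sep="\t")

    with _stage("differential", timings):
        res = {
            intensity: run_differential(
                study, intensity, alpha=config.alpha, moderation=config.moderation
            )
            for intensity in ("moderate", "high")
        }
        for intensity, table in res.items():
            table.to_csv(out / f"differential_{intensity}.tsv", sep="\t", index=False)
            volcano_table(table).to_csv(
                out / f"volcano_{intensity}.tsv", sep="\t", index=False
            )

    with _stage("intensity_sets", timings):
        part = partition_by_intensity(res["moderate"], res["high"], config.alpha)
        shared_ids = sorted(part.shared)
        rm = res["moderate"].set_index("protein_id")
        rh = res["high"].set_index("protein_id")
        shared_df = pd.DataFrame(
            {
                "protein_id": shared_ids,
                "direction_moderate": rm.loc[shared_ids, "direction"].to_numpy(),
                "direction_high": rh.loc[shared_ids, "direction"].to_numpy(),
                "fc_moderate": rm.loc[shared_ids, "fold_change"].to_numpy(),
                "fc_high": rh.loc[shared_ids, "fold_change"].to_numpy(),
            }
        )
        discordant = check_concordance(shared_df)
        concordant = shared_df[~shared_df["protein_id"].isin(discordant)].copy()
        concordant["direction"] = concordant["direction_high"]
        dependence = (
            classify_intensity_dependence(concordant)
            if len(concordant)
            else pd.DataFrame(
                columns=[
                    "protein_id",
                    "fc_moderate",
                    "fc_high",
                    "direction",
                    "magnitude_ratio",
                    "klass",
                ]
            )
        )
        membership = pd.DataFrame(
            [
                {"protein_id": p, "set": name}
                for name, ids in (
                    ("moderate_only", part.moderate_only),
                    ("high_only", part.high_only),
                    ("shared", part.shared),
                )
                for p in sorted(ids)
            ]
        )
        membership.to_csv(out / "partition.tsv", sep="\t", index=False)
        dependence.to_csv(out / "dependence.tsv", sep="\t", index=False)
        dep_counts = dependence["klass"].value_counts().to_dict() if len(dependence) else {}

    with _stage("enrichment", timings):
        universe = set(platform_map["gene_symbol"])
        catalog = GeneSetCatalog.from_mapping(gene_sets, universe)
        enr_hits = {}
        for intensity, table in res.items():
            up = table[(table["q_value"] < config.alpha) & (table["direction"] == "up")]
            genes = map_proteins_to_genes(up["protein_id"], platform_map)
            if genes:
                enr = run_enrichment(genes, catalog)
            else:
                enr = pd.DataFrame(
                    columns=["set_name", "k", "n", "K", "N", "fold_enrichment", "p_raw", "p_bonferroni"]
                )
            enr.to_csv(out / f"enrichment_{intensity}.tsv", sep="\t", index=False)
            enr_hits[intensity] = int((enr["p_bonferroni"] < 0.05).sum()) if len(enr) else 0

    with _stage("tissue_inference", timings):
        matrix = TissueExpressionMatrix(tpm=expression, organ_map=organ_map_df)
        platform_profile = aggregate_tissue_profile(
            platform_map["protein_id"], matrix, platform_map
        )
        tissue_summary: dict[str, Any] = {
            "platform_proteins_used": platform_profile.n_proteins_used,
            "platform_proteins_dropped": platform_profile.n_proteins_dropped,
        }
        increased_union: set[str] = set()
        for intensity, table in res.items():
            up = table[(table["q_value"] < config.alpha) & (table["direction"] == "up")]
            increased_union |= set(up["protein_id"])
            tissue_summary[f"n_increased_{intensity}"] = int(len(up))
            if len(up) == 0:
                continue
            profile = aggregate_tissue_profile(up["protein_id"], matrix, platform_map)
            profile.organ_probs.rename("probability").to_csv(
                out / f"tissue_profile_{intensity}.tsv", sep="\t"
            )
            ratios = platform_relative_enrichment(profile, platform_profile)
            ratios.to_csv(out / f"tissue_ratio_{intensity}.tsv", sep="\t", index=False)
            top = ratios.loc[ratios["ratio"].idxmax()]
            tissue_summary[f"top_enriched_system_{intensity}"] = str(
                top["organ_system"]
            )
            if "skeletal_muscle" in set(ratios["organ_system"]):
                muscle = ratios.set_index("organ_system").loc["skeletal_muscle", "ratio"]
                tissue_summary[f"muscle_ratio_{intensity}"] = float(muscle)
        tissue_summary["n_increased_union"] = int(len(increased_union))

    with _stage("trait_simulation", timings):
        records, pqtl_summary, concordance = run_trait_simulation(
            res["moderate"],
            res["high"],
            pqtl,
            gwas,
            threshold=config.gwas_threshold,
            benefit_orientation=config.benefit_orientation,
            alpha=config.alpha,
        )
        records.to_csv(out / "trait_records.tsv", sep="\t", index=False)
        for trait in sorted(set(records["trait"])):
            from exprot.traits import forest_table

            forest_table(records, trait).to_csv(
                out / f"forest_{trait}.tsv", sep="\t", index=False
            )
        with open(out / "trait_concordance.json", "w") as fh:
            json.dump({k: list(v) for k, v in concordance.items()}, fh)

    report = RunReport(
        version=exprot.__version__,
        seed=config.seed,
        config=config.echo(),
        n_proteins=study.abundance.shape[0],
        n_subjects=study.samples["subject_id"].nunique(),
        n_significant_moderate=part.n_moderate_total,
        n_significant_high=part.n_high_total,
        partition=part.counts(),
        n_discordant=len(discordant),
        dependence_counts={k: int(v) for k, v in dep_counts.items()},
        enrichment_hits=enr_hits,
        tissue_summary=tissue_summary,
        pqtl_summary={k: (float(v) if isinstance(v, float) else int(v)) for k, v in pqtl_summary.items()},
        trait_concordance={k: list(v) for k, v in concordance.items()},
        stage_seconds=timings,
    )
    report.to_json(out / "report.json")
    return report
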
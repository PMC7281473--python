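"""End-to-end orchestration: simulate -> score -> annotation -> DE ->
association -> ENV -> enrichment.

Stages run in dependency order; each stage writes its outputs plus a
manifest entry (parameters and SHA-256 of inputs), and a final JSON report
summarizes scores, selected genes, ENV correlations per subtype group and
enrichment tables. A failed stage aborts the run with the stage named;
outputs of completed stages are kept.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import build_annotation, read_gtf
from .counts_de import CountMatrix, NBDifferentialExpression, per_line_logfc
from .dose_response import AtraScorer, read_curves, write_scores
from .enrichment import SSGSEA, compare_groups, preranked_test, read_gmt
from .sensitivity import ScoreAssociation, export_direction_gmt
from .simulate import SimulationConfig, simulate_study
from .te_mimicry import (
    aggregate_families,
    env_score_correlation,
    family_induction,
    median_env_induction,
)

log = logging.getLogger("retinomimic")

ALL_STAGES = ("simulate", "score", "annotation", "de", "assoc", "env", "enrichment")


@dataclass
class RunConfig:
    """Pipeline run configuration (YAML-loadable)."""

    outdir: str = "run"
    seed: int = 0
    fdr: float = 0.05
    score_threshold: float = 0.17
    ssgsea_alpha: float = 0.25
    pseudocount: float = 0.5
    assoc_r_min: float = 0.5
    assoc_min_lines: int = 8
    stages: tuple = ALL_STAGES
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr <= 1 or not 0 < self.score_threshold < 1:
            raise ValueError("thresholds out of range")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the run report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    report: dict = {}
    paths: dict = {}

    def rel(p) -> str:
        # manifest paths are relative to the run directory so identical runs
        # in different locations produce identical manifests
        try:
            return str(Path(p).relative_to(out))
        except ValueError:
            return str(p)

    def record(stage: str, params: dict, inputs: list, outputs: list) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "inputs": {rel(p): _sha256(p) for p in inputs},
            "outputs": [rel(p) for p in outputs],
        }

    enabled = [s for s in ALL_STAGES if s in config.stages]
    try:
        stage = "simulate"
        if stage in enabled:
            log.info("stage simulate")
            sim_cfg = SimulationConfig(**config.simulation)
            study = simulate_study(sim_cfg, seed=config.seed)
            paths.update(study.write(out / "simdata"))
            record(stage, {"seed": config.seed, **config.simulation}, [], list(paths.values()))

        stage = "score"
        if stage in enabled:
            log.info("stage score")
            assays = read_curves(paths["curves"])
            scorer = AtraScorer(threshold=config.score_threshold).fit(assays)
            score_path = out / "scores.tsv"
            write_scores(scorer.scores_, score_path)
            paths["scores"] = score_path
            report["scores"] = {
                "n_lines": len(scorer.scores_),
                "n_high": int((scorer.scores_["binary_class"] == "HIGH").sum()),
            }
            record(stage, {"threshold": config.score_threshold}, [paths["curves"]], [score_path])

        stage = "annotation"
        if stage in enabled:
            log.info("stage annotation")
            custom_gtf = out / "custom.gtf"
            discard_log = out / "discarded_repeats.tsv"
            summary = build_annotation(
                paths["genes_gtf"],
                paths["repeats"],
                custom_gtf,
                family_map_path=paths["families"],
                discard_log_path=discard_log,
            )
            paths["custom_gtf"] = custom_gtf
            report["annotation"] = summary
            record(
                stage,
                {},
                [paths["genes_gtf"], paths["repeats"], paths["families"]],
                [custom_gtf, discard_log],
            )

        stage = "de"
        if stage in enabled:
            log.info("stage de")
            cm = CountMatrix.from_tsv(paths["gene_counts"], paths["samples"])
            de = NBDifferentialExpression(alpha=config.fdr).fit(cm)
            de_path = out / "de.tsv"
            de.results_.to_csv(de_path, sep="\t", float_format="%.10g")
            lfc = per_line_logfc(cm, pseudocount=config.pseudocount)
            lfc_path = out / "per_line_logfc.tsv"
            lfc.to_csv(lfc_path, sep="\t", float_format="%.10g")
            paths["de"], paths["logfc"] = de_path, lfc_path
            report["de"] = {
                "n_features": len(de.results_),
                "n_significant": int((de.results_["adj_p"] <= config.fdr).sum()),
                "filter_threshold": de.filter_threshold_,
            }
            record(stage, {"alpha": config.fdr}, [paths["gene_counts"], paths["samples"]], [de_path, lfc_path])

        stage = "assoc"
        if stage in enabled:
            log.info("stage assoc")
            lfc = pd.read_csv(paths["logfc"], sep="\t", index_col=0)
            scores = pd.read_csv(paths["scores"], sep="\t", index_col=0)["atra_score"]
            assoc = ScoreAssociation(
                fdr=config.fdr, r_min=config.assoc_r_min, min_lines=config.assoc_min_lines
            ).fit(lfc, scores)
            assoc_path = out / "assoc.tsv"
            assoc.results_.to_csv(assoc_path, sep="\t", float_format="%.10g")
            gmt_path = out / "assoc_sets.gmt"
            if assoc.up_genes_ or assoc.down_genes_:
                export_direction_gmt(assoc.results_, gmt_path)
            paths["assoc"] = assoc_path
            report["assoc"] = {
                "n_selected": int(assoc.results_["selected"].sum()),
                "n_up": len(assoc.up_genes_),
                "n_down": len(assoc.down_genes_),
            }
            record(stage, {"fdr": config.fdr}, [paths["logfc"], paths["scores"]], [assoc_path])

        stage = "env"
        if stage in enabled:
            log.info("stage env")
            samples = pd.read_csv(paths["samples"], sep="\t", index_col=0)
            te_counts = pd.read_csv(paths["te_counts"], sep="\t", index_col=0)
            te_cm = CountMatrix(te_counts, samples)
            records = read_gtf(paths["custom_gtf"])
            inst_fam = {
                r.attributes["instance_id"]: r.attributes["family"]
                for r in records
                if r.feature_type == "repeat"
            }
            gene_cm = CountMatrix.from_tsv(paths["gene_counts"], paths["samples"])
            from .counts_de import size_factors as _size_factors

            gene_sf = pd.Series(_size_factors(gene_cm.counts), index=gene_cm.sample_ids)
            fam_cm = aggregate_families(te_cm, inst_fam)
            induction = family_induction(fam_cm, pseudocount=config.pseudocount, sf=gene_sf)
            medians = median_env_induction(induction)
            scores = pd.read_csv(paths["scores"], sep="\t", index_col=0)["atra_score"]
            subtypes = samples.groupby("cell_line")["subtype"].first()
            corr = env_score_correlation(medians, scores, subtypes)
            ind_path, med_path, corr_path = (
                out / "family_induction.tsv",
                out / "env_medians.tsv",
                out / "env_correlation.tsv",
            )
            induction.to_csv(ind_path, sep="\t", index=False, float_format="%.10g")
            medians.to_csv(med_path, sep="\t", float_format="%.10g")
            corr.to_csv(corr_path, sep="\t", float_format="%.10g")
            report["env"] = {g: float(corr.loc[g, "r_squared"]) for g in corr.index}
            record(
                stage,
                {"pseudocount": config.pseudocount},
                [paths["te_counts"], paths["custom_gtf"], paths["scores"]],
                [ind_path, med_path, corr_path],
            )

        stage = "enrichment"
        if stage in enabled:
            log.info("stage enrichment")
            de_res = pd.read_csv(paths["de"], sep="\t", index_col=0)
            gene_sets = read_gmt(paths["gene_sets"])
            ranked = de_res["stat"].dropna()
            enr = preranked_test(ranked, gene_sets)
            enr_path = out / "enrichment.tsv"
            enr.to_csv(enr_path, sep="\t", float_format="%.10g")

            cm = CountMatrix.from_tsv(paths["gene_counts"], paths["samples"])
            from .counts_de import size_factors

            norm = np.log2(cm.counts / size_factors(cm.counts) + 1.0)
            vehicle = cm.samples[cm.samples["condition"] == "DMSO"]
            expr = norm[vehicle.index].T.groupby(vehicle["cell_line"]).mean().T
            ss = SSGSEA(gene_sets, alpha=config.ssgsea_alpha).fit().transform(expr)
            ss_path = out / "ssgsea.tsv"
            ss.to_csv(ss_path, sep="\t", float_format="%.10g")
            scores_tbl = pd.read_csv(paths["scores"], sep="\t", index_col=0)
            labels = scores_tbl["binary_class"]
            cmp_path = out / "ssgsea_group_comparison.tsv"
            if (labels == "HIGH").sum() >= 2 and (labels == "LOW").sum() >= 2:
                cmp = compare_groups(ss, labels)
                cmp.to_csv(cmp_path, sep="\t", float_format="%.10g")
                group_p = cmp["p_value"].to_dict()
            else:
                group_p = {"skipped": "a sensitivity group has < 2 lines"}
            report["enrichment"] = {
                "preranked": enr["p_value"].to_dict(),
                "ssgsea_group_p": group_p,
            }
            record(
                stage,
                {"ssgsea_alpha": config.ssgsea_alpha},
                [paths["de"], paths["gene_sets"], paths["gene_counts"]],
                [enr_path, ss_path, cmp_path],
            )
    except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
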
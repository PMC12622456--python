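"""End-to-end orchestration with a YAML run config and a run manifest.

Stage order follows the analysis design: preprocess each omics layer ->
differential testing per layer -> site classification -> chain-linkage
quantification -> enzyme-substrate mapping.  One global seed spawns
independent per-stage substreams, so adding a stage never perturbs the
draws of earlier stages, and (inputs, config, seed) fully determine every
output byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarker import (
    SummaryStats,
    correlation_matrix,
    roc_auc,
    roc_curve_points,
    ttest_cohort,
    ttest_from_summary,
)
from .diffexpr import DiffParams, count_differential, differential_expression
from .esi import candidate_pairs, rank_retained, retain_modifying
from .integrate import ClassifyParams, classify_sites, summarize_classification
from .io import (
    annotations_frame,
    read_abundance_table,
    read_annotations,
    read_clinical,
    read_design,
    read_esi_library,
    write_results,
)
from .linkage import extract_linkage_sites, linkage_abundance
from .preprocess import PreprocessParams, preprocess_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_integrate", "run_biomarker"]

# substream labels: stable across releases so reruns reproduce
_STAGE_STREAMS = ("preprocess_proteome", "preprocess_ubiquitinome")


@dataclass
class RunConfig:
    """Paths and per-stage parameter blocks for a pipeline run."""

    proteome: str | None = None
    ubiquitinome: str | None = None
    design: str | None = None
    annotations: str | None = None
    esi_library: str | None = None
    clinical: str | None = None
    clinical_summary: dict | None = None  # mean1/sd1/n1/mean2/sd2/n2 [+units]
    roc_variable: str = "Gln"
    group_order: tuple[str, str] | None = None
    out_dir: str = "results"
    seed: int = 0
    zero_is_missing: bool = False
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    diffexpr: DiffParams = field(default_factory=DiffParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "preprocess" in kwargs:
            kwargs["preprocess"] = PreprocessParams(**kwargs["preprocess"])
        if "diffexpr" in kwargs:
            kwargs["diffexpr"] = DiffParams(**kwargs["diffexpr"])
        if "classify" in kwargs:
            kwargs["classify"] = ClassifyParams(**kwargs["classify"])
        if kwargs.get("group_order") is not None:
            kwargs["group_order"] = tuple(kwargs["group_order"])
        return cls(**kwargs)

    def validate_paths(self, required: tuple[str, ...]) -> None:
        missing = []
        for name in required:
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                missing.append(f"{name}={p}")
        if missing:
            raise FileNotFoundError(f"missing input paths: {', '.join(missing)}")

    def params_dict(self) -> dict:
        return {
            "seed": self.seed,
            "group_order": list(self.group_order) if self.group_order else None,
            "zero_is_missing": self.zero_is_missing,
            "preprocess": dataclasses.asdict(self.preprocess),
            "diffexpr": dataclasses.asdict(self.diffexpr),
            "classify": dataclasses.asdict(self.classify),
        }


def _stage_rngs(seed: int, labels: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(labels))
    return {lab: np.random.default_rng(ss) for lab, ss in zip(labels, children)}


def run_integrate(config: RunConfig) -> dict[str, Path]:
    """Execute the full proteome-ubiquitinome integration.

    Writes per-stage TSVs plus a JSON manifest (version, parameters, seed,
    per-stage counts) into ``config.out_dir``; rerunning with the same
    inputs and config reproduces identical files.
    """
    config.validate_paths(("proteome", "ubiquitinome", "design", "annotations"))
    stage = "read_inputs"
    try:
        design = read_design(config.design, config.group_order)
        proteome = read_abundance_table(
            config.proteome, zero_is_missing=config.zero_is_missing
        )
        ubiquitinome = read_abundance_table(
            config.ubiquitinome, zero_is_missing=config.zero_is_missing
        )
        annotations = annotations_frame(read_annotations(config.annotations))
        library = read_esi_library(config.esi_library) if config.esi_library else None

        rngs = _stage_rngs(config.seed, _STAGE_STREAMS)
        counts: dict[str, object] = {
            "proteome_features_in": int(len(proteome.feature_ids)),
            "ubiquitinome_features_in": int(len(ubiquitinome.feature_ids)),
        }

        stage = "preprocess"
        prot = preprocess_matrix(
            proteome, design, config.preprocess.max_missing_protein,
            config.preprocess, rng=rngs["preprocess_proteome"],
        )
        ubi = preprocess_matrix(
            ubiquitinome, design, config.preprocess.max_missing_peptide,
            config.preprocess, rng=rngs["preprocess_ubiquitinome"],
        )
        counts["proteome_features_kept"] = int(len(prot.feature_ids))
        counts["ubiquitinome_features_kept"] = int(len(ubi.feature_ids))
        logger.info(
            "preprocess: proteome %d -> %d, ubiquitinome %d -> %d features",
            counts["proteome_features_in"], counts["proteome_features_kept"],
            counts["ubiquitinome_features_in"], counts["ubiquitinome_features_kept"],
        )

        stage = "diffexpr"
        de_prot = differential_expression(prot, design, config.diffexpr)
        de_ubi = differential_expression(ubi, design, config.diffexpr)
        counts["proteins_up"], counts["proteins_down"] = count_differential(de_prot)
        counts["sites_up"], counts["sites_down"] = count_differential(de_ubi)
        logger.info(
            "differential: %d/%d proteins up/down, %d/%d sites up/down",
            counts["proteins_up"], counts["proteins_down"],
            counts["sites_up"], counts["sites_down"],
        )

        stage = "classify"
        classifications = classify_sites(
            de_ubi, de_prot, annotations, ubi, prot, config.classify
        )
        summary = summarize_classification(classifications)
        counts["classes"] = {
            r["class"]: {"n_sites": r["n_sites"], "n_proteins": r["n_proteins"]}
            for _, r in summary.iterrows()
        }
        logger.info("classification: %s", counts["classes"])

        stage = "linkage"
        linkage_sites = extract_linkage_sites(annotations)
        linkage_table = linkage_abundance(ubi, linkage_sites, design, config.diffexpr)
        counts["linkages_detected"] = int(len(linkage_table))

        stage = "esi"
        tables = {
            "diff_proteome": de_prot,
            "diff_ubiquitinome": de_ubi,
            "site_classification": classifications,
            "classification_summary": summary,
            "linkage_profile": linkage_table,
        }
        if library is not None:
            enzyme_ids = set(library.records["enzyme_id"])
            de_enzymes = de_prot[de_prot["feature_id"].isin(enzyme_ids)]
            pairs = candidate_pairs(de_enzymes, de_ubi, annotations, library)
            pairs = rank_retained(retain_modifying(pairs))
            counts["esi_candidates"] = int(len(pairs))
            counts["esi_retained"] = int(pairs["retained"].sum())
            logger.info(
                "ESI: %d candidate pairs, %d retained",
                counts["esi_candidates"], counts["esi_retained"],
            )
            tables["esi_pairs"] = pairs

        stage = "write"
        manifest = {
            "ubiflow_version": __version__,
            "parameters": config.params_dict(),
            "counts": counts,
        }
        return write_results(tables, config.out_dir, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def run_biomarker(config: RunConfig) -> dict[str, Path]:
    """Clinical statistics: t-test (raw or summary), ROC, correlations."""
    tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, object] = {}
    if config.clinical is not None:
        config.validate_paths(("clinical",))
        cohort = read_clinical(config.clinical)
        var = config.roc_variable
        t, df, p, s = ttest_cohort(cohort, var)
        tables["biomarker_ttest"] = pd.DataFrame(
            [{"variable": var, "t": t, "df": df, "pvalue": p,
              "mean_normal": s.mean1, "sd_normal": s.sd1, "n_normal": s.n1,
              "mean_case": s.mean2, "sd_case": s.sd2, "n_case": s.n2}]
        )
        labels = (cohort.subjects["group"] == cohort.group_order[1]).astype(int)
        scores = cohort.subjects[var].astype(float)
        roc = roc_auc(scores, labels)
        tables["biomarker_roc"] = roc_curve_points(scores, labels)
        tables["biomarker_corr"] = (
            correlation_matrix(cohort).rename_axis("variable").reset_index()
        )
        counts["auc"] = roc.auc
        counts["n_subjects"] = int(len(cohort.subjects))
        counts["ttest_pvalue"] = p
    elif config.clinical_summary is not None:
        s = SummaryStats(**config.clinical_summary)
        t, df, p = ttest_from_summary(s)
        tables["biomarker_ttest"] = pd.DataFrame(
            [{"variable": config.roc_variable, "t": t, "df": df, "pvalue": p,
              "mean_normal": s.mean1, "sd_normal": s.sd1, "n_normal": s.n1,
              "mean_case": s.mean2, "sd_case": s.sd2, "n_case": s.n2}]
        )
        counts["ttest_pvalue"] = p
    else:
        raise ValueError("biomarker stage needs 'clinical' or 'clinical_summary'")
    manifest = {
        "ubiflow_version": __version__,
        "parameters": {"seed": config.seed, "roc_variable": config.roc_variable},
        "counts": counts,
    }
    return write_results(tables, config.out_dir, manifest)
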
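"""Configuration-driven orchestration of the analysis stages.

A :class:`RunConfig` toggles stages and surfaces every operational threshold
by name (selection score 7, z-score 3, 500 tumor cells, miR-21 cutoff 150,
IHC fraction 0.45, recurrence 5, MAF 0.01, CNV log2 0.5 and P 0.05).  All
randomness flows from the single root seed, split per stage inside
:class:`~oncomir.syndata.SimConfig`, so a fixed seed reproduces every
numeric output byte for byte.
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

from . import assays, mirscore, spatial, survstrat, varfilter
from .syndata import SimConfig, drop_truth_columns

logger = logging.getLogger(__name__)

ALL_STAGES = ("syndata", "mirscore", "assays", "tma", "varfilter", "survival")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "oncomir_out"
    stages: dict = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    inputs: dict = field(default_factory=dict)  # optional paths per stage
    syndata: dict = field(default_factory=dict)  # SimConfig overrides
    mirscore: dict = field(default_factory=lambda: {"threshold": 7})
    tma: dict = field(
        default_factory=lambda: {
            "z_threshold": 3.0,
            "min_tumor_cells": 500,
            "mir21_cutoff": 150.0,
            "pairing": "unpaired",
        }
    )
    ihc: dict = field(default_factory=lambda: {"threshold": 0.45})
    varfilter: dict = field(
        default_factory=lambda: {"recurrence_cutoff": 5, "maf_cutoff": 0.01}
    )
    cnv: dict = field(default_factory=lambda: {"log2_cutoff": 0.5, "p_cutoff": 0.05})
    write_cells: bool = False
    make_figures: bool = False

    def __post_init__(self) -> None:
        self.validate()

    _PARAM_DEFAULTS = {
        "mirscore": {"threshold": 7},
        "tma": {"z_threshold": 3.0, "min_tumor_cells": 500,
                "mir21_cutoff": 150.0, "pairing": "unpaired"},
        "ihc": {"threshold": 0.45},
        "varfilter": {"recurrence_cutoff": 5, "maf_cutoff": 0.01},
        "cnv": {"log2_cutoff": 0.5, "p_cutoff": 0.05},
    }

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        full = {s: True for s in ALL_STAGES}
        full.update(self.stages)
        self.stages = full
        # partial parameter blocks inherit the documented defaults
        for block, defaults in self._PARAM_DEFAULTS.items():
            given = getattr(self, block)
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown {block} parameter(s): {sorted(unknown)}")
            merged = dict(defaults)
            merged.update(given)
            setattr(self, block, merged)
        if not 1 <= self.mirscore.get("threshold", 7) <= 8:
            raise ValueError("mirscore.threshold must lie in [1, 8]")
        if self.tma.get("z_threshold", 3.0) <= 0:
            raise ValueError("tma.z_threshold must be positive")
        if self.tma.get("min_tumor_cells", 500) < 0:
            raise ValueError("tma.min_tumor_cells must be >= 0")
        if not 0.0 <= self.ihc.get("threshold", 0.45) <= 1.0:
            raise ValueError("ihc.threshold must lie in [0, 1]")
        if self.varfilter.get("recurrence_cutoff", 5) < 1:
            raise ValueError("varfilter.recurrence_cutoff must be >= 1")
        if not 0.0 <= self.varfilter.get("maf_cutoff", 0.01) <= 1.0:
            raise ValueError("varfilter.maf_cutoff must lie in [0, 1]")
        if not 0.0 <= self.cnv.get("p_cutoff", 0.05) <= 1.0:
            raise ValueError("cnv.p_cutoff must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order.

    Writes per-stage TSV/JSON outputs plus a single ``report.json`` with the
    headline numbers, and returns the report as a dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.stages
    report: dict = {"seed": config.seed, "stages": [s for s in ALL_STAGES if stages[s]]}

    sim = SimConfig(seed=config.seed, **config.syndata) if stages["syndata"] else None

    def _require(stage: str, input_key: str):
        if sim is None and input_key not in config.inputs:
            raise ValueError(
                f"stage {stage!r} needs either the syndata stage enabled or "
                f"inputs[{input_key!r}]"
            )

    # --- miRNA prioritization -------------------------------------------
    if stages["mirscore"]:
        _require("mirscore", "expression")
        if "expression" in config.inputs:
            matrix = mirscore.ExpressionMatrix.from_csv(
                config.inputs["expression"], config.inputs["groups"]
            )
            evidence = pd.read_csv(config.inputs["evidence"], sep="\t")
        else:
            from .syndata import gen_expression_matrix, gen_evidence_table

            matrix = gen_expression_matrix(sim)
            evidence = drop_truth_columns(gen_evidence_table(sim))
            matrix.to_csv(outdir / "expression.csv", outdir / "sample_groups.csv")
            evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
        scores = mirscore.combine_and_select(
            matrix, evidence, threshold=config.mirscore["threshold"]
        )
        scores.to_csv(outdir / "mir_scores.tsv", sep="\t", index=False)
        selected = scores.loc[scores["selected"], "mir_id"].tolist()
        report["mirscore"] = {
            "threshold": config.mirscore["threshold"],
            "n_selected": len(selected),
            "selected": selected,
        }

    # --- reporter assays and CDI ----------------------------------------
    if stages["assays"]:
        _require("assays", "wells")
        if "wells" in config.inputs:
            wells = pd.read_csv(config.inputs["wells"])
        else:
            from .syndata import gen_luciferase_plate

            wells = drop_truth_columns(gen_luciferase_plate(sim))
            wells.to_csv(outdir / "luciferase_wells.csv", index=False)
        activities = assays.normalize_luciferase(wells)
        activities.to_csv(outdir / "luciferase_activities.tsv", sep="\t", index=False)
        cdi_tab = assays.cdi_table(activities)
        cdi_tab.to_csv(outdir / "cdi.tsv", sep="\t", index=False)
        report["assays"] = {
            "activities": {
                r.condition: round(float(r.relative_activity), 6)
                for r in activities.itertuples()
            },
            "cdi": {
                r.combination: {"cdi": round(float(r.cdi), 6),
                                "classification": r.classification}
                for r in cdi_tab.itertuples()
            },
        }

    # --- spatial TMA pipeline -------------------------------------------
    if stages["tma"]:
        _require("tma", "cells")
        if "cells" in config.inputs:
            cells = pd.read_csv(config.inputs["cells"])
        else:
            from .syndata import gen_tma_cohort

            cells = drop_truth_columns(gen_tma_cohort(sim))
        cells = spatial.merge_and_filter(cells, z_threshold=config.tma["z_threshold"])
        if config.write_cells:
            cells.to_csv(outdir / "cells.csv", index=False)
        summaries = spatial.summarize_cores(
            cells, min_tumor_cells=config.tma["min_tumor_cells"]
        )
        summaries.to_csv(outdir / "core_summaries.tsv", sep="\t", index=False)
        ranked = spatial.rank_cores(summaries)
        ranked.to_csv(outdir / "core_ranking.tsv", sep="\t", index=False)
        strat = spatial.stratify_and_test(
            summaries,
            mir21_cutoff=config.tma["mir21_cutoff"],
            pairing=config.tma["pairing"],
        )
        comp = spatial.compare_compartments(cells)
        if config.make_figures and len(cells):
            first = cells.loc[cells["core_id"] == cells["core_id"].iloc[0]]
            spatial.reconstruct(first, outdir / "core_reconstruction.png")
        report["tma"] = {
            "n_cells": int(len(cells)),
            "excluded_fraction": round(float(cells["excluded"].mean()), 6),
            "n_cores": int(len(summaries)),
            "n_included_cores": int(summaries["included"].sum()),
            "mean_pearson_r": round(
                float(summaries.loc[summaries["included"], "pearson_r"].mean()), 6
            ),
            "stratification": {
                "cutoff": config.tma["mir21_cutoff"],
                "n_high": strat.n_high,
                "n_low": strat.n_low,
                "mean_cdk2ap1_high": round(strat.mean_high, 6),
                "mean_cdk2ap1_low": round(strat.mean_low, 6),
                "p_value": strat.p_value,
                "status": strat.status,
            },
            "stroma_tumor_mir21_ratio": round(float(comp["mean_ratio"]), 6),
            "compartment_test_p": comp["p_value"],
        }

    # --- variant cascade -------------------------------------------------
    if stages["varfilter"]:
        _require("varfilter", "variants")
        if "variants" in config.inputs:
            variants = varfilter.read_variants_tsv(config.inputs["variants"])
        else:
            from .syndata import gen_variant_table

            variants = drop_truth_columns(gen_variant_table(sim))
            variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        survivors, tally = varfilter.filter_cascade(
            variants,
            recurrence_cutoff=config.varfilter["recurrence_cutoff"],
            maf_cutoff=config.varfilter["maf_cutoff"],
        )
        survivors.to_csv(outdir / "variant_survivors.tsv", sep="\t", index=False)
        (outdir / "variant_tally.json").write_text(json.dumps(tally, indent=2))
        report["varfilter"] = {"tally": tally, "n_input": int(len(variants))}

    # --- survival stratification ----------------------------------------
    if stages["survival"]:
        _require("survival", "clinical")
        if "clinical" in config.inputs:
            clinical = pd.read_csv(config.inputs["clinical"])
        else:
            from .syndata import gen_survival_cohort

            clinical = drop_truth_columns(gen_survival_cohort(sim))
            clinical.to_csv(outdir / "clinical.csv", index=False)
        ihc_labels = clinical["frac_cdk2ap1_negative"].map(
            lambda f: survstrat.ihc_classify(f, threshold=config.ihc["threshold"])
        )
        km = survstrat.km_logrank(clinical, ihc_labels)
        two = None
        markers = [c for c in clinical.columns if c.startswith("miR-")]
        if len(markers) >= 2:
            two = survstrat.stratify_two_markers(clinical, markers[0], markers[1])
        for name, res in [("ihc", km)] + ([("two_marker", two)] if two else []):
            for g, curve in res.km_curves.items():
                safe = g.replace("/", "-")
                curve.to_csv(outdir / f"km_{name}_{safe}.tsv", sep="\t", index=False)
        report["survival"] = {
            "ihc_threshold": config.ihc["threshold"],
            "ihc_logrank_p": km.p_value,
            "ihc_group_sizes": km.labels.value_counts().to_dict(),
        }
        if two is not None:
            report["survival"]["two_marker"] = {
                "markers": markers[:2],
                "overall_logrank_p": two.p_value,
                "contrasts": two.contrasts,
                "skipped_groups": two.skipped,
            }

    report = _jsonable(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("report written to %s", outdir / "report.json")
    return report
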
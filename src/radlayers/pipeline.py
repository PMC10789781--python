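"""End-to-end orchestration of the three analyses behind one config:
differential methylation (calling, filtering, DMR building, genomic
context), spatial layering (Hi-C layers and layer-wise summaries with the
permutation null), and expression validation.

Driven by a YAML/JSON config; every run writes its outputs, a log, and a
run manifest (config hash + seed) under a run directory, and is
deterministic given config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import chromatin_marks, data_io, diffmeth, expression, nuclear_layers, resampling_stats

logger = logging.getLogger("radlayers")

#: Default analysis thresholds (the values the method is defined with).
DEFAULT_THRESHOLDS = {
    "q_max": 0.05,
    "d_min": 0.58,
    "lambda": 1000,
    "min_probes": 2,
    "n_layers": 5,
    "B": 1000,
    "tss_halfwidth": 2000,
    "fdr_max": 0.05,
    "peak_min_len": 300,
    "peak_max_len": 2000,
}

ALL_STAGES = ("dmp", "dmr", "permute", "layers", "marks", "expression")
_STAGE_DEPS = {
    "dmp": (),
    "dmr": ("dmp",),
    "permute": ("dmp",),
    "layers": ("dmp",),
    "marks": ("dmp", "layers"),
    "expression": ("layers",),
}


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Validated run configuration (paths, comparisons, thresholds, seed)."""

    inputs: dict[str, Any]
    comparisons: list[dict[str, Any]]
    thresholds: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    expression_platform: str = "rnaseq"

    def __post_init__(self) -> None:
        self.thresholds = {**DEFAULT_THRESHOLDS, **self.thresholds}
        if not self.comparisons:
            raise data_io.ValidationError("config needs at least one comparison")
        for comp in self.comparisons:
            for key in ("name", "a", "b"):
                if key not in comp:
                    raise data_io.ValidationError(f"comparison missing key {key!r}: {comp}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            inputs=raw["inputs"],
            comparisons=raw["comparisons"],
            thresholds=raw.get("thresholds", {}),
            seed=int(raw.get("seed", 0)),
            expression_platform=raw.get("expression_platform", "rnaseq"),
        )

    def digest(self) -> str:
        payload = json.dumps(
            {
                "inputs": self.inputs,
                "comparisons": self.comparisons,
                "thresholds": self.thresholds,
                "seed": self.seed,
                "expression_platform": self.expression_platform,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _resolve_stages(stages) -> list[str]:
    if stages is None:
        wanted = set(ALL_STAGES)
    else:
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        wanted = set(stages)
        changed = True
        while changed:
            changed = False
            for s in list(wanted):
                for dep in _STAGE_DEPS[s]:
                    if dep not in wanted:
                        wanted.add(dep)
                        changed = True
    return [s for s in ALL_STAGES if s in wanted]


def _load_inputs(config: PipelineConfig) -> dict[str, Any]:
    paths = config.inputs
    loaded: dict[str, Any] = {}
    manifest = data_io.read_manifest(paths["manifest"])
    beta = data_io.read_matrix(paths["methylation"])
    samples = data_io.read_sample_sheet(paths["samples"])
    loaded["experiment"] = diffmeth.MethylationExperiment(beta, "beta", samples, manifest)
    loaded["manifest"] = manifest
    loaded["hic_track"] = data_io.read_intervals(paths["hic_track"], "bedgraph")
    loaded["islands"] = (
        data_io.read_intervals(paths["islands"], "bed") if "islands" in paths else []
    )
    peaks_cfg = paths.get("peaks", {})
    loaded["raw_peaks"] = {}
    loaded["peak_rules"] = {}
    for mark, spec in peaks_cfg.items():
        path = spec["path"] if isinstance(spec, dict) else spec
        rule = spec.get("score_rule", {}) if isinstance(spec, dict) else {}
        loaded["raw_peaks"][mark] = chromatin_marks.PeakSet(
            mark, data_io.read_intervals(path, "bed")
        )
        loaded["peak_rules"][mark] = (rule.get("op", "ge"), float(rule.get("threshold", 10)))
    if "tss" in paths:
        tss = pd.read_csv(paths["tss"], sep="\t", index_col="gene", dtype={"chrom": str})
        tss["pos0"] = tss.pop("pos") - 1
        loaded["tss"] = tss
    if "gene_bodies" in paths:
        loaded["gene_bodies"] = data_io.read_intervals(paths["gene_bodies"], "bed")
    if "expression_counts" in paths:
        counts = data_io.read_matrix(paths["expression_counts"])
        sheet = pd.read_csv(paths["expression_samples"], sep="\t", index_col="sample_id")
        order = list(dict.fromkeys(sheet["group"]))
        loaded["expression"] = expression.ExpressionExperiment(
            counts.round().astype(int) if config.expression_platform == "rnaseq" else counts,
            config.expression_platform,
            sheet["group"],
            order,
        )
    return loaded


def _resolve_group(experiment, spec: dict, comparison: str) -> list[str]:
    ids = experiment.sample_ids(
        spec["particle"], float(spec["dose_gy"]), spec.get("timepoint")
    )
    if not ids:
        raise PipelineError(
            f"comparison {comparison!r}: no samples match {spec} in the sample sheet"
        )
    return ids


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages=None,
) -> dict:
    """Run the selected stages (dependencies added automatically) and write
    all outputs + summary.json under ``outdir``. Returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        return _run(config, outdir, _resolve_stages(stages))
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path, stages: list[str]) -> dict:
    th = config.thresholds
    summary: dict[str, Any] = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": stages,
    }
    logger.info("loading inputs")
    try:
        data = _load_inputs(config)
    except Exception as exc:
        raise PipelineError(f"stage load: {exc}") from exc
    experiment = data["experiment"]
    manifest = data["manifest"]
    exp_m = experiment.to_m()
    control = diffmeth.define_control(exp_m)

    model = None
    if "layers" in stages or "marks" in stages or "expression" in stages:
        logger.info("building nuclear layers")
        scores, n_uncovered = nuclear_layers.assign_hic_scores(manifest, data["hic_track"])
        model = nuclear_layers.build_layers(scores, manifest, n_layers=th["n_layers"])
        model.n_uncovered = n_uncovered
        summary["layers"] = {
            "n_probes_assigned": int(len(scores)),
            "n_probes_uncovered": n_uncovered,
            "boundaries": [float(b) for b in model.boundaries],
            "occupancy": {k: int(v) for k, v in model.occupancy().items()},
        }
        nuclear_layers.layer_assignment_table(model).to_csv(
            outdir / "layer_assignments.tsv", sep="\t", index_label="probe_id"
        )

    filtered_peaks: dict[str, chromatin_marks.PeakSet] = {}
    if "marks" in stages:
        logger.info("filtering histone peaks")
        summary["marks"] = {"peak_filter": {}}
        for mark, raw in data["raw_peaks"].items():
            kept, removed = chromatin_marks.filter_peaks(
                raw,
                min_len=th["peak_min_len"],
                max_len=th["peak_max_len"],
                score_rule=data["peak_rules"][mark],
            )
            filtered_peaks[mark] = kept
            summary["marks"]["peak_filter"][mark] = {
                "kept": len(kept), "removed": removed,
            }
            data_io.write_intervals(outdir / f"peaks_filtered_{mark}.bed", kept.peaks, "bed")
        mark_flags = chromatin_marks.overlap_probes(filtered_peaks, manifest)
        if model is not None:
            dist = chromatin_marks.layer_mark_distribution(mark_flags, model)
            dist.to_csv(outdir / "layer_mark_distribution.tsv", sep="\t")
            summary["marks"]["layer_distribution"] = _frame_dict(dist)

    summary["comparisons"] = {}
    for comp in config.comparisons:
        name = comp["name"]
        logger.info("comparison %s", name)
        group_a = _resolve_group(experiment, comp["a"], name)
        group_b = _resolve_group(experiment, comp["b"], name)
        comp_out: dict[str, Any] = {}
        dmps = diffmeth.call_dmps(
            exp_m, group_a, group_b, control, q_max=th["q_max"], d_min=th["d_min"]
        )
        dmps = diffmeth.classify_subgroups(dmps, control)
        passing = dmps[dmps["passes"]]
        comp_out["n_dmps"] = int(len(passing))
        comp_out["n_probes_tested"] = int(dmps["p"].notna().sum())
        _write_dmps(outdir / f"dmps_{name}.tsv", dmps, manifest)

        if len(passing):
            rel3 = diffmeth.classify_cpg_relation(
                manifest.df.loc[passing.index, "chrom"].to_numpy(),
                manifest.df.loc[passing.index, "pos0"].to_numpy(),
                data["islands"],
                merged=True,
            ) if data["islands"] else manifest.df.loc[passing.index, "cpg_relation"].to_numpy()
            comp_out["cpg_fractions"] = diffmeth.fraction_table(rel3)["fraction"].to_dict()
            comp_out["genic_fractions"] = diffmeth.fraction_table(
                manifest.df.loc[passing.index, "genic_group"]
            )["fraction"].to_dict()

        if "dmr" in stages:
            dmr_table, in_dmr, frac = diffmeth.build_dmrs(
                passing, manifest, lam=th["lambda"], min_probes=th["min_probes"]
            )
            comp_out["n_dmrs"] = int(len(dmr_table))
            comp_out["fraction_inside_dmrs"] = float(frac)
            if len(dmr_table):
                dmr_table.drop(columns="probe_ids").to_csv(
                    outdir / f"dmrs_{name}.tsv", sep="\t", index=False
                )
                data_io.write_intervals(
                    outdir / f"dmrs_{name}.bed",
                    diffmeth.dmrs_to_intervals(dmr_table),
                    "bed",
                )

        if "permute" in stages:
            perm = resampling_stats.dmr_fraction_permutation_test(
                experiment, group_a, group_b,
                B=th["B"], seed=np.random.default_rng([config.seed, 7]),
                q_max=th["q_max"], d_min=th["d_min"],
                lam=th["lambda"], min_probes=th["min_probes"],
            )
            comp_out["permutation"] = perm.summary()

        if model is not None and len(passing):
            dmp_prof, probe_prof = nuclear_layers.layer_frequency(
                passing.index.intersection(model.layer.index), model
            )
            comp_out["layer_dmp_frequency"] = _series_dict(dmp_prof.values)
            comp_out["layer_mean_abs_change"] = _series_dict(
                nuclear_layers.layer_mean_abs_change(passing, model).values
            )
            comp_out["chromosome_normalized_frequency"] = _series_dict(
                nuclear_layers.chromosome_normalized_frequency(passing.index, manifest)
            )

        if "marks" in stages and model is not None and len(passing):
            mark_flags = chromatin_marks.overlap_probes(filtered_peaks, manifest)
            enr = chromatin_marks.enrichment_table(passing.index, mark_flags, model)
            enr.to_csv(outdir / f"enrichment_marks_{name}.tsv", sep="\t")
            comp_out["mark_enrichment"] = _frame_dict(enr)
            if "tss" in data and "gene_bodies" in data:
                groups = chromatin_marks.build_regulatory_groups(
                    data["tss"], data["gene_bodies"],
                    filtered_peaks.get("H3K4me3", chromatin_marks.PeakSet("H3K4me3")),
                    filtered_peaks.get("H3K27ac", chromatin_marks.PeakSet("H3K27ac")),
                    tss_halfwidth=th["tss_halfwidth"],
                )
                reg_flags = chromatin_marks.regulatory_probe_flags(groups, manifest)
                change = chromatin_marks.group_methylation_change(
                    passing, reg_flags, model, control
                )
                change["mean_abs_delta"].to_csv(
                    outdir / f"regulatory_change_{name}.tsv", sep="\t"
                )
                comp_out["regulatory_mean_abs_delta"] = _frame_dict(change["mean_abs_delta"])

        summary["comparisons"][name] = comp_out

    if "expression" in stages and "expression" in data:
        logger.info("expression validation")
        expr = data["expression"]
        gate_table = expression.de_gate(expr, fdr_max=th["fdr_max"])
        gated = gate_table.index[gate_table["gate"]]
        expr_out: dict[str, Any] = {
            "n_genes": int(len(gate_table)),
            "n_gated": int(len(gated)),
        }
        if len(gated):
            traj = expression.logfc_trajectory(expr, gated)
            expr_out["class_counts"] = traj.cls.value_counts().to_dict()
            expr_out["class_mean_trajectories"] = _frame_dict(traj.class_means)
            expr_out["trend"] = {
                c: {k: {kk: _num(vv) for kk, vv in v.items()} for k, v in tests.items()}
                for c, tests in traj.trend.items()
            }
            out = traj.logfc.copy()
            out["class"] = traj.cls
            out["fdr"] = gate_table.loc[gated, "fdr"]
            out.to_csv(outdir / "expression_trajectories.tsv", sep="\t", index_label="gene")
        summary["expression"] = expr_out

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(
            {"config_digest": config.digest(), "seed": config.seed, "stages": stages},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    logger.info("run complete: %s", summary_path)
    return summary


def _write_dmps(path: Path, dmps: pd.DataFrame, manifest) -> None:
    out = dmps.copy()
    pos = manifest.positions(out.index)
    out.insert(0, "chrom", pos["chrom"])
    out.insert(1, "pos", pos["pos0"] + 1)
    out.to_csv(path, sep="\t", index_label="probe_id")


def _series_dict(s: pd.Series) -> dict:
    return {str(k): _num(v) for k, v in s.items()}


def _frame_dict(df: pd.DataFrame) -> dict:
    return {str(idx): _series_dict(row) for idx, row in df.iterrows()}


def _num(x):
    if isinstance(x, dict):
        return {k: _num(v) for k, v in x.items()}
    if isinstance(x, (np.floating, float)):
        x = float(x)
        return None if np.isnan(x) else x
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, (list, tuple)):
        return [_num(v) for v in x]
    return x


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(_num(v) if not isinstance(v, (dict, list)) else v, ndigits)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return _num(obj)
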
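"""Histone-mark context: peak filtering, probe/peak overlap, layer-wise mark
distributions, the DMP-occurrence enrichment ratio and the five regulatory
region groups (promoter classes by H3K4me3/H3K27ac status plus
H3K27ac-marked enhancers outside genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    GenomicInterval,
    ProbeManifest,
    ValidationError,
    merge_intervals,
    points_in_intervals,
)
from .nuclear_layers import LayerModel, LayerProfile, layer_names

#: The four profiled histone modifications.
MARKS = ("H3K4me3", "H3K27ac", "H3K27me3", "H3K9me3")
#: The five regulatory region classes.
REGULATORY_GROUPS = (
    "k4_promoters",
    "k27ac_promoters",
    "dual_promoters",
    "bare_promoters",
    "k27ac_enhancers",
)


@dataclass
class PeakSet:
    """A named histone mark with its (possibly filtered) peak intervals."""

    mark: str
    peaks: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class RegulatoryGroups:
    """The five promoter/enhancer interval classes.

    The four promoter classes partition the TSS-region set; enhancers are
    H3K27ac peaks disjoint from every TSS region and gene body.
    """

    k4_promoters: list[GenomicInterval]
    k27ac_promoters: list[GenomicInterval]
    dual_promoters: list[GenomicInterval]
    bare_promoters: list[GenomicInterval]
    k27ac_enhancers: list[GenomicInterval]

    def as_dict(self) -> dict[str, list[GenomicInterval]]:
        return {name: getattr(self, name) for name in REGULATORY_GROUPS}


def filter_peaks(
    raw: PeakSet,
    min_len: int = 300,
    max_len: int = 2000,
    score_rule: tuple[str, float] = ("ge", 10.0),
) -> tuple[PeakSet, dict[str, int]]:
    """Keep peaks with length in [min_len, max_len] whose alignment score
    satisfies the rule (``("ge", t)`` keeps score >= t, ``("gt", t)`` keeps
    score > t). Returns the filtered set and removal counts by first failing
    reason (length checked before score).
    """
    op, threshold = score_rule
    if op not in ("ge", "gt"):
        raise ValueError(f"unknown score rule op: {op!r}")
    kept: list[GenomicInterval] = []
    removed = {"too_short": 0, "too_long": 0, "score": 0, "no_score": 0}
    for pk in raw.peaks:
        length = len(pk)
        if length < min_len:
            removed["too_short"] += 1
        elif length > max_len:
            removed["too_long"] += 1
        elif pk.score is None:
            removed["no_score"] += 1
        elif (pk.score >= threshold) if op == "ge" else (pk.score > threshold):
            kept.append(pk)
        else:
            removed["score"] += 1
    return PeakSet(raw.mark, kept), removed


def overlap_probes(
    peak_sets: dict[str, PeakSet], manifest: ProbeManifest
) -> pd.DataFrame:
    """probe x mark boolean flags: probe point lies inside >= 1 peak of the mark.

    A probe may carry several marks (peaks of different marks overlap).
    """
    pos = manifest.positions()
    chroms = pos["chrom"].to_numpy()
    pts = pos["pos0"].to_numpy()
    flags = {}
    for mark, ps in peak_sets.items():
        merged = merge_intervals(ps.peaks)
        flags[mark] = points_in_intervals(chroms, pts, merged)
    return pd.DataFrame(flags, index=pos.index)


def layer_mark_distribution(
    mark_flags: pd.DataFrame, model: LayerModel
) -> pd.DataFrame:
    """mark x layer percentages: how each mark's probes spread over layers.

    Rows sum to 100%; a mark with zero flagged probes yields a NaN row
    (flagged undefined rather than zeros).
    """
    ids = mark_flags.index.intersection(model.layer.index)
    layers = model.layer.loc[ids]
    names = layer_names(model.n_layers)
    rows = {}
    for mark in mark_flags.columns:
        flagged = layers[mark_flags.loc[ids, mark]]
        total = len(flagged)
        if total == 0:
            rows[mark] = pd.Series(np.nan, index=names)
        else:
            rows[mark] = 100 * flagged.value_counts().reindex(names, fill_value=0) / total
    return pd.DataFrame(rows).T.reindex(columns=names)


def dmp_enrichment_ratio(
    dmp_ids,
    region_flags: pd.Series,
    model: LayerModel,
    layer: str,
) -> float:
    """Probability ratio of DMP occurrence in a region class within a layer.

    ratio = (DMPs in-region in-layer / all DMPs)
          / (region probes in-layer / all region probes)

    1.0 means the layer's regions carry exactly their expected share of
    DMPs. Zero denominators yield NaN (undefined, never 0). Only probes
    with a layer assignment participate.
    """
    dmp_ids = pd.Index(dmp_ids).intersection(model.layer.index)
    region_ids = region_flags.index[region_flags.astype(bool)].intersection(model.layer.index)
    n_dmps = len(dmp_ids)
    n_region = len(region_ids)
    if n_dmps == 0 or n_region == 0:
        return float("nan")
    in_layer = model.probes_in(layer)
    region_in_layer = region_ids.intersection(in_layer)
    if len(region_in_layer) == 0:
        return float("nan")
    dmp_region_layer = dmp_ids.intersection(region_in_layer)
    num = len(dmp_region_layer) / n_dmps
    den = len(region_in_layer) / n_region
    return num / den


def enrichment_table(
    dmp_ids, region_flags: pd.DataFrame, model: LayerModel
) -> pd.DataFrame:
    """region-class x layer table of :func:`dmp_enrichment_ratio` values."""
    names = layer_names(model.n_layers)
    out = {}
    for col in region_flags.columns:
        out[col] = pd.Series(
            {ly: dmp_enrichment_ratio(dmp_ids, region_flags[col], model, ly) for ly in names}
        )
    return pd.DataFrame(out).T.reindex(columns=names)


def _regions_overlapping(
    regions: list[GenomicInterval], merged: dict[str, np.ndarray]
) -> np.ndarray:
    """Boolean per region: shares >= 1 bp with the merged interval set."""
    out = np.zeros(len(regions), dtype=bool)
    # group regions per chromosome, then vectorised overlap against the
    # sorted merged set: [s, e) overlaps iff some merged start < e and the
    # running max of merged ends before that index exceeds s.
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        arr = merged.get(chrom)
        if arr is None or len(arr) == 0:
            continue
        starts = arr[:, 0]
        end_cummax = np.maximum.accumulate(arr[:, 1])
        s = np.array([regions[i].start for i in idxs])
        e = np.array([regions[i].end for i in idxs])
        k = np.searchsorted(starts, e, side="left")  # merged intervals starting before e
        hit = (k > 0) & (end_cummax[np.clip(k - 1, 0, None)] > s)
        out[np.array(idxs)] = hit
    return out


def build_regulatory_groups(
    tss: pd.DataFrame,
    gene_bodies: list[GenomicInterval],
    k4: PeakSet,
    k27ac: PeakSet,
    tss_halfwidth: int = 2000,
) -> RegulatoryGroups:
    """Partition TSS regions into four promoter classes and collect enhancers.

    TSS regions are ``[pos0 - halfwidth, pos0 + halfwidth)`` windows
    (clipped at 0), assigned to exactly one class by which filtered marks
    overlap them (>= 1 shared bp). Enhancers are H3K27ac peaks with zero
    overlap of any TSS region or gene body.

    ``tss`` needs columns ``chrom`` and ``pos0`` (index = gene id).
    """
    regions = [
        GenomicInterval(
            row["chrom"],
            max(0, int(row["pos0"]) - tss_halfwidth),
            int(row["pos0"]) + tss_halfwidth,
            name=str(gene),
        )
        for gene, row in tss.iterrows()
    ]
    k4_merged = merge_intervals(k4.peaks)
    k27_merged = merge_intervals(k27ac.peaks)
    has_k4 = _regions_overlapping(regions, k4_merged)
    has_k27 = _regions_overlapping(regions, k27_merged)

    groups: dict[str, list[GenomicInterval]] = {name: [] for name in REGULATORY_GROUPS}
    for region, a, b in zip(regions, has_k4, has_k27):
        if a and b:
            groups["dual_promoters"].append(region)
        elif a:
            groups["k4_promoters"].append(region)
        elif b:
            groups["k27ac_promoters"].append(region)
        else:
            groups["bare_promoters"].append(region)

    excluded = merge_intervals(regions + list(gene_bodies))
    enhancer_hits = _regions_overlapping(k27ac.peaks, excluded)
    groups["k27ac_enhancers"] = [
        pk for pk, hit in zip(k27ac.peaks, enhancer_hits) if not hit
    ]
    return RegulatoryGroups(**groups)


def regulatory_probe_flags(
    groups: RegulatoryGroups, manifest: ProbeManifest
) -> pd.DataFrame:
    """probe x regulatory-group boolean flags (point-in-region)."""
    pos = manifest.positions()
    chroms = pos["chrom"].to_numpy()
    pts = pos["pos0"].to_numpy()
    flags = {}
    for name, intervals in groups.as_dict().items():
        flags[name] = points_in_intervals(chroms, pts, merge_intervals(intervals))
    return pd.DataFrame(flags, index=pos.index)


def group_methylation_change(
    dmps: pd.DataFrame,
    group_flags: pd.DataFrame,
    model: LayerModel,
    baseline_m: pd.Series,
) -> dict[str, pd.DataFrame]:
    """Per-group, per-layer mean |delta| and mean baseline M with counts.

    ``dmps`` must carry ``delta_vs_control``; rows of the output are the
    columns of ``group_flags`` plus an ``all_dmps`` row that reproduces the
    plain layer-wise mean absolute change. Cells without members are NaN.
    """
    names = layer_names(model.n_layers)
    ids = dmps.index.intersection(model.layer.index)
    layers = model.layer.loc[ids]
    abs_delta = dmps.loc[ids, "delta_vs_control"].abs()
    baseline = baseline_m.reindex(ids)

    mean_delta, mean_base, counts = {}, {}, {}
    group_cols = list(group_flags.columns) + ["all_dmps"]
    for name in group_cols:
        sel = (
            pd.Series(True, index=ids)
            if name == "all_dmps"
            else group_flags.loc[ids, name].astype(bool)
        )
        sub = pd.DataFrame(
            {"layer": layers[sel], "ad": abs_delta[sel], "bm": baseline[sel]}
        )
        grp = sub.groupby("layer")
        mean_delta[name] = grp["ad"].mean().reindex(names)
        mean_base[name] = grp["bm"].mean().reindex(names)
        counts[name] = grp["ad"].size().reindex(names, fill_value=0)
    return {
        "mean_abs_delta": pd.DataFrame(mean_delta).T.reindex(columns=names),
        "mean_baseline_m": pd.DataFrame(mean_base).T.reindex(columns=names),
        "counts": pd.DataFrame(counts).T.reindex(columns=names),
    }
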
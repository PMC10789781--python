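"""Radial nuclear layering from Hi-C scores.

Each probe inherits the score of the Hi-C bin containing it; probes are
then rank-split into five equal-occupancy layers, L1 holding the lowest
scores (nuclear periphery) through L5 the highest (interior). Higher score
means deeper in the nucleus. Layer-wise summaries — DMP frequency,
chromosome-normalised frequency and mean absolute methylation change —
mirror the spatial read-outs of the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GenomicInterval, ProbeManifest, ValidationError


def layer_names(n_layers: int) -> list[str]:
    return [f"L{i}" for i in range(1, n_layers + 1)]


@dataclass
class LayerProfile:
    """A per-layer value vector with its metric name and member counts."""

    values: pd.Series
    metric: str
    counts: pd.Series | None = None

    def argmax_layer(self) -> str:
        return str(self.values.idxmax())


@dataclass
class LayerModel:
    """Probe -> Hi-C score and equal-occupancy layer assignment.

    ``boundaries`` are the empirical 0/20/.../100% score quantiles (length
    ``n_layers + 1``); occupancy is enforced by rank, so layer sizes differ
    by at most 1 even under score ties.
    """

    scores: pd.Series
    layer: pd.Series
    boundaries: np.ndarray
    n_layers: int = 5
    n_uncovered: int = 0

    def probes_in(self, layer: str) -> pd.Index:
        return self.layer.index[self.layer == layer]

    def occupancy(self) -> pd.Series:
        return self.layer.value_counts().reindex(layer_names(self.n_layers), fill_value=0)


def assign_hic_scores(
    manifest: ProbeManifest, track: list[GenomicInterval]
) -> tuple[pd.Series, int]:
    """Score of the track interval containing each probe position.

    Track intervals must be non-overlapping per chromosome; probes not
    covered by any interval are dropped (their count is returned).
    Containment follows the half-open convention: a probe at ``pos0 == end``
    belongs to the next bin.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in track:
        if iv.score is None:
            raise ValidationError("Hi-C track intervals must carry a score")
        by_chrom.setdefault(iv.chrom, []).append(iv)

    pos = manifest.positions()
    chrom_arr = pos["chrom"].to_numpy()
    pos_arr = pos["pos0"].to_numpy()
    scores = np.full(len(pos), np.nan)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        if (starts[1:] < ends[:-1]).any():
            raise ValidationError(f"overlapping Hi-C track intervals on {chrom}")
        vals = np.array([iv.score for iv in ivs])
        sel = chrom_arr == chrom
        if not sel.any():
            continue
        idx = np.searchsorted(starts, pos_arr[sel], side="right") - 1
        ok = (idx >= 0) & (pos_arr[sel] < ends[np.clip(idx, 0, None)])
        hit = np.full(sel.sum(), np.nan)
        hit[ok] = vals[idx[ok]]
        scores[sel] = hit
    out = pd.Series(scores, index=pos.index, name="hic_score")
    n_uncovered = int(out.isna().sum())
    return out.dropna(), n_uncovered


def build_layers(
    scores: pd.Series,
    manifest: ProbeManifest,
    n_layers: int = 5,
) -> LayerModel:
    """Split scored probes into ``n_layers`` equal-occupancy layers by rank.

    Probes are ordered by the stable key (score, chrom, pos) and cut into
    contiguous blocks whose sizes differ by at most 1 (earlier layers take
    the remainder). L1 = lowest scores. Reported boundaries are the
    empirical quantiles of the score distribution. All-tied scores still
    fill every layer (rank rule), with a warning.
    """
    if len(scores) < n_layers:
        raise ValidationError(f"need at least {n_layers} scored probes")
    pos = manifest.positions(scores.index)
    order = np.lexsort(
        (pos["pos0"].to_numpy(), pos["chrom"].to_numpy(), scores.to_numpy())
    )
    if scores.nunique() == 1:
        warnings.warn("all Hi-C scores identical; layers filled by rank tie rule")
    n = len(scores)
    base, rem = divmod(n, n_layers)
    sizes = [base + (1 if i < rem else 0) for i in range(n_layers)]
    labels = np.empty(n, dtype=object)
    start = 0
    for i, size in enumerate(sizes):
        labels[order[start : start + size]] = f"L{i + 1}"
        start += size
    boundaries = np.quantile(scores.to_numpy(), np.linspace(0, 1, n_layers + 1))
    return LayerModel(
        scores=scores.copy(),
        layer=pd.Series(labels, index=scores.index, name="layer"),
        boundaries=boundaries,
        n_layers=n_layers,
    )


def layer_frequency(dmp_ids, model: LayerModel) -> tuple[LayerProfile, LayerProfile]:
    """Percent of DMPs per layer, alongside the same profile for non-DMP probes.

    Both profiles sum to 100% (given nonempty inputs).
    """
    dmp_ids = pd.Index(dmp_ids)
    unknown = dmp_ids.difference(model.layer.index)
    if len(unknown):
        raise ValidationError(f"DMPs without layer assignment: {list(unknown[:5])}")
    names = layer_names(model.n_layers)
    dmp_layers = model.layer.loc[dmp_ids]
    other_layers = model.layer.drop(dmp_ids)
    dmp_counts = dmp_layers.value_counts().reindex(names, fill_value=0)
    other_counts = other_layers.value_counts().reindex(names, fill_value=0)
    dmp_prof = LayerProfile(100 * dmp_counts / max(dmp_counts.sum(), 1),
                            "DMP frequency %", dmp_counts)
    other_prof = LayerProfile(100 * other_counts / max(other_counts.sum(), 1),
                              "non-DMP probe frequency %", other_counts)
    return dmp_prof, other_prof


def chromosome_normalized_frequency(dmp_ids, manifest: ProbeManifest) -> pd.Series:
    """Per-chromosome DMP count divided by that chromosome's probe count.

    Normalising by array design removes the bias of uneven probe coverage;
    the result is in [0, 1] per chromosome, sorted descending.
    """
    dmp_ids = pd.Index(dmp_ids)
    unknown = dmp_ids.difference(manifest.probe_ids)
    if len(unknown):
        raise ValidationError(f"DMPs absent from manifest: {list(unknown[:5])}")
    probe_counts = manifest.df["chrom"].value_counts()
    dmp_counts = (
        manifest.df.loc[dmp_ids, "chrom"].value_counts().reindex(probe_counts.index, fill_value=0)
    )
    return (dmp_counts / probe_counts).sort_values(ascending=False)


def per_layer_chromosome_frequency(
    dmp_ids, model: LayerModel, manifest: ProbeManifest
) -> pd.DataFrame:
    """chrom x layer matrix of within-layer DMP frequencies.

    Cell = (DMPs of the chromosome in the layer) / (probes of the
    chromosome in the layer); cells with no probes are NaN (flagged
    missing), never 0.
    """
    dmp_ids = pd.Index(dmp_ids)
    names = layer_names(model.n_layers)
    frame = pd.DataFrame(
        {
            "chrom": manifest.df.loc[model.layer.index, "chrom"],
            "layer": model.layer,
            "is_dmp": model.layer.index.isin(dmp_ids),
        }
    )
    probes = frame.pivot_table(index="chrom", columns="layer", values="is_dmp",
                               aggfunc="size", fill_value=0)
    dmps = frame.pivot_table(index="chrom", columns="layer", values="is_dmp",
                             aggfunc="sum", fill_value=0)
    out = dmps / probes.replace(0, np.nan)
    return out.reindex(columns=names)


def layer_mean_abs_change(dmps: pd.DataFrame, model: LayerModel) -> LayerProfile:
    """Mean |delta_vs_control| of DMPs per layer; empty layers are NaN."""
    ids = dmps.index.intersection(model.layer.index)
    frame = pd.DataFrame(
        {
            "layer": model.layer.loc[ids],
            "abs_delta": dmps.loc[ids, "delta_vs_control"].abs(),
        }
    )
    names = layer_names(model.n_layers)
    means = frame.groupby("layer")["abs_delta"].mean().reindex(names)
    counts = frame.groupby("layer")["abs_delta"].size().reindex(names, fill_value=0)
    return LayerProfile(means, "mean |delta M| vs control", counts)


def layer_assignment_table(model: LayerModel) -> pd.DataFrame:
    """Exportable TSV body: probe_id, score, layer."""
    return pd.DataFrame({"hic_score": model.scores, "layer": model.layer})
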
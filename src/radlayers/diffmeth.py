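"""Differential methylation: Beta/M transforms, per-probe two-group tests,
the q-value / effect-size / vs-control filters, direction subgroups,
distance-chained DMR building and CpG-island context classification.

Effects are thresholded on the M scale, M = log2(Beta / (1 - Beta)).
A probe passes when q < 0.05, |avDiff| >= 0.58 between the compared groups
and |mean M - control mean M| >= 0.58, with the control defined as the
pooled mean of all non-irradiated (dose 0) samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenomicInterval, ProbeManifest, ValidationError
from .resampling_stats import adjust_fdr

#: Default q-value ceiling for a differentially methylated probe.
DEFAULT_Q_MAX = 0.05
#: Default minimum absolute M-value difference (both between-group and vs control).
DEFAULT_D_MIN = 0.58
#: Boundary clamp for Beta values of exactly 0 or 1 before the logit transform.
BETA_EPS = 1e-6


@dataclass
class MethylationExperiment:
    """A probes x samples value matrix with its sample sheet and manifest.

    ``scale`` is ``"beta"`` (values in (0,1)) or ``"m"`` (logit scale).
    Matrix row ids must be a subset of manifest probe ids.
    """

    values: pd.DataFrame
    scale: str
    samples: pd.DataFrame
    manifest: ProbeManifest

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "m"):
            raise ValidationError(f"unknown scale: {self.scale!r}")
        if self.scale == "beta":
            vals = self.values.to_numpy()
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                    raise ValidationError("beta-scale values must lie in [0, 1]")
        unknown = self.values.index.difference(self.manifest.probe_ids)
        if len(unknown):
            raise ValidationError(
                f"matrix rows absent from manifest: {list(unknown[:5])}"
            )
        unknown_samples = self.values.columns.difference(self.samples.index)
        if len(unknown_samples):
            raise ValidationError(
                f"matrix columns absent from sample sheet: {list(unknown_samples[:5])}"
            )

    def to_m(self) -> "MethylationExperiment":
        """Return the experiment on the M scale (no-op if already there)."""
        if self.scale == "m":
            return self
        m = pd.DataFrame(
            beta_to_m(self.values.to_numpy()),
            index=self.values.index,
            columns=self.values.columns,
        )
        return MethylationExperiment(m, "m", self.samples, self.manifest)

    def control_sample_ids(self) -> list[str]:
        """All dose-0 samples, pooled across particle batches."""
        sheet = self.samples.loc[self.values.columns]
        return list(sheet.index[sheet["dose_gy"] == 0])

    def sample_ids(
        self, particle: str, dose_gy: float, timepoint: str | None = None
    ) -> list[str]:
        sheet = self.samples.loc[self.values.columns]
        sel = (sheet["particle"] == particle) & (sheet["dose_gy"] == dose_gy)
        if timepoint is not None:
            sel &= sheet["timepoint"] == timepoint
        return list(sheet.index[sel])


def beta_to_m(beta, eps: float = BETA_EPS):
    """logit2 transform: M = log2(beta / (1 - beta)).

    Values of exactly 0 or 1 are clamped to ``eps`` / ``1 - eps`` with a
    warning; values outside [0, 1] raise.
    """
    arr = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValueError("beta values must lie in [0, 1]")
    at_bound = (arr == 0) | (arr == 1)
    if at_bound.any():
        warnings.warn(
            f"{int(at_bound.sum())} beta value(s) at 0/1 clamped to +/-{eps} before logit",
            stacklevel=2,
        )
        arr = np.clip(arr, eps, 1 - eps)
    out = np.log2(arr / (1 - arr))
    return float(out) if np.isscalar(beta) else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M), always in (0, 1)."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    return float(out) if np.isscalar(m) else out


def define_control(experiment: MethylationExperiment) -> pd.Series:
    """Per-probe control level: mean M over all pooled dose-0 samples.

    Missing values are excluded pairwise (mean of the remaining samples).
    """
    exp_m = experiment.to_m()
    controls = exp_m.control_sample_ids()
    if not controls:
        raise ValidationError("no dose-0 control samples in the experiment")
    return exp_m.values[controls].mean(axis=1)


def _group_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NaN-aware per-row (mean, sample variance, count)."""
    n = np.sum(~np.isnan(values), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(values, axis=1)
        var = np.nanvar(values, axis=1, ddof=1)
    var = np.where(n >= 2, var, np.nan)
    return mean, var, n


def call_dmps(
    experiment: MethylationExperiment,
    group_a: list[str],
    group_b: list[str],
    control: pd.Series,
    q_max: float = DEFAULT_Q_MAX,
    d_min: float = DEFAULT_D_MIN,
) -> pd.DataFrame:
    """Per-probe two-group one-way ANOVA on M values, with the full filter.

    The two-group F statistic equals the squared pooled-variance t; group A
    is the focal condition, so ``av_diff = mean_A - mean_B`` and
    ``delta_vs_control = mean_A - control``. q-values are Benjamini–Hochberg.
    ``passes`` requires q < ``q_max`` and |av_diff| >= ``d_min`` and
    |delta_vs_control| >= ``d_min``.

    Probes where both groups have zero within-group variance are flagged
    ``degenerate`` with p = 0 if the means differ and p = 1 otherwise.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("both comparison groups need at least 2 samples")
    exp_m = experiment.to_m()
    va = exp_m.values[group_a].to_numpy()
    vb = exp_m.values[group_b].to_numpy()
    mean_a, var_a, n_a = _group_stats(va)
    mean_b, var_b, n_b = _group_stats(vb)

    df_denom = n_a + n_b - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df_denom
        se2 = pooled * (1.0 / n_a + 1.0 / n_b)
        av_diff = mean_a - mean_b
        f_stat = av_diff**2 / se2
    p = np.full(len(av_diff), np.nan)
    valid = (n_a >= 2) & (n_b >= 2) & (pooled > 0)
    p[valid] = stats.f.sf(f_stat[valid], 1, df_denom[valid])

    degenerate = (n_a >= 2) & (n_b >= 2) & (pooled == 0)
    if degenerate.any():
        same = degenerate & (av_diff == 0)
        diff = degenerate & (av_diff != 0)
        p[same] = 1.0
        p[diff] = 0.0
        f_stat = np.where(diff, np.inf, f_stat)
        f_stat = np.where(same, 0.0, f_stat)

    q = adjust_fdr(p)
    delta_vs_control = mean_a - control.reindex(exp_m.values.index).to_numpy()
    passes = (
        (q < q_max)
        & (np.abs(av_diff) >= d_min)
        & (np.abs(delta_vs_control) >= d_min)
    )
    passes = np.where(np.isnan(q), False, passes).astype(bool)

    return pd.DataFrame(
        {
            "f_stat": f_stat,
            "p": p,
            "q": q,
            "av_diff": av_diff,
            "delta_vs_control": delta_vs_control,
            "passes": passes,
            "degenerate": degenerate,
        },
        index=exp_m.values.index.copy(),
    )


def classify_subgroups(dmps: pd.DataFrame, control: pd.Series) -> pd.DataFrame:
    """Add baseline state and change direction to a DMP table.

    Baseline is hypomethylated when the control mean M < 0, hypermethylated
    when > 0; an exact 0 counts as hyper (flagged ``baseline_tie``).
    Direction is up when delta_vs_control > 0, down otherwise.
    """
    out = dmps.copy()
    ctrl = control.reindex(dmps.index)
    out["baseline_state"] = np.where(ctrl < 0, "hypo", "hyper")
    out["baseline_tie"] = (ctrl == 0).to_numpy()
    out["direction"] = np.where(out["delta_vs_control"] > 0, "up", "down")
    return out


def build_dmrs(
    dmps: pd.DataFrame,
    manifest: ProbeManifest,
    lam: int = 1000,
    min_probes: int = 2,
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Chain passing probes into differentially methylated regions.

    Per chromosome, probes sorted by position are chained while the gap to
    the previous probe is <= ``lam`` bp; chains with >= ``min_probes``
    members become DMRs spanning first to last probe. Returns
    ``(dmr_table, in_dmr flags per probe, fraction_inside)``; input row
    order is irrelevant. An empty input yields an empty table.

    ``dmps`` may be a full DMP table (rows with ``passes`` False are
    dropped) or any frame indexed by probe id with a ``delta_vs_control``
    column.
    """
    if "passes" in dmps.columns:
        dmps = dmps[dmps["passes"]]
    if len(dmps) == 0:
        empty = pd.DataFrame(
            columns=["chrom", "start", "end", "n_probes", "mean_delta", "probe_ids"]
        )
        return empty, pd.Series(dtype=bool), 0.0

    pos = manifest.positions(dmps.index)
    frame = pd.DataFrame(
        {
            "chrom": pos["chrom"].to_numpy(),
            "pos0": pos["pos0"].to_numpy(),
            "delta": dmps["delta_vs_control"].to_numpy(),
        },
        index=dmps.index,
    ).sort_values(["chrom", "pos0"], kind="mergesort")

    gaps = frame["pos0"].diff()
    new_chain = (frame["chrom"] != frame["chrom"].shift()) | (gaps > lam)
    chain_id = new_chain.cumsum()

    records = []
    in_dmr = pd.Series(False, index=frame.index)
    for _, chain in frame.groupby(chain_id):
        if len(chain) < min_probes:
            continue
        in_dmr.loc[chain.index] = True
        records.append(
            {
                "chrom": chain["chrom"].iloc[0],
                "start": int(chain["pos0"].iloc[0]),
                "end": int(chain["pos0"].iloc[-1]) + 1,
                "n_probes": len(chain),
                "mean_delta": float(chain["delta"].mean()),
                "probe_ids": list(chain.index),
            }
        )
    dmr_table = pd.DataFrame(
        records, columns=["chrom", "start", "end", "n_probes", "mean_delta", "probe_ids"]
    )
    fraction_inside = float(in_dmr.mean())
    return dmr_table, in_dmr.reindex(dmps.index), fraction_inside


def dmrs_to_intervals(dmr_table: pd.DataFrame) -> list[GenomicInterval]:
    """DMR table rows as BED-ready intervals (score = mean delta)."""
    return [
        GenomicInterval(
            r["chrom"], r["start"], r["end"],
            score=r["mean_delta"], name=f"dmr_{i}",
        )
        for i, r in dmr_table.iterrows()
    ]


def classify_cpg_relation(
    chroms,
    pos0,
    islands: list[GenomicInterval],
    shore_bp: int = 2000,
    shelf_bp: int = 4000,
    merged: bool = False,
) -> np.ndarray:
    """Island-relative class of each probe point.

    Distance is bp from the point to the nearest island edge (0 inside an
    island). Island at 0; Shore up to ``shore_bp`` (inclusive); Shelf up to
    ``shelf_bp`` (inclusive); OpenSea beyond. With ``merged=True`` shores
    and shelves are combined into ``ShoreShelf`` (3-level variant).
    Islands must be non-overlapping per chromosome.
    """
    chroms = np.asarray(chroms)
    pos0 = np.asarray(pos0, dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in islands:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    dist = np.full(len(pos0), np.iinfo(np.int64).max, dtype=np.int64)
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        arr = np.array(pairs, dtype=np.int64)
        if len(arr) > 1 and (arr[1:, 0] < arr[:-1, 1]).any():
            raise ValidationError(f"islands overlap on {chrom}")
        sel = chroms == chrom
        if not sel.any():
            continue
        pts = pos0[sel]
        idx = np.searchsorted(arr[:, 0], pts, side="right") - 1
        d = np.full(len(pts), np.iinfo(np.int64).max, dtype=np.int64)
        ok = idx >= 0
        inside = np.zeros(len(pts), dtype=bool)
        inside[ok] = pts[ok] < arr[idx[ok], 1]
        d[inside] = 0
        # distance to the end of the previous island (point sits past it)
        left_ok = ok & ~inside
        d[left_ok] = np.minimum(d[left_ok], pts[left_ok] - arr[idx[left_ok], 1] + 1)
        # distance to the start of the next island
        nxt = idx + 1
        right_ok = (nxt < len(arr)) & ~inside
        d[right_ok] = np.minimum(d[right_ok], arr[nxt[right_ok], 0] - pts[right_ok])
        dist[sel] = d

    out = np.where(
        dist == 0,
        "Island",
        np.where(dist <= shore_bp, "Shore", np.where(dist <= shelf_bp, "Shelf", "OpenSea")),
    ).astype(object)
    if merged:
        out[(out == "Shore") | (out == "Shelf")] = "ShoreShelf"
    return out


def fraction_table(labels, categories=None) -> pd.DataFrame:
    """Counts and fractions per category; fractions sum to 1.

    ``categories`` fixes the row order (missing categories get count 0).
    """
    s = pd.Series(list(labels))
    if len(s) == 0:
        raise ValueError("fraction_table needs a nonempty input")
    counts = s.value_counts()
    if categories is not None:
        counts = counts.reindex(list(categories), fill_value=0)
    return pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})
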
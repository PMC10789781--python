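"""Transcriptomic validation of methylation persistence.

TMM (trimmed mean of M-values) library normalization, the microarray
median-intensity filter, the astronaut pseudo-replicate timepoint pairing,
a first-timepoint differential-expression gate (FDR < 0.05), per-gene logFC
trajectories with up/down classification, and layer-wise expression change.

The differential test is a pooled-variance t-test on TMM-normalized
log-CPM (or normalized intensities for microarrays) with empirical-Bayes
variance moderation across genes (gene variances squeezed toward a fitted
scaled-inverse-chi-square prior, the standard remedy for few-replicate
designs); the negative-binomial GLM machinery of dedicated count packages
is deliberately out of scope here — trend recovery, not count-model
equivalence, is the purpose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_io import ValidationError
from .nuclear_layers import LayerModel, LayerProfile, layer_names
from .resampling_stats import adjust_fdr, mann_kendall, slope_anova

#: Pseudo-count added to counts before the log-CPM transform.
LOGCPM_PRIOR = 0.5


@dataclass
class ExpressionExperiment:
    """genes x samples values with platform tag and ordered group labels.

    ``platform`` is ``"rnaseq"`` (nonnegative integer counts) or
    ``"microarray"`` (already-normalized intensities). ``groups`` maps each
    sample to an ordered timepoint label; the first label of ``group_order``
    is the designated control.
    """

    values: pd.DataFrame
    platform: str
    groups: pd.Series
    group_order: list[str]

    def __post_init__(self) -> None:
        if self.platform not in ("rnaseq", "microarray"):
            raise ValidationError(f"unknown platform: {self.platform!r}")
        if self.platform == "rnaseq":
            arr = self.values.to_numpy()
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValidationError("rnaseq values must be nonnegative integers")
        missing = self.values.columns.difference(self.groups.index)
        if len(missing):
            raise ValidationError(f"samples without group label: {list(missing[:5])}")
        unknown = set(self.groups.loc[self.values.columns]) - set(self.group_order)
        if unknown:
            raise ValidationError(f"group labels outside group_order: {sorted(unknown)}")

    @property
    def control_group(self) -> str:
        return self.group_order[0]

    def samples_in(self, group: str) -> list[str]:
        g = self.groups.loc[self.values.columns]
        return list(g.index[g == group])


@dataclass
class Trajectory:
    """Per-gene logFC vs control across ordered timepoints.

    ``gate`` marks genes passing the first-timepoint FDR filter; ``cls`` is
    "up"/"down" by the sign of the first-timepoint logFC.
    """

    logfc: pd.DataFrame  # genes x timepoints
    gate: pd.Series
    cls: pd.Series
    class_means: pd.DataFrame  # class x timepoints
    trend: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# TMM normalization (weighted trimmed mean of log expression ratios)

def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    The reference sample is the one whose upper-quartile (of counts/library
    size) is closest to the mean upper-quartile. For each sample, gene-wise
    log2 ratios vs the reference (M) and average log2 abundances (A) are
    computed over genes expressed in both; the most extreme 30% of M and 5%
    of A are rank-trimmed away and the factor is 2^(weighted mean M), with
    inverse-variance (delta-method binomial) weights.
    """
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValidationError(f"samples with zero total count: {bad}")
    uq = np.quantile(arr / lib, 0.75, axis=0)  # upper quartile incl. zeros
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        factors[j] = _tmm_pair(arr[:, j], arr[:, ref], lib[j], lib[ref],
                               logratio_trim, abundance_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float, abundance_trim: float,
) -> float:
    fin = (obs > 0) & (ref > 0)
    if not fin.any():
        return 1.0
    o, r = obs[fin], ref[fin]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)  # delta-method var of M
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])  # inverse-variance weights
    if np.isnan(f):
        return 1.0
    return float(2.0**f)


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes."""
    lib = counts.sum(axis=0)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    return np.log2(
        (counts + LOGCPM_PRIOR).div(lib + 1.0, axis=1) * 1e6
    )


# ---------------------------------------------------------------------------
# microarray filter and astronaut grouping

def filter_microarray(intensities: pd.DataFrame, min_median: float = 3.0) -> pd.Index:
    """Genes whose median intensity across samples is >= ``min_median``."""
    medians = intensities.median(axis=1)
    kept = intensities.index[medians >= min_median]
    if len(kept) == 0:
        warnings.warn("microarray median filter removed every gene")
    return kept


#: Default astronaut pairing: ten raw timepoints folded into five groups of
#: two pseudo-replicates (pre-flight control, two in-flight, two post-flight).
DEFAULT_ASTRONAUT_PAIRING = {
    "L-112": "control", "L-56": "control",
    "L+5": "flight_early", "L+30": "flight_early",
    "L+120": "flight_late", "R-8": "flight_late",
    "R+3": "post_early", "R+30": "post_early",
    "R+60": "post_late", "R+120": "post_late",
}
ASTRONAUT_GROUP_ORDER = ["control", "flight_early", "flight_late", "post_early", "post_late"]


def group_astronaut_timepoints(
    sample_labels: pd.Series,
    pairing: dict[str, str] | None = None,
    group_order: list[str] | None = None,
    allow_unbalanced: bool = False,
) -> tuple[pd.Series, list[str]]:
    """Fold a single-replicate timepoint series into grouped pseudo-replicates.

    ``sample_labels`` maps sample id -> raw timepoint label. Under the
    default pairing every group must receive exactly 2 samples; other sizes
    require ``allow_unbalanced=True``. Unmapped labels raise, naming the
    label. Returns (sample -> group, ordered group list with the control
    first).
    """
    pairing = dict(DEFAULT_ASTRONAUT_PAIRING if pairing is None else pairing)
    order = list(ASTRONAUT_GROUP_ORDER if group_order is None else group_order)
    unmapped = sorted(set(sample_labels) - set(pairing))
    if unmapped:
        raise ValidationError(f"raw timepoint labels without a pairing: {unmapped}")
    groups = sample_labels.map(pairing)
    sizes = groups.value_counts()
    bad = sizes[sizes != 2]
    if len(bad) and not allow_unbalanced:
        raise ValidationError(
            f"groups without exactly 2 pseudo-replicates: {dict(bad)} "
            "(pass allow_unbalanced=True to accept)"
        )
    missing_groups = [g for g in order if g not in set(groups)]
    if missing_groups:
        raise ValidationError(f"pairing produced no samples for groups: {missing_groups}")
    return groups, order


# ---------------------------------------------------------------------------
# differential gate and trajectories

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        step = tri * (1 - tri / x) / special.polygamma(2, y)
        y += step
        if abs(step) < 1e-8 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes squeeze of gene-wise variances.

    Fits a scaled-inverse-chi-square prior (``d0`` prior df, ``s0²`` prior
    value) to the observed sample variances by matching moments of
    ``log s²``, then returns the posterior variances
    ``(d0 s0² + df s²) / (d0 + df)``. With homogeneous variances the fitted
    ``d0`` grows large and the posterior approaches the common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if e_var > 0:
        d0 = 2 * _trigamma_inverse(e_var)
        s02 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = np.inf
        s02 = float(np.exp(e_mean))
    if np.isfinite(d0):
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        post = np.full_like(s2, s02)
    return post, d0, s02


def de_gate(
    experiment: ExpressionExperiment,
    fdr_max: float = 0.05,
    adjustment: str = "bh",
) -> pd.DataFrame:
    """First-timepoint differential expression gate vs the control group.

    Moderated pooled-variance t-test per gene on normalized log-scale
    values (TMM log-CPM for RNA-seq, intensities as-is for microarray):
    gene variances are squeezed toward the fitted prior
    (:func:`squeeze_variances`) and tested on ``df + d0`` degrees of
    freedom, then adjusted by Benjamini–Hochberg or Bonferroni. Returns
    per-gene ``logfc``, ``p``, ``fdr`` and the boolean ``gate``
    (fdr < ``fdr_max``). Genes with zero sample variance are flagged
    degenerate (the prior still yields a proper test; should the prior
    itself collapse, p falls back to the means comparison).
    """
    if adjustment not in ("bh", "bonferroni"):
        raise ValueError(f"unknown adjustment: {adjustment!r}")
    first = experiment.group_order[1]
    ctrl_ids = experiment.samples_in(experiment.control_group)
    first_ids = experiment.samples_in(first)
    if len(ctrl_ids) < 2 or len(first_ids) < 2:
        raise ValidationError("need >= 2 replicates in control and first timepoint")
    values = _normalized_values(experiment)
    va = values[first_ids].to_numpy()
    vb = values[ctrl_ids].to_numpy()
    n_a, n_b = va.shape[1], vb.shape[1]
    mean_a, mean_b = va.mean(axis=1), vb.mean(axis=1)
    var_a = va.var(axis=1, ddof=1)
    var_b = vb.var(axis=1, ddof=1)
    df = n_a + n_b - 2
    pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    logfc = mean_a - mean_b
    post_var, d0, _ = squeeze_variances(pooled, df)
    df_total = df + d0 if np.isfinite(d0) else 1e9
    with np.errstate(invalid="ignore", divide="ignore"):
        t = logfc / np.sqrt(post_var * (1 / n_a + 1 / n_b))
    p = 2 * stats.t.sf(np.abs(t), df_total)
    degenerate = pooled == 0
    collapsed = post_var == 0
    p[collapsed & (logfc == 0)] = 1.0
    p[collapsed & (logfc != 0)] = 0.0
    if adjustment == "bh":
        fdr = adjust_fdr(p)
    else:
        fdr = np.minimum(p * len(p), 1.0)
    return pd.DataFrame(
        {
            "logfc": logfc,
            "p": p,
            "fdr": fdr,
            "gate": fdr < fdr_max,
            "degenerate": degenerate,
        },
        index=values.index,
    )


def _normalized_values(experiment: ExpressionExperiment) -> pd.DataFrame:
    if experiment.platform == "rnaseq":
        factors = tmm_factors(experiment.values)
        return log_cpm(experiment.values, factors)
    return experiment.values


def logfc_trajectory(
    experiment: ExpressionExperiment,
    gated_genes: pd.Index,
) -> Trajectory:
    """Per-gene logFC vs control at every timepoint, with per-class means.

    Classes (up/down) follow the sign of the first-timepoint logFC. Mean
    trajectories per class are tested for trend with the slope ANOVA and —
    when at least 4 timepoints exist — the Mann–Kendall test.
    """
    gated_genes = pd.Index(gated_genes)
    if len(gated_genes) == 0:
        raise ValidationError("gated gene set is empty")
    values = _normalized_values(experiment).loc[gated_genes]
    ctrl_ids = experiment.samples_in(experiment.control_group)
    ctrl_mean = values[ctrl_ids].mean(axis=1)
    tps = experiment.group_order[1:]
    logfc = pd.DataFrame(index=gated_genes, columns=tps, dtype=float)
    for tp in tps:
        ids = experiment.samples_in(tp)
        logfc[tp] = values[ids].mean(axis=1) - ctrl_mean
    cls = pd.Series(
        np.where(logfc[tps[0]] > 0, "up", "down"), index=gated_genes, name="class"
    )
    class_means = logfc.groupby(cls).mean().reindex(["up", "down"])
    trend: dict[str, dict] = {}
    x = np.arange(1, len(tps) + 1, dtype=float)
    for c in class_means.index:
        row = class_means.loc[c].to_numpy(dtype=float)
        if np.isnan(row).any():
            continue
        entry = {"slope_anova": slope_anova(row, x)}
        if len(tps) >= 4:
            entry["mann_kendall"] = mann_kendall(row)
        trend[c] = entry
    gate = pd.Series(True, index=gated_genes, name="gate")
    return Trajectory(logfc=logfc, gate=gate, cls=cls, class_means=class_means, trend=trend)


def layer_expression_change(
    logfc_first: pd.Series,
    gene_tss: pd.DataFrame,
    hic_track,
    model: LayerModel,
) -> tuple[LayerProfile, int]:
    """Per-layer mean |logFC| at the first timepoint, genes placed by TSS.

    Each gene's TSS inherits the score of the containing Hi-C bin and is
    assigned a layer by comparison against the probe-derived layer score
    boundaries. Genes on chromosomes without track coverage are excluded
    and counted (returned alongside the profile).
    """
    by_chrom: dict[str, list] = {}
    for iv in hic_track:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    names = layer_names(model.n_layers)
    inner = model.boundaries[1:-1]  # cut points between layers
    records = []
    n_unmapped = 0
    for gene in logfc_first.index:
        if gene not in gene_tss.index:
            n_unmapped += 1
            continue
        chrom = gene_tss.loc[gene, "chrom"]
        pos0 = int(gene_tss.loc[gene, "pos0"])
        ivs = by_chrom.get(chrom)
        score = None
        if ivs:
            for iv in ivs:
                if iv.contains(pos0):
                    score = iv.score
                    break
        if score is None:
            n_unmapped += 1
            continue
        layer = names[int(np.searchsorted(inner, score, side="right"))]
        records.append((layer, abs(float(logfc_first[gene]))))
    if not records:
        return LayerProfile(pd.Series(np.nan, index=names), "mean |logFC|"), n_unmapped
    frame = pd.DataFrame(records, columns=["layer", "abs_logfc"])
    means = frame.groupby("layer")["abs_logfc"].mean().reindex(names)
    counts = frame.groupby("layer")["abs_logfc"].size().reindex(names, fill_value=0)
    return LayerProfile(means, "mean |logFC|", counts), n_unmapped
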
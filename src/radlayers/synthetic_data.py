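"""Synthetic inputs with planted ground truth.

Generates all six input kinds the pipeline consumes — probe manifest with
CpG-island and gene annotation, Hi-C score track, bimodal Beta methylation
matrix with a replicated condition design, histone peak sets with a planted
radial placement gradient, and negative-binomial expression counts — under
a single seeded configuration, together with the planted truth needed for
recovery tests.

The generative assumptions encode the qualitative biology being modelled:
iron ions plant a persistent methylation increase while silicon and X-ray
plant a decaying decrease; effect magnitude peaks in the middle nuclear
layer; heterochromatin (H3K9me3) peaks prefer low Hi-C scores (periphery)
and H3K27ac high scores; a fraction of true differential probes sits in
tight 1 kb clusters (CpG-island probe groups) so that region-building has
signal to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import diffmeth
from .chromatin_marks import MARKS, PeakSet
from .data_io import GenomicInterval, ProbeManifest
from .nuclear_layers import build_layers


class ConfigError(ValueError):
    """Simulation configuration violates a structural requirement."""


@dataclass(frozen=True)
class ParticleSpec:
    """One irradiation condition and its planted methylation effect."""

    name: str
    dose_gy: float
    effect_direction: int  # +1 or -1
    effect_size_m: float
    persistence: str  # "persistent" | "decaying"
    decay_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.effect_direction not in (+1, -1):
            raise ConfigError(f"{self.name}: effect_direction must be +1 or -1")
        if self.persistence not in ("persistent", "decaying"):
            raise ConfigError(f"{self.name}: unknown persistence {self.persistence!r}")


#: Default irradiation conditions: a persistent hypermethylating iron-like
#: particle versus decaying hypomethylating silicon-like and X-ray-like ones.
DEFAULT_PARTICLES = (
    ParticleSpec("Fe", 1.0, +1, 1.5, "persistent"),
    ParticleSpec("Si", 1.0, -1, 1.5, "decaying", 0.5),
    ParticleSpec("X", 1.0, -1, 1.0, "decaying", 0.5),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    The default scale (20,000 probes on 4 chromosomes, 3 replicates per
    condition) is a desk-scale stand-in for a 485k-probe array. Replicate
    noise is Gaussian on the M scale (sd 0.15, the scale on which effects
    are thresholded); the layer effect profile defaults to an L3 peak.
    """

    seed: int
    n_probes: int = 20_000
    n_chroms: int = 4
    chrom_length: int = 25_000_000
    replicates_per_condition: int = 3
    particles: tuple[ParticleSpec, ...] = DEFAULT_PARTICLES
    dmp_fraction: float = 0.05
    clustered_fraction: float = 0.5
    layer_effect_profile: tuple[float, ...] = (0.5, 0.8, 1.0, 0.8, 0.6)
    noise_sd_m: float = 0.15
    timepoints: tuple[str, ...] = ("48h", "1m", "4m")
    # manifest structure
    island_probe_fraction: float = 0.3
    probes_per_island: int = 5
    island_width: int = 1000
    genes_per_chrom: int = 100
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    # Hi-C track
    hic_bin_width: int = 100_000
    hic_chrom_spread: float = 1.0
    hic_noise_sd: float = 1.0
    # histone peaks
    peaks_per_mark: int = 1500
    # expression counts
    n_genes_expr: int = 4000
    de_fraction: float = 0.05
    de_logfc: float = 2.0
    nb_dispersion: float = 0.1
    expr_timepoints: tuple[str, ...] = ("tp1", "tp2", "tp3", "tp4")
    expr_replicates: int = 3
    expr_decay_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_probes < 10 * self.n_chroms:
            raise ConfigError("need at least 10 probes per chromosome")
        if not 0 <= self.dmp_fraction < 1:
            raise ConfigError("dmp_fraction must lie in [0, 1)")
        if not 0 <= self.clustered_fraction <= 1:
            raise ConfigError("clustered_fraction must lie in [0, 1]")
        if len(self.layer_effect_profile) != 5:
            raise ConfigError("layer_effect_profile needs exactly 5 weights")
        if any(w < 0 for w in self.layer_effect_profile):
            raise ConfigError("layer_effect_profile weights must be nonnegative")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What was planted: per-particle true DMP sets and first-timepoint
    deltas, the planted layer of every probe, and mark context flags."""

    true_dmp_ids: dict[str, frozenset] = field(default_factory=dict)
    planted_delta: dict[str, pd.Series] = field(default_factory=dict)
    planted_layer: pd.Series | None = None
    mark_flags: pd.DataFrame | None = None


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per generator stage
    return np.random.default_rng([config.seed, stream])


def _chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chroms)]


def _probes_per_chrom(config: SimulationConfig) -> list[int]:
    base, rem = divmod(config.n_probes, config.n_chroms)
    return [base + (1 if i < rem else 0) for i in range(config.n_chroms)]


# ---------------------------------------------------------------------------
# manifest + annotation

def generate_manifest(
    config: SimulationConfig,
) -> tuple[ProbeManifest, list[GenomicInterval], pd.DataFrame, list[GenomicInterval]]:
    """Probe manifest plus CpG islands, TSS table and gene-body intervals.

    A configurable fraction of probes sits in dense within-island clusters
    (mirroring the island-heavy design of methylation arrays, and giving
    region-building genuine 1 kb structure); the rest are uniform. CpG
    relation is assigned from the distance to the nearest generated island
    (0 inside; <= 2 kb shore; <= 4 kb shelf; open sea beyond) and genic
    group from the generated TSS/body intervals.
    """
    rng = _rng(config, 0)
    chroms = _chrom_names(config)
    ppcs = _probes_per_chrom(config)

    islands: list[GenomicInterval] = []
    tss_rows = []
    bodies: list[GenomicInterval] = []
    probe_chrom: list[str] = []
    probe_pos: list[np.ndarray] = []

    for chrom, ppc in zip(chroms, ppcs):
        n_island_probes = int(round(config.island_probe_fraction * ppc))
        n_islands = max(1, n_island_probes // config.probes_per_island)
        # islands on a coarse grid to keep them apart and non-overlapping
        grid_step = max(config.island_width * 10, config.chrom_length // max(n_islands * 4, 1))
        n_slots = config.chrom_length // grid_step
        slots = rng.choice(n_slots, size=min(n_islands, n_slots), replace=False)
        starts = np.sort(slots * grid_step + rng.integers(0, grid_step // 2, size=len(slots)))
        for s in starts:
            islands.append(
                GenomicInterval(chrom, int(s), int(s) + config.island_width)
            )

        pos_list = []
        for s in starts:
            within = rng.choice(config.island_width, size=config.probes_per_island, replace=False)
            pos_list.append(np.sort(within) + s)
        n_rest = ppc - len(starts) * config.probes_per_island
        rest = rng.choice(config.chrom_length, size=max(n_rest, 0) * 2, replace=False)
        pos = np.unique(np.concatenate(pos_list + [rest[: max(n_rest, 0)]]))
        # duplicate collisions between island and uniform probes are dropped;
        # top up uniformly until the chromosome holds exactly ppc probes
        while len(pos) < ppc:
            extra = rng.integers(0, config.chrom_length, size=ppc - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        pos = pos[:ppc]
        probe_chrom.extend([chrom] * len(pos))
        probe_pos.append(pos)

        # genes: TSS uniform, plus strand only, bodies to the right
        lo, hi = config.gene_length_range
        tss_pos = np.sort(
            rng.choice(config.chrom_length - hi, size=config.genes_per_chrom, replace=False)
        )
        lengths = rng.integers(lo, hi, size=config.genes_per_chrom)
        for k, (tp, ln) in enumerate(zip(tss_pos, lengths)):
            gene = f"{chrom}_g{k:04d}"
            tss_rows.append({"gene": gene, "chrom": chrom, "pos0": int(tp)})
            bodies.append(GenomicInterval(chrom, int(tp), int(tp + ln), name=gene))

    all_pos = np.concatenate(probe_pos)
    all_chrom = np.asarray(probe_chrom)
    probe_ids = [f"cg{i:08d}" for i in range(len(all_pos))]

    cpg_rel = diffmeth.classify_cpg_relation(all_chrom, all_pos, islands)
    tss_df = pd.DataFrame(tss_rows).set_index("gene")
    genic = _genic_groups(all_chrom, all_pos, tss_df, bodies)

    frame = pd.DataFrame(
        {
            "chrom": all_chrom,
            "pos0": all_pos.astype(np.int64),
            "cpg_relation": cpg_rel,
            "genic_group": genic,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeManifest(frame), islands, tss_df, bodies


def _genic_groups(
    chroms: np.ndarray,
    pos0: np.ndarray,
    tss: pd.DataFrame,
    bodies: list[GenomicInterval],
    promoter_bp: int = 2000,
    flank_bp: int = 10_000,
) -> np.ndarray:
    """Promoter within 2 kb of a TSS; Body inside a gene; Upstream /
    Downstream within 10 kb of a gene edge (5' / 3' of the plus-strand
    gene); Intergenic otherwise. Precedence: Promoter > Body > Upstream >
    Downstream."""
    out = np.full(len(pos0), "Intergenic", dtype=object)
    from .data_io import merge_intervals, points_in_intervals

    body_merged = merge_intervals(bodies)
    in_body = points_in_intervals(chroms, pos0, body_merged)

    for chrom in np.unique(chroms):
        sel = chroms == chrom
        pts = pos0[sel]
        tss_pos = np.sort(tss.loc[tss["chrom"] == chrom, "pos0"].to_numpy())
        ends = np.sort(
            np.array([iv.end for iv in bodies if iv.chrom == chrom], dtype=np.int64)
        )
        # distance to nearest TSS
        d_tss = _nearest_distance(pts, tss_pos)
        d_end = _nearest_signed_after(pts, ends)
        lab = np.full(len(pts), "Intergenic", dtype=object)
        lab[(d_end > 0) & (d_end <= flank_bp)] = "Downstream"
        lab[(d_tss > promoter_bp) & (d_tss <= flank_bp)] = "Upstream"
        lab[in_body[sel]] = "Body"
        lab[d_tss <= promoter_bp] = "Promoter"
        out[sel] = lab
    return out


def _nearest_distance(points: np.ndarray, targets: np.ndarray) -> np.ndarray:
    if len(targets) == 0:
        return np.full(len(points), np.iinfo(np.int64).max)
    idx = np.searchsorted(targets, points)
    left = np.where(idx > 0, points - targets[np.clip(idx - 1, 0, None)], np.iinfo(np.int64).max)
    right = np.where(
        idx < len(targets), targets[np.clip(idx, None, len(targets) - 1)] - points,
        np.iinfo(np.int64).max,
    )
    return np.minimum(np.abs(left), np.abs(right))


def _nearest_signed_after(points: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Distance from each point to the closest edge at or before it (bp past
    the gene end); max int where no edge precedes the point."""
    if len(edges) == 0:
        return np.full(len(points), np.iinfo(np.int64).max)
    idx = np.searchsorted(edges, points, side="right") - 1
    out = np.full(len(points), np.iinfo(np.int64).max)
    ok = idx >= 0
    out[ok] = points[ok] - edges[idx[ok]] + 1
    return out


# ---------------------------------------------------------------------------
# Hi-C track

def generate_hic_track(config: SimulationConfig) -> list[GenomicInterval]:
    """Fixed-width score bins tiling every chromosome.

    Chromosomes get distinct radial preferences (evenly spaced mean shifts
    over ``+/- hic_chrom_spread``) with within-chromosome Gaussian noise, so
    layering has genuine per-chromosome structure to recover.
    """
    rng = _rng(config, 1)
    chroms = _chrom_names(config)
    shifts = np.linspace(-config.hic_chrom_spread, config.hic_chrom_spread, len(chroms))
    track: list[GenomicInterval] = []
    for chrom, shift in zip(chroms, shifts):
        start = 0
        while start < config.chrom_length:
            end = min(start + config.hic_bin_width, config.chrom_length)
            score = float(shift + rng.normal(0, config.hic_noise_sd))
            track.append(GenomicInterval(chrom, start, end, score=score))
            start = end
    return track


# ---------------------------------------------------------------------------
# methylation matrix

def generate_methylation(
    config: SimulationConfig,
    manifest: ProbeManifest,
    hic_track: list[GenomicInterval],
) -> tuple[diffmeth.MethylationExperiment, GroundTruth]:
    """Beta-scale methylation matrix with planted particle effects.

    Baseline Beta per probe comes from a bimodal mixture (hypomethylated
    mode near 0.1, hypermethylated near 0.9) shared across samples.
    Replicate noise is Gaussian on the M scale. For each particle a
    ``dmp_fraction`` subset of probes receives a planted
    ``delta = direction * effect_size * layer_weight`` on M, decaying
    geometrically over timepoints for non-persistent particles. A
    ``clustered_fraction`` of each particle's true probes is drawn from
    whole within-island probe clusters (<= 1 kb span).
    """
    rng = _rng(config, 2)
    for part in config.particles:
        if part.effect_size_m <= 0:
            raise ConfigError(f"{part.name}: effect_size_m must be > 0")

    from .nuclear_layers import assign_hic_scores

    scores, _ = assign_hic_scores(manifest, hic_track)
    model = build_layers(scores, manifest, n_layers=5)
    planted_layer = model.layer.str.slice(1).astype(int)  # "L3" -> 3
    weights = np.asarray(config.layer_effect_profile)
    probe_weight = pd.Series(
        weights[planted_layer.to_numpy() - 1], index=planted_layer.index
    ).reindex(manifest.probe_ids, fill_value=1.0)

    n = len(manifest)
    hyper = rng.random(n) < 0.5
    baseline_beta = np.where(hyper, rng.beta(18, 2, size=n), rng.beta(2, 18, size=n))
    baseline_m = diffmeth.beta_to_m(np.clip(baseline_beta, 1e-4, 1 - 1e-4))
    baseline_m = pd.Series(baseline_m, index=manifest.probe_ids)

    truth = GroundTruth(planted_layer=planted_layer)
    deltas_first: dict[str, np.ndarray] = {}
    for part in config.particles:
        ids = _select_true_dmps(config, manifest, rng)
        truth.true_dmp_ids[part.name] = frozenset(ids)
        delta = (
            part.effect_direction
            * part.effect_size_m
            * probe_weight.loc[ids].to_numpy()
        )
        truth.planted_delta[part.name] = pd.Series(delta, index=pd.Index(ids, name="probe_id"))
        deltas_first[part.name] = delta

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    reps = config.replicates_per_condition
    tp0 = config.timepoints[0]
    for part in config.particles:
        for r in range(1, reps + 1):
            sid = f"{part.name}_0Gy_{tp0}_r{r}"
            columns[sid] = baseline_m.to_numpy() + rng.normal(0, config.noise_sd_m, n)
            sheet_rows.append(
                {"sample_id": sid, "particle": part.name, "dose_gy": 0.0,
                 "timepoint": tp0, "replicate": r}
            )
        idx = manifest.probe_ids.get_indexer(truth.planted_delta[part.name].index)
        for t, tp in enumerate(config.timepoints):
            decay = part.decay_ratio**t if part.persistence == "decaying" else 1.0
            effect = np.zeros(n)
            effect[idx] = deltas_first[part.name] * decay
            for r in range(1, reps + 1):
                sid = f"{part.name}_{part.dose_gy:g}Gy_{tp}_r{r}"
                columns[sid] = (
                    baseline_m.to_numpy() + effect + rng.normal(0, config.noise_sd_m, n)
                )
                sheet_rows.append(
                    {"sample_id": sid, "particle": part.name, "dose_gy": part.dose_gy,
                     "timepoint": tp, "replicate": r}
                )

    m_matrix = pd.DataFrame(columns, index=manifest.probe_ids.copy())
    beta_matrix = pd.DataFrame(
        diffmeth.m_to_beta(m_matrix.to_numpy()),
        index=m_matrix.index, columns=m_matrix.columns,
    )
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    experiment = diffmeth.MethylationExperiment(beta_matrix, "beta", sheet, manifest)
    return experiment, truth


def _select_true_dmps(
    config: SimulationConfig, manifest: ProbeManifest, rng: np.random.Generator
) -> np.ndarray:
    """Pick the planted probe set: whole island clusters for the clustered
    fraction, uniform probes for the rest."""
    k = int(round(config.dmp_fraction * len(manifest)))
    if k == 0:
        return np.array([], dtype=object)
    k_clust = int(round(config.clustered_fraction * k))

    chosen: list[str] = []
    if k_clust > 0:
        island_probes = manifest.df[manifest.df["cpg_relation"] == "Island"]
        clusters = []
        for _, sub in island_probes.groupby(
            [island_probes["chrom"], island_probes["pos0"] // (config.island_width * 10)]
        ):
            # group by island grid cell; members span <= island_width (1 kb)
            if len(sub) >= 2:
                clusters.append(list(sub.index))
        order = rng.permutation(len(clusters))
        for ci in order:
            if len(chosen) >= k_clust:
                break
            chosen.extend(clusters[ci])
        chosen = chosen[:k_clust]

    rest_pool = manifest.probe_ids.difference(pd.Index(chosen))
    n_rest = k - len(chosen)
    rest = rng.choice(rest_pool.to_numpy(), size=n_rest, replace=False)
    return np.concatenate([np.asarray(chosen, dtype=object), rest.astype(object)])


# ---------------------------------------------------------------------------
# histone peaks

def generate_peaks(
    config: SimulationConfig,
    hic_track: list[GenomicInterval],
    marks=MARKS,
) -> dict[str, PeakSet]:
    """Peak sets with widths in [300, 2000] and a planted radial gradient.

    Bin choice probability decreases with the bin's score percentile for
    H3K9me3 (peripheral heterochromatin), increases for H3K27ac, and is
    flat for H3K4me3/H3K27me3. Every peak carries an alignment score
    (uniform on [0, 50]).
    """
    rng = _rng(config, 3)
    out: dict[str, PeakSet] = {}
    if len(marks) == 0 or config.peaks_per_mark == 0:
        return {m: PeakSet(m, []) for m in marks}
    track_scores = np.array([iv.score for iv in hic_track])
    pct = pd.Series(track_scores).rank(pct=True).to_numpy()
    weight_fn = {
        "H3K9me3": 1.0 - pct,
        "H3K27ac": pct,
        "H3K4me3": np.ones_like(pct),
        "H3K27me3": np.ones_like(pct),
    }
    for mark in marks:
        w = weight_fn.get(mark, np.ones_like(pct)).astype(float) + 1e-9
        w /= w.sum()
        bins = rng.choice(len(hic_track), size=config.peaks_per_mark, p=w)
        peaks = []
        for b in bins:
            iv = hic_track[b]
            width = int(rng.integers(300, 2001))
            lo = iv.start
            hi = max(iv.end - width, lo + 1)
            start = int(rng.integers(lo, hi))
            score = float(rng.uniform(0, 50))
            peaks.append(GenomicInterval(iv.chrom, start, start + width, score=score))
        out[mark] = PeakSet(mark, peaks)
    return out


# ---------------------------------------------------------------------------
# expression counts

def generate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted logFC trajectories.

    Returns ``(counts, timepoint sheet, planted logFC genes x timepoints)``.
    A ``de_fraction`` subset of genes gets nonzero logFC at the first
    timepoint — half up, half down; within each half, half persistent and
    half decaying geometrically (``expr_decay_ratio``). Library sizes vary
    uniformly over a factor of [0.5, 2].
    """
    if config.expr_replicates < 2:
        raise ConfigError("need at least 2 replicates per expression group")
    rng = _rng(config, 4)
    n_genes = config.n_genes_expr
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")
    tps = list(config.expr_timepoints)
    groups = ["control"] + tps

    base = rng.lognormal(mean=np.log(200), sigma=1.0, size=n_genes)
    planted = pd.DataFrame(0.0, index=genes, columns=tps)
    k = int(round(config.de_fraction * n_genes))
    if k:
        de_idx = rng.choice(n_genes, size=k, replace=False)
        signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        persistent = np.arange(k) % 4 < 2  # alternate persistent/decaying per sign
        for j, (gi, sign, keep) in enumerate(zip(de_idx, signs, persistent)):
            for t in range(len(tps)):
                ratio = 1.0 if keep else config.expr_decay_ratio**t
                planted.iloc[gi, t] = sign * config.de_logfc * ratio

    r = 1.0 / config.nb_dispersion
    columns = {}
    sheet_rows = []
    for grp in groups:
        lfc = planted[grp].to_numpy() if grp != "control" else np.zeros(n_genes)
        mu_gene = base * np.exp2(lfc)
        for rep in range(1, config.expr_replicates + 1):
            lib = rng.uniform(0.5, 2.0)
            mu = mu_gene * lib
            p = r / (r + mu)
            columns[f"{grp}_r{rep}"] = rng.negative_binomial(r, p)
            sheet_rows.append({"sample_id": f"{grp}_r{rep}", "group": grp, "replicate": rep})
    counts = pd.DataFrame(columns, index=genes)
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    return counts, sheet, planted


# ---------------------------------------------------------------------------
# one-call bundle

@dataclass
class SimulatedBundle:
    """Everything one simulation emits, ready for the pipeline."""

    config: SimulationConfig
    manifest: ProbeManifest
    islands: list[GenomicInterval]
    tss: pd.DataFrame
    gene_bodies: list[GenomicInterval]
    hic_track: list[GenomicInterval]
    experiment: diffmeth.MethylationExperiment
    truth: GroundTruth
    peaks: dict[str, PeakSet]
    counts: pd.DataFrame
    count_sheet: pd.DataFrame
    planted_logfc: pd.DataFrame


def simulate_all(config: SimulationConfig) -> SimulatedBundle:
    """Run every generator stage under one config (deterministic per seed)."""
    manifest, islands, tss, bodies = generate_manifest(config)
    hic = generate_hic_track(config)
    experiment, truth = generate_methylation(config, manifest, hic)
    peaks = generate_peaks(config, hic)
    counts, count_sheet, planted_logfc = generate_counts(config)
    from .chromatin_marks import overlap_probes

    truth.mark_flags = overlap_probes(peaks, manifest)
    return SimulatedBundle(
        config=config, manifest=manifest, islands=islands, tss=tss,
        gene_bodies=bodies, hic_track=hic, experiment=experiment, truth=truth,
        peaks=peaks, counts=counts, count_sheet=count_sheet,
        planted_logfc=planted_logfc,
    )


def write_simulation(bundle: SimulatedBundle, outdir) -> None:
    """Write all six input kinds (data_io formats) plus the ground truth."""
    from pathlib import Path

    from . import data_io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data_io.write_manifest(out / "manifest.tsv", bundle.manifest)
    data_io.write_intervals(out / "islands.bed", bundle.islands, "bed")
    data_io.write_intervals(out / "hic_track.bedgraph", bundle.hic_track, "bedgraph")
    data_io.write_intervals(out / "gene_bodies.bed", bundle.gene_bodies, "bed")
    tss = bundle.tss.copy()
    tss["pos"] = tss.pop("pos0") + 1
    tss.to_csv(out / "tss.tsv", sep="\t", index_label="gene")
    data_io.write_matrix(out / "methylation_beta.tsv", bundle.experiment.values)
    data_io.write_sample_sheet(out / "samples.tsv", bundle.experiment.samples)
    for mark, ps in bundle.peaks.items():
        data_io.write_intervals(out / f"peaks_{mark}.bed", ps.peaks, "bed")
    data_io.write_matrix(out / "expression_counts.tsv", bundle.counts.astype(float))
    bundle.count_sheet.to_csv(out / "expression_samples.tsv", sep="\t", index_label="sample_id")
    rows = []
    for particle, ids in bundle.truth.true_dmp_ids.items():
        deltas = bundle.truth.planted_delta[particle]
        for pid in sorted(ids):
            rows.append({"particle": particle, "probe_id": pid, "planted_delta": deltas[pid]})
    pd.DataFrame(rows).to_csv(out / "ground_truth_dmps.tsv", sep="\t", index=False)
    bundle.planted_logfc.to_csv(out / "ground_truth_logfc.tsv", sep="\t")
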
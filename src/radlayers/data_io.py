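"""Readers and writers for the tabular and interval formats used across the pipeline.

All genomic intervals are held 0-based half-open (BED convention). Probe
manifests arrive with 1-based point positions and are converted to 0-based
(``pos0 = pos - 1``) on load; writers emit 1-based positions again. All
readers accept plain or gzip-compressed files transparently (by ``.gz``
suffix).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A file could not be parsed; message names the offending line/cell."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


#: Island-relative distance classes of a methylation probe.
CPG_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
#: Merged 3-level variant (shores and shelves combined).
CPG_RELATIONS_3 = ("Island", "ShoreShelf", "OpenSea")
#: Gene-relative location classes of a probe.
GENIC_GROUPS = ("Promoter", "Upstream", "Downstream", "Body", "Intergenic")

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na", "N/A"}


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


@dataclass
class GenomicInterval:
    """A 0-based half-open genomic interval with optional score and name."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.score is not None and not math.isfinite(self.score):
            raise ValidationError(
                f"interval score must be finite: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        """Whether the 0-based point ``pos0`` falls inside the interval."""
        return self.start <= pos0 < self.end


class ProbeManifest:
    """Coordinate backbone of the analysis: one genomic point per probe.

    Wraps a DataFrame indexed by unique probe id with columns ``chrom``,
    ``pos0`` (0-based point), ``cpg_relation`` and ``genic_group``.
    """

    COLUMNS = ("chrom", "pos0", "cpg_relation", "genic_group")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
        bad_rel = set(frame["cpg_relation"]) - set(CPG_RELATIONS)
        if bad_rel:
            raise ValidationError(f"unknown cpg_relation values: {sorted(bad_rel)}")
        bad_gen = set(frame["genic_group"]) - set(GENIC_GROUPS)
        if bad_gen:
            raise ValidationError(f"unknown genic_group values: {sorted(bad_gen)}")
        if (frame["pos0"] < 0).any():
            raise ValidationError("manifest positions must be >= 1 (1-based)")
        self.df = frame[list(self.COLUMNS)].copy()
        self.df.index.name = "probe_id"

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def positions(self, probe_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """``chrom``/``pos0`` for the requested probes (all by default)."""
        if probe_ids is None:
            return self.df[["chrom", "pos0"]]
        return self.df.loc[list(probe_ids), ["chrom", "pos0"]]


def read_intervals(path: str | Path, format: str = "bed") -> list[GenomicInterval]:
    """Read a BED or bedGraph file into a list of intervals (file order kept).

    BED: columns chrom/start/end with optional name (col 4) and score
    (col 5). bedGraph: chrom/start/end/value, value mapped to ``score``.
    """
    if format not in ("bed", "bedgraph"):
        raise ValueError(f"unknown interval format: {format!r}")
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric start/end") from exc
            name: str | None = None
            score: float | None = None
            if format == "bedgraph":
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
                try:
                    score = float(fields[3])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric bedGraph value") from exc
            else:
                if len(fields) >= 4 and fields[3] != ".":
                    name = fields[3]
                if len(fields) >= 5 and fields[4] != ".":
                    try:
                        score = float(fields[4])
                    except ValueError as exc:
                        raise ParseError(f"{path}:{lineno}: non-numeric BED score") from exc
            try:
                out.append(GenomicInterval(chrom, start, end, score=score, name=name))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(
    path: str | Path, intervals: Iterable[GenomicInterval], format: str = "bed"
) -> None:
    """Write intervals as BED (5 columns) or bedGraph (4 columns)."""
    if format not in ("bed", "bedgraph"):
        raise ValueError(f"unknown interval format: {format!r}")
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            if format == "bedgraph":
                if iv.score is None:
                    raise ValidationError("bedGraph output requires a score on every interval")
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_fmt(iv.score)}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = _fmt(iv.score) if iv.score is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


def _fmt(x: float) -> str:
    # repr round-trips floats exactly; integers stay compact
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_manifest(path: str | Path) -> ProbeManifest:
    """Read a probe manifest TSV (probe_id, chrom, pos 1-based, cpg_relation, genic_group)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "pos", "cpg_relation", "genic_group"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    if not pd.api.types.is_integer_dtype(df["pos"]):
        raise ParseError(f"{path}: manifest pos column must be integer")
    if (df["pos"] < 1).any():
        raise ValidationError(f"{path}: manifest positions must be >= 1")
    frame = df.set_index("probe_id")
    frame["pos0"] = frame.pop("pos") - 1
    return ProbeManifest(frame)


def write_manifest(path: str | Path, manifest: ProbeManifest) -> None:
    out = manifest.df.copy()
    out["pos"] = out.pop("pos0") + 1
    out = out[["chrom", "pos", "cpg_relation", "genic_group"]]
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV value matrix (header = sample ids, first column = row ids).

    Missing cells (empty/NA/NaN) become NaN, never zero. Ragged rows and
    non-numeric cells raise :class:`ParseError` naming the position.
    """
    with _open_text(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise ParseError(f"{path}: empty matrix file")
        header = header_line.split("\t")
        ncol = len(header) - 1
        columns = header[1:]
        row_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1 and fields[0] == "":
                continue
            if len(fields) != ncol + 1:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(fields) - 1} cells, expected {ncol})"
                )
            row_ids.append(fields[0])
            vals = np.empty(ncol, dtype=float)
            for j, cell in enumerate(fields[1:]):
                if cell in _MISSING_TOKENS:
                    vals[j] = np.nan
                else:
                    try:
                        vals[j] = float(cell)
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric cell {cell!r} "
                            f"(row {fields[0]!r}, column {columns[j]!r})"
                        ) from exc
            rows.append(vals)
    values = np.vstack(rows) if rows else np.empty((0, ncol))
    return pd.DataFrame(values, index=pd.Index(row_ids, name=header[0]), columns=columns)


def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label=matrix.index.name or "id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV (sample_id, particle, dose_gy, timepoint, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "particle": str, "timepoint": str})
    required = {"sample_id", "particle", "dose_gy", "timepoint", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    if (df["dose_gy"] < 0).any():
        raise ValidationError(f"{path}: dose_gy must be >= 0")
    return df.set_index("sample_id")


def write_sample_sheet(path: str | Path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, sep="\t", index_label="sample_id")


def merge_intervals(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merge overlapping intervals per chromosome.

    Returns ``chrom -> (k, 2) array`` of sorted disjoint [start, end) pairs;
    the workhorse behind all point-in-region queries.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        acc: list[list[int]] = []
        for s, e in pairs:
            if acc and s <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[chrom] = np.array(acc, dtype=np.int64)
    return merged


def points_in_intervals(
    chroms: Sequence[str], pos0: np.ndarray, merged: dict[str, np.ndarray]
) -> np.ndarray:
    """Boolean mask: does each 0-based point fall inside the merged interval set."""
    chroms = np.asarray(chroms)
    pos0 = np.asarray(pos0)
    mask = np.zeros(len(pos0), dtype=bool)
    for chrom, arr in merged.items():
        sel = chroms == chrom
        if not sel.any() or len(arr) == 0:
            continue
        idx = np.searchsorted(arr[:, 0], pos0[sel], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(sel.sum(), dtype=bool)
        hit[ok] = pos0[sel][ok] < arr[idx[ok], 1]
        mask[sel] = hit
    return mask


def iter_chrom_blocks(frame: pd.DataFrame) -> Iterator[tuple[str, pd.DataFrame]]:
    """Yield (chrom, sub-frame sorted by pos0) per chromosome, in sorted chrom order."""
    for chrom in sorted(frame["chrom"].unique()):
        sub = frame[frame["chrom"] == chrom].sort_values("pos0", kind="mergesort")
        yield chrom, sub
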
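"""Cohort I/O: probe maps, log2-ratio matrices, SEG files, clinical and expression tables.

All genomic coordinates are held internally as 1-based inclusive intervals
(the SEG convention). BED input/output is converted at the boundary
(0-based half-open). Chromosomes are restricted to the human autosomes
plus chrX, ordered naturally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


class CohortIOError(ValueError):
    """Raised on malformed or invariant-violating input files."""


def chrom_rank(chrom: str) -> int:
    try:
        return _CHROM_RANK[chrom]
    except KeyError:
        raise CohortIOError(
            f"unsupported chromosome {chrom!r}; expected one of chr1..chr22, chrX"
        ) from None


@dataclass(frozen=True)
class ProbeMap:
    """Ordered positional scaffold of array probes.

    ``table`` has columns probe_id, chrom, start, end (1-based inclusive),
    strictly sorted by (chrom, start), with unique probe ids.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["probe_id", "chrom", "start", "end"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise CohortIOError(f"probe map missing columns: {missing}")
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise CohortIOError(f"duplicate probe id {dup!r}")
        for c in t["chrom"].unique():
            chrom_rank(c)
        if (t["start"] > t["end"]).any():
            bad = t.index[t["start"] > t["end"]][0]
            raise CohortIOError(f"probe {t.loc[bad, 'probe_id']!r}: start > end")
        ranks = t["chrom"].map(_CHROM_RANK).to_numpy()
        starts = t["start"].to_numpy()
        key = ranks.astype(np.int64) * (starts.max() + 1 if len(starts) else 1) + starts
        if np.any(np.diff(key) < 0):
            raise CohortIOError("probe map not sorted by (chrom, start)")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        t = self.table
        return (t["start"].to_numpy() + t["end"].to_numpy()) / 2.0

    def chromosome_blocks(self) -> list[tuple[str, np.ndarray]]:
        """Contiguous probe-index blocks per chromosome, in genome order."""
        out = []
        chroms = self.chroms
        idx = np.arange(len(chroms))
        for c in CHROMOSOMES:
            sel = idx[chroms == c]
            if len(sel):
                out.append((c, sel))
        return out

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> "ProbeMap":
        t = frame.copy()
        t["chrom_rank"] = t["chrom"].map(_CHROM_RANK)
        if t["chrom_rank"].isna().any():
            bad = t.loc[t["chrom_rank"].isna(), "chrom"].iloc[0]
            raise CohortIOError(f"unsupported chromosome {bad!r}")
        sorted_t = t.sort_values(["chrom_rank", "start"], kind="mergesort")
        if not sorted_t.index.equals(t.index):
            logger.info("probe map rows were not in genome order; re-sorted")
        sorted_t = sorted_t.drop(columns="chrom_rank").reset_index(drop=True)
        return ProbeMap(sorted_t)


def read_probe_map(path) -> ProbeMap:
    """Read a BED-style probe map (0-based half-open) into a ProbeMap.

    Columns: chrom, start, end, probe_id, tab-separated, no header.
    Rows out of genome order are sorted with a logged notice.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise CohortIOError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, start_s, end_s, probe_id = parts[:4]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError:
                raise CohortIOError(f"{path}:{lineno}: non-integer coordinates") from None
            if start0 >= end0:
                raise CohortIOError(f"{path}:{lineno}: start >= end ({start0} >= {end0})")
            if start0 < 0:
                raise CohortIOError(f"{path}:{lineno}: negative start")
            # BED half-open -> 1-based inclusive
            rows.append((probe_id, chrom, start0 + 1, end0))
    if not rows:
        raise CohortIOError(f"{path}: empty probe map")
    frame = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])
    pm = ProbeMap.from_frame(frame)
    t = pm.table
    same_chrom = t["chrom"].to_numpy()[1:] == t["chrom"].to_numpy()[:-1]
    overlap = same_chrom & (t["start"].to_numpy()[1:] <= t["end"].to_numpy()[:-1])
    if overlap.any():
        i = int(np.flatnonzero(overlap)[0])
        raise CohortIOError(
            f"{path}: probes {t['probe_id'].iloc[i]!r} and "
            f"{t['probe_id'].iloc[i + 1]!r} have overlapping coordinates"
        )
    return pm


def write_probe_map(probe_map: ProbeMap, path) -> None:
    """Write a ProbeMap as BED (0-based half-open)."""
    t = probe_map.table
    out = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "start": t["start"] - 1,
            "end": t["end"],
            "probe_id": t["probe_id"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class CopyNumberMatrix:
    """Per-probe log2 ratios (probes x samples), aligned to a ProbeMap.

    Missing values are NaN and are excluded from downstream statistics.
    """

    values: pd.DataFrame
    probe_map: ProbeMap = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.probe_map):
            raise CohortIOError(
                f"matrix has {len(self.values)} rows but probe map has "
                f"{len(self.probe_map)} probes"
            )
        if self.values.columns.duplicated().any():
            raise CohortIOError("duplicate sample ids")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values.to_numpy(dtype=float)).any():
                raise CohortIOError("non-finite (inf) log2 ratio values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def read_matrix(path, probe_map: ProbeMap) -> CopyNumberMatrix:
    """Read a probes x samples TSV of log2 ratios, aligned to ``probe_map``.

    Probes present in the map but absent from the file become missing rows.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    unknown = raw.index.difference(probe_map.probe_ids)
    if len(unknown):
        raise CohortIOError(f"{path}: probe {unknown[0]!r} not in probe map")
    if raw.index.duplicated().any():
        raise CohortIOError(f"{path}: duplicated probe row")
    vals = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col].replace({"NA": None, "": None}), errors="coerce")
        bad = converted.isna() & raw[col].notna() & ~raw[col].isin(["NA", ""])
        if bad.any():
            probe = raw.index[bad.to_numpy()][0]
            raise CohortIOError(
                f"{path}: non-numeric value {raw.loc[probe, col]!r} "
                f"at probe {probe!r}, sample {col!r}"
            )
        vals[col] = converted
    aligned = vals.reindex(probe_map.probe_ids)
    aligned.index.name = "probe_id"
    return CopyNumberMatrix(aligned, probe_map)


def write_matrix(matrix: CopyNumberMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA")


@dataclass(frozen=True)
class SegmentRecord:
    """One piecewise-constant segment of one sample's profile."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    seg_mean: float

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise CohortIOError(f"segment with n_probes={self.n_probes} < 1")
        if self.start > self.end:
            raise CohortIOError("segment start > end")


def _check_non_overlapping(records: list[SegmentRecord]) -> None:
    by_sample: dict[str, list[SegmentRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    for sample, recs in by_sample.items():
        recs = sorted(recs, key=lambda r: (chrom_rank(r.chrom), r.start))
        for a, b in zip(recs, recs[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise CohortIOError(
                    f"overlapping segments for sample {sample!r} on {a.chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def write_seg(records: list[SegmentRecord], path) -> None:
    """Write SEG format (1-based inclusive, 4-decimal seg.mean)."""
    _check_non_overlapping(records)
    frame = pd.DataFrame(
        {
            "ID": [r.sample_id for r in records],
            "chrom": [r.chrom for r in records],
            "loc.start": [r.start for r in records],
            "loc.end": [r.end for r in records],
            "num.mark": [r.n_probes for r in records],
            "seg.mean": [f"{r.seg_mean:.4f}" for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_seg(path) -> list[SegmentRecord]:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortIOError(f"{path}: SEG file missing columns {missing}")
    records = [
        SegmentRecord(
            sample_id=str(row["ID"]),
            chrom=str(row["chrom"]),
            start=int(row["loc.start"]),
            end=int(row["loc.end"]),
            n_probes=int(row["num.mark"]),
            seg_mean=float(row["seg.mean"]),
        )
        for _, row in frame.iterrows()
    ]
    _check_non_overlapping(records)
    return records


CLINICAL_COLUMNS = [
    "sample_id",
    "er_status",
    "pgr_status",
    "ln_status",
    "size_mm",
    "grade",
    "intrinsic_subtype",
    "brca_status",
    "os_time",
    "os_event",
    "dmfs_time",
    "dmfs_event",
]


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample covariates, endpoints and mutation status.

    Times are in years; event flags are 0/1; categorical fields may be 'NA'.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise CohortIOError(f"clinical table missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise CohortIOError("duplicate sample id in clinical table")
        for col in ("os_time", "dmfs_time"):
            if (t[col].astype(float) < 0).any():
                raise CohortIOError(f"negative {col}")
        for col in ("os_event", "dmfs_event"):
            if not t[col].astype(int).isin([0, 1]).all():
                raise CohortIOError(f"{col} must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])


def read_clinical(path) -> ClinicalTable:
    frame = pd.read_csv(path, sep="\t")
    return ClinicalTable(frame)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized log expression (genes x samples) with gene coordinates.

    ``genes`` has columns gene_id, chrom, start, end (1-based inclusive),
    index-aligned with the rows of ``values``.
    """

    values: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genes["gene_id"].duplicated().any():
            raise CohortIOError("duplicate gene id")
        if len(self.genes) != len(self.values):
            raise CohortIOError("gene annotation / expression row mismatch")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_expression(path) -> ExpressionMatrix:
    """Read a gene-expression TSV: gene_id, chrom, start, end, then samples."""
    frame = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "start", "end"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CohortIOError(f"{path}: expression table missing columns {missing}")
    genes = frame[required].copy()
    values = frame.drop(columns=required).astype(float)
    values.index = pd.Index(genes["gene_id"], name="gene_id")
    genes.index = values.index
    return ExpressionMatrix(values, genes)


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = pd.concat(
        [expr.genes.reset_index(drop=True), expr.values.reset_index(drop=True)], axis=1
    )
    out.to_csv(path, sep="\t", index=False)
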
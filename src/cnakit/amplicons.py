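"""Recurrent high-level amplicon cataloging and coamplification analysis.

Per sample, maximal probe runs flagged as high-level amplification
(segment mean >= amp_cut, default log2 >= 1) form amplified intervals;
intervals are clustered across samples into loci by single-linkage probe
overlap. The coamplification matrix is directed: entry (A, B) is the
fraction of A-carriers that also carry B, so it is generally asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gistic import GisticRegionTable
from .io import ProbeMap
from .segmentation import CallCohort

class AmpliconError(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconLocus:
    chrom: str
    start: int  # bp, 1-based inclusive
    end: int
    start_probe: int
    end_probe: int
    carriers: frozenset[str]
    frequency: float
    mode_probe: int  # probe amplified in the most carriers
    gistic_region: int | None  # index into the annotating region table, if any

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class AmpliconCatalog:
    loci: list[AmpliconLocus]
    n_samples: int
    probe_map: ProbeMap = field(repr=False)

    def __len__(self) -> int:
        return len(self.loci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": [l.label for l in self.loci],
                "chrom": [l.chrom for l in self.loci],
                "start": [l.start for l in self.loci],
                "end": [l.end for l in self.loci],
                "n_carriers": [len(l.carriers) for l in self.loci],
                "frequency": [l.frequency for l in self.loci],
                "gistic_region": [l.gistic_region for l in self.loci],
            }
        )


def detect_amplicons(
    calls: CallCohort,
    recurrence: float = 0.01,
    regions: GisticRegionTable | None = None,
) -> AmpliconCatalog:
    """Cluster per-sample high-amplification runs into recurrent loci.

    Loci are retained when their carrier frequency strictly exceeds
    ``recurrence``. Each locus is annotated with the gain region (if any)
    whose wide span contains the locus's modal probe.
    """
    high = calls.high_amp.to_numpy()
    probe_map = calls.probe_map
    sample_ids = list(calls.states.columns)
    n_samples = len(sample_ids)

    intervals: list[tuple[int, int, int]] = []  # (start_probe, end_probe, sample_ix)
    for _, block in probe_map.chromosome_blocks():
        sub = high[block, :]
        for s in range(n_samples):
            col = sub[:, s]
            if not col.any():
                continue
            padded = np.concatenate(([False], col, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(int)))
            for a, b in zip(edges[::2], edges[1::2]):
                intervals.append((int(block[a]), int(block[b - 1]), s))

    intervals.sort(key=lambda t: (t[0], t[1]))
    clusters: list[list[tuple[int, int, int]]] = []
    cur: list[tuple[int, int, int]] = []
    cur_end = -1
    for iv in intervals:
        if cur and iv[0] <= cur_end:
            cur.append(iv)
            cur_end = max(cur_end, iv[1])
        else:
            if cur:
                clusters.append(cur)
            cur = [iv]
            cur_end = iv[1]
    if cur:
        clusters.append(cur)

    table = probe_map.table
    loci: list[AmpliconLocus] = []
    for members in clusters:
        carriers = frozenset(sample_ids[s] for _, _, s in members)
        freq = len(carriers) / n_samples
        if freq <= recurrence:
            continue
        lo = min(m[0] for m in members)
        hi = max(m[1] for m in members)
        counts = np.zeros(hi - lo + 1, dtype=int)
        for a, b, _ in members:
            counts[a - lo : b - lo + 1] += 1
        mode_probe = int(lo + np.argmax(counts))
        region_ix = None
        if regions is not None:
            for k, reg in enumerate(regions.regions):
                if reg.kind == "gain" and mode_probe in reg.wide_probes:
                    region_ix = k
                    break
        loci.append(
            AmpliconLocus(
                chrom=str(table["chrom"].iloc[lo]),
                start=int(table["start"].iloc[lo]),
                end=int(table["end"].iloc[hi]),
                start_probe=lo,
                end_probe=hi,
                carriers=carriers,
                frequency=freq,
                mode_probe=mode_probe,
                gistic_region=region_ix,
            )
        )
    loci.sort(key=lambda l: (l.start_probe, l.end_probe))
    return AmpliconCatalog(loci, n_samples, probe_map)


@dataclass
class CoampMatrix:
    """Directed coamplification fractions over recurrent loci.

    ``raw[A, B]`` = |carriers(A) & carriers(B)| / |carriers(A)|; ``masked``
    replaces entries below the display threshold with NaN (diagonal kept).
    """

    raw: pd.DataFrame
    masked: pd.DataFrame
    carrier_counts: pd.Series


def coamplification(
    catalog: AmpliconCatalog,
    min_carriers: int = 3,
    display_cut: float = 0.2,
) -> CoampMatrix:
    """Directed coamplification matrix over loci with >= ``min_carriers`` carriers."""
    if len(catalog) == 0:
        raise AmpliconError("empty amplicon catalog")
    kept = [l for l in catalog.loci if len(l.carriers) >= min_carriers]
    labels = [l.label for l in kept]
    n = len(kept)
    raw = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            inter = len(kept[a].carriers & kept[b].carriers)
            raw[a, b] = inter / len(kept[a].carriers)
    raw_df = pd.DataFrame(raw, index=labels, columns=labels)
    masked = raw_df.where((raw_df >= display_cut) | np.eye(n, dtype=bool))
    counts = pd.Series([len(l.carriers) for l in kept], index=labels, name="n_carriers")
    return CoampMatrix(raw_df, masked, counts)
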
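"""Recurrent copy-number region scoring with permutation significance and peel-off.

Each probe gets a G-score, the sum over aberrant samples of |segment mean|
(capped), i.e. frequency x average amplitude. Significance comes from a null
in which every sample's probe-level aberration profile is independently
cyclically shifted, preserving within-sample segment structure and aberration
load. Probe p-values are converted to Benjamini-Hochberg q-values; peaks are
extracted iteratively, peeling off the driving samples' aberrations so that
independent regions on the same chromosome survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .io import ProbeMap
from .segmentation import STATE_GAIN, STATE_LOSS, CallCohort, SegmentedCohort

KINDS = ("gain", "loss")


class GisticError(ValueError):
    pass


def _target_state(kind: str) -> int:
    if kind == "gain":
        return STATE_GAIN
    if kind == "loss":
        return STATE_LOSS
    raise GisticError(f"kind must be one of {KINDS}, got {kind!r}")


def _contributions(
    seg_means: np.ndarray, states: np.ndarray, kind: str, cap: float
) -> np.ndarray:
    """Per-probe, per-sample capped amplitude contributions for one kind."""
    target = _target_state(kind)
    amp = np.where(np.isfinite(seg_means), np.abs(seg_means), 0.0)
    return np.where(states == target, np.minimum(amp, cap), 0.0)


def gscore(
    seg_means: np.ndarray, states: np.ndarray, kind: str, cap: float = 2.0
) -> np.ndarray:
    """Per-probe G-score: sum of capped |segment mean| over aberrant samples."""
    return _contributions(seg_means, states, kind, cap).sum(axis=1)


def permutation_null(
    seg_means: np.ndarray,
    states: np.ndarray,
    kind: str,
    n_perm: int = 1000,
    seed: int = 0,
    cap: float = 2.0,
) -> np.ndarray:
    """Null G-score matrix (n_perm x n_probes) from per-sample cyclic shifts."""
    if n_perm < 100:
        raise GisticError("n_perm must be >= 100")
    contrib = _contributions(seg_means, states, kind, cap)
    n_probes, n_samples = contrib.shape
    rng = np.random.default_rng(seed)
    shifts = rng.integers(0, n_probes, size=(n_perm, n_samples))
    null = np.empty((n_perm, n_probes))
    rows = np.arange(n_probes)[:, None]
    cols = np.arange(n_samples)[None, :]
    for p in range(n_perm):
        null[p] = contrib[(rows - shifts[p][None, :]) % n_probes, cols].sum(axis=1)
    return null


def pvalues_from_null(g_obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Per-probe permutation p-values: (1 + #{perm G >= observed G}) / (n_perm + 1)."""
    n_perm = null.shape[0]
    count = (null >= g_obs[None, :]).sum(axis=0)
    return (1.0 + count) / (n_perm + 1.0)


def q_values(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg monotone q-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise GisticError("p-values must lie in (0, 1]")
    return false_discovery_control(p, method="bh")


@dataclass(frozen=True)
class GisticRegion:
    kind: str
    chrom: str
    wide_start: int
    wide_end: int
    peak_start: int
    peak_end: int
    peak_probes: tuple[int, ...]  # probe indices into the probe map
    wide_probes: tuple[int, ...]
    gscore: float
    qvalue: float
    frequency: float  # fraction of samples aberrant at the peak's maximal probe


@dataclass
class GisticRegionTable:
    regions: list[GisticRegion]
    probe_map: ProbeMap = field(repr=False)

    def __len__(self) -> int:
        return len(self.regions)

    def by_kind(self, kind: str) -> list[GisticRegion]:
        _target_state(kind)
        return [r for r in self.regions if r.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [r.kind for r in self.regions],
                "chrom": [r.chrom for r in self.regions],
                "wide_start": [r.wide_start for r in self.regions],
                "wide_end": [r.wide_end for r in self.regions],
                "peak_start": [r.peak_start for r in self.regions],
                "peak_end": [r.peak_end for r in self.regions],
                "n_peak_probes": [len(r.peak_probes) for r in self.regions],
                "gscore": [r.gscore for r in self.regions],
                "qvalue": [r.qvalue for r in self.regions],
                "frequency": [r.frequency for r in self.regions],
            }
        )


def write_regions(table: GisticRegionTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_regions(path, probe_map: ProbeMap) -> GisticRegionTable:
    """Rebuild a region table from its TSV, recovering probe indices from bounds."""
    frame = pd.read_csv(path, sep="\t")
    starts = probe_map.table["start"].to_numpy()
    ends = probe_map.table["end"].to_numpy()
    chroms = probe_map.chroms
    regions = []
    for _, row in frame.iterrows():
        on_chr = chroms == row["chrom"]
        wide = np.flatnonzero(on_chr & (starts >= row["wide_start"]) & (ends <= row["wide_end"]))
        peak = np.flatnonzero(on_chr & (starts >= row["peak_start"]) & (ends <= row["peak_end"]))
        if len(peak) == 0 or len(wide) == 0:
            raise GisticError(f"region {row.to_dict()} matches no probes")
        regions.append(
            GisticRegion(
                kind=str(row["kind"]),
                chrom=str(row["chrom"]),
                wide_start=int(row["wide_start"]),
                wide_end=int(row["wide_end"]),
                peak_start=int(row["peak_start"]),
                peak_end=int(row["peak_end"]),
                peak_probes=tuple(int(i) for i in peak),
                wide_probes=tuple(int(i) for i in wide),
                gscore=float(row["gscore"]),
                qvalue=float(row["qvalue"]),
                frequency=float(row["frequency"]),
            )
        )
    return GisticRegionTable(regions, probe_map)


def _contiguous_run(mask: np.ndarray, center: int) -> np.ndarray:
    """Indices of the maximal True run of ``mask`` containing ``center``."""
    lo = center
    while lo - 1 >= 0 and mask[lo - 1]:
        lo -= 1
    hi = center
    while hi + 1 < len(mask) and mask[hi + 1]:
        hi += 1
    return np.arange(lo, hi + 1)


def peel_off(
    seg_means: np.ndarray,
    states: np.ndarray,
    kind: str,
    probe_map: ProbeMap,
    null: np.ndarray,
    q_threshold: float = 0.25,
    cap: float = 2.0,
    plateau_fraction: float = 0.95,
    merge_gap: int = 5,
    max_regions: int = 200,
) -> GisticRegionTable:
    """Extract independent significant regions by iterative peel-off.

    Significance is assessed once, on the original G-scores: q-values come
    from the fixed permutation null, and the smallest G among q-significant
    probes becomes the retention threshold g*. Peel-off then repeatedly takes
    the maximal re-scored probe, records its peak (plateau run) and wide
    region (original significant run), removes the driving samples'
    contiguous aberrant runs, and stops when no probe's re-scored G
    reaches g*.
    """
    target = _target_state(kind)
    work_states = states.copy()
    contrib = _contributions(seg_means, work_states, kind, cap)
    table = probe_map.table
    chrom_of = probe_map.chroms
    blocks = {c: b for c, b in probe_map.chromosome_blocks()}

    orig_aberrant_frac = (states == target).mean(axis=1)
    g_obs = contrib.sum(axis=1)
    q = q_values(pvalues_from_null(g_obs, null))
    sig0 = (q < q_threshold) & (g_obs > 0)
    if not sig0.any():
        return GisticRegionTable([], probe_map)
    g_star = float(g_obs[sig0].min())

    regions: list[GisticRegion] = []
    for _ in range(max_regions):
        g = contrib.sum(axis=1)
        candidates = g >= g_star
        if not candidates.any():
            break
        m_star = int(np.flatnonzero(candidates)[np.argmax(g[candidates])])
        chrom = chrom_of[m_star]
        block = blocks[chrom]
        b0 = block[0]
        g_block = g[block]
        local = m_star - b0
        peak_rel = _contiguous_run(g_block >= plateau_fraction * g[m_star], local)
        wide_rel = _contiguous_run(sig0[block], local)
        peak = block[peak_rel]
        wide = block[wide_rel]
        if not sig0[m_star]:
            # re-scored maximum outside the originally significant set:
            # treat its own probe as the wide span
            wide = peak
        regions.append(
            GisticRegion(
                kind=kind,
                chrom=chrom,
                wide_start=int(table["start"].iloc[wide[0]]),
                wide_end=int(table["end"].iloc[wide[-1]]),
                peak_start=int(table["start"].iloc[peak[0]]),
                peak_end=int(table["end"].iloc[peak[-1]]),
                peak_probes=tuple(int(i) for i in peak),
                wide_probes=tuple(int(i) for i in wide),
                gscore=float(g[m_star]),
                qvalue=float(q[m_star]),
                frequency=float(orig_aberrant_frac[m_star]),
            )
        )
        # peel: for each sample aberrant at the peak's maximal probe, remove its
        # contiguous same-kind aberrant run containing that probe
        drivers = np.flatnonzero(work_states[m_star, :] == target)
        for s in drivers:
            run_rel = _contiguous_run(work_states[block, s] == target, local)
            run = block[run_rel]
            work_states[run, s] = 0
            contrib[run, s] = 0.0

    regions = _merge_close(regions, merge_gap)
    return GisticRegionTable(regions, probe_map)


def _merge_close(regions: list[GisticRegion], merge_gap: int) -> list[GisticRegion]:
    """Merge same-chromosome peaks separated by fewer than ``merge_gap`` probes."""
    if not regions:
        return regions
    ordered = sorted(regions, key=lambda r: (r.chrom, min(r.peak_probes)))
    merged: list[GisticRegion] = [ordered[0]]
    for r in ordered[1:]:
        prev = merged[-1]
        gap = min(r.peak_probes) - max(prev.peak_probes) - 1
        if r.chrom == prev.chrom and r.kind == prev.kind and gap < merge_gap:
            peak = tuple(sorted(set(prev.peak_probes) | set(r.peak_probes)))
            wide = tuple(sorted(set(prev.wide_probes) | set(r.wide_probes)))
            merged[-1] = GisticRegion(
                kind=prev.kind,
                chrom=prev.chrom,
                wide_start=min(prev.wide_start, r.wide_start),
                wide_end=max(prev.wide_end, r.wide_end),
                peak_start=min(prev.peak_start, r.peak_start),
                peak_end=max(prev.peak_end, r.peak_end),
                peak_probes=peak,
                wide_probes=wide,
                gscore=max(prev.gscore, r.gscore),
                qvalue=min(prev.qvalue, r.qvalue),
                frequency=max(prev.frequency, r.frequency),
            )
        else:
            merged.append(r)
    return merged


def run_gistic(
    seg: SegmentedCohort,
    calls: CallCohort,
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.25,
    cap: float = 2.0,
    plateau_fraction: float = 0.95,
    merge_gap: int = 5,
    kinds: tuple[str, ...] = KINDS,
) -> GisticRegionTable:
    """Score both gains and losses for a cohort and return all retained regions."""
    seg_means = seg.seg_means.to_numpy()
    states = calls.states.to_numpy()
    all_regions: list[GisticRegion] = []
    for kind in kinds:
        null = permutation_null(seg_means, states, kind, n_perm=n_perm, seed=seed, cap=cap)
        part = peel_off(
            seg_means,
            states,
            kind,
            seg.probe_map,
            null,
            q_threshold=q_threshold,
            cap=cap,
            plateau_fraction=plateau_fraction,
            merge_gap=merge_gap,
        )
        all_regions.extend(part.regions)
    return GisticRegionTable(all_regions, seg.probe_map)
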
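"""Circular binary segmentation, adaptive gain/loss calling, and genome-altered fraction.

Each sample's probe-ordered log2 profile is partitioned per chromosome by
recursive circular binary splits: the arc with the maximal mean-shift
statistic is tested against a within-segment permutation reference and the
split is accepted at p < alpha. Gain/loss states are then assigned by
sample-adaptive thresholds derived from the robust scale (MAD) of 250-kbp
smoothed data, with segments shorter than a minimum probe count forced
neutral and segment means at or above ``amp_cut`` flagged as high-level
amplifications.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io import CopyNumberMatrix, ProbeMap, SegmentRecord

logger = logging.getLogger(__name__)

STATE_LOSS, STATE_NEUTRAL, STATE_GAIN = -1, 0, 1


class SegmentationError(ValueError):
    pass


@njit(cache=True)
def _max_arc_stat(c: np.ndarray, n: int) -> tuple[float, int, int]:
    """Maximal circular-arc mean-shift statistic over valid split pairs.

    ``c`` is the cumulative sum with c[0]=0. Valid arcs [i, j) have length
    2..n-2 and leave no linear piece of fewer than 2 probes. The statistic is
    |sum(arc) - k*mean_total| / sqrt(k*(n-k)/n), i.e. the two-sample z
    numerator; the (permutation-invariant) scale divides out later.
    """
    total = c[n]
    best = -1.0
    bi = -1
    bj = -1
    for k in range(2, n - 1):
        denom = math.sqrt(k * (n - k) / n)
        expect = k * total / n
        for i in range(0, n - k + 1):
            j = i + k
            if i == 1 or j == n - 1:
                continue
            stat = abs(c[j] - c[i] - expect) / denom
            if stat > best:
                best = stat
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _perm_exceed_count(
    x: np.ndarray, n: int, obs: float, n_perm: int, stop_at: int, seed: int
) -> tuple[int, int]:
    """Count permutations whose maximal arc statistic reaches ``obs``.

    Stops early once ``stop_at`` exceedances are seen (the split can then no
    longer be significant, whatever the remaining permutations would show).
    """
    np.random.seed(seed)
    y = x.copy()
    c = np.empty(n + 1)
    cnt = 0
    for p in range(n_perm):
        for t in range(n - 1, 0, -1):
            u = np.random.randint(0, t + 1)
            tmp = y[t]
            y[t] = y[u]
            y[u] = tmp
        c[0] = 0.0
        for t in range(n):
            c[t + 1] = c[t] + y[t]
        total = c[n]
        exceeded = False
        for k in range(2, n - 1):
            thresh = obs * math.sqrt(k * (n - k) / n)
            expect = k * total / n
            for i in range(0, n - k + 1):
                j = i + k
                if i == 1 or j == n - 1:
                    continue
                if abs(c[j] - c[i] - expect) >= thresh:
                    exceeded = True
                    break
            if exceeded:
                break
        if exceeded:
            cnt += 1
            if cnt >= stop_at:
                return cnt, p + 1
    return cnt, n_perm


def _split_segment(
    x: np.ndarray, alpha: float, n_perm: int, seed: int
) -> tuple[int, int] | None:
    """Return accepted circular change-points (i, j) within ``x``, or None."""
    n = len(x)
    if n < 4:
        return None
    if np.std(x) < 1e-12:
        return None
    c = np.concatenate(([0.0], np.cumsum(x)))
    best, i, j = _max_arc_stat(c, n)
    if best < 0:
        return None
    # significance requires (1 + cnt) / (n_perm + 1) < alpha
    limit = alpha * (n_perm + 1) - 1
    if limit <= 0:
        return None
    stop_at = int(math.floor(limit)) + 1
    cnt, n_done = _perm_exceed_count(x, n, best, n_perm, stop_at, seed)
    if n_done < n_perm or (1 + cnt) / (n_perm + 1) >= alpha:
        return None
    return i, j


@dataclass
class SegmentedProfile:
    """One sample's CBS result: segment records plus per-probe segment stats."""

    sample_id: str
    records: list[SegmentRecord]
    probe_seg_mean: np.ndarray  # NaN at missing probes
    probe_seg_size: np.ndarray  # probes in the covering segment, 0 if missing
    probe_map: ProbeMap = field(repr=False)


def cbs_segment(
    values: np.ndarray,
    probe_map: ProbeMap,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    sample_id: str = "sample",
) -> SegmentedProfile:
    """Segment a per-probe log2 vector with circular binary segmentation.

    Missing probes are excluded; segments partition the non-missing probes of
    each chromosome. All-missing chromosomes are skipped with a log notice.
    """
    if not 0.0 < alpha < 1.0:
        raise SegmentationError(f"alpha {alpha} outside (0, 1)")
    values = np.asarray(values, dtype=float)
    if len(values) != len(probe_map):
        raise SegmentationError("value vector / probe map length mismatch")

    table = probe_map.table
    seg_mean = np.full(len(values), np.nan)
    seg_size = np.zeros(len(values), dtype=np.int64)
    records: list[SegmentRecord] = []
    test_counter = 0

    for chrom, block in probe_map.chromosome_blocks():
        obs_ix = block[np.isfinite(values[block])]
        if len(obs_ix) == 0:
            logger.info("sample %s: chromosome %s all missing, skipped", sample_id, chrom)
            continue
        x = values[obs_ix]
        n = len(x)
        boundaries = [0, n]
        stack = [(0, n)]
        while stack:
            lo, hi = stack.pop()
            test_counter += 1
            sub_seed = (seed * 1_000_003 + test_counter * 7919) % (2**31 - 1)
            split = _split_segment(x[lo:hi], alpha, n_perm, sub_seed)
            if split is None:
                continue
            i, j = split
            pieces = sorted({lo, lo + i, lo + j, hi})
            for p in pieces[1:-1]:
                boundaries.append(p)
            for a, b in zip(pieces, pieces[1:]):
                if b - a >= 4:
                    stack.append((a, b))
        boundaries = sorted(set(boundaries))
        for a, b in zip(boundaries, boundaries[1:]):
            members = obs_ix[a:b]
            mean = float(np.mean(values[members]))
            seg_mean[members] = mean
            seg_size[members] = b - a
            records.append(
                SegmentRecord(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(table["start"].iloc[members[0]]),
                    end=int(table["end"].iloc[members[-1]]),
                    n_probes=b - a,
                    seg_mean=mean,
                )
            )
    return SegmentedProfile(sample_id, records, seg_mean, seg_size, probe_map)


@dataclass
class SegmentedCohort:
    """CBS results for a whole cohort, aligned to the probe map."""

    seg_means: pd.DataFrame  # probes x samples
    seg_sizes: pd.DataFrame  # probes x samples (int)
    records: list[SegmentRecord]
    probe_map: ProbeMap = field(repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.seg_means.columns)


def segment_cohort(
    cn: CopyNumberMatrix,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> SegmentedCohort:
    """Run cbs_segment on every sample of a CopyNumberMatrix."""
    means = {}
    sizes = {}
    records: list[SegmentRecord] = []
    for k, sid in enumerate(cn.sample_ids):
        prof = cbs_segment(
            cn.values[sid].to_numpy(),
            cn.probe_map,
            alpha=alpha,
            n_perm=n_perm,
            seed=(seed + 97 * k) % (2**31 - 1),
            sample_id=sid,
        )
        means[sid] = prof.probe_seg_mean
        sizes[sid] = prof.probe_seg_size
        records.extend(prof.records)
    seg_means = pd.DataFrame(means, index=cn.probe_map.probe_ids)
    seg_sizes = pd.DataFrame(sizes, index=cn.probe_map.probe_ids)
    return SegmentedCohort(seg_means, seg_sizes, records, cn.probe_map)


def smooth_window(
    values: np.ndarray, probe_map: ProbeMap, window_bp: int = 250_000
) -> np.ndarray:
    """Mean-smooth a per-probe vector over probes within +-window_bp/2 (by midpoint).

    Smoothing never crosses chromosome boundaries. Missing probes are excluded
    from window means and stay missing in the output.
    """
    if window_bp <= 0:
        raise SegmentationError("window_bp must be positive")
    values = np.asarray(values, dtype=float)
    out = np.full(len(values), np.nan)
    mids = probe_map.midpoints
    half = window_bp / 2.0
    for _, block in probe_map.chromosome_blocks():
        m = mids[block]
        v = values[block]
        lo = np.searchsorted(m, m - half, side="left")
        hi = np.searchsorted(m, m + half, side="right")
        finite = np.isfinite(v)
        cs = np.concatenate(([0.0], np.cumsum(np.where(finite, v, 0.0))))
        cnt = np.concatenate(([0], np.cumsum(finite.astype(int))))
        sums = cs[hi] - cs[lo]
        counts = cnt[hi] - cnt[lo]
        with np.errstate(invalid="ignore"):
            sm = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        sm[~finite] = np.nan
        out[block] = sm
    return out


def adaptive_thresholds(
    smoothed: np.ndarray, k: float = 2.5, tau_min: float = 0.1
) -> tuple[float, float]:
    """Sample-adaptive gain/loss thresholds from smoothed data.

    The robust scale s is the MAD about the median, scaled to a
    Gaussian-consistent sd (x1.4826); thresholds are median +- max(k*s, tau_min).
    """
    x = np.asarray(smoothed, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise SegmentationError(f"need >= 10 smoothed values, got {len(x)}")
    med = float(np.median(x))
    s = 1.4826 * float(np.median(np.abs(x - med)))
    delta = max(k * s, tau_min)
    return med + delta, med - delta


@dataclass
class CallProfile:
    """Discrete per-probe states for one sample."""

    sample_id: str
    states: np.ndarray  # int8: -1 loss, 0 neutral, 1 gain
    high_amp: np.ndarray  # bool
    valid: np.ndarray  # bool, False at missing probes
    tau_gain: float
    tau_loss: float


def call_states(
    seg: SegmentedProfile,
    thresholds: tuple[float, float],
    amp_cut: float = 1.0,
    min_probes: int = 4,
) -> CallProfile:
    """Assign gain/loss/neutral per probe from its segment mean.

    Segments of fewer than ``min_probes`` probes are forced neutral; the
    high-amplification flag requires both a gain state and a segment mean at
    or above ``amp_cut``.
    """
    tau_gain, tau_loss = thresholds
    if tau_gain <= tau_loss:
        raise SegmentationError("tau_gain must exceed tau_loss")
    mean = seg.probe_seg_mean
    valid = np.isfinite(mean)
    usable = valid & (seg.probe_seg_size >= min_probes)
    states = np.zeros(len(mean), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        states[usable & (mean >= tau_gain)] = STATE_GAIN
        states[usable & (mean <= tau_loss)] = STATE_LOSS
        high = (states == STATE_GAIN) & (mean >= amp_cut)
    return CallProfile(seg.sample_id, states, high, valid, tau_gain, tau_loss)


def fga(calls: CallProfile) -> tuple[float, float, float]:
    """Fraction of the genome altered: (total, gained, lost), probe-weighted."""
    n = int(calls.valid.sum())
    if n == 0:
        raise SegmentationError("no non-missing probes")
    g = float((calls.states[calls.valid] == STATE_GAIN).sum()) / n
    l = float((calls.states[calls.valid] == STATE_LOSS).sum()) / n
    return g + l, g, l


@dataclass
class CallCohort:
    """Discrete calls for a whole cohort."""

    states: pd.DataFrame  # int8, probes x samples
    high_amp: pd.DataFrame  # bool
    valid: pd.DataFrame  # bool
    thresholds: pd.DataFrame  # samples x (tau_gain, tau_loss)
    probe_map: ProbeMap = field(repr=False)


def call_cohort(
    cn: CopyNumberMatrix,
    seg: SegmentedCohort,
    window_bp: int = 250_000,
    k: float = 2.5,
    tau_min: float = 0.1,
    amp_cut: float = 1.0,
    min_probes: int = 4,
) -> CallCohort:
    """Smooth, derive per-sample thresholds, and call states for a cohort."""
    states = {}
    high = {}
    valid = {}
    thr = {}
    for sid in seg.sample_ids:
        smoothed = smooth_window(cn.values[sid].to_numpy(), cn.probe_map, window_bp)
        thresholds = adaptive_thresholds(smoothed, k=k, tau_min=tau_min)
        prof = SegmentedProfile(
            sid,
            [],
            seg.seg_means[sid].to_numpy(),
            seg.seg_sizes[sid].to_numpy(),
            cn.probe_map,
        )
        cp = call_states(prof, thresholds, amp_cut=amp_cut, min_probes=min_probes)
        states[sid] = cp.states
        high[sid] = cp.high_amp
        valid[sid] = cp.valid
        thr[sid] = thresholds
    idx = cn.probe_map.probe_ids
    return CallCohort(
        pd.DataFrame(states, index=idx),
        pd.DataFrame(high, index=idx),
        pd.DataFrame(valid, index=idx),
        pd.DataFrame(thr, index=["tau_gain", "tau_loss"]).T,
        cn.probe_map,
    )


def cohort_from_records(
    records: list[SegmentRecord], probe_map: ProbeMap
) -> SegmentedCohort:
    """Rebuild per-probe segment means/sizes from SEG records (e.g. read from file)."""
    sample_ids = list(dict.fromkeys(r.sample_id for r in records))
    table = probe_map.table
    starts = table["start"].to_numpy()
    ends = table["end"].to_numpy()
    chroms = probe_map.chroms
    means = {s: np.full(len(probe_map), np.nan) for s in sample_ids}
    sizes = {s: np.zeros(len(probe_map), dtype=np.int64) for s in sample_ids}
    for r in records:
        sel = (chroms == r.chrom) & (starts >= r.start) & (ends <= r.end)
        means[r.sample_id][sel] = r.seg_mean
        sizes[r.sample_id][sel] = r.n_probes
    idx = probe_map.probe_ids
    return SegmentedCohort(
        pd.DataFrame(means, index=idx)[sample_ids],
        pd.DataFrame(sizes, index=idx)[sample_ids],
        list(records),
        probe_map,
    )


def write_calls(calls: CallCohort, path) -> None:
    """Write per-probe states as TSV: -1 loss, 0 neutral, 1 gain, 2 high-amp gain; NA missing."""
    coded = calls.states.astype(int).where(~calls.high_amp, 2)
    coded = coded.where(calls.valid)
    coded.to_csv(path, sep="\t", na_rep="NA")


def read_calls(path, probe_map: ProbeMap) -> CallCohort:
    """Read a calls TSV written by :func:`write_calls` (thresholds not recoverable)."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw = raw.reindex(probe_map.probe_ids)
    valid = raw.notna()
    high = raw == 2
    states = raw.replace(2, 1).fillna(0).astype(np.int8)
    thr = pd.DataFrame(
        {"tau_gain": np.nan, "tau_loss": np.nan}, index=raw.columns
    )
    return CallCohort(states, high, valid, thr, probe_map)


def fga_cohort(calls: CallCohort) -> pd.DataFrame:
    """Per-sample FGA table with columns fga_total, fga_gain, fga_loss."""
    rows = {}
    for sid in calls.states.columns:
        cp = CallProfile(
            sid,
            calls.states[sid].to_numpy(),
            calls.high_amp[sid].to_numpy(),
            calls.valid[sid].to_numpy(),
            float(calls.thresholds.loc[sid, "tau_gain"]),
            float(calls.thresholds.loc[sid, "tau_loss"]),
        )
        total, g, l = fga(cp)
        rows[sid] = (total, g, l)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["fga_total", "fga_gain", "fga_loss"]
    )
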
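"""Expression-dosage integration: genes whose mRNA tracks their local copy number.

Genes are assigned to significant regions whose probe span (expanded by one
probe on each side to include borderline genes) overlaps the gene interval.
Each gene's expression is correlated (Pearson) with its region's per-sample
mean segmented log2 ratio; the pass cutoff r* is the empirical (1 - alpha)
quantile of correlations recomputed under permutations of the copy-number
sample labels, pooled across genes. Arbitrary gene signatures can be scored
per sample by list means or centroid correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gistic import GisticRegionTable
from .io import ExpressionMatrix
from .segmentation import SegmentedCohort

logger = logging.getLogger(__name__)


class IntegrationError(ValueError):
    pass


def map_genes_to_regions(
    genes: pd.DataFrame,
    regions: GisticRegionTable,
    flank_probes: int = 1,
) -> pd.DataFrame:
    """Assign genes to regions by interval overlap with a probe-expanded span.

    ``genes`` needs columns gene_id, chrom, start, end. A gene may map to
    several regions; genes with unusable coordinates are excluded with a log
    notice. Returns a frame with columns gene_id, region (region-table index).
    """
    table = regions.probe_map.table
    n_probes = len(table)
    chroms = regions.probe_map.chroms
    spans = []
    for k, reg in enumerate(regions.regions):
        lo, hi = min(reg.wide_probes), max(reg.wide_probes)
        for _ in range(flank_probes):
            if lo - 1 >= 0 and chroms[lo - 1] == reg.chrom:
                lo -= 1
            if hi + 1 < n_probes and chroms[hi + 1] == reg.chrom:
                hi += 1
        spans.append((k, reg.chrom, int(table["start"].iloc[lo]), int(table["end"].iloc[hi])))

    rows = []
    for _, g in genes.iterrows():
        try:
            gstart, gend = int(g["start"]), int(g["end"])
            gchrom = str(g["chrom"])
        except (TypeError, ValueError):
            logger.info("gene %s has unusable coordinates; excluded", g.get("gene_id"))
            continue
        if not np.isfinite(gstart) or gstart > gend:
            logger.info("gene %s has unusable coordinates; excluded", g.get("gene_id"))
            continue
        for k, chrom, lo, hi in spans:
            if gchrom == chrom and gstart <= hi and gend >= lo:
                rows.append((g["gene_id"], k))
    return pd.DataFrame(rows, columns=["gene_id", "region"])


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores (population sd); returns (z, zero-variance mask)."""
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    zero = sd[:, 0] < 1e-12
    z = (x - mean) / np.where(sd > 0, sd, 1.0)
    z[zero, :] = 0.0
    return z, zero


@dataclass
class DosageCorrelationResult:
    """Per-gene dosage correlations with the permutation-derived cutoff r*."""

    table: pd.DataFrame  # gene_id, region, r, passed
    r_star: float
    alpha: float
    two_sided: bool


def dosage_correlation(
    expr: ExpressionMatrix,
    region_values: pd.DataFrame,
    assignment: pd.DataFrame,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    two_sided: bool = False,
) -> DosageCorrelationResult:
    """Correlate mapped genes with their region's per-sample copy-number value.

    ``region_values`` is regions x samples (mean segmented log2 per region);
    ``assignment`` comes from :func:`map_genes_to_regions`. The null permutes
    the copy-number sample labels ``n_perm`` times and pools all gene
    correlations; r* is the pooled (1 - alpha) quantile (of |r| when
    ``two_sided``). Zero-variance genes or regions are skipped with a notice.
    """
    if n_perm < 100:
        raise IntegrationError("n_perm must be >= 100")
    shared = [s for s in expr.sample_ids if s in region_values.columns]
    if len(shared) < 10:
        raise IntegrationError(f"need >= 10 shared samples, got {len(shared)}")

    pairs = assignment[assignment["gene_id"].isin(expr.values.index)]
    e = expr.values.loc[pairs["gene_id"], shared].to_numpy(dtype=float)
    rvals = region_values.loc[pairs["region"], shared].to_numpy(dtype=float)
    ez, e_zero = _standardize_rows(e)
    rz, r_zero = _standardize_rows(rvals)
    skip = e_zero | r_zero
    for gid in pairs.loc[skip, "gene_id"]:
        logger.info("gene %s skipped: zero-variance expression or region vector", gid)

    n = len(shared)
    r_obs = (ez * rz).sum(axis=1) / n

    rng = np.random.default_rng(seed)
    null_pool = []
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_null = (ez * rz[:, perm]).sum(axis=1) / n
        null_pool.append(r_null[~skip])
    pooled = np.concatenate(null_pool) if null_pool else np.array([0.0])
    if two_sided:
        r_star = float(np.quantile(np.abs(pooled), 1 - alpha))
        passed = np.abs(r_obs) >= r_star
    else:
        r_star = float(np.quantile(pooled, 1 - alpha))
        passed = r_obs >= r_star
    passed = passed & ~skip

    out = pd.DataFrame(
        {
            "gene_id": pairs["gene_id"].to_numpy(),
            "region": pairs["region"].to_numpy(),
            "r": np.where(skip, np.nan, r_obs),
            "passed": passed,
        }
    )
    return DosageCorrelationResult(out, r_star, alpha, two_sided)


def global_probe_correlation(
    expr: ExpressionMatrix, seg: SegmentedCohort
) -> pd.DataFrame:
    """Per-gene Pearson r against the nearest probe's segmented log2 ratio."""
    shared = [s for s in expr.sample_ids if s in seg.seg_means.columns]
    if len(shared) < 3:
        raise IntegrationError("need >= 3 shared samples")
    mids = seg.probe_map.midpoints
    chroms = seg.probe_map.chroms
    seg_vals = seg.seg_means[shared].to_numpy()
    rows = []
    for gid, g in expr.genes.iterrows():
        on_chr = np.flatnonzero(chroms == str(g["chrom"]))
        if len(on_chr) == 0:
            logger.info("gene %s on unmapped chromosome; skipped", gid)
            continue
        gmid = (float(g["start"]) + float(g["end"])) / 2.0
        probe_ix = int(on_chr[np.argmin(np.abs(mids[on_chr] - gmid))])
        x = seg_vals[probe_ix, :]
        y = expr.values.loc[gid, shared].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) < 1e-12 or np.std(y[ok]) < 1e-12:
            logger.info("gene %s skipped: constant probe or expression", gid)
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        rows.append((gid, probe_ix, r))
    return pd.DataFrame(rows, columns=["gene_id", "probe", "r"])


def signature_score(
    expr: ExpressionMatrix,
    gene_list: list[str],
    centroid: pd.Series | None = None,
) -> pd.Series:
    """Score samples against a gene list: centroid correlation or list mean."""
    present = [g for g in gene_list if g in expr.values.index]
    if not present:
        raise IntegrationError("no listed genes present in expression matrix")
    sub = expr.values.loc[present]
    if centroid is None:
        return sub.mean(axis=0).rename("score")
    cen = centroid.reindex(present).dropna()
    if cen.empty:
        raise IntegrationError("centroid shares no genes with expression matrix")
    sub = sub.loc[cen.index]
    scores = {}
    c = cen.to_numpy(dtype=float)
    for sid in sub.columns:
        v = sub[sid].to_numpy(dtype=float)
        scores[sid] = float(np.corrcoef(v, c)[0, 1]) if np.std(v) > 0 and np.std(c) > 0 else np.nan
    return pd.Series(scores, name="score")
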
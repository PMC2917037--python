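"""Genomic subtyping: clustering samples on significant-region summaries.

Samples are represented by per-region average scaled log2 ratios (per-region
z-scores of per-sample means over the region's peak probes) and clustered
agglomeratively with correlation distance and complete linkage. Subtypes are
characterized by supervised per-region Welch t-tests (Bonferroni-adjusted,
frequency-filtered) and exported as gene-expression centroids for
nearest-centroid classification of external cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from scipy.stats import ttest_ind

from .gistic import GisticRegionTable
from .io import ExpressionMatrix
from .segmentation import STATE_GAIN, STATE_LOSS, CallCohort, SegmentedCohort

logger = logging.getLogger(__name__)


class SubtypingError(ValueError):
    pass


def region_means(regions: GisticRegionTable, seg: SegmentedCohort) -> pd.DataFrame:
    """Per-region, per-sample mean segmented log2 ratio over the peak probes."""
    if len(regions) == 0:
        raise SubtypingError("empty region table")
    seg_vals = seg.seg_means.to_numpy()
    rows = []
    for k, reg in enumerate(regions.regions):
        probes = np.array(reg.peak_probes, dtype=int)
        if len(probes) == 0:
            raise SubtypingError(f"region {k} has zero probes")
        with np.errstate(invalid="ignore"):
            rows.append(np.nanmean(seg_vals[probes, :], axis=0))
    return pd.DataFrame(rows, index=range(len(regions.regions)), columns=seg.sample_ids)


@dataclass
class RegionSampleMatrix:
    """Regions x samples matrix of average scaled log2 ratios."""

    values: pd.DataFrame  # z-scored per region (rows) unless scale=False
    raw: pd.DataFrame
    row_mean: pd.Series
    row_sd: pd.Series


def build_region_matrix(
    regions: GisticRegionTable, seg: SegmentedCohort, scale: bool = True
) -> RegionSampleMatrix:
    """Summarize each region per sample, then standardize per region.

    Regions constant across samples (sd 0) are emitted as all-zero rows with
    a logged notice.
    """
    raw = region_means(regions, seg)
    mean = raw.mean(axis=1)
    sd = raw.std(axis=1, ddof=0)
    if not scale:
        return RegionSampleMatrix(raw.copy(), raw, mean, sd)
    degenerate = sd < 1e-12
    for k in raw.index[degenerate]:
        logger.info("region %s constant across samples; emitted as zeros", k)
    z = raw.sub(mean, axis=0).div(sd.where(~degenerate, 1.0), axis=0)
    z[degenerate] = 0.0
    return RegionSampleMatrix(z, raw, mean, sd)


@dataclass
class SubtypeAssignment:
    """Sample -> subtype labels with clustering provenance."""

    labels: pd.Series  # sample_id -> label
    linkage_matrix: np.ndarray = field(repr=False)
    k: int
    name_map: dict[str, str] = field(default_factory=dict)

    def relabel(self, mapping: dict[str, str]) -> "SubtypeAssignment":
        return SubtypeAssignment(
            self.labels.map(lambda l: mapping.get(l, l)),
            self.linkage_matrix,
            self.k,
            {**self.name_map, **mapping},
        )


def cluster_subtypes(matrix: RegionSampleMatrix, k: int = 6) -> SubtypeAssignment:
    """Agglomerative clustering with correlation distance and complete linkage."""
    x = matrix.values.to_numpy().T  # samples x regions
    samples = list(matrix.values.columns)
    if k < 2:
        raise SubtypingError("k must be >= 2")
    if k > len(samples):
        raise SubtypingError(f"k={k} exceeds {len(samples)} samples")
    sds = x.std(axis=1)
    if np.any(sds < 1e-12):
        bad = samples[int(np.argmin(sds))]
        raise SubtypingError(f"sample {bad!r} has a zero-variance region vector")
    d = pdist(x, metric="correlation")
    z = linkage(d, method="complete")
    flat = fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series(
        [f"cluster_{c}" for c in flat], index=pd.Index(samples, name="sample_id"),
        name="subtype",
    )
    return SubtypeAssignment(labels, z, k)


def name_clusters_by_template(
    assignment: SubtypeAssignment,
    seg: SegmentedCohort,
    templates: pd.DataFrame,
) -> SubtypeAssignment:
    """Rename clusters by matching mean profiles to archetype templates.

    ``templates`` is probes x archetype-names (expected mean log2). Clusters
    and templates are matched one-to-one to maximize total Pearson
    correlation of the cluster-mean segmented profile with the template;
    the mapping is logged.
    """
    clusters = sorted(assignment.labels.unique())
    names = list(templates.columns)
    seg_vals = seg.seg_means
    profiles = {}
    for c in clusters:
        members = assignment.labels.index[assignment.labels == c]
        profiles[c] = np.nan_to_num(seg_vals[list(members)].mean(axis=1).to_numpy())
    corr = np.zeros((len(clusters), len(names)))
    for i, c in enumerate(clusters):
        for j, name in enumerate(names):
            t = templates[name].to_numpy()
            if np.std(profiles[c]) < 1e-12 or np.std(t) < 1e-12:
                corr[i, j] = 0.0
            else:
                corr[i, j] = np.corrcoef(profiles[c], t)[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    mapping = {clusters[i]: names[j] for i, j in zip(rows, cols)}
    # clusters beyond the template count keep their cluster label
    logger.info("cluster naming by template match: %s", mapping)
    return assignment.relabel(mapping)


def supervised_region_tests(
    matrix: RegionSampleMatrix,
    regions: GisticRegionTable,
    groups: pd.Series,
    calls: CallCohort,
    freq_cut: float = 0.2,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-region two-group Welch t-tests with Bonferroni adjustment.

    ``groups`` maps sample id to one of exactly two labels. Reported regions
    satisfy adjusted P < alpha and have aberration frequency (fraction of
    group samples aberrant in the region's direction at any peak probe)
    >= ``freq_cut`` in at least one group.
    """
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise SubtypingError(f"expected exactly 2 groups, got {levels}")
    ga = groups.index[groups == levels[0]]
    gb = groups.index[groups == levels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise SubtypingError("both groups need >= 2 samples")
    states = calls.states
    n_tested = len(matrix.values)
    rows = []
    for k in matrix.values.index:
        va = matrix.values.loc[k, ga].to_numpy(dtype=float)
        vb = matrix.values.loc[k, gb].to_numpy(dtype=float)
        if np.std(np.concatenate([va, vb])) < 1e-12:
            p = 1.0
        else:
            p = float(ttest_ind(va, vb, equal_var=equal_var).pvalue)
            if not np.isfinite(p):
                p = 1.0
        reg = regions.regions[k]
        target = STATE_GAIN if reg.kind == "gain" else STATE_LOSS
        probes = list(reg.peak_probes)
        fa = float((states.iloc[probes][list(ga)] == target).any(axis=0).mean())
        fb = float((states.iloc[probes][list(gb)] == target).any(axis=0).mean())
        p_adj = min(1.0, p * n_tested)
        more = levels[0] if va.mean() * (1 if target == STATE_GAIN else -1) > vb.mean() * (
            1 if target == STATE_GAIN else -1
        ) else levels[1]
        rows.append((k, reg.kind, reg.chrom, p, p_adj, fa, fb, more))
    out = pd.DataFrame(
        rows,
        columns=[
            "region", "kind", "chrom", "p", "p_bonferroni",
            f"freq_{levels[0]}", f"freq_{levels[1]}", "more_aberrant_group",
        ],
    )
    keep = (out["p_bonferroni"] < alpha) & (
        (out[f"freq_{levels[0]}"] >= freq_cut) | (out[f"freq_{levels[1]}"] >= freq_cut)
    )
    return out[keep].reset_index(drop=True)


def build_centroids(
    expr: ExpressionMatrix,
    assignment: SubtypeAssignment,
    gene_list: list[str],
) -> pd.DataFrame:
    """Per-subtype mean expression over member samples, for the listed genes.

    Returns genes x subtypes. Genes absent from the expression matrix are
    dropped symmetrically; subtypes with no expression samples are excluded
    with a notice.
    """
    present = [g for g in gene_list if g in expr.values.index]
    if not present:
        raise SubtypingError("no listed genes present in expression matrix")
    cols = {}
    for label in sorted(assignment.labels.unique()):
        members = [
            s for s in assignment.labels.index[assignment.labels == label]
            if s in expr.values.columns
        ]
        if not members:
            logger.info("subtype %s has no expression samples; excluded", label)
            continue
        cols[label] = expr.values.loc[present, members].mean(axis=1)
    if not cols:
        raise SubtypingError("no subtype has expression samples")
    return pd.DataFrame(cols)


def classify_by_centroid(
    sample: pd.Series,
    centroids: pd.DataFrame,
    min_r: float | None = None,
) -> tuple[str, pd.Series]:
    """Nearest-centroid classification by maximal Pearson correlation.

    Ties are broken by centroid column order (logged); with ``min_r`` set,
    a best correlation below it yields the label 'unclassified'.
    """
    shared = centroids.index.intersection(sample.index)
    if len(shared) < 5:
        raise SubtypingError(f"need >= 5 shared genes, got {len(shared)}")
    v = sample.loc[shared].to_numpy(dtype=float)
    corrs = {}
    for label in centroids.columns:
        c = centroids.loc[shared, label].to_numpy(dtype=float)
        if np.std(v) < 1e-12 or np.std(c) < 1e-12:
            corrs[label] = np.nan
        else:
            corrs[label] = float(np.corrcoef(v, c)[0, 1])
    series = pd.Series(corrs)
    best = series.max()
    winners = [l for l in centroids.columns if series[l] == best]
    if len(winners) > 1:
        logger.info("centroid tie between %s; taking %s", winners, winners[0])
    label = winners[0]
    if min_r is not None and (not np.isfinite(best) or best < min_r):
        return "unclassified", series
    return label, series


def classify_cohort(
    expr: ExpressionMatrix,
    centroids: pd.DataFrame,
    min_r: float | None = None,
) -> pd.DataFrame:
    """Classify every sample of an expression matrix by nearest centroid."""
    rows = []
    for sid in expr.sample_ids:
        label, corrs = classify_by_centroid(expr.values[sid], centroids, min_r=min_r)
        rows.append((sid, label, corrs.max()))
    return pd.DataFrame(rows, columns=["sample_id", "label", "best_r"]).set_index(
        "sample_id"
    )
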
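"""Synthetic tumor-cohort generator.

Emulates a tiling BAC-array cohort: a probe scaffold over the 22 human
autosomes, per-sample segmental log2-ratio profiles drawn from subtype
archetypes (recurrent gains/losses plus high-level amplicons with
log2 >= 1), dosage-driven expression for cis genes, and subtype-dependent
exponential survival with independent censoring.

The archetype catalog encodes six genomic subtypes of breast cancer:
luminal-simple (1q/16p gain, 16q loss, genomically quiet), luminal-complex,
basal-complex (high aberration load), 17q12 (HER2-locus amplicon),
amplifier (8p12 amplicon with frequent 11q13 coamplification), and mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    CopyNumberMatrix,
    ExpressionMatrix,
    ProbeMap,
)

# Autosome lengths (Mb) and p-arm fractions, approximating the human genome.
_CHR_MB = {
    1: 245, 2: 243, 3: 199, 4: 191, 5: 181, 6: 171, 7: 159, 8: 146,
    9: 138, 10: 135, 11: 134, 12: 132, 13: 114, 14: 106, 15: 100, 16: 89,
    17: 79, 18: 76, 19: 64, 20: 62, 21: 47, 22: 50,
}
_P_ARM_FRAC = {
    1: 0.50, 2: 0.38, 3: 0.45, 4: 0.26, 5: 0.26, 6: 0.36, 7: 0.38, 8: 0.31,
    9: 0.35, 10: 0.30, 11: 0.40, 12: 0.27, 13: 0.16, 14: 0.17, 15: 0.19,
    16: 0.41, 17: 0.30, 18: 0.23, 19: 0.44, 20: 0.44, 21: 0.27, 22: 0.29,
}

# Named genomic regions as (chrom, fractional start, fractional end).
REGIONS: dict[str, tuple[str, float, float]] = {
    "1q": ("chr1", 0.50, 1.00),
    "3p": ("chr3", 0.00, 0.45),
    "4": ("chr4", 0.00, 1.00),
    "5q": ("chr5", 0.26, 1.00),
    "6p": ("chr6", 0.00, 0.40),
    "8p": ("chr8", 0.00, 0.31),
    "8p12": ("chr8", 0.20, 0.26),
    "8q": ("chr8", 0.31, 1.00),
    "8q24": ("chr8", 0.86, 0.92),
    "9p": ("chr9", 0.00, 0.35),
    "10p": ("chr10", 0.00, 0.30),
    "11q13": ("chr11", 0.50, 0.58),
    "11q13.3": ("chr11", 0.50, 0.54),
    "11q25": ("chr11", 0.92, 1.00),
    "12q15": ("chr12", 0.51, 0.55),
    "13q": ("chr13", 0.16, 1.00),
    "14q": ("chr14", 0.20, 1.00),
    "16p": ("chr16", 0.00, 0.41),
    "16q": ("chr16", 0.41, 1.00),
    "17p": ("chr17", 0.00, 0.30),
    "17q": ("chr17", 0.30, 1.00),
    "17q12": ("chr17", 0.45, 0.51),
    "18q": ("chr18", 0.40, 1.00),
    "19p": ("chr19", 0.00, 0.44),
    "19q": ("chr19", 0.44, 1.00),
    "20q13": ("chr20", 0.55, 0.70),
}

EVENT_KINDS = ("gain", "loss", "high_amp")


class SimulationError(ValueError):
    """Raised on invalid generator configuration."""


@dataclass(frozen=True)
class CNAEvent:
    """One catalog entry: a recurrent aberration with carrier probability.

    ``mean``/``sd`` parameterize the log2 amplitude (negative for losses).
    ``condition_on`` makes the carrier probability conditional on another
    event of the same archetype (``conditional_probability`` when the parent
    is present, ``probability`` otherwise), modelling coamplification.
    """

    region: str
    kind: str
    probability: float
    mean: float
    sd: float = 0.1
    condition_on: str | None = None
    conditional_probability: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SimulationError(f"unknown event kind {self.kind!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise SimulationError(f"probability {self.probability} outside [0,1]")
        if self.conditional_probability is not None and not (
            0.0 <= self.conditional_probability <= 1.0
        ):
            raise SimulationError("conditional probability outside [0,1]")
        if self.region not in REGIONS:
            raise SimulationError(f"unknown region {self.region!r}")
        if self.kind == "high_amp" and self.mean < 1.0:
            raise SimulationError("high_amp amplitude mean must be >= 1.0")
        if self.kind == "loss" and self.mean >= 0:
            raise SimulationError("loss amplitude mean must be negative")


@dataclass(frozen=True)
class SubtypeArchetype:
    """A genomic subtype's event catalog plus background instability level."""

    name: str
    events: tuple[CNAEvent, ...]
    background_rate: float = 0.03
    fga_band: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_rate <= 1.0:
            raise SimulationError("background rate outside [0,1]")


def default_archetypes() -> list[SubtypeArchetype]:
    """The six built-in genomic-subtype archetypes."""
    return [
        SubtypeArchetype(
            "luminal-simple",
            (
                CNAEvent("1q", "gain", 1.00, 0.40),
                CNAEvent("16p", "gain", 0.85, 0.35),
                CNAEvent("16q", "loss", 0.95, -0.40),
            ),
            background_rate=0.01,
            fga_band=(0.02, 0.15),
        ),
        SubtypeArchetype(
            "luminal-complex",
            (
                CNAEvent("1q", "gain", 0.95, 0.40),
                CNAEvent("8q", "gain", 0.90, 0.40),
                CNAEvent("11q13.3", "gain", 0.60, 0.50),
                CNAEvent("20q13", "gain", 0.85, 0.40),
                CNAEvent("3p", "loss", 0.60, -0.35),
                CNAEvent("8p", "loss", 0.85, -0.40),
                CNAEvent("9p", "loss", 0.55, -0.35),
                CNAEvent("11q25", "loss", 0.85, -0.40),
                CNAEvent("13q", "loss", 0.85, -0.35),
                CNAEvent("16q", "loss", 0.50, -0.35),
            ),
            background_rate=0.04,
            fga_band=(0.15, 0.40),
        ),
        SubtypeArchetype(
            "basal-complex",
            (
                CNAEvent("5q", "loss", 0.95, -0.35),
                CNAEvent("4", "loss", 0.85, -0.30),
                CNAEvent("10p", "gain", 0.90, 0.35),
                CNAEvent("6p", "gain", 0.85, 0.35),
                CNAEvent("8q", "gain", 0.60, 0.35),
                CNAEvent("3p", "loss", 0.50, -0.30),
                CNAEvent("9p", "loss", 0.50, -0.30),
                CNAEvent("1q", "gain", 0.40, 0.30),
            ),
            background_rate=0.10,
            fga_band=(0.30, 0.65),
        ),
        SubtypeArchetype(
            "17q12",
            (
                CNAEvent("17q12", "high_amp", 0.90, 1.80, 0.30),
                CNAEvent("17q", "gain", 0.90, 0.35),
                CNAEvent("17p", "loss", 0.75, -0.35),
                CNAEvent("1q", "gain", 0.40, 0.35),
            ),
            background_rate=0.04,
            fga_band=(0.05, 0.30),
        ),
        SubtypeArchetype(
            "amplifier",
            (
                CNAEvent("8p12", "high_amp", 0.95, 1.70, 0.30),
                CNAEvent(
                    "11q13",
                    "high_amp",
                    0.05,
                    1.60,
                    0.30,
                    condition_on="8p12",
                    conditional_probability=0.70,
                ),
                CNAEvent("1q", "gain", 0.90, 0.35),
                CNAEvent("19p", "gain", 0.95, 0.35),
                CNAEvent("19q", "gain", 0.95, 0.35),
                CNAEvent("8p", "loss", 0.95, -0.40),
                CNAEvent("17p", "loss", 0.80, -0.35),
            ),
            background_rate=0.04,
            fga_band=(0.10, 0.35),
        ),
        SubtypeArchetype(
            "mixed",
            (
                CNAEvent("8p", "loss", 0.95, -0.35),
                CNAEvent("13q", "loss", 0.95, -0.35),
                CNAEvent("17p", "loss", 0.85, -0.35),
                CNAEvent("14q", "loss", 0.95, -0.35),
                CNAEvent("18q", "loss", 0.95, -0.35),
                CNAEvent("1q", "gain", 0.65, 0.35),
                CNAEvent("8q24", "high_amp", 0.04, 1.50, 0.25),
            ),
            background_rate=0.06,
            fga_band=(0.10, 0.35),
        ),
    ]


_DEFAULT_HAZARDS = {
    "luminal-simple": 0.030,
    "luminal-complex": 0.070,
    "mixed": 0.090,
    "amplifier": 0.100,
    "basal-complex": 0.110,
    "17q12": 0.160,
}

_INTRINSIC = {
    "luminal-simple": [("LumA", 0.8), ("LumB", 0.1), ("Normal", 0.1)],
    "luminal-complex": [("LumB", 0.5), ("LumA", 0.4), ("HER2", 0.1)],
    "basal-complex": [("Basal", 0.85), ("HER2", 0.1), ("Normal", 0.05)],
    "17q12": [("HER2", 0.8), ("LumB", 0.15), ("Basal", 0.05)],
    "amplifier": [("LumB", 0.5), ("LumA", 0.3), ("HER2", 0.2)],
    "mixed": [("LumA", 0.4), ("LumB", 0.3), ("Basal", 0.2), ("Normal", 0.1)],
}

_ER_POS_PROB = {
    "luminal-simple": 0.90,
    "luminal-complex": 0.85,
    "basal-complex": 0.10,
    "17q12": 0.40,
    "amplifier": 0.80,
    "mixed": 0.60,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Defaults are the study conditions used throughout the test suite:
    5,000 probes over 22 autosomes, per-probe Gaussian noise sd 0.15,
    dosage slope 1 with expression noise sd 0.2, 10 cis genes per recurrent
    region, administrative censoring at 10 years plus uniform dropout.
    """

    n_samples: int = 200
    archetypes: list[SubtypeArchetype] = field(default_factory=default_archetypes)
    proportions: dict[str, float] | None = None  # default: equal
    n_probes: int = 5000
    noise_sd: float = 0.15
    cis_genes_per_region: int = 10
    n_trans_genes: int = 200
    dosage_slope: float = 1.0
    expr_noise_sd: float = 0.2
    hazards: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_HAZARDS))
    default_hazard: float = 0.08
    dmfs_hazard_factor: float = 1.3
    censor_horizon_years: float = 10.0
    dropout_scale_years: float = 25.0

    def __post_init__(self) -> None:
        if not self.archetypes:
            raise SimulationError("archetype catalog is empty")
        if self.n_probes <= 0 or self.n_samples <= 0:
            raise SimulationError("probe and sample counts must be positive")
        if self.noise_sd < 0:
            raise SimulationError("noise sd must be non-negative")
        names = [a.name for a in self.archetypes]
        if len(set(names)) != len(names):
            raise SimulationError("archetype names must be unique")
        if self.proportions is None:
            self.proportions = {n: 1.0 / len(names) for n in names}
        if set(self.proportions) != set(names):
            raise SimulationError("proportions must name exactly the archetypes")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise SimulationError(f"proportions sum to {total}, expected 1")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a simulated cohort, for recovery checks."""

    subtypes: pd.Series  # sample_id -> archetype name
    events: pd.DataFrame  # sample_id, region, chrom, probe span, kind, mean
    fga: pd.Series  # sample_id -> fraction of probes covered by any event
    cis_genes: pd.DataFrame  # gene_id, region, is_cis
    hazards: pd.Series  # sample_id -> true OS hazard rate


def build_probe_map(n_probes: int = 5000, spacing_bp: int = 50_000) -> ProbeMap:
    """Tile ``n_probes`` probes across a scaled 22-autosome genome.

    Probes are allocated proportionally to chromosome length (at least 20 per
    chromosome) and the genome is scaled so probes sit ``spacing_bp`` apart,
    emulating a densely tiled BAC array: relative arm lengths are preserved
    while the 250-kbp smoothing window still covers several probes.
    """
    total_mb = sum(_CHR_MB.values())
    counts = {c: max(20, int(round(n_probes * mb / total_mb))) for c, mb in _CHR_MB.items()}
    width = max(1, int(spacing_bp * 0.6))
    rows = []
    for c in range(1, 23):
        for i in range(counts[c]):
            start = i * spacing_bp + 1
            rows.append((f"P{c:02d}_{i:04d}", f"chr{c}", start, start + width - 1))
    frame = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])
    return ProbeMap.from_frame(frame)


def _chrom_lengths(probe_map: ProbeMap) -> dict[str, int]:
    return probe_map.table.groupby("chrom", sort=False)["end"].max().to_dict()


def _region_probe_slice(probe_map: ProbeMap, chrom: str, f0: float, f1: float) -> np.ndarray:
    length = _chrom_lengths(probe_map)[chrom]
    lo, hi = f0 * length, f1 * length
    mids = probe_map.midpoints
    mask = (probe_map.chroms == chrom) & (mids >= lo) & (mids <= hi)
    return np.flatnonzero(mask)


def _allocate_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    # largest-remainder allocation so every archetype with positive share appears
    names = list(proportions)
    exact = np.array([proportions[k] * n for k in names])
    base = np.floor(exact).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(names, base))


def _arm_intervals() -> list[tuple[str, float, float]]:
    arms = []
    for c in range(1, 23):
        split = _P_ARM_FRAC[c]
        arms.append((f"chr{c}", 0.0, split))
        arms.append((f"chr{c}", split, 1.0))
    return arms


def archetype_templates(probe_map: ProbeMap, archetypes: list[SubtypeArchetype]) -> pd.DataFrame:
    """Expected per-probe mean log2 per archetype (probability x amplitude).

    Used for post hoc naming of clusters by template matching.
    """
    out = {}
    for arch in archetypes:
        vec = np.zeros(len(probe_map))
        for ev in arch.events:
            chrom, f0, f1 = REGIONS[ev.region]
            sel = _region_probe_slice(probe_map, chrom, f0, f1)
            p = ev.probability
            if ev.condition_on is not None and ev.conditional_probability is not None:
                parent = next((e for e in arch.events if e.region == ev.condition_on), None)
                if parent is not None:
                    p = parent.probability * ev.conditional_probability + (
                        1 - parent.probability
                    ) * ev.probability
            vec[sel] += p * ev.mean
        out[arch.name] = vec
    return pd.DataFrame(out, index=probe_map.probe_ids)


def _draw_amplitude(rng: np.random.Generator, ev: CNAEvent) -> float:
    amp = rng.normal(ev.mean, ev.sd)
    if ev.kind == "high_amp":
        return max(amp, 1.0)
    if ev.kind == "gain":
        return max(amp, 0.2)
    return min(amp, -0.2)


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[ProbeMap, CopyNumberMatrix, ExpressionMatrix, ClinicalTable, CohortTruth]:
    """Generate a full synthetic cohort, reproducibly for a given seed."""
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(seed)
    probe_map = build_probe_map(config.n_probes)
    n_probes = len(probe_map)
    n = config.n_samples

    counts = _allocate_counts(n, config.proportions)
    labels: list[str] = []
    for name, k in counts.items():
        labels.extend([name] * k)
    labels = [labels[i] for i in rng.permutation(n)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    arch_by_name = {a.name: a for a in config.archetypes}
    arms = _arm_intervals()

    planted = np.zeros((n_probes, n))
    event_rows = []
    for j, (sid, label) in enumerate(zip(sample_ids, labels)):
        arch = arch_by_name[label]
        present: dict[str, bool] = {}
        for ev in arch.events:
            if ev.condition_on is not None and present.get(ev.condition_on, False):
                p = (
                    ev.conditional_probability
                    if ev.conditional_probability is not None
                    else ev.probability
                )
            else:
                p = ev.probability
            carried = rng.random() < p
            present[ev.region] = carried
            if not carried:
                continue
            chrom, f0, f1 = REGIONS[ev.region]
            sel = _region_probe_slice(probe_map, chrom, f0, f1)
            if len(sel) == 0:
                continue
            amp = _draw_amplitude(rng, ev)
            planted[sel, j] += amp
            event_rows.append(
                (sid, ev.region, chrom, sel[0], sel[-1], ev.kind, amp)
            )
        # background instability: random sub-arm events
        for chrom, a0, a1 in arms:
            if rng.random() >= arch.background_rate:
                continue
            span = a1 - a0
            frac_len = rng.uniform(0.15, 0.5) * span
            start = a0 + rng.uniform(0.0, span - frac_len)
            sel = _region_probe_slice(probe_map, chrom, start, start + frac_len)
            if len(sel) < 4:
                continue
            amp = rng.uniform(0.2, 0.35) * (1 if rng.random() < 0.5 else -1)
            planted[sel, j] += amp
            event_rows.append(
                (sid, f"bg:{chrom}", chrom, sel[0], sel[-1],
                 "gain" if amp > 0 else "loss", amp)
            )

    noise = rng.normal(0.0, config.noise_sd, size=planted.shape) if config.noise_sd > 0 else 0.0
    values = pd.DataFrame(
        planted + noise, index=probe_map.probe_ids, columns=sample_ids
    )
    values.index.name = "probe_id"
    cn = CopyNumberMatrix(values, probe_map)

    truth_events = pd.DataFrame(
        event_rows,
        columns=["sample_id", "region", "chrom", "start_probe", "end_probe", "kind", "mean"],
    )
    fga = pd.Series(
        (planted != 0).mean(axis=0), index=sample_ids, name="true_fga"
    )

    expr, cis_genes = _generate_expression(
        config, rng, probe_map, planted, sample_ids, arch_by_name
    )
    clinical, hazards = _generate_clinical(config, rng, sample_ids, labels)

    truth = CohortTruth(
        subtypes=pd.Series(labels, index=sample_ids, name="subtype"),
        events=truth_events,
        fga=fga,
        cis_genes=cis_genes,
        hazards=hazards,
    )
    return probe_map, cn, expr, clinical, truth


def _generate_expression(config, rng, probe_map, planted, sample_ids, arch_by_name):
    region_names = sorted(
        {ev.region for arch in arch_by_name.values() for ev in arch.events}
    )
    mids = probe_map.midpoints
    chroms = probe_map.chroms
    lengths = _chrom_lengths(probe_map)
    gene_rows = []
    expr_rows = []
    cis_rows = []
    for region in region_names:
        chrom, f0, f1 = REGIONS[region]
        length = lengths[chrom]
        for g in range(config.cis_genes_per_region):
            pos = rng.uniform(f0, f1) * length
            gid = f"G_{region.replace('.', '_')}_{g:02d}"
            # nearest probe on the chromosome carries the gene's true dosage
            on_chr = np.flatnonzero(chroms == chrom)
            probe_ix = on_chr[np.argmin(np.abs(mids[on_chr] - pos))]
            dosage = planted[probe_ix, :]
            vals = config.dosage_slope * dosage + rng.normal(
                0.0, config.expr_noise_sd, size=len(sample_ids)
            )
            gene_rows.append((gid, chrom, int(pos), int(pos) + 10_000))
            expr_rows.append(vals)
            cis_rows.append((gid, region, True))
    for g in range(config.n_trans_genes):
        c = int(rng.integers(1, 23))
        length = lengths[f"chr{c}"]
        pos = int(rng.uniform(0, max(length - 10_000, 1)))
        gid = f"G_trans_{g:03d}"
        gene_rows.append((gid, f"chr{c}", pos + 1, pos + 10_000))
        expr_rows.append(rng.normal(0.0, 1.0, size=len(sample_ids)))
        cis_rows.append((gid, "", False))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    values = pd.DataFrame(
        np.vstack(expr_rows), index=pd.Index(genes["gene_id"], name="gene_id"),
        columns=sample_ids,
    )
    genes.index = values.index
    cis = pd.DataFrame(cis_rows, columns=["gene_id", "region", "is_cis"])
    return ExpressionMatrix(values, genes), cis


def _categorical(rng, options):
    names = [o[0] for o in options]
    probs = np.array([o[1] for o in options])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def _generate_clinical(config, rng, sample_ids, labels):
    rows = []
    hazard_list = []
    for sid, label in zip(sample_ids, labels):
        hazard = config.hazards.get(label, config.default_hazard)
        hazard_list.append(hazard)
        er = "pos" if rng.random() < _ER_POS_PROB.get(label, 0.6) else "neg"
        pgr = er if rng.random() < 0.8 else ("neg" if er == "pos" else "pos")
        ln = "pos" if rng.random() < 0.4 else "neg"
        size = float(np.clip(rng.normal(22.0, 8.0), 5.0, 60.0))
        if label == "basal-complex":
            grade = _categorical(rng, [("3", 0.8), ("2", 0.15), ("1", 0.05)])
        elif label == "luminal-simple":
            grade = _categorical(rng, [("1", 0.45), ("2", 0.45), ("3", 0.10)])
        else:
            grade = _categorical(rng, [("1", 0.15), ("2", 0.45), ("3", 0.40)])
        intrinsic = _categorical(rng, _INTRINSIC.get(label, [("LumA", 1.0)]))
        if label == "basal-complex" and rng.random() < 0.15:
            brca = "BRCA1"
        elif label == "luminal-complex" and rng.random() < 0.15:
            brca = "BRCA2"
        elif rng.random() < 0.2:
            brca = "familial"
        else:
            brca = "sporadic"

        def endpoint(rate: float) -> tuple[float, int]:
            raw = rng.exponential(1.0 / rate)
            censor = min(config.censor_horizon_years, rng.uniform(0, config.dropout_scale_years))
            t = min(raw, censor)
            return max(t, 1e-3), int(raw <= censor)

        os_time, os_event = endpoint(hazard)
        dmfs_time, dmfs_event = endpoint(hazard * config.dmfs_hazard_factor)
        rows.append(
            (sid, er, pgr, ln, round(size, 1), grade, intrinsic, brca,
             round(os_time, 4), os_event, round(dmfs_time, 4), dmfs_event)
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "er_status", "pgr_status", "ln_status", "size_mm",
            "grade", "intrinsic_subtype", "brca_status",
            "os_time", "os_event", "dmfs_time", "dmfs_event",
        ],
    )
    hazards = pd.Series(hazard_list, index=sample_ids, name="os_hazard")
    return ClinicalTable(table), hazards
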
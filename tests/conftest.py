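"""Shared fixtures and probe-map builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cnakit.io import ProbeMap


def make_probe_map(
    chrom_probes: dict[str, int],
    spacing: int = 100_000,
    width: int = 50_000,
) -> ProbeMap:
    """Evenly spaced probes per chromosome, 1-based inclusive coordinates."""
    rows = []
    i = 0
    for chrom, n in chrom_probes.items():
        for k in range(n):
            start = k * spacing + 1
            rows.append((f"P{i:05d}", chrom, start, start + width - 1))
            i += 1
    return ProbeMap.from_frame(
        pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])
    )


@pytest.fixture
def probe_map_1chr() -> ProbeMap:
    return make_probe_map({"chr1": 100})


@pytest.fixture
def probe_map_2chr() -> ProbeMap:
    return make_probe_map({"chr1": 60, "chr2": 40})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
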
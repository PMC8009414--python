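"""Shared fixtures: hand-built toy panels and seeded synthetic panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ascertain as asc


def make_panel(
    positions,
    freq,
    pop_names,
    chrom="chr1",
    quality=100.0,
    depth=100,
    exonic=None,
    clusters=None,
    modes=None,
    outgroup=None,
    commercial=None,
    cm=None,
):
    """Small hand-specified SnpPanel for unit tests."""
    positions = np.asarray(positions)
    freq = np.asarray(freq, dtype=float)
    n = len(positions)
    chroms = [chrom] * n if isinstance(chrom, str) else list(chrom)
    loci = pd.DataFrame(
        {
            "chrom": chroms,
            "bp": positions.astype(np.int64),
            "cM": np.asarray(cm, float) if cm is not None else positions / 1e6,
            "quality": np.full(n, quality, dtype=float)
            if np.isscalar(quality) else np.asarray(quality, float),
            "depth": np.full(n, depth, dtype=np.int64)
            if np.isscalar(depth) else np.asarray(depth, np.int64),
            "exonic": np.zeros(n, dtype=bool) if exonic is None else np.asarray(exonic, bool),
            "ref": ["A"] * n,
            "alt": ["G"] * n,
        }
    )
    k = len(pop_names)
    pop_meta = pd.DataFrame(
        {
            "mode": modes or ["pool"] * k,
            "sample_size": [10] * k,
            "mean_depth": [30.0] * k,
            "cluster": clusters or [""] * k,
            "commercial": commercial or [False] * k,
            "outgroup": [p == outgroup for p in pop_names],
        },
        index=pd.Index(pop_names, name="population"),
    )
    return asc.SnpPanel(loci=loci, freq=freq, pop_meta=pop_meta)


def uniform_map(chrom="chr1", length=1_000_000, cm_per_mb=1.0):
    return asc.GeneticMap(
        {chrom: np.array([[1.0, 0.0], [float(length), cm_per_mb * length / 1e6]])}
    )


@pytest.fixture(scope="session")
def mid_panel():
    """Seeded synthetic panel at moderate size for property tests."""
    cfg = asc.default_config(n_populations=24, n_loci=12_000, seed=42)
    panel = asc.simulate_panel(cfg)
    panel.ancestral_is_ref = panel.loci["ancestral_is_ref_true"].to_numpy(bool)
    return panel


@pytest.fixture(scope="session")
def mid_map():
    cfg = asc.default_config(n_populations=24, n_loci=12_000, seed=42)
    return asc.simulate_map(cfg)


@pytest.fixture(scope="session")
def mid_groups(mid_panel):
    return asc.assign_groups(mid_panel, 8, 8, rng=42)


@pytest.fixture(scope="session")
def mid_design(mid_panel, mid_groups, mid_map):
    return asc.design_array(mid_panel, mid_groups, mid_map)
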
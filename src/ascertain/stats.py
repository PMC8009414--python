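"""Population-genetic statistics: polarization, spectra, H_exp, OHE, Nei distance.

Expected heterozygosity is the Hardy-Weinberg value averaged over loci,

    H_exp = (1/L) * sum_l 2 p_l (1 - p_l),

with ``p_l`` the reference-allele frequency at locus ``l``.  The
overestimation of H_exp (OHE) of an ascertained SNP set relative to a
reference set is

    OHE = (H_exp,set - H_exp,ref) / H_exp,ref,

zero when the sets agree and one when the ascertained estimate doubles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import ConfigError, SnpPanel, StatisticError


@dataclass
class AfsSummary:
    """A binned allele-frequency spectrum (proportions over [0, 1])."""

    edges: np.ndarray
    density: np.ndarray
    group: str = "all"
    step: str = "truth"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if not np.all(np.diff(self.edges) > 0):
            raise ConfigError("bin edges must be strictly increasing")
        if abs(self.density.sum() - 1.0) > 1e-9:
            raise ConfigError("AFS densities must sum to 1")

    def mass(self, lo: float, hi: float) -> float:
        """Total proportion in bins fully inside [lo, hi]."""
        sel = (self.edges[:-1] >= lo - 1e-12) & (self.edges[1:] <= hi + 1e-12)
        return float(self.density[sel].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.edges[:-1],
                "bin_right": self.edges[1:],
                "density": self.density,
                "group": self.group,
                "step": self.step,
            }
        )


def expected_heterozygosity(freq: np.ndarray) -> float:
    """Mean 2p(1-p) over loci for one population's frequencies."""
    freq = np.asarray(freq, dtype=float)
    if freq.size == 0:
        raise StatisticError("H_exp undefined on an empty SNP set")
    return float(np.mean(2.0 * freq * (1.0 - freq)))


def hexp_by_population(panel: SnpPanel, indices: np.ndarray | None = None) -> pd.Series:
    """H_exp per population over a SNP set (all loci by default)."""
    f = panel.freq if indices is None else panel.freq[np.asarray(indices, dtype=int)]
    if f.shape[0] == 0:
        raise StatisticError("H_exp undefined on an empty SNP set")
    return pd.Series(np.mean(2.0 * f * (1.0 - f), axis=0), index=panel.populations)


def ohe(h_set: float, h_ref: float) -> float:
    """Overestimation of H_exp: relative deviation of the ascertained estimate."""
    if h_ref <= 0:
        raise StatisticError("OHE undefined for a zero reference heterozygosity")
    return (h_set - h_ref) / h_ref


def nei_distance(px: np.ndarray, py: np.ndarray) -> float:
    """Nei's standard genetic distance between two populations, biallelic loci.

    D = -ln( Jxy / sqrt(Jx * Jy) ) with J the mean gene identities; returns
    ``inf`` when the populations share no alleles (Jxy = 0).
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    if px.shape != py.shape or px.size == 0:
        raise StatisticError("need matching non-empty frequency vectors")
    jxy = float(np.mean(px * py + (1 - px) * (1 - py)))
    jx = float(np.mean(px**2 + (1 - px) ** 2))
    jy = float(np.mean(py**2 + (1 - py) ** 2))
    if jxy <= 0:
        return float("inf")
    return max(0.0, -np.log(jxy / np.sqrt(jx * jy)))


def nei_distance_matrix(panel: SnpPanel, populations: Sequence[str] | None = None) -> pd.DataFrame:
    pops = list(populations) if populations is not None else panel.populations
    idx = panel.pop_index(pops)
    out = np.zeros((len(pops), len(pops)))
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            d = nei_distance(panel.freq[:, idx[a]], panel.freq[:, idx[b]])
            out[a, b] = out[b, a] = d
    return pd.DataFrame(out, index=pops, columns=pops)


def infer_ancestral(
    panel: SnpPanel,
    wild_populations: Sequence[str],
    weights: Sequence[float] = (1.0, 1.0, 2.0),
) -> np.ndarray:
    """Polarize loci from wild-population frequencies.

    The ancestral allele is taken to be the major allele across the given
    wild populations with the stated weights (the diverged outgroup counting
    double by default): with weighted reference frequency ``w``, ancestral =
    reference iff ``w >= 0.5`` (ties to reference).  Returns the per-locus
    flags and stores them on ``panel.ancestral_is_ref``.
    """
    if len(wild_populations) != len(weights):
        raise ConfigError("one weight per wild population required")
    missing = [p for p in wild_populations if p not in panel.populations]
    if missing:
        raise ConfigError(f"wild populations absent from panel: {missing}")
    idx = panel.pop_index(wild_populations)
    wts = np.asarray(weights, dtype=float)
    w = panel.freq[:, idx] @ wts / wts.sum()
    flags = w >= 0.5
    panel.ancestral_is_ref = flags
    return flags


def derived_frequencies(
    panel: SnpPanel,
    indices: np.ndarray | None = None,
    populations: Sequence[str] | None = None,
) -> np.ndarray:
    """Mean derived-allele frequency per locus over the chosen populations."""
    if panel.ancestral_is_ref is None:
        raise StatisticError("panel is not polarized; run infer_ancestral first")
    f = panel.freq
    anc = panel.ancestral_is_ref
    if indices is not None:
        indices = np.asarray(indices, dtype=int)
        f = f[indices]
        anc = anc[indices]
    cols = panel.pop_index(populations) if populations is not None else slice(None)
    mean_ref = f[:, cols].mean(axis=1)
    return np.where(anc, 1.0 - mean_ref, mean_ref)


def derived_afs(
    panel: SnpPanel,
    indices: np.ndarray | None = None,
    populations: Sequence[str] | None = None,
    bins: int = 50,
    group: str = "all",
    step: str = "truth",
) -> AfsSummary:
    """Unfolded (derived) allele-frequency spectrum as bin proportions.

    Loci at exactly 0 or 1 fall in the terminal bins.
    """
    d = derived_frequencies(panel, indices, populations)
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    if counts.sum() == 0:
        raise StatisticError("empty SNP set for AFS")
    return AfsSummary(edges=edges, density=counts / counts.sum(), group=group, step=step)


def ohe_table(
    panel: SnpPanel,
    design,
    groups,
    replicate: int = 0,
    h_ref: pd.Series | None = None,
) -> pd.DataFrame:
    """Long-format OHE records: one row per population per design step.

    The reference heterozygosity is computed over the full truth panel unless
    ``h_ref`` (per-population Series) is supplied.
    """
    if h_ref is None:
        h_ref = hexp_by_population(panel)
    rows = []
    for snp_set in design.steps:
        h_set = hexp_by_population(panel, snp_set.indices)
        for pop in panel.populations:
            rows.append(
                {
                    "population": pop,
                    "group": groups.assignment[pop],
                    "replicate": replicate,
                    "step": snp_set.step,
                    "h_set": float(h_set[pop]),
                    "h_ref": float(h_ref[pop]),
                    "ohe": ohe(float(h_set[pop]), float(h_ref[pop])),
                }
            )
    return pd.DataFrame(rows)
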
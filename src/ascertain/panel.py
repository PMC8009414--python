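"""Core data containers: SNP panels, genetic maps and population groupings.

A :class:`SnpPanel` holds per-locus metadata together with a loci x populations
matrix of reference-allele frequencies.  It is the common currency of the
package: the synthetic generator produces one, the array-design pipeline
subsets it, and the population-genetic statistics consume it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOCI_COLUMNS = ["chrom", "bp", "cM", "quality", "depth", "exonic", "ref", "alt"]
GROUP_NAMES = ("discovery", "validation", "application", "outgroup")


class ConfigError(ValueError):
    """Invalid configuration or infeasible request."""


class FormatError(ValueError):
    """Malformed input file."""


class StatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. empty SNP set)."""


@dataclass
class GeneticMap:
    """Per-chromosome monotone (bp, cM) anchors with linear interpolation.

    ``anchors`` maps chromosome name to an ``(n, 2)`` float array whose columns
    are 1-based bp position and cM position.  bp must be strictly increasing
    and cM non-decreasing; queries outside the anchored range are clamped to
    the terminal anchor with a logged warning.
    """

    anchors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.anchors.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ConfigError(f"map for {chrom!r} needs >=2 (bp, cM) anchors")
            if not np.all(np.diff(arr[:, 0]) > 0):
                raise ConfigError(f"map bp not strictly increasing on {chrom!r}")
            if not np.all(np.diff(arr[:, 1]) >= 0):
                raise ConfigError(f"map cM decreasing on {chrom!r}")
            self.anchors[chrom] = arr

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def interpolate(self, chrom: str, bp) -> np.ndarray:
        """Piecewise-linear bp -> cM; exact at anchors, clamped outside."""
        if chrom not in self.anchors:
            raise ConfigError(f"chromosome {chrom!r} absent from genetic map")
        arr = self.anchors[chrom]
        bp = np.asarray(bp, dtype=float)
        if bp.size and (bp.min() < arr[0, 0] or bp.max() > arr[-1, 0]):
            logger.warning(
                "map query outside anchor range on %s; clamping to terminal anchors", chrom
            )
        return np.interp(bp, arr[:, 0], arr[:, 1])

    def chrom_bounds_cM(self, chrom: str) -> tuple[float, float]:
        arr = self.anchors[chrom]
        return float(arr[0, 1]), float(arr[-1, 1])

    def chrom_bounds_bp(self, chrom: str) -> tuple[int, int]:
        arr = self.anchors[chrom]
        return int(arr[0, 0]), int(arr[-1, 0])

    def total_cM(self) -> float:
        return float(sum(a[-1, 1] - a[0, 1] for a in self.anchors.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, int(bp), cm)
            for chrom, arr in self.anchors.items()
            for bp, cm in arr
        ]
        return pd.DataFrame(rows, columns=["chrom", "bp", "cM"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        anchors = {
            str(chrom): sub[["bp", "cM"]].to_numpy(dtype=float)
            for chrom, sub in df.groupby("chrom", sort=False)
        }
        return cls(anchors)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, path: str | Path) -> "GeneticMap":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))


@dataclass
class SnpPanel:
    """Multi-population SNP panel: loci metadata plus a frequency matrix.

    Parameters
    ----------
    loci
        DataFrame with columns ``chrom, bp, cM, quality, depth, exonic, ref,
        alt``; bp strictly increasing within chromosome, cM non-decreasing.
    freq
        ``(n_loci, n_populations)`` array of reference-allele frequencies in
        [0, 1] (estimated from genotypes or from allelic-depth ratios).
    pop_meta
        Per-population metadata indexed by population name with columns
        ``mode`` (``individual``/``pool``), ``sample_size``, ``mean_depth``,
        ``cluster``, ``commercial``, ``outgroup``.
    ancestral_is_ref
        Optional per-locus flag, absent until the panel has been polarized.
    true_freq
        Optional noiseless frequency matrix; only set by the synthetic
        generator, never serialized as part of the observed panel.
    """

    loci: pd.DataFrame
    freq: np.ndarray
    pop_meta: pd.DataFrame
    ancestral_is_ref: np.ndarray | None = None
    true_freq: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.validate()

    # -- basic introspection -------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        return list(self.pop_meta.index)

    def pop_index(self, names: str | Iterable[str]):
        cols = list(self.pop_meta.index)
        if isinstance(names, str):
            return cols.index(names)
        return np.array([cols.index(n) for n in names], dtype=int)

    @property
    def outgroup_population(self) -> str | None:
        og = self.pop_meta.index[self.pop_meta["outgroup"].astype(bool)]
        return str(og[0]) if len(og) else None

    def validate(self) -> None:
        missing = [c for c in LOCI_COLUMNS if c not in self.loci.columns]
        if missing:
            raise ConfigError(f"loci table missing columns {missing}")
        if self.freq.shape != (len(self.loci), len(self.pop_meta)):
            raise ConfigError(
                f"freq shape {self.freq.shape} != (n_loci={len(self.loci)}, "
                f"n_pops={len(self.pop_meta)})"
            )
        finite = self.freq[np.isfinite(self.freq)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ConfigError("frequencies outside [0, 1]")
        if self.pop_meta.index.duplicated().any():
            raise ConfigError("duplicate population names")
        if int(self.pop_meta["outgroup"].astype(bool).sum()) > 1:
            raise ConfigError("more than one population flagged outgroup")
        for chrom, sub in self.loci.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["bp"].to_numpy()) > 0):
                raise ConfigError(f"bp not strictly increasing on {chrom!r}")
            cm = sub["cM"].to_numpy(dtype=float)
            if not np.isnan(cm).any() and not np.all(np.diff(cm) >= -1e-12):
                raise ConfigError(f"cM decreasing with bp on {chrom!r}")
        if self.ancestral_is_ref is not None and len(self.ancestral_is_ref) != len(self.loci):
            raise ConfigError("ancestral flag length mismatch")

    # -- serialization -------------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        """Write loci.tsv, freq.tsv and populations.tsv into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        loci = self.loci.copy()
        if self.ancestral_is_ref is not None:
            loci["ancestral_is_ref"] = self.ancestral_is_ref.astype(int)
        loci.to_csv(outdir / "loci.tsv", sep="\t", index=False, float_format="%.17g")
        freq = pd.DataFrame(self.freq, columns=self.populations)
        freq.to_csv(outdir / "freq.tsv", sep="\t", index=False, float_format="%.17g")
        self.pop_meta.to_csv(outdir / "populations.tsv", sep="\t", index_label="population")

    @classmethod
    def read(cls, indir: str | Path) -> "SnpPanel":
        indir = Path(indir)
        loci = pd.read_csv(indir / "loci.tsv", sep="\t", comment="#")
        freq = pd.read_csv(indir / "freq.tsv", sep="\t", comment="#")
        pop_meta = pd.read_csv(indir / "populations.tsv", sep="\t", index_col="population")
        anc = None
        if "ancestral_is_ref" in loci.columns:
            anc = loci.pop("ancestral_is_ref").to_numpy(dtype=bool)
        loci["chrom"] = loci["chrom"].astype(str)
        return cls(loci=loci, freq=freq.to_numpy(dtype=float), pop_meta=pop_meta,
                   ancestral_is_ref=anc)

    # -- convenience ---------------------------------------------------------
    def drop_missing(self) -> "SnpPanel":
        """Drop loci with any missing population frequency (logged)."""
        keep = np.isfinite(self.freq).all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d loci with missing frequencies", dropped)
        return SnpPanel(
            loci=self.loci.loc[keep].reset_index(drop=True),
            freq=self.freq[keep],
            pop_meta=self.pop_meta,
            ancestral_is_ref=None if self.ancestral_is_ref is None else self.ancestral_is_ref[keep],
            true_freq=None if self.true_freq is None else self.true_freq[keep],
        )


@dataclass
class PopulationGroups:
    """Assignment of panel populations to the four design roles.

    ``assignment`` maps every population name to one of ``discovery``,
    ``validation``, ``application`` or ``outgroup``.  Discovery populations
    additionally carry a sub-cluster label (used for the sub-cluster
    backbones and for the per-sub-cluster density multipliers of the
    downsampling step; default multiplier 1).
    """

    assignment: dict[str, str]
    subclusters: dict[str, str] = field(default_factory=dict)
    density_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g for g in self.assignment.values()} - set(GROUP_NAMES)
        if bad:
            raise ConfigError(f"unknown group labels {bad}")
        n_out = sum(1 for g in self.assignment.values() if g == "outgroup")
        if n_out != 1:
            raise ConfigError(f"exactly one outgroup required, got {n_out}")
        missing = set(self.assignment) & {"discovery"}
        for pop, g in self.assignment.items():
            if g == "discovery" and pop not in self.subclusters:
                self.subclusters[pop] = "discovery"

    def members(self, group: str, order: Iterable[str] | None = None) -> list[str]:
        pops = [p for p, g in self.assignment.items() if g == group]
        if order is not None:
            rank = {p: i for i, p in enumerate(order)}
            pops.sort(key=lambda p: rank.get(p, len(rank)))
        return pops

    @property
    def discovery(self) -> list[str]:
        return self.members("discovery")

    @property
    def validation(self) -> list[str]:
        return self.members("validation")

    @property
    def application(self) -> list[str]:
        return self.members("application")

    @property
    def outgroup(self) -> str:
        return self.members("outgroup")[0]

    def multiplier(self, pop: str) -> float:
        return float(self.density_multipliers.get(self.subclusters.get(pop, ""), 1.0))

    def check_panel(self, panel: SnpPanel) -> None:
        pops = set(panel.populations)
        if set(self.assignment) != pops:
            raise ConfigError("group assignment does not cover the panel populations exactly")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop, g in self.assignment.items():
            sub = self.subclusters.get(pop, "")
            rows.append((pop, g, sub, self.density_multipliers.get(sub, 1.0)))
        return pd.DataFrame(rows, columns=["population", "group", "subcluster", "multiplier"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PopulationGroups":
        df = pd.read_csv(path, sep="\t", comment="#").fillna({"subcluster": ""})
        assignment = dict(zip(df["population"], df["group"]))
        sub = {p: s for p, s in zip(df["population"], df["subcluster"]) if s}
        mult = {
            s: float(m)
            for s, m in zip(df["subcluster"], df["multiplier"])
            if s and np.isfinite(m)
        }
        return cls(assignment=assignment, subclusters=sub, density_multipliers=mult)
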
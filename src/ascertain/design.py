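"""The five-step SNP-array ascertainment pipeline.

Starting from a truth panel the pipeline mimics how commercial genotyping
arrays are designed:

1. **discovery** — keep loci passing quality, coverage and discovery-panel
   MAF filters (MAF computed on the unweighted mean of the discovery
   populations' frequencies).
2. **cluster_removal** — drop loci with too few invariant flanking bases on
   both sides among the discovered SNPs (probe-binding constraint).
3. **equal_spacing** — build a backbone of loci segregating in all discovery
   populations (plus one backbone per discovery sub-cluster) at a minimum
   physical spacing, then iterate over discovery populations filling gaps
   with the loci closest to equidistant cM positions at a target density of
   segregating SNPs per cM.
4. **validation** — keep loci segregating in enough validation populations.
5. **downsampling** — like step 3 but keeping all exonic loci, without the
   sub-cluster backbones, and with per-sub-cluster density multipliers
   (historically 3x in broiler-like lines).

Every step is deterministic given its inputs; each step's SNP set is a
subset of its predecessor's.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import ConfigError, GeneticMap, PopulationGroups, SnpPanel

logger = logging.getLogger(__name__)

STEP_ORDER = ("discovery", "cluster_removal", "equal_spacing", "validation", "downsampling")


@dataclass(frozen=True)
class DesignConfig:
    """Thresholds and knobs of the ascertainment pipeline (field defaults
    follow the historical chicken-array design)."""

    quality_min: float = 60.0
    maf_min: float = 0.05
    coverage_sd_mult: float = 3.0
    cluster_near_bp: int = 4
    cluster_far_bp: int = 10
    backbone_min_dist_bp: int = 2000
    target_density: float = 667.0  # segregating SNPs per cM
    validation_min_pops: int = 8  # out of a 19-population validation group
    use_backbone: bool = True
    subgroup_density_multipliers: Mapping[str, float] | None = None
    segregation_eps: float = 0.0  # segregating = freq in (eps, 1 - eps)

    def validate(self) -> None:
        if min(self.quality_min, self.maf_min, self.coverage_sd_mult) < 0:
            raise ConfigError("thresholds must be non-negative")
        if self.cluster_near_bp > self.cluster_far_bp:
            raise ConfigError("cluster near-flank must be <= far-flank")
        if self.backbone_min_dist_bp < 1 or self.validation_min_pops < 1:
            raise ConfigError("backbone distance and validation threshold must be positive")
        if self.target_density < 0:
            raise ConfigError("target density must be >= 0")
        if not 0 <= self.segregation_eps < 0.5:
            raise ConfigError("segregation_eps must lie in [0, 0.5)")


@dataclass
class SnpSet:
    """An ordered subset of panel loci produced by one design step."""

    indices: np.ndarray
    step: str
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and not np.all(np.diff(self.indices) > 0):
            raise ConfigError("SnpSet indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class ArrayDesign:
    """The chain of SNP sets from all executed design steps."""

    steps: list[SnpSet]
    config: DesignConfig
    groups: PopulationGroups
    seed: int | None = None

    def step(self, name: str) -> SnpSet:
        for s in self.steps:
            if s.step == name:
                return s
        raise KeyError(name)

    @property
    def final(self) -> SnpSet:
        return self.steps[-1]

    def counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": [s.step for s in self.steps], "n_snps": [len(s) for s in self.steps]}
        )

    def provenance_counts(self, step: str = "equal_spacing") -> pd.Series:
        prov = self.step(step).provenance
        return pd.Series(prov.values(), dtype="object").value_counts()

    def check_chain(self) -> None:
        for prev, cur in zip(self.steps, self.steps[1:]):
            if not np.isin(cur.indices, prev.indices).all():
                raise ConfigError(f"{cur.step} is not a subset of {prev.step}")


# -- helpers -----------------------------------------------------------------

def segregating(panel: SnpPanel, eps: float = 0.0) -> np.ndarray:
    """Boolean loci x populations matrix: frequency strictly inside (eps, 1-eps)."""
    return (panel.freq > eps) & (panel.freq < 1.0 - eps)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def discovery_population_order(panel: SnpPanel, groups: PopulationGroups) -> list[str]:
    """Fixed gap-filling order: sub-cluster (first appearance in panel order),
    then panel order within sub-cluster."""
    disc = [p for p in panel.populations if groups.assignment.get(p) == "discovery"]
    sub_rank: dict[str, int] = {}
    for p in disc:
        sub_rank.setdefault(groups.subclusters.get(p, ""), len(sub_rank))
    return sorted(disc, key=lambda p: (sub_rank[groups.subclusters.get(p, "")], disc.index(p)))


def _chrom_index(panel: SnpPanel) -> dict[str, np.ndarray]:
    return {
        str(chrom): sub.index.to_numpy()
        for chrom, sub in panel.loci.groupby("chrom", sort=False)
    }


# -- step 1: discovery filter -------------------------------------------------

def discovery_filter(panel: SnpPanel, groups: PopulationGroups, cfg: DesignConfig) -> SnpSet:
    """Quality, coverage and discovery-panel MAF filters.

    Coverage mean/sd are computed over all panel loci; the discovery-panel
    frequency is the unweighted mean over discovery populations and its MAF
    is ``min(f, 1 - f)``.
    """
    cfg.validate()
    disc = groups.members("discovery", order=panel.populations)
    if not disc:
        raise ConfigError("empty discovery group")
    depth = panel.loci["depth"].to_numpy(dtype=float)
    depth_cap = depth.mean() + cfg.coverage_sd_mult * depth.std(ddof=0)
    f = panel.freq[:, panel.pop_index(disc)].mean(axis=1)
    maf = np.minimum(f, 1.0 - f)
    keep = (
        (panel.loci["quality"].to_numpy(dtype=float) >= cfg.quality_min)
        & (depth <= depth_cap)
        & (maf >= cfg.maf_min)
    )
    return SnpSet(np.flatnonzero(keep), "discovery")


# -- step 2: cluster removal ---------------------------------------------------

def remove_clusters(panel: SnpPanel, candidate: SnpSet, cfg: DesignConfig) -> SnpSet:
    """Drop loci with too-short invariant flanks among the discovered SNPs.

    For each candidate locus the left/right flank is the number of invariant
    bases to the nearest discovery-variable SNP on that side (neighbor
    distance in bp minus one); chromosome ends count as infinite flanks.  A
    locus is removed iff one flank is shorter than ``cluster_near_bp`` and
    the other shorter than ``cluster_far_bp``.
    """
    if len(candidate) == 0:
        raise ConfigError("cluster removal on an empty candidate set")
    idx = candidate.indices
    chroms = panel.loci["chrom"].to_numpy()[idx]
    bp = panel.loci["bp"].to_numpy()[idx]
    left = np.full(len(idx), np.inf)
    right = np.full(len(idx), np.inf)
    # candidates are in panel order, hence sorted by bp within chromosome
    same_prev = np.zeros(len(idx), dtype=bool)
    same_prev[1:] = chroms[1:] == chroms[:-1]
    gaps = np.zeros(len(idx))
    gaps[1:] = bp[1:] - bp[:-1] - 1
    left[same_prev] = gaps[same_prev]
    same_next = np.zeros(len(idx), dtype=bool)
    same_next[:-1] = same_prev[1:]
    right[same_next] = gaps[1:][same_prev[1:]]
    near, far = cfg.cluster_near_bp, cfg.cluster_far_bp
    clustered = ((left < near) & (right < far)) | ((left < far) & (right < near))
    return SnpSet(idx[~clustered], "cluster_removal")


# -- step 3 parts: backbone and equal spacing ---------------------------------

def build_backbone(
    panel: SnpPanel,
    candidate_indices: np.ndarray,
    populations: Sequence[str],
    min_dist_bp: int,
    seg: np.ndarray | None = None,
    eps: float = 0.0,
) -> np.ndarray:
    """Loci segregating in *every* listed population, greedily thinned to a
    minimum bp spacing per chromosome (left-to-right scan)."""
    if not populations:
        raise ConfigError("backbone requires a non-empty population list")
    if seg is None:
        seg = segregating(panel, eps)
    cols = panel.pop_index(populations)
    idx = np.asarray(candidate_indices, dtype=int)
    eligible = idx[seg[np.ix_(idx, cols)].all(axis=1)]
    if eligible.size == 0:
        return eligible
    chroms = panel.loci["chrom"].to_numpy()[eligible]
    bp = panel.loci["bp"].to_numpy()[eligible]
    kept = []
    last_chrom, last_bp = None, -np.inf
    for i in range(eligible.size):
        if chroms[i] != last_chrom or bp[i] - last_bp >= min_dist_bp:
            kept.append(eligible[i])
            last_chrom, last_bp = chroms[i], bp[i]
    return np.asarray(kept, dtype=int)


def _pick_nearest(cand_cm, cand_bp, used, ideal) -> int:
    """Index into the candidate arrays of the unused locus with minimal
    |cM - ideal|, ties broken toward smaller bp.  -1 when all used."""
    j = int(np.searchsorted(cand_cm, ideal))
    best, bestd = -1, np.inf
    i = j - 1
    while i >= 0:
        d = ideal - cand_cm[i]
        if best >= 0 and d > bestd:
            break
        if not used[i] and (d < bestd or (d == bestd and cand_bp[i] < cand_bp[best])):
            best, bestd = i, d
        i -= 1
    i = j
    while i < len(cand_cm):
        d = cand_cm[i] - ideal
        if best >= 0 and d > bestd:
            break
        if not used[i] and (d < bestd or (d == bestd and (best < 0 or cand_bp[i] < cand_bp[best]))):
            best, bestd = i, d
        i += 1
    return best


def _fill_gaps(
    panel: SnpPanel,
    gmap: GeneticMap,
    candidate_mask: np.ndarray,
    seed_mask: np.ndarray,
    selected: np.ndarray,
    pop_order: Sequence[str],
    densities: Mapping[str, float],
    seg: np.ndarray,
    provenance: dict[int, str],
) -> None:
    """In-place gap filling (part two of the spacing algorithm).

    For each population in order, the gaps are the intervals between
    consecutive part-one seed loci (backbone/exonic keeps) that segregate in
    that population, with chromosome ends at the terminal map anchors as
    boundaries; the gap structure is fixed throughout part two.  Each gap of
    ``g`` cM has a target of ``round(density * g)`` SNPs segregating in the
    population, less the already-selected in-gap loci segregating in it
    (earlier populations' picks count toward the local density, which is why
    the first population contributes the most).  For each ideal equidistant
    cM position, in left-to-right order, the nearest unselected in-gap
    candidate segregating in the population is selected (ties toward
    smaller bp).
    """
    bp_all = panel.loci["bp"].to_numpy()
    cm_all = panel.loci["cM"].to_numpy(dtype=float)
    by_chrom = _chrom_index(panel)
    for pop in pop_order:
        dens = float(densities.get(pop, 0.0))
        if dens <= 0:
            continue
        segp = seg[:, panel.pop_index(pop)]
        for chrom, loci_idx in by_chrom.items():
            if chrom not in gmap.anchors:
                raise ConfigError(f"genetic map lacks chromosome {chrom!r}")
            bp = bp_all[loci_idx]
            cm = cm_all[loci_idx]
            cm_start, cm_end = gmap.chrom_bounds_cM(chrom)
            bp_start, bp_end = gmap.chrom_bounds_bp(chrom)
            anchor = seed_mask[loci_idx] & segp[loci_idx]
            b_cm = np.concatenate([[cm_start], cm[anchor], [cm_end]])
            b_bp = np.concatenate([[bp_start - 1], bp[anchor], [bp_end + 1]])
            for g in range(len(b_cm) - 1):
                span = b_cm[g + 1] - b_cm[g]
                n_target = _round_half_up(dens * span)
                if n_target <= 0:
                    continue
                lo = int(np.searchsorted(bp, b_bp[g], side="right"))
                hi = int(np.searchsorted(bp, b_bp[g + 1], side="left"))
                if hi <= lo:
                    continue
                sub = loci_idx[lo:hi]
                n_target -= int((selected[sub] & segp[sub]).sum())
                if n_target <= 0:
                    continue
                ok = candidate_mask[sub] & ~selected[sub] & segp[sub]
                cand = sub[ok]
                if cand.size == 0:
                    continue
                cand_cm = cm_all[cand]
                cand_bp = bp_all[cand]
                used = np.zeros(cand.size, dtype=bool)
                for k in range(1, n_target + 1):
                    ideal = b_cm[g] + span * k / (n_target + 1)
                    pick = _pick_nearest(cand_cm, cand_bp, used, ideal)
                    if pick < 0:
                        break
                    used[pick] = True
                    gi = int(cand[pick])
                    selected[gi] = True
                    provenance[gi] = f"gap-fill:{pop}"


def _spacing_core(
    panel: SnpPanel,
    candidate: SnpSet,
    groups: PopulationGroups,
    gmap: GeneticMap,
    cfg: DesignConfig,
    *,
    step_label: str,
    subcluster_backbones: bool,
    multipliers: Mapping[str, float] | None,
    keep_exonic: bool,
) -> SnpSet:
    cfg.validate()
    groups.check_panel(panel)
    seg = segregating(panel, cfg.segregation_eps)
    cand_mask = np.zeros(panel.n_loci, dtype=bool)
    cand_mask[candidate.indices] = True
    selected = np.zeros(panel.n_loci, dtype=bool)
    provenance: dict[int, str] = {}
    pop_order = discovery_population_order(panel, groups)
    if not pop_order:
        raise ConfigError("empty discovery group")

    if keep_exonic:
        exonic = candidate.indices[
            panel.loci["exonic"].to_numpy(dtype=bool)[candidate.indices]
        ]
        selected[exonic] = True
        for i in exonic:
            provenance[int(i)] = "exonic-keep"

    use_backbone = cfg.use_backbone or keep_exonic  # downsampling always seeds the all-pop backbone
    if use_backbone:
        bb = build_backbone(
            panel, candidate.indices, pop_order, cfg.backbone_min_dist_bp,
            seg=seg, eps=cfg.segregation_eps,
        )
        new = bb[~selected[bb]]
        selected[bb] = True
        for i in new:
            provenance[int(i)] = "backbone-all"
        if subcluster_backbones:
            sub_order: dict[str, list[str]] = {}
            for p in pop_order:
                sub_order.setdefault(groups.subclusters.get(p, ""), []).append(p)
            for label, members in sub_order.items():
                if len(members) < 2:
                    continue  # a singleton sub-cluster backbone is degenerate
                bb = build_backbone(
                    panel, candidate.indices, members, cfg.backbone_min_dist_bp,
                    seg=seg, eps=cfg.segregation_eps,
                )
                new = bb[~selected[bb]]
                selected[new] = True
                for i in new:
                    provenance[int(i)] = f"backbone-subgroup:{label}"

    if multipliers is None:
        densities = {p: cfg.target_density for p in pop_order}
    else:
        densities = {
            p: cfg.target_density * float(multipliers.get(groups.subclusters.get(p, ""), 1.0))
            for p in pop_order
        }
    seed_mask = selected.copy()
    _fill_gaps(panel, gmap, cand_mask, seed_mask, selected, pop_order, densities, seg, provenance)
    return SnpSet(np.flatnonzero(selected), step_label, provenance)


def equal_spacing(
    panel: SnpPanel,
    candidate: SnpSet,
    groups: PopulationGroups,
    gmap: GeneticMap,
    cfg: DesignConfig,
) -> SnpSet:
    """Step 3: backbone(s) plus per-population equidistant gap filling."""
    return _spacing_core(
        panel, candidate, groups, gmap, cfg,
        step_label="equal_spacing",
        subcluster_backbones=cfg.use_backbone,
        multipliers=None,
        keep_exonic=False,
    )


# -- step 4: validation --------------------------------------------------------

def validate_snps(
    panel: SnpPanel, candidate: SnpSet, groups: PopulationGroups, cfg: DesignConfig
) -> SnpSet:
    """Keep loci segregating in enough validation populations.

    The historical rule is 8 of 19; for smaller validation groups the
    threshold scales proportionally (ceil, minimum 1).
    """
    val = groups.members("validation", order=panel.populations)
    if not val:
        raise ConfigError("empty validation group")
    thresh = cfg.validation_min_pops
    if len(val) < 19:
        thresh = max(1, math.ceil(cfg.validation_min_pops / 19 * len(val)))
    seg = segregating(panel, cfg.segregation_eps)
    counts = seg[np.ix_(candidate.indices, panel.pop_index(val))].sum(axis=1)
    return SnpSet(candidate.indices[counts >= thresh], "validation")


# -- step 5: downsampling --------------------------------------------------------

def downsample(
    panel: SnpPanel,
    candidate: SnpSet,
    groups: PopulationGroups,
    gmap: GeneticMap,
    cfg: DesignConfig,
) -> SnpSet:
    """Step 5: keep exonic loci and the all-population backbone, then fill
    gaps with per-sub-cluster density multipliers (default 3x broiler-like)."""
    mult = cfg.subgroup_density_multipliers
    if mult is None:
        mult = groups.density_multipliers
    return _spacing_core(
        panel, candidate, groups, gmap, cfg,
        step_label="downsampling",
        subcluster_backbones=False,
        multipliers=mult,
        keep_exonic=True,
    )


# -- full pipeline ----------------------------------------------------------------

def design_array(
    panel: SnpPanel,
    groups: PopulationGroups,
    gmap: GeneticMap,
    cfg: DesignConfig | None = None,
    through: str | None = None,
    seed: int | None = None,
) -> ArrayDesign:
    """Run the ascertainment steps in order, keeping every intermediate set.

    ``through`` optionally stops after the named step (e.g. density sweeps
    only need ``equal_spacing``).
    """
    if cfg is None:
        cfg = DesignConfig()
    cfg.validate()
    groups.check_panel(panel)
    last = through or STEP_ORDER[-1]
    if last not in STEP_ORDER:
        raise ConfigError(f"unknown step {last!r}")
    steps: list[SnpSet] = []
    s = discovery_filter(panel, groups, cfg)
    steps.append(s)
    if last != "discovery":
        s = remove_clusters(panel, s, cfg)
        steps.append(s)
    if last not in ("discovery", "cluster_removal"):
        s = equal_spacing(panel, s, groups, gmap, cfg)
        steps.append(s)
    if last in ("validation", "downsampling"):
        s = validate_snps(panel, s, groups, cfg)
        steps.append(s)
    if last == "downsampling":
        s = downsample(panel, s, groups, gmap, cfg)
        steps.append(s)
    design = ArrayDesign(steps=steps, config=cfg, groups=groups, seed=seed)
    design.check_chain()
    logger.info("design counts: %s", {st.step: len(st) for st in steps})
    return design
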
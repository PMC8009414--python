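"""Synthetic multi-population SNP panels.

The generative model, from the top down:

* Per locus, an ancestral *derived*-allele frequency ``x`` is drawn from the
  neutral-equilibrium site-frequency spectrum, density proportional to
  ``1/x`` truncated to ``[t, 1 - t]`` — rich in rare alleles.
* Cluster frequencies drift around ``x`` under the Balding-Nichols model,
  ``Beta(x (1-F)/F, (1-x)(1-F)/F)`` with cluster-level ``F``; population
  frequencies drift likewise around their cluster frequency with
  population-level ``F``, giving a two-level relatedness hierarchy (tight
  broiler-like clusters vs. loose local clusters).
* The outgroup drifts directly around ``x`` with a large divergence ``F``
  (most loci effectively fixed, as expected after lineage sorting in a
  diverged species), and additionally owns a fraction of private loci that
  are variable only in the outgroup.
* Observation layer: individually sequenced populations report allele counts
  out of ``2 * sample_size`` genotypes; pooled populations report the ratio
  of reference allelic depth to total depth at a Poisson read depth.

Locus quality and depth covariates are simulated independently of frequency.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .config import SimConfig
from .panel import ConfigError, GeneticMap, PopulationGroups, SnpPanel

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# Dedicated RNG substreams so that e.g. the map is reproducible on its own.
_MAP_STREAM, _PANEL_STREAM, _GROUP_STREAM = 1, 2, 3


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream])


def simulate_map(config: SimConfig, rng: np.random.Generator | None = None) -> GeneticMap:
    """Simulate a monotone piecewise-linear bp -> cM map per chromosome.

    Anchors run from (1 bp, 0 cM) to the chromosome end; inter-anchor cM
    increments are the configured rate with multiplicative jitter, floored at
    zero (occasional flat segments, as in real linkage maps).
    """
    config.validate()
    if rng is None:
        rng = _rng(config.seed, _MAP_STREAM)
    anchors: dict[str, np.ndarray] = {}
    n = config.map_anchors_per_chromosome
    for chrom in config.chromosomes:
        bp = np.unique(np.round(np.linspace(1, config.chromosome_length_bp, n)).astype(int))
        seg_mb = np.diff(bp) / 1e6
        jitter = np.maximum(0.0, 1.0 + config.map_jitter * rng.standard_normal(len(seg_mb)))
        inc = config.map_rate_cM_per_Mb * seg_mb * jitter
        cm = np.concatenate([[0.0], np.cumsum(inc)])
        anchors[chrom] = np.column_stack([bp.astype(float), cm])
    return GeneticMap(anchors)


def _balding_nichols(rng, mean: np.ndarray, F: float) -> np.ndarray:
    """Draw drifted frequencies around ``mean`` with Wright's F.

    Frequencies already fixed (0 or 1) stay fixed; Beta draws may underflow
    to exact 0/1 for extreme parameters, which is the intended fixation.
    """
    out = np.array(mean, dtype=float, copy=True)
    interior = (mean > 0) & (mean < 1)
    if F <= 0 or not interior.any():
        return out
    scale = (1.0 - F) / F
    m = mean[interior]
    out[interior] = rng.beta(np.maximum(m * scale, 1e-12),
                             np.maximum((1.0 - m) * scale, 1e-12))
    return out


def _draw_sfs(rng, n: int, truncation: float) -> np.ndarray:
    """Ancestral derived frequencies with density prop. to 1/x on [t, 1-t]."""
    t = truncation
    u = rng.random(n)
    return t * ((1.0 - t) / t) ** u


def _exonic_intervals(rng, length: int, fraction: float, mean_len: float = 5_000.0):
    """Random intervals (merged, half-open bp) covering ~``fraction`` of a chromosome."""
    target = fraction * length
    starts, ends = [], []
    covered = 0.0
    while covered < target:
        ln = max(50, int(rng.exponential(mean_len)))
        s = int(rng.integers(0, max(1, length - ln)))
        starts.append(s)
        ends.append(s + ln)
        covered += ln
    order = np.argsort(starts)
    merged = []
    for i in order:
        if merged and starts[i] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], ends[i])
        else:
            merged.append([starts[i], ends[i]])
    return np.array(merged, dtype=int).reshape(-1, 2)


def simulate_panel(config: SimConfig) -> SnpPanel:
    """Generate a seeded synthetic :class:`SnpPanel` under ``config``.

    Deterministic given the config (including its seed): repeated calls
    return bit-identical panels.  The returned panel carries the noiseless
    frequencies in ``true_freq`` and the simulated polarization truth in
    ``loci["ancestral_is_ref_true"]`` for diagnostics; the observed panel
    itself is unpolarized (``ancestral_is_ref`` is None).
    """
    config.validate()
    rng = _rng(config.seed, _PANEL_STREAM)
    gmap = simulate_map(config)

    n = config.n_loci
    chroms = config.chromosomes
    per_chrom = np.full(len(chroms), n // len(chroms))
    per_chrom[: n % len(chroms)] += 1

    chrom_col, bp_col, cm_col, exon_col = [], [], [], []
    for chrom, k in zip(chroms, per_chrom):
        pos = np.sort(rng.choice(config.chromosome_length_bp, size=k, replace=False)) + 1
        chrom_col.append(np.full(k, chrom))
        bp_col.append(pos)
        cm_col.append(gmap.interpolate(chrom, pos))
        iv = _exonic_intervals(rng, config.chromosome_length_bp, config.exonic_fraction)
        j = np.searchsorted(iv[:, 0], pos - 1, side="right") - 1
        exon = (j >= 0) & ((pos - 1) < iv[np.maximum(j, 0), 1])
        exon_col.append(exon)
    chrom_all = np.concatenate(chrom_col)
    bp_all = np.concatenate(bp_col)
    cm_all = np.concatenate(cm_col)
    exon_all = np.concatenate(exon_col)

    # ancestral derived frequency and polarization of the reference allele
    x = _draw_sfs(rng, n, config.sfs_truncation)
    ancestral_is_ref = rng.random(n) < config.ancestral_ref_prob

    out_pop = next((p for p in config.populations if p.outgroup), None)
    private = np.zeros(n, dtype=bool)
    if out_pop is not None and config.outgroup_private_fraction > 0:
        private = rng.random(n) < config.outgroup_private_fraction

    # cluster-level drift (derived-allele scale)
    cluster_freq: dict[str, np.ndarray] = {}
    for p in config.populations:
        if p.outgroup or p.cluster in cluster_freq:
            continue
        fc = float(config.cluster_drift.get(p.cluster, 0.05))
        q = _balding_nichols(rng, x, fc)
        q[private] = 0.0  # private loci: derived allele absent outside the outgroup
        cluster_freq[p.cluster] = q

    # population-level drift + observation
    true_ref = np.empty((n, len(config.populations)))
    obs_ref = np.empty_like(true_ref)
    for j, p in enumerate(config.populations):
        if p.outgroup:
            q = _balding_nichols(rng, x, config.outgroup_divergence)
            if private.any():
                q[private] = _balding_nichols(
                    rng, x[private], config.outgroup_private_drift
                )
        else:
            q = _balding_nichols(rng, cluster_freq[p.cluster], p.drift)
            q[private] = 0.0
        p_ref = np.where(ancestral_is_ref, 1.0 - q, q)
        true_ref[:, j] = p_ref
        if p.mode == "individual":
            m = 2 * p.sample_size
            obs_ref[:, j] = rng.binomial(m, p_ref) / m
        else:
            depth = np.maximum(1, rng.poisson(p.mean_depth, size=n))
            obs_ref[:, j] = rng.binomial(depth, p_ref) / depth

    quality = np.maximum(0.0, rng.normal(config.quality_mean, config.quality_sd, n))
    lam = sum(p.mean_depth for p in config.populations)
    depth_cov = rng.poisson(lam * rng.gamma(20.0, 1.0 / 20.0, size=n))

    ref = _BASES[rng.integers(0, 4, n)]
    alt = _BASES[(np.char.find("".join(_BASES), ref) + rng.integers(1, 4, n)) % 4]

    loci = pd.DataFrame(
        {
            "chrom": chrom_all,
            "bp": bp_all.astype(np.int64),
            "cM": cm_all,
            "quality": quality,
            "depth": depth_cov.astype(np.int64),
            "exonic": exon_all,
            "ref": ref,
            "alt": alt,
            "ancestral_is_ref_true": ancestral_is_ref,
        }
    )
    pop_meta = pd.DataFrame(
        {
            "mode": [p.mode for p in config.populations],
            "sample_size": [p.sample_size for p in config.populations],
            "mean_depth": [p.mean_depth for p in config.populations],
            "cluster": [p.cluster for p in config.populations],
            "commercial": [p.commercial for p in config.populations],
            "outgroup": [p.outgroup for p in config.populations],
        },
        index=pd.Index([p.name for p in config.populations], name="population"),
    )
    return SnpPanel(loci=loci, freq=obs_ref, pop_meta=pop_meta, true_freq=true_ref)


def assign_groups(
    panel: SnpPanel,
    n_discovery: int,
    n_validation: int,
    rng: np.random.Generator | int | None = None,
    mode: str = "random",
    density_multipliers: Mapping[str, float] | None = None,
) -> PopulationGroups:
    """Assign panel populations to discovery/validation/application/outgroup.

    The population flagged outgroup in ``pop_meta`` is always the outgroup.
    ``random`` mode draws the discovery and validation sets uniformly without
    replacement.  ``nearest-to-commercial`` mode seeds the discovery set with
    the populations flagged commercial and adds, for each seed in panel
    order, its nearest not-yet-selected population by Nei's standard genetic
    distance (``n_discovery`` is then implied as twice the seed count).

    Discovery sub-cluster labels are taken from each population's simulated
    (or user-annotated) cluster; the default per-sub-cluster density
    multiplier is 3 for the broiler-like cluster and 1 otherwise, applied
    only in the downsampling step.
    """
    from .stats import nei_distance  # local import to avoid a cycle

    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = _rng(0 if rng is None else int(rng), _GROUP_STREAM)
    out_pop = panel.outgroup_population
    if out_pop is None:
        raise ConfigError("panel has no population flagged outgroup")
    ingroup = [p for p in panel.populations if p != out_pop]

    if mode == "random":
        if n_discovery < 1 or n_validation < 1 or n_discovery + n_validation >= len(ingroup):
            raise ConfigError(
                f"infeasible group sizes ({n_discovery}, {n_validation}) "
                f"for {len(ingroup)} non-outgroup populations"
            )
        perm = list(rng.permutation(ingroup))
        discovery = perm[:n_discovery]
        validation = perm[n_discovery : n_discovery + n_validation]
    elif mode == "nearest-to-commercial":
        seeds = [p for p in ingroup if bool(panel.pop_meta.loc[p, "commercial"])]
        if not seeds:
            raise ConfigError("nearest mode requires populations flagged commercial")
        chosen = list(seeds)
        for seed_pop in seeds:
            i = panel.pop_index(seed_pop)
            dists = {
                q: nei_distance(panel.freq[:, i], panel.freq[:, panel.pop_index(q)])
                for q in ingroup
                if q not in chosen
            }
            chosen.append(min(dists, key=lambda q: (dists[q], q)))
        discovery = chosen
        rest = [p for p in ingroup if p not in discovery]
        if n_validation < 1 or n_validation >= len(rest):
            raise ConfigError("infeasible validation size in nearest mode")
        perm = list(rng.permutation(rest))
        validation = perm[:n_validation]
    else:
        raise ConfigError(f"unknown grouping mode {mode!r}")

    assignment = {out_pop: "outgroup"}
    for p in discovery:
        assignment[p] = "discovery"
    for p in validation:
        assignment[p] = "validation"
    for p in ingroup:
        assignment.setdefault(p, "application")

    subclusters = {p: str(panel.pop_meta.loc[p, "cluster"]) for p in discovery}
    if density_multipliers is None:
        density_multipliers = {"broiler": 3.0}
    return PopulationGroups(
        assignment=assignment,
        subclusters=subclusters,
        density_multipliers=dict(density_multipliers),
    )
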
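"""Simulation configuration: population specs, genome scale, observation model.

The default configuration emulates a diversity panel of commercial and local
chicken-like populations: a tight broiler-like cluster and a looser
layer-like cluster (each anchored by two individually genotyped commercial
lines), several loose clusters of pooled-sequenced local populations, two
wild populations used for ancestral-allele inference, and one strongly
diverged outgroup sequenced as a pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .panel import ConfigError

OBSERVATION_MODES = ("individual", "pool")


@dataclass(frozen=True)
class PopulationDef:
    """One simulated population.

    ``drift`` is the Balding-Nichols F of the population around its cluster
    frequency; ``mode`` selects the frequency-observation layer (genotype
    counting for individually sequenced populations, allelic-depth ratios for
    pools).
    """

    name: str
    cluster: str
    drift: float
    mode: str = "pool"
    sample_size: int = 10
    mean_depth: float = 30.0
    commercial: bool = False
    outgroup: bool = False

    def validate(self) -> None:
        if not 0 < self.drift < 1:
            raise ConfigError(f"{self.name}: drift F must lie in (0,1)")
        if self.mode not in OBSERVATION_MODES:
            raise ConfigError(f"{self.name}: unknown observation mode {self.mode!r}")
        if self.sample_size < 1 or self.mean_depth <= 0:
            raise ConfigError(f"{self.name}: non-positive sample size or depth")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic multi-population SNP panel."""

    populations: tuple[PopulationDef, ...]
    n_chromosomes: int = 3
    chromosome_length_bp: int = 600_000
    n_loci: int = 50_000
    outgroup_divergence: float = 0.98
    outgroup_private_fraction: float = 0.15
    outgroup_private_drift: float = 0.2
    sfs_truncation: float = 0.01
    exonic_fraction: float = 0.05
    map_rate_cM_per_Mb: float = 3.0
    map_jitter: float = 0.3
    map_anchors_per_chromosome: int = 21
    cluster_drift: Mapping[str, float] = field(default_factory=dict)
    quality_mean: float = 80.0
    quality_sd: float = 20.0
    ancestral_ref_prob: float = 0.86
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length_bp < 2:
            raise ConfigError("non-positive genome dimensions")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if not 0 < self.sfs_truncation < 0.5:
            raise ConfigError("sfs_truncation must lie in (0, 0.5)")
        if not 0 < self.outgroup_divergence < 1:
            raise ConfigError("outgroup_divergence must lie in (0,1)")
        if not 0 <= self.outgroup_private_fraction < 1:
            raise ConfigError("outgroup_private_fraction must lie in [0,1)")
        if not 0 < self.exonic_fraction < 1:
            raise ConfigError("exonic_fraction must lie in (0,1)")
        if self.map_rate_cM_per_Mb <= 0:
            raise ConfigError("map rate must be positive")
        if self.map_anchors_per_chromosome < 2:
            raise ConfigError("need >=2 map anchors per chromosome")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigError("population names must be unique")
        if sum(p.outgroup for p in self.populations) > 1:
            raise ConfigError("at most one population may be flagged outgroup")
        for p in self.populations:
            p.validate()
            if not 0 < self.cluster_drift.get(p.cluster, 0.05) < 1:
                raise ConfigError(f"cluster drift for {p.cluster!r} outside (0,1)")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


# Cluster templates: (cluster label, cluster-level F, population-level F).
# Population-level drift is calibrated so that pairwise Nei distances match
# the regime reported for commercial chicken lines (tight broiler group,
# max pairwise distance ~0.06; much looser layer group).
_CLUSTER_TEMPLATES = (
    ("broiler", 0.03, 0.25),
    ("layer", 0.10, 0.45),
    ("local_a", 0.10, 0.35),
    ("local_b", 0.15, 0.45),
)


def default_population_spec(n_populations: int = 24) -> tuple[PopulationDef, ...]:
    """Build a hierarchical population spec with ``n_populations`` members.

    Always includes two wild populations and one outgroup; the remaining
    populations are spread over a tight broiler-like cluster, a looser
    layer-like cluster and two loose clusters of local pooled populations.
    The first two broiler and layer populations are individually sequenced
    commercial lines (20 and 25 animals); all others are pools of 10 animals
    at 30x depth.
    """
    if n_populations < 8:
        raise ConfigError("need at least 8 populations (4 clusters + wild pair + outgroup)")
    remaining = n_populations - 3
    weights = [5, 5, 6, 5]
    counts = [max(2, int(round(remaining * w / sum(weights)))) for w in weights]
    while sum(counts) > remaining:
        counts[counts.index(max(counts))] -= 1
    while sum(counts) < remaining:
        counts[counts.index(min(counts))] += 1

    pops: list[PopulationDef] = []
    for (cluster, _fc, fpop), count in zip(_CLUSTER_TEMPLATES, counts):
        for i in range(count):
            commercial = cluster in ("broiler", "layer") and i < 2
            if commercial:
                pops.append(
                    PopulationDef(
                        name=f"{cluster}_{i + 1}",
                        cluster=cluster,
                        drift=fpop,
                        mode="individual",
                        sample_size=20 if cluster == "broiler" else 25,
                        mean_depth=8.0,
                        commercial=True,
                    )
                )
            else:
                pops.append(
                    PopulationDef(
                        name=f"{cluster}_{i + 1}",
                        cluster=cluster,
                        drift=fpop,
                        mode="pool",
                        sample_size=10,
                        mean_depth=30.0,
                    )
                )
    pops.append(PopulationDef("wild_gallus", "wild", 0.25, "pool", 10, 30.0))
    pops.append(PopulationDef("wild_spadiceus", "wild", 0.25, "pool", 10, 30.0))
    pops.append(
        PopulationDef("outgroup_varius", "outgroup", 0.5, "pool", 2, 30.0, outgroup=True)
    )
    return tuple(pops)


def default_cluster_drift() -> dict[str, float]:
    d = {label: fc for label, fc, _ in _CLUSTER_TEMPLATES}
    d["wild"] = 0.05
    d["outgroup"] = 0.05  # unused for the outgroup itself (divergence applies)
    return d


def default_config(
    n_populations: int = 24,
    n_loci: int = 50_000,
    n_chromosomes: int = 3,
    chromosome_length_bp: int = 600_000,
    seed: int = 0,
) -> SimConfig:
    """Default study conditions: hierarchical panel, rare-allele-rich SFS.

    The genome is scaled down so that the candidate SNP density per cM is in
    the regime where the default equal-spacing target density (667
    segregating SNPs/cM) is an active constraint, as it is on real
    whole-genome data.
    """
    cfg = SimConfig(
        populations=default_population_spec(n_populations),
        n_chromosomes=n_chromosomes,
        chromosome_length_bp=chromosome_length_bp,
        n_loci=n_loci,
        cluster_drift=default_cluster_drift(),
        seed=seed,
    )
    cfg.validate()
    return cfg


# -- YAML round trip ---------------------------------------------------------

def load_sim_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML file (see ``sim_config_to_dict``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    pops = tuple(PopulationDef(**p) for p in raw.pop("populations"))
    cfg = SimConfig(populations=pops, **raw)
    cfg.validate()
    return cfg


def sim_config_to_dict(cfg: SimConfig) -> dict:
    d = {
        k: getattr(cfg, k)
        for k in (
            "n_chromosomes", "chromosome_length_bp", "n_loci", "outgroup_divergence",
            "outgroup_private_fraction", "outgroup_private_drift",
            "sfs_truncation", "exonic_fraction",
            "map_rate_cM_per_Mb", "map_jitter", "map_anchors_per_chromosome",
            "quality_mean", "quality_sd", "ancestral_ref_prob", "seed",
        )
    }
    d["cluster_drift"] = dict(cfg.cluster_drift)
    d["populations"] = [vars(p).copy() for p in cfg.populations]
    return d


def save_sim_config(cfg: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(sim_config_to_dict(cfg), fh, sort_keys=False)
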
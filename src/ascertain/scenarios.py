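"""Replicated design experiments and the OHE group-contrast model.

Three experiment layouts are provided, mirroring how array-design bias is
usually probed: repeated random population groupings at fixed group sizes, a
sweep over the number of discovery populations, and a sweep over the
equal-spacing target density with or without the common-SNP backbone.

Replicate OHE values are compared between population groups with the linear
mixed model

    OHE_ijk = mu + popG_i + rep_j + e_ijk,

a fixed population-group effect plus a random intercept per random-grouping
replicate, fitted by REML.  Estimated marginal group means (LSMEANS) and all
pairwise group differences with Tukey-adjusted p-values are reported; a
singular fit (zero replicate variance) falls back to a fixed-effects model
and is flagged.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import (
    DesignConfig,
    design_array,
    discovery_filter,
    equal_spacing,
    remove_clusters,
)
from .panel import ConfigError, GROUP_NAMES, GeneticMap, PopulationGroups, SnpPanel
from .simulate import assign_groups
from .stats import hexp_by_population, ohe_table

logger = logging.getLogger(__name__)


@dataclass
class SweepResult:
    """Long-format OHE records plus per-replicate design counts."""

    ohe: pd.DataFrame
    counts: pd.DataFrame
    axis: str

    def write(self, path) -> None:
        self.ohe.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _rep_rng(master_seed: int, rep: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), 17, rep, extra])


def run_random_groupings(
    panel: SnpPanel,
    gmap: GeneticMap,
    cfg: DesignConfig | None = None,
    n_reps: int = 50,
    sizes: tuple[int, int, int] = (8, 19, 18),
    seed: int = 0,
    through: str | None = None,
) -> SweepResult:
    """Repeat the whole design with fresh random groupings (outgroup fixed)."""
    cfg = cfg or DesignConfig()
    n_ingroup = len(panel.populations) - 1
    if sum(sizes) != n_ingroup:
        raise ConfigError(f"group sizes {sizes} do not partition {n_ingroup} ingroup populations")
    h_ref = hexp_by_population(panel)
    ohe_rows, count_rows = [], []
    for rep in range(n_reps):
        groups = assign_groups(panel, sizes[0], sizes[1], rng=_rep_rng(seed, rep))
        design = design_array(panel, groups, gmap, cfg, through=through, seed=seed)
        tbl = ohe_table(panel, design, groups, replicate=rep, h_ref=h_ref)
        ohe_rows.append(tbl)
        for _, row in design.counts().iterrows():
            count_rows.append({"replicate": rep, "step": row["step"], "n_snps": row["n_snps"]})
    return SweepResult(
        ohe=pd.concat(ohe_rows, ignore_index=True),
        counts=pd.DataFrame(count_rows),
        axis="grouping",
    )


def sweep_discovery_count(
    panel: SnpPanel,
    gmap: GeneticMap,
    cfg: DesignConfig | None = None,
    counts: Iterable[int] = range(4, 41),
    reps: int = 20,
    seed: int = 0,
    through: str | None = None,
) -> SweepResult:
    """Vary the number of discovery populations; the remaining ingroup
    populations are split into validation and application groups of equal
    size (an odd remainder goes to validation)."""
    cfg = cfg or DesignConfig()
    n_ingroup = len(panel.populations) - 1
    counts = list(counts)
    if max(counts) >= n_ingroup:
        raise ConfigError("discovery count must leave room for validation and application")
    h_ref = hexp_by_population(panel)
    ohe_rows, count_rows = [], []
    for n_disc in counts:
        rest = n_ingroup - n_disc
        n_val = rest // 2 + rest % 2
        for rep in range(reps):
            groups = assign_groups(panel, n_disc, n_val, rng=_rep_rng(seed, rep, n_disc))
            design = design_array(panel, groups, gmap, cfg, through=through, seed=seed)
            tbl = ohe_table(panel, design, groups, replicate=rep, h_ref=h_ref)
            tbl["n_discovery"] = n_disc
            ohe_rows.append(tbl)
            for _, row in design.counts().iterrows():
                count_rows.append(
                    {"n_discovery": n_disc, "replicate": rep,
                     "step": row["step"], "n_snps": row["n_snps"]}
                )
    return SweepResult(
        ohe=pd.concat(ohe_rows, ignore_index=True),
        counts=pd.DataFrame(count_rows),
        axis="n_discovery",
    )


def sweep_density(
    panel: SnpPanel,
    gmap: GeneticMap,
    cfg: DesignConfig | None = None,
    densities: Iterable[float] = (33, 100, 333, 667, 1000, 3333),
    backbones: Sequence[bool] = (True, False),
    reps: int = 20,
    sizes: tuple[int, int, int] = (8, 19, 18),
    seed: int = 0,
) -> SweepResult:
    """Vary the equal-spacing target density, with/without the backbone.

    The pipeline is run through the equal-spacing step only; the
    grouping-dependent discovery and cluster-removal steps are computed once
    per replicate and reused across densities.
    """
    cfg = cfg or DesignConfig()
    n_ingroup = len(panel.populations) - 1
    if sum(sizes) != n_ingroup:
        raise ConfigError(f"group sizes {sizes} do not partition {n_ingroup} ingroup populations")
    if min(densities) < 0:
        raise ConfigError("densities must be positive")
    h_ref = hexp_by_population(panel)
    ohe_rows, count_rows = [], []
    for rep in range(reps):
        groups = assign_groups(panel, sizes[0], sizes[1], rng=_rep_rng(seed, rep))
        step1 = discovery_filter(panel, groups, cfg)
        step2 = remove_clusters(panel, step1, cfg)
        for use_bb in backbones:
            for dens in densities:
                cfg_d = replace(cfg, target_density=float(dens), use_backbone=bool(use_bb))
                step3 = equal_spacing(panel, step2, groups, gmap, cfg_d)
                h_set = hexp_by_population(panel, step3.indices)
                for pop in panel.populations:
                    ohe_rows.append(
                        {
                            "population": pop,
                            "group": groups.assignment[pop],
                            "replicate": rep,
                            "step": "equal_spacing",
                            "h_set": float(h_set[pop]),
                            "h_ref": float(h_ref[pop]),
                            "ohe": (h_set[pop] - h_ref[pop]) / h_ref[pop],
                            "density": float(dens),
                            "backbone": bool(use_bb),
                        }
                    )
                count_rows.append(
                    {"replicate": rep, "density": float(dens), "backbone": bool(use_bb),
                     "step": "equal_spacing", "n_snps": len(step3)}
                )
    return SweepResult(
        ohe=pd.DataFrame(ohe_rows), counts=pd.DataFrame(count_rows), axis="density"
    )


# -- mixed-model group contrasts -------------------------------------------------

@dataclass
class ContrastResult:
    """LSMEANS, Tukey-adjusted pairwise contrasts and variance components."""

    lsmeans: pd.DataFrame
    contrasts: pd.DataFrame
    var_rep: float
    var_resid: float
    fallback_ols: bool

    def summary(self) -> str:
        lines = ["OHE group contrasts (mixed model, REML)"]
        if self.fallback_ols:
            lines[0] += " — singular fit, fixed-effects fallback"
        lines.append(f"variance components: replicate={self.var_rep:.3g}, "
                     f"residual={self.var_resid:.3g}")
        lines.append("\nLSMEANS:")
        lines.append(self.lsmeans.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        lines.append("\nPairwise contrasts (Tukey-adjusted):")
        lines.append(self.contrasts.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def ohe_group_model(
    data: SweepResult | pd.DataFrame,
    step: str = "discovery",
    where: dict | None = None,
) -> ContrastResult:
    """Fit OHE ~ group (fixed) + replicate (random intercept), REML.

    ``where`` optionally filters additional columns (e.g. a sweep axis value)
    before fitting.  LSMEANS use cell-means coding, so for balanced data with
    zero replicate variance they coincide with raw group means.
    """
    import statsmodels.api as sm

    df = data.ohe if isinstance(data, SweepResult) else data
    df = df[df["step"] == step]
    if where:
        for k, v in where.items():
            df = df[df[k] == v]
    if df["replicate"].nunique() < 2 or df["group"].nunique() < 2:
        raise ConfigError("need >=2 replicates and >=2 groups for the contrast model")
    df = df.reset_index(drop=True)
    groups_present = [g for g in GROUP_NAMES if g in set(df["group"])]
    X = pd.DataFrame(
        {g: (df["group"] == g).astype(float) for g in groups_present}
    )
    y = df["ohe"].to_numpy(dtype=float)
    n, k = len(df), len(groups_present)

    fallback = False
    var_rep = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = sm.MixedLM(y, X.to_numpy(), groups=df["replicate"].to_numpy())
            fit = md.fit(reml=True)
            var_rep = float(np.asarray(fit.cov_re).ravel()[0])
            var_resid = float(fit.scale)
            params = np.asarray(fit.fe_params)
            cov = np.asarray(fit.cov_params())[:k, :k]
            if not fit.converged or var_rep < 1e-12:
                fallback = True
        except Exception:  # pragma: no cover - singular designs
            fallback = True
    if fallback:
        fit = sm.OLS(y, X.to_numpy()).fit()
        params = np.asarray(fit.params)
        cov = np.asarray(fit.cov_params())
        var_rep = 0.0
        var_resid = float(fit.scale)

    lsmeans = pd.DataFrame(
        {"group": groups_present, "lsmean": params, "se": np.sqrt(np.diag(cov))}
    )
    n_reps = df["replicate"].nunique()
    ddf = max(1, n - k - (0 if fallback else n_reps - 1))
    rows = []
    for a, b in itertools.combinations(range(k), 2):
        est = params[a] - params[b]
        se = float(np.sqrt(cov[a, a] + cov[b, b] - 2 * cov[a, b]))
        q = abs(est) / se * np.sqrt(2.0) if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, ddf)) if np.isfinite(q) else 0.0
        rows.append(
            {"group_a": groups_present[a], "group_b": groups_present[b],
             "estimate": est, "se": se, "q": q, "p_tukey": p}
        )
    return ContrastResult(
        lsmeans=lsmeans,
        contrasts=pd.DataFrame(rows),
        var_rep=var_rep,
        var_resid=var_resid,
        fallback_ols=fallback,
    )
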
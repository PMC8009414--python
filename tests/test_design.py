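"""The five ascertainment steps: filters, backbone, spacing (vs. brute force)."""

import numpy as np
import pytest

import ascertain as asc
from ascertain.design import (
    DesignConfig,
    SnpSet,
    build_backbone,
    design_array,
    discovery_filter,
    downsample,
    equal_spacing,
    remove_clusters,
    segregating,
    validate_snps,
)
from conftest import make_panel, uniform_map


def groups_for(panel, discovery, validation=(), multipliers=None, subclusters=None):
    out = panel.outgroup_population
    assignment = {out: "outgroup"}
    for p in discovery:
        assignment[p] = "discovery"
    for p in validation:
        assignment[p] = "validation"
    for p in panel.populations:
        assignment.setdefault(p, "application")
    return asc.PopulationGroups(
        assignment=assignment,
        subclusters=subclusters or {p: "sub" for p in discovery},
        density_multipliers=multipliers or {},
    )


class TestDiscoveryFilter:
    def make(self, freqs, quality=100.0, depth=100):
        n = len(freqs)
        freq = np.column_stack([np.asarray(freqs, float).reshape(n, -1),
                                np.full((n, 1), 0.5)])
        k = freq.shape[1] - 1
        pops = [f"d{i}" for i in range(k)] + ["og"]
        panel = make_panel(np.arange(1, n + 1) * 1000, freq, pops,
                           quality=quality, depth=depth, outgroup="og")
        return panel, groups_for(panel, [f"d{i}" for i in range(k)])

    def test_high_frequency_locus_fails_panel_maf(self):
        # discovery frequencies averaging 0.99125 -> MAF 0.00875 < 0.05
        row = [0.98, 0.99, 1.0, 0.97, 1.0, 1.0, 0.99, 1.0]
        panel, groups = self.make([row, [0.5] * 8])
        kept = discovery_filter(panel, groups, DesignConfig())
        assert kept.indices.tolist() == [1]

    def test_quality_just_below_threshold_removed(self):
        panel, groups = self.make([[0.5], [0.5]], quality=[59.9, 60.0])
        kept = discovery_filter(panel, groups, DesignConfig())
        assert kept.indices.tolist() == [1]

    def test_all_passing_kept(self):
        panel, groups = self.make([[0.5]] * 5)
        kept = discovery_filter(panel, groups, DesignConfig())
        assert len(kept) == 5

    def test_coverage_outliers_removed(self):
        depth = [100] * 20 + [100000]
        panel, groups = self.make([[0.5]] * 21, depth=depth)
        kept = discovery_filter(panel, groups, DesignConfig())
        assert 20 not in kept.indices

    def test_empty_discovery_group_rejected(self):
        panel, _ = self.make([[0.5]] * 3)
        groups = groups_for(panel, [])
        with pytest.raises(asc.ConfigError):
            discovery_filter(panel, groups, DesignConfig())


class TestClusterRemoval:
    def run(self, positions):
        n = len(positions)
        panel = make_panel(positions, np.full((n, 2), 0.5), ["d0", "og"], outgroup="og")
        cand = SnpSet(np.arange(n), "discovery")
        return remove_clusters(panel, cand, DesignConfig()).indices

    def test_tight_cluster_center_removed(self):
        # 103 has flanks (2, 6): 2 < 4 and 6 < 10 -> removed
        kept = self.run([100, 103, 110])
        assert 1 not in kept
        # 100 has flanks (inf, 2): kept; 110 flanks (6, inf): kept
        assert {0, 2} <= set(kept)

    def test_long_far_flank_spares_locus(self):
        # 103 has flanks (2, 96): 96 >= 10 -> kept
        kept = self.run([100, 103, 200])
        assert set(kept) == {0, 1, 2}

    def test_single_snp_has_infinite_flanks(self):
        assert self.run([100]).tolist() == [0]

    def test_asymmetric_rule(self):
        # 105 has flanks (4, 2): 4 < 10 and 2 < 4 -> removed
        kept = self.run([100, 105, 108])
        assert 1 not in kept


class TestBackbone:
    def test_greedy_min_distance_scan(self):
        panel = make_panel([1000, 2500, 3100, 5200], np.full((4, 2), 0.5),
                           ["d0", "og"], outgroup="og")
        kept = build_backbone(panel, np.arange(4), ["d0"], 2000)
        assert panel.loci["bp"].to_numpy()[kept].tolist() == [1000, 3100, 5200]

    def test_no_common_segregants_gives_empty_backbone(self):
        freq = np.array([[0.5, 1.0], [0.3, 0.0]])
        panel = make_panel([1000, 5000], freq, ["d0", "d1"])
        assert len(build_backbone(panel, np.arange(2), ["d0", "d1"], 2000)) == 0

    def test_unit_min_distance_keeps_all(self):
        panel = make_panel([10, 11, 12], np.full((3, 1), 0.5), ["d0"])
        assert len(build_backbone(panel, np.arange(3), ["d0"], 1)) == 3

    def test_min_spacing_property_on_synthetic_run(self, mid_panel, mid_design):
        es = mid_design.step("equal_spacing")
        bb = [i for i, tag in es.provenance.items() if tag == "backbone-all"]
        sub = mid_panel.loci.loc[sorted(bb)]
        for _, chrom_loci in sub.groupby("chrom"):
            assert np.all(np.diff(chrom_loci["bp"].to_numpy()) >= 2000)


def spacing_oracle(panel, candidate, groups, gmap, cfg, multipliers=None, keep_exonic=False,
                   subcluster_backbones=None):
    """Plain-loop reference implementation of the spacing step.

    Independent of the package's implementation: recomputes backbones by
    direct scanning and fills gaps by enumerating every ideal point and every
    remaining candidate.
    """
    import math

    seg = (panel.freq > cfg.segregation_eps) & (panel.freq < 1 - cfg.segregation_eps)
    bp = panel.loci["bp"].to_numpy()
    cm = panel.loci["cM"].to_numpy(float)
    chrom = panel.loci["chrom"].to_numpy()
    cand = set(int(i) for i in candidate.indices)
    disc = [p for p in panel.populations if groups.assignment.get(p) == "discovery"]
    sub_rank = {}
    for p in disc:
        sub_rank.setdefault(groups.subclusters.get(p, ""), len(sub_rank))
    order = sorted(disc, key=lambda p: (sub_rank[groups.subclusters.get(p, "")], disc.index(p)))

    def backbone(pops):
        cols = [panel.pop_index(p) for p in pops]
        out = []
        for c in dict.fromkeys(chrom):
            last = None
            for i in sorted(cand):
                if chrom[i] != c or not all(seg[i, j] for j in cols):
                    continue
                if last is None or bp[i] - last >= cfg.backbone_min_dist_bp:
                    out.append(i)
                    last = bp[i]
        return out

    selected = set()
    if keep_exonic:
        selected |= {i for i in cand if panel.loci["exonic"].iloc[i]}
    use_bb = cfg.use_backbone or keep_exonic
    if subcluster_backbones is None:
        subcluster_backbones = cfg.use_backbone and not keep_exonic
    if use_bb:
        selected |= set(backbone(order))
        if subcluster_backbones:
            subs = {}
            for p in order:
                subs.setdefault(groups.subclusters.get(p, ""), []).append(p)
            for label, members in subs.items():
                if len(members) >= 2:
                    selected |= set(backbone(members))
    seed = set(selected)
    for p in order:
        dens = cfg.target_density
        if multipliers:
            dens *= multipliers.get(groups.subclusters.get(p, ""), 1.0)
        if dens <= 0:
            continue
        col = panel.pop_index(p)
        for c in dict.fromkeys(chrom):
            cm0, cm1 = gmap.chrom_bounds_cM(c)
            bp0, bp1 = gmap.chrom_bounds_bp(c)
            anchors = sorted(
                [(bp[i], cm[i]) for i in seed if chrom[i] == c and seg[i, col]]
            )
            bounds = [(bp0 - 1, cm0)] + anchors + [(bp1 + 1, cm1)]
            for (lbp, lcm), (rbp, rcm) in zip(bounds, bounds[1:]):
                span = rcm - lcm
                n = math.floor(dens * span + 0.5)
                n -= sum(
                    1 for i in selected
                    if chrom[i] == c and lbp < bp[i] < rbp and seg[i, col]
                )
                if n <= 0:
                    continue
                pool = [
                    i for i in cand
                    if chrom[i] == c and lbp < bp[i] < rbp
                    and i not in selected and seg[i, col]
                ]
                for k in range(1, n + 1):
                    if not pool:
                        break
                    ideal = lcm + span * k / (n + 1)
                    best = min(pool, key=lambda i: (abs(cm[i] - ideal), bp[i]))
                    selected.add(best)
                    pool.remove(best)
    return np.array(sorted(selected), dtype=int)


def random_instance(rng, n_pops=2, max_loci=15):
    n = int(rng.integers(4, max_loci + 1))
    positions = np.sort(rng.choice(np.arange(100, 100_000, 97), size=n, replace=False))
    freq = rng.random((n, n_pops + 1))
    freq[rng.random((n, n_pops + 1)) < 0.3] = 1.0  # some fixed entries
    pops = [f"d{i}" for i in range(n_pops)] + ["og"]
    exonic = rng.random(n) < 0.2
    panel = make_panel(positions, freq, pops, exonic=exonic, outgroup="og")
    gmap = uniform_map(length=120_000, cm_per_mb=float(rng.uniform(20, 60)))
    panel.loci["cM"] = gmap.interpolate("chr1", panel.loci["bp"].to_numpy())
    groups = groups_for(panel, [f"d{i}" for i in range(n_pops)])
    cfg = DesignConfig(
        target_density=float(rng.choice([0.3, 0.6, 1.0, 2.0])),
        backbone_min_dist_bp=int(rng.choice([500, 2000, 10_000])),
        use_backbone=bool(rng.integers(0, 2)),
    )
    return panel, gmap, groups, cfg


class TestEqualSpacing:
    def test_ideal_point_count_from_density(self):
        # one 0.003 cM gap at density 667 -> round(2.001) = 2 picks
        positions = np.array([100, 200, 300, 400, 500])
        panel = make_panel(positions, np.full((5, 2), 0.5), ["d0", "og"], outgroup="og")
        gmap = asc.GeneticMap({"chr1": np.array([[1.0, 0.0], [600.0, 0.003]])})
        panel.loci["cM"] = gmap.interpolate("chr1", positions)
        groups = groups_for(panel, ["d0"])
        cfg = DesignConfig(target_density=667.0, use_backbone=False)
        out = equal_spacing(panel, SnpSet(np.arange(5), "cluster_removal"), groups, gmap, cfg)
        assert len(out) == 2

    def test_zero_density_returns_backbone_only(self, mid_panel, mid_groups, mid_map):
        cfg = DesignConfig(target_density=0.0, use_backbone=True)
        s1 = discovery_filter(mid_panel, mid_groups, cfg)
        s2 = remove_clusters(mid_panel, s1, cfg)
        out = equal_spacing(mid_panel, s2, mid_groups, mid_map, cfg)
        assert set(out.provenance.values()) <= {"backbone-all"} | {
            f"backbone-subgroup:{s}" for s in set(mid_groups.subclusters.values())
        }
        assert len(out) == len(out.provenance)

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            panel, gmap, groups, cfg = random_instance(rng)
            cand = SnpSet(np.arange(panel.n_loci), "cluster_removal")
            fast = equal_spacing(panel, cand, groups, gmap, cfg)
            slow = spacing_oracle(panel, cand, groups, gmap, cfg)
            np.testing.assert_array_equal(fast.indices, slow)

    def test_missing_map_chromosome_rejected(self):
        panel = make_panel([100, 200], np.full((2, 2), 0.5), ["d0", "og"],
                           chrom="chr7", outgroup="og")
        gmap = uniform_map(chrom="chr1")
        groups = groups_for(panel, ["d0"])
        with pytest.raises(asc.ConfigError):
            equal_spacing(panel, SnpSet(np.arange(2), "x"), groups, gmap,
                          DesignConfig(use_backbone=False))


class TestValidation:
    def make(self, seg_count, n_val=19):
        # one locus segregating in `seg_count` validation populations
        freq = np.concatenate([
            np.full(1, 0.5),                       # discovery pop
            np.where(np.arange(n_val) < seg_count, 0.5, 1.0),
            np.full(1, 1.0),                       # outgroup
        ]).reshape(1, -1)
        pops = ["d0"] + [f"v{i}" for i in range(n_val)] + ["og"]
        panel = make_panel([100], freq, pops, outgroup="og")
        groups = groups_for(panel, ["d0"], validation=[f"v{i}" for i in range(n_val)])
        return panel, groups

    @pytest.mark.parametrize("seg_count,kept", [(8, True), (7, False), (0, False)])
    def test_eight_of_nineteen_rule(self, seg_count, kept):
        panel, groups = self.make(seg_count)
        out = validate_snps(panel, SnpSet(np.array([0]), "x"), groups, DesignConfig())
        assert (len(out) == 1) is kept

    def test_threshold_scales_with_group_size(self):
        # 8 validation populations -> ceil(8/19 * 8) = 4 required
        panel, groups = self.make(4, n_val=8)
        out = validate_snps(panel, SnpSet(np.array([0]), "x"), groups, DesignConfig())
        assert len(out) == 1
        panel, groups = self.make(3, n_val=8)
        out = validate_snps(panel, SnpSet(np.array([0]), "x"), groups, DesignConfig())
        assert len(out) == 0


class TestDownsample:
    def test_all_exonic_candidates_survive(self):
        panel = make_panel([100, 5000, 9000], np.full((3, 2), 0.5), ["d0", "og"],
                           exonic=[True] * 3, outgroup="og")
        gmap = uniform_map(length=10_000)
        panel.loci["cM"] = gmap.interpolate("chr1", panel.loci["bp"].to_numpy())
        groups = groups_for(panel, ["d0"])
        out = downsample(panel, SnpSet(np.arange(3), "validation"), groups, gmap,
                         DesignConfig(target_density=0.0))
        assert out.indices.tolist() == [0, 1, 2]

    def test_no_exonic_zero_density_gives_backbone(self):
        panel = make_panel([100, 5000, 9000], np.full((3, 2), 0.5), ["d0", "og"],
                           outgroup="og")
        gmap = uniform_map(length=10_000)
        panel.loci["cM"] = gmap.interpolate("chr1", panel.loci["bp"].to_numpy())
        groups = groups_for(panel, ["d0"])
        out = downsample(panel, SnpSet(np.arange(3), "validation"), groups, gmap,
                         DesignConfig(target_density=0.0))
        assert set(out.provenance.values()) == {"backbone-all"}
        # 2 kb greedy scan keeps 100, 5000, 9000 (spacing 4900, 4000)
        assert len(out) == 3

    def test_density_multiplier_boosts_subcluster_contribution(self, mid_panel, mid_map):
        # symmetric groups from two equal-size sub-clusters; one gets 3x density
        disc = [p for p in mid_panel.populations if p.startswith("broiler")][:3] + \
               [p for p in mid_panel.populations if p.startswith("layer")][:3]
        groups = groups_for(
            mid_panel, disc,
            validation=[p for p in mid_panel.populations if p.startswith("local_a")],
            subclusters={p: ("fast" if p.startswith("broiler") else "slow") for p in disc},
            multipliers={"fast": 3.0, "slow": 1.0},
        )
        cfg = DesignConfig(target_density=300.0)
        s1 = discovery_filter(mid_panel, groups, cfg)
        s2 = remove_clusters(mid_panel, s1, cfg)
        s3 = equal_spacing(mid_panel, s2, groups, mid_map, cfg)
        s4 = validate_snps(mid_panel, s3, groups, cfg)
        s5 = downsample(mid_panel, s4, groups, mid_map, cfg)
        fills = [tag for tag in s5.provenance.values() if tag.startswith("gap-fill:")]
        fast = sum(1 for t in fills if t.split(":")[1].startswith("broiler"))
        slow = sum(1 for t in fills if t.split(":")[1].startswith("layer"))
        assert fast >= slow

    def test_downsample_matches_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            panel, gmap, groups, cfg = random_instance(rng)
            groups.density_multipliers = {"sub": 3.0}
            cand = SnpSet(np.arange(panel.n_loci), "validation")
            fast = downsample(panel, cand, groups, gmap, cfg)
            slow = spacing_oracle(panel, cand, groups, gmap, cfg,
                                  multipliers={"sub": 3.0}, keep_exonic=True,
                                  subcluster_backbones=False)
            np.testing.assert_array_equal(fast.indices, slow)


class TestFullPipeline:
    def test_chain_subset_and_monotone_counts(self, mid_design):
        mid_design.check_chain()
        counts = mid_design.counts().set_index("step")["n_snps"]
        assert counts["discovery"] > counts["equal_spacing"]

    def test_deterministic_rerun(self, mid_panel, mid_groups, mid_map):
        d1 = asc.design_array(mid_panel, mid_groups, mid_map)
        d2 = asc.design_array(mid_panel, mid_groups, mid_map)
        for s1, s2 in zip(d1.steps, d2.steps):
            np.testing.assert_array_equal(s1.indices, s2.indices)
            assert s1.provenance == s2.provenance

    def test_discovery_maf_never_decreases_at_filter_and_spacing(
        self, mid_panel, mid_groups, mid_design
    ):
        disc_idx = mid_panel.pop_index(mid_groups.discovery)

        def mean_maf(indices):
            f = mid_panel.freq[np.ix_(indices, disc_idx)].mean(axis=1)
            return np.minimum(f, 1 - f).mean()

        truth = mean_maf(np.arange(mid_panel.n_loci))
        s1 = mean_maf(mid_design.step("discovery").indices)
        s2 = mean_maf(mid_design.step("cluster_removal").indices)
        s3 = mean_maf(mid_design.step("equal_spacing").indices)
        assert s1 >= truth
        assert s3 >= s2

    def test_through_argument_stops_early(self, mid_panel, mid_groups, mid_map):
        d = asc.design_array(mid_panel, mid_groups, mid_map, through="equal_spacing")
        assert [s.step for s in d.steps] == ["discovery", "cluster_removal", "equal_spacing"]
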
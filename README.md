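# ascertain

Simulate SNP-array design and quantify the ascertainment bias it creates.

Genotyping arrays carry SNPs that were *chosen* — discovered in a small set
of populations, filtered for common alleles, spaced along the genetic map,
validated, and downsampled. Population-genetic statistics computed from such
markers are therefore biased relative to whole-genome sequence: rare alleles
are underrepresented and expected heterozygosity is overestimated, more so
in the populations that took part in the design. `ascertain` is for
population geneticists and breeding researchers who want to study these
effects quantitatively: it generates synthetic multi-population allele
frequency panels with known structure, replays a realistic five-step array
design pipeline on them (or on user-supplied VCF data), and measures the
distortion each step introduces.

## The model and statistics

**Synthetic panels.** Per locus, an ancestral derived-allele frequency *x*
is drawn from a truncated neutral spectrum (density ∝ 1/*x*), so the truth
panel is rich in rare alleles. Population frequencies drift around *x*
under a two-level Balding–Nichols hierarchy — cluster frequency
~ Beta(*x*(1−*F*)/*F*, (1−*x*)(1−*F*)/*F*) with cluster-level *F*, then
population frequency likewise around the cluster — giving tight
commercial-like clusters and looser local clusters. One strongly diverged
outgroup drifts directly from *x* (most loci effectively fixed) and owns a
fraction of private loci. Frequencies are *observed* through either
genotype counts (2·*n* alleles) or pooled sequencing (ratio of reference
allelic depth to total depth at Poisson read depth).

**Array design** (five deterministic steps, each a subset of the last):
quality/coverage/MAF discovery filter → removal of tight SNP clusters
(invariant-flank rule) → a 2 kb-spaced backbone of SNPs segregating in all
discovery populations (plus per-sub-cluster backbones), then per-population
gap filling toward equidistant cM positions at a target density of 667
segregating SNPs/cM → validation (segregating in ≥ 8 of 19 validation
populations) → final downsampling keeping exonic SNPs, with 3× density in
the broiler-like sub-cluster.

**Bias statistics.** Expected heterozygosity per population over a SNP set
*S*: H<sub>exp</sub> = (1/|S|) Σ<sub>l∈S</sub> 2p<sub>l</sub>(1−p<sub>l</sub>).
Its overestimation relative to the full panel:
OHE = (H<sub>exp,set</sub> − H<sub>exp,ref</sub>) / H<sub>exp,ref</sub>
(0 = unbiased, 1 = doubled). Spectra are reported as unfolded derived-allele
frequency histograms after polarizing with wild-population frequencies
(outgroup weighted double). Group contrasts over replicated random design
runs are estimated with a linear mixed model, OHE ~ group + (1 | replicate),
with LSMEANS and Tukey-adjusted pairwise tests. Nei's standard genetic
distance drives the "nearest-to-commercial" discovery-set construction.

## Worked example

```python
import ascertain as asc

cfg = asc.default_config(n_populations=24, n_loci=50_000, seed=1)
panel = asc.simulate_panel(cfg)
gmap = asc.simulate_map(cfg)
groups = asc.assign_groups(panel, n_discovery=8, n_validation=8, rng=1)
design = asc.design_array(panel, groups, gmap)
print(design.counts().to_string(index=False))

panel.ancestral_is_ref = panel.loci["ancestral_is_ref_true"].to_numpy(bool)
truth = asc.derived_afs(panel)
final = asc.derived_afs(panel, design.final.indices)
print(f"derived-allele mass below 0.05: truth {truth.mass(0, 0.05):.3f} "
      f"-> array {final.mass(0, 0.05):.3f}")

tbl = asc.ohe_table(panel, design, groups)
print(tbl.groupby(["group", "step"])["ohe"].mean().unstack()[
    ["discovery", "equal_spacing", "downsampling"]].round(2).to_string())
```

prints

```
           step  n_snps
      discovery   21436
cluster_removal   21265
  equal_spacing   10069
     validation    7957
   downsampling    7902

derived-allele mass below 0.05: truth 0.414 -> array 0.001

step         discovery  equal_spacing  downsampling
group
application       0.73           0.94          1.21
discovery         0.84           1.09          1.29
outgroup         -0.79          -0.78         -0.76
validation        0.69           0.89          1.26
```

Reading this: of 50 000 truth SNPs, 21 436 survive the discovery filters and
7 902 end up on the array. Rare derived alleles (frequency < 0.05) make up
41% of the truth panel but essentially vanish from the array. Expected
heterozygosity is consequently overestimated everywhere — by more in the
populations used for discovery (OHE 0.84 after step 1 vs. 0.73 for
uninvolved application populations) — while the diverged outgroup, whose
variation the array does not carry, is strongly *under*estimated
(OHE ≈ −0.8).

The same pipeline is scriptable from the shell
(`ascertain simulate / design / stats / sweep`), and
`ascertain.read_frequency_vcf` plus `read_exonic_bed`/`flag_exonic` feed
real VCF + BED + genetic-map data into the identical machinery.

## Module map

| module | contents |
| --- | --- |
| `ascertain.config` | `SimConfig`, population specs, YAML round trip |
| `ascertain.simulate` | `simulate_map`, `simulate_panel`, `assign_groups` |
| `ascertain.panel` | `SnpPanel`, `GeneticMap`, `PopulationGroups` containers + TSV serialization |
| `ascertain.io` | VCF frequency extraction, BED exonic flags, map interpolation |
| `ascertain.design` | `DesignConfig`, the five design steps, `design_array` |
| `ascertain.stats` | polarization, derived AFS, H_exp, OHE, Nei distance |
| `ascertain.scenarios` | replicated groupings, discovery-count and density sweeps, mixed-model contrasts |
| `ascertain.cli` | `ascertain` command-line entry point |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
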
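# Methods

## The generative model

A synthetic panel is defined per locus by an ancestral derived-allele
frequency and a hierarchy of drifted population frequencies.

**Site-frequency spectrum.** The ancestral derived frequency *x* is drawn
with density ∝ 1/*x* on [*t*, 1−*t*] (inverse-CDF sampling,
*x* = *t*((1−*t*)/*t*)^*u*). This is the standard neutral-equilibrium shape
and guarantees the rare-allele richness that makes ascertainment bias
visible. The truncation *t* (default 0.01) controls how extreme the rare
tail is; at the default, ~35–42% of loci have panel-mean derived frequency
below 0.05.

**Drift hierarchy.** Frequencies drift under the Balding–Nichols model:
given a mean *m* and drift parameter *F*, the drifted frequency is
Beta(*m*(1−*F*)/*F*, (1−*m*)(1−*F*)/*F*), with mean *m* and variance
*F·m*(1−*m*). Two levels are stacked: cluster around ancestral, population
around cluster. Default cluster/population F values:

| cluster | cluster F | population F | character |
| --- | --- | --- | --- |
| broiler | 0.03 | 0.25 | tight cluster of bottlenecked commercial lines |
| layer | 0.10 | 0.45 | loose group of strongly drifted lines |
| local_a | 0.10 | 0.35 | local breeds |
| local_b | 0.15 | 0.45 | local breeds, more isolated |
| wild | 0.05 | 0.25 | wild reference populations |

The population-level values are deliberately large: commercial poultry-like
lines are heavily bottlenecked, and these settings reproduce the pairwise
Nei standard distances reported for such panels (maximum within the tight
broiler-like group ≈ 0.06; substantially larger within the layer-like
group). Nei distance computed on a rare-allele-rich panel saturates around
2·F·E[x(1−x)]/J, so very large distances require very large F — the layer
figure lands near 0.09–0.10 here, the right order but below the most extreme
real values. With these defaults the per-population OHE of ascertained sets
falls in the 0.7–1.3 range for ingroup populations, matching the magnitudes
such studies report.

**Outgroup.** The outgroup drifts directly around *x* with a large
divergence F (default 0.98): after long isolation most shared polymorphisms
have sorted to fixation, so the outgroup is nearly fixed at loci that
segregate in the ingroup. Additionally a fraction of loci (default 0.15) is
private to the outgroup: the derived allele is absent in every ingroup
population while the outgroup drifts around *x* with a moderate F (default
0.2). The private fraction carries most of the outgroup's true
heterozygosity; since arrays never select those loci (they fail the
discovery MAF filter), the outgroup's heterozygosity is underestimated and
its OHE is negative at every ascertained step — a moment calculation with
the defaults puts it near −0.5 to −0.8, and seeded runs give ≈ −0.75.

**Observation layer.** Individually genotyped populations report
Binomial(2n, p)/2n allele counts (n = 20–25 for the commercial anchors).
Pooled populations report the reference allelic depth over total depth with
per-locus depth ~ Poisson(mean depth, default 30×, minimum 1). Pool
composition (animals, then reads) is not modelled as a two-stage process;
the pool frequency estimate is unbiased and only its variance is slightly
understated, which does not affect the ascertainment contrasts studied
here. Locus quality (Normal(80, 20) truncated at 0) and a per-locus total
depth covariate (overdispersed Poisson) are simulated independently of
frequency; no joint model is claimed.

**Genome and map.** Default genome: 3 chromosomes × 600 kb with 50 000 loci
and a piecewise-linear genetic map at 3 cM/Mb with multiplicative jitter
per segment, floored at zero (occasional flat segments, as in real linkage
maps). The scale is chosen so that ≈ 316 kb ≈ 1 cM (the chicken-like ratio)
and the candidate density after the discovery step is a few thousand SNPs
per cM — the regime in which the default equal-spacing target of 667
segregating SNPs/cM is an active constraint, as it is on real whole-genome
data. Everything downstream treats loci as exchangeable given the map:
there is no linkage disequilibrium and no sequence-level error model (see
Limitations).

## The design pipeline

1. **Discovery filter.** Keep loci with quality ≥ 60, depth ≤ mean + 3 sd
   (moments over all loci), and discovery-panel MAF ≥ 0.05, where the
   discovery-panel frequency is the *unweighted mean* of the discovery
   populations' frequencies — population-size agnostic and appropriate for
   pooled discovery panels.
2. **Cluster removal.** A locus is dropped iff its invariant flanks among
   the discovered SNPs (neighbor bp distance − 1; chromosome ends are
   infinite) are shorter than 4 bp on one side *and* 10 bp on the other.
3. **Equal spacing.** Part one: a backbone of loci segregating
   (frequency strictly in (0,1); threshold configurable for noisy pools) in
   *all* discovery populations, thinned left-to-right to ≥ 2 kb spacing, plus
   one backbone per discovery sub-cluster with ≥ 2 members (a singleton
   "segregates in all" backbone would degenerate to that population's
   segregating loci, so singletons are skipped). Part two: populations are
   visited in a fixed, documented order (sub-cluster order of first
   appearance, panel order within). For each population the gap structure is
   fixed by the part-one loci segregating in it (terminal map anchors close
   the ends); a gap of *g* cM has a target of round-half-up(667·*g*) SNPs
   segregating in that population, *minus* in-gap loci already selected by
   earlier populations that segregate in it. Ideal points are placed
   equidistantly in cM and each takes the nearest unselected in-gap
   candidate segregating in the population (ties to smaller bp). Counting
   earlier picks toward the local density is what makes the first
   population contribute the most and later populations little, matching
   the strongly decreasing contribution profile reported for this style of
   algorithm.
4. **Validation.** Keep loci segregating in ≥ 8 of 19 validation
   populations; for validation groups smaller than 19 the threshold scales
   proportionally (ceil, minimum 1) — the proportional rule is this
   package's choice where only the 8-of-19 case is defined.
5. **Downsampling.** Keep all exonic candidates and the all-population
   backbone (no sub-cluster backbones), then gap-fill as in step 3 with
   per-sub-cluster density multipliers (default 3× for the broiler-like
   sub-cluster).

All steps are deterministic given their inputs; randomness enters only
through panel simulation and group assignment. Each step's output indexes a
subset of its predecessor's.

## Statistics

H_exp is the mean of 2p(1−p) over the set's loci, per population, computed
from the same observed frequencies used by the design (as with real pooled
data, estimation and ascertainment share one observation). OHE divides the
deviation from the full-truth-panel H_exp by the latter; in synthetic mode
the reference set is the entire truth panel, since no variant-caller
filtering stage is simulated and hence no unfiltered/filtered distinction
exists. Loci with any missing population frequency are dropped panel-wide
before design (logged). Derived spectra are histograms (50 bins by
default) of the mean derived frequency over the chosen populations —
histograms, not kernel densities, for testability; boundary frequencies 0
and 1 fall in the terminal bins. Polarization takes the ancestral allele as
the weighted major allele of three wild populations with the diverged
outgroup counted twice; a weighted reference frequency of exactly 0.5
resolves to the reference allele.

The group-contrast model is OHE ~ group (fixed, cell-means coding) +
replicate (random intercept), fitted by REML via statsmodels' MixedLM.
LSMEANS are the cell means with their model SEs; pairwise contrasts use the
studentized-range (Tukey) distribution with residual degrees of freedom
n − k − (r − 1) — an approximation adequate for the balanced layouts
produced here. A singular fit (replicate variance ≈ 0 or non-convergence)
falls back to OLS and is flagged in the result.

## Scenario layouts and problem sizes

Replicated experiments derive per-replicate RNGs from (master seed,
replicate index), so results are identical regardless of execution order.
Random groupings fix the outgroup and draw the other groups uniformly;
discovery-count sweeps split the remainder into equal validation and
application halves, odd remainder to validation. Density sweeps rerun only
the spacing step per (density, backbone) cell, reusing the per-replicate
discovery/cluster-removal steps, which depend only on the grouping.

Default problem sizes used by the tests and the acceptance script: the
structural and spectrum checks run on a 24-population, 50 000-locus panel;
the replicated sweeps use a 46-population, 20 000-locus panel (46
populations are required to probe discovery sets of 32, and the smaller
locus count keeps hundreds of replicated designs comfortably fast).

## What the generator does and does not show

The synthetic panel reproduces the statistical skeleton the analysis needs:
a rare-rich spectrum, hierarchical relatedness with realistic pairwise Nei
distances, pooled/individual observation noise, a diverged outgroup with
private variation, exonic flags and a monotone genetic map. Passing tests
on it demonstrate the pipeline's selection logic and the directional
behavior of ascertainment bias (rare-allele depletion; discovery-panel
advantage shrinking with panel size; backbone-driven mid-frequency
enrichment at low density; negative outgroup OHE).

It deliberately omits linkage disequilibrium (loci are exchangeable given
the map), coalescent-exact genealogies, migration/admixture, and
sequencing error. One documented consequence: in real data the equal
spacing step largely *masks* the discovery-vs-application OHE gap created
by the discovery filter, whereas here the gap persists through the spacing
step at all densities with or without the backbone. Decomposition on the
simulated truth shows why: the gap is composition-intrinsic (it survives
with noiseless frequencies, and conditioning on broad discovery segregation
enlarges rather than shrinks it), so with exchangeable loci no
within-population positional selection can remove it. Reproducing the
masking would require the excluded real-data structure (LD and deeply
shared haplotype variation), and results about gap *magnitudes* after
spacing should therefore not be read as predictions for real arrays; the
directional density/backbone trends are the transferable part.

## Numerical choices

Round-half-up for gap targets (unbiased over many gaps); ties in the
nearest-candidate search resolved toward smaller bp (the original
algorithm's tie rule is unpublished; this stand-in is documented); map
queries outside the anchored range clamp to terminal anchors with a logged
warning; Nei distance returns +inf when populations share no alleles;
backbone scans are independent per backbone (the 2 kb guarantee holds
within each backbone, not across their union); frequencies are serialized
with 17 significant digits for exact round trips.
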
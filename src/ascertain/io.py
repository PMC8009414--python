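"""Readers for the standard formats feeding the pipeline: VCF, BED, maps.

Coordinate conventions: panel and VCF positions are 1-based; BED intervals
are half-open 0-based and converted exactly once, at the BED boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .panel import FormatError, GeneticMap, SnpPanel

logger = logging.getLogger(__name__)


def interpolate_cM(gmap: GeneticMap, chrom: str, bp) -> np.ndarray:
    """Piecewise-linear bp -> cM lookup (delegates to the map object)."""
    return gmap.interpolate(chrom, bp)


def attach_map(panel: SnpPanel, gmap: GeneticMap) -> SnpPanel:
    """Fill the panel's cM column from a genetic map (in place, returned)."""
    cm = np.empty(panel.n_loci)
    for chrom, sub in panel.loci.groupby("chrom", sort=False):
        cm[sub.index.to_numpy()] = gmap.interpolate(str(chrom), sub["bp"].to_numpy())
    panel.loci["cM"] = cm
    return panel


# -- VCF ----------------------------------------------------------------------

def read_frequency_vcf(
    path: str | Path,
    pop_sample_map: Mapping[str, Mapping],
    exclude_chroms: Sequence[str] = (),
) -> SnpPanel:
    """Build a SnpPanel from a VCF with per-population AD or GT fields.

    ``pop_sample_map`` maps population name to ``{"samples": [...], "mode":
    "pool"|"individual"}``.  Pool populations estimate the reference-allele
    frequency as the ratio of reference allelic depth to total depth (summed
    over the population's samples); individually genotyped populations count
    reference alleles over called genotypes, excluding missing calls from
    the denominator.  Multiallelic records are skipped with a logged count;
    records on chromosomes named in ``exclude_chroms`` (e.g. sex
    chromosomes) are excluded.  Records missing both AD and GT raise
    :class:`FormatError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pop_cols: dict[str, np.ndarray] = {}
    modes: dict[str, str] = {}
    for pop, spec in pop_sample_map.items():
        missing = [s for s in spec["samples"] if s not in samples]
        if missing:
            raise FormatError(f"samples {missing} of population {pop!r} absent from VCF")
        pop_cols[pop] = np.array([samples.index(s) for s in spec["samples"]])
        modes[pop] = spec.get("mode", "pool")

    excl = set(map(str, exclude_chroms))
    rows, freqs = [], []
    n_multi = n_excluded = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_multi += 1
            continue
        if str(v.CHROM) in excl:
            n_excluded += 1
            continue
        ad = v.format("AD")
        gts = None
        rec = np.full(len(pop_sample_map), np.nan)
        for j, pop in enumerate(pop_sample_map):
            cols = pop_cols[pop]
            if modes[pop] == "pool":
                if ad is None:
                    raise FormatError(f"pool population {pop!r} requires an AD field")
                sub = ad[cols].astype(float)
                sub[sub < 0] = np.nan  # cyvcf2 encodes missing AD as negative
                ref_ad = np.nansum(sub[:, 0])
                tot = np.nansum(sub[:, :2])
                rec[j] = ref_ad / tot if tot > 0 else np.nan
            else:
                if gts is None:
                    gts = v.genotype.array()
                    if gts is None:
                        raise FormatError(f"population {pop!r} requires a GT field")
                alleles = gts[cols][:, :2].astype(float)
                called = alleles >= 0
                n_alleles = called.sum()
                if n_alleles == 0:
                    rec[j] = np.nan
                else:
                    rec[j] = (alleles[called] == 0).sum() / n_alleles
        depth = int(np.nansum(np.where(ad.astype(float) >= 0, ad, 0))) if ad is not None else 0
        rows.append((str(v.CHROM), int(v.POS), np.nan, float(v.QUAL or 0.0),
                     depth, False, v.REF, v.ALT[0]))
        freqs.append(rec)
    if n_multi:
        logger.info("skipped %d multiallelic/non-SNP records", n_multi)
    if n_excluded:
        logger.info("excluded %d records on non-autosomal chromosomes", n_excluded)
    if not rows:
        raise FormatError(f"no usable biallelic SNP records in {path}")
    loci = pd.DataFrame(
        rows, columns=["chrom", "bp", "cM", "quality", "depth", "exonic", "ref", "alt"]
    )
    pop_meta = pd.DataFrame(
        {
            "mode": [modes[p] for p in pop_sample_map],
            "sample_size": [len(pop_cols[p]) for p in pop_sample_map],
            "mean_depth": np.nan,
            "cluster": "",
            "commercial": False,
            "outgroup": False,
        },
        index=pd.Index(list(pop_sample_map), name="population"),
    )
    return SnpPanel(loci=loci, freq=np.asarray(freqs, dtype=float), pop_meta=pop_meta)


# -- BED ------------------------------------------------------------------------

def read_exonic_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Parse a BED file (half-open, 0-based) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty/inverted interval")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    for t in trees.values():
        t.merge_overlaps()
    return trees


def flag_exonic(panel: SnpPanel, intervals: Mapping[str, IntervalTree]) -> SnpPanel:
    """Set the exonic flag: locus at bp is exonic iff (bp - 1) falls in an
    interval on its chromosome (computed once, overlaps pre-merged)."""
    flags = np.zeros(panel.n_loci, dtype=bool)
    for chrom, sub in panel.loci.groupby("chrom", sort=False):
        tree = intervals.get(str(chrom))
        if tree is None:
            continue
        pos = sub["bp"].to_numpy()
        flags[sub.index.to_numpy()] = [bool(tree[p - 1]) for p in pos]
    panel.loci["exonic"] = flags
    return panel
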
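"""Variant allele frequency from amplicon counts and mutant-allele-copy
inference on a locus of known ploidy.

The binning rule divides the VAF percent scale into `total_copies` equal
ranges with inclusive upper edges: on a triploid locus, 1-33% maps to one
mutant allele, 34-66% to two, and 67-100% to three; VAF 0 is wild type.
The observed VAF is rounded to the nearest integer percent before binning,
so 33.4% is one copy and 33.6% is two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass
class VariantCounts:
    sample_id: str
    ref_reads: int
    alt_reads: int

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads


@dataclass
class AlleleCopyCall:
    vaf: float
    total_copies: int
    mutant_copies: int
    bin_edges: tuple  # percent thresholds (upper edge of each copy bin)


def compute_vaf(counts: VariantCounts) -> float:
    """alt / (alt + ref), reported to 4 decimals.  Zero depth is flagged."""
    if counts.ref_reads < 0 or counts.alt_reads < 0:
        raise ValueError("read counts must be >= 0")
    if counts.depth == 0:
        raise ValueError(f"sample {counts.sample_id}: zero depth, VAF undefined")
    return round(counts.alt_reads / counts.depth, 4)


def infer_allele_copies(vaf: float, total_copies: int = 3) -> AlleleCopyCall:
    """Map a VAF to a mutant-allele copy number by equal-thirds-style binning.

    The percent VAF is rounded to the nearest integer and assigned
    copies = ceil(percent/100 * total_copies); 0 maps to 0 copies.  For a
    triploid locus this reproduces the 1-33 / 34-66 / 67-100 ranges.
    Generalization to other ploidies follows the same equal-range rule.
    """
    if total_copies < 1:
        raise ValueError("total_copies must be >= 1")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    pct = round(vaf * 100.0)
    copies = 0 if pct == 0 else math.ceil(pct / 100.0 * total_copies)
    copies = min(copies, total_copies)
    edges = tuple(round(k / total_copies * 100) for k in range(1, total_copies + 1))
    return AlleleCopyCall(vaf=vaf, total_copies=total_copies,
                          mutant_copies=copies, bin_edges=edges)


def genotype_table(counts: pd.DataFrame, total_copies: int = 3) -> pd.DataFrame:
    """Per-sample VAF and copy calls from a counts table
    (columns sample_id, ref_reads, alt_reads)."""
    rows = []
    for _, r in counts.iterrows():
        vc = VariantCounts(str(r["sample_id"]), int(r["ref_reads"]),
                           int(r["alt_reads"]))
        vaf = compute_vaf(vc)
        call = infer_allele_copies(vaf, total_copies)
        rows.append((vc.sample_id, vc.ref_reads, vc.alt_reads, vaf,
                     call.mutant_copies, total_copies))
    return pd.DataFrame(rows, columns=["sample_id", "ref_reads", "alt_reads",
                                       "vaf", "mutant_copies", "total_copies"])


def read_vcf_allelic_depths(path: str, sample: str | None = None) -> pd.DataFrame:
    """Ref/alt depths from the AD FORMAT field of a VCF.

    One row per record x sample; convenience reader for single-site
    amplicon genotyping.
    """
    from cyvcf2 import VCF  # optional reader; imported on demand

    vcf = VCF(str(path))
    names = vcf.samples
    rows = []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            continue
        for i, sname in enumerate(names):
            if sample is not None and sname != sample:
                continue
            rows.append((sname, var.CHROM, var.POS,
                         int(ad[i][0]), int(ad[i][1])))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos",
                                       "ref_reads", "alt_reads"])
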
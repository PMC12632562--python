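"""SSNG exonic-splicing-enhancer motif counting, enrichment, and metagenes.

The SSNG motif family is the set of 4-mers with a strong base (G or C) at
positions 1-2, any base at position 3 and G at position 4 — 16 variants in
all, covering the CCNG class (bound more tightly by mutant SRSF2) and the
GGNG class (bound more weakly).  Counting is on the sense-oriented exon
sequence; overlapping occurrences all count; windows containing N never
match.

Enrichment for a variant is the pseudocounted ratio of its total count in
exons with increased inclusion to its total in exons with decreased
inclusion.  Metagene profiles anchor two windows at the cassette exon's
3' and 5' splice sites, total per-position motif starts within each set,
and report log2((inc+pc)/(dec+pc)) with percentile-bootstrap confidence
bands over exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MOTIF_LEN = 4

SSNG_VARIANTS = tuple(
    s1 + s2 + n + "G" for s1 in "CG" for s2 in "CG" for n in "ACGT"
)
CCNG_VARIANTS = tuple(v for v in SSNG_VARIANTS if v.startswith("CC"))
GGNG_VARIANTS = tuple(v for v in SSNG_VARIANTS if v.startswith("GG"))

_ALPHABET = set("ACGTN")


@dataclass
class ExonRecord:
    exon_id: str
    sequence: str
    exon_start: int
    exon_end: int

    def __post_init__(self):
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"exon {self.exon_id}: sequence must be uppercase ACGTN, "
                f"found {sorted(bad)}"
            )
        if not (0 <= self.exon_start <= self.exon_end <= len(self.sequence)):
            raise ValueError(f"exon {self.exon_id}: exon interval outside record")

    @property
    def exon_seq(self) -> str:
        return self.sequence[self.exon_start:self.exon_end]


@dataclass
class ExonSequenceSet:
    """A labeled set of exon+flank sequences (sense orientation)."""

    label: str  # increased | decreased
    records: list[ExonRecord] = field(default_factory=list)

    @classmethod
    def from_dicts(cls, label: str, dicts) -> "ExonSequenceSet":
        return cls(label, [ExonRecord(d["exon_id"], d["sequence"],
                                      d["exon_start"], d["exon_end"])
                           for d in dicts])

    def __len__(self):
        return len(self.records)


@dataclass
class MotifEnrichment:
    motif: str
    count_increased: int
    count_decreased: int
    mean_enrichment: float
    log2_enrichment: float
    per_exon_enrichment: float | None = None  # size-normalized variant


def count_motifs(sequence: str, patterns=SSNG_VARIANTS) -> dict[str, int]:
    """Sliding-window occurrence counts for each pattern, zero-filled.

    Overlapping occurrences all count; any window containing N never
    matches.  Lowercase or non-nucleotide characters are rejected.
    """
    bad = set(sequence) - _ALPHABET
    if bad:
        raise ValueError(f"sequence must be uppercase over ACGTN, found {sorted(bad)}")
    counts = dict.fromkeys(patterns, 0)
    want = set(patterns)
    for i in range(len(sequence) - MOTIF_LEN + 1):
        w = sequence[i:i + MOTIF_LEN]
        if w in want:
            counts[w] += 1
    return counts


def _set_totals(seqset: ExonSequenceSet, motif: str) -> int:
    return sum(count_motifs(r.exon_seq, (motif,))[motif] for r in seqset.records)


def mean_enrichment(increased: ExonSequenceSet, decreased: ExonSequenceSet,
                    motif: str, pseudocount: float = 1.0) -> MotifEnrichment:
    """Pseudocounted increased/decreased count ratio for one motif variant.

    Totals run over exon intervals only (flanks excluded).  When the two
    sets differ in size a per-exon-normalized ratio (totals divided by set
    sizes) is reported alongside the raw ratio.
    """
    if len(increased) == 0 or len(decreased) == 0:
        raise ValueError(
            "both exon sets must be non-empty; the ratio is undefined on an "
            "empty set even with a pseudocount"
        )
    ci = _set_totals(increased, motif)
    cd = _set_totals(decreased, motif)
    ratio = (ci + pseudocount) / (cd + pseudocount)
    per_exon = None
    if len(increased) != len(decreased):
        per_exon = ((ci / len(increased) + pseudocount)
                    / (cd / len(decreased) + pseudocount))
    return MotifEnrichment(
        motif=motif, count_increased=ci, count_decreased=cd,
        mean_enrichment=ratio, log2_enrichment=float(np.log2(ratio)),
        per_exon_enrichment=per_exon,
    )


def enrichment_table(increased: ExonSequenceSet, decreased: ExonSequenceSet,
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """One row per SSNG variant."""
    rows = [mean_enrichment(increased, decreased, m, pseudocount)
            for m in SSNG_VARIANTS]
    return pd.DataFrame(
        {
            "motif": [r.motif for r in rows],
            "count_increased": [r.count_increased for r in rows],
            "count_decreased": [r.count_decreased for r in rows],
            "mean_enrichment": [r.mean_enrichment for r in rows],
            "log2_enrichment": [r.log2_enrichment for r in rows],
            "per_exon_enrichment": [r.per_exon_enrichment for r in rows],
        }
    )


def class_enrichment(increased: ExonSequenceSet, decreased: ExonSequenceSet,
                     motif_class: str, pseudocount: float = 1.0) -> MotifEnrichment:
    """Enrichment pooled over the four variants of one class (CCNG or GGNG)."""
    variants = _class_variants(motif_class)
    ci = sum(_set_totals(increased, m) for m in variants)
    cd = sum(_set_totals(decreased, m) for m in variants)
    ratio = (ci + pseudocount) / (cd + pseudocount)
    per_exon = None
    if len(increased) != len(decreased):
        per_exon = ((ci / len(increased) + pseudocount)
                    / (cd / len(decreased) + pseudocount))
    return MotifEnrichment(motif_class, ci, cd, ratio, float(np.log2(ratio)),
                           per_exon)


def _class_variants(motif_class: str):
    table = {"CCNG": CCNG_VARIANTS, "GGNG": GGNG_VARIANTS, "SSNG": SSNG_VARIANTS}
    if motif_class not in table:
        raise ValueError(f"motif_class must be one of {sorted(table)}")
    return table[motif_class]


def bootstrap_enrichment_ci(increased: ExonSequenceSet,
                            decreased: ExonSequenceSet,
                            motif_class: str = "CCNG",
                            pseudocount: float = 1.0,
                            n_bootstrap: int = 1000,
                            seed: int | None = None) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI for the pooled class enrichment ratio,
    resampling exons with replacement within each set."""
    variants = _class_variants(motif_class)
    ci = np.array([sum(count_motifs(r.exon_seq, variants).values())
                   for r in increased.records], dtype=float)
    cd = np.array([sum(count_motifs(r.exon_seq, variants).values())
                   for r in decreased.records], dtype=float)
    rng = np.random.default_rng(seed)
    n_i, n_d = ci.size, cd.size
    wi = rng.multinomial(n_i, np.full(n_i, 1.0 / n_i), size=n_bootstrap)
    wd = rng.multinomial(n_d, np.full(n_d, 1.0 / n_d), size=n_bootstrap)
    ratios = (wi @ ci + pseudocount) / (wd @ cd + pseudocount)
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# metagene


def _position_matrix(seqset: ExonSequenceSet, variants, w_exonic: int,
                     w_intronic: int) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Per-exon, per-position motif-start indicator counts.

    Columns are (anchor, offset) pairs: 3'ss anchor covers intronic offsets
    -w_intronic..-1 then exonic 0..w_exonic-1; the 5'ss anchor mirrors this
    (exonic -w_exonic..-1, intronic 0..w_intronic-1).  A motif belongs to
    the offset of its start position.
    """
    cols_3 = [("3ss", o) for o in range(-w_intronic, w_exonic)]
    cols_5 = [("5ss", o) for o in range(-w_exonic, w_intronic)]
    columns = cols_3 + cols_5
    want = set(variants)
    mat = np.zeros((len(seqset.records), len(columns)), dtype=np.int32)
    for i, rec in enumerate(seqset.records):
        seq = rec.sequence
        if rec.exon_start < w_intronic or len(seq) - rec.exon_end < w_intronic + MOTIF_LEN - 1:
            raise ValueError(
                f"record {rec.exon_id}: intronic window {w_intronic} exceeds "
                f"available flank"
            )
        if rec.exon_end - rec.exon_start < w_exonic:
            raise ValueError(
                f"record {rec.exon_id}: exonic window {w_exonic} exceeds exon length"
            )
        j = 0
        for anchor, off in columns:
            pos = (rec.exon_start + off) if anchor == "3ss" else (rec.exon_end + off)
            if seq[pos:pos + MOTIF_LEN] in want:
                mat[i, j] += 1
            j += 1
    return mat, columns


def metagene_profile(increased: ExonSequenceSet, decreased: ExonSequenceSet,
                     motif_class: str = "CCNG",
                     window: tuple[int, int] = (50, 50),
                     n_bootstrap: int = 1000, seed: int | None = None,
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """Positional log2 enrichment profile around cassette-exon splice sites.

    window is (exonic nt, intronic nt).  Returns a frame with columns
    anchor, offset, log2_ratio and, when n_bootstrap > 0, ci_low/ci_high
    from a seeded percentile bootstrap resampling exons with replacement
    within each set.
    """
    if n_bootstrap < 0:
        raise ValueError("n_bootstrap must be >= 0")
    w_e, w_i = window
    variants = _class_variants(motif_class)
    mat_inc, columns = _position_matrix(increased, variants, w_e, w_i)
    mat_dec, _ = _position_matrix(decreased, variants, w_e, w_i)

    tot_inc = mat_inc.sum(axis=0)
    tot_dec = mat_dec.sum(axis=0)
    with np.errstate(divide="ignore"):  # pseudocount 0 legitimately yields -inf
        log2_ratio = np.log2((tot_inc + pseudocount) / (tot_dec + pseudocount))

    out = pd.DataFrame(
        {
            "anchor": [a for a, _ in columns],
            "offset": [o for _, o in columns],
            "log2_ratio": log2_ratio,
        }
    )
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n_i, n_d = len(increased), len(decreased)
        wi = rng.multinomial(n_i, np.full(n_i, 1.0 / n_i), size=n_bootstrap)
        wd = rng.multinomial(n_d, np.full(n_d, 1.0 / n_d), size=n_bootstrap)
        bi = wi.astype(float) @ mat_inc
        bd = wd.astype(float) @ mat_dec
        boots = np.log2((bi + pseudocount) / (bd + pseudocount))
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
        # percentile intervals are widened, if needed, to bracket the point
        # estimate so the band is always interpretable around the line
        out["ci_low"] = np.minimum(lo, log2_ratio)
        out["ci_high"] = np.maximum(hi, log2_ratio)
    return out
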
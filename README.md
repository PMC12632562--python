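# splicepharm

Analysis pipeline for studying how spliceosome-mutant leukemias
(prototypically *SRSF2* P95H/L/R) rewire exon inclusion and how that
rewiring tracks with drug sensitivity. It covers the three quantitative
arms such a study needs:

- **Splicing** — per-sample percent-spliced-in (Ψ) from inclusion/exclusion
  junction reads via a Beta-Binomial posterior, differential-inclusion
  calling between mutant and wild-type conditions with a Savage–Dickey
  Bayes factor (significant when |ΔΨ| ≥ 0.10 and BF ≥ 5), per-event-class
  summaries, and Ψ grouped by mutant-allele dosage.
- **Motifs** — occurrence counts of the 16 SSNG exonic-splicing-enhancer
  4-mers (S ∈ {G,C}; CCNG vs GGNG subfamilies), increased/decreased
  enrichment ratios with bootstrap CIs, and positional metagene
  log₂-enrichment profiles around cassette-exon splice sites.
- **Pharmacology & genotyping** — DMSO-normalized dose-response curves;
  drug sensitivity scores (DSS: normalized area of inhibition above an
  activity threshold over log₁₀ concentration); growth-rate inhibition
  metrics (GR, GR₅₀); four-parameter-logistic IC₅₀ fits; Mann–Whitney,
  OLS VAF-vs-DSS regression and ANOVA/Tukey group statistics; and
  mutant-allele copy calls from amplicon VAF (triploid rule: 1–33% → 1
  copy, 34–66% → 2, 67–100% → 3).

A synthetic-data module generates every input with planted ground truth
(binomial junction counts at specified Ψ, exon sequences with planted
motif rates, Hill-curve viability plates, binomial allele reads), so the
whole pipeline is testable end to end without external data. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from splicepharm import (SimConfig, gen_splicing_dataset, gen_motif_sets,
                         run_differential_analysis, summarize_by_class,
                         ExonSequenceSet, class_enrichment,
                         infer_allele_copies, mann_whitney)

cfg = SimConfig(n_events=200, delta_psi=0.3, read_depth=200.0, seed=42)
events, counts, truth = gen_splicing_dataset(cfg)
calls = run_differential_analysis(events, counts)
print(calls.head(3).round(3).to_string(index=False))
print("significant:", int(calls.significant.sum()), "of", len(calls))
```

```
event_id event_class  psi_wt  psi_mut  delta_psi  bayes_factor  significant direction
  E00001         MXE   0.512    0.397     -0.115         1.832        False      none
  E00002          CE   0.654    0.583     -0.071         0.378        False      none
  E00003        A5SS   0.433    0.557      0.124         2.311        False      none
significant: 100 of 200
```

E00001 shows why both thresholds matter: its |ΔΨ| clears 10% but a Bayes
factor of 1.8 means the junction evidence cannot rule out a chance
fluctuation, so it is not called. Exactly the 100 events planted with a
true ΔΨ of ±0.3 are recovered. Class totals
(`summarize_by_class(calls, events)`) split those 100 calls by event type
and direction, cassette exons dominating (28 increased / 23 decreased).

Motif enrichment on simulated exon sets with planted enhancer bias
(CCNG motifs in increased-inclusion exons, GGNG in decreased):

```python
inc, dec, _ = gen_motif_sets(500, SimConfig(seed=7))
inc = ExonSequenceSet.from_dicts("increased", inc)
dec = ExonSequenceSet.from_dicts("decreased", dec)
for cls in ("CCNG", "GGNG"):
    r = class_enrichment(inc, dec, cls)
    print(f"{cls}: mean_enrichment={r.mean_enrichment:.2f} log2={r.log2_enrichment:+.2f}")

print("VAF 50% on triploid locus ->", infer_allele_copies(0.50).mutant_copies, "mutant copies")
u, p = mann_whitney([31.2, 28.4, 25.1, 33.0], [11.0, 8.9, 14.2, 6.5])
print(f"Mann-Whitney U={u}, p={p:.4f}")
```

```
CCNG: mean_enrichment=2.97 log2=+1.57
GGNG: mean_enrichment=0.31 log2=-1.69
VAF 50% on triploid locus -> 2 mutant copies
Mann-Whitney U=16.0, p=0.0286
```

The enrichment ratios recover the planted direction — CCNG ~3-fold
enriched among increased-inclusion exons, GGNG mirrored below 1. A 50%
variant allele frequency on a three-copy locus maps to two mutant
alleles. The two DSS groups of four are completely separated (U = 16),
which full enumeration of all 70 assignments scores at the smallest
attainable exact two-sided p, 2/70 ≈ 0.0286.

## Command-line pipeline

```bash
splicepharm all --outdir run1 --seed 7        # simulate + every stage
splicepharm splice --outdir run1              # rerun one stage in place
```

Outputs are TSV/BED/FASTA/JSON with JSON sidecars recording parameters
and seeds; `run_report.json` carries per-stage timings, record counts and
sha256 checksums of every output (two runs with the same seed match
checksum-for-checksum).

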
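# trescan

Response-element grammar scanning and ChIP peak analytics for nuclear
hormone receptors.

Thyroid hormone receptor β (TRβ) and its relatives bind DNA at response
elements built from AGGTCA-like hexamer half-sites arranged as direct,
everted or inverted repeats with characteristic spacers (DR-n, ER-n,
IP-n). Interpreting a genome-wide TRβ ChIP experiment means answering a
handful of quantitative questions: how often does each element grammar
occur inside the bound peaks relative to the genome at large; what
consensus do the strongest peaks define; where do peaks sit relative to
gene anatomy; how much does the binding landscape change with hormone;
and how does binding near transcription start sites (TSS) relate to which
genes the hormone induces or represses. `trescan` implements that whole
analysis as a tested Python library plus a small CLI, driven end-to-end
by a synthetic-study generator with planted ground truth, so every stage
can be exercised and validated without any external downloads.

It is intended for regulatory-genomics analysts who have peak calls
(BED), a genome (FASTA), gene models (refFlat) and a small expression
matrix, and want transparent, reproducible versions of the standard
peak-analytics computations.

## The core quantities

For a motif *m* (an IUPAC pattern or a dyad `LEFT-k-RIGHT`, where *k* is
the spacer in bp) and a region set *R*, scanning is bidirectional (both
strands; a self-reverse-complementary footprint counts once) and
overlapping occurrences all count. The package reports:

- **occurrence rate** `r(R, m) = total hits / total bp` (length
  normalized) and the **fraction of regions with ≥ 1 hit**;
- **fold enrichment** `F = r(peaks, m) / r(background, m)` where the
  background is the whole genome, the genome minus the peaks, or any
  explicit region set;
- a **position frequency matrix** built by anchoring each top-ranked peak
  on its best half-site seed match (re-oriented to the seed strand),
  its IUPAC consensus (majority base at ≥ 0.6, else the smallest
  degenerate code covering ≥ 0.8 of the column), and the corresponding
  log2-odds PWM `log2((c_b + λ·bg_b) / (n + λ) / bg_b)`;
- a **feature-class partition** of peaks (promoter > 5′UTR > 3′UTR >
  exon > intron > downstream > intergenic, classified at the peak
  midpoint with a 5 kb promoter/downstream window) with per-class fold
  versus the genome's bp composition, plus TSS-centred frequency
  profiles and shared/condition-specific peak counts;
- **regulated-gene calls** from `log2(intensity + 50)` quantile-normalized
  expression via a moderated two-sample t (empirical-Bayes variance
  shrinkage) with Benjamini–Hochberg adjustment and a 1.7-fold cutoff,
  and the fraction of each gene class with a peak within 1 / 5 / 25 kb
  of the TSS.

## Worked example

```python
from trescan import (SimulationConfig, simulate_study, parse_motif_notation,
                     fold_enrichment, condition_overlap, region_occurrences)

bundle = simulate_study(SimulationConfig(seed=1))   # genome + genes + peaks + expression
dr4 = parse_motif_notation("AGGnCA-4-AGGnCA")       # direct repeat, 4 bp spacer

regions = bundle.peak_regions()
occ = region_occurrences(regions, bundle.genome, dr4)
res = fold_enrichment(regions, bundle.genome, dr4, exclude_foreground=True)
print(f"peaks with a DR-4 element: {100*occ.fraction_with_hit:.1f}%")
print(f"DR-4 rate in peaks: {res.foreground.rate_per_bp:.2e} per bp")
print(f"fold enrichment vs background: {res.fold_enrichment:.2f}")

ov = condition_overlap(bundle.peak_sets['untreated'], bundle.peak_sets['T3'])
print(f"peaks shared between conditions: {100*ov['fraction_shared']:.0f}%")
```

prints

```
peaks with a DR-4 element: 30.9%
DR-4 rate in peaks: 1.08e-03 per bp
fold enrichment vs background: 10.55
peaks shared between conditions: 30%
```

The default synthetic study plants a DR-4 element ten times denser inside
peaks than outside and makes 30% of peaks shared between the untreated
and hormone-treated conditions — the measured 10.55× and 30% recover
those planted truths. The same objects feed the annotation, consensus
and expression-association stages (see `trescan --help` for the CLI
subcommands; `trescan pipeline --seed 3 --outdir out/` runs everything
end to end and writes TSV reports).

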
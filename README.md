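# sweepscan

Window-based selection-signature scanning for multi-population phased
haplotype data, plus local-GEBV QTL discovery and an overlap-enrichment test
between the two — with a bundled forward Wright–Fisher simulator that
generates everything the pipeline consumes.

## What it computes

All statistics are computed in sliding windows (default 250 kb, 50 kb step,
anchored at bp 0, 0-based half-open internally):

- **HAPH** — haplotype homozygosity: the population variance of
  distinct-haplotype frequencies in non-overlapping 30/31-SNP segments,
  averaged into windows by segment midpoint and standardized by dividing by
  the mean over all windows (so the genome-wide mean is 1). Top-fraction
  windows closer than 1 Mb merge into candidate sweep regions.
- **|iHS|** — the ancestral allele is called by outgroup majority; EHH decay
  curves are integrated (trapezoid, decay threshold 0.5) for the ancestral
  and derived allele at each SNP (MAF > 0.001); the log10 iEHH ratio is
  standardized to mean 0 / SD 1 in 20 equal-width bins of ancestral-allele
  frequency; each window keeps its maximum |iHS|.
- **F_ST** — per-SNP pairwise F_ST from allele frequencies,
  `[(p1-p̄)² + (p2-p̄)²]/2 / [p̄(1-p̄)]`, averaged per window for every
  population pair (8 populations → 28 pairs), standardized per pair; the
  dairy-vs-beef contrast tests cross-group vs within-group standardized
  values window by window with a one-sided Mann–Whitney U test.
- **Local GEBV variance** — SNP effects from ridge (SNP-BLUP) or a
  BayesR-style 4-component mixture Gibbs sampler; the variance across animals
  of each window's local GEBV flags putative QTL windows (top 5%).
- **Enrichment** — a 1-df chi-squared test on the 2×2 overlap of top-5%
  selection windows and top-5% QTL windows, with every cell divided by 5
  (= width/step, the number of times each genome segment is counted across
  overlapping windows) and Bonferroni adjustment across tests.

The simulator (`sweepscan.simulate`) provides drift-differentiated breeds
from a common base, optional hard sweeps (genic selection, deterministic
update + binomial sampling, retry-on-loss), a polygenic trait under optional
truncation selection, and an outgroup panel for ancestral-allele calling,
all seeded and bit-reproducible.

## CLI

```bash
sweepscan simulate --seed 1 --out simulated/           # synthetic dataset
sweepscan scan-haph --vcf simulated/panels.vcf --samples simulated/samples.tsv
sweepscan scan-ihs  --vcf ... --samples ... --outgroup simulated/outgroup.tsv
sweepscan scan-fst  --vcf ... --samples ... --groups groups.tsv
sweepscan gebv-var  --vcf ... --samples ... --phenotypes ... --trait trait --population holstein
sweepscan enrich    --selection haph_windows.tsv --qtl gebv_windows.tsv
sweepscan run --seed 1 --out results/                  # whole pipeline
```

`run` accepts a YAML config (see `sweepscan.pipeline.RunConfig`); every knob
defaults to the published analysis setting. Outputs are TSV window tables
(1-based inclusive coordinates, noted in a header comment), a sweep-region
BED (0-based half-open), per-SNP iHS tables, an enrichment report, and a
manifest with config hash, seed and file checksums — identical config + seed
reproduce identical outputs.

## Layout

```
src/sweepscan/
  core.py        GenomeMap, HaplotypePanel, SimulationTruth
  simulate.py    forward Wright-Fisher simulator (breeds, sweeps, trait, outgroup)
  windows.py     grid construction, point assignment, standardization, flags
  haph.py        segment partition, HAPH, window aggregation, sweep regions
  ihs.py         ancestral calling, EHH/iEHH, iHS standardization, window max
  fst.py         pairwise F_ST, per-pair standardization, group contrast
  gebv.py        ridge / BayesR effect models, local-GEBV window variance
  enrichment.py  overlap chi-squared, Bonferroni, report
  io.py          phased VCF, window TSV, BED, truth JSON
  pipeline.py    end-to-end orchestration + manifest
  cli.py         click subcommands
```
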
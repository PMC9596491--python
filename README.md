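# sexscan

Identification of sex chromosomes from population genotype data in
male-heterogametic (XY) species, with companion analyses for repeat-landscape
divergence and karyotype–scaffold concordance.

## The problem

In an XY system, three population-genomic signals mark the X chromosome in a
panel of males and females genotyped against a female-derived assembly:

1. **Depth ratio** `r = mean(male depth) / mean(female depth)` per SNP.
   Autosomes sit near `r = 1`; the hemizygous region of the X (HRX) sits near
   `r = 0.5` because males carry one copy.
2. **Sex GWAS.** Fixed differences between X and Y gametologs appear as
   male-limited heterozygous calls when Y reads map onto the X scaffold. A
   two-sided Fisher exact test on the allelic 2×2 table (sex × allele), with
   Bonferroni control `α / M` over the `M` tested markers, flags these
   Y-linked SNPs.
3. **Relative male heterozygosity** `ΔH = H_m − H_f`. Y-linked SNPs show
   `ΔH ≫ 0`; X-linked polymorphisms show `ΔH ≤ 0` because hemizygous males
   are called homozygous.

`sexscan` applies the standard filters (genotype depth < 4 reads → missing;
≥ 70% site completeness; minor allele frequency > 5%), computes the three
statistics, calls depth-ratio outliers with the Tukey rule
(quartiles ± 1.5·IQR, type-7 quantiles), classifies SNPs
(Y-linked = significant GWAS hit; X-linked = low-depth outlier with
`ΔH ≤ 0`; duplicated-candidate = significant hit with *high* depth ratio),
and finally segments the focal scaffold into PAR1 / HRX / PAR2 by tallying
the percent of sex-linked SNPs in 1 Mb windows and taking the maximal
above-threshold run.

Because real resequencing panels are large, the package ships a synthetic
population generator that reproduces exactly the statistical structure the
method relies on — Hardy–Weinberg autosomes, Poisson depth proportional to
copy number, gametolog heterozygosity, X-restricted polymorphism — with
ground truth, so every stage is verifiable at desk scale.

Two further modules mirror the companion genome analyses:

* **repeat_landscape** — CpG-corrected Kimura 2-parameter divergence of
  repeat inserts from family consensus
  (`K = −½·ln((1−2p−q)·√(1−2q))`, transitions at consensus CpG sites
  weighted 1/10), landscape binning by `floor(100·K)`, and a per-family
  Kruskal–Wallis comparison of the recent (`K ≤ 10%`) fraction between two
  genomes.
* **karyotype_concordance** — per-chromosome size estimates from karyotype
  area fractions (`est_i = area_i / Σ areas × assembly size`) regressed
  against scaffold sizes (OLS, r², F test).

## Worked example

The numbered scripts under `analysis/` run the whole study at desk scale and
write their tables under `results/`:

```bash
python analysis/01_simulate_population.py
python analysis/02_identify_sex_chromosome.py
```

prints

```
simulated 20406 SNPs x 50 samples (seed 1); truth spans: PAR1 1-21000000, HRX 21000001-92000000, PAR2 92000001-111000000
filtered sites: 19868
significant sex-GWAS markers: 285 (100.0% on scaffold_7)
male-het excess among hits: 100.0%
class counts: {'autosomal': 17194, 'X-linked': 2389, 'Y-linked': 284, 'duplicated-candidate': 1}
recovered spans on scaffold_7: {'PAR1': [1, 21000000], 'HRX': [21000001, 92000000], 'PAR2': [92000001, 111000000]}
```

Reading: of ~20k filtered SNPs, the Fisher GWAS finds 285 Bonferroni-
significant markers, all on the X scaffold and all with excess male
heterozygosity (Y-linked gametologs); ~2.4k low-depth-ratio outliers with
`ΔH ≤ 0` are called X-linked; and the windowed tally recovers the planted
21 / 71 / 19 Mb PAR1 / HRX / PAR2 structure exactly.
`analysis/03_boundary_recovery.py` repeats this over 10 seeds (0 bp boundary
error in all of them), `04_repeat_landscapes.py` contrasts a recent- against
an ancient-insertion genome (Kruskal–Wallis p < 1e-11 for the shifted
classes), and `05_karyotype_concordance.py` regresses scaffold sizes on
area-fraction estimates (r² = 0.999 at 3% measurement noise).

The same stages are available as subcommands of the `sexscan` CLI
(`simulate`, `filter`, `gwas`, `classify`, `segment`, `repeats`,
`karyotype`, `run-all`) for user-supplied VCF + sex-map inputs.

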
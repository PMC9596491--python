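# Methods

## Population model and what the simulator emulates

The simulator generates the genotype/depth matrix a diploid variant caller
would emit for a panel of `n_m` males and `n_f` females from an XY species
mapped against a female (XX) assembly. Default study conditions: 25 males +
25 females; a genome of three autosomal scaffolds (150, 130, 120 Mb) plus a
111 Mb X scaffold split into PAR1 (21 Mb), HRX (71 Mb) and PAR2 (19 Mb);
SNPs at exponentially distributed spacing with mean 25 kb (≈ 20k sites,
≥ 2000 per compartment of interest); alt-allele frequencies uniform on
[0.05, 0.5].

Per-site behaviour by compartment:

* **autosomal / PAR** — Hardy–Weinberg genotypes in both sexes, copy
  number 2 everywhere.
* **HRX, X-restricted polymorphism** (fraction 0.9 of HRX sites) — females
  Hardy–Weinberg diploid; males draw a single X allele and are *called
  homozygous* for it, because diploid-assuming callers emit hom calls for
  haploid data. Male copy number 1.
* **HRX, gametolog** (fraction 0.1) — a fixed X–Y difference. Females are
  hom-ref (copy 2). Each male is called heterozygous with probability ρ
  (`y_mapping_rate`, default 1): the event that reads from the diverged Y
  copy co-map onto the X scaffold. The same Bernoulli draw adds the Y copy
  to his copy number (1 + ρ in expectation), so gametolog sites combine
  male heterozygosity with near-normal male depth — which is why they must
  be caught by the GWAS, not the depth ratio.
* Any HRX remainder (when the two fractions sum below 1) is monomorphic
  hemizygous filler.

Depth is `Poisson(copy_number × depth_per_copy)` per sample per site
(default per-copy mean 10, so diploid mean 20). An optional
`depth_overdispersion` parameter switches to gamma–Poisson mixing; the
default is pure Poisson, the simplest model consistent with ratio logic
(`E[r] = 0.5` at male copy 1, `1.0` at copy 2). Genotypes are masked
completely at random at `dropout_rate` = 0.01; the depth-threshold filter
adds the depth-dependent missingness mechanism downstream.

Deliberately **not** emulated: linkage disequilibrium and genealogical
correlation between sites (every site is independent), population structure,
allele-frequency spectra from a demographic model, mapping and calling
artifacts other than the Y-co-mapping event, and read-level error. Passing
recovery tests therefore demonstrate that the statistics and the
segmentation logic are correct under the stated sampling model — not that
the pipeline is robust to structure or artifacts in real resequencing data.

For the repeat module, the generator draws a uniform-random consensus,
solves per-site transition/transversion probabilities (2:1 ratio) so the
K2P closed form of the expected mismatch proportions equals the requested
divergence, and applies one round of independent per-site substitutions.
With `cpg_density > 0` it plants CpG dinucleotides and multiplies the
transition rate there by 10 — the hypermutation the estimator's 1/10 CpG
weight undoes. At `cpg_density = 0` the consensus is made CpG-free so the
correction is exactly a no-op under that setting. The karyotype generator
produces areas proportional to chromosome size with lognormal measurement
noise (default CV 3%), emulating an XX metaphase complement (each
chromosome's two homologs measured; the X contributes two X areas, no Y).

## Filters

Stage 1 masks genotypes supported by fewer than 4 reads; stage 2 drops sites
with data in less than 70% of samples (ties pass: non-missing fraction
≥ 0.70); stage 3 drops sites with minor allele frequency ≤ 5% (strictly
"larger than" survives). MAF is computed on the allele scale from observed
genotypes only — the package deliberately does not impute missing genotypes;
all downstream statistics are missing-aware instead. A mapping-quality
filter belongs to the caller and is out of reach of a GT:DP-only VCF.

## Sex GWAS

Each site is tested with a two-sided Fisher exact test on the allelic
(sex × allele) 2×2 table; allelic rather than genotypic coding is the
case/control convention of standard GWAS tooling and makes male-limited
heterozygosity visible as an allele-frequency contrast. The two-sided p sums
hypergeometric point probabilities ≤ the observed one, with the standard
`1 + 1e-7` relative tie tolerance; the implementation (log-gamma based) is
oracle-tested against exhaustive enumeration. Sites with any zero margin or
fewer than 2 non-missing samples in either sex are untested and excluded
from the Bonferroni denominator `M`, which counts tested markers only.

## Classification and thresholds

Depth-ratio outlier thresholds use the Tukey rule on the genome-wide `r`
distribution: quartiles by type-7 (linearly interpolated) quantiles,
bounds `Q1 − 1.5·IQR` and `Q3 + 1.5·IQR`. Type-7 is a documented choice
(the rule itself does not fix a convention) and is oracle-tested; thresholds
are computed genome-wide, not per scaffold, so that the autosomal bulk
defines "normal". Depth means include zero-depth samples — hemizygosity is a
depth signal, not missingness.

Class precedence: **duplicated-candidate** (significant *and* high-depth
outlier — the autosome/Y duplication signature of male coverage excess)
→ **Y-linked** (significant) → **X-linked** (low-depth outlier with
`ΔH ≤ 0`) → autosomal; undefined statistics give "unclassified". Y before X
resolves the rare site passing both rules. The duplicated class must be
checked before Y or it would be unreachable.

The sliding-window depth summary uses 2 Mb windows at 500 kb step and means
of `log2 r` (base 2 so halved coverage reads as −1); terminal partial
windows are retained.

## PAR/HRX segmentation

Sex-linked percentages are tallied in non-overlapping 1 Mb windows on the
focal scaffold (chosen as the scaffold carrying the largest share of all
sex-linked SNPs, overridable). The HRX is the maximal run of windows with
percent > τ, bridging up to 2 consecutive sub-threshold or SNP-free windows;
PARs are the flanks. τ is data driven: the maximum window percent observed
on non-focal scaffolds (an empirical null for misclassification noise) plus
one percentage point, floored at 5%. The run rule and τ are this module's
own contract — the underlying boundary criterion is otherwise
under-determined — and every run logs the values used. Under the default
conditions recovered boundaries land on the truth to within one window
(exactly, in the runs reported by `analysis/03_boundary_recovery.py`).

A caveat established during null testing: permuting sex *labels* destroys
the association statistics but not the depth ratio, which is a physical
consequence of each sample's true sex; a sex-unbalanced permutation can
leave an attenuated copy-number signal in the HRX. Label-permutation is
therefore a valid null for the GWAS but not for the depth channel; an
all-autosomal simulation is the clean full null (and reports no HRX).

## Repeat landscapes

`K = −½·ln((1−2p−q)·√(1−2q))` over ungapped, unambiguous aligned columns;
`p` is the (weighted) transition proportion, `q` the transversion
proportion. With CpG correction, a transition whose consensus position lies
in a consensus CpG dinucleotide (adjacency computed on the consensus,
skipping gaps) counts 1/10 — the convention of the standard repeat-
annotation tooling; the weight is switchable. Alignments with fewer than 20
usable columns are excluded; saturated alignments (log argument ≤ 0) are
flagged and dropped from landscapes rather than clamped, with logged counts.
Landscape bins are left-closed `[k%, (k+1)%)` on `floor(100·K)`; bin mass is
ungapped insert bp divided by genome size.

The recent-activity comparison takes the repeat *family* as observation
unit — a deliberate choice; element- or bin-level units would pseudo-
replicate within families — with value = the family's genome proportion at
`K ≤ 10%`, groups = the two genomes, and a Kruskal–Wallis test (midranks,
tie correction, chi-square with 1 df; degenerate all-tied input returns
H = 0, p = 1).

## Karyotype concordance

`est_i = area_i / Σ areas × assembly size` (estimates sum to the assembly
size by construction), then OLS of scaffold size on estimate. r² is
symmetric in the regression direction, so the headline statistic does not
depend on that choice; the slope's F test equals its t test with one
predictor.

## Numerical and scale choices

All randomness flows through one `numpy` Generator per simulation seed;
fixed seed ⇒ byte-identical outputs. Fisher p-values agree with exhaustive
enumeration to 1e-12 (tested for margins ≤ 12); quantiles, Kruskal–Wallis
and OLS are each cross-checked against independent re-implementations.
Problem sizes used throughout (≈20k SNPs × 50 samples per simulation; 10
seeds for boundary recovery; 20 for null calibration; 100 kb of alignment
per repeat class) keep each analysis in seconds-to-a-minute on one CPU while
leaving ≥ 2000 sites per compartment for the Monte-Carlo checks, whose
tolerances (±0.02 on mean depth ratios) sit several standard errors above
the sampling noise at that size.

## Known limitations

Independent-site simulation understates the variance of windowed statistics
relative to real linked data; the data-driven τ assumes at least one
non-focal scaffold to serve as a null; the depth model ignores GC and
mappability bias; the duplicated-candidate class is an interpretation, not a
validated call; and the karyotype analysis assumes one-to-one
chromosome–scaffold pairing.
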
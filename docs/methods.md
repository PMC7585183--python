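# Methods

## Scope and model

`sweepscan` detects artificial-selection footprints in a candidate-gene panel
by contrasting three populations sampled from a domestication series: wild
(ancestral), local (domesticated) and improved (modern breeding lines). It is
a windowed outlier scan, not a model-based (composite-likelihood or
haplotype) method: all inference is on per-site allele counts of biallelic
variants, and "selected" means jointly extreme in the empirical distribution
of three statistics over the scanned windows.

Each gene region is the gene span plus a 2,000-bp extension on the
strand-defined upstream side (clamped at the chromosome start), tiled with
1-kb windows advanced by 100 bp; the final window is truncated at the region
end and a region shorter than one window yields a single covering window.

### Statistics

* **π** — per-site unbiased heterozygosity `2a(n−a)/(n(n−1))` (`a` alternate
  alleles among `n` called allele copies; equal to the mean pairwise
  difference over allele-copy pairs), summed over a window's variant sites and
  divided by the full window length in bp. Invariant positions contribute 0;
  sites with fewer than two called alleles in a population are skipped. The
  per-bp denominator (rather than "number of genotyped sites") matches common
  selective-sweep practice for near-complete resequencing panels.
* **F_ST** — sample-size-corrected Hudson estimator per site, combined across
  a window as a ratio of averages (ΣN/ΣD). This estimator is robust to small
  and unequal panel sizes and has no within-population weighting artifacts; a
  Weir–Cockerham-style moment estimator on allele counts is available as
  `fst_estimator="wc"` because published scans do not always name their
  estimator and the two differ slightly on real panels. The choice is echoed
  in output metadata.
* **ROD** — `1 − π_derived/π_ancestral` per window; domestication uses
  (wild → local), breeding uses (local → improved).

Undefined values — ROD with zero ancestral π, F_ST with ΣD = 0, any statistic
in a population with fewer than two called alleles — propagate as NaN. They
are excluded from percentile pools and fail every selection criterion; they
are never coerced to 0 or 1. Indels participate in π/F_ST as ordinary
biallelic presence/absence markers.

### Thresholds and calls

Stage-specific cutoffs are empirical quantiles of the pooled window
distribution over all gene regions in the panel (the scan's own regions, not
a genome-wide background — this matters for comparing absolute cutoffs):
top 1% of F_ST, top 1% of ROD, bottom 5% of the derived population's π.
Quantiles use linear interpolation (the common type-7 convention; a
nearest-rank switch exists and the method tag is recorded). Window calls use
strict inequalities. A gene is selected when at least one of its windows is;
variants inside selected genes' regions are rescreened individually against
the *same* cutoffs, with per-site π, F_ST and ROD. Per-site π is a
heterozygosity (scale 0–0.5), not a per-bp density, so the π criterion at
site level effectively requires a near-monomorphic derived population — the
intended signature of a completed sweep.

One consequence worth stating: a site monomorphic in the *ancestral*
population has π_ancestral = 0 and therefore undefined ROD, so it can never
be called selected even when the derived population is fixed for the other
allele. The scan targets loci polymorphic in the ancestor and swept in the
derivative, which is the scientifically meaningful case.

### Variant effects

Coding effects use gene models (GFF3 CDS features) and the standard codon
table: SNPs in CDS are translated on the coding strand (reverse complement
for − genes) for the reference and alternate codon; indels touching CDS are
`cds_frameshift_or_indel`; positions in the strand-aware upstream flank are
`upstream_2kb`; everything else genic (introns, UTRs) collapses to
`other_genic`. The upstream boundary is measured from the gene span, not the
first CDS base. Domain overlap is a lookup of the affected residue in
user-supplied protein-coordinate intervals; domain *prediction* is out of
scope.

### TFBS gains and losses

Candidate regulatory variants are represented by 60-bp windows: 30 bp of 5′
flank, the allele, and 3′ flank filling to 60 bp (alternate windows change
length with indels; windows truncate, flagged, at contig ends). JASPAR-format
position frequency matrices are converted to log2-odds PWMs with a
background-weighted pseudocount (default 0.8, uniform background); both
strands are scanned at every offset and a motif is *present* when any offset
reaches a relative score `(score − min)/(max − min)` of at least 0.80 — the
common JASPAR-scan convention; no threshold is canonical and the flag is
recorded in outputs. Presence is per matrix identity, so a site that merely
shifts position is neither lost nor gained. Ambiguity bases (N) contribute 0
log-odds, i.e. score as background.

### Expression

Tissue-profile similarity is the Pearson correlation over tissues for every
unordered gene pair; the summary reports the full r matrix, the mean over the
upper triangle and the fraction of pairs above a cutoff (default 0.8).
Zero-variance genes carry no correlation information and are excluded with a
warning. Correlation is computed on raw abundances by default; a log2(x+1)
switch exists because r is scale-dependent and published values do not always
state the scale. qPCR fold changes use 2^−ΔΔCt with technical replicates
arithmetically averaged before differencing.

## The synthetic panel

`simulate_genotypes` is a frequency-perturbation model, deliberately not a
coalescent: no linkage, recombination or demography, just the marginal
allele-frequency structure the scan consumes.

* Wild allele frequencies are Beta(0.8, 0.8) — a U-shaped site-frequency
  spectrum typical of standing variation.
* Local = wild + N(0, σ=0.08) clamped to [0,1]; improved = local + N(0, 0.04).
  These drift scales give a low-divergence background (mean window F_ST
  wild–local ≈ 0.03) against which sweeps are outliers.
* In each designated sweep gene, a contiguous **sweep core** (default 2.5 kb
  of the 6-kb region, randomly placed) has each site's derived-population
  frequency pushed to its nearest boundary {0, 1} with probability s = 0.95.
  The core mimics the local footprint of a sweep: real selected regions are
  subintervals of a gene region, and a localized core concentrates the F_ST
  and ROD extremes on the same windows, which is what makes the joint
  criterion recover planted genes reliably. (A uniform whole-region sweep
  spreads the two 1% tails across different windows — F_ST rank is dominated
  by wild-frequency luck, ROD rank by escape counts — and recovery becomes
  erratic.)
* Variant density is 0.07/bp, mirroring the density of the motivating panel
  (~47.8k variants over 44 gene regions); 10% of variants are short indels;
  genotypes are drawn binomially per diploid sample and 5% of genotypes are
  masked as missing, comfortably under the 20% per-site filter.
* Default panel: 44 genes on separate contigs, 2 sweep genes, 20/20/10
  diploid samples per population, giving 2,244 windows and ~18.5k variants —
  a deliberately scaled-down panel that one scan processes in ~0.5 s.

What the generator does **not** emulate: linkage disequilibrium and hitchhiking
gradients, site-frequency correlations along the chromosome, sequencing error,
population substructure within groups, and selection on standing variation
with soft-sweep signatures. Passing recovery tests therefore demonstrates the
statistical machinery (windowing, estimators, thresholds, joint calling) under
the idealized frequency model, not power on real LD-structured data.

`simulate_expression` builds each gene as `scale · (w·common + (1−w)·noise)`
with lognormal common/noise profiles of matched scale; mean pairwise r grows
monotonically from ≈0 (w = 0) to 1 (w = 1). The default w = 0.79 was set by a
calibration sweep so the default panel's mean pairwise r lands in the
0.8–0.9 regime (≈0.85 across seeds) — the "strong shared tissue profile"
regime the expression module is meant to summarize.

`simulate_tfbs_fixture` plants an 8-bp maximal-information consensus
(counts 20/0/0/0 per column). At the fixture's relative-score threshold of
0.90 a hit requires an exact consensus (or reverse-complement) match — one
mismatch scores 1 − 1/8 = 0.875 — so a SNP inside the site destroys it, a SNP
completing a planted one-mismatch site creates one, and a 2-bp deletion
upstream of a site shifts it without changing presence. Backgrounds are
resampled (deterministically) until no accidental consensus occurs in any
scanned window, so the truth table is fixed by construction and independent
of the scanner.

## Numerical and interface choices

* Coordinates are 1-based inclusive at every file interface (VCF/GFF
  convention) and 0-based half-open internally for windows.
* Multi-allelic VCF records are split into biallelic records sharing a
  position; within a split record, alleles belonging to the other alternates
  are recorded as missing. Half-missing diploid calls contribute their known
  allele and one missing slot. Missingness is pooled over all samples and
  strictly greater than the cutoff removes a site.
* The tabular genotype dialect (`chrom pos ref alt` + one `a/b` column per
  sample) round-trips exactly through `write_table`/`load_variants` and is
  what the fixture writer emits.
* Thresholds require ≥ 20 defined windows per statistic; degenerate pools
  (all values equal) yield cutoffs nothing strictly exceeds, so the scan
  returns no calls rather than arbitrary ones.
* Determinism: every simulator consumes a single `numpy` Generator seeded
  from the config; identical config + seed reproduces byte-identical fixture
  bundles, and re-running the pipeline on unchanged inputs reproduces output
  tables byte-identically.

## Known limitations

* The percentile pool is the scanned panel itself; absolute cutoff values are
  therefore panel-dependent and not comparable across panels of different
  composition.
* Hudson F_ST is undefined for windows where every site lacks two called
  alleles in a population; such windows are reported with NaN and never
  called.
* TFBS presence/absence depends on the PFM set and the relative-score
  threshold; motif-set differences across database versions change gain/loss
  sets, which is why the module treats the PFM file as an input.
* The effect classifier handles single-nucleotide coding changes exactly but
  does not recompute protein consequences of indels (reported categorically
  as `cds_frameshift_or_indel`).
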
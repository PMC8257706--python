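# Methods

This note records the models, conventions and numerical choices behind
`hybrid-ase`, and what the synthetic-data validation does and does not
establish.

## Coordinates and strain orientation

VCF and SAM positions are 1-based; all internal interval arithmetic is
0-based half-open, with conversions confined to readers and writers. Genome
1 always carries the SNP table's reference allele (the reference-strain,
paternal role in the cross this package models); genome 2 carries the
alternate allele (maternal role). Reciprocal crosses are handled by the
`swap_strains` flag on the SNP readers rather than by re-deriving tables.

## SNP consensus and N-masking

Only biallelic single-base substitutions are used; indels and multi-allelic
records are dropped and counted. Intersecting two SNP tables keeps positions
present in both with agreeing alleles; allele-discordant positions are
dropped (counted), since a position whose alleles the two sources dispute
cannot be used for assignment. When the genome base at a SNP disagrees with
the recorded reference allele, the position is still masked and a warning is
counted: masking too much costs a little signal, masking too little
re-introduces alignment bias, so masking is the conservative side.

## Duplicate removal and allele assignment

PCR duplicates are collapsed on the conventional key (chromosome, 5′
position, strand, mate position), keeping the first record at each key; the
input must be coordinate-sorted. Assignment walks the CIGAR: M consumes
reference and read, N/D reference only, S/I read only, so a SNP under a
splice gap or deletion is uninformative. Base qualities are ignored —
assignment is a deterministic function of the aligned bases. A read (or
fragment, summing mates) with bases matching only genome 1 at covered SNPs
is GENOME1, only genome 2 GENOME2, both CONFLICTING, neither UNASSIGNED. A
base matching *neither* allele (a sequencing error or third allele) is
simply uninformative rather than conflicting, so a lone error cannot flip a
category. Conflicting fragments are excluded from both per-genome outputs
(they are counted in the summary); the four categories always partition the
input.

## Counting, filters, normalization

Fragment counting uses featureCounts paired-end defaults: ≥1 aligned base on
a gene's exon union counts the fragment for that gene, mates count once
together, and fragments touching the exons of more than one gene are
discarded as ambiguous. The low-expression filter keeps genes with strictly
more than 8 fragments summed over all samples of the comparison; X-linked
genes are removed first (the modelled hybrid lines are male; order does not
affect the result). Size factors are median-of-ratios with reference genes
those nonzero in every sample. Note an algebraic property often misstated:
scaling one sample's column by c scales its factor by c^((n−1)/n) — the
per-gene geometric means also move — while the factor *relative to any other
sample* scales by exactly c; tests assert the correct law. Allele-resolved
counts are divided by their sample's bulk size factor, so allelic ratios are
normalization-invariant. The allelic filter removes a gene only when
maternal+paternal normalized counts fall below 10 in *every* wild-type
replicate.

Marker Z-scores (for lineage-marker panels) divide each sample by its upper
quartile over nonzero genes, then by the sample's adjusted reference-gene
(e.g. beta-actin) value, then Z-score each gene across samples with ddof=1 —
the convention under which two samples give ±1/√2. Zero-spread genes get a
zero row with a warning.

## Allelic ratios, testing, classification

Per replicate, r = mat/(mat+pat) on normalized counts; zero-total replicates
are excluded from the mean; a gene with no informative replicate is NA. The
bands are inclusive: mean ratio ≤ 0.33 paternal, ≥ 0.67 maternal, otherwise
biallelic. Imbalance is tested on pooled **raw** integer counts (a
proportion test needs integers; normalization rescales totals but not
within-sample proportions) with the exact binomial two-sided test — doubling
the smaller tail, capped at 1 — or a chi-square-with-continuity variant by
flag; BH correction runs across genes. Wild-type imprinting calls require
both the ratio band and q < 0.05; mutant classification uses the band alone
(a flag changes either behavior), since loss of imprinting should not be
masked by the mutant's own significance gating.

Condition comparison for a wild-type monoallelic gene: a mutant ratio inside
(0.33, 0.67) is full loss ("Biallelic"); outside the band, a flip across 0.5
by more than δ is "All. bias inverted"; a move toward 0.5 by more than δ in
the same direction is "All. bias reduced"; otherwise "Unchanged". δ = 0.1 by
default — a deliberate, configurable buffer so replicate noise near the
band's edge does not masquerade as a bias change.

## Differential expression

A deliberately simplified NB Wald analysis: per gene,
K_ij ~ NB(mean = s_j·q_i·2^(β_i·x_j), dispersion α_i) with Var = μ + αμ².
Dispersion: method-of-moments from residual variance around group means of
normalized counts, with the E[q̂²] noise term subtracted from the
denominator so the estimator is not biased downward; a trend α(q) = a0 +
a1/q is fitted across genes by least squares on the *unfloored* MoM values
(their sampling distribution is right-skewed, so trimmed or median fits
would pull the trend low); gene-wise estimates are shrunk toward the trend
in log space with fixed prior variance 0.05 against a log-MoM sampling
variance of ~1.0 at typical replicate numbers — i.e. heavy moderation,
appropriate when per-gene dispersion information is weak. Final values are
floored at 1% of the trend. β and its SE come from a per-gene NB GLM fit
(IRLS, log link, log s_j offset); p = two-sided normal tail of β̂/SE; BH
across genes. Genes with identical counts everywhere, or zero counts in both
groups, are returned as log2FC 0, p 1; a gene with one all-zero group is
refit with +0.5 pseudocounts to keep the MLE finite.

Small-sample calibration, measured by the package's own null simulations:
at 3 vs 3 replicates (μ = 100, α = 0.1) the realized type-I rate at nominal
p < 0.05 is ≈ 0.054 even when the *true* dispersion is supplied — the usual
mild liberality of a plug-in normal Wald test — and the dispersion-estimation
machinery adds nothing measurable on top. Calibration tightens with more
replicates; planted log2FC = 2 is recovered with |bias| < 0.02 at 3+3 and
< 0.05 at 20+20. There is no outlier handling, independent filtering or LFC
shrinkage, and no equivalence with any specific DE tool is claimed.

Enrichment of a gene list among DE calls is the upper-tail hypergeometric
P(X ≥ k) with the universe N = genes surviving the low-count filter (the
set actually tested); the list (e.g. known imprinted genes) is a plain
one-gene-per-line input.

## Peak statistics

Interval intersection reports each peak of set A overlapping ≥1 bp of set B
once (`bedtools intersect -u` semantics); half-open abutment is not overlap.
Gene-to-peak distance anchors on the full gene span: 0 on overlap, otherwise
the half-open gap in bp (bookended intervals therefore also read 0; the
bedtools `-d` column instead reports gap+1 — a ≤1 bp convention difference
that cannot affect any downstream threshold here). Genes on peak-free
chromosomes are NA and excluded from CDFs. The two-sample KS test takes
D = sup|ECDF_x − ECDF_y| with the asymptotic Kolmogorov p-value at effective
size n_x·n_y/(n_x+n_y); with the hundreds of genes typical here the
asymptotic tail is adequate, and no exact small-sample variant is provided.

## The synthetic-data generator

The generator's defaults are the modelled study conditions: two biological
replicates per condition, ~4 SNPs/kb strain divergence, true maternal
fractions 0.95 / 0.05 / 0.5 for maternal / paternal / biallelic genes,
complete loss of imprinting (ρ → 0.5) in the mutant, NB dispersion 0.05,
lognormal gene means around 2^7, library-size factors in [0.7, 1.4],
80 bp paired reads on 250 bp fragments. Counts are gamma-Poisson draws;
maternal counts are binomial thinnings of the totals, so maternal + paternal
= bulk exactly. Alignments copy bases from the allele-of-origin haplotype
with optional per-base errors; genes are single-exon and non-overlapping by
default to isolate counting logic, with a spliced mode (M-N-M CIGARs) to
exercise the CIGAR walk. Peaks are placed within 50 kb of imprinted genes
and ≥1 Mb from controls (clamped on short fixture chromosomes, which
shrinks the contrast accordingly). Everything derives from one seeded numpy
Generator; equal configs give byte-identical output.

What this does **not** emulate: isoforms and overlapping transcription, GC
and positional bias, allele-specific mappability, reference bias from real
aligners, cell heterogeneity, or dispersion that varies systematically with
biology. Passing tests therefore demonstrate that the *pipeline logic and
statistics* behave correctly under the stated model, not that any particular
biological dataset would yield a given result.

A separate helper builds a synthetic stand-in for a pair of ChIP-seq peak
catalogs with chosen set sizes and planted overlap count (defaults 544,
6986, 457); it reproduces only that geometry, not real coordinates, and is
used to verify that interval intersection recovers a planted overlap at
catalog scale.

## Problem sizes in the shipped validation

The test suite and `scripts/acceptance.py` use: 10,000 random reads for the
assignment oracle; ~4,800 error-free fragments for truth recovery; 600 genes
(200 per class, mean coverage 200, 2 replicates) for classification
accuracy plus 2,000 balanced genes for false-call control; 2,000 null and
200 planted genes at 3+3 for DE calibration; 500-interval brute-force
comparisons; 60 genes (30 near / 30 far) for the KS discrimination; and a
30-gene, 4-sample alignment-level simulation (~36,000 fragments) for the
end-to-end imprinting-loss recovery. These sizes give stable Monte-Carlo
estimates while keeping the full suite under a minute of compute.

## Known limitations

Beta-binomial overdispersion of allelic counts is not modelled (the
proportion test is exact-binomial conditional on totals); multi-factor
designs, isoform-level quantification, multi-mapper rescue and BAM/CRAM
binary I/O are out of scope; the KS p-value is asymptotic; and the DE module
is a simplified reimplementation intended for analysis-structure validation
rather than a drop-in replacement for a production DE tool.
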
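# Methods

`cellsafety` implements the computational genomic-safety assessment for an
autologous gene-corrected cell product manufactured through three stages:
parental dermal fibroblasts, CRISPR-corrected induced pluripotent stem (iPS)
cells derived from them, and the differentiated induced skin composite (iSC)
graft product. The central question is forensic: which variants in the final
product were introduced or selected by manufacturing, and is there any
guide-dependent CAS9 off-target signature? This note records the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Variant consensus and the merged AF table

Variants are accepted per cell type only when a configurable number of
callers (default: all of them, mirroring a three-caller full-overlap rule)
report the identical normalized key (chrom, pos, ref, alt). Keys are
normalized before matching: multiallelic records are decomposed to biallelic
keys, shared allele suffixes then prefixes are trimmed (parsimony), and —
when a reference sequence is supplied — InDels are left-aligned by the
standard truncate-and-extend-left iteration. Without normalization,
full-overlap consensus spuriously drops InDels that different callers
represent with different padding. Consensus AF/depth come from a designated
primary caller (default: the first listed), with a mean-across-reporting-
callers fallback.

Variants matching a known-sites catalogue (a dbSNP-style VCF) are removed by
exact key equality. Each survivor gets exactly one region category by
precedence `exonic > splice_site > UTR > promoter_enhancer > intronic >
intergenic`; variants hitting no feature interval are intergenic. Variant
positions are 1-based (VCF convention); feature intervals are 0-based
half-open (BED convention); the conversion happens once, inside
`annotate_regions`.

The three cell types are merged into one table keyed by the union of
variants. An uncalled locus contributes AF 0 at its covered depth — never a
missing value — because the specificity analyses require a complete triple
`(AF_fibro, AF_ipsc, AF_isc)` per variant. If no depth track covers an
uncalled locus, depth is recorded as 0 and a warning is logged; the row is
retained.

## Cell-type specificity: two strategies

**k-means on AF vectors.** Each variant's AF triple is a point in
`[0,1]^3`; Lloyd's algorithm clusters all variants jointly (SNVs and InDels
together, with the option to split). The protocol parameters: maximum 1000
iterations, seeded initiation for reproducibility, k scanned from 3 to 9,
reporting the smallest k whose clustering contains a cluster with the
manufacturing-associated centroid pattern (fibroblast AF below 0.25, iPSC
and iSC AF above it — the same cutoffs as the filter below, replacing a
visual call with an explicit rule). Open choices fixed here: initiation is a
seeded uniformly random partition of rows into k clusters; nearest-centroid
ties break to the lowest cluster index; a cluster emptied during
reassignment is repaired by moving in the point farthest from its own
centroid. A single Lloyd run from a random partition can land in a local
optimum on pathological geometries — accepted, since the protocol specifies
a single seeded run, and on the cohort structures this package targets the
planted partition is recovered (verified against scikit-learn's multi-start
k-means on separated data and against planted ground truth).

**AF/odds-ratio cutoff filter.** Over-representation of the mutant allele
in cell type a versus b is measured by the odds ratio

    OR(a, b) = AF_a (1 − AF_b) / (AF_b (1 − AF_a)),

with both AFs clamped into `[ε, 1−ε]`, default ε = 1e−3. Clamping is the
package's resolution of the 0/0 and x/0 cases: a variant absent from
fibroblasts but present at AF 0.5 in iPS cells must pass an OR > 2 cutoff,
and with ε = 1e−3 it does (OR ≈ 999) while staying finite. Three conjunctive
filter blocks, all inequalities strict, classify each variant:

| label | AF conditions | OR conditions |
|---|---|---|
| SHARED_IPSC_ISC | fibro < 0.25, ipsc > 0.25, isc > 0.25 | OR(ipsc,fibro) > 2, OR(isc,fibro) > 2 |
| IPSC_ONLY | fibro < 0.25, ipsc > 0.25, isc < 0.25 | OR(ipsc,fibro) > 2, OR(ipsc,isc) > 2 |
| ISC_ONLY | fibro < 0.25, ipsc < 0.25, isc > 0.25 | OR(isc,fibro) > 2, OR(isc,ipsc) > 2 |
| NONE | otherwise | |

**Concordance and cross-patient overlap.** Concordance is
`|kmeans ∩ filter| / |kmeans|` — the fraction of k-means-flagged variants
the filter also labels shared-specific; the k-means set is the denominator
(reading the comparison as "what the filter confirms of the clustering
call"). Cross-patient overlap reports exact keys present in ≥ 2 patient
lines; an empty map is the expected no-positive-selection outcome.

## Off-target forensics

**Homology scan.** Within a window around each candidate variant (default
25 bases total, centred — the alternative ±N-around semantics is exposed as
a parameter), every position on both strands where a 20-mer sits immediately
5′ of a PAM match (IUPAC pattern, default NRG; SpCas9 geometry) is
enumerated, and mismatches against the guide (default sgRNA C4,
`ACTCACGGTGGATCCCGCTG`) are counted positionwise — pure Hamming distance, no
gaps; bulged off-targets are out of scope. The full 20-mer is compared, not
a PAM-proximal seed subsequence. The minus strand is scanned as the reverse
complement with offsets reported in forward window coordinates, making the
scan strand-symmetric. A minimum of ≥ 6 mismatches over all PAM-adjacent
placements argues against guide-dependent mutagenesis, since CAS9 cutting
with > 3 mismatches is very inefficient.

**Coverage and deletion calling.** Normalized coverage is per-base depth
divided by the chromosome mean. Deletions are maximal runs of positions
whose (optionally median-smoothed) normalized depth falls below the upper
heterozygous bound relative to the local flank median; a run whose raw mean
sits in the het band (default [0.3, 0.7] of the flank level — centred on the
expected 0.5 of a heterozygous loss, with noise margin) is called het, below
0.3 hom. Defaults: no smoothing and `min_run = 1`, the short-event mode that
recovers 1 bp and 10 bp heterozygous dips exactly on clean tracks; for
depth-40 noisy tracks a median window of ~15 suppresses single-base
fluctuations while moving the boundaries of a large (654 bp) event by only a
few bases, as the median filter preserves step edges.

## Editing-outcome quantification

* Editing efficiency: `((FAM·100)/HEX)·2` percent heterozygously edited
  cells — FAM is the edited-allele probe concentration (copies/µL), HEX a
  bi-allelic reference; the factor 2 encodes the mono-allelic-edit
  assumption. Values above 200% are arithmetically expressible but
  biologically impossible; they are flagged assay-inconsistent, not clamped.
* Competitive assay: `((mt·100)/(mt+wt))·2` percent of cells carrying the
  mutant allele (heterozygous carriers assumed), so a 3% allele frequency
  reads out as 6% of cells.
* Clone gates: edited/reference ratio in 0.5 ± 0.19 → mono-allelic,
  1.0 ± 0.19 → bi-allelic, else flagged. Band endpoints are inclusive (the
  ± notation states no open/closed convention; closed intervals keep the
  printed endpoints inside their band). The ratio is FAM/HEX directly, with
  no per-clone renormalization.
* Coupling efficiency: `%CE = live sorted iSCs / iPS cell input · 100`; the
  inversion `input = target / (CE/100)` rounds up to a whole cell (a 1e−12
  relative guard absorbs float noise in exact quotients before the ceil).
* Amplicon classification: reads are globally aligned to the reference and
  the donor-repaired (HDR) amplicon with fixed scoring (match 2, mismatch
  −1, gap open −5, gap extend −1) — fixed for reproducibility; the class
  definitions, not alignment scores, are the contract. Within a
  quantification window covering the cut site and all template-encoded
  variants: any indel → `indel`; otherwise all intended variants installed →
  `complete_donor`, a nonempty strict subset → `incomplete_donor`, none →
  `unmodified`; a read covering no intended position and aligning equally
  well to both amplicons → `ambiguous`. Stray substitutions at
  non-discriminating window positions do not change the class — the
  discriminating features are the intended positions and indel status, which
  keeps classification stable under sequencing-error-level noise.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the methods consume, with
ground truth, at the study's stated scale (depth ~40x, ~read-backed AFs):

* **Cohort.** Five classes with true AF triples: germline het
  (0.5, 0.5, 0.5), germline hom (1, 1, 1), rare pre-existing somatic
  (u, u, u) with u ~ U[0.01, 0.30], clonally amplified (u, 0.5, 0.5) with
  u ~ U[0.01, 0.20] — a rare fibroblast subclone fixed by single-cell iPSC
  derivation — and de novo iSC-only (0, 0, 0.5). Observed AF is
  `Binomial(depth, true AF)/depth` with depth ~ Poisson(40) floored at 1; a
  variant is called in a cell type iff ≥ 1 alternate read was drawn. The
  default class mix (2500/1000/800/500/200, total 5000) keeps germline
  variants dominant, as in real WGS call sets. A `noiseless` flag gives the
  infinite-depth limit.
* **Planted homology.** Random background with 20-mers at exact controlled
  Hamming distance from the guide, followed by a chosen PAM, on the forward
  strand; footprints may not overlap.
* **Coverage.** Expected depth scaled ×0.5 (het) or ×0 (hom) inside planted
  deletions; binomial noise draws per-base depth
  `Binomial(2·mean, expected/(2·mean))`, giving the correct mean with
  sequencing-like dispersion.
* **Amplicon reads.** Class counts follow the requested proportions
  deterministically (largest remainder), so noiseless round-trips are exact;
  incomplete reads carry a random nonempty strict subset of intended
  variants, indel reads a random 1–20 bp event at the cut site.

Not emulated: linkage, mutational signatures, mapping artefacts, strand
bias, caller-specific error modes, or depth heterogeneity beyond
Poisson/binomial sampling. Passing tests therefore demonstrate correctness
of the decision rules and estimators under the assumed sampling model, not
robustness to alignment or calling pathologies in real WGS.

One property worth stating precisely: with clonally-amplified fibroblast AF
uniform on [0.01, 0.20] and depth ~ Poisson(40), the expected sensitivity of
the cutoff filter on that class is ≈ 0.950, because a true fibroblast AF
near 0.20 has an appreciable chance of an observed AF ≥ 0.25 at 40x. Any
single cohort realisation therefore scatters around 0.95 (sd ≈ 0.01 at 500
planted variants); `analysis/02_variant_specificity.py` and the acceptance
script report the realised value for their seed.

## Problem sizes

Default analysis and test sizes: 5,000-variant cohorts; 100 replicates of
5 kb coverage tracks for deletion recovery; 100 × 1 kb windows for the
homology oracle; 1,000-read amplicon mixtures. These sizes give stable
estimates (binomial sd ≤ ~1% on the reported rates) while keeping every
script and the full test suite in the seconds-to-a-minute range.

## Known limitations

* The k-means is a single seeded Lloyd run by design; it inherits that
  algorithm's local-optimum behaviour.
* The homology scan does not model RNA:DNA bulges or position-weighted
  mismatch penalties (no CFD-style scoring).
* Deletion zygosity is a band rule on mean normalized depth; no split-read
  or paired-end evidence is used, so breakpoints are resolution-limited by
  coverage smoothing.
* The amplicon classifier assumes substitution-only donor templates
  (equal-length ref/HDR amplicons).
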
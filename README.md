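# cellsafety

Genomic safety assessment for gene-corrected autologous cell products.

When a patient's fibroblasts are CRISPR-corrected, reprogrammed to induced
pluripotent stem (iPS) cells, and differentiated into a graft product (an
induced skin composite, iSC), release of that product requires evidence
that manufacturing did not introduce or select harmful variants and that
the CAS9 guide did not cut off target. `cellsafety` implements that
assessment as a library plus analysis drivers:

* **Variant consensus and merging** (`cellsafety.variants`) — per-cell-type
  multi-caller VCF consensus, known-site (dbSNP-style) exclusion, region
  annotation, and a merged table in which every variant carries a complete
  allele-frequency triple `(AF_fibro, AF_ipsc, AF_isc)`.
* **Cell-type specificity** (`cellsafety.specificity`) — two complementary
  strategies: seeded Lloyd k-means on AF vectors with a k-scan (3..9) for a
  cluster with low fibroblast AF but elevated iPSC/iSC AF, and an
  AF/odds-ratio cutoff filter,

      OR(a, b) = AF_a (1 − AF_b) / (AF_b (1 − AF_a)),

  labelling variants SHARED_IPSC_ISC / IPSC_ONLY / ISC_ONLY / NONE at
  AF cutoff 0.25 and OR cutoff 2.0; plus their concordance and
  cross-patient overlap.
* **Off-target forensics** (`cellsafety.offtarget`) — PAM-adjacent (NRG)
  protospacer homology scanning on both strands with Hamming mismatch
  counts, normalized-coverage profiles, and coverage-drop detection of
  CAS9-induced deletions from 1 bp to hundreds of bp.
* **Editing QC** (`cellsafety.editing`) — ddPCR editing efficiency
  `((FAM·100)/HEX)·2`, competitive mutant-fraction assay, mono/bi-allelic
  clone gates (0.5 ± 0.19 / 1.0 ± 0.19), coupling-efficiency culture
  sizing, and amplicon donor-integration read classification
  (unmodified / complete / incomplete / indel / ambiguous).
* **Synthetic data** (`cellsafety.synthetic`) — generators with ground
  truth for every input: three-cell-type variant cohorts with five planted
  classes at ~40x binomially sampled depth, planted protospacer
  homologies, depth tracks with planted deletions, and amplicon read
  mixtures.
* **Pipeline + CLI** (`cellsafety.pipeline`, `cellsafety.cli`) — one
  config drives consensus → merge → specificity → off-target → summary;
  `cellsafety` console commands `simulate`, `consensus`, `specificity`,
  `offtarget`, `editqc`, `run`.

## Worked example

The numbered scripts under `analysis/` run the whole assessment on
synthetic data with ground truth:

```bash
python analysis/01_simulate_cohort.py --seed 0     # cohort -> results/cohort/
python analysis/02_variant_specificity.py --seed 0
python analysis/03_offtarget_forensics.py --seed 0
python analysis/04_editing_outcomes.py --seed 0
```

`02_variant_specificity.py` prints (seed 0):

```
merged table: 4991 variants with complete AF triples
cutoff-filter labels:
label
NONE               4280
SHARED_IPSC_ISC     485
ISC_ONLY            210
IPSC_ONLY            16
k-scan: smallest k with a shared-specific cluster = 4; 537 variants flagged
strategy concordance (filter ∩ k-means / k-means) = 0.883
planted clonally-amplified recovery: 472/500 = 0.944
```

Reading: of 5,000 simulated variants, the cutoff filter labels 485 as
shared iPSC/iSC-specific — essentially the 500 planted clonally-amplified
variants (a rare fibroblast subclone fixed at AF 0.5 by single-cell iPSC
derivation), recovered at 94% sensitivity with a germline false-positive
rate near zero. The k-scan independently finds the same subpopulation as a
flagged cluster at k = 4, and 88% of its members are confirmed by the
filter. `04_editing_outcomes.py` prints the assay arithmetic, e.g. a
clone screen with 3 bi-allelic integrations among 479 clones (0.63%, below
the 1% line) and the culture-sizing inversion: manufacturing 1.5×10⁹ graft
cells at 75% coupling efficiency requires 2×10⁹ iPS cells.

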
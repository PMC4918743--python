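# sigscar

Mutational-signature analysis for cancer genomics: 96-channel catalogue
construction, de novo signature extraction, constrained exposure
refitting, microhomology-deletion genomic scars, and the association
statistics that link them — with a synthetic-data generator that makes
every stage testable against known ground truth.

## The problem

Failure of homologous-recombination (HR) double-strand-break repair — the
defect behind *BRCA1/2*-mutant breast, ovarian and pancreatic cancers —
leaves characteristic marks in a tumour genome: a specific base-substitution
signature (COSMIC signature 3), an excess of large deletions (>3 bp) with
overlapping microhomology at their breakpoints, and elevated structural
variant counts. Detecting these scars from somatic mutation lists matters
clinically because HR-deficient tumours respond to platinum drugs and PARP
inhibitors. `sigscar` implements the computational chain for this kind of
analysis, for researchers working from variant calls (VCF/TSV) and a
reference FASTA.

## The models

**Catalogues.** Each sample's somatic SNVs — after germline-site and
panel-of-normals filtering (discard a variant supported by ≥2 reads in ≥2
normals) — are counted into 96 channels: six pyrimidine-referenced
substitution classes × the 5' and 3' flanking bases, with purine-strand
events reverse-complemented.

**Extraction.** The cohort matrix M (96 × samples) is factorized M ≈ W·H
(W, H ≥ 0) by multiplicative-update NMF under the Frobenius norm, across
multinomial bootstrap resamples; pooled per-bootstrap signatures are
reduced to consensus signatures by average-linkage agglomerative
clustering under cosine distance, and the rank is chosen by reproducibility
(silhouette stability with split- and noise-cluster guards).

**Refitting.** Given a catalogue m with N mutations and candidate
signature densities s₁…s_q, exposures E solve

    min ‖m − Σᵢ Eᵢ sᵢ‖₂   s.t.  Eᵢ ≥ 0,  Eᵢ ≤ N,  ΣEᵢ = N,

so each Eᵢ is the number of mutations attributed to signature i. The
candidate set is chosen per sample from a cancer-type registry with
feature-based exclusions (e.g. a repeat-indel signature is dropped when
the sample has few such indels).

**Scars and associations.** Deletion breakpoint microhomology is the
longest overlap between the deleted sequence and its flanks (tandem-repeat
deletions excluded); per-sample burdens are compared between
signature-positive and -negative groups with the Mann-Whitney U test
(exact enumeration for small samples), and categorical associations (e.g.
histology) with the two-sided Fisher exact test.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

`examples/03_refit_exposures.py` simulates the default cohort regime
(100 samples, 12% carrying the first signature), refits exposures, and
calls signature presence:

```
sample S009: total 2745 mutations, residual 46.0
  sig_1:    389.6 mutations (14.2%)
  sig_2:    894.4 mutations (32.6%)
  sig_3:    845.1 mutations (30.8%)
  sig_4:    616.0 mutations (22.4%)
calls agreeing with planted truth: 99/100
```

The exposures are mutation counts summing to the sample total; sample S009
carries the signature of interest at 14.2% of its mutations, above the
call thresholds (≥10 mutations and ≥5%), and 99 of 100 planted
presence/absence labels are recovered. The other scripts in `examples/`
cover catalogue building, de novo extraction, microhomology scoring
(`median MH burden: positive 687 vs negative 170, p = 2.17e-08`) and the
Fisher tests; each prints what it computes and what the numbers mean.

A command-line interface mirrors the stages for shell use:

```bash
sigscar simulate --outdir sim --seed 3
sigscar refit --catalogues sim/catalogues.tsv --signatures sim/signatures.tsv --out exposures.tsv
sigscar run --config run.ini        # full pipeline from a config file
```

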
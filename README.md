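# splicescore

Tools for quantifying pathogenic exon skipping from RNA-seq and relating it
to inflammatory transcriptional signatures — the analysis setting is an
X-linked autoinflammatory disease (NDAS) in which synonymous or intronic
mutations in *IKBKG* (encoding NEMO) promote skipping of the 153-nt exon 5,
producing an in-frame NEMO-Δex5 isoform that drives NF-κB and type I
interferon response programs. The package is aimed at computational
researchers who need the same three measurements on their own data or on
fully synthetic replicas of the study design:

1. **Exon-skipping splicing index (%AS).** From a coordinate-sorted BAM and
   a single-gene coding-exon model, count spliced reads supporting the
   inclusion junction (exon 4|5) and the skipping junction (exon 4|6), and
   report

   ```
   %AS = 100 × count(4|6) / count(4|5)
   ```

   a skip-to-inclusion *ratio* — deliberately not the conventional
   PSI = inclusion/(inclusion+skipping) — so values above 100% are
   meaningful. The gene model also yields the coding consequence of
   skipping any internal exon (deleted nucleotides, frame preservation,
   deleted residue range when exon boundaries are codon-aligned).

2. **Control-referenced signature scores.** RPKM-like expression values are
   transformed gene-by-gene to Z scores against a healthy-control set,
   z = (x − μ_ctrl)/σ_ctrl (sample sd, ddof 1), and a per-sample IFN or
   NF-κB score is the mean Z over a curated gene list. Scores are then
   regressed on the splicing index by ordinary least squares (slope, R²,
   two-sided p).

3. **Pseudogene-aware cohort allele counting.** Near the *IKBKG*/*IKBKGP1*
   duplication, mapping quality cannot assign reads to a locus, so per
   individual we pool base calls from every read overlapping either the
   primary site or its paralog position — with *no* mapping-quality filter —
   drop calls below Phred 30, require ≥ 20 pooled calls per individual, and
   summarize reference/alternate base fractions across the cohort.

A seeded synthetic-data generator emulates every input (toy genome +
gene/paralog pair, spliced reads from a two-isoform mixture, expression
matrices with a planted score = α + β·AS + ε relationship, cohort
alignments with planted carriers) and emits ground-truth manifests used as
test oracles.

## Worked example

```
splicescore run-all --seed 1 --outdir run1
```

simulates the default study (15 controls, 18 cases, a 1197-individual
cohort; all configurable via `--config`), counts junctions, scores
signatures, fits the regressions and writes `run1/report.json`. It prints:

```
splicescore run summary
=======================
control %AS: mean 8.5% (95% CI 7.7-9.4%, n=15)
  case CASE01: %AS = 5.0%
  ...
  case CASE18: %AS = 65.0%
IFN score ~ %AS: slope 0.0553, R^2 = 0.93, P = 1.5e-19, n = 33
NFKB score ~ %AS: slope 0.0575, R^2 = 0.94, P = 4e-20, n = 33
paralog cohort: 1152 pass depth, 45 fail, 0 carrier(s)
```

Read it as: healthy controls show a baseline skipping ratio near 8.5%,
case samples span the planted 5–65% range, both signature scores rise
linearly with the splicing index (the generator plants slope β = 0.05 Z
per %AS point in the case samples; the case-only fit recovers it to within
a few percent, while this all-sample fit is slightly steeper because
control scores sit at baseline), and in the 1197-individual healthy
cohort no individual carries the alternate base at the duplicated locus
after the Phred ≥ 30 / depth ≥ 20 filters.

Library use mirrors the CLI:

```python
from splicescore import (load_gene_model, count_junction_reads,
                         compute_percent_AS, exon_skip_consequence)

model = load_gene_model("toy_gene.bed", "TOYG")
print(exon_skip_consequence(model, 5))
# SkipConsequence(deleted_nt=153, frame_preserved=True,
#                 deleted_aa_first=174, deleted_aa_last=224, residues_exact=True)
rec = count_junction_reads("sample.bam", model, trio=(4, 5, 6))
print(compute_percent_AS(rec).percent_AS)
```

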
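# Methods

## The splicing index

The statistic of interest is the percent alternative splicing of an
internal exon, measured from spliced short-read alignments:

    %AS = 100 × count(4|6) / count(4|5)

where count(4|5) is the number of distinct read names supporting the
junction that joins the exon-4 donor to the exon-5 acceptor (inclusion)
and count(4|6) the number supporting the exon-4 → exon-6 junction
(skipping). This is a skip-to-inclusion ratio, not a fraction of the
total: unlike PSI = incl/(incl+skip) it is unbounded above, and the two
are related by %AS = 100·(1−PSI)/PSI. We keep the ratio form exactly as
defined and let values exceed 100 when the skipping isoform dominates.

Two counting modes are provided.

* **junction-exact** (default): a read supports a junction iff one of its
  CIGAR `N` gaps coincides exactly (0-base tolerance) with the junction's
  donor/acceptor boundaries. Exact matching is appropriate in the
  annotated-junction setting and avoids mis-assignment between the
  closely spaced 4|5 and 4|6 gaps.
* **exon-overlap**: a read supports a pair iff its aligned blocks
  intersect both exons of the pair and miss the intervening exon. This is
  the literal "overlapping both exons" reading; on clean single-gap
  junction reads shorter than the flanking exons the two modes count
  identically (a tested invariant).

Unmapped, secondary, supplementary and (by default) duplicate records are
excluded. Mates are counted independently but one query name contributes
at most once per junction pair. When the inclusion count is zero the
index is reported undefined with a flag rather than raising or returning
infinity — the situation is degenerate but reachable. A low-coverage flag
marks samples with fewer than `min_informative` (default 10) informative
reads; no depth floor is applied to the index itself.

## Exon-skip consequence

Gene models are ordered coding exons (0-based half-open internally; GTF
1-based-inclusive input is converted at the parsing boundary, BED12
blocks are used as-is). Skipping an internal exon of coding length L
deletes L nt; the frame is preserved iff L mod 3 = 0. When the cumulative
coding length upstream of the skipped exon is divisible by 3 the deleted
residue range is exact: first = upstream/3 + 1, last = (upstream+L)/3.
Otherwise the affected codon interval is reported and flagged
approximate. The packaged toy gene places 519 coding nt (173 codons)
upstream of a 153-nt fifth exon, so skipping it removes residues 174–224
in frame — the flagship case is codon-aligned. Minus-strand genes mirror
donor/acceptor semantics; the toy gene is on the + strand for
readability.

## Signature scores and regression

Expression input is an RPKM-like genes × samples matrix. Z-referencing
uses only the designated healthy controls: per gene, z = (x − μ)/σ with
the sample standard deviation (ddof 1); the raw scale is used (no log
transform by default, a log2(x+1) flag exists). Genes with zero control
variance are dropped with a warning. By construction the control set then
has per-gene mean 0 and sd 1, and with the default **mean** aggregator
the control cohort's mean signature score is exactly 0 — both are exact
algebraic identities checked to 1e-9. Median and sum aggregators are
available; the choice is recorded in the output metadata. The regression
of score on %AS is ordinary least squares (scipy `linregress`); R² is the
squared Pearson correlation and the p-value is the two-sided test of zero
slope. Fewer than 3 pairs or a constant predictor is an error. No
multiple-testing correction is applied: the analysis fits two
pre-specified regressions.

The packaged IFN and NF-κB gene lists are editable placeholders of
canonical pathway members; all tests use the generator's own planted
lists, so nothing depends on the placeholder membership.

## Duplicated-locus base counting

For a gene/pseudogene pair with near-total sequence identity, reads map
interchangeably between loci and mapping quality is uninformative, so the
counting deliberately applies **no MAPQ filter** (a tested invariance:
permuting MAPQ changes nothing). Per individual, every primary read
overlapping either the primary site or the homologous paralog position
contributes at most one base call per site it overlaps; calls below
Phred 30 are excluded and tallied, `N` calls and non-base events
(deletions, reference skips spanning the site) are tallied separately and
never enter the denominator. Individuals with fewer than 20 pooled calls
are excluded from the cohort summary. Both thresholds are sharp by
construction and tested at 29/30 and 19/20. Overlapping mates are counted
twice by default (a mate-dedup flag exists). "Carrier" is an explicit
reporting construct of this package — an individual whose pooled
alt-base fraction reaches a configurable threshold (default 0.10) —
because the source analysis only reports the absence of variant-positive
individuals and defines no positive call rule.

## The synthetic-data generator

The generator defines the study conditions and doubles as the test
oracle; all streams derive from one seed via per-component spawn keys, so
any subset regenerates reproducibly and byte-identically.

* **Toy locus.** A random chromosome (~5.9 kb) carrying a 10-exon gene
  (exon lengths 120/150/129/120/**153**/150/120/132/120/126, introns
  250 nt) and, 500 bp past the gene, a 300-bp window copied from around
  the primary site with exactly two substitutions (99.3% identity), never
  at the site itself. Emitted as FASTA (+faidx), BED12 and GTF from one
  coordinate table.
* **Spliced reads.** Two isoforms: inclusion (all exons) and skipping
  (exon 5 removed). Per sample, the isoform counts are allocated exactly,
  n_skip = round(f·N), so the emitted mixture equals the target fraction
  up to rounding; a `binomial` mode draws each read's isoform
  independently instead and is exercised by the convergence tests. Reads
  default to **junction-anchored** placement (each read spans the exon-4
  donor junction), which gives the two isoforms equal junction capture so
  the counted %AS estimates 100·f/(1−f) directly; `uniform` placement
  scatters reads along the isoform, in which case capture probabilities
  differ by the isoform-length ratio and the anchored identity no longer
  holds. Reads are error-free with flat Q40 qualities so junction-exact
  counting has a clean oracle; the truth table records the exact emitted
  junction-read counts per sample. Default depth is 2000 reads/sample.
* **Study layout.** 15 controls with true %AS evenly spanning 6.1–11.0
  (mean 8.55) and 18 cases spanning 5–65, matching the observed healthy
  baseline and the case range over which scores climb.
* **Expression.** Per-gene log-normal baseline (meanlog ~ U(2,4), sdlog
  0.15; positivity matches RPKM units). For each case and signature a
  target score t = α + β·AS + ε is drawn (defaults α = 0, β = 0.05 Z per
  %AS point, σ = 0.25) and signature-gene values are set to
  μ̂ + z·σ̂ using the *empirical* control mean/sd (ddof 1) with per-gene
  jitter (sd 0.5) centred across the signature — so the mean-aggregated
  score equals t exactly and parameter-recovery tests see pure planted
  noise. Background genes (200) stay at baseline. Values are clipped at
  zero; at the default baseline the clip never binds in practice.
* **Cohort.** Subgroup sizes default to 1158/8/17/14 (total 1197) with
  ancestry labels; per-individual depth is Poisson(30) (overridable per
  individual), reads cover exactly one of the two sites, site-call
  quality drops to Q20 with probability 0.05, MAPQ is randomized 0–60.
  Planted carriers (default **zero**, matching the observed cohort) carry
  the alt base in an exact round(0.4·depth) subset of calls, so carrier
  recovery is deterministic given adequate depth; carriers whose Poisson
  depth falls below the 20-call floor are legitimately invisible and the
  truth table exposes depth for exactly this comparison.

What passing tests show — and what they do not: the generator produces
idealized error-free reads with exact junctions, a single transcript per
gene, no expression heteroskedasticity beyond the log-normal baseline,
and no mapping ambiguity beyond the planted paralog copy. Green tests
demonstrate the *statistical machinery* (counting, referencing, scoring,
regression, filtering) is correct under known truth; they do not
establish robustness to alignment artifacts, sequencing error, fragment
biases, or annotation mismatch in real data.

## Numerical and design choices

* Junction-match tolerance is 0 bases; coordinates are 0-based half-open
  everywhere internally, converted only at parse boundaries.
* Control sd uses ddof 1; aggregator defaults to the mean (it makes the
  control-centering identity exact); both recorded in output metadata.
* The control %AS confidence interval uses the t distribution on the
  control sample (method name recorded in the report); identical control
  values give a degenerate interval rather than an error.
* The cohort summary's 95% CI and the regression's slope CI are exact
  normal-theory intervals; coverage is verified by simulation.
* Phred+33 encoding is assumed for SAM qualities.
* Exit codes: 0 success, 2 configuration error, 3 stage failure (the
  failing stage is named and a FAILED marker is left beside partial
  outputs).
* Serial samples are treated as independent points in the regression, and
  %AS is reported per sample only — no averaging across serial samples.

## Problem sizes

Defaults were chosen as the smallest sizes at which the statistical
identities are sharp: 2000 junction-anchored reads per sample (rounding
error in %AS ≤ 0.1 point), 250 genes × 33 samples expression matrices,
500 replicates for CI-coverage estimates, and the full 1197-individual
cohort at Poisson(30) depth. The complete test suite runs in well under a
minute on one CPU; `scripts/acceptance.py` in about one minute.

## Known limitations

* Single-gene models only; no genome-wide quantification, no de novo
  junction discovery, no multi-isoform deconvolution.
* The %AS statistic is a ratio estimator: at low inclusion counts it is
  biased upward and noisy; the low-coverage flag is the only guard.
* BED12 models carry no CDS offset (blocks are treated as pure CDS);
  models with a 5′ UTR inside the first listed exon must set `cds_offset`
  programmatically.
* Real-data use requires the user's own exon numbering/annotation; the
  toy model's geometry (exon 5 = 153 nt, residues 174–224) documents the
  convention but carries no genomic coordinates from any real assembly.
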
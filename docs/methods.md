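# Methods

`scdropout` quantifies what is gained and lost when the same exposed tissue
is profiled by conventional bulk RNA-seq and by droplet-based single-cell
RNA-seq collapsed to a pseudo-bulk profile.  Because the two assays share
the biology but not the technical path, every systematic difference between
them must be attributable to a dissociation effect, a droplet (capture)
effect, or a dropout effect.  The package implements (i) a generative model
of the paired design with those three mechanisms made explicit, and (ii)
the comparison statistics themselves — differential expression calling,
the low-expressor coverage statistic with a sensitivity-matched filter, a
transcription-factor (TF) detection proxy, DEG set overlaps, and a
per-cell-type dropout test.

## The paired design

Six datasets model a toxicant-exposure study in a testis-like tissue:

| label | condition | preparation | assay |
|-------|-----------|-------------|-------|
| CI | control | intact | bulk |
| CD | control | dissociated | bulk |
| CB | control | dissociated | bulk (paired with CP) |
| TB | exposed | dissociated | bulk (paired with TP) |
| CP | control | dissociated + droplet capture | single-cell |
| TP | exposed | dissociated + droplet capture | single-cell |

Replicates default to CI/CD/CB/CP n = 3 and TB/TP n = 2.  Comparisons are
written `AxB` (A vs B): CDxCI isolates dissociation, CPxCB and TPxTB the
droplet effect, TBxCB and TPxCP the exposure as seen by each method, and
TCxCC the per-cluster exposure contrasts.

## Generative model

**Tissue.** Ten germ-cell maturation stages (SSC → spermatogonia → four
spermatocyte stages → round/elongating spermatids → two sperm clusters).
Control proportions put sperm at ~23% (sperm + spermatids ~30%) and
spermatogonia + early spermatocytes at ~30%.  Exposure shifts tissue
composition only mildly (sperm 23% → 20%); the dramatic shifts the
single-cell assay reports arise downstream, from stress-dependent capture
loss.

**Expression.** Per-gene baselines are a two-component mixture: an
expressed component, log-normal with σ = 1.6 on the natural-log scale, and
a *trace* component (~`e^-6` lower) modelling genes effectively silent in
this tissue — deep bulk sequencing still skims a few reads of them, droplet
capture loses them outright.  30% of genes are trace (55% among TFs:
TFs proxy short, low-expressed transcripts, and the expressed TFs carry a
further −0.5 log-mean shift).  A single log-normal cannot reproduce both
the bulk-vs-pseudo-bulk detection gap and a stable low-expressor window;
the mixture is the minimal model that does.  Cell-type identity enters as
per-gene, per-type log-normal factors (σ = 0.8).  Mitochondrial content is
a pinned 4% share of every healthy cell's output carried by 20 abundant
genes (mtDNA encodes few, abundant transcripts); it is flat across types
and excluded from all differential programs, so QC's mito filter responds
to stress, not identity.

**Counts.** Per cell, gene counts are negative binomial (gamma–Poisson)
with mean `library_factor × baseline[type] × 2^(active program LFCs)` and a
dispersion of 0.3 shared across genes; library factors are log-normal
(σ = 0.3).  Cells carry ~14,000 captured transcripts (UMI-like counts; the
study-scale figure of ~120,000 reads/cell corresponds to roughly this many
molecules at typical 3' conversion).  Bulk libraries are one multinomial
draw of 60 M reads over the pooled pre-capture suspension of 2,000 cells.

**Programs.** Dissociation scales 100 genes up and 100 down by |LFC| = 2
and inflates mito counts by `1 + 3 × stress`; the droplet-specific artifact
scales 80 expressed nuclear genes by LFC 1.5 in the single-cell branch
only.  Droplet-program genes are drawn below the 90th abundance percentile:
an "artifact" on the single dominant transcript would rescale the whole
library (and with it every max-relative statistic) rather than add a
program signature.
Exposure programs are 25 genes per cell type at LFC 4, sampled from the
low-mid band of expressed genes (5th–35th percentile) and enriched 12× in
their target type — the model's picture of responsive, marker-like
programs.  Both choices are structural.  The enrichment makes a
cell-type-restricted effect visible in a bulk average at all (an
unenriched LFC-4 effect in a 10%-abundance type changes the bulk signal by
well under two-fold, because the fold depends on the fraction of the
gene's expression coming from that type).  The low-mid band keeps the
enriched-and-induced genes from dominating an exposed cell's library —
that fraction is independent of the gene's absolute abundance, but the
library share is not, and letting 25 genes × 64-fold swallow half a
library would drag every bystander gene's CPM past the DEG threshold.
Deep bulk sequencing still measures the band's genes with hundreds of
counts.

**Stress and capture.** Each cell's stress score is
`susceptibility × (0.05 + 0.80·exposed)`; late germ cells carry
susceptibility 0.9–1.0, spermatogonial types 0.05.  Droplet capture retains
a cell with probability `(1 − 1/3) × (1 − stress)` — the standard one-third
loss multiplied by a stress factor, so control tissue loses the cited third
while exposed sperm collapse to ~4% of the captured population.  Retained
counts are thinned binomially with detection rate
`σ(12 × (log(count+1) − 1.5) + length_offset)`: a transcript species
either clears a ~3–4-copy threshold and is captured nearly fully, or drops
out.  The steepness is deliberate.  With a shallow curve, partial detection
*compresses* mid-expressed genes relative to abundant ones, pushing them
under the 1%-of-maximum line and inflating the pseudo-bulk low-expressor
coverage above bulk — the opposite of what droplet data show.  Short genes
(3' bias proxy) get a −0.25 logit offset.

## Analysis definitions

* **Detected transcript** — total raw count ≥ 1 across a dataset's
  replicates.
* **QC** — cells need ≥ 500 detected features and mito fraction strictly
  < 10%; clusters need ≥ 30 cells after cell filtering; filters run in that
  order, then collapse.  Collapse sums raw counts per sample and keeps
  zero rows, so bulk and pseudo-bulk share one gene universe.
* **DEG rule** — raw p < 0.01 (strict) and |log2 FC| ≥ 1 (inclusive) on
  CPM means with a pseudocount of 1; no multiple-testing correction by
  default (a BH flag exists).  Replicate-level tests use an in-house NB
  Wald test: CPM-scale group means, a common dispersion estimated by
  averaging per-gene unbiased moment estimates over well-measured genes
  (individually those estimates are hopeless at n = 2–3; their mean over
  ~2,000 genes is tight, and unlike a sum-weighted estimator it is not
  hostage to the most abundant genes' variance noise), delta-method
  standard errors with per-sample scale factors, and a normal reference.  Its empirical type-I error at α = 0.01 sits near
  0.012 on 2,000-gene null simulations.  Per-cluster DE uses a two-sided
  rank-sum test on per-cell CPM — exact enumeration (midranks, deviation
  rule) when both groups have ≤ 8 cells, tie-corrected normal approximation
  otherwise.
* **Low expressor** — detected gene whose normalized (CPM) count sum is at
  most 1% of the dataset's maximum per-gene sum; the lower bound is the
  one-read detection floor.  Both bounds inclusive.  Coverage is
  `100 × |low| / |detected|` within the same dataset — the denominator the
  unfiltered/filtered contrast needs to be well-defined.
* **Matched filter** — the reference (pseudo-bulk) dataset's smallest
  positive per-replicate CPM among detected genes, applied to bulk as an
  inclusive lower limit.  Because the limit cannot exceed the low-expressor
  cutoff, filtering removes only low expressors, and
  `(L−k)/(D−k) ≤ L/D` guarantees coverage never rises — with strict
  reduction whenever any low expressor falls below the limit.  The paired
  one-tailed t-test (filtered < unfiltered, Student on per-replicate
  differences) summarizes the reduction.
* **Proportional-dropout test** — H0: every cell is retained independently
  at the pooled rate `r̂ = Σpost/Σpre`; per type, a two-sided binomial test
  of the retained count against `Binomial(pre, r̂)`, BH-corrected across
  types.  With thousands of cells this p-value rejects for *every* type
  whenever one abundant type collapses (the pooled rate moves away from
  everyone), so the *flag* additionally requires a ≥ 1.5-fold deviation of
  the type's retention rate from `r̂`.  P-values are reported unmodified.
* **PCA** — samples as points, log2(CPM+1), centred per gene, SVD; a 1-D
  silhouette on PC1 by preparation method summarizes the bulk/pseudo-bulk
  split.

## What the generator does and does not emulate

It reproduces the statistical structure the comparison depends on: paired
replicate design, composition shifts, dissociation/droplet expression
programs, stress-dependent cell loss, abundance- and length-dependent
transcript capture, a TF-enriched low-expression tail, and QC-relevant
mito behaviour.  It does not model reads (no FASTQ, alignment, UMI
collisions), doublets, ambient RNA, batch chemistry, graph clustering
(cells carry true type labels; "clusters" are those labels), or a genuine
25,000-gene genome — the universe is 2,000 genes with depths scaled to
keep per-gene abundance realistic.  Passing tests therefore certify the
pipeline's statistics and the direction and rough magnitude of the
method-contrast effects under this model, not numerical agreement with any
particular real tissue.

## Numerical and design choices

* Problem sizes: 2,000 genes; 4,000 cells loaded per single-cell sample
  (20,000 total), 2,000 cells per bulk suspension; 60 M reads per bulk
  replicate.  A full pipeline run takes well under five minutes on one CPU.
* All randomness flows from one seed through named, label-derived
  substreams, so any dataset can be regenerated alone, identically; the
  same seed yields byte-identical bundles and reports.
* Degenerate cases: zero-variance t-tests return p = 0.5 (no difference) or
  p → 0/1 (constant non-zero difference), flagged; the Yates-corrected
  |ad−bc| − N/2 is clamped at zero; all-zero cells have no defined mito
  fraction and are rejected; an empty matched filter warns rather than
  raises.
* A `max_mito_fraction` of 1.0 disables the mito filter (otherwise the
  strict `<` would still drop cells with fraction exactly 1).
* The chi-squared p-value uses `erfc(√(X²/2))`, exact for 1 df; Fisher's
  test sums hypergeometric probabilities not exceeding the observed
  table's, with a 1+1e-9 relative tolerance for floating-point ties.

## Known limitations

* The NB Wald test is mildly anti-conservative at n = 2–3 (type-I ~0.012
  at a nominal 0.01); with so few replicates no unshrunk test does much
  better, and the DEG thresholds are joint p-and-LFC rules anyway.
* The capture model thins realized counts, so a gene's detection is
  slightly smeared around the threshold by counting noise; real droplet
  data show additional gene-level zero inflation this does not capture.
* Coverage percentages depend on the top gene's dominance and therefore
  drift between catalogue draws (50–85% across seeds); the method
  *contrasts* (pseudo-bulk below bulk; filtered below unfiltered) are the
  stable, tested quantities.
* The dropout flag's 1.5-fold effect threshold is a pragmatic guard
  against the pooled-rate artifact described above, not an inferential
  quantity; sensitivity to it can be probed via
  `proportional_dropout_test(..., effect_threshold=...)`.
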
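# Methods

## Scope and model

`cernet` infers competing-endogenous-RNA (ceRNA) triplets
(ce, miRNA, mRNA), the ce being a lncRNA or circRNA, from a two-condition
RNA-seq design with replicates.  A triplet is accepted when

1. the miRNA has a predicted seed site on both the ce and the mRNA and is
   negatively co-expressed with each (Spearman ρ < −0.7, strict);
2. the ce and mRNA are positively co-expressed (Pearson r > 0.9, strict);
3. the two transcripts share more regulator miRNAs than expected by
   chance: hypergeometric upper tail P(X ≥ x) < 0.05 (strict), where
   x = |C∩D| for regulator sets C (size M) and D (size N) drawn from a
   universe of U miRNAs.

All three thresholds follow the inequality directions of the published
criteria they implement; each is configurable in one place
(`network_pipeline.DEFAULT_THRESHOLDS`).

### Differential expression

The published analysis defines significance (fold change ≥ 2, FDR < 0.05)
but not its test engine.  We use CPM normalisation, log₂(CPM+1), and a
two-sided Welch *t*-test per feature, with Benjamini–Hochberg adjustment
(statsmodels).  This engine is deliberately transparent and swappable: the
downstream stages consume only (log2fc, fdr, status).  Degenerate features
(zero variance in both groups) get p = 1 when group means coincide, p = 0
when they differ deterministically.  Fold change uses pseudocount 1
(avoids division by zero at three replicates); "fold change ≥ 2" is read
two-sidedly as |log₂FC| ≥ 1, consistent with up- and down-regulated
features both being reported.

Known limitation: per-class CPM is compositional — a handful of extremely
strong DE features in a small class shifts every other feature's CPM in
the opposite direction.  Count-model engines with robust size factors
(edgeR/DESeq2-style) are out of scope by design; the extension point is
`diffexpr.de_test`.

### Target prediction

Canonical seed matching: the site taxonomy is 6mer (match to miRNA
positions 2–7), 7mer-A1 (6mer + A opposite position 1), 7mer-m8 (match to
2–8), 8mer (both), with the strongest type reported per locus and the A1
anchor recognised as a literal A.  Whole transcripts are scanned because
lncRNA/circRNA sponges carry no UTR annotation.  The default admission
threshold is 7mer-m8, which limits false positives when scanning whole
transcripts.  U/T equivalence is applied at this boundary; sequences are
stored as DNA on disk.

### Sponge test

The hypergeometric upper tail is accumulated in log space via log-gamma
(no overflow for any realistic U); the summation range is clipped to the
support max(x, M+N−U)..min(M,N).  p-values are used raw, matching the
published "p < 0.05" criterion; a BH switch across tested pairs exists
(`assemble_triplets(adjust_sponge=True)`) but defaults off.  The universe
U defaults to the number of differential miRNAs in the analysis — our
reading of "all the miRNAs in the work" — and is configurable because that
phrase is ambiguous.  Note a structural consequence: with x = M = N = 1
the tail is exactly 1/U, so single-shared-miRNA triplets can only be
significant when the analysis contains more than 20 differential miRNAs.

### Correlations

Computed on log₂(CPM+1) across the pooled samples of both conditions (the
only interpretation that leaves n ≥ 3 at a 3-vs-3 design).  Zero-variance
vectors yield NaN, which never passes a threshold.

### Positional lncRNA classification

Five categories by fixed precedence: sense_overlapping (same strand,
≥ 1 bp exonic overlap) → intronic (same strand, span inside one intron) →
antisense (opposite strand, any span overlap) → bidirectional (no overlap,
divergent TSSs within a window) → intergenic.  The window defaults to
1,000 bp, a common divergent-promoter definition.  TSS is the span start
on +, span end on −.  Intronic is restricted to the same strand;
opposite-strand intron containment falls to antisense via precedence — a
deliberate, explicit choice where no published rule exists.  Intervals are
1-based closed throughout, matching GTF.

### Small-RNA screening

Four rules, applied in order (the first failure is reported): mean base
quality ≤ 20 (only when quality data exists; tag-level FASTA carries
none), residual adapter, length < 18 nt, polyA.  "polyA" is defined as
≥ 80 % A over the tag: no published fraction exists, and this catches
homopolymer artifacts without discarding A-rich miRNAs.  Annotation
resolves a tag's category memberships to the highest-priority one
(structural RNAs — rRNA/scRNA/snoRNA/snRNA/tRNA bundled — ahead of miRNA
classes ahead of genomic context); no membership means unannotated.
Alignment against the reference databases themselves is out of scope:
membership flags are inputs.

## Synthetic scenarios

The generator emulates the 3-vs-3 two-condition ovary design by default
and scales to any replicate number.

* **Counts**: negative binomial, parameterised by mean and dispersion
  (default 0.1, typical for bulk RNA-seq replicates), per-feature base
  means log-normal around 500 expected counts (spread σ = 0.5 on the log),
  and per-sample library-size factors log-normal(0, 0.1).
* **Planted DE**: symmetric ±log2fc/2 shifts (default fold change 4);
  directions alternate every second triplet so each ce class receives
  both directions — keeping planted shifts balanced within a class
  protects per-class CPM from compositional drift.
* **Coupling**: a planted miRNA's realized log-signal is standardised per
  sample and its targets' NB means are multiplied by exp(−κ·z) (κ =
  coupling_strength, default 2.0).  Both targets of one miRNA share the
  same modulation, producing negative miRNA–target and positive ce–mRNA
  correlation in expectation.  Targets additionally receive an explicit
  opposite-direction DE shift so triplet members pass the DE gate even at
  κ = 0.
* **Sequences**: every target-class sequence (default 300 nt) is sampled
  clean of *all* miRNA 6mer seed cores — rejection sampling, with a
  deterministic best-local point-substitution repair once the core set is
  dense enough that rejection cannot succeed — and planted targets then
  receive exactly one designed 8mer site.  Predicted target relations
  therefore equal the planted ones, so recovery scores measure the
  statistical filters rather than accidental sequence matches.  miRNA
  seed cores are sampled pairwise distinct.
* **Transcript models**: protein-coding three-exon genes laid out on one
  chromosome, with lncRNA placements cycling the five positional
  categories against them.
* Identical seeds give bit-identical scenarios and fixture files.

What the generator does **not** emulate: read-level errors, alignment and
quantification noise, correlated biological covariates (batch, sex, age),
realistic transcript length/GC structure, isoform ambiguity, or miRNA
target-site context (accessibility, conservation).  Passing recovery
tests therefore shows the inference machinery is correct and calibrated
on data satisfying its own assumptions, not that the thresholds are
optimal on real ovary transcriptomes.

## Problem sizes and calibration checks

The validation suite uses desk-scale scenarios: a null scenario of 2,000
features (500 per class, 20 replicates per group, no planted signal),
where the raw Welch p < 0.05 fraction lands near 5 %, nothing survives the
joint FC+FDR gate, and no triplet is emitted; and recovery scenarios of 30
planted triplets among ~300 decoy features (20 replicates per group,
dispersion 0.05, κ = 2.0) across ten seeds, where median recall and
precision against the planted truth both reach at least 0.8 (observed:
1.0).  Thirty triplets also make the miRNA universe large enough
(U ≈ 35 > 20) for single-shared-miRNA sponge tests to clear p < 0.05 —
see the structural note above.

## Numerical choices

* Hypergeometric tail in log space; exactness is verified against exact
  rational enumeration for all admissible (x, M, N, U) with U ≤ 12 and
  against an independent survival-function implementation at larger sizes.
* BH adjustment is verified against the O(m²) textbook step-up definition
  to 10⁻¹², correlations against textbook formulas likewise.
* Triplet output is sorted (ce, miRNA, mRNA) lexicographically; network
  node and edge lists are sorted; fixture files are written
  deterministically — byte-identical reruns under a fixed seed.
* The published association table is transcribed verbatim, including one
  truncated lncRNA identifier and one whitespace-separated list cell; the
  loader splits list cells on commas and then whitespace, and the
  truncated id is treated as distinct rather than silently merged.

## Known limitations

* The DE engine is a transform-then-*t* approximation, slightly
  conservative at three replicates; its printed DE counts on real data
  will not match count-model engines.
* The sponge test inherits the published raw-p criterion: across many
  tested pairs it does not control the family-wise error (the BH switch
  addresses this when fidelity to the criterion is not required).
* Whole-transcript seed scanning over-predicts relative to UTR-restricted,
  context-scored predictors on real transcripts.
* The positional classifier depends on the completeness of the coding
  annotation: missing coding genes inflate the intergenic class.
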
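# Methods

This note records the models behind each analysis, the conventions chosen
where several were defensible, and what the synthetic generator does and
does not emulate.

## The artifact models

**Homopolymer bleed.**  A substitution call is classified bleed-type when
its alternate allele equals the base of an A/T homopolymer run whose
boundary lies within a proximity window (default 5 bp) of the call; a
single-base indel qualifies through its inserted/deleted base.  Distance is
measured from the run boundary: a call inside the run or touching its
boundary base has distance 0 ("immediately next to or within"), and ties
between equidistant runs go to the lower start coordinate.  Allele identity
with the run base is required by default (`--no-allele-match` relaxes it).
G/C runs are tallied separately and never feed the bleed class: the bleed
mechanism is chemistry-dependent and biased to one base pair class per
protocol, and the A/T-vs-G/C asymmetry is itself a diagnostic.  Same-read
co-errors (AAAAACACACA read as AAAAAAAAAAA, giving several calls on one
run) are resolved by grouping bleed calls that share a run and an alternate
allele and chain within the window.

**Run-length regression.**  Per run-length bin, the rate is bleed calls
attributed to runs of that length divided by the total bp in runs of that
length; the fit is unweighted OLS of log₁₀(rate) on length at the bin level
(so df = bins − 2), with zero-call bins dropped and reported.  Bin-level
fitting is chosen because the error structure of interest lives at the bin
level; call-level weighting would let the longest runs dominate.

**Mis-mapping.**  Clusters are maximal chains of calls with consecutive
positions ≤ window bp apart (default 10), by default pooled across samples
since mis-mapping afflicts a locus, not a sample (`--per-sample`
restricts).  Recurrence flags sites whose identical variant appears in
strictly more than the sample threshold (default 10) distinct samples.
Because a call can carry both fingerprints, the raw clustered and recurrent
percentages are reported alongside their exclusive union.

## Spectra and equilibrium content

The 96 dinucleotide mutation classes are the single-base transitions
between dinucleotides (16 sources × 2 positions × 3 alternatives), written
`CA>TA`.  Each SNV is counted once at its 5′-side dinucleotide
(second-position change) and once at its 3′-side dinucleotide
(first-position change); calls lacking context (chromosome ends, Ns) are
excluded and counted.  This both-flank convention is the package's default
because it is the only one that populates all 96 classes from plus-strand
calls and yields an irreducible 16-state chain — under a single-flank
convention second-position classes are structurally empty and no
equilibrium exists.  Single-flank modes (`flank="three"`, `"five"`) are
available for sensitivity analysis, and output metadata always records the
convention.  Counts are normalized by the occurrence of each source
dinucleotide in the evaluated region, counted over overlapping windows.
For reporting, classes can be strand-collapsed onto their reverse
complements (48 pairs); the AA/TT resolved-end share is computed on the
uncollapsed relative normalized rates, since "resolving to AA or TT" is a
statement about the literal called strand.

Two spectra are compared by chi-square on the 2×96 count table (classes
with zero total pooled out and reported; df = 95 when all classes are
populated), with per-class Pearson residuals ranked to surface the
discrepant classes.

The 16×16 rate matrix Q takes each class's normalized rate as the rate of
its dinucleotide transition; entries for double changes are structural
zeros and the diagonal makes rows sum to zero — a continuous-time chain.  A
discrete per-generation formulation differs only by time scaling and leaves
the stationary distribution unchanged.  π solves πQ = 0 with the
normalization constraint (least squares on the augmented system), checked
for irreducibility via strongly connected components and cross-checked
internally by power iteration; tests check it independently against the
long-time matrix exponential at 1e-8.

Equilibrium-vs-observed compares π with the observed intergenic
dinucleotide frequencies: a least-squares fit of predicted on observed over
the 16 states, then an outlier test for the designated states (default AA,
TT): the fit is recomputed excluding them, each gets an externally
studentized prediction residual and a two-sided t p-value (df = n − 2 on
the reduced fit), and the joint p-value takes the maximum absolute residual
with Šidák correction for the number of designated states.  Frequencies are
compared on the raw scale; several states can be rare in small genomes and
a log scale would let them dominate.

## Region rates, gene classes, metagene

Every position receives exactly one region class by precedence
CDS > intron > TE > centromere > intergenic (configurable), so per-class
base and call counts partition the genome and the call set; "intergenic"
therefore means non-TE, non-centromeric intergenic sequence.  Paired
region comparisons use a paired t-test across the 96 class-normalized
rates, excluding zero-denominator classes (df adjusted); both the mean
per-class ratio and the ratio of mean rates are reported because the former
is inflated by small-count noise (Jensen's inequality) while the latter is
not.

Gene-class heterogeneity tests observed per-class call counts in a feature
(CDS or intron) against expectation proportional to class feature bp — the
rate-homogeneity null — by chi-square with df = 3, with per-gene rates
giving the class s.e.m. and a validity flag when any expected count is
below 5.  Genes carry one of four classes (essential, morphological,
cellular/biochemical, environmental) in proportions 719:861:297:522,
matching curated phenotype-class sizes.

Metagene profiles anchor at the stranded gene start (TSS) and end (TTS),
flip minus-strand genes, and accumulate events into uniform bins over
±window (defaults 3,000 bp window, 100 bp bins — exposed, not claimed from
any external convention); density is events per bp per anchored gene, and
an event inside several genes' windows counts once per window.  The same
machinery profiles real calls, simulated homopolymer errors, and TE base
pairs, which is what lets a composition profile (TEs, runs) be compared
bin-by-bin against a call profile.

## The synthetic generator

The generator emulates a selfing-plant resequencing study in miniature.
Defaults (all exposed on `SimulationConfig`): 5 chromosomes × 1 Mb, 36% GC
(an Arabidopsis-like base composition), 1,000 genes of 4×300 bp exons and
3×300 bp introns, one central centromere covering 10% of each chromosome,
TEs covering 30% of intergenic gaps, and 100 samples.  Sizes are chosen so
that every analysis has comfortable counts while a full study runs in
seconds.

*Runs.*  Background sequence is generated free of homopolymer runs at or
above the detection threshold (4 bp); A/T runs with lengths uniform on
4–12 are then seeded explicitly — at 5×10⁻⁴ per bp in CDS and 5-fold that
in introns and intergenic space — with flanking bases forced to G/C so
every run is maximal with known length.  Seeded runs keep more than twice
the bleed window apart, so every injected bleed call is attributable to a
unique run; run-density enrichment and the distance histogram are then
exact ground truth rather than estimates.  Real genomes, by contrast, have
a continuous background of short runs; the suppression is a deliberate
idealization that makes recall-by-construction testable.

*True mutations* (default 5,000) sample positions with weight 1, raised
10-fold at the C and G of every CpG (methylated-CpG hypermutability;
those positions mutate to T/A respectively), 4-fold across TEs
(methylation-mediated TE instability), and by a configurable factor on
essential-gene bodies (default 1 — the homogeneity null).  Multipliers
stack.  All true calls have ≥2 reads on each strand.

*Bleed errors* (default 2,500) pick an A/T run with per-bp rate
proportional to 10^(0.27·length) — the run weight is length×10^(slope·length),
which makes the configured slope exactly the estimand of the run-length
regression — then a position at distance d ∈ [0,5] outside the run with
probability ∝ exp(−d/1 bp); the alternate allele is the run base.  80% of
bleed calls have support on only one strand; 30% spawn same-read co-errors
stepping 2 bp further from the run (the ACACA pattern), capped at the
proximity window.  Bleed errors may recur at one position across samples,
as a mechanism-driven artifact does; positions never collide across
provenance classes (colliding draws are redrawn), so the ledger tags stay
unambiguous and counts exact.  The generator injects substitutions only;
the classifier additionally handles single-base indels.

*Mis-mapping* injects 400 clusters of 3 calls within 10 bp (one sample per
cluster, half anchored inside centromeres) and 30 recurrent sites, each
called identically in 12 samples.

One seed drives four named substreams (genome, truth, bleed, cluster), so
stages can be regenerated independently; output is deterministic given the
seed.

**What passing tests do and do not show.**  The generator reproduces the
*mechanisms* (run-length dependence, decay, strand bias, co-errors,
clustering, recurrence, centromere bias, CpG/TE hypermutability) but not
read-level reality: no FASTQ, no quality scores, no mapping, no coverage
variation, no true indel artifacts, and a homopolymer landscape far
sparser and cleaner than a real genome's.  Parameter recovery here
demonstrates the estimators are consistent under their own model, not that
real data meet that model.

## Numerical and policy choices

* Default filter policy: ≥2 reads per strand, ≥4 total, site shared by ≤10
  samples.  Unknown support fails strand rules.  "Uncallable" is judged
  from the query call's own evidence; reference-coverage checks that a
  full pipeline would add are out of scope here.
* Concordance matches on (chrom, pos, ref, alt, sample); `ignore_sample`
  relaxes to site+allele.
* Zero-rate regression bins are dropped, never pseudocounted; the count of
  dropped bins is reported.
* Identical vectors in the paired t-test return t = 0, p = 1 rather than
  the 0/0 of the naive formula.
* The stationary solve raises if the solve and the internal power
  iteration disagree beyond 1e-6, or if the chain is reducible (components
  are reported).
* Duplicate calls (same chrom/pos/ref/alt/sample) collapse with a warning;
  VCF multi-allelic records decompose into one call per alternate allele.

## Known limitations

* The bleed classifier cannot distinguish an injected artifact from a true
  mutation that legitimately sits near a run with a matching allele; its
  false-positive rate is bounded by run density × window and is visible in
  the worked example (28.0% detected vs 27.6% injected).
* The outlier test treats the 16 dinucleotide frequencies as independent
  observations; they are compositional (they sum to 1), which the t
  reference distribution ignores.  The type-I calibration test shows the
  effect is small at these sizes.
* Gene-class s.e.m. uses per-gene rates of mostly-zero counts and is a
  descriptive error bar, not an inferential one; the chi-square is the
  test.
* GFF3 support covers the vocabulary this pipeline needs (gene, exon, CDS,
  intron, TE, centromere); other feature types are ignored on read.
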
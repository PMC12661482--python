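# Methods

`rohbench` is a controlled experiment on runs-of-homozygosity (ROH)
detection.  Instead of asking how well a caller does on real resequencing
data — where the truth is unknown — it plants known ROH into synthetic
diploid genomes, re-detects them through a full sequencing-and-calling
pipeline, and measures the bias of the inbreeding coefficient
F_ROH = (total ROH length) / (genome length) as a function of sequencing
depth, read length, reference contiguity and reference divergence.

## The synthetic population

A reference genome of `n_contigs` i.i.d.-uniform A/C/G/T contigs stands in
for a gapless chromosome-level assembly.  One diploid individual is planted
per target inbreeding level; the default ladder of eight levels spans
F_ROH = 5.66% to 47.73%, emulating a small inbred population of strongly
varying inbreeding.

Per individual:

- **ROH intervals** are drawn from a length mix over the reporting classes
  (0.5–1, 1–5, 5–10, 10–25 Mb; weights 0.25/0.50/0.20/0.05, lengths capped
  at 60% of the longest contig) and placed by slot-aware sampling until the
  total length matches the target F_ROH; the final interval is cut to the
  exact remaining deficit, so realised F_ROH sits within ±0.5 percentage
  points of the target (the configured tolerance).  Placement keeps
  ≥600 kb between intervals: the post-processing merge step joins detected
  segments across gaps ≤500 kb, and truth intervals closer than that would
  be merged *correctly*, making the truth/detected correspondence
  ill-defined.
- **Heterozygous SNPs** fall as a Poisson process at rate θ = 10⁻³ per base
  strictly outside the ROH.  θ is the package's choice of a realistic
  mammalian heterozygosity; the study organisms' values are not published
  per individual, and θ only sets the information density available to the
  caller.
- **Homozygous-alternate SNPs** fall at rate φ = θ genome-wide, inside ROH
  too.  Without them an ROH would contain no SNP sites at all and any
  density-based caller would reject it; real inbred genomes carry abundant
  homozygous variation inside IBD tracts.

The population is merged into one multi-sample variant table (the union of
sites; non-carriers are hom-ref there), which is what a jointly called VCF
looks like.  All coordinates are 0-based half-open internally and 1-based
only on VCF export.

## Sequencing and genotype calling

Each individual's genotypes are substituted into the reference to build two
haploid sequences (hom-alt on both, het on one chosen by a seeded fair
coin — inputs are unphased and phase is irrelevant to ROH truth).
Error-free paired-end fragments of Normal(500, 50) bp are placed uniformly
along each haplotype, `round(depth · L / (4 · read_len))` pairs per
haplotype so the pooled diploid coverage equals the nominal depth.  Lower
depths are derived by Bernoulli-thinning one master read set, preserving
across-depth correlation, exactly as one would subsample a real FASTQ.

Because reads are simulated, each knows its source haplotype, so genotypes
are called by an exact origin-aware pileup instead of a mapping stage: per
site, reads from each haplotype contribute that haplotype's allele
(optionally flipped with probability `base_err`; default 0).  The call rule
is threshold-based: fewer than `min_depth` reads → missing; both alleles
seen at least `min_allele_reads` times → het; otherwise the homozygote of
the majority allele.  This is the simplest mechanism that produces the two
phenomena under study: per-site missingness P(n < min_depth) and
heterozygote→homozygote *allele dropout*, which for a site covered by n
reads occurs with probability exactly 2^(1−n).

`min_depth` defaults to 1: production callers emit genotypes from a single
read, and with this default the under→over transition of the depth
response sits at 2–3×, where the depth bias of low-coverage pipelines is
observed in practice.  With stricter thresholds the whole response shifts
right; the knob is exposed.

The SNP error ratio is reported as erroneously called SNPs over the number
of SNPs genotyped (non-missing calls), with the missingness rate reported
separately — the error ratio tracks call quality, the missingness rate
tracks call completeness.

## ROH detection

The window caller reimplements the two-step PLINK procedure with the seven
standard knobs (n1–n7):

1. *LD pruning* (`--indep-pairwise n1 n2 n3`): a sliding window (n1 sites,
   or kilobases via a unit flag — the bare "50" of the usual command line
   is a SNP-count window, which is the default here) advancing n2 sites;
   whenever a pair of surviving sites has squared Pearson dosage
   correlation above n3 (missing genotypes excluded pairwise), the later
   site is removed.  Each pair is decided at the first window containing
   both sites; since a surviving pair keeps its r², this is equivalent to
   the literal re-scan, and the test suite checks that equivalence against
   a brute-force oracle.
2. *Homozygosity scan* (`--homozyg`): windows of n4 = 50 sites; a window is
   homozygous if it has ≤1 het and ≤5 missing calls; a site passes if ≥5%
   of the windows containing it are homozygous; maximal runs of passing
   sites are trimmed to homozygous non-missing ends, split at inter-site
   gaps >1 Mb, and kept if span ≥ n6 = 500 kb, sites ≥ n7 = 100 and mean
   density ≤ n5 = 50 kb/SNP.  The unstated allowances are the PLINK 1.9
   defaults; density is the mean span/count test (PLINK's semantics), not a
   local sliding density.

Detected segments are *gap-merged* — adjacent segments concatenate when the
gap between them is ≤500 kb AND at least one flank is ≥4 Mb, repeated to
fixpoint — and finally filtered to spans strictly >500 kb, the reporting
convention for all summaries.  The merge rule is reconstructed from the
stated failure condition of merging (fragments shorter than 4 Mb, or gaps
longer than 500 kb, stay fragmented) and both thresholds are flags.

Pruning is off in the default sweep pipeline: the planted individuals are
statistically independent, so consecutive sites private to one individual
have identical dosage columns (r² = 1) and pruning at r² = 0.8 would strip
most informative sites — an artefact of planted rather than coalescent
genotypes.  The pruning step is fully implemented, oracle-tested, and
engaged by the presets and the parameter-grid driver.

A deliberately simplified two-state Viterbi HMM (distance-dependent
transitions 1 − exp(−d/mean_tract_len); per-site Bernoulli het emissions,
p_het in/out of ROH = 10⁻³/0.2 as per-*site* probabilities; missing sites
uninformative) is provided as the alternative caller; it exists to show
rule-based and HMM callers disagree mainly on sub-500 kb fragments, not to
clone any particular tool.

## Reference degradation

Contiguity is degraded by iterative random insertion of 300-bp N runs;
contig N50 and maximum contig length are computed from the non-N segments
after every cycle, and a descending target ladder picks the closest
snapshots (within a factor of two).  Ns **replace** bases, so coordinates —
truth intervals, variant positions — stay valid across the ladder; with a
lift-over the comparisons would be identical, and replacement removes that
entire subsystem.

Fragmentation reaches the caller as an error channel on the genotype calls
(reads are not re-mapped): sites inside N runs become missing ("omitted"),
and sites within 5 kb of a gap boundary flip hom↔het with probability 0.02
("erroneous").  The window/probability pair is an artifact parameter —
the consequence (long ROH break at assembly gaps) is what is being
modelled, the per-site error process around a gap is not published — and
both are exposed.  A few flipped hets at a gap make the local windows fail,
splitting the ROH there; whether the pieces reunite is then exactly the
gap-merge rule above, which is how the N50 response and its failure mode
arise.

Reference divergence (a related-species reference) is emulated
phenomenologically: base substitutions at a configurable rate plus
rearrangement breakpoints that shuffle segment order and orientation
("mosaic-like collinearity").  Downstream, the breakpoints act as an
implied gap map — the stated mechanism by which a diverged reference
behaves like a fragmented one — and substitutions as extra apparent
homozygous differences.  Cross-species read mapping itself is out of scope.

## Problem sizes

The default study scale is 2 contigs × 25 Mb for saturating-depth truth
recovery and 2 × 10 Mb for the replicated sweeps (8 individuals, 10 seeds
for the depth and contiguity axes), the package's choice of a scale large
enough for stable ≥500 kb ROH statistics while keeping a full sweep in
minutes on one core.  The full-genome axes (15 depth levels to 100×, 13
N50 levels) are configuration, not defaults.

## Numerical and design notes

- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical seeds give bit-identical outputs,
  and sweep tables are byte-reproducible.
- A depth cell simulated at its master depth equals a direct simulation at
  that depth (thinning with fraction 1 is the identity), which keeps shared
  cells consistent across sweep groups.
- ROH placement failure (target unreachable with the configured mix,
  separation and genome size) raises a generation error after bounded
  retries; a documented failure beats a silently biased truth set.  The
  lowest default target (5.66%) needs ≥ ~8.5 Mb of genome for one
  minimum-length ROH within tolerance.
- Length classes are right-closed above (a 5 Mb segment is in the 1–5 Mb
  class), matching the printed reporting convention.
- The correct-detection rule for a truth segment is reciprocal overlap:
  detected segments must cover ≥ q of it and overhang it by ≤ (1−q) of its
  length, q = 0.9 by default and reported with results; the criterion is a
  stated convention, not an inference.
- F_ROH always divides by the *original* genome length, also on fragmented
  references (coordinates are preserved by design), keeping the
  denominator fixed across the ladder.

## What the generator does not model

No recombination or pedigree structure (ROH are planted, not inherited),
no mutation spectrum, no sequencing-error profiles or ancient-DNA damage,
no CNVs, no mapping-quality effects, no X chromosome.  Consequently,
passing tests show the *detection machinery's* response to depth,
contiguity and divergence under clean conditions; they do not certify
performance on real libraries, where alignment artefacts and error spectra
add further biases on top of the ones measured here.
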
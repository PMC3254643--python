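# Methods

This note records the model, the defaults, and the choices made where the
procedure was genuinely open, in enough detail to re-derive or deliberately
change any of them.

## The statistic

The pipeline's distance between two samples is built from *directed*
comparisons.  For the ordered pair (a → b), sample a's common-region reads
are aligned to sample b's consensus references; at every reference site
the consensus of a's aligned reads is called, and a SNP is a site where
that consensus differs from b's reference base.  The directed rate divides
the SNP count by the **sum of aligned read lengths**, not by the reference
span.  Consequences worth being explicit about:

* the rate scales inversely with coverage depth (the same divergence
  sequenced twice as deep yields half the rate).  This is intentional: it
  up-weights SNPs discovered by samples with few reads, which would
  otherwise be under-represented, and it is why duplicating every read
  halves the rate without changing the SNP count (asserted in the tests);
* the two directions of a pair differ (different references, different
  read sets); the symmetric distance is their mean, D(a,b) =
  (r(a→b) + r(b→a))/2;
* distances are therefore comparable *within* a panel processed together,
  not across studies with different depths.

Reported matrices are rounded half-away-from-zero at 8 decimal places.

## Consensus calling and ploidy

Site consensus (both in reference polishing and SNP calling) is the most
frequent base, requiring depth ≥ `min_depth` (default 3) and allele
fraction ≥ `min_allele_fraction` (default 1/(2·ploidy), with the *query*
sample's ploidy).  For a triploid, one homoeologous copy contributes an
expected one third of reads; the 1/6 floor means a single diverged
homoeolog can never flip the consensus away from the majority allele, which
is the behaviour a ploidy-aware caller run with three haplotypes would
give.  Frequency ties resolve to the alphabetically first base and are
counted in the log.  Calls below the gates are no-calls and contribute no
SNPs (their bases still count in the denominator, which is defined by
aligned reads, not by called sites).

## Assembly

A deliberately small de Bruijn assembler is used for all three assembly
phases (pooled, per-sample, k-sweep):

* nodes are k-mers from both strands (odd k only, so no k-mer is its own
  reverse complement); no coverage cutoff and no expected-coverage
  parameter, since transcript coverage is uneven by nature;
* dead-end tips shorter than 2k nodes are trimmed — with reads shorter
  than 2k+1 bases, a sequencing error almost always produces a tip;
* variant and error bubbles are merged tour-bus style: a bounded BFS from
  each branching node finds the nearest reconvergence of two paths and
  deletes the weaker arm (total k-mer coverage; ties by canonical arm
  sequence, so both strand twins resolve identically).  Merging iterates
  to a fixed point, which resolves the dense, staggered chains of bubbles
  that arise when several diverged samples and homoeologs are pooled;
* maximal unbranched paths become contigs, deduplicated to the
  lexicographically smaller strand and numbered by (length desc, sequence),
  making contig identifiers reproducible;
* reads are placed back by anchoring any exact k-mer and accepting the
  best full-length gapless fit with at most `placement_max_mismatches`
  (default 3) mismatches; ties in quality go to the lowest contig id.

Mismatch-tolerant placement (rather than exact-substring placement) is
essential, not cosmetic: after bubbles are merged toward the majority
allele, the reads that *carry* the minority alleles — exactly the reads the
SNP stage needs — no longer match any contig exactly.  Exact placement
would silently restrict the common regions to invariant sequence and drive
all downstream SNP counts to zero.

The default k is 19 for 40 bp reads, for a specific reason: a read with
one mismatch at position p has an exact k-mer on one side of it provided
p < k or p ≥ (L − k), which covers *every* p only when L ≥ 2k.  At k = 31
most variant-spanning reads would have no anchor and be dropped; at
k ≤ L/2 none are.  k = 19 is the largest odd value satisfying this for
40 bp reads while staying far above the random-collision scale of a
transcriptome-sized k-mer space.

## Alignment

Seed-and-extend, gapless: the first 20 bases of the read (on each strand)
must match a reference exactly; candidates are extended over the full read
and kept if mismatches ≤ 3.  A tie between distinct best placements leaves
the read unmapped — paralogs should not donate SNPs.  Gapless alignment is
appropriate for 40 bp reads and a SNP-only analysis; indels are out of
scope throughout.

## Trees and support

Neighbor joining is the classical Saitou–Nei formulation, exact on
additive matrices (property-tested against path-distance oracles of random
trees).  Q-criterion ties join the lexicographically smallest label pair;
negative branch lengths are clamped to zero and logged.  Bootstrap
resampling operates on the aligned reads within each directed pair — the
natural exchangeable unit of the rate statistic — with the original count
restored in every replicate; supports are the percentage of replicate
trees containing each split, attached to the strict-majority (>50%)
consensus.  Splits at exactly 50% are excluded.

## Assembly evaluation

For transcript assemblies, N50 and the single longest contig respond
poorly to k; the selection metric is the mean length of the 100 longest
contigs (all contigs if fewer).  The independent validation metric counts
reference bases covered by maximal exact matches ≥ 50 bp (either strand),
accepted greedily by decreasing length with overlapping matches on the
same reference *discarded*, not clipped — 100%-identity, non-overlapping
coverage.  Exact-match semantics replace a megablast-at-100%-identity
step; at full identity the two are equivalent, and the 50 bp floor
suppresses chance matches.

## The generator and the study conditions

The synthetic module emulates the data the pipeline targets: S samples
related by a known unrooted binary tree; Jukes–Cantor substitutions along
branches (the simplest model with the closed form p = 3/4·(1−e^{−4d/3})
used for calibration checks); ploidy-p samples carrying p haplotype copies
further mutated by `homoeolog_divergence`; per-taxon per-locus log-normal
expression weights (σ = 1.0) emulating differential expression; uniform
per-base substitution errors; a trailing-N artifact hitting 61% of reads
by default, and optional internal Ns.  Reads are 40 bp, single-end,
strand-uniform, quality placeholder only.

Defaults for the validation cohorts: 7 samples (six triploid, one
diploid), 40 loci × 600 bp at 30× depth, internal branches 0.005–0.008 and
external branches 0.001–0.002 substitutions/site, homoeolog divergence
0.001, error rate 0.001.  The branch-length split reflects the scientific
question — internal branches carry the topology signal being tested, while
closely related cultivars have short terminal branches — and the locus
count and length were sized so a study of 20 cohorts completes in minutes
on one core while leaving dozens of expected substitutions per internal
branch, far above the noise floor.  The k-sweep test-bed uses 15 gene
families × 4 paralogs at 12% divergence (so small k has a genuine
misassembly incentive), ~600 bp transcripts at 20× depth with 0.4% error
(so large k fragments on coverage gaps), giving both metrics an interior
optimum.

What the generator does **not** emulate, and hence what passing tests do
not establish about real data: indels, quality-score error profiles,
paired ends, PCR duplicates, splice isoforms, and realistic homoeologous
divergence — real polyploid homoeologs can differ by percents, far more
than the default here, and would fragment the common regions more than the
simulations do.  Recovery rates on synthetic cohorts are evidence about
the pipeline's statistical machinery, not a field-performance guarantee.

## Numerical and degenerate-input conventions

Reporting rounds half-away-from-zero at 8 decimals.  All randomness flows
through seeded NumPy generators; identical seeds give byte-identical
FASTQ, tables and manifests (checksummed per run).  Empty read sets,
empty references, all-zero expression weights, k out of range, missing
pair directions and sub-3-taxon NJ all raise immediately with the
offending entity named.  Reads left shorter than 20 bp after trimming are
discarded (counted separately); consensus references shorter than the
read length are dropped because no full-length read can align to them.
With two samples the pipeline still produces QC, rates and the distance
matrix but skips tree inference.

## Known limitations

* SNP sites inside the ~k bases flanking contig ends are under-covered;
  distances are slightly deflated for very close pairs.
* The rate statistic confounds divergence with depth (by design); branch
  lengths of the NJ tree are in per-aligned-base units, not
  substitutions/site.
* The assembler's bubble merging assumes variant density well below 1/k;
  pooling samples beyond a few percent divergence will fragment common
  regions sharply.
* Bootstrap resampling of reads captures sampling noise of the rate
  estimates, not assembly uncertainty: the assemblies and alignments are
  fixed across replicates.
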
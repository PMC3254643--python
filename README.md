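# snptree — reference-free SNP phylogenetics from short-read transcriptome data

`snptree` distinguishes closely related plant genotypes — lines that marker
panels such as AFLP often cannot separate — directly from raw short cDNA
reads, without any reference genome.  It was built around the setting of
clonally propagated bioenergy grasses: a panel of *Miscanthus* cultivars
sequenced as ~40 bp single-end Illumina cDNA reads, most samples triploid,
with no genome assembly available.

## The method

For samples $1..S$, each contributing a FASTQ of short reads:

1. **QC** — a single trailing `N` (an artifact of early Illumina chemistry
   that can affect >60% of reads) is trimmed; any read still containing `N`
   is discarded.
2. **Common regions** — reads from all samples are pooled and assembled with
   a simplified de Bruijn assembler (no coverage cutoff, tips trimmed,
   variant bubbles merged toward the majority arm).  Only contigs carrying
   at least one read from *every* sample are kept: these are the cDNA
   regions expressed and sequenced in the whole panel, the only regions in
   which all samples can be compared.
3. **Per-sample consensus** — each sample's common-region reads are
   re-assembled alone and polished to the per-position majority base,
   yielding consensus reference sequences per sample.
4. **Directed SNP rates** — for every ordered pair $(a \to b)$, sample $a$'s
   reads are aligned gaplessly (seed-and-extend) to sample $b$'s consensus.
   A SNP is a site where the ploidy-aware consensus of $a$'s aligned reads
   differs from $b$'s reference base; with ploidy $p$ a base must reach
   depth ≥ 3 and allele fraction ≥ $1/2p$ to be called, so a single
   homoeologous copy of a triploid cannot flip a call.  The directed rate is

   $$r_{a\to b} = \frac{\#\text{SNP sites}}{\sum_{\text{aligned reads}} \text{read length}},$$

   i.e. SNPs **per aligned base**, which deliberately up-weights SNPs found
   by samples with few reads.
5. **Distance and tree** — the symmetric distance is the mean of
   reciprocals, $D_{ab} = (r_{a\to b} + r_{b\to a})/2$; the tree is
   classical neighbor joining, with node support from 200 bootstrap
   replicates (each directed pair's aligned reads resampled with
   replacement, rates and NJ recomputed, majority-rule consensus).

A second component evaluates de novo *transcript* assemblies across k-mer
sizes: N50, longest contig, total length, and the **mean length of the 100
longest contigs** — the selection metric appropriate for transcript data,
where expected coverage is meaningless — validated against the number of
reference-transcript bases covered by non-overlapping 100%-identity matches.

A synthetic-data module generates multi-sample read sets from a known
phylogeny (Jukes–Cantor substitutions, triploid homoeolog copies,
log-normal expression skew, per-base errors, trailing-N artifact), so the
whole pipeline can be validated by exact topology recovery.

## Worked example

The package ships the 42 published directed SNP/bp rates for a seven-sample
*Miscanthus* panel — three 'Freedom' accessions (FF, FO, FN), 'Illinois'
(I), 'Canada' (C), a plant labelled *M. floridulus* (F) and a diploid
*M. sinensis* outgroup (MS).  `python analysis/01_reproduce_distance_matrix.py`
averages them into the distance matrix and prints:

```
	FF	FO	FN	I	C	F	MS
FF	-
FO	0.00036395	-
FN	0.00035394	0.00035940	-
I	0.00037910	0.00038370	0.00039340	-
C	0.00035337	0.00035939	0.00037356	0.00039326	-
F	0.00032469	0.00031221	0.00032834	0.00032252	0.00030237	-
MS	0.00036052	0.00037322	0.00039360	0.00041745	0.00038531	0.00041991	-

The three 'Freedom' samples are mutually closer (max 0.00036395) than any
of them is to 'Illinois' (min 0.00037910).
```

together with the NJ tree in Newick.  Each entry is the mean number of SNPs
per aligned base between two samples over their common cDNA regions — a
normalised measure of genetic variation; e.g. FF vs FO is
(0.000413390 + 0.000314511)/2 = 0.00036395.

The remaining drivers run the synthetic studies:

```sh
python analysis/02_simulate_cohort.py          # 7-sample cohort + truth tree
python analysis/03_snp_phylogeny.py            # full pipeline, RF vs truth
python analysis/04_topology_recovery.py        # recovery rate over 20 cohorts
python analysis/05_assembly_ksweep.py          # k sweep + identity validation
```

There is also a CLI (`snptree simulate|qc|common-regions|consensus|pairdist|tree|asm-metrics|run-all`)
wrapping the same library calls.

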
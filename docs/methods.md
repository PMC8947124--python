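# Methods

## The estimation problem

Shotgun metagenomic reads from a community of bacteria are mapped against a
reference set holding one representative genome per species-level genome
bin (SGB). Two genomes that share sequence (conserved operons, mobile
elements, closely related species) attract each other's reads, so naive
read counting both miscounts abundant species and hallucinates absent ones.
URA (Unique Relative Abundance) sidesteps this by construction: only reads
whose best mapping is to a location that is *unique within the whole
reference set* are counted, and coverage is measured per window of fixed
unique-read capacity rather than per base.

## Reference build

For a fixed read length `r` (default 100 bp), every substring of every
representative is enumerated with a one-base step. A substring is **unique**
when its strand-canonical form (the lexicographic minimum of the substring
and its reverse complement) occurs at exactly one `(genome, position)` pair
over the entire set. Canonicalization emulates the strand-agnostic behavior
of a short-read aligner; a read occurring twice within one genome is
non-unique under this definition, matching what an aligner would report as
a multi-mapping read. Substrings containing `N` are excluded; coordinates
are 0-based with half-open intervals.

The unique start positions of each genome, in genomic order, are grouped
into consecutive **windows of exactly W = 100 unique positions**. Windows
vary in genomic span (sparse-uniqueness regions yield long windows) but
hold identical unique capacity, which makes expected per-window read counts
equal across genomes at equal copy-number abundance — the core premise of
the estimator, and the reason genome length and uniqueness fraction cancel
out. A trailing group of fewer than W positions is discarded so every
window is strictly comparable.

Representative selection keeps an SGB when its genus appears exactly once
in the metadata or when it is supported by at least 5 assemblies; small
same-genus splinter bins are presumed clustering artifacts. An optional
MinHash (Mash) screen flags representative pairs closer than distance 0.05
— close pairs starve each other of unique reads. The sketch uses canonical
k-mers (k = 21, sketch size 1000 by default) hashed with BLAKE2b 8-byte
digests (deterministic across processes, unlike Python's salted builtin
hash), and the distance is `D = -(1/k) ln(2J/(1+J))` with `J` the
bottom-s merged-sketch Jaccard estimate; `J = 0` is capped at `D = 1`.
Sub-threshold pairs produce warnings, not failures: the build may
legitimately proceed with reduced sensitivity for those genomes.

## Read assignment

The shipped mapper is exact-match: a sample read is canonicalized and
looked up in the substring table, giving `unique` (one occurrence),
`multi` (several) or `unmapped` (none, wrong length, or contains `N`).
Exactness is self-consistent with the build, which enumerates exact
substrings; mismatch-tolerant mapping is delegated to external aligners
via SAM import, where a read is unique iff exactly one non-supplementary
alignment carries an alignment score (`AS`) of at least −40 (configurable)
— a co-optimal secondary alignment therefore demotes the read to multi.

Samples are downsampled to a fixed mapped-read depth (unique + multi reads,
uniformly without replacement, deterministic per seed; all reads kept when
fewer are available) so that abundance estimates are comparable across
sequencing efforts. Unique assignments whose start position belongs to a
window increment that window; positions in the trailing remainder count
nowhere; a "unique" position unknown to the database raises, signalling a
database/sample mismatch.

## Coverage estimation and presence calling

Per genome, with window-count vector `c` of length `N` and mean `m`
(zeros included — zero windows are informative of absence, and the dense
mean later discounts strain deletions):

1. **Enlargement.** `k = argmin_{k≥1} |k·m − 20|` (ties to smaller k)
   consecutive windows are summed so the typical summed count is about 20
   reads — large enough to be informative for low-abundance genomes. A
   diagnostic flag records whether `k·m` lands in the intended
   [13.3, 30] band; an integer k cannot always achieve it, so the band is
   not a gate. If `m = 0` or at most 5 enlarged windows would remain
   (`floor(N/k) ≤ 5`), the genome is called absent outright.
2. **Dense mean.** Sort the `n = floor(N/k)` summed counts; among all
   contiguous runs of `ceil(n/2)` sorted values take the one with minimal
   (max − min); ties go to the run containing the lower median (index
   `(n−1)//2` of the sorted vector), then leftmost. The run mean estimates
   the summed-window coverage; a plain mean would be dragged up by hot
   regions (plasmids, amplifications, horizontal transfer that escaped
   the uniqueness filter) and down by segments of the representative the
   sampled strain lacks.
3. **Presence.** The genome is present iff the selected run's minimum is
   strictly positive — if the densest half of the coverage distribution
   includes a zero-count window, the modal state of the genome is
   "uncovered" and it is called absent with coverage exactly 0. Present
   genomes get `coverage = dense mean / k`, reads per unique-capacity
   window.

Relative abundances are each present genome's coverage divided by the sum
over present genomes; they live on the simplex (fractions, `--percent` on
the CLI rescales to 100) and are proportional to genome *copy number*,
not read share.

The dense mean of a right-skewed count distribution sits a few percent
below the arithmetic mean (about 5% low for Poisson(20) summed counts).
Because enlargement drives every genome toward the same ~20-read regime,
this small bias is shared across genomes and cancels in the normalized
abundances; the benchmarks below confirm recovery at r > 0.999 despite it.

## Association statistics

* **Alpha diversity**: Shannon index of each sample's abundance vector,
  base 2 by default (configurable), after renormalizing nonzero entries.
* **Deciles**: samples ranked by diversity and split into ten near-equal
  bins (stable order on ties); per phenotype, a two-sided Mann–Whitney
  test contrasts the extreme bins, with Benjamini–Hochberg FDR across
  phenotypes. Exact enumeration is used when both groups have at most 20
  untied values, otherwise the tie-corrected normal approximation; fully
  tied inputs short-circuit to p = 1.
* **Running averages**: samples sorted by a phenotype; means of windows
  advanced by a fixed shift (final partial window dropped) trace the
  diversity trend along the phenotype.
* **Correlation atlas**: per (species, phenotype), Spearman (average
  ranks) and Pearson on pairwise-complete observations of log10
  abundances floored at 1e-5 (floor recorded in output metadata);
  BH-FDR within each phenotype family over the Spearman p-values;
  zero-variance species are reported with NaN statistics and excluded
  from the family.
* **KO pseudo-abundance**: for each KEGG ortholog,
  `Σ_species RA × copy number` (the copy-weighted form; a presence-sum
  variant is available behind `weight_by_copies=False`). KOs with fewer
  than 5 total copies across representatives are excluded — they add
  nothing over single-species abundances.
* **Enrichment**: KOs scored by their association with a phenotype;
  member scores of each module/pathway vs all non-member scores by
  two-sided Mann–Whitney, BH-FDR within the module family and within
  the pathway family separately, with the sign of the median difference
  reported.

## Synthetic data

The simulator emulates exactly the structures the estimator must handle:
i.i.d. uniform ACGT representatives with optional verbatim shared blocks
(defeating uniqueness locally); strains derived from representatives by
block deletions (a deletion fraction split over a few contiguous blocks,
default 4 — strain absence is block-like, not scattered), tandem CNV
amplifications and per-base substitutions; error-free fixed-length reads
with multinomial genome origins weighted by copy-number abundance × strain
length, uniform positions and strands; and phenotypes that are noisy
linear functions of log10 abundances with a recorded signal fraction.

It deliberately omits sequencing error and quality models, paired ends,
GC and coverage biases, and real phylogenetic sequence structure. Passing
the benchmarks therefore demonstrates the estimator's combinatorial and
statistical correctness under its own model assumptions — not performance
on real gut metagenomes, where mismatch-tolerant alignment (via the SAM
import path) and quality control happen upstream.

## Benchmark conditions

The standard conditions, used by the test suite and `scripts/acceptance.py`:

* **Recovery**: 20 genomes × 50 kb, read length 100, windows of 100 unique
  positions; flat Dirichlet(1) abundances over 18 genomes with 2 held at
  exactly zero (so both presence and absence calls are exercised in one
  experiment); 2M error-free reads, downsampling depth 2M. Reported:
  Pearson/Spearman r of true vs estimated abundances, presence/absence
  call accuracy.
* **Deletion robustness**: same community with 20% of every strain
  deleted in 4 blocks.
* **CNV robustness**: 4 genomes × 20 kb at equal abundance, 200 k reads;
  genome 0 carries a 10× tandem amplification covering 5% of its genome;
  inflation = its coverage over the median of the others − 1, median over
  20 seeds. The smaller community keeps the 20-seed sweep cheap; the
  per-genome window statistics match the recovery setting.
* **Atlas calibration**: 500 samples × 40 Dirichlet(1) species;
  20 null seeds (phenotype = pure N(0,1) noise) for the false-positive
  rate at BH q < 0.05, and 50 seeds with a planted weight of 1.0 on one
  species' log10 abundance (noise sd 1.0) for sign recovery, plus a
  two-species opposite-sign design.

## Numerical and degenerate-input conventions

* Empty count vectors, empty read sets and all-absent samples produce
  absent calls / empty flagged profiles, never exceptions.
* Dense-run tie-breaking (lower-median containment, then leftmost) is the
  package's convention and is what the exhaustive-search oracle in the
  test suite implements; both appear in output metadata implicitly through
  determinism.
* Palindromic reads equal their reverse complement and are counted once at
  their position.
* All randomness flows through `numpy.random.default_rng` seeds; every
  simulation function is reproducible bit-for-bit given its seed.

## Known limitations

* The exact mapper tolerates no mismatches: reads crossing a simulated SNP
  go unmapped. Real-data use requires an external aligner and SAM import.
* Strain-level (within-SGB) resolution is out of scope: representatives
  closer than Mash 0.05 undercut each other's uniqueness.
* Absolute abundances are not estimable; outputs are compositional.
* With very small enlarged-window counts (6–10), the dense mean is noisy
  and presence calls near the detection limit (roughly when a genome's
  expected read count per window falls so low that k exceeds N/6) become
  conservative absences by design.
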
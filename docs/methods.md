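# Methods

`oysterkit` re-implements, as a tested pipeline over synthetic data, the
bespoke computational steps used to produce and annotate a chromosome-level
assembly of a highly heterozygous bivalve genome: k-mer genome profiling,
iterative haplotig purging, coverage-based assembly QC, SV-based error
filtering, linkage-map anchoring, and structure-based Helitron/Helentron
annotation with family clustering and density statistics.  Because the real
analyses run on ~50–70× whole-genome data for a ~650-Mb genome, every stage
here is exercised on generated genomes with planted ground truth at desk
scale (0.3–5 Mb), and correctness is established by parameter recovery and
oracle equivalence rather than by reproducing survey-scale numbers.

## Synthetic data generator

The generator (`simulate`) defines the study conditions; its defaults are
the observed statistics of the system being emulated.

**Elements.** Helitron-like elements have length ~ Normal(1092, 558) bp
truncated at 200 bp (negative lengths are impossible; the truncated mean is
~1158 bp and tests compare against the analytic truncated mean).  Each
element starts `TC`, ends `CTAG`, and carries a perfect palindromic hairpin
of span 16/18/20 bp (loop 0) with a GC-rich stem (stem GC ≥ 0.6), ending
2–12 bp upstream of the terminal `CTAG`.  Elements insert between the A and
T of a host `AT` dinucleotide with probability 0.86, else at a uniform
non-AT position; strands are drawn 50/50.  Substructure rates default to
the observed fractions: subTIR 0.342, 5′ IR 0.33 (of subTIR carriers),
5′ microsatellite 0.0013.  Family members share an exact 30-bp terminus
(20-bp palindrome + 6-bp spacer + `CTAG`).

Two constraints keep the generator/detector round trip exact:

* element-internal sequence never contains `TC` except at position 0
  (palindromic parts also avoid `GA` so their reverse complements stay
  TC-free).  The screen pairs each 3′ terminus with the *nearest* upstream
  `TC` at a compatible distance; an interior `TC` ≥ 200 bp from the 3′ end
  would win that pairing and shift the recovered 5′ coordinate.
* the single host base flanking each planted subTIR copy is resampled if it
  would extend the inverted-repeat pair by chance; otherwise detectors
  recover a longer subTIR than was planted and the 5′-IR lookup (which
  matches the reverse complement of the *detected* subTIR) fails.

Elements are planted mutation-free by default, separating detector
correctness from robustness.  Planting a mixture of element groups happens
in one pass (`plant_many`): all insertion points are chosen on the
unmodified host so truth coordinates remain valid.

**Assemblies.** Chromosomes (default 3 × 400 kb, GC 0.33) are split into
even-sized contigs with ±20% jitter; a fraction (default 0.4) of contigs
gains a haplotig duplicate — a subsequence covering 50–100% of its source,
substituted at 3% per base, and at least 15 kb so it is comfortably above
the 10-kb removal floor of the purge rule.  Gene and repeat annotation
truth is drawn per 100-kb block from a shared latent intensity with
opposite sign for genes and repeats, producing the negative gene/repeat
density correlations typical of repeat-rich genomes.

**Depth, reads, markers, SVs.** Per-base depth is Poisson with a linear GC
bias on 1-kb window means; designated junk scaffolds receive 0.1× the mean
(several SD below it).  Reads (150 bp) are drawn uniformly from both
haplotypes and strands with substitution errors; the second haplotype is
the first substituted at the heterozygosity rate.  Markers get cM positions
linear in physical position (50 cM per chromosome) plus Gaussian noise, and
MAPQ values with a configurable low-MAPQ fraction.  The SV set plants
errors (≥ 50 bp, reference ratio < 0.2) among benign calls.

What the generator does **not** emulate: indels and structural divergence
between haplotypes, element degradation and nesting, sequencing-error
profiles beyond uniform substitutions, GC-dependent fragmentation, repeat
families other than the planted elements, and linkage-map genotyping error
beyond Gaussian cM noise.  Passing tests therefore demonstrate algorithmic
correctness under clean conditions, not field performance on real data.

## Detection screen (`heliscan`)

`find_hairpins` is a general inverted-repeat scanner: for each (start,
span) with span in [16, 20] it reports the largest stem whose arms are
reverse-complementary up to a mismatch budget (default stem ≥ 6, ≤ 1
mismatch), suppressing hairpins strictly nested inside another of equal
stem.  The genome screen, however, uses a stricter hairpin geometry:
perfect palindrome (no loop, no mismatches), stem ≥ 8, stem GC ≥ 0.5.  A
null-model calculation (and measurement on random 2-Mb sequence at oyster
GC) shows why: at the loose setting, CTAG occurrences (~1/330 bp) carry a
chance qualifying hairpin in the 2–30-bp gap window roughly half the time,
i.e. thousands of false 3′ termini per Mb; the strict geometry plus the GC
requirement brings this to ≲ 1 false element per Mb while remaining 100%
sensitive to the planted (perfect, GC-rich) hairpins.  GC-rich hairpins are
the canonical description of the Helitron 3′ structure.

Pairing takes, for each 3′ terminus, the nearest upstream `TC` giving an
element length in [200, 20000] bp (bracketing the 1092 ± 558 length scale);
the AT-site flag requires `A` immediately 5′ and `T` immediately 3′ of the
element.  Overlapping candidates on a strand are resolved by fewest hairpin
mismatches, then shortest element, then leftmost — the "shortest" rule also
ensures a downstream chance `CTAG` a few bases past a real terminus cannot
displace the true interval.  Both strands are scanned (reverse via reverse
complement, coordinates mapped back), making `scan(revcomp(G))` exactly the
mirror of `scan(G)`.

Known limitation: because the hairpin is a palindrome, the reverse
complement of an element's 3′ tail begins `CTAG...palindrome`, and if the
reverse-complemented interior happens to contain a `CTAG` at gap distance
(~8% of elements), an opposite-strand "shadow" candidate appears overlapping
the true element.  Cross-strand overlap resolution is deliberately not
applied; shadow candidates inflate raw counts slightly (measured ~8% on
dense plantings) and are absent from element-free sequence.

## Substructure screening and classification (`helentron`)

subTIRs are searched as the longest reverse-complementary pair between the
first and last 50-bp windows of an element, minimum 12 bp with 0 mismatches,
ties broken toward the termini (implemented as a diagonal two-pointer over
the 5′-window × revcomp(3′-window) match matrix; brute-force enumeration is
the test oracle).  The spec-suggested 10 bp/≤1 mismatch setting produces
~11% false subTIRs on random termini — enough to break binomial-CI recovery
of the planted 34.2% rate — so the stricter default was adopted; both knobs
are configurable.  The 5′ IR is a non-overlapping match to the reverse
complement of the subTIR's 5′ copy within the 5′ window; the microsatellite
is the longest perfect tandem run (unit 1–6, ≥ 3 copies, span ≥ 9) in the 5′
window.  Classification: no subTIR → `helitron`; subTIR with IR or
microsatellite → `helentron_like`; subTIR alone → `intermediate`.

## k-mer profiling (`kmer_profile`)

Canonical k-mers (2-bit encoding, lexicographic min of k-mer and reverse
complement; k odd) are counted with vectorized rolling codes; N-containing
windows are skipped.  The error cutoff is the first local minimum of the
histogram smoothed by a width-3 centered moving average.  Peaks are local
maxima above the cutoff; a diploid pair requires a depth ratio in [1.6,
2.4] and a partner at ≥ 10% of the primary peak's height (shot noise in the
sparse tail otherwise fabricates a partner for haploid spectra).  Genome
size is total informative mass over the homozygous peak depth (quadratic
peak interpolation refines the integer peak).  Heterozygosity uses the
het-peak mass fraction F (cutoff to the inter-peak valley):  a k-window is
heterozygous if any base differs between haplotypes, so F = 1 − (1 − h)^k
and h = 1 − (1 − F)^(1/k).  This is a transparent simplification of
mixture-model fitters (no negative-binomial mixture is fitted); recovery is
within ±0.3 pp at 1–2% and ±0.5 pp at 3.2% under the generator conditions.

## Haplotig purging (`purge`)

An internal approximate mapper makes the purge self-contained: canonical
minimizers (k = 15, w = 10, hashes mixed by a 64-bit finalizer so minimizer
choice is not lexicographic), matched per 500-bp query window; a window is
covered when ≥ 10 of its minimizers occur in the target, and the covered
fraction is the union of covered windows over the query length.  Repeat
intervals can be soft-masked (minimizers touching masked bases are dropped
on both sides).  The iterative rule: sort contigs by decreasing length
(ties by id), take the longest unprocessed as reference, remove any other
unprocessed contig mapping ≥ 30% of its length (inclusive) that is itself
longer than 10 kb (the length condition applies to the removed contig; the
alternative matched-span reading is exposed as `min_match_span`), keep the
reference, iterate.  Decisions match a chunk-wise exact edit-distance
oracle on 20-contig fixtures, and the procedure is idempotent on its own
output.  External keep-lists are intersected set-wise, with non-intersected
contigs reported as `external_only`, then the purge is re-run at identical
thresholds.

## Coverage QC and SV filter (`asm_qc`)

Median depth per 1-kb non-overlapping window; GC normalization by binned
median ratio (2% GC bins, ≥ 10 windows per populated bin, global median
taken over populated-bin windows so a single populated bin gives factor
exactly 1; sparse bins inherit the nearest populated factor).  Outliers
deviate strictly more than 2 SD from the assembly-wide mean of normalized
medians (mean/SD assembly-wide, not per scaffold: per-scaffold statistics
would make deviation self-referential for small scaffolds); a scaffold is
flagged iff strictly more than 70% of its windows are outliers.  Flags are
invariant under global depth rescaling.  The method presumes low-accuracy
scaffolds are a small minority of windows; if they dominate, they inflate
the global SD and hide themselves.  SV errors: length ≥ 50 bp (inclusive)
and reference-support ratio strictly below 0.2; zero-support records are
excluded with a warning.  Which VCF fields supply the supports is
configurable (Sniffles-style `DR`/`DV` defaults).

## Anchoring (`anchor`)

Markers aligned with MAPQ strictly above 16 are retained.  Each scaffold
takes the modal LG of its markers (support fraction reported; a runner-up
LG above 20% flags a conflict — conflicts are surfaced, not silently
resolved).  Within an LG, scaffolds are ordered by mean marker cM and
oriented by the sign of the Spearman correlation between cM and physical
position (rank correlation because the cM–bp relation is monotone, not
linear); |ρ| < 0.5 is reported `uncertain`, fewer than 2 markers `unknown`.
The AGP writer emits fixed 100-N map-evidence gaps between anchored
scaffolds.

## Family clustering and densities (`repeatstats`)

3′-end 30-mers are clustered greedily: unique sequences in order of
decreasing abundance (ties by first occurrence) join the best centroid with
identity ≥ 0.80 (inclusive, matching a `-id 0.80` floor) or found a new
family.  Identity is matching columns over alignment columns of a global
alignment with match +1, mismatch −1, gap −2 and penalized end gaps — the
identity definition depends on the alignment produced, so the scoring is
fixed and documented.  On well-separated fixtures the result equals
single-linkage connected components.  "Conserved 3′ ends" counts members of
families of size ≥ 2 by default (`count_all` counts every element).  The
capture screen translates elements in six frames, splits at stops (so
alignments cannot span a stop codon), and locally aligns segments against
proteins (BLOSUM62, gap open −11/extend −1); a match needs > 50 alignment
columns and ≥ 85% identity.  Window statistics count each feature once, in
the 100-kb window with the larger overlap (ties to the lower window).
Correlations are Pearson by default (two-sided p from the t transform on
n − 2 df; Spearman by flag); zero-variance input returns an undefined
marker, not 0.  Element density is conserved 3′ ends per Mb; a chromosome
is enriched when its density exceeds the across-chromosome mean by more
than one population SD.

## Problem sizes and numerics

Analysis drivers use 3 × 400-kb chromosomes, ~270 planted elements, 55×
read depth on 0.4-Mb diploids, and 1-Mb haploids for size recovery; the
acceptance checks use up to 2.6-Mb hosts with 200–2000 planted elements.
These sizes give every statistic enough events for its tolerance (binomial
99% CIs at n = 1000–2000; ±5% size; ±0.5 pp heterozygosity) while keeping
any single stage under a couple of minutes on one CPU.  All randomness
flows from a single seeded `numpy` PCG64 generator per run; identical seeds
give byte-identical outputs.  Planted-element densities in the annotation
driver (~150–375 per Mb) are far above the real genome's (~1 per Mb) so
that per-chromosome enrichment and clustering statistics have power at
desk scale.
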
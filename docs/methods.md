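# Methods

## Genotype model and QC

Genotypes are diploid biallelic SNP calls on the 38 canine autosomes,
coded per locus as 0 (homozygous A), 1 (heterozygous), 2 (homozygous B)
or missing, with A/B assigned by lexicographic order of the observed
allele characters.  Coordinates are 1-based inclusive throughout
(MAP/VCF convention).  QC removes SNPs with minor allele frequency
**≤** the threshold (default 0.01 — the boundary value is excluded) and
SNPs with call rate **<** the threshold (default 0.99 — the boundary is
retained); both statistics are computed on the merged cohort, after any
panel merging, not per panel.  Merging intersects SNP maps by
identifier, requires identical chromosome/position, and harmonizes
alleles only by exact label match (flipping 0↔2 where the labels are
reversed); no strand inference is attempted, because frequency-based
strand assignment is unreliable in cohorts of tens of individuals.
Irreconcilable SNPs are dropped and counted.

A consequence of character-based PED files is that a site monomorphic
for the lexicographically larger allele cannot preserve its numeric
coding through a write/read cycle (the reader sees only one allele and
codes it 0).  Genotypes as allele pairs survive exactly, and a second
cycle is the identity; VCF round-trips are exact because REF/ALT are
stored.  The tests assert precisely these properties.

## ROH detection

A ROH is a maximal run of consecutive homozygous calls within one
chromosome of one individual satisfying: at least `min_snps` SNPs
(default 40), span at least `min_length_bp` (default 1 Mb), zero
heterozygous and zero missing calls, and every inter-SNP gap
≤ `max_gap_bp` (default 1 Mb, inclusive — the gap cap keeps sparse map
regions from bridging runs).  With zero tolerated disqualifying calls,
maximal-window detection reduces to a single left-to-right sweep that
breaks runs at any heterozygous call, missing call, chromosome end, or
oversized gap; sweep and window formulations coincide, which the test
suite verifies by exact comparison against a brute-force
maximal-window enumerator on hundreds of random instances.
Heterozygote- or missing-tolerant windows are out of scope and the
parameters reject them explicitly.

Numerical conventions, fixed because observed data cannot adjudicate
them: segment length is `end_bp − start_bp + 1` with boundaries at the
first/last SNP of the run (no extension into flanking space); length
classes (0–2, 2–4, 4–8, 8–16, > 16 Mb) are half-open `[lo, hi)`, so a
segment of exactly 2 Mb falls in 2–4 Mb.

## ROH islands

Per-SNP incidence counts the samples with at least one ROH covering the
SNP's position.  TOP_SNPs are those with incidence ≥ ⌊n/2⌋ + 1 ("50% of
samples plus one"; 18 for n = 34 — the floor convention is ours, the
rule does not address odd n).  Islands are maximal runs of
map-consecutive TOP_SNPs on one chromosome, split by any sub-threshold
SNP with no bridging tolerance, and bounded by their first/last TOP_SNP.
Annotation intersects islands with gene intervals (≥ 1 bp overlap on
1-based inclusive coordinates, no flank extension) from GFF3 (via
gffutils; only `gene` features carrying a `Name`/`gene_name` attribute)
or BED4+.

## Inbreeding coefficients

**F_HOM.** The homozygosity-excess ratio is computed in count form,
`(HomOb − HomEx) / (N − HomEx)` with `HomEx = Σ_j (1 − 2 p_j q_j)` over
the individual's non-missing SNPs — the proportion and count forms are
identical after dividing through by N, and the count form keeps the
ratio dimensionless.  Allele frequencies come from the analyzed cohort
itself; there is no external reference panel, so in cohorts of close
relatives the shared ancestry is partly absorbed into the frequencies
and F_HOM sits below F_ROH (visible in the simulated study cohort:
cohort means 0.013 vs 0.089).  An optional small-sample correction
(2pq·2n/(2n−1)) exists but is off by default.

**F_ROH.** Total ROH length over `L_aut`, where `L_aut` defaults to the
sum of per-chromosome first-to-last SNP spans of the loaded map and can
be overridden with a published constant (2,201,412,378 bp for the
canine array map) for cross-study comparability.  Per-chromosome F_ROH
uses the chromosome's SNP-covered span as denominator (not its physical
length, which the map does not know).

**F_PED.** The additive relationship matrix is built by the tabular
method in topological order; `F_i = a(sire_i, dam_i)/2`, with unknown
parents treated as unrelated non-inbred founders, so truncated
pedigrees bound F_PED from below exactly as in studbook practice.  The
tests cross-check against an independent Wright path-counting oracle,
including pedigrees with inbred common ancestors.

Pairwise coefficient comparisons use simple OLS with R² = squared
Pearson correlation; a flat response is reported as slope 0, R² 0
rather than an error.

## The gene-dropping simulator

Founder haplotypes carry unique labels and alleles drawn independently
per SNP from a Beta(0.5, 0.5) ancestral frequency distribution — a
U-shaped spectrum resembling array SNPs after drift.  SNP positions are
uniform per chromosome; meioses place crossovers as a Poisson process
(Haldane, no interference) at a uniform 1 cM/Mb; offspring haplotypes
are mosaics of parental segments.  Because labels are tracked at
segment resolution, autozygous tracts (both haplotypes descending from
one founder haplotype) are exact intervals, not genotype inferences.
Mating templates (full-sib 0.25, half-sib 0.125, first-cousin 0.0625)
are replicated as independent families, one focal offspring each, so
means over offspring converge to the pedigree expectation.

Two genome profiles: a 5-chromosome, 200 Mb "fast" genome (validation
default; at 50 SNPs/Mb it gives 10,000 SNPs and runs in seconds) and a
38-chromosome genome with linearly decreasing lengths summing to
2,201,412,378 bp for canine-scale runs.  Validation problem sizes —
200 offspring for recovery, 100 × 10,000 for the null, 500 random
instances ≤ 300 SNPs for the oracle comparison — were chosen once as
the smallest sizes at which Monte-Carlo error is far below the effects
being checked.

What the simulator does **not** model — linkage disequilibrium beyond
pedigree descent, mutation, genotyping-error structure, crossover
interference, selection, realistic canine demography — bounds what
passing tests show.  In particular, neutral gene dropping does not
concentrate ROH at shared loci: in the simulated 34-dog study cohort no
SNP reaches the 18-sample island threshold (max incidence 8), which is
the expected behavior, since real TOP_ROH islands reflect directional
selection rather than inbreeding alone.  Island calling is therefore
validated on constructed fixtures, not on the neutral cohort.  Recent
pedigree inbreeding also produces long ROH (cohort mean ≈ 17 Mb) rather
than the short-ROH-dominated spectra of real breeds, whose autozygosity
largely descends from remote ancestors beyond a 4-generation pedigree.

## Degenerate inputs and tie-breaks

All-missing SNPs have undefined frequency (NaN, flagged) and are
removed by any call-rate filter; samples with no non-missing calls get
NaN F_HOM; an empty segment list yields all-zero summaries and
F_ROH = 0; zero-variance regressors raise; pedigree cycles raise naming
the individual; a segment extending beyond its chromosome span raises.
Pipeline outputs are TSV with fixed column order and 6-decimal floats,
plus a JSON manifest of every parameter, so identical config + inputs
give byte-identical outputs (checksummed in the tests).
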
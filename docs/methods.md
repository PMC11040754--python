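# Methods

`pantropon` implements the bespoke computations of a comparative pangenome
analysis contrasting an allotetraploid genome (subgenomes At and Dt) with
its two diploid progenitors (A2 and D5), plus a population panel of
accessions for gene presence/absence analysis. This note records the models
and procedures, the defaults and why they hold, the design choices that were
genuinely open, and what the synthetic data generator does and does not
emulate.

## Coordinate and threshold conventions

All in-memory coordinates are 0-based half-open; GFF3 files are read and
written 1-based inclusive with exact conversion at the boundary; BED is
0-based half-open. Every length/identity filter follows a strict
("longer than", "higher than") reading: a 500 bp contig is discarded by a
500 bp minimum, a 0.90-identity alignment is discarded by a 0.90 identity
floor, and a sequence with a masked fraction of exactly 0.20 is *not* lost
(lost requires < 0.20). The residual-interval filter after pangenome
subtraction uses the same strict convention, so an exactly-500-bp residual
is dropped.

## Non-reference sequence (NRS) extraction

Contigs longer than 500 bp are aligned to the reference; alignment records
survive when strictly longer than 300 bp at identity strictly above 0.90.
Contigs with no surviving alignment are emitted whole; otherwise maximal
unaligned query intervals longer than 500 bp are emitted. Overlapping
surviving alignments are flattened (union) before computing unaligned
intervals — the alternative (per-alignment gaps) would double-count overlap
boundaries. Redundancy removal is a single deterministic pass: sequences
are visited in decreasing length order and join the first centroid for
which the shorter sequence aligns end-to-end (semi-global, free end gaps on
the longer) at >= 0.90 identity; k-mer containment of the shorter sequence
prefilters centroid candidates so unrelated pairs never reach the aligner.
One greedy pass replaces the usual two-stage redundancy removal because at
the scales this package targets a deterministic single criterion is easier
to reason about and to test; contamination screening is out of scope and is
exposed only as an external keep-list hook.

## Gene presence/absence (PAV)

A gene is present in an accession iff the covered fraction of its total
exon length at read depth >= 2 is strictly greater than 0.8. The coverage
convention admits two published readings (a "lost below 0.2" rule and a
"present above 0.8" rule); the 0.8 covered-fraction rule is the primary
decision rule here and the 0.2 lost-cutoff is available as
`mode="lost_cutoff"`. Occupancy classes for an n-accession panel use
integer boundaries `core_min = floor(0.99 n)`, `soft_min = ceil(0.95 n)`,
`cloud_max = ceil(0.01 n)`: core iff count > core_min, soft-core iff
soft_min <= count <= core_min, cloud iff count < cloud_max, shell
otherwise. At n = 341 these reproduce the familiar 337 / 324 / 4
boundaries.

Pan/core rarefaction draws accession subsets without replacement (default
1000 samplings per size) and reports means with a 99% percentile interval.
A `nested=True` mode draws one permutation per replicate and evaluates all
sizes on its prefixes, which makes pan counts non-decreasing and core
counts non-increasing within each replicate — that is the form in which the
monotonicity property is testable.

The group-differential frequency scan uses Fisher's exact test on the
presence-by-group 2x2 table with Benjamini-Hochberg FDR; the fold change
adds 0.5 to all four cells (Haldane) only when a zero cell exists. The
published analysis names neither the test nor the FDR procedure; the exact
test is the natural choice at these counts and BH is the standard FDR
control. Verdicts need both the fold-change criterion (> 2 or < 0.5,
strict) and q < 0.001. Dispensable-gene clustering feeds the 0/1 rows to
Euclidean k-means (10 restarts, seeded): squared Euclidean distance on
binary vectors is twice the Hamming distance, so the ordering is the
intended one. PAV-based tree building is out of scope; a Jaccard distance
matrix export is provided for external tree builders.

## Genome-specific k-mers

Canonical 15-mers (minimum of forward and reverse-complement 2-bit codes;
k must be odd so no k-mer is its own reverse complement) are counted per
genome as packed integer codes in numpy; k-mers containing non-ACGT bases
are skipped. The abundance floor scales with genome length:
`max(2, round(100 * genome_len / 1.6e9))`, so the "count above 100"
convention at a ~1.6 Gb genome becomes a floor of 2 on megabase-scale test
genomes; the floor applies to the *maximum* count across genomes
(strictly), so a k-mer retained for one genome is visible in all columns.
Relative abundance is count over the genome's total retained k-mer count
("relative" is otherwise undefined); a k-mer is genome-specific when its
relative abundance strictly exceeds twice that in the partner genome. A
zero partner count assigns the k-mer outright — its own retention already
passed the abundance floor. Candidate k-mers are clustered by k-means on
column-z-scaled relative abundances; bootstrap support is the fraction of
50% resamplings in which a k-mer's re-clustered label maps to its full-data
cluster (bootstrap centroids are matched to full-data centroids by nearest
distance). Whole genomes are compared by default; a homoeologous
chromosome pairing map can restrict the comparison.

## Sequence origin after polyploidisation

Each query genome is split into 1 kb windows after removing N runs (the
terminal remainder is kept), windows are flagged mapped/unmapped against
the partner genome, maximal runs of coordinate-contiguous unmapped windows
are merged, spans backed by the pangenome are subtracted, and each residual
sequence is masked with the query genome's specific k-mers. Masked runs
separated by less than 50 bp are joined *before* the masked fraction is
computed (joining is described as a prior step, so the fraction follows
it). Verdict: lost from the partner iff the masked fraction is strictly
below 0.20, else nascent in the query. Masking uses canonical k-mers, so
the verdict is invariant to reverse-complementing the sequence.

At test scale the mapped/unmapped contract is served by a built-in exact
31-mer seed mapper: a window is mapped when the best (chromosome, diagonal
band) locus is supported by more than 50% of its seed windows, which also
implements the "ignore small secondary duplicates" step — secondary loci do
not count toward support. Full-scale users supply external alignments
instead.

The distance permutation test measures the mean distance to the nearest
gene (0 when overlapping), compares to length-matched uniform random
placements on the same chromosomes, and reports empirical p-values with the
+1 correction (`p = (1 + #{null <= obs}) / (n_perm + 1)`), for both the
closer- and farther-than-random tails. Queries on chromosomes carrying no
genes are excluded; all-excluded input is an error.

## Gene age

A pangene's age bin is the deepest taxon sharing its orthogroup on the
ladder rice -> Arabidopsis -> G. kirkii -> G. raimondii; pangenome-only
genes (including unclustered singletons) are the youngest bin. Age1 is the
oldest bin; the internal ladder is configurable for reuse with other taxon
sets. Feature-versus-age trends are Spearman correlations of the feature
against the bin index, with per-bin medians; a constant feature reports
rho = 0 by convention (the correlation is undefined but the scientifically
relevant statement is "no trend").

## Single-copy gene fate

Families with exactly one member in each diploid are classified by the
tetraploid member count: 2 with one member per subgenome is balanced; 0 is
lost in both; 1 reverts to single copy (the empty subgenome is recorded);
more than 2 is gained. A 2+0 split is flagged `unbalanced_retention` rather
than silently counted as balanced — the 1:1:2 ratio convention does not
distinguish the two, and conflating them would hide homoeologous
replacement. Loss mechanisms are traced by aligning the retained diploid
gene against the losing subgenome: a single alignment covering strictly
more than 90% of the gene indicates a small variation or annotation
omission; otherwise two or more alignments on one chromosome whose
consecutive target spans are separated by at most 25 kb (the *gap*, not the
total span — the gap is what an inserted element occupies) with a TE
annotation overlapping the gap indicate TE disruption; anything else is
unexplained. The built-in exact-seed chainer breaks chains at diagonal
shifts above 1 kb, so a multi-kb insertion splits the alignment while small
indels do not.

## LTR retrotransposon dynamics

**Dating.** The two terminal repeats of a full-length element are globally
aligned with free end gaps and internal gaps penalised above substitutions
(match +1, mismatch -2, gap open -7, extend -2); gap columns are excluded;
p = mismatches / compared sites; K = -(3/4) ln(1 - (4/3) p) (Jukes-Cantor);
T = K / (f r) with mutation rate r = 9e-9 per site per year. A unit-cost
(edit-distance) alignment is deliberately *not* used for counting: its tie
structure re-explains clustered substitutions as indel pairs and deflates p
by 1-2% systematically. Equal-length pairs whose edit distance equals
their Hamming distance take a fast path, since the substitution-only
alignment is then provably optimal under any gap-penalised scoring.
p >= 0.75 is a saturation error. The divergence factor f defaults to 1
(the printed T = K/r convention, under which the generator's planted ages
are recovered); f = 2 gives the two-sided clock in which each repeat
mutates independently at rate r, halving all ages. The two conventions
differ by exactly 2x and the flag makes the bookkeeping explicit.

**Clustering and specificity.** Full-length sequences are clustered by the
same deterministic greedy 90/90 centroid pass as NRS deduplication.
Cluster genome specificity applies four rules in order on the composition
fractions: (1) one genome > 90% -> that genome; (2) best pair > 90% ->
pair label; (3) smallest contributor < 10% -> the remaining three genomes
(this is how an element family shared by A2, At and Dt but absent from D5
gets labelled A2_At_Dt); (4) otherwise common. Labels order genomes as
A2, At, D5, Dt. Lifespan is the (95th, 5th) percentile of member insertion
ages (linear-interpolation percentiles), oldest to youngest; fewer than two
dated members is NA.

**Retention.** Each homologous truncated-LTR locus carries one retained
LTR length per genome and a total alignment length; retention rate is
retained/total. The coefficient of variation of the four retained lengths
(sample sd over mean, ddof 1) selects variable loci; per-genome means and
pairwise Welch t-tests are reported per CV cutoff. The multiple-alignment
step of the full-scale procedure is bypassed at test scale — retained
lengths come from annotation coordinates — and a hook ingests externally
computed alignments.

**Spatial statistics.** Per superfamily: nearest-gene distances, the same
permutation test as above, and OLS regression of distance (kb) on age
(Myr); only the slope convention (kb/Myr) is fixed, as published analyses
report slopes without naming the fit. Adjacent-homolog spacing conservation
uses log2(tetraploid/diploid spacing) for gene pairs adjacent in the same
order in both genomes; the null shuffles inter-gene distances within each
genome while preserving order, and observed versus null histograms (decile
bins of the null) are compared by chi-square.

## The synthetic quartet

The generator is the package's source of ground truth, not a fixture: the
planted-truth tables are what every recovery test and the acceptance script
measure against.

Construction: a random ancestor (default 4 chromosomes x 1 Mb) is mutated
into A- and D-lineage backbones (3% substitution divergence); At and Dt
start as exact copies of their diploid backbones. All planted features
reserve space in one global registry on ancestral coordinates (rejection
sampling; exhaustion raises a diagnostic error), so no two planted entities
overlap anywhere in the quartet and every truth interval maps exactly onto
final coordinates.

Planted per genome: (i) nascent insertions (default 20 of 8-20 kb) built by
concatenating repeat monomers from a small novel library private to the
genome or shared by At and Dt — repetition is what lifts their k-mers over
the abundance floor, exactly as repeat bursts do in real genomes;
(ii) full-length LTR elements (5 families x 40 elements of 8.5 kb with
3 kb terminal repeats, family-to-genome profiles covering single-genome,
tetraploid-shared, diploid-subgenome-shared and common patterns) whose
terminal repeats are aged by a forward Jukes-Cantor process (per-site
Poisson event counts, uniform choice among the 3 alternative bases) with
pair divergence r x age; (iii) sequence losses deleted from each subgenome
(coordinates recorded on the retaining diploid); (iv) single-copy gene
fates — full deletions in both subgenomes, reversions by mid-gene LTR
insertion (TE disruption) or by a small internal deletion (5% of gene
length), and gained duplicate copies; (v) an accession panel with
group-structured presence frequencies and a uniform site-frequency spectrum
for dispensable genes, from which noise-free per-exon depth summaries are
emitted (present genes covered over 85-100% of each exon, absent over
0-60%).

Default scale keeps every stage within minutes on one CPU while leaving
~200 datable elements for estimator recovery; the terminal repeats are at
the long end of the observed range for Gypsy-dominated genomes, which keeps
the mismatch counts of the youngest planted elements informative.

What the generator does not emulate — and therefore what green tests do not
establish about real data: sequencing error and read-level noise (depth
summaries are drawn directly, not from reads), substitution divergence
between a diploid and its derived subgenome backbone (divergence is only
via planted insertions/deletions, which is what makes the "zero backbone
k-mers called specific" property exact rather than approximate), indels
inside terminal repeats (dating is substitution-only by design, matching
the estimator's model so parameter recovery is exact), nested or truncated
TE insertions, recombination, and real orthology inference noise (the
orthogroup table is emitted consistent with planted ages). Recovery rates
on real data will be lower than the planted-truth rates reported here;
the tests establish correctness of the computations, not field accuracy.

## Numerical and reproducibility choices

Every stochastic stage draws from `default_rng(SeedSequence([seed,
crc32(stage_name)]))`, so stages are independently reproducible and a fixed
seed makes fixtures byte-identical. K-mer machinery is vectorised numpy
(2-bit packed codes, searchsorted membership); pairwise identity checks go
through edlib except terminal-repeat dating (see above). Percentiles are
linear-interpolation (numpy default). Empirical p-values always use the +1
correction. Statistical tests come from scipy/statsmodels (Fisher exact,
Mann-Whitney, Welch t, chi-square, BH FDR) and clustering from
scikit-learn. Calibration tests assert rejection rates against nominal
levels with one-sided binomial slack at ~99% confidence — an exact
"<= nominal" assertion would itself be miscalibrated.

## Problem sizes

The recovery suites (origin calls, PAV round trip, fates, TE tracing) run
on a 2-chromosome, 2-Mb quartet that still carries every planted feature
class; estimator recovery and clustering run on the 4-Mb default with ~200
datable elements. Null calibration uses 100 seeds for each test (1000
null genes per seed for the frequency scan, 400 permutations per seed for
the distance test). These sizes keep each suite within a few minutes on
one CPU while leaving the statistical margins of the pass criteria intact.

## Known limitations

The greedy centroid clustering is order-dependent by construction
(deterministic, but a different length ordering could merge differently
near the 90% boundary). The seed mapper is exact-match only and has no
mismatch tolerance within seeds; it is adequate for the identical-backbone
quartet but not a general-purpose mapper. `distance_permutation_test`
places nulls uniformly per chromosome without excluding assembly gaps.
The k-mer counter is in-memory and sized for genomes up to tens of
megabases, not disk-backed counting at gigabase scale.
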
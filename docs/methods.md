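# Methods

## The fixed-allele-difference model

A balanced (or recently spread) chromosomal rearrangement suppresses
recombination between the two arrangements across the rearranged region.
Loci inside the region therefore segregate with the arrangement itself: one
frozen haplotype per arrangement. In a diploid 0/1/2 call matrix this
predicts, for every captured locus, opposite homozygous calls in the two
homozygous karyotype groups (AA vs. MM) and a heterozygous call in every
heterokaryotype (MA). The classifier tests exactly this pattern:

- FIXED iff all AA calls equal h ∈ {0, 2}, all MM calls equal 2 − h, and
  (strict policy) all MA calls equal 1. The orientation (which homozygote
  the AA group carries) is locus-local, since DArT calls are unpolarized.
- A group smaller than `min_group_size` (default 2) or any missing call
  (default `allow_missing=False`) makes the locus INELIGIBLE rather than
  raising — ineligibility is a data property, not an error.
- `ma_consistency`, the fraction of non-missing MA calls equal to 1, is
  reported even when MA individuals do not veto (lenient mode), so the
  heterokaryotype signal is always visible.

The strict missing-call stance mirrors a call-rate-1 filter: with any
missingness the locus cannot witness fixation in every individual. Under
independent missingness m and symmetric genotyping error e, a truly linked
locus survives the strict filter with probability ≈ ((1−m)(1−e))^N over the
N individuals examined — the lenient modes exist precisely because real
data pay this penalty (at the defaults m=0.05, e=0.01, N=13 that is ≈ 45 %
recall, with precision still 1 in practice).

Assumptions worth stating: karyotype labels are correct (a mislabelled
individual vetoes every truly linked locus); no double crossovers or gene
conversion inside the region (heterokaryotypes carry exactly one haplotype
of each); the two homozygous groups share no residual gene flow at linked
loci. The false-positive side is quantified analytically: an unlinked locus
in Hardy–Weinberg proportions with alt frequency p shows the fixed-opposite
pattern with probability (p²)^n_AA (q²)^n_MM + (q²)^n_AA (p²)^n_MM
(`expected_false_fixed_rate`; the MA constraint only lowers it). At
p = 0.5 and 5 vs. 5 individuals this is ≈ 1.9 × 10⁻⁶ per locus — the reason
a genome-wide scan of tens of thousands of loci yields a handful of fixed
differences concentrated on one scaffold rather than a diffuse background.

## Tag placement and synteny filters

BLAST tabular hits are filtered per tag: e-value ≤ 5e−7, identity ≥ 70 %,
aligned length ≥ 70 % of the *full tag length* (the aligned-span
denominator would be circular), and a per-base composition window of
3–60 % on the tag — interpreted as a low-complexity screen and disablable,
since the underlying rule is stated ambiguously in DArT workflows. Among
survivors the single best hit wins: highest bitscore, then lowest e-value,
then lexicographically smallest subject, then smallest subject start. The
aligner-side culling limit has no post-hoc analogue; it is recorded in the
run manifest only. Coordinates are 0-based half-open internally, 1-based
inclusive only at format boundaries.

Whole-genome alignment blocks are reduced to one-to-one synteny greedily:
descending length (ties by reference position), discarding any block that
overlaps an accepted block on either genome, then dropping blocks ≤ 500 bp
(strict inequality). Identity statistics are unweighted per block with
sample standard deviation; a length-weighted variant is available because
"identity of the scaffolds" can be read either way.

## Distances, clustering, trees

The individual-level distance over candidate loci is the Euclidean norm of
the call-vector difference restricted to jointly non-missing loci, rescaled
by √(L / L_complete) so missingness does not deflate distances
(switchable). Agglomerative clustering (single/complete/average; default
average) is implemented directly so the tie-break — merge the pair whose
smallest leaf labels sort first — is deterministic; heights are verified
against scipy in the test suite.

For trees, each locus contributes one IUPAC character per individual
(0 → ref, 2 → alt, 1 → two-base ambiguity code, missing → N), concatenated
in scaffold-position order. Because characters are positionally homologous
by construction, no multiple alignment is needed. Pairwise distance is an
expected allelic p-distance: identical characters 0 (including identical
heterozygotes — same genotype), disjoint base sets 1, one shared allele
0.5; N sites excluded per pair. The tree is Saitou–Nei neighbor joining
with a deterministic Q-tie-break (lexicographically smallest pair) and
negative branch lengths clamped to zero with the deficit moved to the
sister branch (pair sum preserved), midpoint-rooted at the longest
leaf-to-leaf path (ties by smallest label pair). This NJ tree is a
distance-based stand-in for likelihood inference in proprietary software;
FASTA/NEXUS export exists so users can rerun that step externally. How such
software treats ambiguity codes under default settings is not specifiable,
so no equivalence is claimed.

## Repeat windows and the rank-sum contrast

Repeat features are unioned per class before coverage so overlapping
annotations cannot push a window fraction above 1. Windows tile the
scaffold at 100 kb (default); the final short window keeps its true width.
Normalized density divides by the per-scaffold maximum (all-zero profiles
stay zero). The two-scaffold contrast treats windowed covered fractions as
observations in a Wilcoxon rank-sum test: exact two-sided p by
dynamic-programming enumeration of rank subsets when n₁+n₂ ≤ 25 and the
pooled values are tie-free, otherwise a tie-corrected normal approximation
with 0.5 continuity correction (agreement with an exact/permutation oracle
is tested to < 0.005 / < 0.01). CpG islands use the classic rule
(obs/exp ≥ 0.6, GC ≥ 0.5, length ≥ 200), all thresholds configurable, since
no specific caller is prescribed by the upstream workflow.

## Probe tiling

Oligo candidates start every 3 nt; at each start the length in 43–45 nt
minimizing |Tm − target| is chosen (ties → shortest), where Tm is the
GC-content formula 64.9 + 41·(GC − 16.4)/len — a ranking heuristic, not a
duplex model. The default Tm target is the median Tm of all 44-mer windows
of the unmasked target, which operationalizes "minimize the thermodynamic
range" without an external oracle. Candidates overlapping the homology mask
(merged hit spans; book-ended intervals merge because half-open adjacency
has no gap base) or containing N are dropped. Uniqueness = every canonical
k-mer (k = 21, matching the homology word size) of the oligo occurs exactly
once in the hybrid genome, both strands collapsed. The published probe-set
size depended on a proprietary thermodynamic screen and differs between its
own two reported figures (27,392 vs. 27,387; lengths 43–45 vs. 45–47 nt);
this package follows the 43–45 nt specification, asserts the structural
contract (candidate counts, masking monotonicity, duplicate flagging), and
treats the exact count as out of reach by design.

## The simulator

`simulate_cohort` emulates the study design: four populations with
karyotype compositions (AA/MA/MM) of 0/3/5, 5/3/5, 0/0/5 and 5/3/0 — 34
individuals, one western-style population carrying all three karyotypes —
over seven scaffolds whose relative sizes match the real candidate set,
scaled to ~10 kb per Mb so a full run takes seconds; the planted rearranged
region covers the middle half of the third scaffold. Loci fall on scaffolds
proportionally to length; inside the region a locus is rearrangement-linked
with probability 0.8 (noiseless calls AA→0, MA→1, MM→2); elsewhere the alt
frequency is drawn from U(0.05, 0.5) and genotypes follow Hardy–Weinberg.
Genotyping error replaces a call with one of the other two states uniformly
(probability 0.01 per call by default) — the simplest symmetric
perturbation, chosen so the linked-locus survival formula above is exact —
and missingness (0.05) is independent. Tags are 69-bp genome slices, so
simulated hit tables, probe tiling and coordinates are internally
consistent. One master seed feeds per-stage substreams (genome, loci,
calls, error, missing, hits), so each stage reproduces in isolation.

What the simulator does **not** model: linkage disequilibrium outside the
region, population structure in allele frequencies, allele-specific or
batch-structured errors, indels or repeat evolution in the genome, and
partial recombination suppression at the region's edges. Passing tests
therefore demonstrate correctness of the machinery under the stated model,
not robustness to those real-data complications.

## Numerical and design choices

- Missing-call tokens "-", "NA" and empty parse as missing; "-" is written.
- Karyotype labels live in a metadata table joined on individual id, never
  parsed out of ids (specimen ids can resemble karyotype codes).
- Assignment selection enforces ≤ 1 assignment per locus by construction
  and asserts it.
- The reference cohort for the scan is optional; when a reference
  population is named the karyotype groups are formed only from it (the
  natural choice is the one population containing all three karyotypes),
  and the manifest records the choice.
- Heat-map export orders individuals by the dendrogram and renders raw
  calls; the pairwise distance matrix is exported separately, since the
  individual-level figure can be read as either.
- Degenerate inputs: empty matrices are valid; all-zero repeat profiles
  normalize to zero; an all-N window reports NaN GC; a pair of individuals
  with no jointly non-missing loci is an error, not a silent zero.

## Problem sizes

Tests run the simulator at 150–4,000 loci and 34 individuals, NJ at 4–34
taxa, and the permutation oracle at 10⁵ permutations; the acceptance script
uses 600-locus cohorts, 20 noisy replicates for the ranking check and
5,000 loci for the false-positive check. These sizes give stable statistics
while keeping a full run in the tens of seconds on one core.
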
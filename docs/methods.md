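# Methods

This note records the models, parameter choices and numerical conventions
behind each analysis stage, what the synthetic-data generators do and do
not emulate, and the design choices made where more than one reasonable
convention exists.

## Coalescent site simulator

Loci are independent (free recombination between, none within). The
species tree is (((P1,P2)t1,P3)t2,O)t3 with times in coalescent units of
2N generations and one pulse of introgression: tracing the single P2
lineage backward, at time tm (< t1) it is reassigned to the P3 population
with probability γ. Within every population interval, coalescence waits
are exponential with rate k(k−1)/2 for k resident lineages — the exact
structured coalescent, not a pattern-probability approximation — and the
implementation is fully vectorized over loci by enumerating the small set
of event histories a four-tip genealogy can take (three merge events over
tip bitmasks).

One mutation per locus is placed uniformly on the genealogy's total branch
length (infinite-sites), so each locus contributes exactly one polarized
biallelic pattern, mirroring single-site ABBA/BABA counting on genome
trios. Mutations landing on the outgroup's pendant branch are emitted as
O=1/ingroup=0; they are simply uninformative downstream. Loci are placed
at a fixed spacing (default 2,000 bp) on one synthetic chromosome so that
100-kb jackknife binning is exercised: 50,000 loci span 1,000 blocks of
~50 loci each.

Default study conditions for calibration runs: t1=1, t2=2, t3=3, tm=0.5,
50,000 loci, with γ=0 for the null and γ=0.2 for the introgressed case.
Under these times roughly 1.5% of loci are ABBA/BABA-informative at γ=0,
several hundred informative sites genome-wide — enough for the jackknife
z-test to be well calibrated while keeping a single replicate under a
second of compute.

The simulator is cross-checked in the test suite against msprime under the
identical demography (mass migration pulse + population splits): ABBA and
BABA locus fractions agree within Monte-carlo error. Multi-tip window
genealogies for topology weighting are generated with msprime directly
(ploidy 1, population size 1, so msprime time equals coalescent units); the
four-tip locus sampler is in-package because it doubles as the D-statistic
oracle and needs exact single-mutation semantics.

What the generator does not emulate: intra-locus recombination, multiple
or continuous migration, selection, sequencing error, and reference bias.
Passing calibration therefore shows the statistics behave correctly under
the model's assumptions, not that real data meet them.

## D-statistic and jackknife

D is computed from pooled genome-wide counts; blocks only matter for the
variance. The delete-m_j weighted jackknife (Busing et al. 1999) is used
with block weights m_j = informative sites per block; blocks with zero
informative sites are excluded. When all leave-one-out estimates coincide
the SE is reported as 0 with a degenerate-variance warning rather than
NaN. Significance is two-sided normal at |z| > 3.9 (p < 1e-4); the
threshold is a flag. An unweighted jackknife is a special case (equal
block counts) and was not separately exposed.

Counting is binary (one haploid allele per taxon), matching the use of
genome assemblies as taxa; heterozygous diploid genotypes are treated as
missing for that taxon and the site dropped. Polarization keeps only
sites biallelic across the quartet with a called, unambiguous outgroup;
drop reasons are returned as audit counts.

## Topology weighting

Weights are exact: every one-tip-per-group combination (the outgroup group
iterated like any other) is pruned and the induced rooted topology read
off. Rooting is at the chosen outgroup tip, so trees supplied unrooted are
handled uniformly. The induced topology is computed from per-node chosen-
tip bitmasks on a single DFS; a cluster counts as resolved only when the
branch-length path to its induced parent is positive. Internal edges of
exactly zero length therefore collapse, and unresolved combinations give
1/(number of compatible topologies) credit to each compatible topology
(compatibility = the polytomy's clusters are a subset of the candidate's).
Absent branch lengths are treated as resolved.

Genome-wide summaries normalize summed weights and attach 95% percentile
bootstrap CIs from resampling windows with replacement (1,000 draws by
default); the CI method is a package convention since no standard exists
for weight sums. Windows of exactly 100 or 500 polymorphic sites are
non-overlapping and never span chromosomes; trailing partial windows are
dropped.

Local window trees are NJ on allele-sharing distances, rooted on the
outgroup branch midpoint. This replaces maximum-likelihood window trees
(GTR+CAT) to stay self-contained and fast; the weighting operation is
tree-agnostic, so externally estimated Newick trees can be supplied
instead. Invariant windows return a star tree with a warning.

## Per-gene topology tests

For a quartet alignment each of the three rooted topologies maps to an
unrooted quartet; branch lengths (5 per topology) are optimized by
coordinate ascent with bounded scalar minimization (bounds [0, 10],
xatol 1e-8), sweeping until the log-likelihood improves by less than 1e-6.
The substitution model is JC69: the simplest model with an exact pruning
likelihood, and the test's contract (which topology wins, not the branch
lengths) is insensitive to this choice on synthetic data generated under
nucleotide models. Gaps and Ns are marginalized per site; all-gap
alignments are omitted with reason `no_signal`.

Topology support is the RELL bootstrap win proportion over 10,000
multinomial resamples of site patterns — an approximation to the AU test
that shares its resampling core while avoiding the multiscale-bootstrap
machinery. The selection threshold (support > 0.95) and the omission of
genes with exactly tied likelihoods (difference < 1e-9) follow the
analysis convention this package reproduces. Ties inside a bootstrap
replicate split credit equally; support is invariant to site order by
construction.

Recovery conditions used in tests: genes of 2,000 aligned sites evolved on
(((P1:0.1,P2:0.1):0.05,P3:0.15):0.05,O:0.3) — a 0.05-substitutions/site
internal branch yields ~95%+ correct selection, exercising the threshold
rather than saturating it.

## Distances and neighbor joining

The allele-sharing distance is 1 minus the mean per-site Kronecker-delta
similarity: for diploids the mean of δ over the four ordered allele
pairings (so Aa vs AA scores 1/2), for haploids δ itself; sites with
missingness in a pair are skipped for that pair only. The exact printed
form of the source distance equation is not public; this standard
identity-by-state form is adopted as the package's definition.

K2P and JC69 distances raise a typed saturation error when a log argument
is non-positive rather than returning NaN. NJ is classic Saitou–Nei with
the Q criterion, ties broken by the lowest (row, column) index pair for
reproducibility, and negative branch-length estimates clamped to zero with
a warning. On additive matrices NJ reproduces the generating tree's path
lengths exactly (verified to 1e-9 against 100 random 8-taxon trees and
cross-checked against scikit-bio's NJ). Classic NJ stands in for
balanced-minimum-evolution tree building; for population-level trees the
topological behavior is equivalent on clean distance matrices and fully
deterministic.

## LTR dating and family classification

T = d / (2 × rate) with rate 1.3e-8 substitutions/site/year: both LTR
copies accumulate divergence, hence the factor 2. The rate constant is
described in the source literature as already being twice a synonymous
rate, which leaves an ambiguity; the conventional 2-rate denominator is
the default and `half_denominator=False` exposes the alternative.
Saturated pairs (K2P log argument ≤ 0) are flagged, not dated. Unaligned
pairs can be passed through a simple affine-gap global aligner (match 2,
mismatch −1, open −5, extend −1) before distancing.

The 80-80-80 thresholds are all inclusive (≥), reading "at least"
literally; best hit = highest identity, then longest alignment, then
lexicographic family id, making classification order-invariant.

## PAV reconciliation

Sizes 50–100,000 bp inclusive; read-based calls need support strictly
greater than 5; assembly-based calls carry no support requirement.
Overlap collapsing uses *reciprocal* 70% (both calls) to prevent a large
call absorbing unrelated small ones; a one-way mode is behind a flag. The
collapse iterates to a fixed point so the operation is idempotent — union
spans that newly satisfy the threshold merge in later passes — and the
representative is the coordinate union with a member count. Matching
expands assembly breakpoints by ±500 bp and pairs calls greedily by
decreasing overlap (ties to the leftmost), one-to-one. Density counts a
call in every 500-kb window it intersects; cross-chromosome statistical
comparison is left to standard tooling.

The dual-caller simulator truncates breakpoint jitter at ±3σ, so with the
default σ = 100 bp every true pair stays inside the 500-bp pad — recovery
failures in tests would therefore indicate matcher bugs, not simulation
noise. False calls are placed uniformly, disjoint from the truth set, and
can occasionally coincide between the two callers on small chromosomes.

## Coverage deletions

The 0.05× cutoff is an absolute mean depth (reads per base), not relative
to the sample's genome-wide mean — consistent with the observation that
per-variety coverage does not drive deletion counts — and a relative mode
is available behind a flag. The deletion call is strict (< 0.05); the
population-frequency exclusion is inclusive (≥ 0.3); genes never deleted
are flagged "core". Simulated tracks use Poisson(λ) depth with λ ≥ 5 and
exact zeros in deleted genes, so frequency recovery is exact and the tests
do not probe behavior near the 0.05 boundary under noise — boundary
behavior is tested directly on constructed means instead.

## Genotype QC

Filters apply in order (indel flank, missingness, heterozygosity) and each
removed site is charged to the first rule that hits it, so audit counts
sum to the total removed. "Within 5 bp" is inclusive (≤ 5); the 20% and
5% thresholds are strict (">"), so sites exactly at a threshold survive.
Pruning bins anchor at position 1 per chromosome and draw one site
uniformly at random (seeded) per non-empty 200-kb bin; the random choice
(rather than first-per-bin) is a documented convention since the source
procedure does not specify. Imputation and phasing are out of scope; the
pipeline accepts called genotypes.

## Numerical conventions

Internal coordinates are 0-based half-open everywhere; VCF and the 1-based
inclusive SV-table dialect convert at the I/O boundary, and conversions
are involutions. All generators draw from a private, explicitly seeded
`numpy.random.Generator`; identical configurations are bit-reproducible
and no global random state is touched. Likelihoods are floored at 1e-300
before logs; weight vectors are normalized exactly and asserted to sum to
1 within 1e-9.

## Known limitations

- The coalescent sampler covers exactly one pulse and four taxa; the
  frequency-based (Durand-style) D over population allele frequencies is
  not implemented — counting is binary per taxon.
- RELL support is not an AU p-value; near-tied topologies are judged more
  liberally than the full multiscale bootstrap would.
- NJ replaces BME/ML tree building throughout; on noisy, non-additive
  matrices the topologies may differ from those tools.
- The PAV matcher is greedy; a maximum-weight matching could differ on
  pathological overlap structures.
- Deletion calling trusts the depth input; no mappability or GC
  correction is applied.
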
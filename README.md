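# admixscan

Comparative and population-genomic analyses for multi-genome studies of
closely related plant populations — the kind of questions raised by rice
variety groups (circum-basmati, circum-aus, japonica, indica and their wild
relatives): did gene flow occur between groups, which local genealogies
dominate the genome, how old are the LTR retrotransposons, which genes are
missing from which varieties, and how do two structural-variant callers
agree?

Every analysis stage is paired with a synthetic-data generator with known
truth, so the whole pipeline is testable end to end without sequencing
data.

## What it computes

**ABBA-BABA D-statistic.** For a quartet (((P1,P2),P3),O) with sites
polarized against the outgroup, ABBA sites carry the derived allele in P2
and P3 and BABA sites in P1 and P3. Under incomplete lineage sorting alone
E(ABBA) = E(BABA); introgression breaks the symmetry:

    D = (nABBA − nBABA) / (nABBA + nBABA)

The standard error comes from a delete-one *weighted block jackknife* over
100-kb bins (weights = informative sites per block, Busing-style), and
|z| > 3.9 (p < 1e-4) flags significance. The site simulator is an exact
structured coalescent on the species tree with a single introgression pulse
(P2 → P3 backward in time with probability γ), one mutation per locus.

**Topology weighting.** For k population groups plus an outgroup, every
combination of one tip per group is pruned from a local tree and the
induced rooted topology tallied — the exact ("complete") weighting.
Zero-length collapses yield fractional credit across compatible
topologies. Genome-wide weights get percentile bootstrap CIs over windows.

**Per-gene topology tests.** JC69 branch lengths are fitted per candidate
quartet topology by Felsenstein pruning; RELL bootstrap resampling of
per-site log-likelihoods gives topology support, with selection only above
0.95 and omission of genes whose likelihoods tie exactly.

**Distances and trees.** Allele-sharing (identity-by-state) distances,
JC69 and K2P corrected distances (d = −½ln(1−2P−Q) − ¼ln(1−2Q)), and
deterministic Saitou–Nei neighbor joining that is exact on additive
matrices.

**LTR retrotransposon dating.** Two LTRs are identical at insertion, so
their K2P divergence d dates the element: T = d / (2 × 1.3e-8) years.
Family assignment follows the 80-80-80 rule.

**PAV reconciliation.** Size filtering (50–100,000 bp), >5-read support
for read-based calls, reciprocal-70% overlap collapsing, ±500-bp padded
breakpoint matching between assembly-based and read-based call sets, and
per-window density summaries.

**Gene deletions from coverage.** A gene is deleted in a sample when its
mean depth is below 0.05×; population deletion frequencies flag core genes
(never deleted) and genes at frequency ≥ 0.3 for exclusion.

**Genotype QC.** SNPs within 5 bp of an indel, sites missing in >20% of
samples, sites heterozygous in >5% of samples; random one-site-per-200-kb
pruning.

## Worked example

```python
import admixscan as ax

cfg = ax.AdmixtureSimConfig(t1=1.0, t2=2.0, t3=3.0, tm=0.5, gamma=0.2,
                            n_loci=50_000, seed=42)
sites = ax.simulate_admixture_sites(cfg)
res = ax.d_statistic(ax.count_patterns(sites, block_bp=100_000))
print(res.d, res.se, res.z, res.significant)
```

Running `python examples/01_abba_baba.py` prints:

```
ABBA = 1506, BABA = 303
D = 0.665 +/- 0.017  (z = 38.97, significant at |z| > 3.9: True)
gamma=0 control: D = 0.081 (z = 2.16, significant: False)
```

With a γ = 0.2 pulse, P2 and P3 share derived alleles five times more
often than the lineage-sorting expectation, giving a strongly positive D;
the no-gene-flow control is statistically indistinguishable from zero.
The other scripts in `examples/` walk through topology weighting, gene
topology tests, NJ population trees, LTR dating, PAV reconciliation and
deletion calling the same way, each printing the numbers it computes.

A thin CLI mirrors the library for the tool-like stages:

```sh
admixscan sim sites --gamma 0.2 --n-loci 50000 --seed 1 --out sites.tsv
admixscan dstat --vcf cohort.vcf --p1 A --p2 B --p3 C --outgroup O --out d.tsv
admixscan qc --vcf cohort.vcf --prune 200000 --out pruned.vcf
```

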
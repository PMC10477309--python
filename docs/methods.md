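# Methods

`digestnet` reconstructs, as a reusable pipeline, the statistical workflow
used to map metabolic interactions in an anaerobic-digester (AD)
microbiome from a two-year 16S amplicon time series: community structure
analyses, a time-resolved co-occurrence network, configuration indicator
taxa, genome (MAG) linkage with expression overlay, and
methanogen-centred subnetwork enrichment. This note records the models,
parameter choices, and numerical conventions, and what the synthetic
benchmark does and does not establish.

## The analysis chain

**Inputs.** An ASV-by-sample count table whose samples carry a date and a
process-configuration label (the reference layout has four configurations
— two standard operation periods, a chemically-enhanced-primary-treatment
period, and a serial-flow period); a dated physicochemical parameter
table (28 parameters by default); ASV representative V4 sequences; MAG
records (16S sequences, GTDB-style taxonomy, completeness/contamination,
rRNA gene counts, annotated genes); and per-gene read counts with lengths
for matched metagenome (MG) and metatranscriptome (MT) libraries.

**Pre-filtering.** ASVs with a mean count below 1 across samples are
removed. Prevalence for the core-microbiome screen is presence
(count > 0) in at least `ceil(0.8 n)` samples; no detection floor beyond
count > 0 is applied.

**Physicochemical alignment.** Parameters measured off the biological
sampling grid are interpolated with a natural cubic spline (exact at the
knots, zero second derivative at the ends). The natural end condition is
chosen over the not-a-knot/"fmm" family for cross-language
reproducibility; the two differ only inside the boundary intervals.
Extrapolation outside the measured range is refused, and interpolated
values straying beyond the measured range widened to 1.5x its span are
flagged for review — an automated stand-in for plotting-based manual
checks. The environmental-subset search (bioenv/BEST) z-standardizes
parameters, computes Euclidean distances per subset, and rank-correlates
(Spearman) these with the community Bray-Curtis distances over all
subsets up to a size cap; the search refuses more than 2^20 subsets.

**Community structure.** Bray-Curtis dissimilarity, complete-linkage
hierarchical clustering (exported as Newick), classical PCoA by
double-centering (negative eigenvalues are reported, never silently
dropped; variance fractions are taken over the positive spectrum), and
PERMANOVA with the Gower-centred pseudo-F and freely permuted sample
labels, `p = (1 + #{F_perm >= F_obs}) / (1 + B)`.

**Co-occurrence network.** Nodes are ASVs present in at least 25% of
samples, sized by mean relative abundance. Two edge definitions are
provided because both are in circulation for this kind of data:

- `bicor_fdr` (default): the biweight midcorrelation between every pair
  of relative-abundance traces, a Student-t p-value with df = n - 2,
  Benjamini-Hochberg correction across all pairs, and an edge wherever
  q < 0.05 with r > 0 (positive co-occurrence only). The biweight
  midcorrelation replaces the mean/SD with the median/MAD and weights
  each point by a Tukey biweight in `u = (x - med) / (9 MAD)`, so
  bloom/crash outliers cannot dominate an edge. A zero-MAD trace falls
  back to the Pearson z-score with a warning (the standard degenerate
  rule).
- `clr_glasso`: graphical lasso on centred-log-ratio transformed counts
  (pseudocount 1) over a log-spaced penalty path from `lambda_max` down
  to `0.1 lambda_max`, with the penalty chosen by StARS — the densest
  graph whose monotonized average edge instability over 20 seeded
  subsamples of size `min(n, 10 sqrt(n))` stays within 0.05. Edge weights
  are sign-carrying partial correlations.

Network statistics use the convention that nodes of degree < 2 contribute
0 to the average clustering coefficient; the exclusion convention is
available by flag since published values may use either.

**Indicator taxa.** Group-equalized IndVal on relative abundances:
specificity `A = mean abundance in group / sum of group means`, fidelity
`B = within-group prevalence`, `stat = sqrt(A B)`. Each ASV's best
configuration is tested by permuting sample-to-configuration labels
(999 permutations by default, group sizes preserved), with BH correction
across ASVs at alpha = 0.05. Relative abundances make the statistic
invariant to sequencing depth; the permutation p-value is valid
regardless of the count distribution.

**Genome linking.** The V4 region is cut from each MAG 16S gene between
the 515F site and the reverse-complemented 806R site
(IUPAC-degenerate matching, no mismatches in the primer sites; leftmost
forward hit and nearest downstream reverse hit when multiple). An ASV
pairs with a MAG when the best ungapped end-to-end placement of the ASV
in the extracted region has identity `1 - mismatches / query length`
above 0.995 — over a 273-bp V4 fragment that admits at most one mismatch
— and the two taxonomies agree at their shared deepest annotated rank
(LCA concordance, prefix- and case-normalized). Ties between MAGs are
broken by identity, then quality score `completeness - 5 contamination`,
then lexicographic id, so the accepted pair set is independent of input
order. Quality tiers follow MIMAG-style thresholds: HQ needs >90%
completeness, <5% contamination, and all three rRNA subunit genes; MQ
needs >50%, <10%, and any rRNA gene.

**Expression.** Gene counts become TPM
(`(c/l) / sum(c/l) * 1e6` per sample), are summed per MAG, and the
MG-vs-MT MAG abundance coupling is summarized by Spearman's rho (with t
and df = n - 2) over all MAG-sample observations, excluding methanogen
MAGs — whose transcription decouples from genome abundance — from the
correlation. Guild labels (hydrogenotrophic methanogen, acetoclastic
methanogen, syntroph) come from an editable taxonomy table covering the
methanogen families Methanoregulaceae, Methanospirillaceae,
Methanomicrobiaceae and Methanobacteriaceae, the acetoclastic
Methanosaetaceae/*Methanothrix*, and the syntroph lineages Syntrophaceae,
Syntrophorhabdaceae, Syntrophomonadaceae, Synergistaceae, *Smithella*;
the deepest annotated hit wins. Pathway-marker reports cover
hydrogenotrophic methanogenesis (mcrABCDG + mtrABCDEFH), acetoclastic
markers (ack, pta), the Wood-Ljungdahl methyl branch (fdh, fhs, fol,
met), and the glycine cleavage system; a marker is "expressed" only if
encoded and its genes have nonzero TPM.

**Subnetworks and enrichment.** Each hydrogenotrophic-methanogen node
seeds a breadth-first neighbourhood of radius 2 (primary + secondary
edges); overlapping neighbourhoods merge, and subnetworks are numbered by
descending size (ties by smallest member id). The guild composition of a
size-k subnetwork is tested against 10,000 uniform draws of k nodes from
the parent network; the default criterion is jointly "at least" the
observed syntroph and methanogen counts, with an exact-counts mode
available since "the probability of observing s and m" is ambiguous
between the two. The closed-form twin is the multivariate hypergeometric
sum, always computed alongside the empirical value; the empirical
probability is reported raw (it may be 0), with the `(r+1)/(B+1)`
convention available for inference.

## The synthetic benchmark

The generator emulates the statistical structure the analysis assumes,
at desk scale: 40 biweekly samples in four configuration blocks
(15/10/9/6 — proportional to a 16/10/11/6 sampling design over 43
dates), 300 ASVs, and 20,000 multinomial reads per sample (column sums
are exact). Latent per-sample log-abundances are multivariate normal:
baseline log-means spread with SD 1.5 across ASVs (a heavy-tailed
rank-abundance curve whose top taxon holds a few percent of the
community), per-sample log-SD 0.6, and five planted guild modules — each
one hydrogenotrophic methanogen plus two syntrophs — with intra-module
latent correlation 0.9. Module members' baselines are drawn at
`N(1.0, 0.5)` on the log scale (~0.1-1% relative abundance), the level at
which methanogen and syntroph populations actually sit in AD communities
and the level required for them to appear in a prevalence-filtered
network at all. Four of the five modules are up-shifted 4 log2 units
(16-fold) in one configuration each — conditionally-rare-taxon dynamics,
which is what makes them genuine indicators; the fifth is a pure
correlation module. Physicochemical series are configuration means (8 of
28 parameters coupled, SD 2 against noise SD 0.5) measured weekly.

MAG fixtures embed each ASV's V4 (mutated at an exact, requested Hamming
distance) between concrete realizations of the degenerate primer sites
inside random flanks, so primer extraction provably recovers a region at
the planted distance; mutations land only between the primers, so they
can never disrupt a primer site. Expression fixtures couple MT to MG
latents as `mt = c * mg + sqrt(1 - c^2) * noise`, so the coupling
parameter is itself the latent MG-MT correlation (1 gives identical
tables, 0 independence); designated methanogen MAGs instead receive
independent MT latents inflated by 3 log units. Gene counts are expected
counts (library-size-scaled, length-weighted), so MAG-level TPM
aggregation recovers the latent abundances without sampling noise.

What passing the benchmark does *not* show about real data: the latent
series are white in time (no autocorrelation, no retention-time memory),
taxa outside modules are independent (real communities share
environmental drivers broadly), there is no sequencing batch structure,
no chimeras or sequencing error, and compositional closure is the only
coupling between non-module taxa.

## Numerical conventions and known limitations

- The correlation t-test is exact for bivariate normal data but only
  approximate for bicor on skewed, zero-inflated relative abundances.
  Under the compositional generator the raw edge p-values are very
  slightly anti-conservative in the far tail; a few borderline false
  edges at q just under 0.05 are therefore expected alongside strong
  planted signals. The null-calibration tests use iid noise traces,
  where the approximation is sound; on real compositional data, the
  `clr_glasso` method is the principled alternative.
- StARS averages edge instability over all node pairs, so its default
  threshold (0.05) presumes hundreds of taxa; on toy problems with tens
  of pairs a single flickering edge dominates the average and the
  selection degenerates toward the empty graph. Tests exercising exact
  structure recovery use a stricter threshold on a larger background for
  this reason.
- `p = (1 + exceedances) / (1 + B)` everywhere a permutation test is
  reported for inference; the enrichment routine reports the raw
  empirical fraction by default because it estimates a probability, not
  a test level.
- Exact ties in MAG pairing, subnetwork numbering, and bioenv ranking are
  broken deterministically (documented in each function) so outputs are
  independent of input order and bitwise reproducible under a fixed seed.
- Subnetwork-module recovery presumes the inferred network retains
  within-module connectivity; when edge recall drops below ~0.9 on a
  given seed, a module member can disconnect and the module splits.
- The average clustering coefficient of the synthetic default network
  (~0.05) is a property of the scenario's sparse planted structure, not
  a target of the generator.
- Batch correction of sequencing plates, read-level simulation, CCA-style
  constrained ordination, and assembly/binning/annotation are out of
  scope; their outputs are this package's inputs.
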
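# Methods

## Problem and model

`kinclass` estimates the family relationship between two people from their
diploid biallelic SNP genotypes alone, in the regime where the genotypes are
unreliable: profiles from degraded samples (typical of missing-persons
casework) can carry per-genotype error rates of 5–10%. Likelihood and
IBD-segment methods degrade quickly under such error and need allele
frequencies or haplotype integrity; single moment estimators such as the
KING-robust kinship coefficient are more tolerant but still drift with error.
The package's approach is supervised: simulate labeled pairs under controlled
error, describe each pair by 17 genotype-only relatedness measures, and train
classifiers that map the joint pattern of those measures to a relationship
degree (unrelated / 1st / 2nd / 3rd) and then to a type within the degree
(parent-child, full-sibling; grandparent, half-sibling, uncle-nephew;
first-cousin, grand-uncle, half-uncle, great-grandparent).

The 17 measures per pair (i, j) are, writing n_ab for the count of loci where
i carries genotype a and j carries b (both observed):

* **K1 (KING-robust)** = (n11 − 2(n02 + n20)) / (N_het(i) + N_het(j)).
  Expectation is the kinship coefficient φ: 0.25, 0.125, 0.0625, 0 for
  1st/2nd/3rd-degree and unrelated pairs; 0.5 for a self pair.
* **K0 (KING-homo)** = (1 − D / (4 Σ_m p_m(1 − p_m))) / 2 with
  D = Σ_m (x_im − x_jm)²; p_m is the sample allele frequency estimated once
  from all genotypes in the analyzed dataset. Also unbiased for φ in a
  homogeneous population.
* **IBS0, IBS1, IBS2** — fractions of loci sharing 0/1/2 alleles identical by
  state — and their pairwise unions IBS01, IBS12, IBS02.
* **j1…j9** — the nine ordered joint-genotype fractions, row-major in
  (g_i, g_j): j1=(0,0), j2=(0,1), j3=(0,2), j4=(1,0), j5=(1,1), j6=(1,2),
  j7=(2,0), j8=(2,1), j9=(2,2).

Loci missing in either profile are excluded from every count. Features built
on population allele-frequency panels or on IBD segments are deliberately out
of scope: the former are often unavailable or wrong for casework samples, the
latter break down exactly in the high-error regime this package targets.

Several identities tie the set together (j's sum to 1; IBS0 = j3 + j7;
IBS2 = j1 + j5 + j9; the unions are sums) — the measures are highly
redundant, which is why feature selection matters.

### Which joint fraction is "j4"?

The literature that uses the nine joint-genotype fractions does not fix a
universal numbering. This package fixes the row-major (g_i, g_j) convention
above and uses it everywhere (tables, reports, selected-feature names). Only
naming is affected: the information content of the set is invariant, and for
every relationship considered here the joint genotype distribution is
exchangeable in expectation, so each off-diagonal cell carries the same
expected signal as its mirror.

## The synthetic cohort generator

Training data come from a built-in gene-dropping simulator rather than from
real reference genomes. Its defaults define the study conditions:

* **Founders.** Unrelated founders with phased haplotypes drawn in linkage
  equilibrium; per-locus allele-1 frequencies uniform on (0.05, 0.95), so
  founder genotypes are in Hardy–Weinberg equilibrium by construction. The
  default panel holds 503 founders; each family samples its six founder slots
  from the panel without replacement within the family (reuse across families
  is allowed, mirroring a finite reference cohort).
* **Genetic map.** 22 equal pseudo-chromosomes, evenly spaced loci, ~1 cM/Mb,
  3,500 cM (35 Morgans) total — roughly the human autosomal sex-averaged map
  length.
* **Meiosis.** Crossover counts per chromosome are Poisson in its genetic
  length; positions uniform in cM; the transmitted haplotype alternates from
  a fair random start drawn independently per chromosome (independent
  assortment). No crossover interference (a Haldane-model simplification).
* **Pedigree.** A fixed 12-member, 4-generation family — founders F1–F3 and
  married-in spouses S1–S3; children C1, C2 (F1×F2) and C3 (F1×F3);
  grandchildren G1 (C1×S1) and H1 (C2×S2); great-grandchild GG1 (G1×S3).
  From each simulated family exactly one pair of each of the ten relationship
  types is sampled (the unrelated pair is the two married-in founders F2, F3),
  so every dataset is balanced by type: 10 × n_families pairs. At the degree
  level this implies the 1:2:3:4 imbalance (unrelated:1st:2nd:3rd) that the
  balanced-type design induces; it is kept as-is.
* **Genotyping error.** With probability ε per called genotype, one of the
  two alleles (chosen uniformly) is flipped: homozygotes always become
  heterozygous, heterozygotes become either homozygote with equal
  probability. Every flip changes the called genotype, so ε is exactly the
  expected changed-genotype fraction. The study grid is
  ε ∈ {0, 0.01, 0.03, 0.05, 0.07, 0.1}.
* **Marker deletion.** Column deletion of a uniformly random ⌊rate · n⌋
  locus subset, emulating panel thinning rather than per-genotype dropout.

### What the generator does not emulate

Linkage disequilibrium between markers, a realistic allele-frequency
spectrum, sex-specific maps, crossover interference, de novo mutation,
population structure and admixture. Consequently: (a) estimator noise at a
given marker count is somewhat smaller than on a real LD-bearing panel of the
same size, because effective marker number is higher; (b) within-degree type
separation — which rests largely on the *variance* of realized IBD sharing
across the genome, itself shaped by recombination structure — is reproduced
qualitatively but not to the decimal. Passing tests therefore demonstrate the
pipeline's behavior under idealized marker independence, not performance on
any particular genotyping platform.

## Classification pipeline

* **Backends.** Random forest (default: 300 trees, √p features per split,
  unlimited depth, fixed seed) consuming raw features, and an RBF-kernel SVM
  (C = 1, γ = "scale") whose inputs are z-scored inside the fold pipeline so
  scaling statistics never leak from validation folds. The forest is the
  default backend; the SVM exists for backend comparisons. 300 trees is
  enough that CV accuracy is stable to well under a percentage point at these
  sample sizes; the forest size is configurable.
* **Accuracy.** Stratified k-fold cross-validation (default k = 10), folds
  fixed by seed, classifier retrained per fold.
* **Forward selection.** Greedy wrapper: at each step every unselected
  feature is evaluated appended to the current set and the cross-validated
  argmax is kept. The same folds are reused for every candidate within a run,
  so comparisons are paired; ties break to the canonical feature order. Run
  to 17 steps the curve shows the characteristic rise / plateau / fall.
* **Consensus across error rates.** Features are selected separately per GER
  (each GER contributes its accuracy-maximizing prefix; for the degree task
  the counted prefix is capped at 7, where its curve plateaus), then counted
  across GERs and ranked by count (ties: mean within-trace position, then
  canonical order). The final set is the count-ordered prefix maximizing mean
  CV accuracy across all GERs (ties to the smaller prefix). This trades a
  little per-GER accuracy for robustness when the true error rate of a case
  profile is unknown. The degree-task consensus set used throughout reporting
  is {K1, j4, j7, K0, IBS0, j6, j8}.
* **Hierarchy.** One 4-class degree classifier over all pairs, then one type
  classifier per degree trained only on pairs of that degree. At prediction
  time the degree is assigned first; pairs called unrelated are typed
  "unrelated" without invoking a type model. Evaluation is reported
  per-stage by default (type models scored on true-degree subsets), with
  composed end-to-end evaluation available.
* **Baselines.** (1) K1 alone under the same backend and CV protocol;
  (2) the classical kinship-threshold rule for degrees, with right-closed
  bins at 2^−1.5, 2^−2.5, 2^−3.5, 2^−4.5 (the duplicate/twin bin above
  2^−1.5 has no class here and is mapped to 1st degree for 4-class scoring);
  (3) the IBS0 < 0.005 cutoff for parent-child vs full-sibling within the
  1st degree (the exact classical constant is panel-dependent; 0.005 is the
  package default and configurable).

## Numerical and degenerate-input choices

* Missing genotypes are a reserved sentinel (−1) excluded from every count.
* Pairs with no mutually observed loci, or with a zero K1/K0 denominator,
  yield NaN features and are dropped from feature tables with a logged count;
  no imputation.
* All tie-breaks (greedy candidates, consensus ranking, prefix choice) fall
  back to the canonical 17-feature order, making every stage deterministic
  given its seed.
* Per-stage seeds are derived by hashing (master seed, stage name, replicate
  index) into [0, 2^31), giving independent, reproducible streams; identical
  resolved configuration and master seed reproduce reports byte-for-byte.

## Replication scales

The full-size design (10,000 families × 582,000 SNPs) is available via the
`full` preset but is not the default. The `desk` preset — used by the test
suite and by `scripts/acceptance.py` — runs 2,000 families × 30,000 SNPs.
Kinship-estimator noise at 30,000 independent loci (sd ≈ 0.005 for K1) is
already far below the between-degree gaps (0.0625), so degree-level results
reproduce closely; within-degree results inherit more sampling noise and are
checked against wider bands.

At desk scale the greedy wrapper is the dominant cost (~150 candidate
evaluations × folds × GERs per task), so the selection *stage* runs on a
120-family-per-type subsample with a 40-tree forest and 5-fold CV, while all
*reported* accuracies use the full pair set, the 300-tree forest and 10-fold
CV. The train×test error-rate grid defaults to 3 replicate simulations per
cell and reuses one corrupted test set per test GER within a replicate. The
marker-deletion robustness check is run against a 100,000-locus panel rather
than the 30,000-locus desk panel: 90% deletion then retains 10,000 loci,
keeping the comparison inside the regime the full-scale study probes (tens of
thousands of retained markers, where estimator noise stays subdominant to the
spread of realized sharing).

## Known limitations

* Relationships beyond the 3rd degree are out of scope, as are gradient
  boosting / deep backends and probability calibration.
* The error model is a one-parameter stand-in for platform-specific error
  processes; real array or sequencing error is structured (allele-frequency-
  and cluster-dependent), and a classifier trained on the synthetic model may
  be optimistic on real degraded profiles.
* K0 depends on dataset-wide sample allele frequencies; with very few
  individuals or strong structure that estimate is poor, and K0's value
  degrades accordingly while K1 is unaffected.
* Within-2nd/3rd-degree type accuracy is intrinsically limited under this
  generator: all types in a degree share not just the same expected kinship
  but the same expected IBD-state probabilities (for the 2nd degree,
  (k0, k1, k2) = (0.5, 0.5, 0) for grandparent, half-sibling and avuncular
  alike), so every aggregate genotype feature has an identical expectation
  across the types and discrimination rests solely on the variance of
  realized sharing (grandparent widest, avuncular narrowest). A same-mean,
  variance-only 3-class problem at the spreads this map produces has a Bayes
  rate of roughly 40%, and the trained classifiers sit near it at ε = 0;
  segment-aware features (IBD segment counts and lengths) would be required
  to do better, and are out of scope by design. As genotyping error grows the
  spread differences are swamped and the within-degree classifiers approach
  the balanced random-guess rates (1/3 and 1/4).
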
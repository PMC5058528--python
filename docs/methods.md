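# Methods

`hostscan` re-implements, as a tested pipeline, a host-race divergence
analysis for a phytophagous insect sampled from two sympatric host plants:
anonymous dominant (presence/absence) markers genome-wide, plus one nuclear
protein-coding locus sequenced as diploid consensus. Because the original
raw data of such studies are rarely deposited, the package ships a
synthetic-data generator whose defaults encode the study design, and every
statistical stage is validated by recovery and calibration tests against the
generator's ground truth.

## The synthetic-data generator

**Dominant markers.** Each locus has an ancestral presence-allele frequency
`p0 ~ Uniform(0.05, 0.95)`. Host-level frequencies follow the
Balding–Nichols parameterization `p ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F)`, so a
single parameter `F` is the expected fixation index between host-associated
populations: `background_fst = 0.057` for neutral loci, a small
`location_fst = 0.02` for within-host geographic structure. A band is
present with probability `1 − (1−p)²` (presence dominant, absence homozygote
silent, HWE within populations). Replicate genotypings duplicate an
individual and flip every call (original and replicate alike) independently
with `miscall_rate = 0.055`, which makes the expected replicate mismatch
fraction `2m(1−m)`.

Outlier loci are *planted*, not forward-simulated. An independent
Balding–Nichols pair at high `F` frequently fails to realize any divergence
(both demes drift the same way), which would make the planted class
meaningless as a power benchmark. Instead the pair is constructed around a
mid-range mean frequency with separation chosen so the two-population
variance-component fixation index equals `outlier_fst = 0.49` exactly:
`(p1−p2)²/2 = F·p̄(1−p̄)/(1−F/2)`. The realized estimator mean over planted
loci then sits at the intended magnitude (≈0.49 against a ≈0.057
background).

**Sequence locus.** A 910-bp alignment with 22 biallelic SNPs confined to
third codon positions (relative to a configurable frame offset). Haplotypes
live in two host pools grown by stepwise mutation from a shared root:
36 haplotypes for the ancestral host, 15 for the novel host, a few shared.
One diagnostic SNP is assigned derived/ancestral states greedily so per-host
derived-allele frequencies approximate the configured targets
(0.007 ancestral host, 0.8755 novel host — i.e. nearly fixed, with a
minority of heterozygous and introgressed individuals on the novel host).
Pool frequencies are geometric with one dominant haplotype
(`top_mass` 0.25 ancestral / 0.65 novel), which reproduces the observed
asymmetry in haplotype diversity (~0.8 vs ~0.5) and singleton counts.
Individuals draw two haplotypes i.i.d. from their host's pool and are
emitted as IUPAC-coded diploid consensus sequences; the truth record stores
the phases, pools and realized segregating sites.

What the generator does **not** emulate: linkage between marker loci,
recombination within the sequence locus, selection dynamics, uneven
per-location sample sizes (balance is the default; imbalance is left to the
configuration), or genotyping artefacts beyond symmetric miscalls. Passing
tests therefore demonstrate estimator correctness and calibration under the
stated model, not robustness to every artefact of real AFLP data.

## Dominant-marker estimation

Absence-allele frequencies come from the absence-phenotype fraction under
HWE. Three estimators: plain square root; the Lynch–Milligan
Taylor-corrected square root; and (default) the Bayesian posterior mean of
`q` given `n_absent ~ Binomial(n, q²)` with a uniform prior on `q`,
evaluated in closed form via beta functions. The uniform-on-q prior is a
fixed dialect choice; the estimator never returns 0 in finite samples.

FST uses Weir–Cockerham-style variance components on per-population
estimated frequencies, with two calibrations that matter for dominant data:

1. **Response inversion.** Plug-in square-root-type estimators respond
   sublinearly to `q` at weakly informative loci (band nearly always
   present), which attenuates between-population components. The estimate is
   pushed through the inverse of the estimator's *exact* mean response
   `g(q) = E[q̂ | q]`, computed by binomial sums on a grid.
2. **Exact sampling variance at the pooled frequency.** Each population
   enters the components with an effective allele-copy count
   `m = q(1−q)/Var(q̂)`, with the variance evaluated exactly at the pooled
   frequency rather than at per-population plug-ins (which are degenerate at
   boundary counts). The Lynch–Milligan delta-method variance
   `(1−q²)/(4n)` is the asymptotic form of the same correction.

With these calibrations the multilocus ratio-of-sums estimator recovers the
generator's realized fixation index to within ±0.013 at 250 loci and 2×90
individuals (the residual large-sample bias is about +0.007). Significance
is by permutation of individuals across groups (group sizes preserved, LD
structure intact), `p = (hits+1)/(n_perm+1)`.

Gene diversity: HJ uses the sample-size-weighted mean of per-population
allele frequencies (total gene diversity), HS averages per-population
expected heterozygosities — so populations fixed for alternative alleles
contribute 0.5 to HJ and 0 to HS.

## Two-locus disequilibrium from dominant phenotypes

A pair of dominant loci yields four phenotype classes whose probabilities
are quadratic in the four haplotype frequencies under random union of
gametes. The MLE is found by EM over the ten unordered haplotype pairs,
multi-started (independence start plus four corner-biased starts) because
the likelihood can be flat or multimodal at small n; a short Nelder–Mead
polish on softmax-parametrized frequencies closes the residual gap that EM's
collapsing step sizes leave near boundary optima (verified against a
zooming grid search to 1e−6 in log-likelihood). The likelihood-ratio
statistic against the closed-form independence fit is referred to
chi-square(1) — an approximation retained even for boundary MLEs, whose
aggregate size stays near nominal (type-I ≈ 0.05 over independent pairs).
Convergence: absolute log-likelihood change < 1e−10, 10⁴ iterations for the
scalar path (3×10⁴ for the vectorized scan). FDR: Benjamini–Hochberg by
default; `pike_robust` maps to the two-stage sharpened step-up.

## QC rules

Error rate = mismatched replicate calls / compared calls. Filters, in fixed
order, each logged with initial/removed/retained counts: (1) any replicate
discordance removes the locus (strict, because mismatch-prone loci are
worse than the average error rate suggests); (2) fragment sizes matching
negative-control peaks; (3) same-size cross-primer pairs in significant LD
(FDR 0.05 within the candidate set) collapsed to the lexicographically
first locus id; (4) singletons (rarer phenotype in exactly one individual).
Fragment sizes outside 76–800 bp are dropped at read time. Filtering is
idempotent and the log always reconstructs the initial locus count.

## The outlier scan

A neutral (He, FST) cloud is simulated with the same Balding–Nichols
sampling and the *same* dominant-data estimators as the empirical analysis,
then reduced to per-He-bin 50/95/99% quantile curves (equal-occupancy bins,
≥20 bins, ≥50 points per bin). The seed statistic is the 30% trimmed mean of
empirical locus FST values — and this is matched *as a statistic*: the
generating `F` is found by bisection so that the simulated trimmed mean
equals the seed. (Plugging the trimmed mean in directly as the beta
parameter understates the null — the locus-FST distribution is right-skewed,
its trimmed mean sits well below the generating `F` — and inflates the
false-positive rate threefold.) Beta sampling replaces a coalescent island
simulation; for conditional-quantile envelopes the stationary frequency
distribution is the same one-parameter family. Loci above their bin's 95%
(99%) quantile are flagged; loci flagged in ≥2 independent comparisons form
the consensus set, and the report exposes the four nested counts
(anywhere / multiple / combined / robust). Calibration on fully neutral
fixtures keeps the 95% flag rate inside the exact binomial interval around
5%; planted outliers at 0.49 are detected with ≥93% power at 2×90.

## Sequence-locus analyses

SNPs are called per column, counting IUPAC codes as both alleles; columns
with N or gaps are excluded, columns with >2 alleles flagged. Phasing is the
classical haplotype-frequency EM under random pairing; individuals get their
most probable pair, with confidence = posterior probability of that pair.
Individuals below confidence 0.9 (default) are left unphased — the
single-program analogue of requiring multi-program consensus — as are
individuals with more than 15 heterozygous sites (pair enumeration is
2^(h−1)). Individuals with ≤1 heterozygous site have a unique phase and
confidence exactly 1. On the default skewed-pool fixtures ≥90% of phased
individuals match the true phase.

Diversity per group over haplotype copies: `Hd = n/(n−1)(1−Σpᵢ²)`, π = mean
pairwise difference per site, Sn = count-1 haplotypes, Rm by the
Hudson–Kaplan four-gamete interval method (minimal incompatible intervals,
greedy disjoint count — verified exactly against an exhaustive subset
search). Distances: closed-form F84 ML distance from empirical base
frequencies and transition/transversion counts, gaps pairwise-deleted,
saturation reported as infinite; degenerate compositions (a missing
purine/pyrimidine class) fall back to a Jukes–Cantor-style correction. ΦST
is a two-level AMOVA on squared distances with permutation of individuals
(copy pairs move together); all-identical data reports 0 with p = 1.
Codon effects translate both alleles in the majority-sequence codon with
the standard code.

## Median-joining network

Bandelt's scheme on Hamming distances over cleaned columns: iterate
(minimum spanning network = union of all MSTs, via Kruskal by distance
class) → (sitewise majority medians of connected triples, added when their
connection cost is within ε of the round minimum; ε = 0 default) until no
new medians; prune medians of degree ≤1; return the MSN of the remaining
set. Determinism comes from lexicographic node ordering and resolving
three-way site ties to the first sequence of the triple. Any MST of the
final node set is a subgraph of the network; direct observed–observed MST
edges may legitimately be replaced once medians exist. Rooting marks the
node(s) minimizing total Hamming distance to the outgroups (ties kept).
Exports: GraphML, DOT, node/edge TSV.

## Ordination and distance-based tests

Jaccard distances on band presences (scipy `pdist`); all-zero samples are an
error. NMDS minimizes Kruskal stress-1 (scikit-learn's nonmetric MDS);
restart 1 starts from classical metric scaling, the rest from seeded random
configurations, best stress kept and reported as a fraction. The factor fit
is the categorical goodness-of-fit on scores (between-centroid R², label
permutation), invariant to score rotation. The permutational MANOVA uses the
McArdle–Anderson construction (Gower-centered squared distances, sequential
hat-matrix partitioning); nesting "host within location" is the term
sequence `location, location:host`, with free permutation of individuals
within location strata. Sequential (not marginal) sums of squares are fixed;
R² terms plus residual sum to 1 by construction, and the one-term case
reduces exactly to the classical one-way ANOVA F on Euclidean univariate
data.

## Pipeline defaults and problem sizes

Permutation counts default to 5000 (FST, adonis, factor fit) and 1000
(ΦST); trimmed mean 30%; FDR 0.05; envelope 50 000 simulated loci; NMDS 20
restarts; the ≥5-individuals-per-host rule selects locations for
within-location comparisons, applied identically to FST and ΦST. All stage
seeds derive from the single run seed; the same configuration and seed
reproduce byte-identical report tables. The test suite and the acceptance
script run their recovery checks at 2 groups × 90 individuals × 250 loci
(the study's scale) with noise-free calibration fixtures — genotyping noise
attenuates FST (miscalls push both groups toward 0.5), so estimator-recovery
checks isolate the estimator while QC checks keep the 5.5% miscall rate.

## Known limitations

- Dominant-marker FST retains a small positive large-sample bias (~+0.007 at
  F = 0.12) from evaluating the sampling variance at the pooled frequency.
- The chi-square(1) reference for the LD test is approximate at boundary
  MLEs; aggregate calibration is verified, per-table accuracy is not.
- The EM phaser ignores recombination; with more than ~15 heterozygous
  sites an individual is left unphased rather than approximated.
- The network construction does not implement reduced-median preprocessing
  or frequency-weighted post-processing; published figure topologies are
  not reproduced exactly.
- BayeScan-style posterior-probability outlier detection is out of scope;
  the multi-comparison consensus rule stands in for cross-method agreement.
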
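# Methods

## The estimator

`argwalker` estimates, for every haplotype in a sample, how much meiotic
recombination its ancestry has experienced at a focal hotspot.  The input
is an ancestral recombination graph (ARG) `G(V, E)` of the sample over a
SNP window containing the hotspot: a DAG whose edges point from ancestor
to descendant, whose leaves are the sampled haplotypes, and whose
recombination events appear as nodes with in-degree ≥ 2.  Reconstructed
ARGs are typically partial (subARGs) and may have several roots; both are
supported.

The estimator is deterministic and has three steps.

1. **Backward walk (edge weights).**  Each edge `u→v` receives the integer
   weight

   `W(u→v) = 1 + Σ_{(v,w) ∈ E} W(v→w)`,

   computed leaves-first in reverse topological order.  `W(u→v)` is one
   plus the number of nodes reachable from `v` counted with path
   multiplicity, so a recombination node reachable along two paths counts
   twice.  Edges whose descendant sets are rich in recombination nodes
   therefore accumulate large weights.  Weights are kept in exact integer
   arithmetic (they can grow like `2^r` with `r` descendant recombination
   nodes; Python integers make this lossless).

2. **Normalization (transition matrix).**  `T(u→v) = W(u→v) / Σ_k W(u→k)`.
   Rows of internal nodes are stochastic to 1e-12; leaves are absorbing.

3. **Forward walk (signal collection).**  A signal vector `I` is
   initialized on the roots — each root gets the sum of its outgoing
   weights (rescaled by a power of two if it would overflow double
   precision; the normalized profile is invariant to this) — and the pair
   of updates `I ← I·T`, `V_L ← V_L + I` is iterated until `I` is
   numerically zero (tolerance 1e-15, hard cap `n+1` iterations; with
   absorbing leaves both tests coincide).  `V_L` masked to the labelled
   leaves is the strength profile; normalized to unit sum it is the
   probability profile `V_p`.  Mass absorbed at unlabelled sinks is logged
   as lost mass so conservation checks can account for it.

Signal mass is conserved: the sum of leaf strengths equals the total root
initialization (relative tolerance 1e-9 in the tests).  On trees the walk
spreads mass by subtree weight; recombination nodes merge the flows of
their parents, which is what lets leaves below recombination-rich ancestry
collect more signal.

**Profile symmetrization.**  Haplotypes with identical sequences are
exchangeable given the data — no method whose input is the haplotype
matrix can tell them apart — so pipeline profiles replace each strength by
the mean over its identical-sequence group.  This removes genealogical
detail that is unresolvable in principle and leaves the total mass
unchanged.

## Unimodality filter

When a hotspot segregates hot and cold alleles, the strength profile
should be bimodal; when every haplotype carries the same allele it should
be unimodal.  Profiles are screened with Hartigan & Hartigan's dip
statistic — the sup-norm distance between the empirical CDF and the
nearest unimodal CDF — implemented with the classical greatest-convex-
minorant / least-concave-majorant shrinking algorithm in exact count
units.  The implementation is validated in the tests against a brute-force
oracle that minimizes the sup-distance by linear programming over
piecewise-linear unimodal CDFs for every candidate mode placement
(collapsing ties to support points with multiplicities, since a unimodal
CDF may jump only at its mode).

p-values are Monte-Carlo against the standard conservative uniform(0,1)
null: `p = (1 + #{D* ≥ D}) / (1 + n_null)` with `n_null = 10,000` samples
of the profile's size (null tables are cached per size; the +1 keeps
p > 0).  A profile is kept when `−log10(p) ≥ 2.473`, the operating
threshold of the original screen; the boundary value is kept.  Profiles
with all strengths equal are dropped with reason "degenerate" — a flat
profile carries no evidence of strength variation.  Because the dip is
invariant under strictly increasing transforms, testing `V_p` and `V_L`
is equivalent; `V_p` is used.

## Association scan

Each hotspot's strengths form a quantitative phenotype over haplotypes.
For every SNP, a two-sided unpaired Student t-test (pooled variance;
Welch behind a flag) compares strengths between allele-0 and allele-1
carriers.  The association unit is the haplotype, matching the phased
per-haplotype strengths; pairs with an allele group smaller than two or
zero pooled variance are excluded as untestable and counted in the log.
Significance uses the fixed thresholds p < 10^-7.3 (genome-wide) and
p < 5e-8 (MHC screen); no further multiple-testing correction is applied.
SNPs below a minor-allele-frequency floor of 0.01 are removed before
scanning.  Chromosome-wise phenotypes are built by standardizing each
hotspot vector to (x − mean)/SD and averaging the standardized vectors;
zero-SD hotspots are skipped with a warning.

## Synthetic data

The generator replaces an external forward-simulation pipeline and
produces everything the walker needs, including the **true ARG** of the
sample, so no reconstruction tool is required.

A Wright–Fisher population of `pop_size = 500` diploids evolves for
`generations = 200` generations over a window of ~100 SNPs (jittered
uniformly in [90, 110]) spanning 200 kb.  One biallelic causal SNP at the
window centre controls the hotspot: per meiosis, the transmitting
haplotype crosses over at the hotspot with probability
`base_crossover = 0.02` if it carries the cold allele and
`hot_cold_ratio × base_crossover` (default ratio 10) if it carries the hot
allele; an additional background crossover falls on a uniformly chosen
non-hotspot boundary with probability `background_rate = 0.002` per
meiosis.  The hotspot occupies `hotspot_snp_width = 1` inter-SNP boundary
just right of the causal site, so the rate-determining allele always
travels with the gamete.  Biased gene conversion acts at the causal site
only: when a hotspot crossover occurs in a causal-site heterozygote, the
transmitted causal allele is the cold (hotspot-disrupting) allele with
probability `0.5 + bgc_rate`.

Two structural choices matter and were made deliberately:

* **Founder clades.**  A biallelic variant at intermediate frequency is an
  old polymorphism whose carriers share deep ancestry.  The population is
  seeded from `n_founders = 40` founder haplotypes (neutral alleles drawn
  per founder at frequencies uniform(0.1, 0.9)), a fraction `causal_maf`
  of which carry the hot allele.  Sample lineages that fail to coalesce
  within the simulated epoch coalesce at their founder.

* **Conditioning on the realized MAF.**  The causal MAF is a property of
  the analysed sample, not of the founding generation, so realizations
  whose sampled MAF drifted more than 0.1 from the target (or lost the
  allele) are rejected and resimulated with a derived seed (cap 50).

The true ARG is extracted by tracing ancestral genomic segments backwards
through the recorded pedigree: an ancestor is retained only while it
carries window material ancestral to the sample, and a crossover ancestor
keeps two parents only when both sides transmit such material — retained
in-degree-2 nodes are exactly the sampled-lineage breakpoints inside the
window.  The graph is then coarsened to the resolution a sequence-based
method could achieve: recombination-free subtrees are contracted to stars
around their roots (their internal coalescent structure is invisible to
haplotype data), and remaining unary chains are contracted (skipping a
contraction that would create a parallel edge).  Fixed sites are dropped
from the emitted matrix — a monomorphic column is not a SNP.

Numbers behind the defaults: with 180 sampled haplotypes in a population
of 1,000 and a 200-generation epoch, most lineages coalesce within the
epoch; at ratio 10 a hot lineage experiences an expected 0.2 crossovers
per meiosis at the hotspot versus 0.02 for a cold lineage, giving a
roughly tenfold contrast in registered ancestral recombination events.
`pop_size`, `generations`, crossover scales and `n_founders` are not
stated by the original study design and are desk-scale choices; all are
exposed on `Scenario`.

**What the generator does not emulate.**  Mutation during the epoch
(diversity enters only through founders), conversion tracts (BGC acts on
the causal site only), demographic structure, multi-hotspot windows, and —
most consequentially — ARG *reconstruction*: the walker here runs on the
simulator's exact ARG.  Passing tests therefore show that the estimator
recovers allele-specific recombination history from correct graphs; they
do not bound the additional error a reconstruction step would introduce on
real data.

## Evaluation harness

Haplotypes are labelled hot/cold from a profile by an exact 1-D 2-means
split of `V_p` (full scan over sorted split points minimizing
within-cluster sum of squares; the higher-mean cluster is "hot"; an
all-equal profile is flagged degenerate and labelled all-cold).  The
labelling rule of the original study is not recorded anywhere, so this
deterministic rule is this package's own convention.  Sensitivity,
specificity and accuracy are computed per sample with "hot" as the
positive class and averaged across replicates; an undefined rate (truth
all one class) is reported as NaN, never 0.  The dip experiment simulates
50 two-allele and 50 no-variation samples (25 all-hot, 25 all-cold),
dip-tests each profile, and summarizes discrimination as a rank
(Mann–Whitney, tie-corrected) ROC AUC over the `−log10(p)` scores.

### Observed behaviour and known limitations

Under the default study conditions the harness reproduces the qualitative
validation results: classification accuracy rises from chance at ratio 1
(median ≈ 0.5) to well above chance at ratio 5-10 (median ≈ 0.75), and hot
haplotypes out-collect cold ones in well over 80% of replicates at ratio
10.  Running on true ARGs, accuracy is somewhat higher than the ~0.6-0.7
reported for reconstruction-based pipelines, as expected for an upper
bound.

The dip-filter *operating point* does not transfer to true-ARG profiles.
Because the walker is sensitive to coalescent topology, symmetrized
profiles contain groups of identical values ("atoms") at several levels in
every arm, and any such profile is far in the tail of the continuous
uniform dip null.  `−log10(p)` is therefore large for most no-variation
samples too: at threshold 2.473 only ~20-25% of no-variation samples are
removed (versus 88% in the original screen), ~90-98% of two-allele
samples are kept (87.8% originally), and the score ROC reaches an AUC of
only ~0.7 (0.956 originally).  The sharper original separation evidently
rests on properties of reconstructed subARGs — far fewer, data-supported
recombination events and no pedigree-level detail — which are outside this
package's scope.  The acceptance suite asserts the original operating
characteristics at their stated tolerances and the two operating-point
checks fail honestly under this generator.

## Numerical and interface conventions

* Exact integer edge weights; double-precision transitions and signals;
  sparse matrices throughout.
* Deterministic everywhere: seeded `numpy` Generators, derived seeds for
  retries and replicates, lexicographic row order in all writers —
  identical seeds give byte-identical outputs.
* Tie-breaks: the 2-means scan keeps the first (smallest) optimal split;
  the dip filter keeps profiles exactly at the threshold.
* Windows: hotspot windows are `width` SNPs centred on the nearest SNP,
  truncated at chromosome ends with a warning; overlapping windows are
  dropped greedily in genomic order.
* Coordinates are 1-based inclusive in user-facing files, 0-based
  half-open internally.
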
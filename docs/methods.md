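# Methods

This note records the models, conventions and design choices behind
`barcodegap`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic-data tests do and do not
demonstrate about real data.

## Distances

Pairwise divergence uses the Kimura 2-parameter model. For each pair, sites
are classified under **pairwise deletion**: a position enters the comparison
only if both sequences carry an unambiguous A/C/G/T there; gaps and IUPAC
ambiguity codes are skipped per pair, never globally trimmed, and never
counted as matches or mismatches. With transition proportion P and
transversion proportion Q over the compared sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)   [substitutions/site].

Two failure modes are kept distinct: a **missing pair** (fewer comparable
sites than the overlap floor, default 300 — necessary because 650-bp and
1800-bp products co-occur and a 40-site overlap would otherwise yield a
"distance") and a **saturated pair** (a log argument ≤ 0, divergence beyond
what the correction can invert). Both are NaN in the matrix with a recorded
reason; they are excluded from every summary and are an error (or, on
request, max-distance imputation) for tree building.

Distances are proportions internally. Level summaries and nearest-neighbour
tables print percent (×100) except the level SD, which is printed on the
proportion scale — the convention of the classic barcode-gap tables. Dating
works on proportions throughout.

## Trees

Neighbour joining is the standard Saitou–Nei agglomeration with the
rate-corrected Q-criterion. Conventions pinned for determinism:

* Q-criterion ties are broken by the smallest (i, j) index pair;
* a negative branch-length estimate is clamped to zero and its deficit moved
  to the sister branch, so the joined pair's distance is preserved;
* the output is unrooted (final trifurcation), exact on additive matrices —
  leaf-to-leaf path lengths reproduce the input, which the property tests
  check up to n = 12 against a brute-force path-length oracle and against
  scikit-bio's independent NJ.

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path; ties for the diameter pair are broken by the lexicographically
smallest leaf-name pair; an all-zero-length tree is rooted arbitrarily with
a warning. On a clock-like tree the midpoint coincides with the true root,
which is why the simulator generates ultrametric trees (below).

The tree is built over *individuals*; species/lineage-level quantities
(patristic distances between lineages, exclusivity) collapse leaves a
posteriori, the between-lineage distance being the mean path length over
cross-lineage leaf pairs.

## Barcode-gap summaries

Every unordered pair is assigned to the finest taxonomic rank the two
specimens share: within species; within genus among species; within family
among genera; within order among families. Species sampled once contribute
no within-species pair. The fold ratio is
mean(within-genus-among-species) / mean(within-species), rendered as
"N-fold" after rounding.

Nearest-neighbour distance per species is the minimum K2P distance to any
heterospecific individual, binned on the percent scale with half-open
left edges: [0, 0.1), [0.1, 1.0), [1.0, 2.7), [2.7, ∞). The published table
headers leave edge inclusivity ambiguous; a deterministic rule is required
for testing, and this one is documented wherever the bins are reported.

Species diagnosis on the midpoint-rooted NJ tree:

* **captured** — the species' individuals form an exclusive (private)
  cluster *and* its minimum interspecific distance is positive;
* **mixed** — not exclusive, or minimum interspecific distance zero
  (haplotype sharing implies both);
* **new_lineage_candidate** — an exclusive, positively diverged cluster
  whose label is in the caller-supplied set of new-locality populations.
  No metadata field can express "this population is a newly discovered
  locality", so the set is an explicit argument (the simulator's ground
  truth provides it in tests; a config list provides it in the pipeline).

## Phylogenetic community structure (Pi_ST)

Input: a lineage × region presence/absence matrix (abundances are not used;
the unit is lineage occurrence per region) and a lineage-level phylogenetic
distance matrix (mean patristic distance on the midpoint-rooted NJ tree).
With δ_within the mean distance between distinct co-occurring lineages
(averaged over regions) and δ_among the mean distance between distinct
lineages of different regions (averaged over region pairs, shared lineages
excluded from the pair count),

    Pi_ST = 1 - δ_within / δ_among.

Significance is a one-sided upper-tail (clustering) permutation test:
lineage identities are shuffled globally on the distance matrix and
p = (1 + #{Pi_perm ≥ Pi_obs}) / (1 + n_perm), default 10,000 permutations,
seeded. Regions hosting fewer than two lineages carry no within pair and
are dropped with a warning; all-singleton inputs are an undefined-signal
error, not a zero.

Small-community caveat: the global label shuffle is discrete. With k
lineages, at most k! distinct relabellings exist and highly symmetric
configurations put large point masses on the observed value — a 2-site,
4-lineage community cannot reach p < 1/3 no matter how clustered it is.
Significance claims in the tests therefore use communities of a dozen or
more lineages. The exhaustive oracle comparison enumerates *all* presence
matrices for shapes with ≤ 12 cells and samples the larger shapes up to
6 lineages × 4 sites (full enumeration of 2^24 matrices would be pointless
as well as slow).

## Divergence dating and calibration

Rates are interpreted as **pairwise divergence per Myr** — t = d/r, not
d/(2r) — which is the only reading consistent with the published arithmetic
(0.137 / 0.005 = 27.4 Myr). Three literature hypotheses ship as constants:
minimum 0.005, fish 0.012, vertebrate 0.02 substitutions/site/Myr; two dated
uplift events likewise: Lengguru arch 8–11 Myr (attached to the six
between-clade divergences) and Mok ridge 1.65–3.4 Myr (attached to the
within-IB divergence). (One published passage gives the Lengguru uplift as
12–9 Myr; the 8–11 Myr values used by the calibration table are the
defaults.)

Clade statistics: "within X" averages heterospecific intra-clade pairs
(conspecific pairs measure population variation, not lineage divergence);
"X vs Y" averages all cross-clade individual pairs. The reported SE is
sd(pairwise distances)/√n_pairs — a *descriptive* dispersion only, since
pairwise distances share tree paths and are far from independent.

Calibration: an event at [age_min, age_max] bounds the rate to
[d/age_max, d/age_min]. Reporting rounds rates to 3 decimals, switching to
4 when a bound would round below 0.01/Myr (the Mok interval 0.0094–0.0194).
Concordance — which named hypothesis falls inside each calibrated interval —
is evaluated at this reporting precision, matching how the published
comparison reads its own table (0.137/11 = 0.01245 counts as containing
0.012).

## The simulator

The generator emulates the *statistical* structure of a barcoded radiation,
not its demography:

* an ultrametric tree in which clades split at `clade_depth`, species within
  clades at `species_depth`, and individuals coalesce at
  `intraspecies_depth` (all in expected substitutions/site, so truth and K2P
  estimates share units). Defaults 0.0685 / 0.0295 / 0.00325 reproduce the
  observed levels of the rainbowfish survey: between-clade pairwise
  divergence ≈ 0.137, within-clade among-species ≈ 0.059, within-species
  ≈ 0.0065;
* sequences evolved branch-by-branch under the K2P process
  (transition/transversion rate ratio κ, default 4) using the exact
  end-to-end substitution probabilities, so a branch is one multinomial
  draw per site;
* optional stop-avoidance (`stop_free`, default on): codons that would
  become vertebrate-mitochondrial stops (TAA, TAG, AGA, AGG) in frame 0 are
  redrawn, falling back to the parent codon — the emitted barcodes then pass
  the coding-sequence validation, as real functional COI does;
* 15 planted "new lineages": singleton pendant branches attached at a
  clade's crown, nearest neighbour ≈ 2 × `species_depth` away — exclusive
  and strongly diverged by construction;
* regions: clades are mapped to disjoint region subsets (default: the seven
  survey regions split round-robin over four clades) so regions are
  phylogenetically clustered; a null variant reshuffles the lineage→region
  map to break the clustering.

The default cohort is 4 clades × 13 species × 5 individuals + 15 singletons
= 275 barcodes of 650 bp — the survey's structure at a size where the whole
pipeline runs in seconds.

What the simulator does **not** emulate: rate heterogeneity across sites and
lineages, non-clock evolution, indels and ambiguity codes, coalescent
variation within species, hybridization/introgression (haplotype sharing is
injected in tests by relabelling, not simulated mechanistically), and
uneven sampling. Passing tests therefore demonstrate correctness of the
estimators and bookkeeping under the matched model, not robustness to
real-data violations of it.

Two numerical consequences matter for interpreting tests:

* **stop-avoidance censoring**: rejecting stop-creating draws removes ~4–5 %
  of substitutions at the defaults, so realized divergence sits slightly
  below nominal branch lengths. Parameter-recovery checks that quantify
  estimator bias run with `stop_free=False` (the matched process);
* **shared-branch variance**: all cross-clade pairs traverse the same two
  deep branches, so a cohort's between-clade mean distance fluctuates with
  single-realization noise (sd ≈ 0.0075 at 2 kb) no matter how many pairs
  are averaged; unbiasedness is assessed across replicate cohorts against
  the empirical Monte-Carlo error, never against sd/√n_pairs.

## Problem sizes and determinism

Test and acceptance problem sizes are chosen so the full suite runs in well
under a minute: the 275-barcode cohort for integration stages; 200
replicates × 10,000 sites for estimator recovery (mean relative error
~0.1–0.2 %, bound 2 %); 999–9,999 permutations for Pi_ST significance; 200
replicates × 199 permutations for the p-value uniformity (KS) check; 30
replicate cohorts at 5 kb for calibration-interval coverage. All randomness
flows from integer seeds through `numpy.random.default_rng`; no ordering
depends on hash iteration, and reruns with the same config are
byte-identical.

## Known limitations

* Only the K2P model is implemented (no JC/TN93/GTR, no gamma rates); that
  is the convention of the barcode literature this toolkit mirrors.
* The NJ variant and tie-handling of other tools (e.g. the BOLD platform's
  tree module) are undocumented, so leaf-level topologies need not match
  other software even on identical matrices; matched *distances* are exact.
* The permutation scheme shuffles lineage identities globally; other nulls
  (within-clade shuffles, site-pattern permutations) would answer different
  questions and are not provided.
* Table-style outputs assume a single order per dataset is typical; pairs
  sharing no rank at all are excluded from the ladder rather than given a
  fifth level.
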
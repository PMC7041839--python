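# Methods

`oasisnet` re-implements, as a tested pipeline, a movement-ecology analysis of
kin-biased foraging in Egyptian fruit bats (*Rousettus aegyptiacus*) at a
desert oasis: radio-telemetry fixes are turned into nightly foraging-site
visits, visits into weighted space-sharing networks, microsatellite genotypes
into maximum-likelihood pairwise relatedness, and the association between the
two dyadic structures is tested with matrix permutation methods.  Because the
original field dataset is not deposited, a synthetic generator stands in for
it; this note records the models, the defaults and the design choices, and
what a green test does and does not establish.

## Telemetry

Coordinates are planar metres in one projected frame; the study area spans a
few kilometres so no geodesy is attempted.  A bearing defines the *line*
through its station at the given azimuth (dipole antennas are ambiguous by
180°); `triangulate` returns the point minimizing the sum of squared
perpendicular distances to all bearing lines, solved from the 2×2 normal
equations.  Bearings must come from ≥ 2 distinct stations within a
configurable simultaneity window (default 60 s; the field system took bearings
every 2–10 minutes, so 60 s is safely "simultaneous").  If all pairwise line
angles are below 5° the geometry is declared degenerate rather than returning
an ill-conditioned intersection.  A `rays=True` flag restricts solutions to
the forward half-line of every station.

Nights run from local noon to the next local noon, so a fix at 03:00 belongs
to the previous evening's foraging night.  A bat *visits* a site on a night
iff at least `min_fixes_per_visit` (default 2) of its fixes that night fall
inside the site geometry; requiring two fixes suppresses single spurious
triangulations.  Sites are circles of radius 56.42 m — the circle whose area
equals the 100 × 100 m square mapped around each food patch — unless polygon
geometry is supplied.

Tracking effort follows the printed formula literally: the probability of
visiting a new site on night *t* is the mean number of first-seen sites per
tracked bat on night *t* divided by *t*.  The formula's denominator is
ambiguous in the source description; a cumulative-mean alternative is
available via `mode="cumulative"` without any claim about which was used
originally.

## Home ranges

The level-L minimum convex polygon keeps the `floor(L% · n)` fixes nearest the
arithmetic mean centre (one pass, stable sort, ties keep the earlier fix) and
takes their convex hull; the 50% polygon under the same rule is the core area
(CA).  `floor` and the stable tie-break make results reproducible bit for bit.
At least 5 retained fixes are required; distinctness is not, so a bat that
commutes between two exact points still errors (its hull is degenerate below
5 retained), while stacked duplicates of ≥ 5 fixes are fine.  Collinear fixes
return a zero-area range with a `collinear` flag rather than an error.
Kernel estimators and autocorrelation corrections are deliberately out of
scope.  Areas are hectares (m²/10⁴).

## Pairwise relatedness

For a non-inbred diploid pair, genotypes at a locus depend on whether the
pair shares 0, 1 or 2 alleles identical by descent, with probabilities
k = (k0, k1, k2) on the 2-simplex.  The multilocus log-likelihood is
Σ_loci log(k0·P0 + k1·P1 + k2·P2) with the standard IBD-conditional ordered
genotype-pair probabilities under Hardy–Weinberg: P0 is the product of the two
HWE genotype probabilities; P1 sums over candidate shared alleles the chance
that allele is the IBD copy in each genotype times the frequency of the
non-IBD allele; P2 is the HWE probability of the common genotype when the
genotypes coincide.  Each Pm sums to one over all ordered pairs (checked by
enumeration in the tests).  Maximization uses a 0.02-step simplex grid
followed by SLSQP refinement; k is constrained only to the simplex (no
k1² ≥ 4·k0·k2 restriction), and r̂ = k1/2 + k2.

Choices that mirror the common ML-Relate defaults: allele frequencies are
estimated from the full sample including the focal pair, and no
genotyping-error or inbreeding model is fitted.  The estimator is
boundary-biased upward for truly unrelated pairs (k̂0 piles at 1, occasional
pairs escape to r̂ > 0), so recovery tests summarize unrelated pairs by the
median.  "Related pair" for network filtering defaults to r̂ ≥ 0.25 (the
half-sib expectation); this is a configuration knob, not an empirical claim.

The seasonal comparison of relatedness distributions uses the two-sample KS D
between within-season pairwise r̂ sets, with a node-based null: individuals'
season labels are permuted and D recomputed, p = (#{D* ≥ D} + 1)/(n_perm + 1).
D is recomputed per permutation with a direct sorted-ECDF implementation
(scipy's `ks_2samp` is the cross-check in tests but is too slow to call 10⁴
times).  With small groups (≲ 10 per season) the discreteness of D makes this
test conservative; at the study's scale (31/32 individuals) calibration is
nominal — the test suite measures both.

## Space-sharing networks

A site is shared by a pair iff both have a visit record at that site on the
same night; same site on different nights does not connect.  The edge weight
is the shared-site count over the pair's combined repertoire |S_i ∪ S_j|
(Jaccard style).  The source description only says "percentage of shared
foraging sites", so the denominator is configurable (`union`, `min`, `mean`);
union is the default because it is symmetric and bounded in [0, 1].  Weights
are proportions internally and percentages in output files; the published
weighted degrees (≈ 15 with ≈ 15 partners) are consistent with
proportion-scale sums.  Density ρ, normalized degree k = deg/(n−1) and the
local clustering coefficient use the binary adjacency only; weights enter
solely through strength s = Σ_j w_ij.  Filtering to related pairs only zeroes
edges with r̂ below the threshold and keeps all nodes, so filtered density can
only fall.  Co-roosting counts days a pair occupied the same day roost (first
roost of the day if several).

Note one artefact worth knowing: regressing the *filtered* network on
relatedness is partly mechanical, because the filter zeroes edges exactly
where relatedness is low.  The pipeline therefore reports the QAP on both the
filtered (faithful to the original analysis) and the unfiltered sharing
network.

## Permutation inference

MR-QAP with double semi-partialling: observations are the off-diagonal cells
of aligned square matrices (both (i,j) and (j,i); the doubling is the UCINET
convention and leaves coefficients unchanged).  Coefficients come from OLS;
for each predictor, its residual matrix after regressing out the other
predictors cell-wise is permuted by *simultaneous row/column relabelling*,
re-entered into the model, and the two-sided p is
(#{|β*| ≥ |β|} + 1)/(n_perm + 1).  For a single predictor the reported model
correlation is the signed Pearson r of the vectorized matrices; for several
it is the multiple correlation.  Rank-deficient designs error naming a
collinear predictor; constant matrices (after vectorization) error rather
than silently degenerate.

Vector tests on node metrics permute node labels: Welch t (zero-variance
groups map to ±∞ with the sign of the mean difference, or 0 when means tie),
tie-corrected Kruskal–Wallis H (with pairwise Bonferroni-adjusted post-hoc
permutation tests), and the OLS slope with adjusted
r² = 1 − (1 − r²)(n − 1)/(n − 2).  All tests are two-sided — the original
analysis reports a negative spring coefficient, implying two-sided use — and
all use the add-one p-value convention, which can never return 0.  Two-group
tests offer exhaustive enumeration over all label splits (identity included,
no add-one) for exact small-sample checks.

Calibration facts established by the test suite: the DSP p matches the
exhaustive 120-permutation QAP at n = 5; type-I error at nominal 0.05 lies in
[0.03, 0.07] over 500 null matrix regressions (independent node effects,
n = 20, 499 permutations) and over 300 replicates each for the t and slope
tests.

## Synthetic data generator

The generator states a world matching the study design: two seasonal regimes
over one landscape — winter with 12 food patches scattered in a ~2 km disc
(several fruiting species), spring with 2 date patches ~300 m apart — ~32
bats per season tracked 8 nights (the study mean was 8.35 nights/bat), 13
microsatellite loci with 3–10 alleles per locus (study mean 6.15), and
pedigree-derived kinship from a two-generation polygynous pedigree (each
female draws a sire and a Poisson(2) litter, so parent–offspring, full-sib,
half-sib and unrelated pairs all occur).  Per-site fruit-tree counts are
calibrated only qualitatively (the source gives no per-site counts): what is
preserved is the many-patches-vs-few contrast.

Site choice is a multiplicative weight rule.  Each bat each night picks 1–3
distinct sites with probability proportional to

    availability^a × (1 + 4·phi if previously used) × exp(gamma · mean r to bats already at the site)

Bats are assigned sequentially within a night (order reshuffled nightly) so
kin attraction can reference earlier arrivals.  The rule nests the null:
gamma = 0 makes choice independent of kinship, which the type-I tests rely
on; gamma ≥ 3 produces a detectable sharing–kinship correlation (power ≥ 80%
at n = 20 bats).  phi ∈ [0, 1] scales a fivefold fidelity preference at
phi = 1; default 0.3.  Fixes are Gaussian scatter (sd 25 m) around chosen
site centres plus commuting fixes on the roost–site leg; with the noise at 0
the recovered visit table equals the generator's ground truth exactly, which
anchors the telemetry oracle test.

What the generator does *not* emulate: continuous movement paths, signal
propagation and bearing error structure, torpor/energetics, weather, seasonal
turnover of individuals, genotyping error and allelic dropout.  A green test
therefore establishes internal correctness and calibration of the estimators
on data with the stated structure — not field realism.

One emergent caveat: on saturated synthetic networks (spring density ≈ 1.0)
the pooled sites-visited ~ degree regression can invert its sign relative to
the original finding, because degree hits its ceiling while site counts still
vary between regimes.  The per-season networks are the informative ones
there.

## Determinism and outputs

Every random step flows from one seeded `numpy` generator recorded in the
run manifest; rerunning a pipeline config reproduces `report.json` byte for
byte (tested).  Artifacts are plain text: CSV tables, GeoJSON sites, GraphML
networks, YAML manifests, JSON reports.
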
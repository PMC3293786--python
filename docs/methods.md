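# Methods

This note records the models implemented, the conventions chosen where the
underlying methods admit more than one reading, and what the synthetic-data
tests do and do not demonstrate.

## Sequence statistics

Alignments are strings over {A, C, G, T, N, -}. Sites with N or gaps are
handled by **pairwise deletion** by default: a site enters a pairwise
comparison only when both sequences carry an unambiguous base; complete
deletion (drop the column for everyone) is available on the distance
configuration. Haplotype collapsing follows the same logic: with
`merge_ambiguous=True` (default) a sequence joins the first earlier
haplotype it is compatible with at all mutually unambiguous sites.

π is reported per site (each pair normalised by its own comparable length).
Tajima's D uses π in per-locus units internally, the statistic's canonical
form; both quantities are exposed. D is undefined (NaN) at S = 0 rather
than 0 — a monomorphic sample carries no information about the frequency
spectrum.

Fu's Fs uses θ̂ = mean pairwise differences and the Ewens sampling
distribution P(K = k) = |s(n,k)| θᵏ / (θ(θ+1)⋯(θ+n−1)). Unsigned Stirling
numbers of the first kind are built by the additive recurrence in log space
(`logaddexp`), which survives n of several hundred where the integers
overflow any float. k_obs = 1 gives S′ = 1 and Fs = +∞ (maximal *deficit*
of haplotypes); π = 0 gives NaN.

TN93 distances split transitions into purine and pyrimidine classes with
base frequencies averaged over both sequences of each pair; the gamma
variant replaces −ln w by α(w^(−1/α) − 1). Domain violations (e.g. p ≥ 3/4
under JC69) yield NaN for that pair, never a clamped number. The
implementation is cross-checked in the test suite against `ape::dist.dna`
through Rscript as an independent oracle.

### AMOVA

The hierarchical decomposition (among groups / among populations within
groups / within populations) follows the standard sums-of-squared-distances
identities with the usual unequal-sample-size coefficients. Input matrices
are treated as **squared** distances by default, matching the convention in
which the count of pairwise differences plays the role of a squared
Euclidean distance; `squared=False` squares the entries first. A
frequency-only mode (0/1 haplotype-identity distances) is available via
`indicator_distance`.

Permutation tests use the three standard schemes — individuals among
populations across the sample (Φ_ST), individuals among populations within
their group (Φ_SC), whole populations among groups (Φ_CT) — with
p = (b+1)/(B+1) and an explicit seed. Default B = 20,000; calibration runs
in the tests use fewer. Two behaviours of these tests are worth knowing:
at small designs the Φ_CT scheme has very few distinct rearrangements, so
its p-values are coarse; and when the test statistic takes few distinct
values (low mutation rates), ties make permutation p-values conservative —
the null-calibration test therefore uses a parameter regime where the
statistic is effectively continuous.

### Haplotype networks

The minimum spanning tree over Hamming distances uses Kruskal with a
deterministic tie-break (weight, then node indices). Because published
network figures often show extra, equally parsimonious connections without
an algorithmic rule, every non-tree edge whose weight equals the maximum
edge weight on the tree path between its endpoints is reported as an
*alternative edge* rather than drawn into the tree.

## ENFA

All valid cells are standardized by the global mean and SD (population
denominator n, matching the z-space convention; both covariance matrices
use the same denominator). With m the (weighted) presence mean in z-space,
R_g and R_s the global and presence covariances:

- W = R_s^(−1/2) R_g R_s^(−1/2), y ∝ R_s^(−1/2) m;
- specialization axes are the eigenvectors of (I − yyᵀ) W (I − yyᵀ)
  back-transformed by R_s^(−1/2) and unit-normalised; the marginality axis
  is m/‖m‖ with specialization λ₁ = yᵀWy;
- overall marginality M = ‖m‖/1.96, so M ≈ 1 means the niche optimum sits
  1.96 global SDs from the global mean.

A small ridge (default 1e-8, recorded in the model) is always added to R_s
before inversion; environmentally identical presences still fail with a
diagnostic, as no ridge can make that informative. Eigenvector signs are
fixed by forcing each axis's largest-magnitude coefficient positive, making
coefficients reproducible across platforms. Note the specialization axes
u_k = R_s^(−1/2) v_k are pairwise conjugate in the R_s metric
(u_iᵀR_s u_j = 0) and plainly orthogonal to the marginality *vector*
(u_kᵀ m = 0); they are not R_s-conjugate to the marginality axis.

Factors are retained by the broken-stick rule (strict inequality, b_k =
(1/p)Σ_{i≥k} 1/i) with the marginality factor always kept. HS scores use
the median algorithm per retained factor — H = min(1, 2·#{presences at
least as far from the presence median, same side}/N, cells at the median
scoring 1 — combined as a weighted mean with w_k = λ_k including the
marginality axis (the original tool's exact weighting of that axis is not
published; "equal" weighting is available and the choice is recorded in the
map object). Binarization uses the minimum training presence with an
HS > 0 guard so a zero threshold still excludes strictly unsuitable cells.

Because per-factor suitabilities are rank counts over the N presence
records, leave-one-out refits shift envelope-cell scores by O(1/N) counts
even for duplicated records; jackknife proportional differences are
therefore small but not identically zero for duplicates.

## Divergence suite

Conventions the source methods leave open are explicit parameters, recorded
in every result object: overprediction is normalised by the split-union
area; overlap by the union (|A∩B|/|A∪B|, symmetric, with |A|, |B| and
valid-cell denominators selectable); each model — including the lumped
model — is binarized at its own minimum training presence. False-positive
rates need a reference truth grid and support an exclusion mask (e.g.
reference records inside the other lineage's convex polygon). The
jackknife difference (HS_full − HS_reduced)/HS_full is evaluated at the
left-out population's cell.

## Synthetic data: what it emulates

The haplotype generator draws a Kingman coalescent per population from a
shared group-ancestral sequence, with infinite-sites mutations at rate θ/2
per lineage per unit coalescent time placed at uniformly drawn distinct
columns (exhausting columns is an error, never silent truncation). Groups
after the first receive a private set of fixed diagnostic columns, giving
AMOVA a known among-group signal without a full structured coalescent. The
star genealogy uses tip branches of total length 2·a₁(n) so E[S] matches
the neutral case while the spectrum is pushed toward singletons — the
expansion signature (strongly negative D and Fs) without a demographic
model. Populations alternate between latitudes 38° and 42° so the 40°N
split bisects every group. Not modelled: recombination, migration,
within-group population divergence; between-population AMOVA signal within
groups is therefore weaker than between groups by construction.

Landscapes are moving-average-smoothed white noise (radius = `smoothness`;
0 is allowed and yields white noise) rescaled to mean 0 / SD 1 over valid
cells, with a nodata border to exercise masking; an optional common
pairwise correlation couples layers. Presences are drawn without
replacement with probability ∝ ∏ exp(−(x−o)²/2b²) via Gumbel top-k, which
is distributionally identical to sequential weighted sampling and couples
draws across scenarios sharing a seed (common random numbers for paired
contrasts). These fields lack the anisotropy, gradients and fat-tailed
distributions of real climate layers, so passing recovery tests shows the
estimators work under controlled conditions, not that real-data results
are unbiased.

The two-lineage scenario generator reflects the study system it emulates:
each lineage is a specialist on the first two layers (niche SD 0.35 of the
background SD there, 3.0 elsewhere — concentrating ~90% of extractable
variation in the leading factors, as real models show), with a shared
optimum 1 background-SD from the global mean. "Divergent" separates the
optima by 3×breadth along the specialist diagonal; both lineages sample
independently. Default 15 presences per lineage is in the range of
population counts such studies use.

### A caveat on lumped-vs-split discrimination

Simulation with this pipeline shows that a 3×breadth niche separation
produces only a weak systematic overprediction signal (divergent mean of
roughly +5%, per-replicate SD of 20–30%), while the conserved null sits
slightly negative (≈ −9%) because the union of two independently noisy
split binary maps inflates relative to the single lumped map. The
mechanism: HS combines factors by a weighted mean, so split models still
cover the inter-modal environmental gap, and near the minimum-training-
presence threshold the binary maps are envelope-like, where the lumped
envelope equals the union of the split envelopes. Overprediction does
increase monotonically with niche offset and becomes strong for widely
separated niches, but per-replicate discrimination at 3×breadth is limited
(divergent exceeds conserved in roughly two-thirds of paired replicates).
Interpredictivity, by contrast, discriminates the same scenarios almost
perfectly and is the more reliable divergence signal at these effect
sizes.

## Numerical and size choices

Simulation sizes in the tests and the acceptance script (e.g. 50 recovery
landscapes at 200×200, 500 null AMOVA datasets at 200 permutations, 400
neutrality replicates, 100 scenario pairs at 120×120) were chosen so each
Monte-Carlo check resolves its target within a few percent on one CPU in
minutes. Tajima's D has a genuinely negative finite-sample mean (about
−0.15 at n = 50, θ = 10); the calibration test therefore compares the
generator against an independent coalescent simulator (msprime) at the
same parameters instead of asserting a zero mean. All stochastic code
takes explicit seeds; identical seeds give byte-identical pipeline
outputs.
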
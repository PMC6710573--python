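# Methods

This note documents the statistical models in `maramsg`, the design choices
made where the methodology was genuinely open, the synthetic-data generator's
assumptions, and known limitations.

## Data model

A census is a list of **sessions** (counts), each holding **social units**; a
unit maps species to positive individual counts. Units are classified as
solitary (one individual), single-species groups (≥ 2 individuals, one
species) or mixed-species groups (≥ 2 species). Sessions are partitioned
into **ecological conditions** by NDVI, with half-open bins
[2500, 5000) = low, [5000, 5500) = intermediate, [5500, 7500] = high; the
bin edges print as overlapping ranges in field studies, so the half-open
convention is imposed (and configurable). Condition assignment uses the
per-session NDVI scalar, not calendar windows.

Filtering precedes all analysis: aggregations larger than 2000 individuals
("super-herds", uncountable from a single vantage point) are dropped, with a
strict > 2000 cutoff. Excluded species (e.g. the migratory wildebeest in the
resident-only branch) are removed *at the composition level* by default, so a
mixed unit containing wildebeest still contributes its resident co-membership;
a drop-whole-unit mode exists for sensitivity analysis. All species totals are
recomputed after filtering — the internally consistent choice when the index
below needs condition-wide totals.

## The social affinity index

```
W_AB = [ Σ_{i} N_iA · N_iB / (N_i − 1) ] · (N_tot − 1) / (N_A · N_B)
```

Units of size 1 are skipped (the (N_i − 1) weight would divide by zero, and a
solitary individual has no groupmates). The parenthesization — the whole sum
multiplied by (N_tot − 1)/(N_A·N_B) — is the only reading consistent with the
index's verbal definition (unit share of B experienced by A, relative to B's
community share, with the focal individual discounted) and with symmetry
W_AB = W_BA, which the implementation enforces bitwise.

Properties worth knowing:

* **Neutral value.** W_AB = 1 when individuals mix proportionally at the
  individual level. Real communities (and the generator below) assemble
  groups from *conspecific blocks*; conspecific aggregation depresses
  heterospecific exposure, so the community-wide mean of W sits below 1 even
  when species ignore each other. Significance must therefore come from the
  constrained null model, never from comparing W to 1.
* **Duplication law.** Replicating the whole census k times rescales W by
  (k·N_tot − 1)/(k·(N_tot − 1)): the −1 self-exclusion terms do not scale.
  The factor tends to 1, so W is scale-invariant only asymptotically; tests
  assert the exact finite-size law.
* **Undefined entries** (species absent from a condition, the diagonal,
  dyads masked by the optional minimum-support threshold) carry IEEE NaN,
  never 0, so "no affinity" and "not measurable" stay distinguishable
  downstream.

The standardized index S_A(B) = W_AB / Σ_C W_AC (sentinels excluded from the
sum) controls for a species' overall grouping propensity; each defined row
sums to 1 and the matrix is intentionally asymmetric. An all-zero row (a
focal that never associates) standardizes to a sentinel row and is flagged.

## Constrained null models

The null randomizes group membership within a condition while preserving
(a) each species' total abundance, (b) each species' multiset of conspecific
block sizes, (c) the number of social units, and (d) the multiset of per-unit
species richness values. Equivalently: the (species, size) blocks are
redistributed over the observed unit skeletons with no skeleton receiving two
blocks of one species. Solitary units participate as richness-1 skeletons.

Two samplers draw from this space, both **exactly uniform** in their
stationary law:

* **Rejection** (default where feasible): deal blocks uniformly into skeleton
  slots — uniform over labelled arrangements — and reject conspecific
  collisions. I.i.d. draws; acceptance decays with the number and richness of
  mixed units.
* **Swap MCMC**: a Metropolis chain proposing to exchange two uniformly
  chosen blocks between units, rejected if a collision would result. The
  proposal is symmetric (unit block-counts never change), so the uniform
  distribution is stationary; the chain starts at the observed arrangement
  with burn-in 30× and thinning 8× the number of blocks. Those multiples were
  fixed after goodness-of-fit checks at 10× thinning passed comfortably on
  enumerable instances.

A naive alternative — sequential random fill of skeletons with restart on
dead ends — was evaluated and *rejected*: on three enumerable instances its
draw frequencies failed chi-square goodness of fit against exhaustive
enumeration catastrophically (p ≈ 1e-55 and worse at 1e5 draws). Sequential
fill is measurably non-uniform on asymmetric instances.

The `auto` mode probes the rejection acceptance rate (3 successes within 300
attempts) and otherwise uses the chain; the probe shares the ensemble's
random stream, so results are reproducible from the seed.

An **exhaustive enumeration oracle** computes exact null distributions on
instances below a configurable arrangement cap (default 10⁶; counted first by
dynamic programming over capacity histograms). Blocks of equal species and
size are exchangeable; skeletons are labelled. Both samplers are tested
against it (30 000 draws, chi-square at α = 0.01).

## Permutation tests

All p-values use the add-one convention p = (1 + #{null ⋛ observed}) /
(1 + n), so p ≥ 1/(n+1) > 0. One randomization of group membership yields the
entire affinity matrix, so all dyads within a condition share one ensemble of
5000 (default) randomized matrices, keyed by (master seed, condition label);
adding analyses never perturbs existing draws.

* **Dyadic valence.** The test statistic is the standardized affinity from
  each focal species' perspective; per tail the smaller of the two focals'
  p-values is reported ("the strongest affinity"), preference = upper tail
  below α, avoidance = lower tail. Because the two focal statistics are
  correlated but not identical, the reported min-p is anticonservative at the
  dyad level: under the null it flags ≈ 8% of dyads at α = 0.05 (measured),
  while each per-focal one-tailed test holds its 5% level (measured 4.4%,
  within the binomial 99% band). This mirrors the published reporting rule
  and is accepted as-is; per-focal p-values are available in the output.
  A raw-W statistic mode exists for sensitivity.
* **Seasonal change.** ΔS between two conditions, observed vs. the paired
  difference of independently randomized conditions; two-tailed by doubling
  the smaller tail (capped at 1); min over focals; the direction comes from
  the min-p focal's observed sign. Randomizing both conditions independently
  (rather than shuffling condition labels) is forced by the constraint set,
  which is defined per condition.
* **Centrality.** Weighted degree (sum of a species' defined W entries),
  two-tailed against the same ensembles, with the signed deviation from the
  null mean reported.

No multiple-testing correction is applied by default (matching the original
reporting convention of significance at p < 0.05); dyads unmeasurable in a
condition are skipped and listed, never silently zeroed.

## Scenario classification

Each dyad's three coded changes (low→intermediate, low→high,
intermediate→high; each up/down/ns) map to six scenarios: 1/2 monotone
increase/decrease with NDVI (rainfall promotes/reduces affinity), 3/4
departure from the low-NDVI condition only (wildebeest presence or drought),
5/6 V-shaped minimum/maximum at intermediate NDVI (both drivers). Rules fire
in priority order with the V-shaped rules first — a significant reversal
between adjacent conditions must not be absorbed by the monotone rules — and
are mutually exclusive; all 27 triplets map to exactly one of
{1..6, none, ambiguous}, and the mapping commutes with the up↔down mirror
(1↔2, 3↔4, 5↔6). Partial patterns with no intermediate-vs-high change and a
single significant departure from low (e.g. (ns, up, ns)) are resolved to
scenarios 3/4 and flagged `tiebreak_used`; this generalizes the footnoted
judgement calls evidenced in the published dyad table rather than
special-casing them. Conflicting patterns are `ambiguous` — a first-class
outcome, since the framework is a most-parsimonious-explanation scheme, not a
total function.

## Network-level statistics

* **Weighted degree** sums a species' defined W entries (absolute W, not S —
  a focal's standardized row always sums to 1, which would make the degree
  trivial). Sentinel entries are skipped and counted.
* **Mantel tests** correlate the dyadic structure of two conditions over
  unordered dyads defined in both matrices, permuting species labels of one
  matrix (rows and columns simultaneously; 9999 permutations, add-one p,
  one-tailed upper by default). The implementation is in-package because
  off-the-shelf Mantel routines require complete distance matrices, whereas
  missing dyads here must be excluded pairwise *per permutation*; it is
  tested to 1e-12 against an independent naive implementation and against
  scikit-bio's statistic on complete matrices. Standardized mode symmetrizes
  S by averaging S_A(B) and S_B(A) — the least-assumption one-value-per-dyad
  reduction — and Pearson product-moment correlation is used (a Spearman
  switch exists).
* **Unit-type profiles** give, per session and species, the fraction of
  individuals found solitary / in single-species groups / in MSGs (summing
  to 1), compared across conditions by Kruskal–Wallis with tie correction
  (fully tied samples defined as H = 0, p = 1; scipy's implementation
  otherwise).

## Synthetic census generator

The generator emulates the study system's structure: ~12 species with
strongly unequal abundance weights; 27/12/27 sessions in low/intermediate/
high NDVI conditions with the migratory species recruitable only in the low
condition; ≈ 134 units per session targeting ≈ 40 solitary, ≈ 62
single-species and ≈ 32 mixed units in expectation (richness-1 probability
0.765, with 0.39 of richness-1 units forced solitary); per-species
conspecific block sizes from zero-truncated negative binomials (means 2–35,
matching single-species groups ≈ 10 and MSGs ≈ 30 individuals); session NDVI
from a normal model truncated to the condition's bin, so generated sessions
always bin back into their intended condition.

Ground-truth attraction enters at species recruitment: a unit of richness r
recruits its first species proportionally to abundance weight, and each
further candidate C proportionally to `weight_C × gmean(θ[C, s])` over the
already-recruited set. The geometric mean keeps θ ≡ 1 exactly neutral and is
order-insensitive in expectation; the functional form is recorded with the
ground truth because it defines what "recovery" means. Block sizes are drawn
independently of partners — attraction acts on species co-presence, which is
exactly what W rewards. The default community carries a persistent attraction
backbone shared across conditions plus condition-dependent dyads (a
rainfall-following dyad, a dry-season dyad, wildebeest attraction for three
partner species) and a few avoided pairs.

What the generator does **not** emulate: spatial structure and the 100 m
grouping criterion (grouping is taken as given), individual identity and
movement, observation error, and temporal autocorrelation between sessions.
Consequently, passing recovery tests shows the statistical machinery works on
block-structured censuses with known attraction; it does not validate field
grouping protocols. Two further honest caveats: (i) the community-wide mean
of W under θ ≡ 1 is ≈ 0.45, not 1 (see the neutral-value note above), so
generator neutrality is validated through null-model self-consistency (type-I
calibration; exact-vs-sampled expectation agreement), not through W ≈ 1; and
(ii) at realistic census sizes the dyad-level sampling noise of Ŵ is large
relative to the simulated structure spread, so cross-condition Mantel
correlations on default synthetic data are weak — unlike the strong
correlations reported from the field community — and Mantel magnitudes are
not used as validation targets.

## Validation experiment designs

Fixed in `maramsg.validation` (shared by the test suite and the analysis
drivers); sizes chosen for clear power at minutes-scale runtime on one core:

* **Sampler GoF**: a six-unit, three-species census with 2511 arrangements;
  30 000 draws vs. exact enumeration, chi-square at α = 0.01 with
  small-expectation bins pooled.
* **Calibration**: 17 neutral six-species communities (6 sessions × ~12
  units), per-focal upper-tail tests of S at α = 0.05 with 999
  randomizations → 510 tests; the rejection count must fall in the central
  99% band of Binomial(510, 0.05).
* **Change recovery**: θ_AB 1 → 6 between conditions, 100 replicates of
  30 sessions × ~25 units, 499 randomizations; expected detection ("up",
  p < 0.05) in ≥ 90% (pilot power ≈ 96%).
* **Monotone recovery**: θ_AB ∈ {0.5, 1, 2, 4, 8} with common random seeds
  per replicate set, 30 sets of 60 sessions × ~30 units (MSG-rich richness
  mix 0.4/0.35/0.25); Ŵ strictly increasing in ≥ 95% of sets.
* **Preference power / dominance**: θ_AB = 8 on 16 sessions × ~18 units;
  preference detection and above-median-W dominance.

## Numerical and reproducibility choices

NaN is the single undefined sentinel throughout; W matrices are symmetrized
bitwise after the BLAS product; enumeration keys round statistics to 12
decimals; ties in permutation counts use ≥/≤ on exact float equality (draws
and observed come from the same code path). One master seed drives
everything; per-ensemble substreams derive from
`SeedSequence(seed, spawn_key=crc32(keys))` with (condition, statistic
family) keys, and the pipeline manifest records the seed, a config hash and
package versions, which suffices to reproduce a run exactly.

## Limitations

Conspecific (within-species) affinity is out of scope — the index's
self-exclusion logic does not extend to A = A without a different estimator.
The change-test null randomizes conditions independently; a session-level
condition-shuffling null would answer a different question and violate the
per-condition constraint set. Whether randomization should be confined
within sessions rather than pooled within conditions is not settled by the
constraint description; the pooled reading is the default, and a
within-session mode (`within_sessions=True`, additionally preserving
per-session species totals) is provided for sensitivity analysis. The
min-p dyad-level report inherits a mild anticonservatism from its published
definition, quantified above.
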
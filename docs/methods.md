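# Methods

This note documents the models, conventions and design choices behind
`benthochange`, in the order the pipeline runs.

## Individual matching

The field practice for corresponding individuals between two georeferenced
mosaics is visual inspection; no algorithm is published for it. The package's
matcher is an explicit, auditable stand-in: among all (T0, T1) pairs sharing
an OTU and lying within a distance tolerance, pairs are accepted greedily in
ascending Euclidean distance, ties broken lexicographically by
(t0_id, t1_id), each individual used at most once. This is deterministic,
invariant to row order, and exact whenever inter-individual spacing exceeds
twice the positional error — the regime repeat monitoring sites are designed
for. It is *not* a globally optimal assignment; in pathological clusters the
greedy choice can differ from the minimum-total-distance matching. Every
`MatchSet` carries a note flagging the automated matching.

The default tolerance is 0.5 m: typical mosaic co-registration RMSE is a few
decimeters (order 0.3–0.4 m on average for ROV surveys), and 0.5 m adds
margin without reaching ordinary inter-colony spacing. Coordinates are
planar projected meters throughout; no geodesic arithmetic is performed at
the ~10 m scale of a monitoring site.

Only baseline individuals inside the repeat survey's coverage region are
accountable, so T0 tables are clipped to the overlap polygon before
matching; with no polygon supplied the tables are assumed pre-clipped.

## Oxygen zones

Sites are summarised by the arithmetic mean of the dive's dissolved-oxygen
series (mL/L) over a configurable closed time window (default: the whole
series — the field definition ties the window to the survey video
timestamps, which the data provider controls, so it is exposed as
configuration rather than fixed). The three OMZ strata are < 0.5, 0.5–1 and
≥ 1 mL/L. The published strata use strict inequalities that leave the
boundary values unassigned; the classifier assigns boundaries upward
(0.5 → MID, 1.0 → HIGH) so the partition is total — no observed site mean
falls on a boundary, so the choice is inert on real inputs. Raw T0-vs-T1
concentration differences are never computed or reported: different
instruments across surveys make absolute comparisons unreliable, so only
zone membership is compared.

## Condition scoring

Let n_k be the number of cohort individuals with initial score k on a
metric. The weight of score s is the cumulative occurrence proportion
w(s) = (n₁ + … + n_s)/n_total with w(0) = 0; unobserved intermediate levels
inherit the carried-forward cumulative value. The severity-scaled component
is w(s) · s/S_max (S_max = 4 for growth, tissue loss, biofouling; 2 for
orientation); negative metrics are multiplied by −1; components are summed.

Two constructions are genuinely open and resolved as follows:

* **Denominator.** Defining n_total as the count of individuals with a
  change on *any* metric breaks the identity (n₁+n₂+n₃+n₄)/n_total = 1 that
  the weighting scheme asserts for the maximum observed level, whenever
  metrics differ in how many individuals they affect. The package therefore
  uses the per-metric denominator (nonzero scorers of that metric) by
  default, under which the identity holds exactly; the any-change global
  denominator is available via `denominator="global"`.
* **Range.** One positive and three negative unit-bounded components span
  [−3, +1], while the score is defined on [−1, 1]. The sum is clamped to
  [−1, 1], pre-clamp components are recorded, and a `clamped` flag is set.
  Clamping only engages when at least two negative metrics are
  simultaneously severe, which is rare in practice and was the observed
  floor (−1) in the field data the design follows.

Weights are pooled globally across the dataset by default (the weighting is
defined by score occurrence without stratification); `pooling="per_site"`
recomputes cohorts per site. Lost individuals have no T1 score and never
enter condition analyses; surviving individuals with all-zero change score 0
and are included in factor means by default, with an
`include_zero_change=False` mode for summaries over changed individuals
only (both conventions appear in published summaries, so both are emitted).
Recruits carry all-zero metrics (they have no baseline) and are excluded
from the condition cohort.

## Abundance change

Δ abundance per OTU within a factor level is 100·(A₁−A₀)/A₀ with counts
pooled over the level's member sites before the ratio — matching the
phylum-level worked convention (10 of 200 lost across sites → −5%), not an
average of per-site ratios. A₀ = 0 (recruit-only OTUs) leaves the ratio
undefined; such rows are flagged, logged, excluded from Δ summaries, and
still counted in the fate tallies.

## Statistical tests

* **Paired Wilcoxon signed-rank**, one-sided "greater" (baseline
  stochastically larger). Zero differences are dropped before ranking (the
  convention of the classical exact-test family) and the reduced n is
  reported. For n ≤ 30 the exact distribution is enumerated over *doubled
  midranks* (integers even under ties) by the shift/generating-function
  recursion, so exact p-values remain correct for tie-rich score data; above
  30, a normal approximation with tie-corrected variance and 0.5 continuity
  correction. Two-sided exact p is 2·min(P≤, P≥) capped at 1.
* **Rank-sum test** for two-level factors, exact by the size-constrained
  version of the same recursion (all C(n, n_a) assignments) when the pooled
  n ≤ 30.
* **Kruskal–Wallis** H with tie correction, p from χ²(k−1) (delegated to
  scipy); a fully degenerate pooled sample reports H = 0, p = 1.
* **Dunn's post hoc** z = (mean-rank difference)/SE with the
  Σ(t³−t)/(12(N−1)) tie term, run when Kruskal–Wallis is significant at α;
  pairwise p-values adjusted by Holm by default (conservative step-down;
  Bonferroni available) — the published analyses state only "adjusted
  significance levels", so the default is the package's choice.
* **Families.** The two headline paired tests (abundance, condition) form a
  Bonferroni family of m = 2. The default pairing unit is the OTU with
  counts pooled across sites (one pair per OTU; condition pairs the OTU's
  mean T1 score against the zero baseline); `test_pairing="per_site_otu"`
  pairs site×OTU units instead. α = 0.05 throughout.

## Synthetic surveys

The generator emulates the data-generating process the analysis assumes:
uniform placement in a rectangular site polygon (optionally with a minimum
spacing, for guaranteed matchability), independent Bernoulli survival with
per-phylum probability, Poisson recruitment per OTU, per-metric independent
ordinal score draws, isotropic Gaussian positional jitter at T1 (emulating
co-registration error), and an area-fraction coverage window applied to the
repeat survey (emission of a survivor is decided by its baseline position,
so clipping T0 to the window restores the fate-conservation identities
exactly). Oxygen series are constant at the configured means plus small
Gaussian sensor noise (default sd 0.02 mL/L). All randomness flows from one
`SeedSequence`; per-site substreams make sites independent and the whole
study reproducible bit-for-bit from (config, seed).

It does **not** model: spatial clustering or habitat gradients within sites,
correlation between condition metrics or between condition and survival,
detection error, size/growth dynamics, or any causal O₂–survival link.
Passing tests on simulated data therefore demonstrate the *pipeline's*
correctness under the assumed structure, not ecological realism of any
particular trend.

`seamount_study_config()` packages 12 sites using the published site table
(depths, survey years, O₂ means — 10 LOW / 1 MID / 1 HIGH at baseline) with
baseline abundances allocated to match the published totals: 527 sponges
and 317 corals (844 total), 190 individuals at the hardest-hit site (172
sponges, 100 of them the dominant sponge OTU) and 73 at the second
low-oxygen decline site. Survival probabilities are constant per phylum
(1 − 143/527 for sponges, 1 − 32/317 for corals) — the simplest allocation
consistent with the study-wide expected losses — and Poisson recruitment
means of 1, 1, 4 and 6 are placed at the four sites where recruitment was
observed (12 expected recruits). Where the published record does not
constrain a parameter it is fixed at a field-plausible value and kept:
15 m × 15 m site extent (published reconstruction footprints are ~120–370
m²), 0.05 m jitter, full repeat coverage, two OTUs per phylum per site with
a 60/40 split, and per-metric score distributions under which roughly
10–15% of survivors show some negative change and ~10% show growth, sponges
slightly worse than corals.

## Problem sizes and numerics

The test suite and the acceptance script run the exact-test-versus-oracle
comparison on 200 random tie-rich instances at n ≤ 10 (where brute force is
exhaustive), the test-size simulation at 10,000 replicates of n = 26, and
the simulator-recovery check over 200 simulated studies of 844 individuals —
sizes at which binomial/Monte-Carlo standard errors are small enough for
3·SE acceptance bands while the whole suite runs in well under a minute for
the unit layer and a few minutes end to end. Exact-test enumeration uses
float counts (exact for n ≤ 30 since 2³⁰ ≪ 2⁵³). Oracle comparisons use an
absolute tolerance of 1e−12; rank comparisons in the brute-force oracles
guard float midranks with a 1e−9 fuzz.

## Known limitations

* The greedy matcher is a documented stand-in for manual tracking; dense
  aggregations with positional error near the tolerance will mis-assign
  some fates (the packaged dense simulated sites show realized study-wide
  matcher loss counts within a few individuals of truth).
* Published per-test p-values from the original field analyses depend on
  unpublished per-OTU tables and are not reproducible from aggregates;
  the package validates its tests against enumeration oracles instead.
* No morphometric condition measures (branch counts, areas, volumes): the
  data model is built for qualitative ordinal scores from 2D mosaics.
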
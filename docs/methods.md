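# Methods

## Scoring model

Each substance (ATC 5th level) carries an integer risk value r(s, c) ∈
{0, 1, 2, 3} for each of nine pharmacological ADE categories
(anticholinergic effects, bleeding, constipation, orthostatism, QT
prolongation, renal toxicity, sedation, seizures, serotonergic effects,
numbered 1–9 in that order).  A patient's category sum is the plain sum of
r(s, c) over their *unique* concurrent substances — a substance dispensed
several times counts once, and substances absent from the knowledge base
contribute 0 (a regional formulary always exceeds the risk-annotated set,
so unknown codes are not an error).  The sum is thresholded into an ordinal
level 0/I/II/III.

The proprietary source rule base does not publish its aggregation formula.
We use a linear sum with thresholds (t_I, t_II, t_III) = (1, 2, 3), the
simplest mapping consistent with the two documented behaviours: a single
value-3 substance reaches level III on its own, and co-treatment with at
least three value-1 drugs is needed for level III (the renal-toxicity
rule).  The thresholds are configurable (`LevelThresholds`) so a different
published rule can be swapped in; a genuinely sub-linear (damped)
aggregation cannot be ruled out, which is a known limitation.  No dose,
duration or patient-factor adjustment is applied — the rule base scores
substances only.

The bundled reference knowledge base (`reference_fixture`) contains the 64
substances with published per-category values (90 nonzero triples).
Unpublished (substance, category) pairs default to 0 even where the real
rule base likely assigns nonzero values; fixture-based prevalences are
therefore lower bounds with respect to the full proprietary base.  The one
combination product (losartan/hydrochlorothiazide, components 2/1 for
orthostatism) is stored as a single record scoring the maximum component
value, with the component values retained as metadata — no published
combination rule exists, and the maximum is the conservative choice.

## Exposure window and exclusions

Concurrent medication is approximated by every unique substance received in
a 120-day window ending at the cutoff day, closed on both ends:
[cutoff − 119, cutoff].  Dispensations commonly cover about three months of
use, so a 120-day look-back captures current medication with slack for
late refills.  (A published study period of 8 July–5 November 2020 spans
121 days inclusive; we implement the stated 120-day literal and note the
one-day discrepancy here.)

Exclusion filters run in a fixed order so that the removal counts in the
`ExclusionReport` are reproducible: (0) events flagged as coming from
private providers; (1) events outside the window — an EHR `order` row
survives if its active interval [order_start, order_end-or-open] intersects
the window, since measure B below needs orders whose start precedes the
window; (2) veterinary events (ATC starting with "Q" or a veterinarian
prescriber); (3) non-resident patients with all their events; (4) patients
dead on or before the window end; (5) patients left with no events.  The
chain is idempotent.

Three measures of concurrent medication are supported: `combined`
(dispensed + administered events in the window; the primary measure),
`dispensed_only` (measure A, the usual pharmacoepidemiology proxy), and
`orders_on_day` (measure B: EHR medication orders active on the cutoff
day).  `prescribed` events keep a patient in the cohort but contribute to
no measure's exposure list.  Because dispensed events are a subset of
combined events, per-category prevalence under measure A can never exceed
the combined measure — the pipeline asserts this monotonicity.  Topical
drug forms (default: cream, ointment, gel, eye drops; configurable) are
dropped before deduplication, because topically applied substances are not
scored for systemic risk; a substance also taken systemically stays in.

## Statistics

Gender differences per category are tested with the two-sided Mann–Whitney
U on midranks; the variance carries the tie correction
σ² = (n₁n₂/12)[(N+1) − Σ(t³−t)/(N(N−1))], and the p-value comes from the
normal approximation without continuity correction (a config flag enables
it).  Age-group differences use Kruskal–Wallis H with the tie correction
1 − Σ(t³−t)/(N³−N) and a chi-square reference with g−1 df.  With cohort
sizes in the thousands and only four distinct ordinal values, the
asymptotic approximations are standard practice; both tests also expose an
`method="exact"` permutation-enumeration path used by the test suite as an
oracle at small N.  When every observation is identical the variance
vanishes; the result is flagged degenerate with p = 1.  No multiple-testing
adjustment is applied across the nine categories; p-values are reported
per category as-is.

The SRV ranking restricts to patients at level III for the category, scores
each substance r(s, c) × n_patients, excludes substances with r = 0, and
breaks ties by n_patients descending then ATC code — a reproducible total
order.

Age is computed in completed years at the cutoff day and grouped as <65,
65–74, ≥75.

## Clustering

k-modes with matching (Hamming) dissimilarity on the 9-vector of levels.
Initialization samples k distinct observed vectors uniformly (simpler than
frequency-weighted initialization, and with `n_init = 10` restarts the
choice is not critical); assignment and per-position mode update alternate
until the cost stops decreasing (cost is asserted non-increasing every
iteration), with emptied clusters re-seeded by the point farthest from its
mode.  Mode ties resolve to the lowest category value and assignment ties
to the lowest cluster index, making the fit deterministic given a seed.
The number of clusters is the interior k maximizing the discrete curvature
cost[k−1] − 2·cost[k] + cost[k+1] of the cost curve (ties toward smaller
k; a non-monotone curve logs a warning but the rule still applies).
Cluster descriptives report n, % female, % per age group, and median, IQR
(Q3 − Q1, linear-interpolation quartiles) and mean of both the number of
unique medications and the profile sum.

## Synthetic data

The generator emulates the statistical structure of a regional extract at
desk scale.  Defaults are fixed study conditions: 5,000 patients, cutoff
2020-11-05 with a 120-day window; 52% female; age mix 62% / 18% / 20%
across <65 / 65–74 / ≥75; distinct substances per patient drawn from a
negative binomial truncated at ≥1 with means 3 / 6 / 8 by age group and
dispersion 2 (an over-dispersed count model, the standard choice for
polypharmacy counts); substance popularity Zipf(1) over a randomly permuted
formulary of the 64 annotated substances plus 200 risk-free ATC-shaped
filler codes (first letter "X", colliding with nothing and never tripping
the veterinary filter); 1–2 dispensed events per substance at uniform dates
in the window, an administered event with probability 0.15, every
dispensed/administered event mirrored as a 90-day EHR order; contamination
rates of 1% veterinary events, 2% deceased, 2% non-resident, 5% topical
forms.  One global seed drives three split `SeedSequence` streams
(population / formulary / events), and outputs are byte-identical across
runs.

What it does *not* emulate: real prevalence levels (the fixture covers only
published risk values, so synthetic prevalences are not comparable to any
real region — calibrating them would be circular), seasonality, adherence,
OTC drugs, dosage, and correlation structure between substances beyond
popularity (no comorbidity-driven co-prescription).  Passing recovery tests
therefore demonstrates correctness of the deterministic machinery —
filtering, scoring, tabulation, ranking, clustering — not realism of any
particular prevalence figure.

Exported ground truth contains the post-filter exposure sets, the profile
table, and exact finite-population prevalences computed by direct counting;
the principal recovery property is that an end-to-end pipeline run over the
CSV round-trip reproduces them exactly (to float round-off in the
proportions).

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at 5,000
patients, exhaustive oracles at n ≤ 10 (rank-test permutation enumeration,
2⁸-assignment k-modes optimum), and the null-calibration experiment at
2,000 replicates of two samples of 200 — sizes at which every oracle is
exact and a full run takes seconds.  Proportions are exact rational counts
divided by n; comparisons in tests use absolute tolerances of 1e-12 where
float division is involved.  Degenerate inputs (empty cohort, empty
knowledge base, all-identical rank samples, k exceeding the number of
distinct vectors) raise or flag explicitly rather than returning NaN.
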
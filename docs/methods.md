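# Methods

## Model and assumptions

`pharmarisk` operationalizes a pre-purchase risk assessment for medicines
offered on the internet. The underlying assumption is that patient harm from
an online purchase has two independent components that can be estimated from
desk research alone:

1. **Severity** — how much harm the product could do if bought and used
   without professional supervision. This is read off the product itself
   (SmPC/PIL attributes, registry status), not off any vendor.
2. **Probability** — how likely a consumer is to actually complete a
   purchase, proxied by online supply (relevant vendor links among the first
   50 search results) and demand-side affordability (price relative to fixed
   thresholds).

Their 3×3 categorical combination prioritizes products for test purchase.
Everything downstream of the purchase — physical inspection, chemical and
microbiological analysis, falsified/substandard classification — is out of
scope by design: those risks cannot be assessed before owning the product.

### Severity rubric

The additive score sums four dimensions (maxima 4 + 5 + 3 + 2 = 14):

- **General pharmaceutical risk.** Dosage form (1 point for parenteral,
  topical or modified-release; 0 for conventional oral — forms that are
  forgiving of unsupervised use) plus application complexity banded by the
  SmPC/PIL instruction count: <5 → 1, 5–10 → 2, >10 → 3. The band floor is 1,
  so any scoreable product totals at least 1.
- **Therapeutic risk.** Five yes/no questions: systemic mode of action,
  documented systemic ADRs, indication on damaged/inflamed tissue, narrow
  therapeutic index, pediatric indication under 6 years. The systemic-ADR
  question is also satisfied by strong local-ADR evidence — at least one
  very common, common, or severe local reaction (CIOMS frequency bands) —
  because such a profile implies meaningful absorption; this evidence path
  can be disabled in the rubric (`local_adr_evidence: false`).
- **Microbiological contamination.** Three equally weighted mitigations,
  each worth 1 risk point when absent: single-dose presentation *or* an
  antimicrobial filter (one combined rule), preservative content, and an
  antibiotic active ingredient.
- **Augmented demand.** Shortage in the evaluation period and documented
  misuse/abuse potential. Prescription-only status is carried as metadata
  but deliberately unscored: shortage alone drives the access sub-score, so
  this dimension cannot dominate the rubric.

A product that is unregistered, investigational, or withdrawn is treated as
potentially counterfeit and overrides the additive path with the theoretical
maximum of 15 points — counterfeiting risk dominates any attribute-level
assessment.

The weighted score divides the total by 10 (not by the 15-point maximum;
the divisor is a config field) and is clamped to 1.0 so that the override
case stays inside the banding domain. Bands: low [0, 0.25], medium
(0.25, 0.75), high [0.75, 1]. The closed/open choices at the boundaries are
fixed so that 0.25 is low, 0.5 is medium, and 0.75 is high, which keeps the
categorical outputs consistent across the severity and probability scales.

### Market probability

Availability: relevant links *n* among the first `top_n` = 50 results;
`availability_point` = *n* / `reference_max` (default 20, the study-specific
maximum) is reported for context but never enters the product — the
categorical value does (≥15 → 1, 5–14 → 0.5, <5 → 0.25). Affordability uses
the mean total price (including shipping) over relevant entries within
`top_n`; the aggregation to a single representative price is a package
choice — the method only requires *a* representative price, and callers can
override it. Thresholds default to $25/$50 (anchored to 5% and 10% of the
2018 Hungarian minimum wage) and are configurable; a price exactly on a
threshold falls in the middle band ("between $25 and $50" read inclusively).
The affordability *point* scale is {1, 0.5, 0} but the *category* scale is
{1, 0.5, 0.25}; the probability multiplies the categories, which keeps the
product strictly positive and inside {1, 0.5, 0.25, 0.125, 0.0625}.

Ledgers must be single-currency (USD by default); mixed currencies are an
error rather than silently converted.

### Ranking and selection

The published method selects informally ("highest score in both
categories"); the package imposes a deterministic total order:
(weighted severity desc, probability desc, relevant links desc, brand name
asc). The default `max-both` policy returns the products whose severity and
probability categories are both maximal *within the assessed set* — on the
packaged fixtures that is exactly the timolol & dorzolamide combination.
`top-k` and `cell-threshold` policies are provided as conveniences, as is
`priority_score` (weighted × probability), a scalar that is *not* part of
the published method.

## Packaged fixtures

The ten reference eye drops ship with per-field provenance tags. Answers
stated directly in the study narrative ("printed": the microbiological
answers, the four products with systemic-ADR documentation, the
damaged-eye indication, the two shortages, the absence of misuse evidence,
registration status, the >10-instruction count of the top product, all
relevant-link counts and price bands) are encoded verbatim. The remaining
answers ("reconstructed": most instruction counts; the mode-of-action, NTI
and pediatric flags) are one admissible assignment chosen to satisfy every
printed constraint — top totals 10 and 9, general dimension spanning exactly
[2, 4] with the 3-point complexity only on the top product, every weighted
score ≥ 0.50 — and are labeled as such in `provenance.json`, including the
choice to put the top product's third therapeutic point on the pediatric
sub-dimension rather than NTI, and the single-dose vs multi-dose conflict
for COSOPT UNO (the fixture follows the scored multi-dose statement).
Ledger URLs are placeholders; link counts and price bands are the
documented values, with relevant links placed on alternating early ranks
and band prices chosen so any prefix mean stays inside the band.

## Synthetic generator

`SyntheticSpec` defaults emulate the study conditions: topical products,
50-result ledgers, a relevance rate of 0.18 (the packaged products average
8.7 relevant links per 50 results), log-uniform prices on $10–$80 (spanning
all three affordability bands), instruction counts 0–15, and independent
Bernoulli(0.5) risk flags. Output is a pure function of the spec and seed
(numpy `default_rng`). Exhaustive mode enumerates all 3 × 2¹⁰ = 3072
(complexity band × binary flag) combinations exactly once, using one
representative instruction count per band (2, 7, 12), which is what the
brute-force oracle tests iterate.

What the generator does **not** emulate: correlation between flags (real
products cluster — e.g. glaucoma combinations tend to have systemic action
*and* documented ADRs), price–availability dependence, rank-dependent
relevance (real vendor links concentrate in early ranks), non-USD markets,
and any free-text SmPC parsing. Passing property tests therefore establish
the arithmetic and orderings of the method, not the field accuracy of any
particular rubric answer.

## Numerical and degenerate-input choices

- Category values are the exact binary fractions 1, 0.5, 0.25 (and products
  0.125, 0.0625), so equality comparisons and serialized decimals are exact;
  only `availability_point` and prices are general floats.
- `availability_point` is not clamped at 1: a product with more links than
  `reference_max` reports a proportion > 1, flagging a stale reference.
- Empty ledgers parse fine (0 relevant links → availability 0.25); an
  affordability score with no priced relevant entry and no override is an
  error, never a silent default.
- Missing profile answers: strict mode (default) aggregates *all* gaps into
  one error; explicit `impute low|high` modes fill them with the 0-risk or
  maximum-risk answer and record the imputed fields on the scorecard.
- Negative counts and prices are domain errors; rubric documents with
  gapped, overlapping, or non-exhaustive count bands are rejected at load.
- Ranking tie-break ends on brand name, making output order independent of
  input order.

## Problem sizes

Tests run the 3072-profile exhaustive enumeration (with its ~30k single-flip
monotonicity comparisons), hypothesis property checks, and the ten-product
pipeline end to end; the suite completes in a few seconds. The acceptance
script scores the ten packaged products and one synthetic profile.

## Known limitations

- The rubric quantifies with equal-weight integer points; it is a screening
  instrument, not a calibrated harm model, and the 10-point divisor means a
  14-point additive profile and an overridden counterfeit product band
  identically (both weighted 1.0).
- Relevance of a search result is an input judgment, as in manual review;
  the package neither queries search engines nor classifies URLs.
- The default rubric is tailored to ophthalmic preparations. Other dosage
  forms need a tailored rubric document; the shipped schema validates its
  structure but cannot validate its clinical content.
- Reconstructed fixture answers are constraint-satisfying stand-ins, not
  recovered source data; conclusions about individual sub-scores of the
  packaged products (beyond the printed constraints) should not be drawn
  from them.
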
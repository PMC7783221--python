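# pharmarisk

Risk assessment for medicines sold on the internet: which products should a
surveillance study or regulator actually test-purchase?

Illicit online pharmacies vastly outnumber legitimate ones, but buying and
analysing every medicine offered online is impossible. `pharmarisk`
implements a rapid, rubric-based method for ranking medicinal products by
patient-safety risk and by how likely they are to be bought online, so that
scarce test-purchase budgets go to the highest-risk products. It is aimed at
pharmacovigilance researchers, medicines regulators, and online-market
surveillance programmes.

## The method

**Severity.** Each product is scored on a configurable rubric of five
dimensions built from the product's SmPC/PIL and registry status:

| dimension | group | max |
| --- | --- | --- |
| 1. General pharmaceutical risk (dosage form; application complexity) | intrinsic | 4 |
| 2. Therapeutic risk (systemic action; systemic ADRs; damaged-eye use; NTI; pediatric) | intrinsic | 5 |
| 3. Microbiological contamination (multi-dose/filter; preservative; antibiotic API) | intrinsic | 3 |
| 4. Augmented demand (shortage; misuse potential) | extrinsic | 2 |
| 5. Counterfeiting (unregistered / investigational / withdrawn) | override | 15 |

Yes/no answers score 0/1; application complexity scores 1–3 by instruction
count (<5, 5–10, >10). The additive total *S* ∈ [1, 14]; a potentially
counterfeit product overrides everything with *S* = 15. The weighted score
*w* = min(*S*/10, 1) is banded: low (*w* ≤ 0.25), medium, high (*w* ≥ 0.75).
The default rubric is tailored to ophthalmic preparations; other dosage forms
are handled by loading a different rubric document (JSON/YAML, schema
shipped).

**Probability.** From a recorded ledger of the first 50 search-engine results
for "buy *INN*": the number of relevant links *n* (sites selling directly to
patients) gives an availability category *A* (≥15 links → 1; 5–14 → 0.5;
<5 → 0.25), and the mean total price of the relevant offers gives an
affordability category *F* (<$25 → 1; $25–50 → 0.5; >$50 → 0.25). The
probability of online purchase is *P* = *A* × *F* ∈
{1, 0.5, 0.25, 0.125, 0.0625}, banded the same way.

**Selection.** Products are placed in the 3×3 severity × probability matrix
and ranked by (*w*, *P*, *n*, name); the default policy selects products
maximal in both categories as test-purchase candidates.

The package ships ten reference eye drops (glaucoma, allergy, infection,
mydriatic) with profiles, 50-result search ledgers, and per-field provenance
notes, plus a seeded synthetic generator for profiles and ledgers.

## Worked example

```sh
pharmarisk fixtures --export data
pharmarisk score  --profiles data/profiles.json --out out
pharmarisk market --ledgers data/ledgers.csv   --out out
pharmarisk assess --scores out/safety_scores.json \
                  --market out/market_scores.json --out out
```

`out/assessments.md` then contains:

```
| rank | product | total | weighted | severity | probability | category | candidate |
| --- | --- | --- | --- | --- | --- | --- | --- |
| 1 | Timolol & dorzolamide | 10 | 1 | high | 1 | high | yes |
| 2 | Cyclopentolate | 9 | 0.9 | high | 0.0625 | low | no |
| 3 | Betaxolol | 7 | 0.7 | medium | 0.25 | low | no |
...
```

The timolol & dorzolamide combination scores 10/15 on the safety rubric
(complex application, systemic beta-blocker effects, documented systemic
ADRs, preserved multi-dose bottle, and a supply shortage) and has both the
most vendors (20 relevant links) and a low price, so its purchase probability
is 1 — it is the only product that is maximal in both matrix dimensions and
is therefore the test-purchase candidate. Cyclopentolate is nearly as
dangerous (9/15) but barely sold online (4 links, >$50), so its probability
is 0.0625 and it is not selected.

The same pipeline is available as a library:

```python
import pharmarisk as pr

fixtures = pr.load_fixtures()
cards = [pr.score_product(p, pr.default_rubric()) for p in fixtures.profiles]
markets = [pr.market_score(ledger) for ledger in fixtures.ledgers]
ranked = pr.rank_products(cards, markets)
pr.select_candidates(ranked)  # -> [Timolol & dorzolamide]
```

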
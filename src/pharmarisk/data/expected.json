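{
 "general_dimension_range": [
  2,
  4
 ],
 "min_weighted": 0.5,
 "safety_totals": {
  "cyclopentolate": 9,
  "timolol_dorzolamide": 10
 },
 "table3": {
  "betaxolol": {
   "affordability_category": 0.25,
   "affordability_point": 0,
   "availability_category": 1,
   "availability_point": 0.75,
   "inn_name": "Betaxolol",
   "price_band": ">50",
   "probability": 0.25,
   "probability_category": "low",
   "relevant_links": 15
  },
  "brinzolamide": {
   "affordability_category": 0.5,
   "affordability_point": 0.5,
   "availability_category": 1,
   "availability_point": 0.75,
   "inn_name": "Brinzolamide",
   "price_band": "25-50",
   "probability": 0.5,
   "probability_category": "medium",
   "relevant_links": 15
  },
  "ciprofloxacin": {
   "affordability_category": 1,
   "affordability_point": 1,
   "availability_category": 0.25,
   "availability_point": 0.2,
   "inn_name": "Ciprofloxacin",
   "price_band": "<25",
   "probability": 0.25,
   "probability_category": "low",
   "relevant_links": 4
  },
  "cyclopentolate": {
   "affordability_category": 0.25,
   "affordability_point": 0,
   "availability_category": 0.25,
   "availability_point": 0.2,
   "inn_name": "Cyclopentolate",
   "price_band": ">50",
   "probability": 0.0625,
   "probability_category": "low",
   "relevant_links": 4
  },
  "sodium_cromoglicate": {
   "affordability_category": 1,
   "affordability_point": 1,
   "availability_category": 0.5,
   "availability_point": 0.55,
   "inn_name": "Sodium cromoglicate",
   "price_band": "<25",
   "probability": 0.5,
   "probability_category": "medium",
   "relevant_links": 11
  },
  "tetryzoline": {
   "affordability_category": 0.5,
   "affordability_point": 0.5,
   "availability_category": 0.25,
   "availability_point": 0.2,
   "inn_name": "Tetryzoline",
   "price_band": "25-50",
   "probability": 0.125,
   "probability_category": "low",
   "relevant_links": 4
  },
  "tetryzoline_antazoline": {
   "affordability_category": 0.5,
   "affordability_point": 0.5,
   "availability_category": 0.25,
   "availability_point": 0.2,
   "inn_name": "Tetryzoline & antazoline",
   "price_band": "25-50",
   "probability": 0.125,
   "probability_category": "low",
   "relevant_links": 4
  },
  "timolol_dorzolamide": {
   "affordability_category": 1,
   "affordability_point": 1,
   "availability_category": 1,
   "availability_point": 1.0,
   "inn_name": "Timolol & dorzolamide",
   "price_band": "<25",
   "probability": 1,
   "probability_category": "high",
   "relevant_links": 20
  },
  "timolol_latanoprost": {
   "affordability_category": 1,
   "affordability_point": 1,
   "availability_category": 0.25,
   "availability_point": 0.15,
   "inn_name": "Timolol & latanoprost",
   "price_band": "<25",
   "probability": 0.25,
   "probability_category": "low",
   "relevant_links": 3
  },
  "travoprost": {
   "affordability_category": 0.5,
   "affordability_point": 0.5,
   "availability_category": 0.5,
   "availability_point": 0.35,
   "inn_name": "Travoprost",
   "price_band": "25-50",
   "probability": 0.25,
   "probability_category": "low",
   "relevant_links": 7
  }
 },
 "test_purchase_candidate": "timolol_dorzolamide"
}
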
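[
 {
  "product_id": "betaxolol",
  "brand_name": "BETOPTIC 5 mg/ml",
  "inn_name": "Betaxolol",
  "atc_code": "S01ED02",
  "dosage_form_class": "parenteral_or_topical",
  "application_instruction_count": 7,
  "mode_of_action_systemic": true,
  "systemic_adr_documented": true,
  "local_adrs": [],
  "indication_damaged_or_inflamed": false,
  "narrow_therapeutic_index": false,
  "pediatric_indication_under6": false,
  "multi_dose": true,
  "antimicrobial_filter": false,
  "contains_preservative": true,
  "api_is_antibiotic": false,
  "in_shortage": false,
  "misuse_potential": false,
  "registration_status": "registered",
  "rx_only": true
 },
 {
  "product_id": "brinzolamide",
  "brand_name": "AZOPT 10 mg/ml",
  "inn_name": "Brinzolamide",
  "atc_code": "S01EC04",
  "dosage_form_class": "parenteral_or_topical",
  "application_instruction_count": 7,
  "mode_of_action_systemic": true,
  "systemic_adr_documented": false,
  "local_adrs": [],
  "indication_damaged_or_inflamed": false,
  "narrow_therapeutic_index": false,
  "pediatric_indication_under6": false,
  "multi_dose": true,
  "antimicrobial_filter": false,
  "contains_preservative": true,
  "api_is_antibiotic": false,
  "in_shortage": false,
  "misuse_potential": false,
  "registration_status": "registered",
  "rx_only": true
 },
 {
  "product_id": "ciprofloxacin",
  "brand_name": "CILOXAN 3 mg/ml",
  "inn_name": "Ciprofloxacin",
  "atc_code": "S03AA07",
  "dosage_form_class": "parenteral_or_topical",
  "application_instruction_count": 6,
  "mode_of_action_systemic": false,
  "systemic_adr_documented": true,
  "local_adrs": [
   {
    "term": "corneal deposits",
    "frequency": "common",
    "severity": "moderate"
   }
  ],
  "indication_damaged_or_inflamed": true,
  "narrow_therapeutic_index": false,
  "pediatric_indication_under6": false,
  "multi_dose": true,
  "antimicrobial_filter": false,
  "contains_preservative": true,
  "api_is_antibiotic": true,
  "in_shortage": false,
  "misuse_potential": false,
  "registration_status": "registered",
  "rx_only": true
 },
 {
  "product_id": "sodium_cromoglicate",
  "brand_name": "ALLEOPTI 20 mg/ml",
  "inn_name": "Sodium cromoglicate",
  "atc_code": "S01GX01",
  "dosage_form_class": "parenteral_or_topical",
  "application_instruction_count": 5,
  "mode_of_action_systemic": false,
  "systemic_adr_documented": false,
  "local_adrs": [],
  "indication_damaged_or_inflamed": false,
  "narrow_therapeutic_index": false,
  "pediatric_indication_under6": false,
  "multi_dose": true,
  "antimicrobial_filter": false,
  "contains_preservative": true,
  "api_is_antibiotic": false,
  "in_shortage": false,
  "misuse_potential": false,
  "registration_status": "registered",
  "rx_only": false
 },
 {
  "product_id": "cyclopentolate",
  "brand_name": "HUMAPENT 5 mg/ml",
  "inn_name": "Cyclopentolate",
  "atc_code": "S01FA04",
  "dosage_form_class": "parenteral_or_topical",
  "application_instruction_count": 7,
  "mode_of_action_systemic": true,
  "systemic_adr_documented": false,
  "local_adrs": [],
  "indication_damaged_or_inflamed": false,
  "narrow_therapeutic_index": true,
  "pediatric_indication_under6": true,
  "multi_dose": true,
  "antimicrobial_filter": false,
  "contains_preservative": true,
  "api_is_antibiotic": false,
  "in_shortage": true,
  "misuse_potential": false,
  "registration_status": "registered",
  "rx_only": true
 },
 {
  "product_id": "tetryzoline_antazoline",
  "brand_name": "SPERSALLERG 0.5 mg/ml + 0.4 mg/ml",
  "inn_name": "Tetryzoline & antazoline",
  "atc_code": "S01GA52",
  "dosage_form_class": "parenteral_or_topical",
  "application_instruction_count": 4,
  "mode_of_action_systemic": true,
  "systemic_adr_documented": false,
  "local_adrs": [],
  "indication_damaged_or_inflamed": false,
  "narrow_therapeutic_index": false,
  "pediatric_indication_under6": false,
  "multi_dose": true,
  "antimicrobial_filter": false,
  "contains_preservative": true,
  "api_is_antibiotic": false,
  "in_shortage": false,
  "misuse_potential": false,
  "registration_status": "registered",
  "rx_only": false
 },
 {
  "product_id": "tetryzoline",
  "brand_name": "VISINE CLASSIC 0.5 mg/ml",
  "inn_name": "Tetryzoline",
  "atc_code": "S01GA02",
  "dosage_form_class": "parenteral_or_topical",
  "application_instruction_count": 4,
  "mode_of_action_systemic": true,
  "systemic_adr_documented": false,
  "local_adrs": [],
  "indication_damaged_or_inflamed": false,
  "narrow_therapeutic_index": false,
  "pediatric_indication_under6": false,
  "multi_dose": true,
  "antimicrobial_filter": false,
  "contains_preservative": true,
  "api_is_antibiotic": false,
  "in_shortage": false,
  "misuse_potential": false,
  "registration_status": "registered",
  "rx_only": false
 },
 {
  "product_id": "timolol_dorzolamide",
  "brand_name": "COSOPT UNO 20 mg/ml + 5 mg/ml",
  "inn_name": "Timolol & dorzolamide",
  "atc_code": "S01ED51",
  "dosage_form_class": "parenteral_or_topical",
  "application_instruction_count": 12,
  "mode_of_action_systemic": true,
  "systemic_adr_documented": true,
  "local_adrs": [
   {
    "term": "ocular burning and stinging",
    "frequency": "very_common",
    "severity": "minor"
   }
  ],
  "indication_damaged_or_inflamed": false,
  "narrow_therapeutic_index": false,
  "pediatric_indication_under6": true,
  "multi_dose": true,
  "antimicrobial_filter": false,
  "contains_preservative": true,
  "api_is_antibiotic": false,
  "in_shortage": true,
  "misuse_potential": false,
  "registration_status": "registered",
  "rx_only": true
 },
 {
  "product_id": "timolol_latanoprost",
  "brand_name": "XALACOM 0.05 mg/ml + 5 mg/ml",
  "inn_name": "Timolol & latanoprost",
  "atc_code": "S01ED51",
  "dosage_form_class": "parenteral_or_topical",
  "application_instruction_count": 7,
  "mode_of_action_systemic": true,
  "systemic_adr_documented": true,
  "local_adrs": [],
  "indication_damaged_or_inflamed": false,
  "narrow_therapeutic_index": false,
  "pediatric_indication_under6": false,
  "multi_dose": true,
  "antimicrobial_filter": false,
  "contains_preservative": true,
  "api_is_antibiotic": false,
  "in_shortage": false,
  "misuse_potential": false,
  "registration_status": "registered",
  "rx_only": true
 },
 {
  "product_id": "travoprost",
  "brand_name": "TRAVATAN 40 ug/ml",
  "inn_name": "Travoprost",
  "atc_code": "S01EE04",
  "dosage_form_class": "parenteral_or_topical",
  "application_instruction_count": 7,
  "mode_of_action_systemic": true,
  "systemic_adr_documented": false,
  "local_adrs": [],
  "indication_damaged_or_inflamed": false,
  "narrow_therapeutic_index": false,
  "pediatric_indication_under6": false,
  "multi_dose": true,
  "antimicrobial_filter": false,
  "contains_preservative": true,
  "api_is_antibiotic": false,
  "in_shortage": false,
  "misuse_potential": false,
  "registration_status": "registered",
  "rx_only": true
 }
]
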
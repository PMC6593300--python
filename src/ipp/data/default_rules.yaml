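# Default macro-category rule table.
#
# One rule per macro-category, in descending order of severity.  Within a
# rule, every non-empty channel is an independent OR: a single in-window
# event matching any channel places the subject in the category.
#
#   exemption_codes      co-pay fee exemption codes on the registry record
#   icd9_ranges          "LOW-HIGH" 3-digit ranges or literal prefixes,
#                        matched against dotless ICD-9-CM discharge codes
#   atc_prefixes         ATC prefixes matched against drug prescriptions
#   outpatient_branches  outpatient specialty branch labels
#   register_flags       pathology registers (heart_failure, diabetes)
#
# The channel structure is fixed by the classification method; the code
# lists below are an editable default, not a clinical standard.
rules:
  - category: severe_disability
    exemption_codes: ["C01", "C05"]
    icd9_ranges: ["342-344"]
    atc_prefixes: []
    outpatient_branches: []
    register_flags: []
  - category: psychiatric_disorders
    exemption_codes: ["044"]
    icd9_ranges: ["290-299", "311-319"]
    atc_prefixes: ["N05A"]
    outpatient_branches: ["psychiatry"]
    register_flags: []
  - category: drug_addictions
    exemption_codes: []
    icd9_ranges: ["303-305"]
    atc_prefixes: ["N07B"]
    outpatient_branches: ["addiction_services"]
    register_flags: []
  - category: transplants
    exemption_codes: ["052"]
    icd9_ranges: ["V42"]
    atc_prefixes: []
    outpatient_branches: []
    register_flags: []
  - category: chronic_renal_insufficiency
    exemption_codes: ["023"]
    icd9_ranges: ["585-586"]
    atc_prefixes: ["B03XA"]
    outpatient_branches: ["dialysis"]
    register_flags: []
  - category: hiv_aids
    exemption_codes: ["020"]
    icd9_ranges: ["042-044"]
    atc_prefixes: ["J05AR"]
    outpatient_branches: []
    register_flags: []
  - category: neoplasm
    exemption_codes: ["048"]
    icd9_ranges: ["140-208"]
    atc_prefixes: ["L01", "L02"]
    outpatient_branches: ["oncology"]
    register_flags: []
  - category: diabetes
    exemption_codes: ["013"]
    icd9_ranges: ["250-250"]
    atc_prefixes: ["A10"]
    outpatient_branches: ["diabetology"]
    register_flags: ["diabetes"]
  - category: cardiovascular
    exemption_codes: ["002", "021"]
    icd9_ranges: ["410-414", "420-429"]
    atc_prefixes: ["C01", "C07", "C09"]
    outpatient_branches: ["cardiology"]
    register_flags: ["heart_failure"]
  - category: copd
    exemption_codes: ["057"]
    icd9_ranges: ["490-496"]
    atc_prefixes: ["R03"]
    outpatient_branches: ["pneumology"]
    register_flags: []
  - category: gastro_enteropathy
    exemption_codes: ["009", "016"]
    icd9_ranges: ["531-535", "555-558", "571-571"]
    atc_prefixes: ["A02B"]
    outpatient_branches: ["gastroenterology"]
    register_flags: []
  - category: neuropathy
    exemption_codes: ["017"]
    icd9_ranges: ["330-337", "340-341", "345-345"]
    atc_prefixes: ["N03"]
    outpatient_branches: ["neurology"]
    register_flags: []
  - category: autoimmune
    exemption_codes: ["006", "028"]
    icd9_ranges: ["710-714", "720-720"]
    atc_prefixes: ["L04"]
    outpatient_branches: ["rheumatology"]
    register_flags: []
  - category: endocrine_metabolic
    exemption_codes: ["027"]
    icd9_ranges: ["240-246", "272-272"]
    atc_prefixes: ["H03", "C10"]
    outpatient_branches: ["endocrinology"]
    register_flags: []
  - category: rare_diseases
    exemption_codes: ["RC0", "RN1"]
    icd9_ranges: ["277-277"]
    atc_prefixes: []
    outpatient_branches: []
    register_flags: []
  - category: pregnancy
    exemption_codes: []
    icd9_ranges: ["630-679", "V22", "V27"]
    atc_prefixes: []
    outpatient_branches: ["obstetrics"]
    register_flags: []
  - category: other_residual
    exemption_codes: ["099"]
    icd9_ranges: ["730-739"]
    atc_prefixes: []
    outpatient_branches: ["rehabilitation"]
    register_flags: []
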
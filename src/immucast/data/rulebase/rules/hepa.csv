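rule_id,vaccine_category,vaccine_codes,rule_class,logic,action_type,dose_number,timing_earliest,timing_recommended,timing_latest,description,citation,executable,ontology_tag
HEPA-R01,hepa,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis A: regular/catchup rule 1 of 6 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPA-R02,hepa,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis A: regular/catchup rule 2 of 6 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPA-R03,hepa,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis A: regular/catchup rule 3 of 6 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPA-R04,hepa,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis A: regular/catchup rule 4 of 6 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPA-R05,hepa,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis A: regular/catchup rule 5 of 6 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPA-R06,hepa,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis A: regular/catchup rule 6 of 6 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPA-M01,hepa,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis A: medical/condition rule 1 of 2 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPA-M02,hepa,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis A: medical/condition rule 2 of 2 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPA-C01,hepa,,contra_precaution,,CONTRAINDICATED,,,,,Hepatitis A: contra/precaution rule 1 of 4 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPA-C02,hepa,,contra_precaution,,CONTRAINDICATED,,,,,Hepatitis A: contra/precaution rule 2 of 4 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPA-C03,hepa,,contra_precaution,,CONTRAINDICATED,,,,,Hepatitis A: contra/precaution rule 3 of 4 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPA-C04,hepa,,contra_precaution,,CONTRAINDICATED,,,,,Hepatitis A: contra/precaution rule 4 of 4 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
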
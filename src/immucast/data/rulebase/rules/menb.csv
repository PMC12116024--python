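rule_id,vaccine_category,vaccine_codes,rule_class,logic,action_type,dose_number,timing_earliest,timing_recommended,timing_latest,description,citation,executable,ontology_tag
MENB-R01,menb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: regular/catchup rule 1 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-R02,menb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: regular/catchup rule 2 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-R03,menb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: regular/catchup rule 3 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-R04,menb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: regular/catchup rule 4 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-R05,menb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: regular/catchup rule 5 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-R06,menb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: regular/catchup rule 6 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-R07,menb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: regular/catchup rule 7 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-R08,menb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: regular/catchup rule 8 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-M01,menb,,medical_condition,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: medical/condition rule 1 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-M02,menb,,medical_condition,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: medical/condition rule 2 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-M03,menb,,medical_condition,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: medical/condition rule 3 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-M04,menb,,medical_condition,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: medical/condition rule 4 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-M05,menb,,medical_condition,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: medical/condition rule 5 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-M06,menb,,medical_condition,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: medical/condition rule 6 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-M07,menb,,medical_condition,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: medical/condition rule 7 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-M08,menb,,medical_condition,,RECOMMEND_DOSE,1,,,,Meningococcal serogroup B: medical/condition rule 8 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-C01,menb,,contra_precaution,,CONTRAINDICATED,,,,,Meningococcal serogroup B: contra/precaution rule 1 of 4 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-C02,menb,,contra_precaution,,CONTRAINDICATED,,,,,Meningococcal serogroup B: contra/precaution rule 2 of 4 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-C03,menb,,contra_precaution,,CONTRAINDICATED,,,,,Meningococcal serogroup B: contra/precaution rule 3 of 4 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
MENB-C04,menb,,contra_precaution,,CONTRAINDICATED,,,,,Meningococcal serogroup B: contra/precaution rule 4 of 4 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
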
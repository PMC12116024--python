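rule_id,vaccine_category,vaccine_codes,rule_class,logic,action_type,dose_number,timing_earliest,timing_recommended,timing_latest,description,citation,executable,ontology_tag
HEPB-R01,hepb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis B: regular/catchup rule 1 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-R02,hepb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis B: regular/catchup rule 2 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-R03,hepb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis B: regular/catchup rule 3 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-R04,hepb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis B: regular/catchup rule 4 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-R05,hepb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis B: regular/catchup rule 5 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-R06,hepb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis B: regular/catchup rule 6 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-R07,hepb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis B: regular/catchup rule 7 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-R08,hepb,,regular_catchup,,RECOMMEND_DOSE,1,,,,Hepatitis B: regular/catchup rule 8 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M01,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 1 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M02,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 2 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M03,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 3 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M04,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 4 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M05,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 5 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M06,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 6 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M07,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 7 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M08,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 8 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M09,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 9 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M10,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 10 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M11,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 11 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M12,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 12 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M13,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 13 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-M14,hepb,,medical_condition,,RECOMMEND_DOSE,1,,,,Hepatitis B: medical/condition rule 14 of 14 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-C01,hepb,,contra_precaution,,CONTRAINDICATED,,,,,Hepatitis B: contra/precaution rule 1 of 3 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-C02,hepb,,contra_precaution,,CONTRAINDICATED,,,,,Hepatitis B: contra/precaution rule 2 of 3 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
HEPB-C03,hepb,,contra_precaution,,CONTRAINDICATED,,,,,Hepatitis B: contra/precaution rule 3 of 3 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
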
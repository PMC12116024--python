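rule_id,vaccine_category,vaccine_codes,rule_class,logic,action_type,dose_number,timing_earliest,timing_recommended,timing_latest,description,citation,executable,ontology_tag
VARICELLA-R01,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 1 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-R02,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 2 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-R03,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 3 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-R04,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 4 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-R05,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 5 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-R06,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 6 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-R07,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 7 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-R08,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 8 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-R09,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 9 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-R10,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 10 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-R11,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 11 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-R12,varicella,,regular_catchup,,RECOMMEND_DOSE,1,,,,Varicella: regular/catchup rule 12 of 12 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-C01,varicella,,contra_precaution,,CONTRAINDICATED,,,,,Varicella: contra/precaution rule 1 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-C02,varicella,,contra_precaution,,CONTRAINDICATED,,,,,Varicella: contra/precaution rule 2 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-C03,varicella,,contra_precaution,,CONTRAINDICATED,,,,,Varicella: contra/precaution rule 3 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-C04,varicella,,contra_precaution,,CONTRAINDICATED,,,,,Varicella: contra/precaution rule 4 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-C05,varicella,,contra_precaution,,CONTRAINDICATED,,,,,Varicella: contra/precaution rule 5 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-C06,varicella,,contra_precaution,,CONTRAINDICATED,,,,,Varicella: contra/precaution rule 6 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-C07,varicella,,contra_precaution,,CONTRAINDICATED,,,,,Varicella: contra/precaution rule 7 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
VARICELLA-C08,varicella,,contra_precaution,,CONTRAINDICATED,,,,,Varicella: contra/precaution rule 8 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
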
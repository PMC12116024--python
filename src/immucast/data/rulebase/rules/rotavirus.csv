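rule_id,vaccine_category,vaccine_codes,rule_class,logic,action_type,dose_number,timing_earliest,timing_recommended,timing_latest,description,citation,executable,ontology_tag
ROTAVIRUS-R01,rotavirus,,regular_catchup,,RECOMMEND_DOSE,1,,,,Rotavirus: regular/catchup rule 1 of 11 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-R02,rotavirus,,regular_catchup,,RECOMMEND_DOSE,1,,,,Rotavirus: regular/catchup rule 2 of 11 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-R03,rotavirus,,regular_catchup,,RECOMMEND_DOSE,1,,,,Rotavirus: regular/catchup rule 3 of 11 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-R04,rotavirus,,regular_catchup,,RECOMMEND_DOSE,1,,,,Rotavirus: regular/catchup rule 4 of 11 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-R05,rotavirus,,regular_catchup,,RECOMMEND_DOSE,1,,,,Rotavirus: regular/catchup rule 5 of 11 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-R06,rotavirus,,regular_catchup,,RECOMMEND_DOSE,1,,,,Rotavirus: regular/catchup rule 6 of 11 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-R07,rotavirus,,regular_catchup,,RECOMMEND_DOSE,1,,,,Rotavirus: regular/catchup rule 7 of 11 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-R08,rotavirus,,regular_catchup,,RECOMMEND_DOSE,1,,,,Rotavirus: regular/catchup rule 8 of 11 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-R09,rotavirus,,regular_catchup,,RECOMMEND_DOSE,1,,,,Rotavirus: regular/catchup rule 9 of 11 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-R10,rotavirus,,regular_catchup,,RECOMMEND_DOSE,1,,,,Rotavirus: regular/catchup rule 10 of 11 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-R11,rotavirus,,regular_catchup,,RECOMMEND_DOSE,1,,,,Rotavirus: regular/catchup rule 11 of 11 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-C01,rotavirus,,contra_precaution,,CONTRAINDICATED,,,,,Rotavirus: contra/precaution rule 1 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-C02,rotavirus,,contra_precaution,,CONTRAINDICATED,,,,,Rotavirus: contra/precaution rule 2 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-C03,rotavirus,,contra_precaution,,CONTRAINDICATED,,,,,Rotavirus: contra/precaution rule 3 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-C04,rotavirus,,contra_precaution,,CONTRAINDICATED,,,,,Rotavirus: contra/precaution rule 4 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-C05,rotavirus,,contra_precaution,,CONTRAINDICATED,,,,,Rotavirus: contra/precaution rule 5 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-C06,rotavirus,,contra_precaution,,CONTRAINDICATED,,,,,Rotavirus: contra/precaution rule 6 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-C07,rotavirus,,contra_precaution,,CONTRAINDICATED,,,,,Rotavirus: contra/precaution rule 7 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
ROTAVIRUS-C08,rotavirus,,contra_precaution,,CONTRAINDICATED,,,,,Rotavirus: contra/precaution rule 8 of 8 (structured encoding pending; counted in the manifest).,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
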
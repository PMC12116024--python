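rule_id,vaccine_category,vaccine_codes,rule_class,logic,action_type,dose_number,timing_earliest,timing_recommended,timing_latest,description,citation,executable,ontology_tag
TDAP-R01,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 1 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-R02,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 2 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-R03,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 3 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-R04,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 4 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-R05,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 5 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-R06,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 6 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-R07,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 7 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-R08,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 8 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-R09,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 9 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-R10,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 10 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-R11,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 11 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-R12,tdap,,regular_catchup,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: regular/catchup rule 12 of 12 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-M01,tdap,,medical_condition,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: medical/condition rule 1 of 9 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-M02,tdap,,medical_condition,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: medical/condition rule 2 of 9 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-M03,tdap,,medical_condition,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: medical/condition rule 3 of 9 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-M04,tdap,,medical_condition,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: medical/condition rule 4 of 9 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-M05,tdap,,medical_condition,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: medical/condition rule 5 of 9 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-M06,tdap,,medical_condition,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: medical/condition rule 6 of 9 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-M07,tdap,,medical_condition,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: medical/condition rule 7 of 9 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-M08,tdap,,medical_condition,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: medical/condition rule 8 of 9 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-M09,tdap,,medical_condition,,RECOMMEND_DOSE,1,,,,"Tetanus, diphtheria, and acellular pertussis: medical/condition rule 9 of 9 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-C01,tdap,,contra_precaution,,CONTRAINDICATED,,,,,"Tetanus, diphtheria, and acellular pertussis: contra/precaution rule 1 of 6 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-C02,tdap,,contra_precaution,,CONTRAINDICATED,,,,,"Tetanus, diphtheria, and acellular pertussis: contra/precaution rule 2 of 6 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-C03,tdap,,contra_precaution,,CONTRAINDICATED,,,,,"Tetanus, diphtheria, and acellular pertussis: contra/precaution rule 3 of 6 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-C04,tdap,,contra_precaution,,CONTRAINDICATED,,,,,"Tetanus, diphtheria, and acellular pertussis: contra/precaution rule 4 of 6 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-C05,tdap,,contra_precaution,,CONTRAINDICATED,,,,,"Tetanus, diphtheria, and acellular pertussis: contra/precaution rule 5 of 6 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
TDAP-C06,tdap,,contra_precaution,,CONTRAINDICATED,,,,,"Tetanus, diphtheria, and acellular pertussis: contra/precaution rule 6 of 6 (structured encoding pending; counted in the manifest).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",false,
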
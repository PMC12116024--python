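rule_id,vaccine_category,vaccine_codes,rule_class,logic,action_type,dose_number,timing_earliest,timing_recommended,timing_latest,description,citation,executable,ontology_tag
MMR-R01,mmr,03|94,regular_catchup,"AND(AGE_GE[12 mo], AGE_LT[16 mo], DOSE_COUNT_EQ[0])",RECOMMEND_DOSE,1,birth+12 mo,birth+12 mo,birth+15 mo,Routine first dose at 12 through 15 months.,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",true,
MMR-R02,mmr,03|94,regular_catchup,"AND(AGE_LT[12 mo], DOSE_COUNT_EQ[0])",SCHEDULE_FOLLOWUP,1,birth+12 mo,birth+12 mo,,Under 12 months: schedule dose 1 at the first birthday.,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",true,
MMR-R03,mmr,03|94,regular_catchup,"AND(AGE_GE[16 mo], AGE_LT[4 y], DOSE_COUNT_EQ[0])",RECOMMEND_DOSE,1,birth+12 mo,,,"Catch-up first dose, 16 months through 3 years.","CDC Child & Adolescent Immunization Schedule 2022, Table 2 (catch-up)",true,
MMR-R04,mmr,03|94,regular_catchup,"AND(AGE_GE[4 y], AGE_LT[7 y], DOSE_COUNT_EQ[0])",RECOMMEND_DOSE,1,birth+12 mo,,,Catch-up first dose at 4 through 6 years.,"CDC Child & Adolescent Immunization Schedule 2022, Table 2 (catch-up)",true,
MMR-R05,mmr,03,regular_catchup,"AND(AGE_GE[7 y], DOSE_COUNT_EQ[0])",RECOMMEND_DOSE,1,birth+12 mo,,,Catch-up first dose at 7 through 18 years.,"CDC Child & Adolescent Immunization Schedule 2022, Table 2 (catch-up)",true,
MMR-R06,mmr,03|94,regular_catchup,"AND(DOSE_COUNT_EQ[1], AGE_LT[4 y])",SCHEDULE_FOLLOWUP,2,birth+4 y,birth+4 y,birth+6 y,One valid dose before age 4: schedule dose 2 for the 4-6-year visit.,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",true,
MMR-R07,mmr,03|94,regular_catchup,"AND(DOSE_COUNT_EQ[1], AGE_GE[4 y], AGE_LT[7 y], INTERVAL_SINCE_DOSE_GE[1, 28 d])",RECOMMEND_DOSE,2,prev_dose+28 d,birth+4 y,birth+6 y,Routine second dose at 4 through 6 years.,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",true,
MMR-R08,mmr,03,regular_catchup,"AND(DOSE_COUNT_EQ[1], AGE_GE[7 y], INTERVAL_SINCE_DOSE_GE[1, 28 d])",RECOMMEND_DOSE,2,prev_dose+28 d,,,Catch-up second dose at 7 through 18 years; minimum interval 4 weeks.,"CDC Child & Adolescent Immunization Schedule 2022, Table 2 (catch-up)",true,
MMR-R09,mmr,03|94,regular_catchup,"AND(DOSE_COUNT_EQ[1], AGE_GE[4 y], INTERVAL_SINCE_DOSE_LT[1, 28 d])",SCHEDULE_FOLLOWUP,2,prev_dose+28 d,prev_dose+28 d,,"Dose 2 due, but the 4-week minimum interval has not yet elapsed.","CDC Child & Adolescent Immunization Schedule 2022, Table 2 (catch-up)",true,
MMR-R10,mmr,03|94,regular_catchup,DOSE_COUNT_GE[2],SERIES_COMPLETE,,,,,Two valid doses: series complete.,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",true,
MMR-R11,mmr,03|94,regular_catchup,"AND(DOSE_COUNT_EQ[0], NOT(PRIOR_DOSE_VALID[1]), AGE_GE[12 mo])",RECOMMEND_DOSE,1,birth+12 mo,,,A dose given before 12 months of age does not count; revaccinate.,"CDC Child & Adolescent Immunization Schedule 2022, Notes",true,
MMR-R12,mmr,03|94,regular_catchup,"AND(DOSE_COUNT_EQ[1], NOT(PRIOR_DOSE_VALID[2]), AGE_GE[4 y], INTERVAL_SINCE_DOSE_GE[1, 28 d])",RECOMMEND_DOSE,2,prev_dose+28 d,,,A second dose given <4 weeks after the first does not count; repeat it.,"CDC Child & Adolescent Immunization Schedule 2022, Notes",true,
MMR-R13,mmr,94,regular_catchup,"AND(AGE_GE[12 mo], AGE_LE[12 y], DOSE_COUNT_EQ[0])",RECOMMEND_DOSE,1,birth+12 mo,,,MMRV may be used for dose 1 through age 12 (credits MMR and varicella).,"CDC Child & Adolescent Immunization Schedule 2022, Notes",true,
MMR-R14,mmr,94,regular_catchup,"AND(DOSE_COUNT_EQ[1], AGE_GE[4 y], AGE_LE[12 y], INTERVAL_SINCE_DOSE_GE[1, 3 mo])",RECOMMEND_DOSE,2,prev_dose+3 mo,birth+4 y,birth+6 y,MMRV option for dose 2 through age 12; recommended interval >=3 months.,"CDC Child & Adolescent Immunization Schedule 2022, Notes",true,
MMR-R15,mmr,03|94,regular_catchup,CONDITION_PRESENT[EVIDENCE-OF-IMMUNITY-MMR],SERIES_COMPLETE,,,,,Documented evidence of immunity: no further doses needed.,"CDC Child & Adolescent Immunization Schedule 2022, Notes",true,
MMR-R16,mmr,03,regular_catchup,"AND(DOSE_COUNT_EQ[1], AGE_GT[12 y], INTERVAL_SINCE_DOSE_GE[1, 28 d])",RECOMMEND_DOSE,2,prev_dose+28 d,,,Older than 12 years: use MMR (not MMRV) for the remaining dose.,"CDC Child & Adolescent Immunization Schedule 2022, Notes",true,
MMR-M01,mmr,03,medical_condition,"AND(CONDITION_PRESENT[INTERNATIONAL-TRAVEL], AGE_GE[6 mo], AGE_LT[12 mo], DOSE_COUNT_EQ[0])",RECOMMEND_DOSE,1,birth+6 mo,,,Infant 6-11 months traveling internationally: one early dose (does not count toward the 2-dose series).,"CDC Child & Adolescent Immunization Schedule 2022, Notes",true,
MMR-M02,mmr,03,medical_condition,"AND(CONDITION_PRESENT[HIV-WITHOUT-SEVERE-IMMUNOSUPPRESSION], AGE_GE[12 mo], DOSE_COUNT_EQ[0])",RECOMMEND_DOSE,1,birth+12 mo,,,HIV infection without severe immunosuppression: 2-dose series from 12 months.,"CDC Child & Adolescent Immunization Schedule 2022, Notes",true,
MMR-C01,mmr,03|94,contra_precaution,CONDITION_PRESENT[ANAPHYLAXIS-PRIOR-MMR-DOSE],CONTRAINDICATED,,,,,Severe allergic reaction (anaphylaxis) after a previous MMR/MMRV dose.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
MMR-C02,mmr,03|94,contra_precaution,CONDITION_PRESENT[ANAPHYLAXIS-NEOMYCIN],CONTRAINDICATED,,,,,Anaphylaxis to neomycin (vaccine component).,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
MMR-C03,mmr,03|94,contra_precaution,CONDITION_PRESENT[ANAPHYLAXIS-GELATIN],CONTRAINDICATED,,,,,Anaphylaxis to gelatin (vaccine component).,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
MMR-C04,mmr,03|94,contra_precaution,CONDITION_PRESENT[SEVERE-IMMUNODEFICIENCY],CONTRAINDICATED,,,,,Severe congenital or acquired immunodeficiency: live vaccine contraindicated.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
MMR-C05,mmr,03|94,contra_precaution,CONDITION_PRESENT[HIV-SEVERE-IMMUNOSUPPRESSION],CONTRAINDICATED,,,,,HIV infection with severe immunosuppression.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
MMR-C06,mmr,03|94,contra_precaution,CONDITION_PRESENT[PREGNANCY],CONTRAINDICATED,,,,,Pregnancy or planned pregnancy within 4 weeks.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
MMR-C07,mmr,03|94,contra_precaution,CONDITION_PRESENT[FAMILY-HISTORY-ALTERED-IMMUNOCOMPETENCE],PRECAUTION,,,,,Family history of altered immunocompetence: defer until immune status verified.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
MMR-C08,mmr,03|94,contra_precaution,CONDITION_PRESENT[RECENT-ANTIBODY-CONTAINING-PRODUCT],PRECAUTION,,,,,Recent antibody-containing blood product: defer (interval up to 11 months).,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
MMR-C09,mmr,03|94,contra_precaution,CONDITION_PRESENT[MODERATE-SEVERE-ACUTE-ILLNESS],PRECAUTION,,,,,Moderate or severe acute illness: defer until resolved.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
MMR-C10,mmr,03|94,contra_precaution,CONDITION_PRESENT[HISTORY-THROMBOCYTOPENIA],PRECAUTION,,,,,History of thrombocytopenia or thrombocytopenic purpura.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
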
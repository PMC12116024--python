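rule_id,vaccine_category,vaccine_codes,rule_class,logic,action_type,dose_number,timing_earliest,timing_recommended,timing_latest,description,citation,executable,ontology_tag
DEN-R01,dengue,56,regular_catchup,"AND(AGE_GE[9 y], AGE_LE[16 y], CONDITION_PRESENT[DENGUE-PREVIOUS-INFECTION-LAB-CONFIRMED], CONDITION_PRESENT[RESIDENCE-DENGUE-ENDEMIC-AREA], DOSE_COUNT_EQ[0])",RECOMMEND_DOSE,1,birth+9 y,,,"Seropositive 9-16-year-olds living in endemic areas: start the 3-dose series (0, 6, 12 months).","CDC Child & Adolescent Immunization Schedule 2022, Table 1",true,
DEN-R02,dengue,56,regular_catchup,"AND(DOSE_COUNT_GE[1], DOSE_COUNT_LE[2])",SCHEDULE_FOLLOWUP,,prev_dose+6 mo,prev_dose+6 mo,,Next dose 6 months after the previous dose.,"CDC Child & Adolescent Immunization Schedule 2022, Table 1",true,
DEN-C01,dengue,56,contra_precaution,CONDITION_PRESENT[DENGUE-SERONEGATIVE],CONTRAINDICATED,,,,,Documented absence of previous dengue infection: do not vaccinate.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
DEN-C02,dengue,56,contra_precaution,CONDITION_PRESENT[ANAPHYLAXIS-PRIOR-DEN4CYD-DOSE],CONTRAINDICATED,,,,,Severe allergic reaction after a previous DEN4CYD dose.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
DEN-C03,dengue,56,contra_precaution,CONDITION_PRESENT[ANAPHYLAXIS-DEN4CYD-COMPONENT],CONTRAINDICATED,,,,,Anaphylaxis to a DEN4CYD component.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
DEN-C04,dengue,56,contra_precaution,CONDITION_PRESENT[SEVERE-IMMUNODEFICIENCY],CONTRAINDICATED,,,,,Severe congenital or acquired immunodeficiency: live vaccine contraindicated.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
DEN-C05,dengue,56,contra_precaution,CONDITION_PRESENT[HIV-SEVERE-IMMUNOSUPPRESSION],CONTRAINDICATED,,,,,HIV infection with severe immunosuppression.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
DEN-C06,dengue,56,contra_precaution,CONDITION_PRESENT[PREGNANCY],CONTRAINDICATED,,,,,Pregnancy.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
DEN-C07,dengue,56,contra_precaution,CONDITION_PRESENT[MODERATE-SEVERE-ACUTE-ILLNESS],PRECAUTION,,,,,Moderate or severe acute illness: defer until resolved.,"CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)",true,
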
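{
  "schedule_version": "CDC child & adolescent immunization schedule, <=18 years, 2022",
  "categories": [
    {
      "name": "Dengue",
      "slug": "dengue",
      "disease_group": "Dengue",
      "abbreviations": [
        "DEN4CYD"
      ],
      "vaccines": [
        "DEN4CYD"
      ],
      "counts": {
        "regular_catchup": 2,
        "medical_condition": 0,
        "contra_precaution": 7
      },
      "executable": true,
      "series": {
        "size": 3,
        "doses": [
          {
            "min_age": "9 y",
            "routine": "9 y"
          },
          {
            "min_interval": "6 mo"
          },
          {
            "min_interval": "6 mo"
          }
        ]
      }
    },
    {
      "name": "Diphtheria, tetanus, and acellular pertussis",
      "slug": "dtap",
      "disease_group": "Diphtheria, tetanus, and pertussis",
      "abbreviations": [
        "DTaP",
        "DT"
      ],
      "vaccines": [
        "DTaP"
      ],
      "counts": {
        "regular_catchup": 16,
        "medical_condition": 14,
        "contra_precaution": 7
      },
      "executable": false
    },
    {
      "name": "Haemophilus influenzae type b",
      "slug": "hib",
      "disease_group": "Haemophilus influenzae type b",
      "abbreviations": [
        "Hib"
      ],
      "vaccines": [
        "Hib"
      ],
      "counts": {
        "regular_catchup": 16,
        "medical_condition": 20,
        "contra_precaution": 4
      },
      "executable": false
    },
    {
      "name": "Hepatitis A",
      "slug": "hepa",
      "disease_group": "Hepatitis A",
      "abbreviations": [
        "HepA",
        "Twinrix"
      ],
      "vaccines": [
        "HepA"
      ],
      "counts": {
        "regular_catchup": 6,
        "medical_condition": 2,
        "contra_precaution": 4
      },
      "executable": false
    },
    {
      "name": "Hepatitis B",
      "slug": "hepb",
      "disease_group": "Hepatitis B",
      "abbreviations": [
        "HepB"
      ],
      "vaccines": [
        "HepB"
      ],
      "counts": {
        "regular_catchup": 8,
        "medical_condition": 14,
        "contra_precaution": 3
      },
      "executable": false
    },
    {
      "name": "Human papillomavirus",
      "slug": "hpv",
      "disease_group": "Human papillomavirus",
      "abbreviations": [
        "HPV"
      ],
      "vaccines": [
        "HPV"
      ],
      "counts": {
        "regular_catchup": 15,
        "medical_condition": 18,
        "contra_precaution": 2
      },
      "executable": false
    },
    {
      "name": "Influenza (inactivated and live and attenuated)",
      "slug": "influenza",
      "disease_group": "Influenza",
      "abbreviations": [
        "IIV4",
        "LAIV4"
      ],
      "vaccines": [
        "IIV4",
        "LAIV4"
      ],
      "counts": {
        "regular_catchup": 13,
        "medical_condition": 0,
        "contra_precaution": 33
      },
      "executable": false
    },
    {
      "name": "Measles, mumps, and rubella",
      "slug": "mmr",
      "disease_group": "Measles, mumps, and rubella",
      "abbreviations": [
        "MMR",
        "MMRV"
      ],
      "vaccines": [
        "MMR",
        "MMRV"
      ],
      "counts": {
        "regular_catchup": 16,
        "medical_condition": 2,
        "contra_precaution": 10
      },
      "executable": true,
      "series": {
        "size": 2,
        "doses": [
          {
            "min_age": "12 mo",
            "routine": "12 mo",
            "routine_latest": "15 mo"
          },
          {
            "min_interval": "28 d",
            "routine": "4 y",
            "routine_latest": "6 y"
          }
        ]
      }
    },
    {
      "name": "Meningococcal serogroups A, C, W, and Y",
      "slug": "menacwy",
      "disease_group": "Meningococcal",
      "abbreviations": [
        "MenACWY-D",
        "MenACWY-CRM",
        "MenACWY-TT"
      ],
      "vaccines": [
        "MenACWY"
      ],
      "counts": {
        "regular_catchup": 12,
        "medical_condition": 34,
        "contra_precaution": 5
      },
      "executable": false
    },
    {
      "name": "Meningococcal serogroup B",
      "slug": "menb",
      "disease_group": "Meningococcal",
      "abbreviations": [
        "MenB-4C",
        "MenB-FHbp"
      ],
      "vaccines": [
        "MenB"
      ],
      "counts": {
        "regular_catchup": 8,
        "medical_condition": 8,
        "contra_precaution": 4
      },
      "executable": false
    },
    {
      "name": "Pneumococcal 13-valent conjugate, 23-valent polysaccharide",
      "slug": "pneumococcal",
      "disease_group": "Pneumococcal",
      "abbreviations": [
        "PCV13",
        "PPSV23"
      ],
      "vaccines": [
        "PCV13",
        "PPSV23"
      ],
      "counts": {
        "regular_catchup": 20,
        "medical_condition": 30,
        "contra_precaution": 4
      },
      "executable": false
    },
    {
      "name": "Poliovirus (inactivated)",
      "slug": "polio",
      "disease_group": "Poliovirus",
      "abbreviations": [
        "IPV",
        "tOPV"
      ],
      "vaccines": [
        "IPV"
      ],
      "counts": {
        "regular_catchup": 33,
        "medical_condition": 6,
        "contra_precaution": 3
      },
      "executable": false
    },
    {
      "name": "Rotavirus",
      "slug": "rotavirus",
      "disease_group": "Rotavirus",
      "abbreviations": [
        "RV1",
        "RV5"
      ],
      "vaccines": [
        "RV1",
        "RV5"
      ],
      "counts": {
        "regular_catchup": 11,
        "medical_condition": 0,
        "contra_precaution": 8
      },
      "executable": false
    },
    {
      "name": "Tetanus, diphtheria, and acellular pertussis",
      "slug": "tdap",
      "disease_group": "Diphtheria, tetanus, and pertussis",
      "abbreviations": [
        "Tdap",
        "Td"
      ],
      "vaccines": [
        "Tdap"
      ],
      "counts": {
        "regular_catchup": 12,
        "medical_condition": 9,
        "contra_precaution": 6
      },
      "executable": false
    },
    {
      "name": "Varicella",
      "slug": "varicella",
      "disease_group": "Varicella",
      "abbreviations": [
        "VAR",
        "MMRV"
      ],
      "vaccines": [
        "VAR",
        "MMRV"
      ],
      "counts": {
        "regular_catchup": 12,
        "medical_condition": 0,
        "contra_precaution": 8
      },
      "executable": false
    }
  ]
}
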
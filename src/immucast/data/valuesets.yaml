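# Minimal CVX value sets bundled with the package (codes from the CDC CVX
# code system; the package ships its own copies rather than querying a
# terminology service).
#
# category_cvx: CVX codes whose dose events count toward each category's
# series.  Combination products appear under every category they credit
# (CVX 94, MMRV, credits both the MMR and the varicella series).
category_cvx:
  dengue: ["56"]
  dtap: ["20", "28"]
  hib: ["48", "49"]
  hepa: ["83"]
  hepb: ["08"]
  hpv: ["165"]
  influenza: ["149", "150"]
  mmr: ["03", "94"]
  menacwy: ["114", "136", "203"]
  menb: ["162", "163"]
  pneumococcal: ["33", "133"]
  polio: ["10"]
  rotavirus: ["116", "119"]
  tdap: ["113", "115"]
  varicella: ["21", "94"]

# product_cvx: the CVX code used when a dose of a named product is recorded.
product_cvx:
  DEN4CYD: "56"
  DTaP: "20"
  Hib: "48"
  HepA: "83"
  HepB: "08"
  HPV: "165"
  IIV4: "150"
  LAIV4: "149"
  MMR: "03"
  MMRV: "94"
  MenACWY: "114"
  MenB: "163"
  PCV13: "133"
  PPSV23: "33"
  IPV: "10"
  RV1: "119"
  RV5: "116"
  Tdap: "115"
  VAR: "21"
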
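{
  "description": "Published unique-compound lists from a five-method urinary GC-MS extraction comparison: compounds detected by exactly one method, plus compounds detected only by the four organic-acid (OA) extraction methods and not by the direct-analysis method.",
  "group_label": "Methods 1-4 (organic acid)",
  "group_methods": ["Method 1", "Method 2", "Method 3", "Method 4"],
  "aliases": {
    "Malonic acid diethyl ester": "Malonic acid"
  },
  "methods": {
    "Method 1": [],
    "Method 2": [
      "Analyte 003",
      "Analyte 013",
      "Analyte 121",
      "Analyte 128",
      "Analyte 135",
      "Analyte 148",
      "Analyte 150",
      "Analyte 156",
      "Analyte 157",
      "Analyte 167",
      "Analyte 171",
      "Analyte 192",
      "Analyte 308"
    ],
    "Method 3": [
      "Analyte 322"
    ],
    "Method 4": [
      "2,3,4-Trihydroxy-butyraldehyde O-methyl-oxime",
      "Analyte 036",
      "Analyte 071",
      "Analyte 209",
      "Analyte 216",
      "Analyte 325",
      "Malonic acid"
    ],
    "Method 5": [
      "2-Amino-benzoic acid",
      "3,4,5-Trihydroxy-pentanoic acid",
      "3,4-Dihydroxy-butyric acid",
      "3R,4S-Tetrahydrofuran-2,3,4-triol",
      "4-Hydroxy-pyrrolidine-2-carboxylic acid",
      "5-Hydroxymethyl-tetrahydro-furan-2,3,4-triol [1]",
      "5-Hydroxymethyl-tetrahydro-furan-2,3,4-triol [2]",
      "5-Oxo-pyrrolidine-2-carboxylic acid",
      "Analyte 004",
      "Analyte 005",
      "Analyte 023",
      "Analyte 025",
      "Analyte 029",
      "Analyte 035",
      "Analyte 038",
      "Analyte 043",
      "Analyte 046",
      "Analyte 050",
      "Analyte 057",
      "Analyte 058",
      "Analyte 061",
      "Analyte 063",
      "Analyte 064",
      "Analyte 070",
      "Analyte 072",
      "Analyte 085",
      "Analyte 086",
      "Analyte 087",
      "Analyte 090",
      "Analyte 096",
      "Analyte 099",
      "Analyte 118",
      "Analyte 125",
      "Analyte 126",
      "Analyte 131",
      "Analyte 137",
      "Analyte 145",
      "Analyte 151",
      "Analyte 177",
      "Analyte 183",
      "Analyte 186",
      "Analyte 199",
      "Analyte 210",
      "Analyte 212",
      "Analyte 218",
      "Analyte 220",
      "Analyte 225",
      "Analyte 251",
      "Analyte 253",
      "Analyte 266",
      "Analyte 276",
      "Analyte 278",
      "Analyte 280",
      "Analyte 285",
      "Analyte 287",
      "Analyte 302",
      "Analyte 305",
      "Analyte 306",
      "Analyte 311",
      "Analyte 321",
      "Analyte 323",
      "Arabinofuranose",
      "Arabinose",
      "Ascorbic acid",
      "Aucubin",
      "Butane-2,3-diol",
      "Creatinine",
      "Dehydroabietic acid",
      "Erythronic acid ç-lactone",
      "Galactose [1]",
      "Galactose [2]",
      "Glucose",
      "Glucuronic acid",
      "Glucuronic acid ç-lactone",
      "Glycerol",
      "Isocitric lactone",
      "meso-Erythritol",
      "Methyl galactoside",
      "Methylmalonic acid",
      "Myo-Inositol [1]",
      "Myo-Inositol [2]",
      "N-Acetyltyrosine",
      "N-benzoyl-glycine",
      "Oxalic acid",
      "Oxalic acid [1]",
      "Oxalic acid [2]",
      "Rhamnose",
      "Ribofuranose",
      "Tagatofuranose",
      "Threo-3-deoxy-pentonic acid",
      "Xylose"
    ]
  },
  "group": [
    "2,3,4-Trihydroxy-butyraldehyde O-methyl-oxime",
    "2,4-Dihydroxybutyric acid",
    "2-Hydroxy-pentanedioic acid",
    "5-Hydroxymethyl-tetrahydro-furan-2,3,4-triol [1]",
    "5-Hydroxymethyl-tetrahydro-furan-2,3,4-triol [2]",
    "Analyte 003",
    "Analyte 013",
    "Analyte 014",
    "Analyte 020",
    "Analyte 022",
    "Analyte 024",
    "Analyte 027",
    "Analyte 031",
    "Analyte 036",
    "Analyte 049",
    "Analyte 052",
    "Analyte 055",
    "Analyte 059",
    "Analyte 071",
    "Analyte 121",
    "Analyte 123",
    "Analyte 128",
    "Analyte 135",
    "Analyte 143",
    "Analyte 144",
    "Analyte 148",
    "Analyte 150",
    "Analyte 156",
    "Analyte 157",
    "Analyte 167",
    "Analyte 168",
    "Analyte 170",
    "Analyte 171",
    "Analyte 173",
    "Analyte 174",
    "Analyte 175",
    "Analyte 176",
    "Analyte 192",
    "Analyte 195",
    "Analyte 205",
    "Analyte 209",
    "Analyte 216",
    "Analyte 226",
    "Analyte 239",
    "Analyte 240",
    "Analyte 255",
    "Analyte 297",
    "Analyte 301",
    "Analyte 308",
    "Analyte 314",
    "Analyte 322",
    "Analyte 325",
    "Benzene-1,2,3-triol",
    "Citric acid [miss ID]",
    "Malonic acid diethyl ester",
    "Octadecanoic acid",
    "Propane-1,2,3-triol [1]",
    "Tetrahydro-pyran-2,3,4,5-tetraol (isomer 2)"
  ]
}
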
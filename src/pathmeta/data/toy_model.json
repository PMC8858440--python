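{
 "compounds": [
  {
   "aliases": [
    "dextrose"
   ],
   "id": "glucose",
   "monoisotopic_mass": 180.06338810244,
   "name": "D-Glucose"
  },
  {
   "aliases": [
    "pyruvic acid"
   ],
   "id": "pyruvate",
   "monoisotopic_mass": 88.01604398708,
   "name": "Pyruvate"
  },
  {
   "aliases": [
    "lactic acid"
   ],
   "id": "lactate",
   "monoisotopic_mass": 90.03169405122,
   "name": "L-Lactate"
  },
  {
   "aliases": [],
   "id": "malate",
   "monoisotopic_mass": 134.02152329042,
   "name": "L-Malate"
  },
  {
   "aliases": [
    "citric acid"
   ],
   "id": "citrate",
   "monoisotopic_mass": 192.02700259376002,
   "name": "Citrate"
  },
  {
   "aliases": [],
   "id": "succinate",
   "monoisotopic_mass": 118.02660867082,
   "name": "Succinate"
  },
  {
   "aliases": [],
   "id": "glycine",
   "monoisotopic_mass": 75.03202840435,
   "name": "Glycine"
  },
  {
   "aliases": [],
   "id": "serine",
   "monoisotopic_mass": 105.04259308809,
   "name": "L-Serine"
  },
  {
   "aliases": [],
   "id": "alanine",
   "monoisotopic_mass": 89.04767846849,
   "name": "L-Alanine"
  },
  {
   "aliases": [],
   "id": "cysteine",
   "monoisotopic_mass": 121.01974946849,
   "name": "L-Cysteine"
  },
  {
   "aliases": [],
   "id": "taurine",
   "monoisotopic_mass": 125.01466408809,
   "name": "Taurine"
  },
  {
   "aliases": [],
   "id": "hypotaurine",
   "monoisotopic_mass": 109.01974946849,
   "name": "Hypotaurine"
  }
 ],
 "metadata": {
  "name": "pathmeta toy model",
  "version": "1.0"
 },
 "pathways": [
  {
   "compound_ids": [
    "glucose",
    "lactate",
    "malate",
    "pyruvate"
   ],
   "gene_symbols": [
    "HK1",
    "LDHA",
    "PKM"
   ],
   "id": "TP1",
   "name": "Glycolysis (toy)",
   "uniprot_ids": [
    "P14618",
    "P19367"
   ]
  },
  {
   "compound_ids": [
    "citrate",
    "malate",
    "pyruvate",
    "succinate"
   ],
   "gene_symbols": [
    "CS",
    "SDHA"
   ],
   "id": "TP2",
   "name": "TCA cycle (toy)",
   "uniprot_ids": [
    "O75390",
    "P31040"
   ]
  },
  {
   "compound_ids": [
    "alanine",
    "cysteine",
    "glycine",
    "hypotaurine",
    "serine",
    "taurine"
   ],
   "gene_symbols": [
    "CDO1",
    "CSAD"
   ],
   "id": "TP3",
   "name": "Sulfur amino acids (toy)",
   "uniprot_ids": [
    "Q16878",
    "Q9Y600"
   ]
  }
 ]
}
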
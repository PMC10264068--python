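{
  "avoided_keys": [
    "Ser:gga",
    "Ser:tga"
  ],
  "cds_length": 300,
  "host_keys": [
    "Thr:tgt",
    "Lys:ttt",
    "Gly:gcc",
    "Leu:taa",
    "Ser:gga",
    "Ser:tga",
    "Ser:gct",
    "Ala:agc",
    "Arg:acg",
    "Asn:gtt",
    "Gln:ttg",
    "Pro:tgg"
  ],
  "host_profile": "gc_rich",
  "mutation_plan": {
    "Gly:gcc": 5,
    "Leu:taa": 6,
    "Lys:ttt": 1,
    "Thr:tgt": 0
  },
  "n_cds": 40,
  "n_phages": 20,
  "phage_profile": "gc_rich",
  "seed": 101,
  "targets": [
    {
      "cleavage_bond": 0,
      "key": "Thr:tgt",
      "motif": null,
      "nuclease_name": "VapC-like"
    },
    {
      "cleavage_bond": 1,
      "key": "Lys:ttt",
      "motif": null,
      "nuclease_name": "PrrC-like"
    },
    {
      "cleavage_bond": 4,
      "key": "Gly:gcc",
      "motif": null,
      "nuclease_name": "MazF-like"
    },
    {
      "cleavage_bond": 5,
      "key": "Leu:taa",
      "motif": null,
      "nuclease_name": "RelE-like"
    },
    {
      "cleavage_bond": "anticodon",
      "key": "Ser:gga",
      "motif": "GA",
      "nuclease_name": "VapC"
    },
    {
      "cleavage_bond": "anticodon",
      "key": "Ser:tga",
      "motif": "GA",
      "nuclease_name": "VapC"
    }
  ]
}
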
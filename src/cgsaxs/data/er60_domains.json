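{
  "comment": "Default domain boundaries for mature human ER-60 (precursor numbering, Ser25-Leu505). The b/b' split at 232/233 follows the standard ERp57 domain annotation and is configurable.",
  "ranges": {
    "a": [[25, 132]],
    "linker": [[133, 133], [365, 365]],
    "b": [[134, 232]],
    "bp": [[233, 364]],
    "ap": [[366, 489]],
    "ctail": [[490, 505]]
  },
  "flexible_labels": ["linker", "ctail"]
}
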
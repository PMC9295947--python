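{
  "type": "object",
  "required": ["version", "seed", "config", "artifacts", "t2star_fits",
               "candidate_bic", "rate_fits", "band_separation",
               "group_stats", "comparisons", "roc"],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "artifacts": {"type": "object"},
    "t2star_fits": {"type": "object"},
    "candidate_bic": {"type": "object"},
    "rate_fits": {"type": "object"},
    "band_separation": {"type": "object"},
    "group_stats": {"type": "array"},
    "comparisons": {"type": "object"},
    "roc": {"type": "object"},
    "phantom": {"type": "object"}
  }
}
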
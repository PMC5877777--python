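{
  "bc_peaks": [
    5
  ],
  "config_hash": "e34848e8c1a5",
  "dccm_vs_eam": {
    "jaccard_percent": 27.77777777777778,
    "per_interval": [
      {
        "end": 8,
        "recovered": 5,
        "size": 8,
        "start": 1,
        "tier": null
      }
    ],
    "percent_consistency": 62.5,
    "query": "dccm",
    "query_size": 15,
    "recovered": 5,
    "reference": "eam",
    "reference_size": 8
  },
  "eam_vs_dccm": {
    "jaccard_percent": 27.77777777777778,
    "per_interval": [
      {
        "end": 7,
        "recovered": 5,
        "size": 5,
        "start": 3,
        "tier": null
      },
      {
        "end": 20,
        "recovered": 0,
        "size": 5,
        "start": 16,
        "tier": null
      },
      {
        "end": 28,
        "recovered": 0,
        "size": 5,
        "start": 24,
        "tier": null
      }
    ],
    "percent_consistency": 33.333333333333336,
    "query": "eam",
    "query_size": 8,
    "recovered": 5,
    "reference": "dccm",
    "reference_size": 15
  }
}
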
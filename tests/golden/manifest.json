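{
  "config": {
    "anti_threshold": -0.4,
    "centrality_cutoff": 7.0,
    "contact_cutoff": 5.7,
    "cost_transform": "neglog",
    "dccm_scheme": "CA",
    "ddg_cutoff": 1.0,
    "ddg_mode": "absolute",
    "delta": 1.5,
    "eam_min_terminal": 4,
    "eam_window": 8,
    "energy_model": "uniform",
    "freq_threshold": 0.5,
    "network_scheme": "CB",
    "overall_dg": 5.0,
    "seed": 11,
    "sites": [
      5
    ],
    "structure": "structure.pdb",
    "superpose": "none",
    "temperature": 298.15,
    "tier_thresholds": [
      0.4,
      0.55,
      0.7
    ],
    "trajectory": "trajectory.pdb",
    "window": [
      0,
      600
    ],
    "window_fraction": 0.1
  },
  "config_hash": "e34848e8c1a5",
  "n_frames": 600,
  "n_residues": 30,
  "outputs": [
    "centrality.tsv",
    "combined_regions.tsv",
    "consensus.json",
    "dccm.tsv",
    "eam_regions.tsv",
    "eam_residues.tsv",
    "edges.tsv",
    "pathways.json",
    "pathways_site5.tsv",
    "regions_site5.tsv",
    "track.tsv"
  ],
  "stages": [
    "read",
    "superpose",
    "dccm",
    "classify",
    "network",
    "pathways",
    "centrality",
    "eam",
    "consensus"
  ],
  "version": "0.1.0"
}
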
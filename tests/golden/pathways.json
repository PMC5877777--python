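{
  "config_hash": "e34848e8c1a5",
  "sites": {
    "5": {
      "edge_union": [
        [
          3,
          4
        ],
        [
          4,
          5
        ],
        [
          4,
          7
        ],
        [
          5,
          6
        ],
        [
          5,
          27
        ],
        [
          14,
          17
        ],
        [
          14,
          24
        ],
        [
          16,
          17
        ],
        [
          16,
          19
        ],
        [
          17,
          18
        ],
        [
          17,
          20
        ],
        [
          24,
          27
        ],
        [
          25,
          28
        ],
        [
          26,
          27
        ],
        [
          27,
          28
        ]
      ],
      "n_found": 15,
      "n_targets": 15
    }
  }
}
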
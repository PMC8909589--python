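{
  "fixtures": {
    "electron_yields.csv": {
      "source_tables": [
        1
      ],
      "sha256": "c5d8057f21da5bc0499b3a953e7b4b0a8ba51ff2f34106610b1d271ede8fbbc5"
    },
    "photon_yields.csv": {
      "source_tables": [
        2,
        4,
        5
      ],
      "sha256": "20bb0d9ba7d77f556782e148cd09ae6d564d891a33840d9dd996a011d982f810"
    },
    "qualities.csv": {
      "source_tables": [
        3
      ],
      "sha256": "cf1fc2ea177456e21567e65b1ef1aae612701c1918a4d6d8e698fd3522853d39"
    }
  }
}
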
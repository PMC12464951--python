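{
  "population": {
    "n_flowers": 100,
    "range_lo": 0.0,
    "range_hi": 1.0,
    "pollen_budget": 160000
  },
  "guild": [
    {
      "label": "bee",
      "transfer_efficiency": 0.02,
      "attraction": {
        "form": "gaussian",
        "optimum": 0.25,
        "peak_value": 0.9,
        "reference_point": 0.75,
        "reference_value": 0.1,
        "label": "bee attraction"
      },
      "removal": {
        "form": "gaussian",
        "optimum": 0.25,
        "peak_value": 10000,
        "reference_point": 0.75,
        "reference_value": 2500,
        "label": "bee removal"
      }
    },
    {
      "label": "hummingbird",
      "transfer_efficiency": 0.04,
      "attraction": {
        "form": "gaussian",
        "optimum": 0.75,
        "peak_value": 0.9,
        "reference_point": 0.25,
        "reference_value": 0.1,
        "label": "hummingbird attraction"
      },
      "removal": {
        "form": "gaussian",
        "optimum": 0.75,
        "peak_value": 10000,
        "reference_point": 0.25,
        "reference_value": 2500,
        "label": "hummingbird removal"
      }
    }
  ],
  "environment": {
    "mixture": [0.5, 0.5],
    "total_visits": 3500,
    "n_iterations": 10,
    "seed": 0
  },
  "analysis": {
    "n_bins": 20,
    "bandwidth": 0.15,
    "grid_points": 1001
  }
}
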
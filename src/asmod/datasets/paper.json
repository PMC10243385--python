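{
  "dataset": null,
  "seed": 0,
  "model": {
    "ridge_factor": 1e-06,
    "allowed_densities": [2, 3],
    "max_inputs_per_submodel": 4,
    "max_nodes_per_input": 15,
    "min_improvement": 0.25
  },
  "responses": {
    "size_um": {
      "missing_policy": "drop",
      "structure": [[["plga_pct", "speed_rpm"], [3, 3]]]
    },
    "uniformity": {
      "missing_policy": "drop",
      "structure": [
        [["drug_pct", "speed_rpm"], [2, 3]],
        [["pva_pct"], [2]],
        [["time_s", "ow_ratio"], [3, 2]],
        [["dilution_ratio"], [2]]
      ]
    },
    "ee_pct": {
      "missing_policy": "drop",
      "structure": [
        [["plga_pct", "ow_ratio"], [2, 3]],
        [["drug_pct", "time_s"], [2, 3]]
      ]
    },
    "dl_pct": {
      "missing_policy": "zero_fill",
      "structure": [[["drug_pct", "plga_pct"], [2, 2]]]
    }
  },
  "selection": {
    "constraints": [
      ["size_um", "<=", 25.0],
      ["ee_pct", ">=", 70.0],
      ["uniformity", "<=", 0.4]
    ],
    "grid_resolution": 5,
    "ranking": ["ee_pct", "maximize"]
  },
  "surfaces": [
    ["size_um", ["plga_pct", "speed_rpm"]],
    ["uniformity", ["pva_pct"]],
    ["uniformity", ["dilution_ratio"]],
    ["ee_pct", ["ow_ratio"]],
    ["dl_pct", ["drug_pct", "plga_pct"]]
  ]
}
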
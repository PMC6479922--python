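{
  "schema_version": 1,
  "flavor": "sugeno",
  "t_norm": "product",
  "inputs": [
    {
      "name": "rANGVx",
      "range": [-120.0, 110.0],
      "mfs": [
        {"name": "i_rest", "shape": "triangle", "params": [-120.0, -50.0, 10.0]},
        {"name": "i_flexion", "shape": "triangle", "params": [-10.0, 15.0, 25.0]},
        {"name": "i_extension", "shape": "triangle", "params": [20.0, 60.0, 110.0]}
      ]
    },
    {
      "name": "rANGx",
      "range": [-180.0, 15.0],
      "mfs": [
        {"name": "i_rest_down", "shape": "triangle", "params": [-180.0, -175.0, -140.0]},
        {"name": "i_move", "shape": "trapezoid", "params": [-150.0, -140.5, -19.9994, -9.98]},
        {"name": "i_rest_up", "shape": "triangle", "params": [-14.999, 0.00043, 15.0]}
      ]
    }
  ],
  "rules": [
    {"antecedent": [0, 0], "consequent": {"kind": "linear", "coeffs": [0.0077, 0.1022, 0.913]}, "dummy": false, "name": "o_rest_down"},
    {"antecedent": [1, 1], "consequent": {"kind": "linear", "coeffs": [0.0008, 0.0002, 1.5907]}, "dummy": false, "name": "o_flexion"},
    {"antecedent": [0, 2], "consequent": {"kind": "linear", "coeffs": [-0.1899, 0.1779, 33.576]}, "dummy": false, "name": "o_rest_up"},
    {"antecedent": [2, 1], "consequent": {"kind": "linear", "coeffs": [-0.0019, -0.0011, 3.5074]}, "dummy": false, "name": "o_extension"},
    {"antecedent": [0, 1], "consequent": {"kind": "linear", "coeffs": [0.0181, -1.0772, -0.5743]}, "dummy": true, "name": "null_1"},
    {"antecedent": [1, 0], "consequent": {"kind": "linear", "coeffs": [-0.0009, -0.0012, 3.3421]}, "dummy": true, "name": "null_2"},
    {"antecedent": [1, 2], "consequent": {"kind": "linear", "coeffs": [-0.0266, 0.0076, 4.2697]}, "dummy": true, "name": "null_3"},
    {"antecedent": [2, 0], "consequent": {"kind": "linear", "coeffs": [-0.0118, 0.0475, 1.1785]}, "dummy": true, "name": "null_4"},
    {"antecedent": [2, 2], "consequent": {"kind": "linear", "coeffs": [0.0011, -0.0427, -4.9702]}, "dummy": true, "name": "null_5"}
  ],
  "metadata": {
    "exercise_id": "A",
    "feature_names": ["rANGVx", "rANGx"],
    "virtual_sentinel": -999.0,
    "virtual_range": [-0.5, 0.0],
    "description": "Published trained first-order Sugeno system for the shoulder flexion-extension exercise (inputs rANGVx, rANGx; 4 real rules + 5 dummy rules over the virtual motions)."
  }
}
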
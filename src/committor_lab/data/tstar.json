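{
 "L40_N40_xi1": {
  "tstar": 0.3775,
  "imbalance": -0.036106666666666565,
  "transitions": 1316,
  "n_split": 18,
  "run_length": 30000000,
  "bracket": [
   0.34,
   0.4
  ],
  "seed": 42,
  "criterion": "equal weight of n< and n>= n_split basins",
  "history": [
   {
    "T": 0.34,
    "w_dilute": 0.04827999999999999,
    "w_agg": 0.95172,
    "transitions": 384
   },
   {
    "T": 0.4,
    "w_dilute": 0.8193866666666667,
    "w_agg": 0.18061333333333332,
    "transitions": 1073
   },
   {
    "T": 0.37,
    "w_dilute": 0.3212666666666667,
    "w_agg": 0.6787333333333333,
    "transitions": 1283
   },
   {
    "T": 0.385,
    "w_dilute": 0.53552,
    "w_agg": 0.46448,
    "transitions": 1546
   },
   {
    "T": 0.3775,
    "w_dilute": 0.5180533333333333,
    "w_agg": 0.4819466666666667,
    "transitions": 1316
   }
  ]
 }
}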
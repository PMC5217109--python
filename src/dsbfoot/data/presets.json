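{
  "WT|Cas9-CRU": {
    "p_short": 0.01,
    "mu_long": 2.024541,
    "sigma_long": 1.025592,
    "lambda_long": 0.961329,
    "max_len": 150,
    "bin_targets": [
      0.57,
      0.23,
      0.15,
      0.05
    ]
  },
  "parp1parp2|Cas9-CRU": {
    "p_short": 0.066315,
    "mu_long": 2.931174,
    "sigma_long": 1.203653,
    "lambda_long": 0.250971,
    "max_len": 150,
    "bin_targets": [
      0.42,
      0.26,
      0.25,
      0.07
    ]
  },
  "ku80|Cas9-CRU": {
    "p_short": 0.95,
    "mu_long": 3.445543,
    "sigma_long": 0.756461,
    "lambda_long": 0.849467,
    "max_len": 150,
    "bin_targets": [
      0.2,
      0.18,
      0.4,
      0.22
    ]
  },
  "ku80parp1parp2|Cas9-CRU": {
    "p_short": 0.95,
    "mu_long": 3.343569,
    "sigma_long": 0.537737,
    "lambda_long": 0.806957,
    "max_len": 150,
    "bin_targets": [
      0.21,
      0.18,
      0.49,
      0.12
    ]
  },
  "WT|Cas9-PPO": {
    "p_short": 0.01,
    "mu_long": 2.434105,
    "sigma_long": 0.695806,
    "lambda_long": 0.766828,
    "max_len": 150,
    "bin_targets": [
      0.33,
      0.32,
      0.22,
      0.13
    ]
  },
  "parp1parp2|Cas9-PPO": {
    "p_short": 0.01,
    "mu_long": 2.472319,
    "sigma_long": 0.715509,
    "lambda_long": 0.602725,
    "max_len": 150,
    "bin_targets": [
      0.2727,
      0.2727,
      0.2424,
      0.2121
    ]
  },
  "ku80|Cas9-PPO": {
    "p_short": 0.019454,
    "mu_long": 3.67905,
    "sigma_long": 0.214404,
    "lambda_long": 0.239953,
    "max_len": 150,
    "bin_targets": [
      0.13,
      0.12,
      0.45,
      0.3
    ]
  },
  "ku80parp1parp2|Cas9-PPO": {
    "p_short": 0.95,
    "mu_long": 3.628978,
    "sigma_long": 0.678868,
    "lambda_long": 0.878974,
    "max_len": 150,
    "bin_targets": [
      0.14,
      0.13,
      0.44,
      0.29
    ]
  }
}
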
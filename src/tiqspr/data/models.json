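[
 {
  "id": 1,
  "response": "BP",
  "regressors": [
   "M2",
   "H",
   "HM",
   "F",
   "R",
   "SC",
   "GA",
   "N"
  ],
  "intercept": 130.938,
  "coefficients": {
   "M2": 7.083,
   "H": -58.424,
   "HM": 1.092,
   "F": -5.986,
   "R": 15.083,
   "SC": 2.502,
   "GA": 8.844,
   "N": 15.475
  },
  "n": 21,
  "r": 0.932,
  "R2": 0.869,
  "SE": 74.919,
  "F": 9.964,
  "RMSE": 63.633,
  "p": 0.0
 },
 {
  "id": 2,
  "response": "MR",
  "regressors": [
   "M1",
   "M2",
   "H",
   "HM",
   "F",
   "ABC",
   "R",
   "SC",
   "GA",
   "N"
  ],
  "intercept": -5.883,
  "coefficients": {
   "M1": 1.652,
   "M2": -1.391,
   "H": 8.146,
   "HM": -0.036,
   "F": 0.382,
   "ABC": 2.829,
   "R": -0.159,
   "SC": 0.037,
   "GA": 1.816,
   "N": -3.368
  },
  "n": 22,
  "r": 0.993,
  "R2": 0.985,
  "SE": 6.408,
  "F": 73.25,
  "RMSE": 4.531,
  "p": 0.0
 },
 {
  "id": 3,
  "response": "P",
  "regressors": [
   "M1",
   "M2",
   "H",
   "HM",
   "F",
   "ABC",
   "R",
   "SC",
   "GA",
   "N"
  ],
  "intercept": -2.012,
  "coefficients": {
   "M1": 0.991,
   "M2": -0.857,
   "H": 2.114,
   "HM": -0.015,
   "F": 0.186,
   "ABC": -2.21,
   "R": -0.134,
   "SC": 0.494,
   "GA": 0.88,
   "N": -0.336
  },
  "n": 21,
  "r": 0.996,
  "R2": 0.991,
  "SE": 2.057,
  "F": 111.297,
  "RMSE": 1.419,
  "p": 0.0
 },
 {
  "id": 4,
  "response": "MV",
  "regressors": [
   "M1",
   "M2",
   "H",
   "HM",
   "F",
   "ABC",
   "R",
   "SC",
   "GA",
   "N"
  ],
  "intercept": 0.829,
  "coefficients": {
   "M1": 20.337,
   "M2": -16.462,
   "H": 23.664,
   "HM": -0.284,
   "F": 3.643,
   "ABC": -76.508,
   "R": -4.307,
   "SC": 11.289,
   "GA": 7.629,
   "N": 0.173
  },
  "n": 22,
  "r": 0.988,
  "R2": 0.977,
  "SE": 24.554,
  "F": 46.274,
  "RMSE": 17.362,
  "p": 0.0
 },
 {
  "id": 5,
  "response": "E",
  "regressors": [
   "M1",
   "M2",
   "H",
   "HM",
   "F",
   "ABC",
   "R",
   "SC",
   "GA",
   "N"
  ],
  "intercept": 34.948,
  "coefficients": {
   "M1": -3.766,
   "M2": 2.66,
   "H": -1.387,
   "HM": 0.03,
   "F": -0.39,
   "ABC": 32.311,
   "R": 1.77,
   "SC": -3.034,
   "GA": -1.006,
   "N": -5.294
  },
  "n": 21,
  "r": 0.944,
  "R2": 0.892,
  "SE": 9.735,
  "F": 8.23,
  "RMSE": 6.718,
  "p": 0.001
 },
 {
  "id": 6,
  "response": "C",
  "regressors": [
   "M1",
   "M2",
   "H",
   "HM",
   "F",
   "ABC",
   "R",
   "SC",
   "GA",
   "N"
  ],
  "intercept": -115.791,
  "coefficients": {
   "M1": -1.752,
   "M2": 14.189,
   "H": -55.935,
   "HM": -0.063,
   "F": -1.712,
   "ABC": 263.177,
   "R": 3.817,
   "SC": -8.104,
   "GA": -34.905,
   "N": -70.874
  },
  "n": 21,
  "r": 0.993,
  "R2": 0.986,
  "SE": 59.764,
  "F": 68.631,
  "RMSE": 41.241,
  "p": 0.001
 },
 {
  "id": 7,
  "response": "MW",
  "regressors": [
   "M1",
   "M2",
   "H",
   "HM",
   "F",
   "ABC",
   "R",
   "SC",
   "GA",
   "N"
  ],
  "intercept": -17.309,
  "coefficients": {
   "M1": 8.481,
   "M2": -2.412,
   "H": 12.147,
   "HM": 0.056,
   "F": 0.32,
   "ABC": 60.661,
   "R": 1.641,
   "SC": 1.952,
   "GA": 2.1,
   "N": -32.396
  },
  "n": 21,
  "r": 0.996,
  "R2": 0.993,
  "SE": 18.435,
  "F": 133.996,
  "RMSE": 12.721,
  "p": 0.0
 }
]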
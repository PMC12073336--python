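{
  "name": "beverage_2015",
  "version": "v2015",
  "water_only_A": true,
  "letter_bands": [["B", 1], ["C", 5], ["D", 9], ["E", null]],
  "components": {
    "energy": {
      "polarity": "unfavorable",
      "unit": "kJ/100mL",
      "bands": [[0, 0], [30, 1], [60, 2], [90, 3], [120, 4], [150, 5], [180, 6], [210, 7], [240, 8], [270, 9]],
      "top_points": 10
    },
    "sugars": {
      "polarity": "unfavorable",
      "unit": "g/100mL",
      "bands": [[0, 0], [1.5, 1], [3.0, 2], [4.5, 3], [6.0, 4], [7.5, 5], [9.0, 6], [10.5, 7], [12.0, 8], [13.5, 9]],
      "top_points": 10
    },
    "satfat": {
      "polarity": "unfavorable",
      "unit": "g/100mL",
      "bands": [[1, 0], [2, 1], [3, 2], [4, 3], [5, 4], [6, 5], [7, 6], [8, 7], [9, 8], [10, 9]],
      "top_points": 10
    },
    "sodium": {
      "polarity": "unfavorable",
      "unit": "mg/100mL",
      "bands": [[90, 0], [180, 1], [270, 2], [360, 3], [450, 4], [540, 5], [630, 6], [720, 7], [810, 8], [900, 9]],
      "top_points": 10
    },
    "protein": {
      "polarity": "favorable",
      "unit": "g/100mL",
      "bands": [[1.6, 0], [3.2, 1], [4.8, 2], [6.4, 3], [8.0, 4]],
      "top_points": 5
    },
    "fiber": {
      "polarity": "favorable",
      "unit": "g/100mL",
      "bands": [[0.7, 0], [1.4, 1], [2.1, 2], [2.8, 3], [3.5, 4]],
      "top_points": 5
    },
    "fvl": {
      "polarity": "favorable",
      "unit": "%",
      "bands": [[40, 0], [60, 2], [80, 4]],
      "top_points": 10
    }
  }
}
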
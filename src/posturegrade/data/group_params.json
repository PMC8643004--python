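{
  "description": "Per-severity-class posture feature distributions (mean, SD) and group sizes of the reference PD cohort. F1-F6, F8 in degrees; F7 in percent of body height. Classes are MDS-UPDRS-III 3.13 scores 0-4.",
  "version": 1,
  "classes": {
    "0": {
      "n": 13,
      "features": {
        "F1": [3.2, 4.5],
        "F2": [0.7, 0.9],
        "F3": [26.5, 8.0],
        "F4": [18.7, 3.4],
        "F5": [8.4, 4.0],
        "F6": [31.1, 5.5],
        "F7": [20.2, 4.2],
        "F8": [14.2, 7.9]
      }
    },
    "1": {
      "n": 12,
      "features": {
        "F1": [5.8, 4.2],
        "F2": [1.1, 1.0],
        "F3": [34.0, 9.9],
        "F4": [20.7, 3.4],
        "F5": [9.8, 3.1],
        "F6": [31.9, 5.0],
        "F7": [22.1, 3.3],
        "F8": [19.8, 9.0]
      }
    },
    "2": {
      "n": 33,
      "features": {
        "F1": [9.4, 6.3],
        "F2": [2.3, 1.8],
        "F3": [42.6, 9.3],
        "F4": [23.9, 4.9],
        "F5": [11.9, 5.7],
        "F6": [36.0, 6.5],
        "F7": [25.2, 4.1],
        "F8": [25.5, 9.1]
      }
    },
    "3": {
      "n": 6,
      "features": {
        "F1": [10.3, 12.0],
        "F2": [4.3, 4.8],
        "F3": [47.8, 14.7],
        "F4": [25.3, 5.9],
        "F5": [13.2, 5.6],
        "F6": [37.7, 2.2],
        "F7": [26.8, 4.0],
        "F8": [29.2, 12.1]
      }
    },
    "4": {
      "n": 6,
      "features": {
        "F1": [10.3, 5.5],
        "F2": [2.3, 1.6],
        "F3": [54.5, 19.0],
        "F4": [41.8, 15.1],
        "F5": [25.8, 18.9],
        "F6": [39.7, 6.5],
        "F7": [46.7, 12.9],
        "F8": [20.8, 17.0]
      }
    }
  }
}
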
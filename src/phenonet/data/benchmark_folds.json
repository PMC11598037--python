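{
  "description": "Published five-fold cross-validation results of the RGB-D lettuce phenotyping benchmark: per-fold values (k1..k5) with the printed average and sample standard-deviation rows. Used as fixed input for the fold-aggregation regression checks.",
  "r2": {
    "fw": {"folds": [0.9747, 0.9736, 0.9740, 0.9734, 0.9701], "average": 0.9732, "std_dev": 0.0018},
    "dw": {"folds": [0.9736, 0.9730, 0.9774, 0.9740, 0.9716], "average": 0.9739, "std_dev": 0.0021},
    "h":  {"folds": [0.9396, 0.9382, 0.9421, 0.9467, 0.9455], "average": 0.9424, "std_dev": 0.0037},
    "d":  {"folds": [0.9263, 0.9300, 0.9242, 0.9455, 0.9078], "average": 0.9268, "std_dev": 0.0135},
    "la": {"folds": [0.9712, 0.9679, 0.9547, 0.9767, 0.9740], "average": 0.9689, "std_dev": 0.0086}
  },
  "mape": {
    "fw": {"folds": [0.0977, 0.1014, 0.1073, 0.1003, 0.0947], "average": 0.1003, "std_dev": 0.0047},
    "dw": {"folds": [0.1505, 0.1864, 0.1629, 0.1667, 0.1444], "average": 0.1622, "std_dev": 0.0163},
    "h":  {"folds": [0.0740, 0.0789, 0.0749, 0.0747, 0.0677], "average": 0.0740, "std_dev": 0.0040},
    "d":  {"folds": [0.0482, 0.0542, 0.0541, 0.0500, 0.0517], "average": 0.0516, "std_dev": 0.0026},
    "la": {"folds": [0.0783, 0.0959, 0.0997, 0.0780, 0.0802], "average": 0.0864, "std_dev": 0.0105}
  },
  "nrmse": {
    "fw": {"folds": [0.0388, 0.0387, 0.0388, 0.0395, 0.0431], "average": 0.0398, "std_dev": 0.0019},
    "dw": {"folds": [0.0365, 0.0430, 0.0328, 0.0417, 0.0394], "average": 0.0387, "std_dev": 0.0041},
    "h":  {"folds": [0.0620, 0.0579, 0.0555, 0.0547, 0.0583], "average": 0.0577, "std_dev": 0.0029},
    "d":  {"folds": [0.0504, 0.0515, 0.0533, 0.0454, 0.0578], "average": 0.0517, "std_dev": 0.0045},
    "la": {"folds": [0.0426, 0.0441, 0.0476, 0.0344, 0.0358], "average": 0.0409, "std_dev": 0.0056}
  },
  "detection": {
    "AP50:95": {"folds": [0.8829, 0.9013, 0.8875, 0.8971, 0.8716], "average": 0.8881, "std_dev": 0.0118},
    "AP50":    {"folds": [0.9899, 0.9999, 1.0, 0.9998, 1.0], "average": 0.9979, "std_dev": 0.0044},
    "AP75":    {"folds": [0.9846, 0.9930, 1.0, 0.9998, 0.9950], "average": 0.9945, "std_dev": 0.0063},
    "F1":      {"folds": [0.9501, 0.9617, 0.9564, 0.9606, 0.9494], "average": 0.9556, "std_dev": 0.0057},
    "AR":      {"folds": [0.9130, 0.9263, 0.9165, 0.9244, 0.9037], "average": 0.9168, "std_dev": 0.0091}
  },
  "segmentation": {
    "AP50:95": {"folds": [0.9002, 0.9060, 0.9028, 0.9059, 0.9058], "average": 0.9041, "std_dev": 0.0026},
    "AP50":    {"folds": [0.9899, 0.9999, 1.0, 0.9998, 1.0], "average": 0.9979, "std_dev": 0.0045},
    "AP75":    {"folds": [0.9846, 0.9999, 1.0, 0.9998, 1.0], "average": 0.9969, "std_dev": 0.0069},
    "F1":      {"folds": [0.9578, 0.9645, 0.9625, 0.9637, 0.9653], "average": 0.9628, "std_dev": 0.0030},
    "AR":      {"folds": [0.9280, 0.9316, 0.9278, 0.9302, 0.9330], "average": 0.9301, "std_dev": 0.0023}
  }
}
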
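"""Published reference values from the clinical benchmark this package
reproduces, used as fixed inputs by the acceptance checks.

These are printed results, not computed ones: the underlying clinic
dataset is not public, so the arithmetic identities they encode (metric
definitions, rank averaging, selection accounting) are what can be
verified offline.
"""

# nine classifiers x seven metrics (accuracy, TPR, TNR, balanced AUC,
# precision, F-score, G-mean) on the full dataset
FULL_DATA_METRICS = {
    "DT":       [0.5876, 0.6309, 0.5360, 0.5834, 0.6184, 0.6246, 0.5815],
    "LDA":      [0.6861, 0.7584, 0.6000, 0.6792, 0.6933, 0.7244, 0.6746],
    "LR":       [0.6861, 0.7383, 0.6240, 0.6811, 0.7006, 0.7190, 0.6787],
    "NB":       [0.6642, 0.7785, 0.5280, 0.6533, 0.6629, 0.7160, 0.6411],
    "SVM":      [0.6898, 0.8188, 0.5360, 0.6774, 0.6778, 0.7416, 0.6625],
    "kNN":      [0.6934, 0.7517, 0.6240, 0.6878, 0.7044, 0.7273, 0.6849],
    "Ensemble": [0.7044, 0.8188, 0.5680, 0.6934, 0.6932, 0.7508, 0.6820],
    "SVM*":     [0.7226, 0.7919, 0.6400, 0.7160, 0.7239, 0.7564, 0.7119],
    "kNN*":     [0.7409, 0.8322, 0.6320, 0.7321, 0.7294, 0.7774, 0.7252],
}

# optimized-kNN row for the Hispanic group, plus that group's class sizes
HISPANIC_KNN_STAR = {"tpr": 0.6316, "tnr": 0.8939, "precision": 0.8372}
HISPANIC_CLASS_SIZES = {"rate_positive": 57, "rate_negative": 66}

# best-of-10-runs selection vector reported for the full dataset
# (31 bits, one per feature)
FULL_DATA_SELECTED_MASK = [
    0, 0, 1, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1, 1, 0, 0,
    0, 1, 1, 0, 1, 1, 1, 0, 1, 1, 1, 0, 0, 1, 1,
]

# before/after feature-selection accounting rows:
# (accuracy before, features before, accuracy after, features after)
IMPROVEMENT_ROWS = {
    "all":      (0.7409, 31, 0.7628, 18),
    "males":    (0.6987, 30, 0.7885, 11),
    "age_le50": (0.7431, 31, 0.8624, 15),
}
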
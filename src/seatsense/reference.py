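"""Published reference metrics of the clinical evaluation of this system.

These are the precision/recall/F1 values reported for the original
8-stroke-survivor evaluation of the pressure-distribution-based detector
(3 decimals as printed). They serve as consistency anchors: every printed
F1 must equal the harmonic mean of its printed precision and recall, and
every "average" cell the unweighted mean of its row, after half-up
rounding to 3 decimals.
"""

from __future__ import annotations

TASK_ORDER = ("back-and-forth", "side-to-side", "up-and-down")
CLASS_ORDER = ("NC", "TLF", "TR", "SE")

#: Binary compensation detection, per reaching task.
BINARY_REFERENCE = {
    "knn": {
        "precision": {"back-and-forth": 0.984, "side-to-side": 0.988, "up-and-down": 0.996},
        "recall": {"back-and-forth": 1.000, "side-to-side": 0.992, "up-and-down": 1.000},
        "f1": {"back-and-forth": 0.992, "side-to-side": 0.990, "up-and-down": 0.998},
        "average": {"precision": 0.989, "recall": 0.997, "f1": 0.993},
    },
    "svm": {
        "precision": {"back-and-forth": 0.988, "side-to-side": 0.996, "up-and-down": 0.996},
        "recall": {"back-and-forth": 1.000, "side-to-side": 0.979, "up-and-down": 1.000},
        "f1": {"back-and-forth": 0.994, "side-to-side": 0.987, "up-and-down": 0.998},
        "average": {"precision": 0.993, "recall": 0.993, "f1": 0.993},
    },
}

#: 4-class compensation-pattern recognition.
MULTICLASS_REFERENCE = {
    "knn": {
        "precision": {"NC": 0.986, "TLF": 0.987, "TR": 0.979, "SE": 0.979},
        "recall": {"NC": 0.993, "TLF": 0.954, "TR": 0.988, "SE": 0.983},
        "f1": {"NC": 0.989, "TLF": 0.970, "TR": 0.983, "SE": 0.981},
        "average": {"precision": 0.983, "recall": 0.980, "f1": 0.981},
    },
    "svm": {
        "precision": {"NC": 0.989, "TLF": 0.996, "TR": 0.975, "SE": 0.967},
        "recall": {"NC": 0.992, "TLF": 0.954, "TR": 0.992, "SE": 0.983},
        "f1": {"NC": 0.990, "TLF": 0.975, "TR": 0.983, "SE": 0.975},
        "average": {"precision": 0.982, "recall": 0.980, "f1": 0.981},
    },
}

#: Every per-task binary F1 exceeded this bound in the clinical evaluation.
F1_BOUND = 0.95
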
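"""Benchmark reference values for the golden-table checks.

Published reference results for the 13-class environment grid, the
scheme-comparison ratio tables and the in-text index accuracies that this
package reproduces.  Two printing artifacts in the source table are
corrected to the symmetric values the construction implies: the class-6
lower bound (printed with a dropped minus sign) and the class-13 progeny
count (printed 2.27 where symmetry gives 2.28).
"""

from __future__ import annotations

import numpy as np

# environment, x lower bound, x upper bound, proportion, x average,
# reference animals (N = 5000), progeny (n = 100)
TABLE1 = np.array(
    [
        [1, -np.inf, -2.00, 0.02, -2.37, 113.75, 2.28],
        [2, -2.00, -1.64, 0.03, -1.80, 140.66, 2.81],
        [3, -1.64, -1.27, 0.05, -1.44, 253.38, 5.07],
        [4, -1.27, -0.91, 0.08, -1.08, 400.47, 8.01],
        [5, -0.91, -0.55, 0.11, -0.72, 555.35, 11.11],
        [6, -0.55, -0.18, 0.14, -0.36, 675.71, 13.51],
        [7, -0.18, 0.18, 0.14, 0.00, 721.37, 14.43],
        [8, 0.18, 0.55, 0.14, 0.36, 675.71, 13.51],
        [9, 0.55, 0.91, 0.11, 0.72, 555.35, 11.11],
        [10, 0.91, 1.27, 0.08, 1.08, 400.47, 8.01],
        [11, 1.27, 1.64, 0.05, 1.44, 253.38, 5.07],
        [12, 1.64, 2.00, 0.03, 1.80, 140.66, 2.81],
        [13, 2.00, np.inf, 0.02, 2.37, 113.75, 2.28],
    ]
)

# (comparison, h2, reference size) -> (low, middle, high) response ratios,
# resilience breeding goal
TABLE3 = {
    ("GS/sib", 0.1, 5_000): (1.38, 1.22, 1.09),
    ("GS/sib", 0.1, 1_000_000): (2.40, 1.84, 1.36),
    ("GS/sib", 0.3, 5_000): (1.60, 1.37, 1.17),
    ("GS/sib", 0.3, 1_000_000): (2.17, 1.64, 1.19),
    ("GS/sib", 0.5, 5_000): (1.69, 1.40, 1.16),
    ("GS/sib", 0.5, 1_000_000): (2.11, 1.57, 1.11),
    ("GS/progeny", 0.1, 5_000): (1.23, 1.17, 1.10),
    ("GS/progeny", 0.1, 1_000_000): (2.14, 1.76, 1.37),
    ("GS/progeny", 0.3, 5_000): (1.47, 1.32, 1.18),
    ("GS/progeny", 0.3, 1_000_000): (1.99, 1.58, 1.19),
    ("GS/progeny", 0.5, 5_000): (1.55, 1.34, 1.16),
    ("GS/progeny", 0.5, 1_000_000): (1.94, 1.51, 1.11),
}

# (comparison, h2, reference size) -> (intercept ratio, slope ratio)
TABLE4 = {
    ("GS/sib", 0.1, 5_000): (1.22, -1.09),
    ("GS/sib", 0.1, 1_000_000): (1.84, -6.35),
    ("GS/sib", 0.3, 5_000): (1.37, -1.48),
    ("GS/sib", 0.3, 1_000_000): (1.64, -4.86),
    ("GS/sib", 0.5, 5_000): (1.40, -1.47),
    ("GS/sib", 0.5, 1_000_000): (1.57, -3.80),
    ("GS/progeny", 0.1, 5_000): (1.17, -54.84),
    ("GS/progeny", 0.1, 1_000_000): (1.76, -319.34),
    ("GS/progeny", 0.3, 5_000): (1.32, -3.60),
    ("GS/progeny", 0.3, 1_000_000): (1.58, -11.80),
    ("GS/progeny", 0.5, 5_000): (1.34, -2.59),
    ("GS/progeny", 0.5, 1_000_000): (1.51, -6.68),
}

# pseudo-BLUP index accuracies r_IH (male, female), proportional goal,
# basic parameters
ACCURACIES = {
    "genomic": (0.73, 0.73),
    "progeny": (0.90, 0.47),
    "sib": (0.45, 0.57),
}

# per-cell tolerances for the golden checks
TOL_TABLE1_ABS = 0.005
TOL_TABLE3_REL = 0.05
TOL_TABLE4_INT_REL = 0.05
TOL_TABLE4_SLOPE_REL = 0.15
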
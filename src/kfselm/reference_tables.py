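"""Published reference values from the original AD/CN connectivity study.

The screening method was developed on a 200-subject (100 AD, 100 CN)
resting-state fMRI cohort with 90 cerebrum regions (4005 edge features);
the raw data are access-restricted, but the study's printed summary tables
are reproducible arithmetic and are frozen here as inputs:

* ``HIGH_WEIGHT_EDGES`` — the 45 key connections with weight >= 6, as
  (region_i, region_j, weight) with 1-based region indices.  Where the
  printed region-name abbreviations disagree with the numeric indices, the
  numeric indices are authoritative (only they reproduce the region sums).
* ``REGION_WEIGHTS_MIN6`` — the corresponding 41 per-region sums (a
  region's weight is the sum of the weights of its incident connections).
* ``GROUP_ACCURACY_TABLE`` — the accuracy-by-weight-threshold table from
  the key-feature validation experiment (thresholds 0..12): feature count,
  percent of the 4005 features, and mean training / validation / test
  accuracy in percent.  Feeding it through the contribution analysis
  reproduces the study's per-weight-group contribution table.
"""

from __future__ import annotations

TOTAL_FEATURES = 4005
REGION_COUNT = 90

# (region_i, region_j, weight), 1-based region indices, weight >= 6
HIGH_WEIGHT_EDGES: list[tuple[int, int, int]] = [
    (56, 82, 12),
    (51, 68, 11), (84, 90, 11), (85, 87, 11),
    (5, 87, 10), (9, 11, 10), (56, 73, 10), (56, 84, 10),
    (2, 80, 9), (7, 11, 9), (51, 69, 9),
    (8, 12, 8), (50, 54, 8), (51, 67, 8), (51, 70, 8), (52, 68, 8),
    (52, 70, 8), (53, 54, 8), (56, 69, 8), (56, 90, 8), (82, 90, 8),
    (87, 89, 8),
    (1, 77, 7), (4, 84, 7), (8, 14, 7), (46, 68, 7), (51, 59, 7),
    (72, 82, 7),
    (4, 78, 6), (5, 70, 6), (5, 85, 6), (9, 13, 6), (11, 23, 6),
    (12, 38, 6), (50, 69, 6), (50, 70, 6), (53, 56, 6), (56, 68, 6),
    (56, 83, 6), (58, 61, 6), (68, 85, 6), (70, 73, 6), (70, 74, 6),
    (85, 90, 6), (86, 87, 6),
]

# region index -> summed weight over the 45 connections above (41 regions)
REGION_WEIGHTS_MIN6: dict[int, int] = {
    56: 66, 51: 43, 70: 40, 68: 38, 87: 35, 90: 33, 85: 29, 84: 28,
    82: 27, 11: 25, 69: 23, 5: 22, 50: 20, 9: 16, 52: 16, 54: 16,
    73: 16, 8: 15, 12: 14, 53: 14, 4: 13, 2: 9, 7: 9, 80: 9,
    67: 8, 89: 8, 1: 7, 14: 7, 46: 7, 59: 7, 72: 7, 77: 7,
    13: 6, 23: 6, 38: 6, 58: 6, 61: 6, 74: 6, 78: 6, 83: 6, 86: 6,
}

# threshold (weight >=) -> (feature count, percent of total,
#   train %, validation %, test %, test std as a fraction)
GROUP_ACCURACY_TABLE: dict[int, tuple[int, float, float, float, float, float]] = {
    0: (4005, 100.00, 100.00, 100.00, 95.33, 0.0035),
    1: (920, 22.97, 100.00, 100.00, 99.20, 0.0021),
    2: (397, 9.91, 100.00, 100.00, 96.92, 0.0057),
    3: (199, 4.97, 100.00, 100.00, 95.24, 0.0048),
    4: (109, 2.72, 100.00, 100.00, 93.33, 0.0074),
    5: (62, 1.55, 100.00, 100.00, 91.68, 0.0090),
    6: (45, 1.12, 100.00, 100.00, 87.84, 0.0106),
    7: (28, 0.70, 100.00, 99.75, 82.19, 0.0126),
    8: (22, 0.55, 100.00, 97.55, 75.27, 0.0195),
    9: (11, 0.27, 100.00, 92.70, 69.03, 0.0170),
    10: (8, 0.20, 100.00, 87.75, 60.14, 0.0359),
    11: (4, 0.10, 100.00, 81.65, 51.69, 0.0251),
    12: (1, 0.02, 58.05, 84.85, 55.34, 0.0140),
}


def group_accuracy_report():
    """The printed accuracy table as a :class:`FeatureGroupReport` (accuracy
    fractions), ready for the contribution analysis."""
    from .validation import FeatureGroupReport, GroupRow

    rows = [
        GroupRow(
            thr, count, pct,
            train / 100.0, val / 100.0, test / 100.0, std,
        )
        for thr, (count, pct, train, val, test, std) in sorted(
            GROUP_ACCURACY_TABLE.items()
        )
    ]
    return FeatureGroupReport(rows, TOTAL_FEATURES)
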
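"""Published reference values from a 35-participant free-living tri-monitor cohort.

These printed cohort numbers (mean min/day per 15-degree bin, split by
prolonged / non-prolonged / total sedentary bouts, to 0.1 min precision) are
used as arithmetic inputs for consistency checks — e.g. that the printed
prolonged and non-prolonged columns add to the printed total within printed
precision — and as the default study conditions of the synthetic generator.
They are not recomputed here: the underlying recordings are not deposited.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_bin_table",
    "additivity_gaps",
    "REFERENCE_FAMILY_ALPHA",
    "REFERENCE_N_CONTRASTS",
]

REFERENCE_FAMILY_ALPHA = 0.05
REFERENCE_N_CONTRASTS = 3

# joint, bin, prolonged, non_prolonged, total (mean min/day)
_ROWS = [
    ("knee", "<15", 16.3, 14.0, 30.3),
    ("knee", "15-30", 32.4, 28.6, 61.0),
    ("knee", "30-45", 33.6, 35.7, 69.2),
    ("knee", "45-60", 7.5, 17.6, 25.1),
    ("knee", "60-75", 26.3, 53.6, 79.8),
    ("knee", ">75", 71.7, 230.3, 302.0),
    ("hip", "<15", 11.8, 10.6, 22.4),
    ("hip", "15-30", 33.3, 26.6, 59.9),
    ("hip", "30-45", 37.1, 42.1, 79.2),
    ("hip", "45-60", 11.3, 21.3, 32.6),
    ("hip", "60-75", 31.4, 78.9, 110.4),
    ("hip", ">75", 53.0, 195.2, 248.2),
]


def reference_bin_table() -> pd.DataFrame:
    """Printed cohort bin-dwell table (mean min/day)."""
    return pd.DataFrame(
        _ROWS, columns=["joint", "bin", "prolonged", "non_prolonged", "total"]
    )


def additivity_gaps() -> pd.Series:
    """|prolonged + non_prolonged - total| per printed row (min/day)."""
    df = reference_bin_table()
    return (df["prolonged"] + df["non_prolonged"] - df["total"]).abs()
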
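"""Reference droplet tallies from the 15-image assay validation series.

For each validation image: the expert manual counts of overall and
fluorescent micro-droplets ("true"), and the counts produced by this
detection pipeline on the same frames ("detected"). These tallies are the
inputs to the concentration readout; the corresponding true/test
concentrations follow from :mod:`dropcount.concentration` with the default
30 um droplet diameter.
"""

from __future__ import annotations

import pandas as pd

# image id -> (overall, fluorescent)
TRUE_COUNTS: dict[int, tuple[int, int]] = {
    1: (161, 21),
    2: (222, 18),
    3: (221, 18),
    4: (223, 16),
    5: (219, 13),
    6: (229, 24),
    7: (250, 27),
    8: (239, 26),
    9: (245, 9),
    10: (381, 36),
    11: (372, 28),
    12: (381, 30),
    13: (347, 33),
    14: (414, 32),
    15: (358, 31),
}

DETECTED_COUNTS: dict[int, tuple[int, int]] = {
    1: (161, 21),
    2: (222, 18),
    3: (221, 18),
    4: (222, 17),
    5: (218, 13),
    6: (229, 24),
    7: (249, 27),
    8: (240, 26),
    9: (245, 9),
    10: (381, 36),
    11: (372, 28),
    12: (381, 30),
    13: (349, 35),
    14: (412, 32),
    15: (357, 31),
}


def validation_table() -> pd.DataFrame:
    """The validation tallies as a tidy DataFrame (one row per image)."""
    rows = []
    for i in sorted(TRUE_COUNTS):
        to, tf = TRUE_COUNTS[i]
        do, df_ = DETECTED_COUNTS[i]
        rows.append(
            {
                "image": i,
                "true_overall": to,
                "true_fluorescent": tf,
                "detected_overall": do,
                "detected_fluorescent": df_,
            }
        )
    return pd.DataFrame(rows)
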
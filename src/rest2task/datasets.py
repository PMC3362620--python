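"""Bundled worked-example data.

The motor-component scoring table below is the standard worked example used
throughout this package: the four raw identification parameters (dipole-fit
residual variance, mu/beta power ratio, and per-hemisphere template distance
and pattern correlation) for the 15 independent components of one subject's
motor-imagery decomposition.  Distances are on a mm scale, residual
variance is stored as a fraction, and components whose dipole fit failed
the 20% residual-variance gate carry NaN in the ranked columns.

Running :func:`rest2task.motor_ic.score_components` on this table must
reject components 11, 12, 13 and 15 and select component 5 (f = 6) as the
left and component 7 (f = 8) as the right motor component.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_NAN = np.nan

_SAMPLE_TABLE = {
    # component: (rv, power_ratio, dist_left, corr_left, dist_right, corr_right)
    1:  (0.022, 2.3, 88,  0.54, 92,  0.07),
    2:  (0.007, 1.3, 100, 0.58, 115, 0.81),
    3:  (0.013, 1.7, 90,  0.76, 111, 0.44),
    4:  (0.010, 1.8, 82,  0.18, 84,  0.14),
    5:  (0.031, 6.3, 21,  0.95, 67,  0.53),
    6:  (0.028, 2.1, 48,  0.42, 39,  0.30),
    7:  (0.025, 4.8, 71,  0.43, 11,  0.94),
    8:  (0.142, 2.8, 78,  0.27, 109, 0.08),
    9:  (0.064, 1.6, 131, 0.23, 123, 0.27),
    10: (0.078, 0.5, 60,  0.22, 117, 0.03),
    11: (0.546, _NAN, _NAN, _NAN, _NAN, _NAN),
    12: (0.323, _NAN, _NAN, _NAN, _NAN, _NAN),
    13: (0.534, _NAN, _NAN, _NAN, _NAN, _NAN),
    14: (0.102, 1.9, 80,  0.05, 103, 0.07),
    15: (0.787, _NAN, _NAN, _NAN, _NAN, _NAN),
}

#: published rank indices and motor-index values for the same subject,
#: used as frozen expected values in tests (NaN where rejected)
SAMPLE_EXPECTED = {
    "I_ratio_left":  [4, 10, 8, 7, 1, 5, 2, 3, 9, 11, _NAN, _NAN, _NAN, 6, _NAN],
    "I_ratio_right": [4, 10, 8, 7, 1, 5, 2, 3, 9, 11, _NAN, _NAN, _NAN, 6, _NAN],
    "I_dist_left":  [8, 10, 9, 7, 1, 2, 4, 5, 11, 3, _NAN, _NAN, _NAN, 6, _NAN],
    "I_corr_left":  [4, 3, 2, 10, 1, 6, 5, 7, 8, 9, _NAN, _NAN, _NAN, 11, _NAN],
    "f_left":       [36, 53, 45, 45, 6, 22, 21, 28, 59, 40, _NAN, _NAN, _NAN, 41, _NAN],
    "I_dist_right": [5, 9, 8, 4, 3, 2, 1, 7, 11, 10, _NAN, _NAN, _NAN, 6, _NAN],
    "I_corr_right": [9, 2, 4, 7, 3, 5, 1, 8, 6, 11, _NAN, _NAN, _NAN, 10, _NAN],
    "f_right":      [32, 49, 44, 33, 14, 21, 8, 35, 57, 63, _NAN, _NAN, _NAN, 40, _NAN],
}

SAMPLE_REJECTED = (11, 12, 13, 15)
SAMPLE_SELECTED = {"left": 5, "right": 7}


def sample_ic_parameters() -> pd.DataFrame:
    """The worked-example scoring table as a DataFrame indexed by component.

    Columns: ``rv`` (fraction), ``power_ratio``, ``dist_left``/``dist_right``
    (mm), ``corr_left``/``corr_right``.
    """
    df = pd.DataFrame.from_dict(
        _SAMPLE_TABLE,
        orient="index",
        columns=["rv", "power_ratio", "dist_left", "corr_left", "dist_right", "corr_right"],
    )
    df.index.name = "component"
    return df
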
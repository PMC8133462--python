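"""Air Quality Index categorization.

China's Ministry of Environmental Protection maps the 0-500 AQI scale to six
official air-quality levels. The level, rather than the raw index, is what
regular weather reports broadcast, so it is the unit of the main level-dummy
analysis. "Good" (51-100) serves as the omitted benchmark level in all
regressions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Official categories: (upper inclusive bound, level name).
LEVEL_BOUNDS = [
    (50, "Excellent"),
    (100, "Good"),
    (150, "Slightly Polluted"),
    (200, "Moderately Polluted"),
    (300, "Heavily Polluted"),
    (np.inf, "Severely Polluted"),
]

LEVELS = [name for _, name in LEVEL_BOUNDS]

#: Level-indicator covariates used in regressions; "Good" is the omitted base.
DUMMY_LEVELS = ["Excellent", "Slightly Polluted", "Moderately Polluted",
                "Heavily Polluted", "Severely Polluted"]


def categorize(aqi):
    """Map AQI value(s) to the official level name(s).

    Accepts a scalar, array or Series; negative values raise.
    """
    arr = np.asarray(aqi, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ValueError("AQI values must be finite and non-negative")
    edges = [b for b, _ in LEVEL_BOUNDS[:-1]]
    idx = np.searchsorted(edges, arr, side="left")
    names = np.array(LEVELS, dtype=object)[idx]
    if arr.ndim == 0:
        return str(names)
    if isinstance(aqi, pd.Series):
        return pd.Series(names, index=aqi.index, name="level")
    return names


def level_dummies(levels, omit: str = "Good") -> pd.DataFrame:
    """Indicator columns for each official level except the omitted base.

    Columns are emitted for all non-base levels that could occur, in official
    order, even when absent from the data (all-zero columns are dropped by the
    design-matrix builder, not here).
    """
    levels = pd.Series(levels).astype(str)
    unknown = set(levels.unique()) - set(LEVELS)
    if unknown:
        raise ValueError(f"unknown AQI levels: {sorted(unknown)}")
    out = {}
    for name in LEVELS:
        if name == omit:
            continue
        out[name] = (levels == name).astype(float).to_numpy()
    return pd.DataFrame(out, index=levels.index)
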
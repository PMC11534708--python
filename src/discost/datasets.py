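"""Bundled example data.

`example_multiplier_table` encodes a published set of Indonesian
standard-of-living extra-cost multipliers (percent of typical per-capita
expenditure, Susenas 2019 round) by disability type, expenditure quintile
and severity threshold, with the non-significant cells blank. It serves as
a worked-example input for the poverty-line adjustment — the underlying
national microdata are restricted, so these printed percentages are data,
not something this package recomputes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .domains import DOMAINS, QUINTILES
from .sol import MultiplierTable

# rows: type -> {threshold -> (Q1..Q5)}; None = blank (not significant at 10%)
_EXAMPLE_CELLS = {
    "seeing": {
        "lower": (2.9, 4.3, 6.0, 7.4, 12.4),
        "higher": (4.9, 9.1, 12.0, 16.2, 22.4),
    },
    "hearing": {
        "lower": (4.7, 5.7, 9.0, 9.4, 14.3),
        "higher": (8.3, 9.4, 11.0, 9.3, 21.9),
    },
    "walking": {
        "lower": (None, None, None, 8.5, 11.8),
        "higher": (None, 6.1, None, 8.8, 19.6),
    },
    "remembering": {
        "lower": (None, 13.2, 9.3, 13.4, 22.1),
        "higher": (None, 9.7, 17.6, 13.5, 18.6),
    },
    "communicating": {
        "lower": (None, 11.4, None, 7.6, 19.8),
        "higher": (None, 19.4, 11.7, 16.4, 16.9),
    },
    "selfcare": {
        "lower": (None, 11.4, None, 7.6, 19.8),
        "higher": (None, None, None, None, 18.4),
    },
}


def example_multiplier_table(include_bottom40: bool = True) -> MultiplierTable:
    """The example per-quintile multiplier table, optionally with pooled B40 rows.

    The published source states its poverty adjustment uses bottom-40%
    (Q1+Q2) multipliers per type; since only per-quintile cells are
    printed, the bundled B40 row takes the Q1 cell when populated, else Q2
    (the poorer available cell — conservative), else stays blank.
    """
    rows = []
    for dtype in DOMAINS:
        for threshold in ("lower", "higher"):
            cells = _EXAMPLE_CELLS[dtype][threshold]
            for q, pct in zip(QUINTILES, cells):
                rows.append(
                    {
                        "type": dtype,
                        "quintile": f"Q{q}",
                        "threshold": threshold,
                        "percent": np.nan if pct is None else pct,
                        "e_hat": np.nan,
                        "p_value": np.nan,
                        "n_obs": np.nan,
                        "n_disabled": np.nan,
                        "blank": pct is None,
                    }
                )
            if include_bottom40:
                b40 = next((p for p in cells[:2] if p is not None), None)
                rows.append(
                    {
                        "type": dtype,
                        "quintile": "B40",
                        "threshold": threshold,
                        "percent": np.nan if b40 is None else b40,
                        "e_hat": np.nan,
                        "p_value": np.nan,
                        "n_obs": np.nan,
                        "n_disabled": np.nan,
                        "blank": b40 is None,
                    }
                )
    return MultiplierTable(pd.DataFrame(rows))
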
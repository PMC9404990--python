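"""Small shared helpers."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd


def percent(count: float, total: float, decimals: int = 2) -> float:
    """Percentage truncated toward zero at ``decimals`` places.

    Truncation (not rounding) is used so that reported shares never overstate
    a class; e.g. 1571 of 3616 gives 43.44, not 43.45.
    """
    if total <= 0:
        return 0.0
    scale = 10 ** decimals
    return float(np.trunc(100.0 * count / total * scale) / scale)


def percentage_table(counts: Mapping[str, int], total: int | None = None,
                     decimals: int = 2) -> pd.DataFrame:
    """Counts plus percentages over ``total`` (default: sum of counts).

    This is the summarizer behind the per-family TIP table and the SNP
    effect-category table; percentages are truncated toward zero at
    ``decimals`` places (see :func:`percent`).
    """
    if total is None:
        total = int(sum(counts.values()))
    rows = [(k, int(v), percent(v, total, decimals)) for k, v in counts.items()]
    return pd.DataFrame(rows, columns=["label", "count", "percent"]).set_index("label")

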
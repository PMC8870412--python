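"""Shared statistical helpers."""
from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with NaN pass-through.

    NaN entries (untested hypotheses) are excluded from the family and
    returned as NaN; the remaining values are adjusted with the usual
    m*p/i cumulative-minimum rule, capped at 1 and never below the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
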
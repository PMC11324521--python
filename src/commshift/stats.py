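"""Shared statistical helpers: BH adjustment and Fisher p-value combination."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

TINY = np.finfo(float).tiny


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (jointly over the vector)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(p: np.ndarray) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi2(2k). Zero p's are clamped to tiny."""
    p = np.clip(np.asarray(p, dtype=float), TINY, 1.0)
    stat, combined = sps.combine_pvalues(p, method="fisher")
    return float(combined)
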
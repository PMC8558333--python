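"""Divergence-time estimates for duplicated gene pairs from Ks values.

Under a molecular clock with synonymous substitution rate R per site per
year, two sequences that diverged T years ago accumulate Ks = 2RT synonymous
substitutions per synonymous site, so T = Ks / (2R).  The default rate is
1.5e-8 substitutions/site/year; times are reported in millions of years
(Mya).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_CLOCK_RATE", "divergence_time", "mean_pairwise_time", "date_table"]

#: Synonymous substitutions per site per year.
DEFAULT_CLOCK_RATE = 1.5e-8


def divergence_time(ks: float, rate: float = DEFAULT_CLOCK_RATE) -> float:
    """T = Ks / (2R), in millions of years."""
    if rate <= 0:
        raise ValueError("clock rate must be > 0")
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    return ks / (2.0 * rate) / 1e6


def mean_pairwise_time(
    ks_values, rate: float = DEFAULT_CLOCK_RATE
) -> tuple[float, float]:
    """Mean Ks over duplicated gene pairs and its divergence time (Mya)."""
    ks = np.asarray(ks_values, dtype=float)
    if ks.size == 0:
        raise ValueError("need at least one Ks record")
    mean_ks = float(ks.mean())
    return mean_ks, divergence_time(mean_ks, rate)


def date_table(records: pd.DataFrame, rate: float = DEFAULT_CLOCK_RATE) -> pd.DataFrame:
    """Per-pair divergence times for a (gene_a, gene_b, ks) table, 2 d.p."""
    out = records.copy()
    out["t_mya"] = [round(divergence_time(k, rate), 2) for k in out["ks"]]
    return out
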
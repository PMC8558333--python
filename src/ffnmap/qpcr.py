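"""Relative expression by the 2^-ddCt method and group comparisons.

Threshold-cycle (Ct) tables carry one row per (sample, gene, biological
replicate, technical replicate).  Technical replicates are averaged first;
dCt normalizes a target gene to a reference gene within each sample and
biological replicate; ddCt subtracts the calibrator sample's mean dCt; the
fold change is 2^-ddCt under the method's assumption of perfect doubling per
cycle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "collapse_technical",
    "relative_expression",
    "summarize_folds",
    "compare_groups",
]

CT_COLUMNS = ["sample", "gene", "bio_rep", "tech_rep", "ct"]


def collapse_technical(records: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates within each (sample, gene, bio_rep).

    Returns one row per biological replicate with the arithmetic mean Ct, its
    SD (0 for a single replicate) and the number of technical replicates.
    """
    missing = set(CT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    if records.duplicated(subset=["sample", "gene", "bio_rep", "tech_rep"]).any():
        raise ValueError("duplicate (sample, gene, bio_rep, tech_rep) rows")
    grouped = records.groupby(["sample", "gene", "bio_rep"], sort=True)["ct"]
    out = grouped.agg(ct="mean", ct_sd=lambda x: float(np.std(x, ddof=0)), n_tech="size")
    return out.reset_index()


def relative_expression(
    collapsed: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str,
) -> pd.DataFrame:
    """2^-ddCt fold changes of ``target`` relative to ``reference``.

    ``collapsed`` is the output of :func:`collapse_technical` (or any table
    with columns sample, gene, bio_rep, ct).  dCt is computed per (sample,
    bio_rep) as Ct_target - Ct_reference; ddCt subtracts the calibrator
    sample's mean dCt, so the calibrator's (geometric mean) fold change is 1
    by construction.
    """
    t = collapsed[collapsed["gene"] == target][["sample", "bio_rep", "ct"]]
    r = collapsed[collapsed["gene"] == reference][["sample", "bio_rep", "ct"]]
    if t.empty:
        raise ValueError(f"no Ct rows for target gene {target!r}")
    merged = t.merge(r, on=["sample", "bio_rep"], suffixes=("_target", "_ref"), how="left")
    no_ref = merged["ct_ref"].isna()
    if no_ref.any():
        bad = sorted(merged.loc[no_ref, "sample"].unique())
        raise ValueError(f"missing reference gene {reference!r} for samples {bad}")
    merged["delta_ct"] = merged["ct_target"] - merged["ct_ref"]
    cal = merged.loc[merged["sample"] == calibrator, "delta_ct"]
    if cal.empty:
        raise ValueError(f"calibrator sample {calibrator!r} absent")
    merged["delta_delta_ct"] = merged["delta_ct"] - cal.mean()
    merged["fold_change"] = 2.0 ** (-merged["delta_delta_ct"])
    return merged[
        ["sample", "bio_rep", "delta_ct", "delta_delta_ct", "fold_change"]
    ].reset_index(drop=True)


def summarize_folds(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean fold change and SE across biological replicates."""
    grouped = expression.groupby("sample", sort=True)["fold_change"]
    out = grouped.agg(
        fold_mean="mean",
        fold_se=lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
        n_bio="size",
    )
    return out.reset_index()


def compare_groups(group_a, group_b, test: str = "t") -> float:
    """Two-sided p-value comparing two groups of fold changes.

    ``t`` is the Welch unequal-variance t test; ``wmw`` is the
    Wilcoxon-Mann-Whitney rank-sum test, exact when the combined sample size
    is at most 20 and tie-free, otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if test == "t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t test needs at least two values per group")
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("zero variance in both groups; t test undefined")
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "wmw":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("wmw needs at least one value per group")
        combined = np.concatenate([a, b])
        ties = len(np.unique(combined)) < len(combined)
        method = "exact" if (len(combined) <= 20 and not ties) else "asymptotic"
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    raise ValueError(f"unknown test {test!r}")
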
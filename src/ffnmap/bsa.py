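"""Bulked-segregant mapping: pool allele frequencies, delta-SNP index,
sliding-window smoothing and peak detection.

Given per-SNP read counts for an early- and a late-flowering pool, the
delta-SNP index at each SNP is the difference in the late-parent-allele
frequency between the pools.  Away from the causal locus the two bulks are
random draws from the F2 and the index is ~0; at a locus driving pool
membership it approaches +/-1.  Window means over a 3 Mb sliding window
advanced in 1 Mb steps reproduce the genome scan from which the peak is read.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "read_pool_counts",
    "pool_allele_frequency",
    "delta_index",
    "window_smooth",
    "detect_peaks",
    "peaks_to_frame",
]

COUNT_COLUMNS = ["chrom", "pos", "pool", "ref_count", "alt_count"]


@dataclasses.dataclass(frozen=True)
class Peak:
    """A run of contiguous outlier windows, ranked by max |mean delta|."""

    chromosome: str
    window_start_bp: int
    window_end_bp: int
    mean_delta: float
    rank: int


def read_pool_counts(path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a per-SNP, per-pool allele count table from TSV or VCF.

    TSV columns: ``chrom, pos, pool, ref_count, alt_count``.  Malformed rows
    (non-numeric or negative counts, missing fields) are skipped and counted
    in a warning.  VCF mode expects one sample per pool carrying an ``AD``
    FORMAT field (ref depth, alt depth); a record without AD is an error.
    Rows are returned sorted by (chrom, pos, pool).
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(COUNT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"count table missing columns {sorted(missing)}")
        df = df[COUNT_COLUMNS].copy()
        for col in ("pos", "ref_count", "alt_count"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = (
            df[["pos", "ref_count", "alt_count"]].isna().any(axis=1)
            | (df["ref_count"] < 0)
            | (df["alt_count"] < 0)
            | (df["pos"] < 1)
        )
        if bad.any():
            logger.warning("skipped %d malformed count rows", int(bad.sum()))
        df = df[~bad].copy()
        for col in ("pos", "ref_count", "alt_count"):
            df[col] = df[col].astype(np.int64)
    elif fmt == "vcf":
        import pysam

        rows = []
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for name, sample in rec.samples.items():
                    ad = sample.get("AD")
                    if ad is None or ad[0] is None:
                        raise ValueError(
                            f"missing AD for sample {name} at {rec.chrom}:{rec.pos}"
                        )
                    rows.append((rec.chrom, rec.pos, name, int(ad[0]), int(ad[1])))
        df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    dup = df.duplicated(subset=["chrom", "pos", "pool"])
    if dup.any():
        raise ValueError("duplicate (chrom, pos, pool) rows in count table")
    return df.sort_values(["chrom", "pos", "pool"], kind="stable").reset_index(drop=True)


def pool_allele_frequency(counts: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Per-pool alt-allele (late-parent) frequency, f = alt / (ref + alt).

    SNPs with depth below ``min_depth`` in a pool get a missing frequency
    there and drop out of the delta index.  Requires exactly the pool labels
    'early' and 'late'.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    pools = set(counts["pool"].unique())
    if pools != {"early", "late"}:
        raise ValueError(f"expected pools {{'early', 'late'}}, found {sorted(pools)}")
    wide = counts.pivot_table(
        index=["chrom", "pos"],
        columns="pool",
        values=["ref_count", "alt_count"],
        aggfunc="first",
    )
    out = pd.DataFrame(index=wide.index)
    for pool in ("early", "late"):
        depth = wide[("ref_count", pool)] + wide[("alt_count", pool)]
        f = wide[("alt_count", pool)] / depth
        f[depth < min_depth] = np.nan
        out[f"f_{pool}"] = f
        out[f"depth_{pool}"] = depth
    return out.reset_index().sort_values(["chrom", "pos"]).reset_index(drop=True)


def delta_index(freqs: pd.DataFrame) -> pd.DataFrame:
    """Signed delta-SNP index per SNP: delta = f_early - f_late.

    SNPs missing in either pool are dropped.
    """
    ok = freqs["f_early"].notna() & freqs["f_late"].notna()
    out = freqs.loc[ok, ["chrom", "pos"]].copy()
    out["delta"] = (freqs.loc[ok, "f_early"] - freqs.loc[ok, "f_late"]).astype(float)
    return out.reset_index(drop=True)


def window_smooth(
    deltas: pd.DataFrame,
    window_bp: int = 3_000_000,
    step_bp: int = 1_000_000,
    min_snps: int = 5,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean delta in half-open windows ``[start, start + window_bp)``.

    Windows are anchored at position 1 on each chromosome and advanced in
    ``step_bp`` steps; the final window is truncated at the chromosome end
    (the last SNP position when lengths are not supplied).  Windows holding
    fewer than ``min_snps`` SNPs are reported with a missing mean.
    """
    if not (window_bp >= step_bp >= 1):
        raise ValueError("need window_bp >= step_bp >= 1")
    cols = ["chrom", "window_start_bp", "window_end_bp", "n_snps", "mean_delta"]
    if len(deltas) == 0:
        warnings.warn("empty delta table; returning empty window table")
        return pd.DataFrame(columns=cols)
    d = deltas.sort_values(["chrom", "pos"], kind="stable")
    rows = []
    for chrom, sub in d.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        val = sub["delta"].to_numpy()
        length = int(chrom_lengths[chrom]) if chrom_lengths else int(pos.max())
        start = 1
        while start <= length:
            end = min(start + window_bp, length + 1)  # half-open
            i0 = int(np.searchsorted(pos, start, side="left"))
            i1 = int(np.searchsorted(pos, end, side="left"))
            n = i1 - i0
            mean = float(np.mean(val[i0:i1])) if n >= min_snps else np.nan
            rows.append((chrom, start, end, n, mean))
            start += step_bp
    return pd.DataFrame(rows, columns=cols)


def _threshold(values: np.ndarray, method: str, z: float, q: float) -> tuple[float, float]:
    """Outlier threshold on |mean delta| values; returns (threshold, spread)."""
    if method == "zscore":
        mu, spread = float(values.mean()), float(values.std(ddof=0))
        return mu + z * spread, spread
    if method == "robust_zscore":
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med))) * 1.4826
        return med + z * mad, mad
    if method == "quantile":
        return float(np.quantile(values, q)), float(values.std(ddof=0))
    raise ValueError(f"unknown peak method {method!r}")


def detect_peaks(
    windows: pd.DataFrame,
    method: str = "zscore",
    z: float = 3.0,
    q: float = 0.99,
) -> list[Peak]:
    """Call peaks as runs of contiguous windows with outlying |mean delta|.

    A window is flagged when |mean_delta| >= genome-wide mean + z * SD of
    |mean_delta| (or the robust median/MAD variant, or a plain quantile cut).
    When the spread degenerates to zero the rule falls back to flagging
    windows with |mean_delta| > 0.  Contiguous flagged windows on a chromosome
    merge into one peak spanning their union; peaks are ranked by their
    maximum |mean_delta|, ties resolved leftmost-first.
    """
    if len(windows) == 0:
        raise ValueError("empty window table")
    finite = windows["mean_delta"].notna()
    if not finite.any():
        raise ValueError("all window means are missing")
    absvals = windows.loc[finite, "mean_delta"].abs().to_numpy()
    thr, spread = _threshold(absvals, method, z, q)
    flags = np.zeros(len(windows), dtype=bool)
    if spread == 0:
        flags[finite.to_numpy()] = absvals > 0
    else:
        flags[finite.to_numpy()] = absvals >= thr
    peaks = []
    chrom_order = list(dict.fromkeys(windows["chrom"]))
    for chrom in chrom_order:
        sub = windows[windows["chrom"] == chrom].reset_index(drop=True)
        fl = flags[(windows["chrom"] == chrom).to_numpy()]
        i = 0
        while i < len(sub):
            if not fl[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and fl[j + 1]:
                j += 1
            run = sub.iloc[i : j + 1]
            best = run.loc[run["mean_delta"].abs().idxmax()]
            peaks.append(
                (
                    chrom,
                    int(run["window_start_bp"].min()),
                    int(run["window_end_bp"].max()),
                    float(best["mean_delta"]),
                    chrom_order.index(chrom),
                )
            )
            i = j + 1
    peaks.sort(key=lambda p: (-abs(p[3]), p[4], p[1]))
    return [
        Peak(chromosome=c, window_start_bp=s, window_end_bp=e, mean_delta=m, rank=r + 1)
        for r, (c, s, e, m, _) in enumerate(peaks)
    ]


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in peaks])
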
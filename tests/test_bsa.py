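"""Delta-SNP index, windowing and peak calling."""

import numpy as np
import pandas as pd
import pytest

from ffnmap import bsa, io
from ffnmap.pipeline import run_bsa_simulation, qtl_in_top_peak
from ffnmap.simulate import (
    PoolSpec,
    QtlModel,
    SeqNoiseModel,
    simulate_cross,
    simulate_pool_counts,
)


def _counts_frame(rows):
    return pd.DataFrame(rows, columns=bsa.COUNT_COLUMNS)


class TestReadPoolCounts:
    def test_tsv_roundtrip_sorted(self, tmp_path):
        df = _counts_frame(
            [("chr02", p, pool, 10, 5) for p in (300, 100, 200) for pool in ("early", "late")]
        )
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t", index=False)
        out = bsa.read_pool_counts(path)
        assert len(out) == 6
        assert list(out["pos"][::2]) == [100, 200, 300]

    def test_malformed_rows_skipped(self, tmp_path, caplog):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "chrom\tpos\tpool\tref_count\talt_count\n"
            "chr01\t100\tearly\t10\t5\n"
            "chr01\t200\tearly\t-3\t5\n"  # negative count
            "chr01\tNA\tearly\t1\t2\n"  # unparsable position
        )
        with caplog.at_level("WARNING"):
            out = bsa.read_pool_counts(path)
        assert len(out) == 1
        assert "skipped 2" in caplog.text

    def test_vcf_allele_depths(self, tmp_path, small_map):
        df = _counts_frame(
            [
                ("chr01", 100, "early", 12, 8),
                ("chr01", 100, "late", 9, 3),
                ("chr01", 900, "early", 7, 0),
                ("chr01", 900, "late", 0, 11),
            ]
        )
        path = tmp_path / "pools.vcf"
        io.write_pool_counts_vcf(df, path, small_map)
        out = bsa.read_pool_counts(path, fmt="vcf")
        merged = out.merge(df, on=["chrom", "pos", "pool"], suffixes=("", "_in"))
        assert (merged["ref_count"] == merged["ref_count_in"]).all()
        assert (merged["alt_count"] == merged["alt_count_in"]).all()

    def test_vcf_missing_ad_is_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr01>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tearly\n"
            "chr01\t100\t.\tA\tT\t.\t.\t.\tGT\t./.\n"
        )
        with pytest.raises(ValueError, match="chr01:100"):
            bsa.read_pool_counts(path, fmt="vcf")


class TestFrequenciesAndDelta:
    def test_frequency_arithmetic_and_missing(self):
        counts = _counts_frame(
            [
                ("chr01", 100, "early", 30, 10),
                ("chr01", 100, "late", 0, 0),
                ("chr01", 500, "early", 50, 150),
                ("chr01", 500, "late", 20, 20),
            ]
        )
        freqs = bsa.pool_allele_frequency(counts, min_depth=10)
        row100 = freqs[freqs["pos"] == 100].iloc[0]
        assert row100["f_early"] == pytest.approx(0.25)
        assert np.isnan(row100["f_late"])
        row500 = freqs[freqs["pos"] == 500].iloc[0]
        assert row500["f_early"] == pytest.approx(0.75)
        assert row500["f_late"] == pytest.approx(0.5)

    def test_binomial_sampling_error_bound(self):
        """Estimated f at depth 200 lies within 3 binomial SEs of truth."""
        rng = np.random.default_rng(17)
        n, f, depth = 2000, 0.75, 200
        alt = rng.binomial(depth, f, n)
        counts = pd.concat(
            [
                _counts_frame(
                    [("chr01", i + 1, "early", depth - alt[i], alt[i]) for i in range(n)]
                ),
                _counts_frame([("chr01", i + 1, "late", 10, 10) for i in range(n)]),
            ]
        )
        freqs = bsa.pool_allele_frequency(counts, min_depth=10)
        se = np.sqrt(f * (1 - f) / depth)
        assert abs(freqs["f_early"].mean() - f) < 3 * se / np.sqrt(n)

    def test_delta_extremes_and_dropping(self):
        freqs = pd.DataFrame(
            {
                "chrom": ["chr01"] * 3,
                "pos": [100, 200, 300],
                "f_early": [1.0, 0.4, np.nan],
                "f_late": [0.0, 0.4, 0.5],
                "depth_early": [50, 50, 0],
                "depth_late": [50, 50, 50],
            }
        )
        deltas = bsa.delta_index(freqs)
        assert list(deltas["delta"]) == [1.0, 0.0]
        assert len(deltas) == 2

    def test_antisymmetric_under_pool_swap(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(50):
            for pool in ("early", "late"):
                rows.append(("chr01", (i + 1) * 1000, pool, rng.integers(5, 50), rng.integers(5, 50)))
        counts = _counts_frame(rows)
        swapped = counts.copy()
        swapped["pool"] = swapped["pool"].map({"early": "late", "late": "early"})
        d1 = bsa.delta_index(bsa.pool_allele_frequency(counts))
        d2 = bsa.delta_index(bsa.pool_allele_frequency(swapped))
        np.testing.assert_allclose(d1["delta"].to_numpy(), -d2["delta"].to_numpy())


def brute_force_windows(deltas, window_bp, step_bp, min_snps, chrom_lengths=None):
    """Naive per-window recomputation used as the windowing oracle."""
    rows = []
    d = deltas.sort_values(["chrom", "pos"], kind="stable")
    for chrom in sorted(d["chrom"].unique()):
        sub = d[d["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        val = sub["delta"].to_numpy()
        length = chrom_lengths[chrom] if chrom_lengths else int(pos.max())
        start = 1
        while start <= length:
            end = min(start + window_bp, length + 1)
            mask = (pos >= start) & (pos < end)
            n = int(mask.sum())
            mean = float(np.mean(val[mask])) if n >= min_snps else np.nan
            rows.append((chrom, start, end, n, mean))
            start += step_bp
    return pd.DataFrame(
        rows, columns=["chrom", "window_start_bp", "window_end_bp", "n_snps", "mean_delta"]
    )


def random_delta_table(rng, n=500):
    chroms = rng.choice(["chr01", "chr02", "chr03"], n)
    pos = np.zeros(n, dtype=int)
    frames = []
    for c in np.unique(chroms):
        m = int((chroms == c).sum())
        p = np.sort(rng.choice(np.arange(1, 30_000_000), m, replace=False))
        frames.append(pd.DataFrame({"chrom": c, "pos": p, "delta": rng.uniform(-1, 1, m)}))
    return pd.concat(frames, ignore_index=True)


class TestWindowSmooth:
    def test_worked_example(self):
        deltas = pd.DataFrame(
            {
                "chrom": ["chr01"] * 3,
                "pos": [500_000, 1_500_000, 2_500_000],
                "delta": [0.2, 0.4, 0.6],
            }
        )
        win = bsa.window_smooth(deltas, 3_000_000, 1_000_000, min_snps=1)
        first = win.iloc[0]
        assert (first["window_start_bp"], first["window_end_bp"]) == (1, 2_500_001)
        assert first["mean_delta"] == pytest.approx(0.4)

    def test_sparse_window_missing(self):
        deltas = pd.DataFrame({"chrom": ["chr01"], "pos": [100], "delta": [0.5]})
        win = bsa.window_smooth(deltas, 1000, 1000, min_snps=2, chrom_lengths={"chr01": 3000})
        assert win["mean_delta"].isna().all()
        assert (win["n_snps"] >= 0).all()

    def test_empty_table_warns(self):
        with pytest.warns(UserWarning):
            win = bsa.window_smooth(pd.DataFrame(columns=["chrom", "pos", "delta"]))
        assert win.empty

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            deltas = random_delta_table(rng)
            got = bsa.window_smooth(deltas, 3_000_000, 1_000_000, min_snps=3)
            want = brute_force_windows(deltas, 3_000_000, 1_000_000, 3)
            pd.testing.assert_frame_equal(got, want, check_exact=True)

    def test_window_mean_bounded_by_members(self):
        rng = np.random.default_rng(5)
        deltas = random_delta_table(rng, 300)
        win = bsa.window_smooth(deltas, 2_000_000, 1_000_000, min_snps=1)
        for _, row in win.dropna(subset=["mean_delta"]).iterrows():
            sub = deltas[
                (deltas["chrom"] == row["chrom"])
                & (deltas["pos"] >= row["window_start_bp"])
                & (deltas["pos"] < row["window_end_bp"])
            ]["delta"]
            assert sub.min() - 1e-12 <= row["mean_delta"] <= sub.max() + 1e-12

    def test_interior_snp_counted_in_expected_windows(self):
        """Away from edges each SNP falls in ceil(window/step) windows."""
        deltas = pd.DataFrame(
            {"chrom": ["chr01"], "pos": [10_500_000], "delta": [0.3]}
        )
        win = bsa.window_smooth(
            deltas, 3_000_000, 1_000_000, min_snps=1, chrom_lengths={"chr01": 30_000_000}
        )
        containing = win[
            (win["window_start_bp"] <= 10_500_000) & (win["window_end_bp"] > 10_500_000)
        ]
        assert (containing["n_snps"] == 1).sum() == 3


class TestDetectPeaks:
    def test_degenerate_single_window(self):
        one = pd.DataFrame(
            {
                "chrom": ["chr01"],
                "window_start_bp": [1],
                "window_end_bp": [1_000_001],
                "n_snps": [10],
                "mean_delta": [0.4],
            }
        )
        peaks = bsa.detect_peaks(one)
        assert len(peaks) == 1 and peaks[0].rank == 1
        zero = one.assign(mean_delta=[0.0])
        assert bsa.detect_peaks(zero) == []

    def test_all_missing_is_error(self):
        win = pd.DataFrame(
            {
                "chrom": ["chr01"],
                "window_start_bp": [1],
                "window_end_bp": [1_000_001],
                "n_snps": [0],
                "mean_delta": [np.nan],
            }
        )
        with pytest.raises(ValueError):
            bsa.detect_peaks(win)

    def test_simulated_qtl_recovered(self):
        run = run_bsa_simulation(seed=1)
        assert qtl_in_top_peak(run)
        assert abs(run.peaks[0].mean_delta) > 0.8

    def test_null_pools_only_weak_peaks(self):
        """Random (phenotype-blind) pools never produce strong peaks.

        Linkage makes window deltas long-range correlated, so a mean+3SD
        threshold does flag occasional weak runs under the null; what
        distinguishes a real locus is the magnitude of the peak delta.
        """
        gmap = run_bsa_simulation(seed=0).gmap
        qtl = QtlModel.default_for(gmap)
        for s in range(15):
            ss = np.random.SeedSequence(s).generate_state(4)
            pop = simulate_cross(gmap, qtl, "F2", 297, seed=int(ss[0]) % 2**31)
            perm = np.random.default_rng(int(ss[1]) % 2**31).permutation(297)
            early = PoolSpec(tuple(sorted(int(i) for i in perm[:30])), "early")
            late = PoolSpec(tuple(sorted(int(i) for i in perm[30:60])), "late")
            counts = pd.concat(
                [
                    simulate_pool_counts(gmap, pop, early, SeqNoiseModel(100, 0.01, int(ss[2]) % 2**31)),
                    simulate_pool_counts(gmap, pop, late, SeqNoiseModel(100, 0.01, int(ss[3]) % 2**31)),
                ],
                ignore_index=True,
            )
            deltas = bsa.delta_index(bsa.pool_allele_frequency(counts))
            windows = bsa.window_smooth(deltas, chrom_lengths=gmap.lengths)
            peaks = bsa.detect_peaks(windows)
            assert all(abs(p.mean_delta) < 0.5 for p in peaks)
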
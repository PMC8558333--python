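"""End-to-end convenience workflows tying the simulator to the analyses."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import bsa, segregation
from .simulate import (
    GeneticMap,
    QtlModel,
    SeqNoiseModel,
    default_map,
    ffn_vector,
    select_extreme_pools,
    simulate_cross,
    simulate_pool_counts,
)

__all__ = ["BsaRun", "run_bsa_simulation", "qtl_in_top_peak", "segregation_ratio_study"]


@dataclasses.dataclass
class BsaRun:
    gmap: GeneticMap
    qtl: QtlModel
    population: list
    pools: tuple
    counts: pd.DataFrame
    windows: pd.DataFrame
    peaks: list


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def run_bsa_simulation(
    seed: int,
    n: int = 297,
    pool_size: int = 30,
    depth: float = 100.0,
    error_rate: float = 0.01,
    gmap: GeneticMap | None = None,
    qtl: QtlModel | None = None,
    window_bp: int = 3_000_000,
    step_bp: int = 1_000_000,
    min_depth: int = 10,
    min_snps: int = 5,
) -> BsaRun:
    """Simulate one F2 bulked-segregant experiment and map the locus.

    Defaults reproduce the study design: 297 F2 plants, extreme pools of 30,
    ~100x pooled depth with 1% allele-flip error, 500 kb-spaced informative
    SNPs over twelve 230 Mb chromosomes, 3 Mb windows in 1 Mb steps.
    """
    gmap = gmap if gmap is not None else default_map()
    qtl = qtl if qtl is not None else QtlModel.default_for(gmap)
    s_cross, s_early, s_late = _spawn_seeds(seed, 3)
    population = simulate_cross(gmap, qtl, "F2", n, seed=s_cross)
    early, late = select_extreme_pools(population, pool_size)
    counts = pd.concat(
        [
            simulate_pool_counts(
                gmap, population, early, SeqNoiseModel(depth, error_rate, s_early)
            ),
            simulate_pool_counts(
                gmap, population, late, SeqNoiseModel(depth, error_rate, s_late)
            ),
        ],
        ignore_index=True,
    )
    freqs = bsa.pool_allele_frequency(counts, min_depth=min_depth)
    deltas = bsa.delta_index(freqs)
    windows = bsa.window_smooth(
        deltas, window_bp, step_bp, min_snps, chrom_lengths=gmap.lengths
    )
    peaks = bsa.detect_peaks(windows)
    return BsaRun(gmap, qtl, population, (early, late), counts, windows, peaks)


def qtl_in_top_peak(run: BsaRun) -> bool:
    """Whether the rank-1 peak span contains the simulated locus position."""
    if not run.peaks:
        return False
    top = run.peaks[0]
    return (
        top.chromosome == run.qtl.chromosome
        and top.window_start_bp <= run.qtl.position_bp < top.window_end_bp
    )


def segregation_ratio_study(
    n_replicates: int,
    seed: int,
    n: int = 297,
    gmap: GeneticMap | None = None,
    qtl: QtlModel | None = None,
    expected_ratio: tuple[float, float] = (3, 1),
) -> pd.DataFrame:
    """Replicate the F2 segregation analysis: antimode, classes, 3:1 test.

    Each replicate simulates a fresh F2, finds the FFN histogram valley,
    classifies plants, and chi-square-tests late:early against the expected
    ratio.  Returns one row per replicate with the threshold, class counts,
    the late/early ratio and the test's statistic and p-value.
    """
    gmap = gmap if gmap is not None else default_map()
    qtl = qtl if qtl is not None else QtlModel.default_for(gmap)
    rows = []
    for child in _spawn_seeds(seed, n_replicates):
        population = simulate_cross(gmap, qtl, "F2", n, seed=child)
        ffn = ffn_vector(population)
        threshold = segregation.find_antimode(ffn)
        classes = segregation.classify_ffn(ffn, threshold)
        test = segregation.chi_square_ratio(
            (classes.n_late, classes.n_early), expected_ratio
        )
        rows.append(
            (
                child,
                threshold,
                classes.n_early,
                classes.n_late,
                classes.n_ambiguous,
                classes.n_late / classes.n_early,
                test.chi_square,
                test.p_value,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seed",
            "threshold",
            "n_early",
            "n_late",
            "n_ambiguous",
            "ratio",
            "chi_square",
            "p_value",
        ],
    )
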
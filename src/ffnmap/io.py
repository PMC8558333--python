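"""Plain-text readers and writers for the pipeline's tables.

Population tables, pool count tables and window/peak results travel as TSV;
pooled counts can additionally be exported as a minimal VCF whose two samples
(early, late) carry read depths in the AD FORMAT field, matching how
pool-seq allele depths are normally exchanged.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import F2Individual, GeneticMap

__all__ = [
    "write_population_tsv",
    "read_phenotypes",
    "write_pool_counts_tsv",
    "write_pool_counts_vcf",
]


def write_population_tsv(
    population: Sequence[F2Individual], gmap: GeneticMap, path
) -> None:
    """One row per individual: index, FFN, then a genotype column per SNP."""
    cols = [f"{c}:{p}" for c, p in zip(gmap.snp_chrom, gmap.snp_pos)]
    geno = pd.DataFrame(
        np.stack([ind.genotypes for ind in population]), columns=cols
    )
    geno.insert(0, "ffn", [ind.ffn for ind in population])
    geno.insert(0, "individual", np.arange(len(population)))
    geno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> np.ndarray:
    """FFN values from a TSV with at least 'individual' and 'ffn' columns."""
    df = pd.read_csv(path, sep="\t")
    if "ffn" not in df.columns:
        raise ValueError("phenotype table needs an 'ffn' column")
    return df["ffn"].to_numpy(dtype=int)


def write_pool_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_pool_counts_vcf(
    counts: pd.DataFrame, path, gmap: GeneticMap | None = None
) -> None:
    """Minimal VCF with one sample per pool and counts in AD.

    Ref/alt bases are synthetic placeholders (A/T): only the depths matter
    for the mapping analysis.
    """
    wide = counts.pivot_table(
        index=["chrom", "pos"],
        columns="pool",
        values=["ref_count", "alt_count"],
        aggfunc="first",
    )
    pools = sorted(counts["pool"].unique())
    lines = ["##fileformat=VCFv4.2", "##source=ffnmap"]
    if gmap is not None:
        for name, length in gmap.chromosomes:
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in dict.fromkeys(counts["chrom"]):
            lines.append(f"##contig=<ID={name}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pools))
    for (chrom, pos), row in wide.iterrows():
        fields = [str(chrom), str(int(pos)), ".", "A", "T", ".", ".", ".", "GT:AD"]
        for pool in pools:
            ref = int(row[("ref_count", pool)])
            alt = int(row[("alt_count", pool)])
            fields.append(f"./.:{ref},{alt}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
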
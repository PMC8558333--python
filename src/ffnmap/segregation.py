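"""Mendelian segregation analysis and CAPS marker prediction.

Covers the single-gene genetics around the flowering-time locus: finding the
valley ("low point") of the bimodal FFN histogram, classifying plants as
early/late flowering, chi-square goodness-of-fit against a 3:1 ratio,
marker-trait cosegregation counting, and in-silico restriction digestion of
CAPS amplicons (e.g. a TaiI assay distinguishing a start-codon SNP).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "ClassificationResult",
    "RatioTest",
    "CapsAssay",
    "CosegregationReport",
    "ENZYMES",
    "find_antimode",
    "classify_ffn",
    "chi_square_ratio",
    "chi_square_pvalue",
    "cosegregation",
    "digest_fragments",
    "caps_patterns",
    "load_enzyme_catalog",
]

#: Small default catalog of restriction enzymes: name -> (IUPAC site, cut offset
#: in bases from the site start).  TaiI (ACGT, cutting after the site) is the
#: enzyme used to score the start-codon SNP marker.
ENZYMES: dict[str, tuple[str, int]] = {
    "TaiI": ("ACGT", 4),
    "EcoRI": ("GAATTC", 1),
    "HindIII": ("AAGCTT", 1),
    "TaqI": ("TCGA", 1),
    "MseI": ("TTAA", 1),
}

_IUPAC = {code: set(bases) for code, bases in ambiguous_dna_values.items()}


@dataclasses.dataclass(frozen=True)
class ClassificationResult:
    """Per-individual early/late/ambiguous call at an FFN threshold."""

    labels: np.ndarray
    threshold: int

    @property
    def n_early(self) -> int:
        return int(np.sum(self.labels == "early"))

    @property
    def n_late(self) -> int:
        return int(np.sum(self.labels == "late"))

    @property
    def n_ambiguous(self) -> int:
        return int(np.sum(self.labels == "ambiguous"))


@dataclasses.dataclass(frozen=True)
class RatioTest:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    chi_square: float
    df: int
    p_value: float


@dataclasses.dataclass(frozen=True)
class CapsAssay:
    """Two allele versions of one amplicon plus the enzyme that splits them."""

    allele_seqs: Mapping[str, str]
    recognition_site: str
    cut_offset: int
    scan_reverse_complement: bool = False

    def __post_init__(self) -> None:
        if len(self.allele_seqs) != 2:
            raise ValueError("a CAPS assay needs exactly two allele sequences")


@dataclasses.dataclass(frozen=True)
class CosegregationReport:
    table: pd.DataFrame
    discordant: int
    n: int


def _histogram_runs(counts: np.ndarray) -> list[tuple[int, int, float]]:
    """Compress a histogram into runs of equal counts: (start, end, count)."""
    runs = []
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            runs.append((start, i - 1, float(counts[start])))
            start = i
    return runs


def find_antimode(phenos: Sequence[int], smooth_window: int = 3, depth_window: int = 5) -> int:
    """FFN threshold at the interior valley ("low point") of the histogram.

    The integer histogram is lightly smoothed with a moving average of width
    ``smooth_window`` (sparse F2 histograms have empty bins that would
    otherwise create spurious extrema), interior local minima between the
    outermost modes become candidate thresholds, and the deepest candidate
    wins, depth being the total raw count in a ``depth_window``-wide
    neighbourhood (a valley is a sparse *region*, not just one empty bin);
    ties resolve to the smaller value.  A histogram without an interior
    valley (e.g. monotone) is an error — pick a threshold by hand.
    """
    x = np.asarray(phenos, dtype=int)
    if x.size < 20:
        raise ValueError("need at least 20 individuals to locate the valley")
    if np.any(x < 1):
        raise ValueError("FFN values must be >= 1")
    for w in (smooth_window, depth_window):
        if w < 1 or w % 2 == 0:
            raise ValueError("smoothing windows must be positive odd integers")
    lo = int(x.min())
    counts = np.bincount(x - lo).astype(float)
    smoothed = np.convolve(counts, np.ones(smooth_window) / smooth_window, mode="same")
    depth = np.convolve(counts, np.ones(depth_window), mode="same")
    runs = _histogram_runs(smoothed)
    last = len(runs) - 1
    maxima = [
        (s, e, c)
        for k, (s, e, c) in enumerate(runs)
        if (k == 0 or runs[k - 1][2] < c) and (k == last or runs[k + 1][2] < c)
    ]
    minima = [
        (s, e, c)
        for k, (s, e, c) in enumerate(runs)
        if 0 < k < last and runs[k - 1][2] > c and runs[k + 1][2] > c
    ]
    if len(maxima) < 2:
        raise ValueError(
            "phenotype histogram has no interior valley; supply a threshold manually"
        )
    left_end, right_start = maxima[0][1], maxima[-1][0]
    candidates = sorted(
        {v for s, e, _ in minima for v in range(s, e + 1) if left_end < v < right_start}
    )
    if not candidates:
        raise ValueError(
            "phenotype histogram has no interior valley; supply a threshold manually"
        )
    best = candidates[int(np.argmin(depth[candidates]))]  # argmin: first -> smaller
    return int(best + lo)


def classify_ffn(phenos: Sequence[int], threshold: int) -> ClassificationResult:
    """Classify plants: early iff FFN < threshold, late iff FFN > threshold.

    Plants exactly at the threshold are 'ambiguous' and excluded from ratio
    tests (the observed early and late classes leave out the valley value).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    x = np.asarray(phenos, dtype=int)
    labels = np.where(x < threshold, "early", np.where(x > threshold, "late", "ambiguous"))
    return ClassificationResult(labels=labels, threshold=int(threshold))


def chi_square_ratio(
    observed: Sequence[int], expected_ratio: Sequence[float] = (3, 1)
) -> RatioTest:
    """Pearson chi-square goodness of fit to a Mendelian ratio.

    No continuity correction is applied; df = number of classes - 1 and the
    p-value is the upper tail of the chi-square distribution.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError("observed and expected_ratio must have the same length")
    if np.any(ratio <= 0):
        raise ValueError("expected ratio terms must be > 0")
    total = obs.sum()
    if total < 1:
        raise ValueError("need at least one observation")
    expected = total * ratio / ratio.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected count")
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = len(obs) - 1
    return RatioTest(
        observed=tuple(int(o) for o in obs),
        expected_ratio=tuple(float(r) for r in ratio),
        chi_square=chi2,
        df=df,
        p_value=chi_square_pvalue(chi2, df),
    )


def chi_square_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-square p-value for a precomputed statistic."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(statistic, df))


def cosegregation(
    marker_genotypes: Sequence[int],
    classes: ClassificationResult,
    early_genotype_code: int = 0,
) -> CosegregationReport:
    """Count discordance between a marker and the early/late classification.

    Discordant plants are early-flowering ones not homozygous for the early
    genotype code plus late-flowering ones that are.  Ambiguous plants are
    tabulated but never counted as discordant.
    """
    geno = np.asarray(marker_genotypes, dtype=int)
    if geno.shape[0] != classes.labels.shape[0]:
        raise ValueError("marker genotypes and classes have different lengths")
    if not np.isin(geno, [0, 1, 2]).all():
        raise ValueError("genotype codes must be in {0, 1, 2}")
    table = pd.crosstab(
        pd.Series(classes.labels, name="class"), pd.Series(geno, name="genotype")
    )
    early = classes.labels == "early"
    late = classes.labels == "late"
    discordant = int(np.sum(early & (geno != early_genotype_code))) + int(
        np.sum(late & (geno == early_genotype_code))
    )
    return CosegregationReport(table=table, discordant=discordant, n=len(geno))


def _matches(seq: str, site: str) -> list[int]:
    """Start positions of IUPAC site matches; overlapping matches allowed.

    Ambiguity codes in the site expand per IUPAC; ambiguity codes in the
    sequence never match (only A/C/G/T sequence characters can satisfy a
    site position).
    """
    m, w = len(seq), len(site)
    expansions = []
    for ch in site:
        if ch not in _IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in recognition site")
        expansions.append(_IUPAC[ch])
    out = []
    for i in range(m - w + 1):
        for j in range(w):
            c = seq[i + j]
            if c not in "ACGT" or c not in expansions[j]:
                break
        else:
            out.append(i)
    return out


def digest_fragments(
    sequence: str,
    recognition_site: str,
    cut_offset: int,
    scan_reverse_complement: bool = False,
) -> list[int]:
    """Predict restriction fragment lengths for one amplicon allele.

    Forward-strand cut coordinates are ``match_start + cut_offset`` (0-based,
    cutting before that base); with ``scan_reverse_complement`` the reverse
    complement is scanned too and its cuts mapped back to forward coordinates.
    Matching is case-insensitive.  Fragment lengths are consecutive
    differences of the cut coordinates including both sequence ends, so they
    always sum to the amplicon length.
    """
    if not sequence or not recognition_site:
        raise ValueError("sequence and recognition site must be non-empty")
    if not (0 <= cut_offset <= len(recognition_site)):
        raise ValueError("cut_offset must lie within the recognition site")
    seq = sequence.upper()
    site = recognition_site.upper()
    length = len(seq)
    cuts = {i + cut_offset for i in _matches(seq, site)}
    if scan_reverse_complement:
        rc = str(Seq(seq).reverse_complement())
        cuts |= {length - (j + cut_offset) for j in _matches(rc, site)}
    cuts = sorted(c for c in cuts if 0 < c < length)
    bounds = [0, *cuts, length]
    return [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]


def caps_patterns(assay: CapsAssay) -> dict:
    """Fragment patterns per genotype for a CAPS assay.

    Homozygote patterns come from digesting each allele sequence; the
    heterozygote lane shows the union of the two band sets.  The marker is
    informative iff the two homozygote patterns differ.
    """
    (name_a, seq_a), (name_b, seq_b) = assay.allele_seqs.items()
    if seq_a.upper() == seq_b.upper():
        warnings.warn("allele sequences are identical; marker is uninformative")
    frag_a = digest_fragments(
        seq_a, assay.recognition_site, assay.cut_offset, assay.scan_reverse_complement
    )
    frag_b = digest_fragments(
        seq_b, assay.recognition_site, assay.cut_offset, assay.scan_reverse_complement
    )
    return {
        name_a: sorted(frag_a),
        name_b: sorted(frag_b),
        "het": sorted(set(frag_a) | set(frag_b)),
        "informative": sorted(frag_a) != sorted(frag_b),
    }


def load_enzyme_catalog(path) -> dict[str, tuple[str, int]]:
    """Load an editable enzyme table (TSV: name, site, offset)."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "site": str, "offset": int})
    return {r["name"]: (r["site"], int(r["offset"])) for _, r in df.iterrows()}
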
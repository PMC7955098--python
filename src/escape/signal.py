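"""Signal quantification and fold-change statistics.

Covers read-count normalization (RPM and spike-in), heatmap matrices at
50-bp resolution around region centers, center-window ranking, average
profiles, per-region log2 fold changes, the one-sided Wilcoxon signed-rank
test (exact by enumeration for small tie-free samples, tie-corrected
normal approximation otherwise), and rounded percentage reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, ReadTrack, RegionSet

__all__ = [
    "NormalizationFactors",
    "SignalMatrix",
    "FoldChangeResult",
    "normalization_scale",
    "build_matrix",
    "region_intensities",
    "center_intensity",
    "center_intensities",
    "rank_regions",
    "average_profile",
    "log2_fold_changes",
    "wilcoxon_signed_rank",
    "percent_report",
]


@dataclass(frozen=True)
class NormalizationFactors:
    """Library and spike-in read counts defining a per-track scale factor."""

    library_reads: int
    spikein_reads: int = 0
    method: str = "RPM"

    def __post_init__(self) -> None:
        if self.method not in ("RPM", "spikein"):
            raise ValueError("method must be 'RPM' or 'spikein'")


def normalization_scale(
    factors: NormalizationFactors, reference_spikein: int | None = None
) -> float:
    """Multiplier turning raw read counts into normalized counts.

    RPM: 1e6 / library reads. Spike-in: the RPM scale times the ratio of
    reference to sample spike-in reads, so a sample that captured half the
    spike-in reads is scaled up two-fold relative to the reference.
    """
    if factors.library_reads <= 0:
        raise ValueError("library_reads must be > 0")
    rpm = 1e6 / factors.library_reads
    if factors.method == "RPM":
        return rpm
    if factors.spikein_reads <= 0:
        raise ValueError("spikein_reads must be > 0 for spike-in normalization")
    if reference_spikein is None or reference_spikein <= 0:
        raise ValueError("spike-in normalization requires reference_spikein > 0")
    return reference_spikein / factors.spikein_reads * rpm


@dataclass
class SignalMatrix:
    """Regions x bins matrix of normalized read counts around centers.

    Row ``r``, column ``j`` holds the scaled count of shifted read
    positions in bin ``j`` of the window ``[center - flank, center + flank)``
    of region ``r``. ``edge_flags`` marks rows whose window runs off the
    chromosome (those bins are zero-padded).
    """

    regions: RegionSet
    bin_bp: int
    flank_bp: int
    values: np.ndarray
    ranking_key: str = ""
    edge_flags: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def build_matrix(
    regions: RegionSet,
    track: ReadTrack,
    scale: float,
    bin_bp: int = 50,
    flank_bp: int = 2000,
    shift: int = 75,
    ranking_key: str = "",
) -> SignalMatrix:
    """Binned signal matrix around region centers at ``bin_bp`` resolution."""
    if flank_bp < 200:
        raise ValueError("flank_bp must be >= 200")
    if (2 * flank_bp) % bin_bp != 0:
        raise ValueError("bin_bp must divide 2*flank_bp")
    n_bins = 2 * flank_bp // bin_bp
    values = np.zeros((len(regions), n_bins))
    edge = np.zeros(len(regions), dtype=bool)
    for r, iv in enumerate(regions):
        lo = iv.center - flank_bp
        hi = iv.center + flank_bp
        chrom_len = track.genome.get(iv.chrom) if track.genome else None
        if lo < 0 or (chrom_len is not None and hi > chrom_len):
            edge[r] = True
        pos = track.shifted_positions(iv.chrom, shift)
        a = np.searchsorted(pos, lo, "left")
        b = np.searchsorted(pos, hi, "left")
        if b > a:
            bins = (pos[a:b] - lo) // bin_bp
            values[r] = np.bincount(bins, minlength=n_bins) * scale
    return SignalMatrix(regions, bin_bp, flank_bp, values,
                        ranking_key=ranking_key, edge_flags=edge)


def region_intensities(
    regions: RegionSet | Sequence[GenomicInterval],
    track: ReadTrack,
    scale: float,
    shift: int = 75,
) -> np.ndarray:
    """Scaled read count over each full region interval."""
    return track.counts_for(regions, shift=shift) * scale


def center_intensity(
    region: GenomicInterval,
    track: ReadTrack,
    scale: float,
    window: int = 400,
    shift: int = 75,
) -> float:
    """Scaled read count in the ``window``-bp window around the region center."""
    half = window // 2
    c = region.center
    return track.count_in(region.chrom, c - half, c + half, shift) * scale


def center_intensities(
    regions: RegionSet | Sequence[GenomicInterval],
    track: ReadTrack,
    scale: float,
    window: int = 400,
    shift: int = 75,
) -> np.ndarray:
    return np.array([
        center_intensity(iv, track, scale, window=window, shift=shift)
        for iv in regions
    ])


def rank_regions(intensities: np.ndarray) -> np.ndarray:
    """Permutation ordering regions by descending intensity, stable in ties."""
    x = np.asarray(intensities, dtype=float)
    return np.argsort(-x, kind="stable")


def average_profile(matrix: SignalMatrix) -> np.ndarray:
    """Per-bin mean signal across regions."""
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot average an empty matrix")
    return matrix.values.mean(axis=0)


def log2_fold_changes(
    regions: RegionSet,
    track_a: ReadTrack,
    track_b: ReadTrack,
    scale_a: float,
    scale_b: float,
    pseudocount: float = 1.0,
    shift: int = 75,
) -> np.ndarray:
    """Per-region log2((a*scale_a + pc) / (b*scale_b + pc))."""
    a = region_intensities(regions, track_a, scale_a, shift=shift)
    b = region_intensities(regions, track_b, scale_b, shift=shift)
    return np.log2((a + pseudocount) / (b + pseudocount))


@dataclass
class FoldChangeResult:
    """Result of a one-sided Wilcoxon signed-rank test on log ratios."""

    log2_ratios: np.ndarray
    n: int
    W_statistic: float
    p_value: float
    exact_flag: bool


def _exact_wplus_tail(ranks: np.ndarray, w_obs: float, alternative: str) -> float:
    """P(W+ >= w) ('greater') or P(W+ <= w) ('less') for integer ranks.

    Dynamic program over the 2^n equiprobable sign assignments: the
    distribution of W+ is the coefficient vector of prod_r (1 + z^r) / 2^n.
    """
    max_w = int(ranks.sum())
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:max_w + 1 - r]
        counts = counts + shifted
    total = counts.sum()
    w = int(round(w_obs))
    if alternative == "greater":
        return float(counts[w:].sum() / total)
    return float(counts[: w + 1].sum() / total)


def wilcoxon_signed_rank(
    x: Sequence[float] | np.ndarray,
    alternative: str = "greater",
    exact_max_n: int = 25,
) -> FoldChangeResult:
    """One-sided Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped (classic treatment). The exact null
    distribution of W+ is enumerated when n <= ``exact_max_n`` and the
    absolute values are tie-free; otherwise a normal approximation with
    tie-corrected variance and continuity correction is used, and
    ``exact_flag`` records which path ran.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    x = x[x != 0]
    if x.size == 0:
        raise ValueError("no nonzero differences")
    n = x.size
    absx = np.abs(x)
    ranks = stats.rankdata(absx)
    w_plus = float(ranks[x > 0].sum())
    has_ties = np.unique(absx).size < n
    if n <= exact_max_n and not has_ties:
        p = _exact_wplus_tail(ranks, w_plus, alternative)
        exact = True
    else:
        mu = n * (n + 1) / 4
        var = n * (n + 1) * (2 * n + 1) / 24
        _, tie_counts = np.unique(absx, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48
        sd = math.sqrt(var)
        if alternative == "greater":
            z = (w_plus - mu - 0.5) / sd
            p = float(stats.norm.sf(z))
        else:
            z = (w_plus - mu + 0.5) / sd
            p = float(stats.norm.cdf(z))
        exact = False
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return FoldChangeResult(log2_ratios=x, n=n, W_statistic=w_plus,
                            p_value=p, exact_flag=exact)


def percent_report(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if numerator > denominator:
        raise ValueError("numerator must be <= denominator")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))
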
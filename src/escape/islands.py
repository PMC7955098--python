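"""Window/gap Poisson island calling with control-based background and BH FDR.

Reads are binned into fixed windows; windows whose counts are improbably
high under a genome-wide Poisson background become eligible, eligible
windows are chained into islands across bounded gaps, and each island is
scored against the control track with a Poisson upper-tail test. Two
preset regimes mirror common practice for broad histone marks
(200-bp windows/gaps, FDR 1e-3) and narrow non-histone factors
(50-bp windows/gaps, FDR 1e-10).

The island background rate is the library-ratio-scaled control count,
floored by the control's local read density (over a window of at least
``local_bg_bp`` around the island) and by one scaled read. The local floor
stabilizes the rate estimate for short islands, where a chance-empty
control window would otherwise understate the background; every term is
linear in control reads, so the p-value is invariant to jointly rescaling
both library sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, ReadTrack, RegionSet

__all__ = [
    "IslandParams",
    "IslandCall",
    "HISTONE_PARAMS",
    "FACTOR_PARAMS",
    "window_counts",
    "poisson_upper_tail",
    "eligible_windows",
    "form_islands",
    "score_islands",
    "call_islands",
    "benjamini_hochberg",
    "top_n_by_significance",
]


@dataclass(frozen=True)
class IslandParams:
    """Parameters of one island-calling regime.

    ``window_w``/``gap_g`` are in bp and the gap must be a multiple of the
    window. ``eligibility_p`` is the single-window Poisson tail threshold
    for a window to seed an island; ``effective_genome_fraction`` scales
    the mappable genome when estimating the background read density;
    ``fragment_shift`` moves each read 5' end toward 3' by half an assumed
    fragment length before counting.
    """

    window_w: int
    gap_g: int
    fdr_alpha: float
    eligibility_p: float = 0.20
    effective_genome_fraction: float = 0.8
    fragment_shift: int = 75
    local_bg_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.window_w < 1:
            raise ValueError("window_w must be >= 1")
        if self.gap_g < 0 or self.gap_g % self.window_w != 0:
            raise ValueError("gap_g must be >= 0 and a multiple of window_w")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if not 0 < self.effective_genome_fraction <= 1:
            raise ValueError("effective_genome_fraction must be in (0, 1]")


#: Broad histone-mark regime (H3K4me1, H3K27ac).
HISTONE_PARAMS = IslandParams(window_w=200, gap_g=200, fdr_alpha=1e-3)
#: Narrow non-histone factor regime (SWI/SNF subunits, TFs, ATAC).
FACTOR_PARAMS = IslandParams(window_w=50, gap_g=50, fdr_alpha=1e-10)


@dataclass
class IslandCall:
    """One called enriched region with its evidence."""

    interval: GenomicInterval
    chip_reads: int
    control_reads: int
    score: float
    p_value: float
    q_value: float = math.nan


def window_counts(
    track: ReadTrack, w: int, genome: Mapping[str, int], shift: int = 0
) -> dict[str, np.ndarray]:
    """Per-chromosome vector of read counts in consecutive ``w``-bp windows.

    Window ``i`` covers ``[i*w, (i+1)*w)``; counts on a chromosome sum to
    the number of reads on it.
    """
    if w < 1:
        raise ValueError("window width must be >= 1")
    out: dict[str, np.ndarray] = {}
    for chrom, length in genome.items():
        n_win = -(-length // w)
        pos = track.shifted_positions(chrom, shift)
        if pos.size == 0:
            out[chrom] = np.zeros(n_win, dtype=np.int64)
        else:
            out[chrom] = np.bincount(pos // w, minlength=n_win).astype(np.int64)
    return out


def poisson_upper_tail(k: int | np.ndarray, lam: float) -> float | np.ndarray:
    """P(X >= k) for X ~ Poisson(lam); equals 1 at k=0 and decreases in k."""
    if lam <= 0:
        raise ValueError("Poisson rate must be > 0")
    return stats.poisson.sf(np.asarray(k) - 1, lam)[()]


def eligible_windows(
    counts: np.ndarray, lam_background: float, eligibility_p: float
) -> np.ndarray:
    """Windows whose count has Poisson tail probability < ``eligibility_p``.

    Implemented as a count threshold: the smallest k with
    P(X >= k) < eligibility_p under the background rate.
    """
    if lam_background <= 0:
        raise ValueError("background rate must be > 0")
    # isf gives the smallest k with sf(k) < p, i.e. P(X >= k+1) < p.
    k_thresh = int(stats.poisson.isf(eligibility_p, lam_background)) + 1
    return np.asarray(counts) >= k_thresh


def form_islands(
    eligible: np.ndarray, w: int, g: int, chrom: str = "chr1"
) -> RegionSet:
    """Chain eligible windows into islands allowing internal gaps <= ``g`` bp.

    Islands are maximal runs of eligible windows in which any internal run
    of ineligible windows spans at most ``g`` bases; islands separated by
    more than ``g`` bases of ineligible windows stay distinct.
    """
    if g % w != 0:
        raise ValueError("gap must be a multiple of the window size")
    idx = np.flatnonzero(np.asarray(eligible, dtype=bool))
    if idx.size == 0:
        return RegionSet([], name="islands")
    max_gap_windows = g // w
    breaks = np.flatnonzero(np.diff(idx) - 1 > max_gap_windows)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    ivs = [
        GenomicInterval(chrom, int(idx[a]) * w, (int(idx[b]) + 1) * w)
        for a, b in zip(starts, ends)
    ]
    return RegionSet(ivs, name="islands")


def benjamini_hochberg(
    p_values: Sequence[float] | np.ndarray,
    alpha: float,
    tiebreak: Sequence[tuple] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, q-values) in input order.

    q-values are monotone non-decreasing along the sorted p-values and the
    rejection set is a prefix of that order. Ties are resolved by a stable
    sort on ``(p, *tiebreak)`` when a tiebreak key is supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if tiebreak is not None:
        order = sorted(range(p.size), key=lambda i: (p[i], *tiebreak[i]))
        order = np.asarray(order)
    else:
        order = np.argsort(p, kind="stable")
    n = p.size
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    passed = p[order] <= np.arange(1, n + 1) / n * alpha
    reject_sorted = np.zeros(n, dtype=bool)
    if passed.any():
        reject_sorted[: int(np.flatnonzero(passed)[-1]) + 1] = True
    reject = np.empty(n, dtype=bool)
    qvals = np.empty(n)
    reject[order] = reject_sorted
    qvals[order] = q_sorted
    return reject, qvals


def _island_lambda(
    island: GenomicInterval,
    control: ReadTrack,
    ratio: float,
    params: IslandParams,
    genome: Mapping[str, int],
) -> tuple[float, int]:
    """Background rate for one island, in chip-scaled read units."""
    length = len(island)
    c_island = control.count_in(island.chrom, island.start, island.end,
                                params.fragment_shift)
    half_extra = max(params.local_bg_bp - length, 0) // 2
    lo = max(island.start - half_extra, 0)
    hi = min(island.end + half_extra, genome[island.chrom])
    c_local = control.count_in(island.chrom, lo, hi, params.fragment_shift)
    local_rate = c_local / max(hi - lo, 1) * length
    lam_control_units = max(c_island, local_rate, 1.0)
    return lam_control_units * ratio, c_island


def score_islands(
    islands: RegionSet,
    chip: ReadTrack,
    control: ReadTrack | None,
    params: IslandParams,
    genome: Mapping[str, int],
) -> list[IslandCall]:
    """Score candidate islands against the control and filter by FDR.

    Each island's p-value is the Poisson upper tail of its chip read count
    at the control-derived background rate; q-values are Benjamini-Hochberg
    over all candidate islands and the output keeps q < ``fdr_alpha``.
    Without a control, the background is the chip genome-wide density over
    the effective genome.
    """
    if chip.n_reads == 0:
        warnings.warn("chip track has zero reads; no islands called", stacklevel=2)
        return []
    genome_len = sum(genome.values())
    chip_density = chip.library_size / (params.effective_genome_fraction * genome_len)
    ratio = (chip.library_size / control.library_size
             if control is not None and control.library_size > 0 else None)

    calls: list[IslandCall] = []
    log_p: list[float] = []
    w = params.window_w
    for iv in islands:
        pos = chip.shifted_positions(iv.chrom, params.fragment_shift)
        a = int(np.searchsorted(pos, iv.start, "left"))
        b = int(np.searchsorted(pos, iv.end, "left"))
        k = b - a
        if control is not None and ratio is not None:
            lam, c_reads = _island_lambda(iv, control, ratio, params, genome)
        else:
            lam, c_reads = chip_density * len(iv), 0
            lam = max(lam, 1e-9)
        lp = float(stats.poisson.logsf(k - 1, lam))
        # Island score: per-window -ln Poisson tail summed over occupied windows.
        lam_w = lam * w / len(iv)
        if k > 0:
            wc = np.bincount((pos[a:b] - iv.start) // w)
            wc = wc[wc > 0]
            score = float(-stats.poisson.logsf(wc - 1, lam_w).sum())
        else:
            score = 0.0
        calls.append(IslandCall(iv, chip_reads=k, control_reads=c_reads,
                                score=score, p_value=float(np.exp(lp))))
        log_p.append(lp)

    if not calls:
        return []
    p = np.exp(np.asarray(log_p))
    tiebreak = [(c.interval.chrom, c.interval.start) for c in calls]
    _, q = benjamini_hochberg(p, params.fdr_alpha, tiebreak=tiebreak)
    out = []
    for c, qv in zip(calls, q):
        c.q_value = float(qv)
        if c.q_value < params.fdr_alpha:
            out.append(c)
    return out


def call_islands(
    chip: ReadTrack,
    control: ReadTrack | None,
    params: IslandParams,
    genome: Mapping[str, int],
) -> list[IslandCall]:
    """Full pipeline: bin, select eligible windows, chain, score, filter."""
    if chip.n_reads == 0:
        warnings.warn("chip track has zero reads; no islands called", stacklevel=2)
        return []
    genome_len = sum(genome.values())
    lam_w = (chip.library_size / (params.effective_genome_fraction * genome_len)
             * params.window_w)
    counts = window_counts(chip, params.window_w, genome, params.fragment_shift)
    candidates: list[GenomicInterval] = []
    for chrom in genome:
        elig = eligible_windows(counts[chrom], lam_w, params.eligibility_p)
        for iv in form_islands(elig, params.window_w, params.gap_g, chrom):
            end = min(iv.end, genome[chrom])
            candidates.append(GenomicInterval(chrom, iv.start, end))
    return score_islands(RegionSet(candidates), chip, control, params, genome)


def islands_to_regions(calls: Sequence[IslandCall], name: str = "",
                       genome: Mapping[str, int] | None = None) -> RegionSet:
    """Called islands as a region set carrying scores."""
    ivs = [replace(c.interval, score=c.score) for c in calls]
    return RegionSet(ivs, name=name,
                     genome=dict(genome) if genome else None).sorted()


def top_n_by_significance(calls: Sequence[IslandCall], n: int = 3000) -> RegionSet:
    """The ``n`` most significant islands by q-value.

    Ties are broken deterministically by (score descending, chrom, start).
    """
    ranked = sorted(
        calls,
        key=lambda c: (c.q_value, -c.score, c.interval.chrom, c.interval.start),
    )
    ivs = [replace(c.interval, score=c.score) for c in ranked[:n]]
    return RegionSet(ivs, name="top_significant")
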
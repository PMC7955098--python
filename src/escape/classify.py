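"""Chromatin-state classification and SWI/SNF complex assignment.

Regions are classified by overlap with promoters (TSS +/- 1 kb) and with
H3K4me1/H3K27ac islands into promoter, active enhancer (H3K4me1+ H3K27ac+
promoter-distal), primed enhancer (H3K4me1+ H3K27ac- promoter-distal) or
other. SWI/SNF sub-complex binding sites are defined by peak co-occupancy
anchored on SMARCA4 coordinates: BAF = SMARCA4+ SS18+ ARID1A+,
PBAF = SMARCA4+ ARID2+, GBAF = SMARCA4+ BRD9+.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import (
    GeneModel,
    GenomicInterval,
    RegionSet,
    merge_intervals,
    overlap_flags,
    subset_overlapping,
)

__all__ = [
    "EnhancerAnnotation",
    "STATES",
    "define_promoters",
    "classify_state",
    "classify_states",
    "assign_complexes",
    "venn_partition",
    "genomic_distribution",
]

#: Classification precedence: a region spanning several classes takes the
#: highest-precedence one it touches.
STATES = ("promoter", "active_enhancer", "primed_enhancer", "other")


@dataclass
class EnhancerAnnotation:
    """A region with its chromatin state, occupancy flags and complexes."""

    interval: GenomicInterval
    state: str
    occupancy: dict[str, bool] = field(default_factory=dict)
    complexes: frozenset[str] = frozenset()


def define_promoters(
    genes: Iterable[GeneModel],
    genome: Mapping[str, int],
    halfwidth: int = 1000,
) -> RegionSet:
    """Promoter regions: TSS +/- ``halfwidth``, clipped and merged."""
    ivs = []
    for g in genes:
        length = genome[g.chrom]
        start = max(g.tss - halfwidth, 0)
        end = min(g.tss + halfwidth, length)
        ivs.append(GenomicInterval(g.chrom, start, end))
    return merge_intervals(RegionSet(ivs, name="promoters", genome=dict(genome)))


def classify_states(
    regions: RegionSet,
    promoters: RegionSet,
    k4me1: RegionSet,
    k27ac: RegionSet,
) -> list[str]:
    """State label per region; promoter overlap takes precedence."""
    at_prom = overlap_flags(regions, promoters)
    has_k4 = overlap_flags(regions, k4me1)
    has_k27 = overlap_flags(regions, k27ac)
    out = []
    for p, k4, k27 in zip(at_prom, has_k4, has_k27):
        if p:
            out.append("promoter")
        elif k4 and k27:
            out.append("active_enhancer")
        elif k4:
            out.append("primed_enhancer")
        else:
            out.append("other")
    return out


def classify_state(
    region: GenomicInterval,
    promoters: RegionSet,
    k4me1: RegionSet,
    k27ac: RegionSet,
) -> str:
    return classify_states(RegionSet([region]), promoters, k4me1, k27ac)[0]


def assign_complexes(
    smarca4: RegionSet,
    ss18: RegionSet,
    arid1a: RegionSet,
    arid2: RegionSet,
    brd9: RegionSet,
) -> dict[str, RegionSet]:
    """BAF/PBAF/GBAF binding sites anchored on SMARCA4 coordinates.

    A SMARCA4 site may belong to several complexes; each returned set keeps
    the SMARCA4 peak coordinates.
    """
    baf = subset_overlapping(subset_overlapping(smarca4, ss18), arid1a)
    pbaf = subset_overlapping(smarca4, arid2)
    gbaf = subset_overlapping(smarca4, brd9)
    baf.name, pbaf.name, gbaf.name = "BAF", "PBAF", "GBAF"
    return {"BAF": baf, "PBAF": pbaf, "GBAF": gbaf}


def venn_partition(
    sets: Mapping[str, RegionSet], anchor: RegionSet
) -> Counter[frozenset[str]]:
    """Counts of anchor intervals per membership pattern over ``sets``.

    Each anchor interval contributes to exactly one pattern (the frozenset
    of set names it overlaps), so pattern counts sum to ``len(anchor)``.
    """
    flags = {name: overlap_flags(anchor, s) for name, s in sets.items()}
    patterns: Counter[frozenset[str]] = Counter()
    for i in range(len(anchor)):
        patterns[frozenset(n for n, f in flags.items() if f[i])] += 1
    return patterns


def genomic_distribution(
    calls: RegionSet,
    promoters: RegionSet,
    k4me1: RegionSet,
    k27ac: RegionSet,
) -> dict[str, float]:
    """Fraction of calls per state class; fractions sum to 1."""
    if len(calls) == 0:
        raise ValueError("empty input")
    labels = classify_states(calls, promoters, k4me1, k27ac)
    counts = Counter(labels)
    n = len(calls)
    return {state: counts.get(state, 0) / n for state in STATES}


def annotate_regions(
    regions: RegionSet,
    promoters: RegionSet,
    k4me1: RegionSet,
    k27ac: RegionSet,
    factor_sets: Mapping[str, RegionSet] | None = None,
) -> list[EnhancerAnnotation]:
    """Full annotation: state, per-factor occupancy flags, complexes."""
    states = classify_states(regions, promoters, k4me1, k27ac)
    occ: dict[str, np.ndarray] = {}
    if factor_sets:
        for name, s in factor_sets.items():
            occ[name] = overlap_flags(regions, s)
    out = []
    for i, (iv, state) in enumerate(zip(regions, states)):
        flags = {name: bool(v[i]) for name, v in occ.items()}
        complexes = set()
        if flags.get("SMARCA4"):
            if flags.get("SS18") and flags.get("ARID1A"):
                complexes.add("BAF")
            if flags.get("ARID2"):
                complexes.add("PBAF")
            if flags.get("BRD9"):
                complexes.add("GBAF")
        out.append(EnhancerAnnotation(iv, state, flags, frozenset(complexes)))
    return out
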
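"""Enhancer dynamics and dependency labels.

Temporal labels compare binding-site sets between an early and a late
timepoint (prebound vs de novo); adipogenic enhancers are active enhancers
bound by at least one lineage-determining factor (C/EBPb, C/EBPa, PPARg);
activation calls compare H3K27ac signal between a treated (ectopic
C/EBPb-expressing) and a control condition with a strict >2-fold rule;
dependency calls compare C/EBPb signal between control and
SMARCA4-depleted cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import ReadTrack, RegionSet, overlap_flags, subset_overlapping, union
from .signal import center_intensities, region_intensities

__all__ = [
    "ActivationParams",
    "classify_temporal",
    "define_adipogenic",
    "stratify_mll4",
    "call_activated_enhancers",
    "classify_smarca4_dependency",
    "partition_by_baf_prebinding",
]


@dataclass(frozen=True)
class ActivationParams:
    """Fold thresholds and pseudocount for activation/dependency calls.

    ``h3k27ac_fold`` is the strict treated/control ratio above which an
    enhancer counts as activated ("over 2-fold"); ``dependency_fold`` is
    the strict control/depleted ratio above which binding counts as
    reduced. The pseudocount (in normalized reads) keeps zero-signal
    ratios finite. Activation uses the normalized read count over the full
    enhancer interval; dependency uses the 400-bp center window that also
    orders the heat maps.
    """

    h3k27ac_fold: float = 2.0
    dependency_fold: float = 2.0
    pseudocount: float = 1.0
    center_window: int = 400
    fragment_shift: int = 75

    def __post_init__(self) -> None:
        if self.h3k27ac_fold <= 1 or self.dependency_fold <= 1:
            raise ValueError("fold thresholds must be > 1")


def classify_temporal(
    bound_late: RegionSet, bound_early: RegionSet
) -> tuple[RegionSet, RegionSet]:
    """Partition late binding sites into (prebound, de_novo).

    A late site overlapping any early site is prebound; the rest are de
    novo. The two outputs partition ``bound_late``.
    """
    flags = overlap_flags(bound_late, bound_early)
    pre = [iv for iv, f in zip(bound_late, flags) if f]
    de_novo = [iv for iv, f in zip(bound_late, flags) if not f]
    return (
        RegionSet(pre, name="prebound", genome=bound_late.genome),
        RegionSet(de_novo, name="de_novo", genome=bound_late.genome),
    )


def define_adipogenic(
    aes: RegionSet, cebpb: RegionSet, cebpa: RegionSet, pparg: RegionSet
) -> RegionSet:
    """Active enhancers bound by C/EBPb, C/EBPa or PPARg."""
    ldtf = union(cebpb, cebpa, pparg, name="LDTF")
    out = subset_overlapping(aes, ldtf)
    out.name = "adipogenic_enhancers"
    return out


def stratify_mll4(sites: RegionSet, mll4: RegionSet) -> tuple[RegionSet, RegionSet]:
    """Disjoint two-way partition of sites into (MLL4+, MLL4-)."""
    flags = overlap_flags(sites, mll4)
    pos = [iv for iv, f in zip(sites, flags) if f]
    neg = [iv for iv, f in zip(sites, flags) if not f]
    return (
        RegionSet(pos, name="MLL4_pos", genome=sites.genome),
        RegionSet(neg, name="MLL4_neg", genome=sites.genome),
    )


def _require_depth(track: ReadTrack, label: str) -> None:
    if track.n_reads == 0 or track.library_size == 0:
        raise ValueError(f"{label} track has zero depth")


def call_activated_enhancers(
    candidates: RegionSet,
    k27ac_treated: ReadTrack,
    k27ac_control: ReadTrack,
    required_flags: Mapping[str, RegionSet] | None = None,
    params: ActivationParams = ActivationParams(),
    scale_treated: float | None = None,
    scale_control: float | None = None,
) -> RegionSet:
    """Enhancers whose H3K27ac rises strictly more than ``h3k27ac_fold``.

    ``candidates`` should already be C/EBPb+ active enhancers;
    ``required_flags`` (typically SMARCA4/ARID1A/MLL4 peak sets) further
    restricts them before the fold rule. Signal is the normalized read
    count over each enhancer interval, plus a pseudocount on both sides of
    the ratio; a ratio of exactly the threshold is excluded.
    """
    _require_depth(k27ac_treated, "treated H3K27ac")
    _require_depth(k27ac_control, "control H3K27ac")
    kept = candidates
    if required_flags:
        for s in required_flags.values():
            kept = subset_overlapping(kept, s)
    if len(kept) == 0:
        return RegionSet([], name="activated", genome=candidates.genome)
    if scale_treated is None:
        scale_treated = 1e6 / k27ac_treated.library_size
    if scale_control is None:
        scale_control = 1e6 / k27ac_control.library_size
    t = region_intensities(kept, k27ac_treated, scale_treated,
                           shift=params.fragment_shift)
    c = region_intensities(kept, k27ac_control, scale_control,
                           shift=params.fragment_shift)
    ratio = (t + params.pseudocount) / (c + params.pseudocount)
    ivs = [iv for iv, r in zip(kept, ratio) if r > params.h3k27ac_fold]
    return RegionSet(ivs, name="activated", genome=candidates.genome)


def classify_smarca4_dependency(
    sites: RegionSet,
    cebpb_control: ReadTrack,
    cebpb_depleted: ReadTrack,
    params: ActivationParams = ActivationParams(),
    scale_control: float | None = None,
    scale_depleted: float | None = None,
) -> tuple[RegionSet, RegionSet]:
    """Partition sites into (SMARCA4_independent, SMARCA4_dependent).

    Binding is SMARCA4-dependent when the normalized C/EBPb center-window
    signal drops strictly more than ``dependency_fold`` upon SMARCA4
    depletion, SMARCA4-independent otherwise.
    """
    _require_depth(cebpb_control, "control C/EBPb")
    if scale_control is None:
        scale_control = 1e6 / cebpb_control.library_size
    if scale_depleted is None:
        scale_depleted = (1e6 / cebpb_depleted.library_size
                          if cebpb_depleted.library_size > 0 else 1.0)
    ctrl = center_intensities(sites, cebpb_control, scale_control,
                              window=params.center_window,
                              shift=params.fragment_shift)
    depl = center_intensities(sites, cebpb_depleted, scale_depleted,
                              window=params.center_window,
                              shift=params.fragment_shift)
    ratio = (ctrl + params.pseudocount) / (depl + params.pseudocount)
    dep_flags = ratio > params.dependency_fold
    independent = [iv for iv, d in zip(sites, dep_flags) if not d]
    dependent = [iv for iv, d in zip(sites, dep_flags) if d]
    return (
        RegionSet(independent, name="smarca4_independent", genome=sites.genome),
        RegionSet(dependent, name="smarca4_dependent", genome=sites.genome),
    )


def partition_by_baf_prebinding(
    activated: RegionSet, baf_control: RegionSet
) -> tuple[RegionSet, RegionSet]:
    """Partition activated enhancers into (BAF_de_novo, BAF_prebound).

    ``baf_control`` is the BAF (SMARCA4+ ARID1A+) binding set in control
    cells before the perturbation.
    """
    pre, de_novo = classify_temporal(activated, baf_control)
    de_novo.name, pre.name = "baf_de_novo", "baf_prebound"
    return de_novo, pre
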
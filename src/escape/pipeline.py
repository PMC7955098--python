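"""End-to-end orchestration on synthetic landscapes, with recovery metrics.

Chains the full analysis — island calling per factor/condition, chromatin
state classification, SWI/SNF complex assignment, temporal/adipogenic/
MLL4 stratification, C/EBPb activation and SMARCA4-dependency calls, and
RNA differential/dependent gene sets — against a generated ground truth,
and reports the fraction of each programmed label class the pipeline
recovers.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .classify import assign_complexes, classify_states, define_promoters
from .dynamics import (
    ActivationParams,
    call_activated_enhancers,
    classify_smarca4_dependency,
    classify_temporal,
    define_adipogenic,
    partition_by_baf_prebinding,
    stratify_mll4,
)
from .expression import dependent_genes, differential_genes
from .intervals import ReadTrack, RegionSet, overlap_flags, subset_overlapping
from .islands import (
    FACTOR_PARAMS,
    HISTONE_PARAMS,
    IslandParams,
    call_islands,
    islands_to_regions,
)
from .simulate import GroundTruth, LandscapeConfig, generate_landscape, \
    simulate_expression, simulate_reads

__all__ = [
    "params_for",
    "simulate_all_tracks",
    "call_peak_sets",
    "run_pipeline",
    "island_recovery",
    "null_island_count",
]

HISTONE_MARKS = ("H3K4me1", "H3K27ac")

#: which matched input track controls each ChIP condition
INPUT_CONDITION = {
    "D2": "D2",
    "D-3": "D-3",
    "ectopic": "preadipocyte",
    "vector": "preadipocyte",
    "ectopic_smarca4dep": "preadipocyte",
}


def params_for(factor: str) -> IslandParams:
    """Island-calling regime for a factor: broad for marks, narrow otherwise."""
    return HISTONE_PARAMS if factor in HISTONE_MARKS else FACTOR_PARAMS


def simulate_all_tracks(truth: GroundTruth) -> dict[tuple[str, str], ReadTrack]:
    return {key: simulate_reads(truth, *key) for key in truth.enrichment}


def call_peak_sets(
    tracks: Mapping[tuple[str, str], ReadTrack],
    genome: Mapping[str, int],
) -> dict[tuple[str, str], RegionSet]:
    """Called island region sets per (factor, condition), input-controlled."""
    peaks: dict[tuple[str, str], RegionSet] = {}
    for (factor, cond), track in tracks.items():
        if factor == "input":
            continue
        control = tracks.get(("input", INPUT_CONDITION.get(cond, cond)))
        calls = call_islands(track, control, params_for(factor), genome)
        peaks[(factor, cond)] = islands_to_regions(
            calls, name=f"{factor}_{cond}", genome=genome
        )
    return peaks


def _ids(regions: RegionSet) -> set[str]:
    return {iv.name for iv in regions if iv.name is not None}


def _recovery(predicted: set[str], programmed: "np.ndarray | list",
              index) -> float:
    """Percent of programmed-positive ids found in the predicted set."""
    truth_ids = set(index[np.asarray(programmed, dtype=bool)])
    if not truth_ids:
        return float("nan")
    return 100.0 * len(truth_ids & predicted) / len(truth_ids)


def run_pipeline(
    truth: GroundTruth | None = None,
    tracks: Mapping[tuple[str, str], ReadTrack] | None = None,
    params: ActivationParams = ActivationParams(),
) -> dict[str, float]:
    """Run the full chain and report per-label-class recovery percentages.

    Every value is the percentage of regions (or genes) programmed with a
    label that the pipeline assigns that label, computed against the
    generated ground truth; ``*_n`` entries carry the programmed class
    sizes.
    """
    truth = truth if truth is not None else generate_landscape()
    tracks = tracks if tracks is not None else simulate_all_tracks(truth)
    genome = truth.genome
    df = truth.regions
    idx = df.index
    peaks = call_peak_sets(tracks, genome)

    out: dict[str, float] = {}

    # chromatin states
    promoters = define_promoters(truth.genes, genome)
    all_regions = truth.region_set(name="truth_regions")
    states = classify_states(all_regions, promoters,
                             peaks[("H3K4me1", "D2")], peaks[("H3K27ac", "D2")])
    states = np.asarray(states, dtype=object)
    for state in ("promoter", "active_enhancer", "primed_enhancer", "other"):
        programmed = (df.state == state).to_numpy()
        if programmed.any():
            out[f"state_{state}"] = 100.0 * float(
                (states[programmed] == state).mean()
            )
            out[f"state_{state}_n"] = int(programmed.sum())

    # SWI/SNF complexes (anchored on truth regions via overlap)
    complexes = assign_complexes(
        peaks[("SMARCA4", "D2")], peaks[("SS18", "D2")],
        peaks[("ARID1A", "D2")], peaks[("ARID2", "D2")], peaks[("BRD9", "D2")],
    )
    for name, col in (("BAF", "baf"), ("PBAF", "pbaf"), ("GBAF", "gbaf")):
        flags = overlap_flags(all_regions, complexes[name])
        programmed = df[col].to_numpy()
        out[f"complex_{name}"] = 100.0 * float(flags[programmed].mean())
        out[f"complex_{name}_n"] = int(programmed.sum())

    # temporal dynamics of BAF-bound active enhancers
    late = truth.region_set(df.baf_ae.to_numpy(), name="baf_ae")
    early = subset_overlapping(
        subset_overlapping(peaks[("SMARCA4", "D-3")], peaks[("SS18", "D-3")]),
        peaks[("ARID1A", "D-3")],
    )
    pre, de_novo = classify_temporal(late, early)
    baf_ae = df.baf_ae.to_numpy()
    out["temporal_prebound"] = _recovery(
        _ids(pre), (df.prebound & df.baf_ae).to_numpy(), idx)
    out["temporal_de_novo"] = _recovery(
        _ids(de_novo), (~df.prebound & df.baf_ae).to_numpy(), idx)
    out["temporal_n"] = int(baf_ae.sum())

    # adipogenic enhancers and MLL4 stratification
    aes = truth.region_set((df.state == "active_enhancer").to_numpy(), name="AEs")
    adip = define_adipogenic(aes, peaks[("CEBPB", "D2")],
                             peaks[("CEBPA", "D2")], peaks[("PPARG", "D2")])
    out["adipogenic"] = _recovery(_ids(adip), df.adipogenic.to_numpy(), idx)
    out["adipogenic_n"] = int(df.adipogenic.sum())
    baf_ae_set = truth.region_set(baf_ae, name="baf_ae")
    mll4_pos, mll4_neg = stratify_mll4(baf_ae_set, peaks[("MLL4", "D2")])
    out["mll4_pos"] = _recovery(
        _ids(mll4_pos), (df.baf_ae & df.occ_MLL4).to_numpy(), idx)
    out["mll4_neg"] = _recovery(
        _ids(mll4_neg), (df.baf_ae & ~df.occ_MLL4).to_numpy(), idx)

    # C/EBPb-activated enhancers (predicted AE state, called ectopic peaks)
    pred_ae = RegionSet(
        [iv for iv, s in zip(all_regions, states) if s == "active_enhancer"],
        name="predicted_AEs", genome=dict(genome),
    )
    candidates = subset_overlapping(pred_ae, peaks[("CEBPB", "ectopic")])
    required = {
        "SMARCA4": peaks[("SMARCA4", "ectopic")],
        "ARID1A": peaks[("ARID1A", "ectopic")],
        "MLL4": peaks[("MLL4", "ectopic")],
    }
    activated = call_activated_enhancers(
        candidates,
        tracks[("H3K27ac", "ectopic")],
        tracks[("H3K27ac", "vector")],
        required_flags=required,
        params=params,
    )
    act_ids = _ids(activated)
    out["activated"] = _recovery(act_ids, df.activated.to_numpy(), idx)
    out["activated_n"] = int(df.activated.sum())
    out["activated_false_calls"] = float(
        len(act_ids - set(idx[df.activated.to_numpy()]))
    )

    # SMARCA4 dependency of predicted activated enhancers
    independent, dependent = classify_smarca4_dependency(
        activated,
        tracks[("CEBPB", "ectopic")],
        tracks[("CEBPB", "ectopic_smarca4dep")],
        params=params,
    )
    out["dependency_dependent"] = _recovery(
        _ids(dependent), (df.activated & df.dependent).to_numpy(), idx)
    out["dependency_independent"] = _recovery(
        _ids(independent), (df.activated & ~df.dependent).to_numpy(), idx)

    # BAF pre-binding partition of activated enhancers (vector cells)
    baf_vector = subset_overlapping(peaks[("SMARCA4", "vector")],
                                    peaks[("ARID1A", "vector")])
    bdn, bpre = partition_by_baf_prebinding(activated, baf_vector)
    out["baf_prebound"] = _recovery(
        _ids(bpre), (df.activated & df.vector_baf).to_numpy(), idx)
    out["baf_de_novo"] = _recovery(
        _ids(bdn), (df.activated & ~df.vector_baf).to_numpy(), idx)

    # RNA: induced and knockout-dependent genes
    expr = simulate_expression(truth)
    r = expr.rpkm()
    up, _down = differential_genes(r["D-3_control"], r["D2_control"])
    gt = truth.gene_truth
    out["rna_induced"] = _recovery(set(up), gt.induced.to_numpy(), gt.index)
    out["rna_induced_n"] = int(gt.induced.sum())
    dep = dependent_genes(up, r["D2_control"], r["D2_ko"])
    out["rna_dependent"] = _recovery(set(dep), gt.dependent.to_numpy(), gt.index)
    out["rna_dependent_n"] = int(gt.dependent.sum())
    return out


def island_recovery(
    truth: GroundTruth,
    factor: str = "SMARCA4",
    condition: str = "D2",
    tracks: Mapping[tuple[str, str], ReadTrack] | None = None,
) -> tuple[float, float]:
    """(sensitivity %, precision %) of island calls against programmed sites."""
    genome = truth.genome
    if tracks is None:
        chip = simulate_reads(truth, factor, condition)
        control = simulate_reads(truth, "input", INPUT_CONDITION[condition])
    else:
        chip = tracks[(factor, condition)]
        control = tracks[("input", INPUT_CONDITION[condition])]
    calls = call_islands(chip, control, params_for(factor), genome)
    called = islands_to_regions(calls, genome=genome)
    programmed = truth.region_set(
        truth.enrichment[(factor, condition)] > 1, name="programmed"
    )
    if len(programmed) == 0:
        return float("nan"), float("nan")
    sens = 100.0 * float(overlap_flags(programmed, called).mean())
    prec = (100.0 * float(overlap_flags(called, programmed).mean())
            if len(called) else float("nan"))
    return sens, prec


def null_island_count(
    seed: int,
    genome: Mapping[str, int] | None = None,
    depth_rate: float = 0.02,
    params: IslandParams = HISTONE_PARAMS,
) -> int:
    """Number of FDR-passing islands when chip and control are both uniform."""
    config = LandscapeConfig(seed=seed)
    if genome is not None:
        config.genome = dict(genome)
    config.background_rate = depth_rate
    truth = generate_landscape(config)
    chip = simulate_reads(truth, "input", "D2")
    control = simulate_reads(truth, "input", "D-3")
    return len(call_islands(chip, control, params, truth.genome))
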
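"""Synthetic regulatory landscapes with ground truth, reads and expression.

The generator lays out non-overlapping promoter and enhancer sites on a
small genome, programs per-site chromatin states, factor occupancy,
temporal dynamics, activation and dependency labels, then emits stylized
single-end ChIP/ATAC read tracks (uniform Poisson background plus
enriched sites), drosophila-style spike-in read counts, and gene-level
expression counts. All outputs are deterministic given the config seed.

Conditions generated by default mirror the contrasts the analysis
consumes: an adipogenesis time course (D-3, D2) in control cells; a
preadipocyte experiment with ("vector") and without ("ectopic") ectopic
C/EBPb; and acute SMARCA4 depletion in the ectopic cells
("ectopic_smarca4dep"). Matched input tracks are pure background.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionTable
from .intervals import (
    GeneModel,
    GenomicInterval,
    ReadTrack,
    RegionSet,
    write_bed,
    write_gene_table,
    write_genome,
    write_reads,
    read_gene_table,
    read_genome,
)

__all__ = [
    "LandscapeConfig",
    "GroundTruth",
    "generate_landscape",
    "simulate_reads",
    "simulate_expression",
    "write_fixture_bundle",
    "load_fixture_bundle",
]

FACTORS = ("SMARCA4", "SS18", "ARID1A", "ARID2", "BRD9", "MLL4", "CBP",
           "CEBPB", "CEBPA", "PPARG", "ATAC", "H3K4me1", "H3K27ac")

#: Per-state probability that a factor occupies a site at D2.
DEFAULT_OCCUPANCY: dict[str, dict[str, float]] = {
    "promoter": {
        "SMARCA4": 0.4, "SS18": 0.15, "ARID1A": 0.15, "ARID2": 0.6,
        "BRD9": 0.1, "MLL4": 0.2, "CBP": 0.3, "CEBPB": 0.1, "CEBPA": 0.05,
        "PPARG": 0.05, "ATAC": 0.9, "H3K4me1": 0.3, "H3K27ac": 0.7,
    },
    "active_enhancer": {
        "SMARCA4": 0.85, "SS18": 0.8, "ARID1A": 0.8, "ARID2": 0.1,
        "BRD9": 0.15, "MLL4": 0.4, "CBP": 0.6, "CEBPB": 0.5, "CEBPA": 0.3,
        "PPARG": 0.3, "ATAC": 0.9, "H3K4me1": 1.0, "H3K27ac": 1.0,
    },
    "primed_enhancer": {
        "SMARCA4": 0.6, "SS18": 0.4, "ARID1A": 0.4, "ARID2": 0.05,
        "BRD9": 0.1, "MLL4": 0.2, "CBP": 0.1, "CEBPB": 0.2, "CEBPA": 0.1,
        "PPARG": 0.1, "ATAC": 0.5, "H3K4me1": 1.0, "H3K27ac": 0.0,
    },
    "other": {
        "SMARCA4": 0.2, "SS18": 0.1, "ARID1A": 0.1, "ARID2": 0.05,
        "BRD9": 0.3, "MLL4": 0.05, "CBP": 0.05, "CEBPB": 0.1, "CEBPA": 0.05,
        "PPARG": 0.05, "ATAC": 0.3, "H3K4me1": 0.0, "H3K27ac": 0.0,
    },
}


@dataclass
class LandscapeConfig:
    """Study-condition parameters of the synthetic landscape."""

    genome: dict[str, int] = field(default_factory=lambda: {"chr1": 10_000_000})
    n_promoters: int = 200
    n_enhancers: int = 1000
    site_width: int = 600
    class_fractions: dict[str, float] = field(default_factory=lambda: {
        "active_enhancer": 0.5, "primed_enhancer": 0.3, "other": 0.2,
    })
    occupancy: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(p) for s, p in DEFAULT_OCCUPANCY.items()}
    )
    dynamics_fractions: dict[str, float] = field(default_factory=lambda: {
        "prebound": 0.4, "de_novo": 0.6,
    })
    activated_fraction: float = 0.5
    dependent_fraction: float = 0.5
    activation_fold: float = 4.0
    knockdown_fold: float = 8.0
    enrichment_fold: float = 8.0
    background_rate: float = 0.02  # reads per bp; x genome size = track depth
    fragment_shift: int = 75
    tag_length: int = 50
    spikein_mean: float = 5000.0
    rna: dict[str, float] = field(default_factory=lambda: {
        "expressed_fraction": 0.8,
        "induced_fraction": 0.1,
        "dependent_fraction": 0.4,
        "induced_fold": 8.0,
        "depth": 1_000_000,
        "rpkm_low": 4.0,
        "rpkm_high": 64.0,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        for label, fr in self.class_fractions.items():
            if not 0 <= fr <= 1:
                raise ValueError(f"class fraction {label} outside [0, 1]")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if abs(sum(self.dynamics_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("dynamics fractions must sum to 1")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "LandscapeConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Programmed regions, labels, per-track enrichment and gene truth."""

    config: LandscapeConfig
    regions: pd.DataFrame          # chrom/start/end/kind/state + truth flags
    enrichment: dict[tuple[str, str], np.ndarray]  # (factor, condition) -> fold/site
    genes: list[GeneModel]
    gene_truth: pd.DataFrame       # base_level/expressed/induced/dependent

    @property
    def genome(self) -> dict[str, int]:
        return self.config.genome

    def region_set(self, mask: np.ndarray | None = None, name: str = "") -> RegionSet:
        df = self.regions if mask is None else self.regions[mask]
        ivs = [
            GenomicInterval(row.chrom, int(row.start), int(row.end), name=str(idx))
            for idx, row in df.iterrows()
        ]
        return RegionSet(ivs, name=name, genome=dict(self.genome))

    def track_keys(self) -> list[tuple[str, str]]:
        return list(self.enrichment)


def _rng_for(config: LandscapeConfig, *tags: str | int) -> np.random.Generator:
    entropy = [int(config.seed) & 0x7FFFFFFF]
    for t in tags:
        entropy.append(zlib.crc32(str(t).encode()))
    return np.random.default_rng(entropy)


def generate_landscape(config: LandscapeConfig | None = None) -> GroundTruth:
    """Lay out sites and draw every programmed truth label."""
    config = config or LandscapeConfig()
    rng = _rng_for(config, "landscape")
    chrom = next(iter(config.genome))
    glen = config.genome[chrom]
    n = config.n_promoters + config.n_enhancers
    slot = glen // (n + 1)
    if slot < 3 * config.site_width:
        raise ValueError("genome too small for the requested number of sites")
    jitter = rng.integers(-slot // 4, slot // 4 + 1, size=n)
    centers = slot * np.arange(1, n + 1) + jitter
    kinds = np.array(["promoter"] * config.n_promoters
                     + ["enhancer"] * config.n_enhancers)
    rng.shuffle(kinds)

    half = config.site_width // 2
    df = pd.DataFrame({
        "chrom": chrom,
        "start": centers - half,
        "end": centers + half,
        "kind": kinds,
    })
    df.index = pd.Index([f"r{i:05d}" for i in range(n)], name="region_id")

    # chromatin state
    states = np.empty(n, dtype=object)
    is_enh = kinds == "enhancer"
    labels = list(config.class_fractions)
    probs = np.array([config.class_fractions[s] for s in labels])
    states[~is_enh] = "promoter"
    states[is_enh] = rng.choice(labels, size=int(is_enh.sum()), p=probs)
    df["state"] = states

    # per-factor D2 occupancy, conditioned on state
    for factor in FACTORS:
        p = np.array([config.occupancy[s][factor] for s in states])
        df[f"occ_{factor}"] = rng.random(n) < p

    baf = df.occ_SMARCA4 & df.occ_SS18 & df.occ_ARID1A
    df["baf"] = baf
    df["pbaf"] = df.occ_SMARCA4 & df.occ_ARID2
    df["gbaf"] = df.occ_SMARCA4 & df.occ_BRD9
    df["baf_ae"] = baf & (df.state == "active_enhancer")

    # temporal dynamics: BAF sites already bound at the early timepoint
    pre_p = config.dynamics_fractions["prebound"]
    df["prebound"] = baf & (rng.random(n) < pre_p)
    df["adipogenic"] = (df.state == "active_enhancer") & (
        df.occ_CEBPB | df.occ_CEBPA | df.occ_PPARG
    )

    # ectopic-C/EBPb experiment: candidates, activation, dependency, and
    # BAF pre-binding in vector (control) preadipocytes
    df["candidate"] = (
        (df.state == "active_enhancer") & df.occ_CEBPB & df.occ_SMARCA4
        & df.occ_ARID1A & df.occ_MLL4
    )
    df["activated"] = df.candidate & (rng.random(n) < config.activated_fraction)
    df["dependent"] = df.activated & (rng.random(n) < config.dependent_fraction)
    df["vector_baf"] = baf & (rng.random(n) < pre_p)

    enrichment = _build_enrichment(config, df)
    genes, gene_truth = _build_genes(config, df, rng)
    return GroundTruth(config=config, regions=df, enrichment=enrichment,
                       genes=genes, gene_truth=gene_truth)


def _build_enrichment(
    config: LandscapeConfig, df: pd.DataFrame
) -> dict[tuple[str, str], np.ndarray]:
    """Per-(factor, condition) enrichment fold over background per site."""
    E = config.enrichment_fold
    n = len(df)

    def fold(mask: pd.Series | np.ndarray, value: float = E) -> np.ndarray:
        out = np.ones(n)
        out[np.asarray(mask, dtype=bool)] = value
        return out

    enr: dict[tuple[str, str], np.ndarray] = {}
    for factor in FACTORS:
        enr[(factor, "D2")] = fold(df[f"occ_{factor}"])
    # early timepoint: BAF factors only where prebound; marks premarked
    for factor in ("SMARCA4", "SS18", "ARID1A"):
        enr[(factor, "D-3")] = fold(df.prebound)
    enr[("H3K4me1", "D-3")] = fold(df.occ_H3K4me1)
    enr[("H3K27ac", "D-3")] = fold(df.occ_H3K27ac)

    # preadipocyte ectopic-C/EBPb experiment
    enr[("CEBPB", "ectopic")] = fold(df.occ_CEBPB)
    for factor in ("SMARCA4", "ARID1A", "MLL4"):
        enr[(factor, "ectopic")] = fold(df[f"occ_{factor}"])
    enr[("H3K27ac", "vector")] = fold(df.occ_H3K27ac)
    treated = fold(df.occ_H3K27ac)
    treated[np.asarray(df.activated, dtype=bool)] = E * config.activation_fold
    enr[("H3K27ac", "ectopic")] = treated
    for factor in ("SMARCA4", "ARID1A"):
        enr[(factor, "vector")] = fold(df.vector_baf)
    depleted = fold(df.occ_CEBPB)
    depleted[np.asarray(df.dependent, dtype=bool)] = max(
        E / config.knockdown_fold, 1.0
    )
    enr[("CEBPB", "ectopic_smarca4dep")] = depleted

    # matched input (pure background) per condition group
    for cond in ("D2", "D-3", "preadipocyte"):
        enr[("input", cond)] = np.ones(n)
    return enr


def _build_genes(
    config: LandscapeConfig, df: pd.DataFrame, rng: np.random.Generator
) -> tuple[list[GeneModel], pd.DataFrame]:
    promoters = df[df.kind == "promoter"]
    n = len(promoters)
    lengths = np.exp(rng.uniform(np.log(1000), np.log(4000), size=n)).astype(int)
    strands = rng.choice(["+", "-"], size=n)
    genes = [
        GeneModel(
            gene_id=f"g{i:04d}",
            chrom=row.chrom,
            tss=int((row.start + row.end) // 2),
            strand=strands[i],
            exonic_length=int(lengths[i]),
        )
        for i, (_, row) in enumerate(promoters.iterrows())
    ]
    rna = config.rna
    expressed = rng.random(n) < rna["expressed_fraction"]
    low, high = rna["rpkm_low"], rna["rpkm_high"]
    base = np.where(
        expressed,
        np.exp(rng.uniform(np.log(low), np.log(high), size=n)),
        rng.uniform(0.05, 0.5, size=n),
    )
    induced = expressed & (rng.random(n) < rna["induced_fraction"])
    dependent = induced & (rng.random(n) < rna["dependent_fraction"])
    truth = pd.DataFrame({
        "base_level": base,
        "expressed": expressed,
        "induced": induced,
        "dependent": dependent,
    }, index=pd.Index([g.gene_id for g in genes], name="gene_id"))
    return genes, truth


def simulate_reads(
    truth: GroundTruth, factor: str, condition: str
) -> ReadTrack:
    """Draw one stylized ChIP/ATAC/input read track for a factor/condition.

    Background reads fall uniformly at ``background_rate`` per bp; each
    programmed site receives additional reads so that its in-site read
    density is its enrichment fold times the background density. Tags are
    placed so the strand-aware fragment shift re-centers them on the site.
    """
    config = truth.config
    key = (factor, condition)
    if key not in truth.enrichment:
        raise KeyError(f"no programmed enrichment for {key}")
    rng = _rng_for(config, "reads", factor, condition)
    folds = truth.enrichment[key]
    shift = config.fragment_shift

    positions: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    for chrom, glen in config.genome.items():
        n_bg = rng.poisson(config.background_rate * glen)
        mid = rng.integers(0, glen, size=n_bg)
        st = rng.choice(np.array([1, -1], dtype=np.int8), size=n_bg)
        pos_parts = [mid - shift * st.astype(np.int64)]
        strand_parts = [st]

        on_chrom = truth.regions.chrom == chrom
        hot = np.flatnonzero(on_chrom & (folds > 1))
        for i in hot:
            row = truth.regions.iloc[i]
            lam = (folds[i] - 1) * config.background_rate * (row.end - row.start)
            n_extra = rng.poisson(lam)
            if n_extra == 0:
                continue
            mid_e = rng.integers(row.start, row.end, size=n_extra)
            st_e = rng.choice(np.array([1, -1], dtype=np.int8), size=n_extra)
            pos_parts.append(mid_e - shift * st_e.astype(np.int64))
            strand_parts.append(st_e)

        pos = np.concatenate(pos_parts)
        st_all = np.concatenate(strand_parts)
        keep = (pos >= 0) & (pos < glen)
        positions[chrom] = pos[keep]
        strands[chrom] = st_all[keep]

    spikein = int(rng.poisson(config.spikein_mean))
    return ReadTrack(positions, strands, genome=config.genome,
                     spikein_reads=spikein)


#: expression conditions: (timepoint, genotype) -> column name
RNA_CONDITIONS = {
    ("D-3", "control"): "D-3_control",
    ("D2", "control"): "D2_control",
    ("D-3", "ko"): "D-3_ko",
    ("D2", "ko"): "D2_ko",
}


def simulate_expression(truth: GroundTruth) -> ExpressionTable:
    """Gene counts for the D-3/D2 x control/knockout grid.

    Induced genes gain ``induced_fold`` at D2 in control cells; dependent
    genes lose that induction in the knockout. Counts are Poisson with
    rate proportional to exonic length and programmed expression level
    (in RPKM units at the nominal library depth). The modeled gene panel
    is treated as sitting inside a full transcriptome library of
    ``rna.depth`` exonic reads, so the RPKM denominator is the nominal
    library size plus the panel's own counts, and programmed levels are
    recovered without composition bias from the unmodeled genes.
    """
    config = truth.config
    rng = _rng_for(config, "expression")
    rna = config.rna
    base = truth.gene_truth.base_level.to_numpy()
    induced = truth.gene_truth.induced.to_numpy()
    dependent = truth.gene_truth.dependent.to_numpy()
    lengths = np.array([g.exonic_length for g in truth.genes])
    kb = lengths / 1e3
    depth_scale = rna["depth"] / 1e6

    levels = {
        "D-3_control": base,
        "D2_control": np.where(induced, base * rna["induced_fold"], base),
        "D-3_ko": base,
        "D2_ko": np.where(induced & ~dependent, base * rna["induced_fold"], base),
    }
    counts = {
        cond: rng.poisson(lev * kb * depth_scale)
        for cond, lev in levels.items()
    }
    library_sizes = {
        cond: float(rna["depth"] + c.sum()) for cond, c in counts.items()
    }
    return ExpressionTable.from_counts(truth.genes, counts, library_sizes)


METADATA_FILES = ("genome.txt", "genes.tsv", "gene_truth.tsv", "regions.tsv",
                  "enrichment.tsv", "expression.tsv", "spikein.tsv", "config.yaml")


def _track_filename(factor: str, condition: str) -> str:
    return f"{factor}_{condition.replace('-', 'm')}.tagAlign"


def write_fixture_bundle(truth: GroundTruth, outdir: str | Path) -> list[Path]:
    """Emit the full text-file bundle every CLI subcommand consumes.

    Writes one tagAlign per (factor, condition), the truth/region tables,
    gene table, genome file, expression counts, spike-in counts and a
    config snapshot. Re-running with the same config yields byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    spike_rows = []
    for (factor, cond) in truth.enrichment:
        track = simulate_reads(truth, factor, cond)
        path = outdir / _track_filename(factor, cond)
        write_reads(track, str(path), tag_length=truth.config.tag_length)
        spike_rows.append((factor, cond, track.spikein_reads, track.n_reads))
        written.append(path)

    write_genome(truth.genome, str(outdir / "genome.txt"))
    write_gene_table(truth.genes, str(outdir / "genes.tsv"))
    truth.gene_truth.to_csv(outdir / "gene_truth.tsv", sep="\t")
    truth.regions.to_csv(outdir / "regions.tsv", sep="\t", index_label="region_id")
    enr = pd.DataFrame(
        {f"{f}|{c}": v for (f, c), v in truth.enrichment.items()},
        index=truth.regions.index,
    )
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index_label="region_id")
    simulate_expression(truth).to_tsv(str(outdir / "expression.tsv"))
    pd.DataFrame(
        spike_rows, columns=["factor", "condition", "spikein_reads", "library_reads"]
    ).to_csv(outdir / "spikein.tsv", sep="\t", index=False)
    truth.config.to_yaml(str(outdir / "config.yaml"))
    written += [outdir / name for name in METADATA_FILES]
    regions_bed = truth.region_set(name="truth_regions")
    write_bed(regions_bed, str(outdir / "regions.bed"))
    written.append(outdir / "regions.bed")
    return written


def load_fixture_bundle(outdir: str | Path) -> GroundTruth:
    """Reload a bundle into the identical in-memory ground truth."""
    outdir = Path(outdir)
    config = LandscapeConfig.from_yaml(str(outdir / "config.yaml"))
    config.genome = read_genome(str(outdir / "genome.txt"))
    regions = pd.read_csv(outdir / "regions.tsv", sep="\t", index_col="region_id")
    enr_df = pd.read_csv(outdir / "enrichment.tsv", sep="\t", index_col="region_id")
    enrichment = {}
    for col in enr_df.columns:
        factor, cond = col.split("|", 1)
        enrichment[(factor, cond)] = enr_df[col].to_numpy()
    genes = read_gene_table(str(outdir / "genes.tsv"))
    gene_truth = pd.read_csv(outdir / "gene_truth.tsv", sep="\t", index_col="gene_id")
    return GroundTruth(config=config, regions=regions, enrichment=enrichment,
                       genes=genes, gene_truth=gene_truth)
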
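# escape

**E**nhancer-**S**tate **C**lassification **A**nd **P**eak **E**valuation — a
post-alignment toolkit for studying how chromatin regulators activate cell
type-specific enhancers, built around the adipogenesis model system
(preadipocyte → adipocyte differentiation) and the SWI/SNF remodeling
complexes BAF, PBAF and GBAF together with the H3K4 methyltransferase MLL4
and the pioneer transcription factor C/EBPβ.

It is written for computational biologists who have aligned ChIP-seq /
ATAC-seq / RNA-seq reads (tagAlign/BED) and want the downstream analysis:
peak calling, enhancer chromatin-state classification, complex assignment by
peak co-occupancy, enhancer dynamics across time and perturbation, signal
quantification and fold-change statistics — plus a synthetic-data generator
with complete ground truth, so that every stage of the pipeline can be
validated without any sequencing data.

## The analysis

**Island calling.** Reads (5′ ends, shifted +75 bp toward 3′) are binned
into fixed windows; windows improbable under a genome-wide Poisson
background (tail probability < 0.2) are chained into islands across bounded
gaps. Each island is tested with a Poisson upper tail
P(X ≥ k<sub>ChIP</sub>) at rate λ = the library-ratio–scaled control count,
floored by the control's local (10 kb) read density; q-values are
Benjamini–Hochberg. Two regimes: broad histone marks use 200-bp
windows/gaps at FDR 10⁻³; narrow non-histone factors use 50-bp windows/gaps
at FDR 10⁻¹⁰.

**Enhancer states.** Promoters are TSS ± 1 kb. Promoter-distal regions are
*active enhancers* (H3K4me1⁺ H3K27ac⁺), *primed enhancers*
(H3K4me1⁺ H3K27ac⁻) or *other*; promoter overlap takes precedence.

**SWI/SNF complexes.** Anchored on SMARCA4 peak coordinates:
BAF = SMARCA4⁺ SS18⁺ ARID1A⁺, PBAF = SMARCA4⁺ ARID2⁺,
GBAF = SMARCA4⁺ BRD9⁺ (membership non-exclusive; overlap = ≥ 1 shared base).

**Dynamics and dependency.** Binding sites at a late timepoint are
*prebound* or *de novo* by overlap with the early set. Adipogenic enhancers
are active enhancers bound by C/EBPβ, C/EBPα or PPARγ. C/EBPβ-activated
enhancers are C/EBPβ⁺ SMARCA4⁺ ARID1A⁺ MLL4⁺ active enhancers whose
normalized H3K27ac signal rises strictly more than 2-fold upon ectopic
C/EBPβ; their C/EBPβ binding is *SMARCA4-dependent* when the 400-bp
center-window signal drops more than 2-fold upon SMARCA4 depletion.

**Signal and statistics.** RPM or spike-in (reference/sample spike reads ×
RPM) normalization; 50-bp heatmap matrices and average profiles around
region centers; descending 400-bp center-intensity ranking; per-region
log2 ratios tested with a one-sided Wilcoxon signed-rank test (exact by
enumeration for small tie-free samples, tie-corrected normal approximation
otherwise). RNA-seq: RPKM, an RPKM > 1 expressed filter, strict > 2.5-fold
differential sets, and knockout-dependent induced-gene subsets.

## Worked example

```python
from escape import (LandscapeConfig, generate_landscape, simulate_reads,
                    call_islands, define_promoters, genomic_distribution)
from escape.islands import islands_to_regions
from escape.pipeline import params_for

config = LandscapeConfig(genome={"chr1": 2_000_000}, n_promoters=40,
                         n_enhancers=200, seed=11)
truth = generate_landscape(config)
tracks = {f: simulate_reads(truth, f, "D2")
          for f in ("SMARCA4", "H3K4me1", "H3K27ac", "input")}
peaks = {}
for f in ("SMARCA4", "H3K4me1", "H3K27ac"):
    calls = call_islands(tracks[f], tracks["input"], params_for(f), truth.genome)
    peaks[f] = islands_to_regions(calls, name=f, genome=truth.genome)
    print(f"{f}: {len(peaks[f])} islands")

promoters = define_promoters(truth.genes, truth.genome)
dist = genomic_distribution(peaks["SMARCA4"], promoters,
                            peaks["H3K4me1"], peaks["H3K27ac"])
print({s: round(f, 3) for s, f in dist.items()})
```

prints

```
SMARCA4: 141 islands
H3K4me1: 169 islands
H3K27ac: 114 islands
{'promoter': 0.149, 'active_enhancer': 0.56, 'primed_enhancer': 0.234, 'other': 0.057}
```

i.e. on this 2-Mb toy landscape the caller recovers 141 SMARCA4 binding
sites and the classifier places 56% of them on active enhancers, 23% on
primed enhancers, 15% at promoters — the genomic-distribution readout used
to characterize where each SWI/SNF subunit binds.

A `click` CLI exposes the same steps
(`escape simulate | callpeaks | classify | dynamics | activate | matrix |
foldchange | regions intersect`); run `escape --help`.

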
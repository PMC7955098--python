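# Methods

This note documents the models, parameter choices and numerical decisions
behind `escape`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Coordinates and interval algebra

All coordinates are 0-based, half-open (BED-native); the paper trail of a
typical ChIP experiment (tagAlign in, BED out) never leaves that
convention. Two intervals overlap when they share at least one base — the
weakest assumption and the default of common intersection tools; any "X⁺"
co-occupancy call in the package means exactly this. Strand is ignored for
interval algebra and used only for TSS placement and read 5′ ends.
Intersections always keep the anchor set's coordinates, so set sizes stay
anchorable to one factor's peak list (needed for reporting counts per
subunit). A normalized region set is sorted by (chrom, start) and
non-overlapping; reciprocal-overlap fractions are not required (a stricter
`min-overlap` policy could be added, but every co-occupancy definition here
is stated in terms of simple overlap).

## Island calling

The caller is a deliberately compact window/gap Poisson formulation:

1. Read 5′ ends are shifted +75 bp toward 3′ (half of an assumed 150-bp
   fragment; configurable) and binned into `w`-bp windows.
2. A window is *eligible* when its count's Poisson upper tail under the
   genome-wide ChIP read density (over an effective genome fraction,
   default 0.8) is below 0.2.
3. Eligible windows are chained into islands; internal runs of ineligible
   windows spanning at most `g` bp are absorbed.
4. Each island is scored against the control: p = P(X ≥ k_chip) with
   λ = (chip/control library ratio) × max(control reads in the island,
   local control density × island length, 1). Benjamini–Hochberg q-values
   are computed over all candidate islands and calls with q < α are kept.

Two regimes mirror standard practice: histone marks (H3K4me1, H3K27ac) use
(w, g, α) = (200 bp, 200 bp, 10⁻³); non-histone factors and ATAC use
(50 bp, 50 bp, 10⁻¹⁰).

The *local-density floor* on λ (step 4) deserves a note. Scoring an island
against only its own control counts is badly behaved for short islands: a
window whose control happens to draw 0–1 reads gets a background estimate
several-fold too low, and among tens of thousands of candidate windows the
coincidence "chip selected high, control by chance empty" occurs often
enough to produce dozens of confidently wrong calls per genome. Estimating
the background from a window of at least 10 kb around the island (akin to
a local-lambda correction) removes this failure mode: under a pure-Poisson
null (chip and control independent uniform draws at 0.02 reads/bp over
10 Mb) the caller averages ≈ 0.1 false islands per run at the broad-mark
FDR, measured over ten seeds. Because every term in λ is linear in control
reads, p-values are exactly invariant to jointly rescaling both library
sizes. The per-island score (the sum of per-window −ln Poisson tails) is
retained for ranking and for selecting the top-3000 most significant
regions (by q, ties broken by score then coordinate) that feed motif
analysis; motif discovery itself is out of scope.

Duplicate-read filtering, fragment-model building and Tn5 offset
correction are deliberately not implemented; ATAC reads are treated as a
generic track.

## Classification and labels

* Promoters: TSS ± 1 kb, clipped to the chromosome, merged when
  overlapping. Promoter overlap takes precedence over the enhancer states,
  since enhancers are defined as promoter-distal; a peak spanning several
  classes takes the highest-precedence class it touches (promoter >
  active > primed > other), which yields the single-label fractions used
  in genomic-distribution summaries.
* Complex assignment is non-exclusive: one SMARCA4 site can be BAF and
  PBAF and GBAF.
* Activation rule: among C/EBPβ⁺ active enhancers that are also SMARCA4⁺
  ARID1A⁺ MLL4⁺, an enhancer is *activated* when
  (treated + 1)/(control + 1) > 2 on RPM-normalized H3K27ac counts over
  the full enhancer interval — strictly greater, so a ratio of exactly 2
  is excluded. The pseudocount of 1 normalized read keeps zero-signal
  ratios finite.
* Dependency rule: C/EBPβ binding at an activated enhancer is
  SMARCA4-dependent when (control + 1)/(depleted + 1) > 2 on the 400-bp
  center window — the same window that orders the heat maps, keeping the
  call consistent with the visual ranking. The 2-fold threshold mirrors
  the activation rule; "reduced vs unchanged" binding has no sharper
  published criterion, so the fold is exposed as a parameter.
* Expression: RPKM = count / (exonic kb) / (million mapped exonic reads).
  Genes with RPKM > 1 in either compared condition form the universe;
  up/down calls use a strict > 2.5 fold rule with a 0.1-RPKM pseudocount;
  a 2.5-fold collapse of the induced level in the knockout defines
  dependent genes.

## Statistics

The one-sided Wilcoxon signed-rank test drops zero differences (classic
treatment, not Pratt). For n ≤ 25 tie-free samples the exact null
distribution of W⁺ is built by dynamic programming over the 2ⁿ sign
assignments; otherwise a normal approximation with tie-corrected variance
(−Σ(t³−t)/48) and a 0.5 continuity correction is used, and the result
records which path ran. The exact path is verified in the tests against
both brute-force 2ⁿ enumeration and an independent library
implementation. Reported percentages are rounded half-up.

Spike-in normalization multiplies the RPM scale by
(reference spike-in reads)/(sample spike-in reads) — the vendor-standard
arithmetic for exogenous-chromatin normalization; the protocol itself
fixes only the experimental design, not the formula.

## Synthetic landscapes

The generator emulates the structure of the study's data: promoter and
enhancer sites laid out non-overlapping on a 10-Mb chromosome; chromatin
states drawn per enhancer (defaults: 50% active, 30% primed, 20% other);
per-state factor-occupancy probabilities for the twelve ChIP targets plus
ATAC; temporal labels (40% of BAF sites prebound, mirroring the reported
4,410/10,813 split); MLL4 on 40% of active enhancers (mirroring the
reported ≈40%); an ectopic-C/EBPβ experiment in which half the eligible
candidate enhancers are programmed activated with a 4× H3K27ac gain and
half of those lose C/EBPβ binding entirely upon SMARCA4 depletion
(mirroring the reported 229/449 dependent fraction); and a 200-gene panel
with 10% of expressed genes induced 8-fold, 40% of which are
knockout-dependent (mirroring 362/937). Reads are stylized 50-bp
single-end tags: a uniform Poisson background at 0.02 reads/bp (2×10⁵
reads per 10-Mb track) plus extra reads in programmed sites so that
in-site density is `enrichment_fold` (default 8) times background; tags
are placed so the +75-bp fragment shift re-centers them on the site.
Spike-in read counts are Poisson(5,000) per track. Problem sizes (10 Mb,
1,000 enhancers, 200 genes, 2×10⁵ reads/track) were chosen so a full
landscape generates in seconds and the complete pipeline runs in well
under a minute.

The RNA model treats the 200-gene panel as embedded in a nominal
full-transcriptome library of 10⁶ exonic reads: programmed levels are in
true RPKM units and the RPKM denominator is the nominal library plus the
panel's own counts. This keeps the RPKM > 1 expressed filter meaningful
and avoids the composition bias a panel-only denominator would introduce
(where inducing 10% of genes deflates every other gene's RPKM); it also
means the generator does not emulate genuine composition effects, which
real RPKM comparisons do suffer when global expression shifts.

What passing the synthetic validation shows: every algorithmic stage is
correct, calibrated under its own null, and recovers programmed labels at
realistic signal-to-noise (≥95% of every label class at 8× enrichment).
What it does not show: robustness to features the generator omits —
duplicate reads, GC and mappability bias, fragment-length variation,
overlapping/nested regulatory elements, diploid copy-number effects, and
composition bias in expression. Recovery degrades smoothly as
`enrichment_fold` approaches 1, and the island caller's eligibility
threshold (0.2) and fragment shift are the knobs to revisit on shallow or
fragmented real data.

## Determinism

Every stochastic output derives from `numpy.random.default_rng` seeded
with the config seed plus stable per-track tags (CRC32 of factor and
condition names), so regenerating any track, expression table or fixture
bundle with the same config is byte-identical, independent of generation
order.
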
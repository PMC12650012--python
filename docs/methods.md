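# Methods

## The motif grammar and its decomposition

A canonical PQS is parsed as four guanine tracts of at least `min_g`
(default 3) consecutive guanines joined by three loops of 1–7 nt
(configurable). Loops are G-free on the motif strand. This is a
deliberate restriction: it makes the decomposition of any matching
window unique (the tracts are exactly the maximal G-runs), which in
turn makes the scanner provably equivalent to brute-force substring
enumeration and keeps every downstream feature label well defined.
Scanners that allow guanines inside loops must adopt an arbitrary
parse among ambiguous alternatives; we instead exclude those motifs
and state so. N bases terminate tracts and loops, so no motif spans an
assembly gap.

A bulged PQS carries exactly one bulge: a run of 1–8 non-G nucleotides
splitting one tract, with at least one guanine on each side. A bulged
tract's `g_count` counts guanines only, and the layer number NT is the
minimum `g_count` over the four tracts. A locus matched by the
canonical grammar is never reported as bulged: bulged candidates
overlapping a selected canonical motif are discarded before selection.

**Overlap resolution.** Per strand, motifs are selected
leftmost-greedy. Among candidates sharing a start the tie-break is:
more tetrad layers, then shorter total loop length, then shorter span
(then smaller bulge, then earlier bulge position). Because a window
may begin or end inside a longer genomic G-run, the shorter-span rule
trims surplus terminal guanines into the flank rather than absorbing
them: a motif ending `...GGG` followed by `GAANN` keeps its three-G
tract and reports `GAANN` as its 3′ flank. Minus-strand motifs are
scanned on the reverse complement and reported in plus-strand
coordinates with the decomposition (tracts, loops, flanks, 5′→3′) on
the G-rich strand. Coordinates are 0-based half-open throughout.

**Feature classifiers.**

- Loop-length class: `all_1nt` (every loop 1 nt), `max_2nt` (longest
  loop 2 nt), `long` otherwise. 3-nt loops therefore fall in `long`:
  the boundary between a "2 nt" and a ">3 nt" class leaves 3-nt loops
  formally unassigned, and sorting them into `long` is one consistent
  choice rather than an established convention.
- Permutation class: three distinct loop lengths are labelled by rank
  (s/m/l per position, e.g. `s-l-m`); a single equal pair is labelled
  by the positional pattern `x-x-z`, `x-y-x` or `x-y-y` together with
  the shape `x=y>z` or `x=y<z`.
- Telomeric status: WT iff a bulge-free core of four exact GGG tracts
  carries three `TTA` loops; an A→T variant additionally allows `TTT`
  loops (at least one). Everything else is non-telomeric.
- Flank patterns are IUPAC strings, right-anchored at the motif start
  (5′ side) or left-anchored at the motif end (3′ side), matched on
  the motif strand. A flank truncated by a contig edge never matches.

## Stability signals and scoring

Two per-base score kinds are supported, both read from 4-column
bedGraph with per-base expansion (overlaps: last record wins, logged):

- `mm_pct` (0–100): polymerase-stalling mismatch percentage; already
  higher-is-more-stable.
- `phred_quality` (0–41): transformed per base as `ln(41.1 − x)`,
  which is strictly decreasing, maps 41 → ln 0.1 ≈ −2.303 and
  0 → ln 41.1 ≈ 3.716, and spreads the dynamic range near the quality
  ceiling where stable G4s concentrate. Values outside [0, 41] beyond
  a 1e−6 tolerance raise a domain error naming the offending position;
  the tolerance absorbs float round-trips at the boundaries.

A motif's score is the **mean** signal (transformed for quality) over
its footprint, optionally extended 3′ by `window_3p` nucleotides
(rightward on `+`, leftward on `−`), since the stall signature sits
just downstream of the G4 initiation site. The mean was chosen over
max/median as the smooth aggregator matching mean-based group
summaries; the aggregation window itself is an analysis choice — the
assays define no canonical per-motif reduction — and defaults to the
footprint alone (`window_3p = 0`). Uncovered bases are skipped and the
coverage fraction recorded; motifs with zero covered bases are
excluded downstream and counted.

## Stratified reports

`group_motifs` assigns each scored motif to at most one label per
feature; motifs matching no label are excluded and counted, so
grouped + excluded always equals the input count. Group labels follow
the stratifications the package is built around: layers × loop class;
bulge presence and size 1–8 (three-layer, 1-nt-loop motifs); total
loop length 3–21; permutation classes; telomeric WT vs A→T; the 3×3
base grids of 1-3-1 and 1-6-1 loop configurations; and 5′/3′ flank
pattern pairs (`NNNTT` vs `NNTGA`, `GAANN` vs `TTNNN`).

The loop-length and permutation groupings condition on three-layer
canonical motifs. This isolates the loop effect from the layer effect:
in a mixed census, four- and five-layer motifs with long loops would
otherwise raise long-loop cells by their layer bonus and mask the
monotone loop penalty.

Each group is summarised by the mean and SD of `resample_n = 1000`
scores drawn with replacement (scores are sorted before drawing, so
results depend only on the score multiset and the seed — group
summaries are invariant to input order). The SD reported is the SD of
the resampled draws, i.e. an estimate of the score SD, not a standard
error; resampled means converge to plain means as `resample_n` grows.

Pairwise contrasts per feature mirror the natural reference of each
stratification: each bulge size vs size 1; each loop-length group vs
its left neighbour; each layer count vs the previous one within a loop
class; each permutation group vs the highest-mean group of its shape
panel; each composition vs `A-A`; two-group features directly.
`wilcoxon_rank_sum` enumerates the exact null when `m + n ≤ 12` with
no ties and otherwise uses the normal approximation with tie and
continuity correction (two constant identical samples give p = 1 by
convention). Raw two-sided p-values drive the ns/*/**/*** symbols at
0.05/0.01/0.001; a Benjamini–Hochberg adjusted column is emitted
alongside but deliberately not used for the symbols, matching the
common practice of reporting raw rank-sum p-values per stratification.

## The synthetic model

The generator is the package's ground truth, not a fixture: it embeds
one motif per stratification cell per replicate (72 cells; default
n = 200 each, ≈14,400 motifs, ≈1.2 Mb) into background sequence, with
roughly half the motifs on the minus strand and ≥50 nt of background
between inserts.

**Latent stability** (free-energy-like units):

    S = baseline + 1.0·(NT − 3) − 0.3·(Ltot − 3) − g(bulge)
        + 2.5·[NT = 3 and all loops 1 nt]
        ± 0.75 (flanks) ± 0.75 (telomeric) ± 0.4 per 1-nt loop base
        + N(0, 0.5)

- The loop penalty of 0.3 per nucleotide mirrors the empirical
  ≈0.3 kcal/mol per added loop nucleotide; the companion T_m simulator
  uses the matching ≈2 °C per nucleotide on the temperature scale.
- The bulge penalty g rises linearly to 1.5 at 5 nt and relaxes by
  0.3/nt beyond — long bulges can fold into compensating internal
  duplexes — giving the V-shaped size profile with its minimum at 5.
- The anomaly bonus of 2.5 exceeds two layer bonuses, reproducing the
  nonmonotonic d(GnT)4 ordering (3 > 5 > 4 layers) for 1-nt loops
  while leaving longer-loop cells monotone in NT.
- Flank effects: 5′ `...TGA` and 3′ `GAA...` stabilise (+0.75),
  TT-adjacent flanks destabilise (−0.75) — i.e. ±1.5 between groups,
  3σ of the motif noise. Telomeric `TTA` loops gain +0.75 over A→T
  substituted loops (−0.75). 1-nt loop bases contribute A −0.4, C 0,
  T +0.4 (the A < C < T ordering for short loops).
- One latent noise draw per motif (σ = 0.5) plus small per-base jitter
  on each signal (σ 0.5 MM-units / 0.1 quality-units): biological and
  technical variance each get one knob, since their split in real data
  is unknown.

Effect sizes were fixed once so every encoded pairwise difference is
detectable at n = 200 per group (smallest encoded gap: 0.3, ≈6
standard errors at σ = 0.5).

**Signal mappings** (both strictly monotone in S, so every encoded
ordering survives the mapping in distribution):

    mm      = 40 · logistic((S − 0) / 2.5)            (increasing)
    quality = clip(41.1 − exp(0.35·S + 0.5), 0, 41)   (decreasing)

The pipeline's transformed-quality score `ln(41.1 − q)` is then
affine in S (exactly so when noise is off — a property the tests
assert). The mappings themselves are modelling choices exposed in the
config: the real relation between thermostability and MM%/quality is
not quantitatively known, so only signs and orderings are treated as
recoverable truths. Background positions get constant levels (MM 1.0,
quality 40.5), written as merged bedGraph intervals.

**Background composition.** Background is drawn at GC ≈ 0.4 and then
every G-run *and* C-run is broken down to single bases (replacements
from {A, T}). Suppressing GGG alone is not enough: a lone `GG` within
bulge range (≤8 nt) of an embedded motif can seed a spurious
earlier-starting bulged parse, and C-runs read as G-runs on the minus
strand, where they generate spurious background-level motifs that both
dilute group means and displace true minus-strand motifs from the
per-strand greedy selection. With both suppressed, re-scanning
recovers 100% of embedded motifs with identical decompositions in
practice (the tests require ≥99%). Neutral flanks are drawn from
{A, C} without CC and so match none of the flank classes on either
strand. What the generator does **not** emulate: read-level error
processes, mappability structure, chromosomal signal autocorrelation,
K⁺/Na⁺ condition differencing, or overlapping/clustered PQS — passing
trend-recovery tests therefore demonstrates pipeline correctness under
the encoded model, not performance on real sequencing data.

**Determinism.** All randomness flows from `numpy.random.default_rng`
seeded from the config (`[seed, 0]` for the library, `[seed, 1]` for
track jitter); identical configs give byte-identical FASTA, truth
TSV, bedGraphs and report TSVs.

**T_m companion model.** `simulate_tm_library` draws total loop
lengths uniform on 3–21 and returns
`Tm = 85 − 2.0·Ltot + N(0, 0.5)` °C and
`ΔG = 8 − 0.3·Ltot + N(0, 0.075)` kcal/mol (noise scaled
proportionally between the scales). The ΔG intercept keeps simulated
unfolding energies within the 1.7–15.6 kcal/mol span reported for
natural promoter quadruplexes. OLS on n = 1000 recovers both slopes
well within 3 standard errors; `scripts/acceptance.py` prints exactly
these two recovered penalties.

## Numerical and degenerate-input choices

- Quality boundary tolerance 1e−6; transform errors name the
  offending position.
- Empty groups are reported as rows with n = 0 and blank statistics,
  never as exceptions; an empty score list yields NaN resampled
  statistics.
- Wilcoxon on two identical constant samples returns (mn/2, p = 1),
  logged as a convention.
- bedGraph overlaps resolve last-wins with a warning; malformed lines
  report their line number.
- Problem sizes: the default library (200/cell, ≈1.2 Mb, both
  strands) runs the full simulate → scan → score → stratify pipeline
  in well under a minute; the brute-force grammar oracle in the test
  suite uses 2 kb sequences, where substring enumeration is exhaustive
  yet fast.

## Known limitations

- Loops are G-free by grammar; G4s with guanine-containing loops,
  vacancy-bearing or multimeric quadruplexes, and duplex-containing
  hybrids are out of scope (only bulge size is modelled, 1–8 nt, one
  bulge per motif).
- Scores aggregate a single track; K⁺-vs-Na⁺ differencing and
  cross-assay concordance metrics are not computed.
- The bulge model places one bulge anywhere in one tract; positional
  and residue-identity effects of bulges are not encoded.
- Significance symbols use raw p-values by design; use the emitted
  `p_bh` column when a corrected view is needed.
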
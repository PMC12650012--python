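# g4strat

Feature-stratified analysis of G-quadruplex (G4) stability from
sequencing-derived per-base signals.

G-quadruplexes are four-stranded structures formed by G-rich DNA: four
guanine tracts stack into planar G-tetrads (NT layers), joined by three
loops. Their thermostability — classically measured one construct at a
time by UV/CD melting — is modulated by a structural grammar: the
number of tetrad layers, the total loop length (≈2 °C of T_m, or
≈0.3 kcal/mol of ΔG, lost per added loop nucleotide), loop ordering and
base composition, bulges interrupting a tract, and the flanking
sequence context. Genome-wide sequencing assays read the same biology
indirectly: a stable G4 stalls the polymerase, raising the local
mismatch percentage (MM%), and depresses base-call quality, so Phred
qualities `x` (0–41) can be placed on the same "higher = more stable"
scale via the transform `ln(41.1 − x)`.

`g4strat` implements that whole comparison as a reusable pipeline:

- **`g4strat.grammar`** — bulge-aware detection of potential quadruplex
  sequences (PQS: `G≥3 (loop1–7 G≥3)×3`, plus a single 1–8 nt bulge)
  with full structural decomposition (tracts, layers, loops, bulges,
  flanks) and feature classifiers (loop-length class, permutation class
  with s/m/l labels, telomeric `(GGGTTA)n` A→T variants, IUPAC flank
  patterns such as 5′ `NNTGA` or 3′ `GAANN`).
- **`g4strat.signals`** — per-base signal tracks from bedGraph
  (`mm_pct` or `phred_quality`), the `ln(41.1 − x)` transform, and
  per-motif stability scores (mean over the motif footprint, with an
  optional 3′ window for the downstream stall signature).
- **`g4strat.stats`** — stratified reports: group scored motifs by a
  structural feature, summarise each group by the mean ± SD of 1000
  resampled scores, and test the feature-appropriate contrasts with the
  two-sided Wilcoxon rank-sum test (exact enumeration for small
  tie-free samples, normal approximation with tie/continuity correction
  otherwise; ns/*/**/*** at 0.05/0.01/0.001, with a Benjamini–Hochberg
  column for transparency).
- **`g4strat.simulate`** — a synthetic genome + signal generator with
  an explicit latent thermostability model (layer bonus, loop-length
  penalty, piecewise bulge penalty peaking at 5 nt, the three-layer
  1-nt-loop "anomalous stability" bonus, flank and composition
  effects), providing exact ground truth for every pipeline stage, plus
  a melting-temperature/free-energy companion simulator.
- **`g4strat.cli`** — `g4strat simulate | scan | score | report |
  run-all`.

## Worked example

```python
import g4strat as g

cfg = g.SyntheticModelConfig(seed=7, n_per_cell=50)
lib = g.generate_library(cfg)                       # genome + truth table
motifs = g.scan_sequences(lib.sequences, g.GrammarParams())
_, qual_track, _, _ = g.emit_tracks(lib)            # phred_quality track
scored, _ = g.score_motifs(motifs, qual_track)      # ln(41.1 - x) scale
rep = g.run_feature_report(scored, "bulge_size", g.ReportConfig(seed=7))
print(rep.to_frame()[["label", "n", "mean", "sd", "vs", "p", "significance"]])
```

prints (seed 7):

```
label   n     mean       sd vs            p significance
    1  50 1.713292 0.179145             NaN
    2  50 1.581855 0.163721  1 2.482435e-04          ***
    3  50 1.502717 0.205805  1 1.371372e-06          ***
    4  50 1.386087 0.165065  1 3.256046e-12          ***
    5  50 1.251379 0.181959  1 1.641465e-15          ***
    6  50 1.401715 0.185629  1 2.949121e-11          ***
    7  50 1.502442 0.179377  1 1.086143e-07          ***
    8  50 1.632695 0.174488  1 8.367092e-03           **
```

Each row is one bulge size (nt) among three-layer, 1-nt-loop motifs:
`mean`/`sd` summarise 1000 resampled transformed-quality scores, and
`p` is the Wilcoxon rank-sum p-value against the 1-nt-bulge reference
group. The means fall to a minimum at bulge size 5 and recover for
larger bulges — the V-shaped size dependence the generator encodes
(destabilisation growing with bulge size up to 5 nt, then compensation
by internal structure in longer bulges), read back out through the full
scan → score → stratify pipeline.

The same run scans 3600 embedded motifs out of 3600 (including 400
bulged ones) from a 310 kb synthetic genome, and the `telomeric_AtoT`
report gives WT mean 0.158 vs A→T-variant mean −0.464 (p ≈ 5e-17).

The equivalent shell pipeline:

```sh
g4strat simulate --seed 7 --n-per-cell 50 -o sim/
g4strat scan sim/genome.fa -o motifs.bed
g4strat score motifs.bed sim/signal_phred_quality.bedgraph \
        --kind phred_quality -o scored.tsv
g4strat report scored.tsv --seed 7 -o reports/
```

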
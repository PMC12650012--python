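"""Synthetic genome + signal-track generator with known ground truth.

The generator embeds PQS motifs covering every stratification cell of
the analysis (tetrad-layer x loop-class grid, bulge sizes 1-8, total
loop lengths 3-21, loop-permutation patterns, telomeric WT and A-to-T
variants, 1-3-1 / 1-6-1 loop-composition grids, and 5'/3' flank
classes) into G-suppressed background sequence, then maps an explicit
latent thermostability model through two monotone signal mappings to
produce matching mismatch-percentage and Phred-quality tracks.

The latent scale is free-energy-like: the default per-loop-nucleotide
penalty of 0.3 follows the empirical ~0.3 kcal/mol per added loop
nucleotide, and the companion melting-temperature simulator
(:func:`simulate_tm_library`) uses the matching ~2 degC per nucleotide
rule.  Encoded trends (signs and orderings) are the object of the
pipeline's recovery tests; the logistic/exponential signal mappings are
modelling choices exposed in the config, not measured facts.

Background sequence carries no G-run longer than a single guanine:
even a lone ``GG`` within bulge range of an embedded motif could seed a
spurious earlier-starting bulged parse, whereas isolated guanines
provably cannot complete any tract.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, PackingError
from .grammar import reverse_complement
from .signals import SignalTrack

__all__ = [
    "SyntheticModelConfig",
    "SyntheticLibrary",
    "generate_library",
    "emit_tracks",
    "write_library",
    "simulate_tm_library",
    "latent_stability",
]

_LOOP_BASES = "ACT"      # loops, bulges and flank Ns stay G-free
_NEUTRAL_BASES = "AC"    # neutral flanks: no TT / TGA / GAA submatches


@dataclass(frozen=True)
class SyntheticModelConfig:
    """All generator parameters; serialised to the run manifest.

    The latent stability of a motif is::

        S = baseline + layer_bonus * (NT - 3) - loop_penalty * (Ltot - 3)
            - bulge_penalty(size) + anomaly_bonus * [NT=3, all loops 1 nt]
            + flank_effect * flank_class + telomeric_effect * telo_class
            + composition_effect * sum(base effects of 1-nt loops)
            + N(0, noise_sd)

    with ``bulge_penalty`` rising linearly to ``bulge_penalty_max`` at
    size 5 and relaxing by ``bulge_relief`` per nucleotide beyond
    (long bulges can fold into compensating internal structure).  The
    signal mappings are strictly monotone in S:
    ``mm = mm_max * logistic((S - mm_mid) / mm_scale)`` (increasing) and
    ``quality = clip(41.1 - exp(a*S + b), 0, 41)`` (decreasing), so the
    pipeline's transformed-quality score ``ln(41.1 - q) = a*S + b`` is
    again increasing in S.
    """

    seed: int = 0
    n_per_cell: int = 200
    flank_width: int = 5
    separation: int = 50
    genome_length: int | None = None
    gc_fraction: float = 0.4
    chrom: str = "chrS1"
    # latent thermostability model (free-energy-like units)
    baseline: float = 0.0
    layer_bonus: float = 1.0
    loop_penalty: float = 0.3
    bulge_penalty_max: float = 1.5
    bulge_relief: float = 0.3
    anomaly_bonus: float = 2.5
    flank_effect: float = 0.75
    telomeric_effect: float = 0.75
    composition_effect: float = 0.4
    noise_sd: float = 0.5
    # signal mappings
    mm_max: float = 40.0
    mm_mid: float = 0.0
    mm_scale: float = 2.5
    quality_slope: float = 0.35
    quality_intercept: float = 0.5
    background_mm: float = 1.0
    background_quality: float = 40.5
    jitter_mm: float = 0.5
    jitter_quality: float = 0.1
    # melting-temperature / free-energy companion model
    tm_intercept: float = 85.0
    tm_loop_penalty: float = 2.0
    tm_noise_sd: float = 0.5
    dg_intercept: float = 8.0
    dg_loop_penalty: float = 0.3
    dg_noise_sd: float = 0.075
    loop_total_range: tuple[int, int] = (3, 21)

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ConfigError("n_per_cell must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigError("gc_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.tm_noise_sd < 0 or self.dg_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.separation < 10:
            raise ConfigError("separation must be >= 10 nt")
        if self.flank_width < 5:
            raise ConfigError("flank_width must be >= 5 (flank patterns)")
        lo, hi = self.loop_total_range
        if not 3 <= lo <= hi:
            raise ConfigError("invalid loop_total_range")

    def bulge_penalty(self, size: int) -> float:
        if size <= 0:
            return 0.0
        if size <= 5:
            return self.bulge_penalty_max * size / 5.0
        return max(0.0, self.bulge_penalty_max
                   - self.bulge_relief * (size - 5))

    def mm_of(self, s):
        return self.mm_max * expit((np.asarray(s, float) - self.mm_mid)
                                   / self.mm_scale)

    def quality_of(self, s):
        raw = 41.1 - np.exp(self.quality_slope * np.asarray(s, float)
                            + self.quality_intercept)
        return np.clip(raw, 0.0, 41.0)


_COMP_EFFECT = {"T": 1.0, "C": 0.0, "A": -1.0}


def latent_stability(cfg: SyntheticModelConfig, nt: int, loops, bulge_size: int,
                     flank5: str, flank3: str) -> float:
    """Deterministic latent stability of a motif from its features."""
    loops = tuple(loops)
    total = sum(len(l) for l in loops)
    s = cfg.baseline + cfg.layer_bonus * (nt - 3)
    s -= cfg.loop_penalty * (total - 3)
    s -= cfg.bulge_penalty(bulge_size)
    if nt == 3 and all(len(l) == 1 for l in loops):
        s += cfg.anomaly_bonus
    if flank5.endswith("TGA"):
        s += cfg.flank_effect
    elif flank5.endswith("TT"):
        s -= cfg.flank_effect
    if flank3.startswith("GAA"):
        s += cfg.flank_effect
    elif flank3.startswith("TT"):
        s -= cfg.flank_effect
    for loop in loops:
        if len(loop) == 1:
            s += cfg.composition_effect * _COMP_EFFECT.get(loop, 0.0)
    if (nt == 3 and bulge_size == 0
            and all(l in ("TTA", "TTT") for l in loops)):
        s += (cfg.telomeric_effect if all(l == "TTA" for l in loops)
              else -cfg.telomeric_effect)
    return float(s)


# ---------------------------------------------------------------------------
# cell construction
# ---------------------------------------------------------------------------

def _rand_string(rng, alphabet: str, length: int) -> str:
    idx = rng.integers(0, len(alphabet), size=length)
    return "".join(alphabet[i] for i in idx)


_CC_RUN = re.compile(r"(?<=C)C+")


def _neutral_flank(rng, width: int) -> str:
    # no CC either: a CC run reads as GG on the opposite strand, where it
    # could complete a spurious tract next to C-rich motif loops
    flank = _rand_string(rng, _NEUTRAL_BASES, width)
    return _CC_RUN.sub(lambda m: "A" * len(m.group(0)), flank)


def _partition_total(rng, total: int) -> tuple[int, int, int]:
    """Random triple of loop lengths in [1, 7] summing to ``total``."""
    l1 = int(rng.integers(max(1, total - 14), min(7, total - 2) + 1))
    rest = total - l1
    l2 = int(rng.integers(max(1, rest - 7), min(7, rest - 1) + 1))
    return l1, l2, rest - l2


_PERM_ORDERS = {
    "s-m-l": (0, 1, 2), "s-l-m": (0, 2, 1), "m-s-l": (1, 0, 2),
    "m-l-s": (1, 2, 0), "l-s-m": (2, 0, 1), "l-m-s": (2, 1, 0),
}


def _build_cells(cfg: SyntheticModelConfig):
    """Yield (family, cell_label, builder); builder(rng) -> motif features."""
    w = cfg.flank_width

    def simple(nt, loops):
        def build(rng):
            return dict(nt=nt, loops=list(loops), bulge=None,
                        flank5=_neutral_flank(rng, w),
                        flank3=_neutral_flank(rng, w))
        return build

    cells = []
    # tetrad layers x loop class
    # the long-loop cell avoids TTT (an all-substitution telomeric variant)
    class_loops = {"all_1nt": ("T",) * 3, "max_2nt": ("TT",) * 3,
                   "long": ("TCA",) * 3}
    for nt in (3, 4, 5):
        for lc, loops in class_loops.items():
            cells.append(("layer", f"NT{nt}|{lc}", simple(nt, loops)))
    # bulge sizes 1..8 on a three-layer, 1-nt-loop core
    for size in range(1, 9):
        def build(rng, size=size):
            offset = int(rng.integers(1, 3))  # split 1+2 or 2+1 guanines
            tract = int(rng.integers(0, 4))
            return dict(nt=3, loops=["T", "T", "T"],
                        bulge=(tract, offset, _rand_string(rng, _LOOP_BASES, size)),
                        flank5=_neutral_flank(rng, w),
                        flank3=_neutral_flank(rng, w))
        cells.append(("bulge", f"bulge_{size}", build))
    # total loop length 3..21, random composition
    lo, hi = cfg.loop_total_range
    for total in range(lo, hi + 1):
        def build(rng, total=total):
            lengths = _partition_total(rng, total)
            return dict(nt=3,
                        loops=[_rand_string(rng, _LOOP_BASES, l)
                               for l in lengths],
                        bulge=None, flank5=_neutral_flank(rng, w),
                        flank3=_neutral_flank(rng, w))
        cells.append(("ltot", f"ltot_{total}", build))
    # loop permutation patterns
    for label, order in _PERM_ORDERS.items():
        def build(rng, order=order):
            values = sorted(rng.choice(np.arange(1, 8), size=3, replace=False))
            lengths = tuple(int(values[k]) for k in order)
            return dict(nt=3,
                        loops=[_rand_string(rng, _LOOP_BASES, l)
                               for l in lengths],
                        bulge=None, flank5=_neutral_flank(rng, w),
                        flank3=_neutral_flank(rng, w))
        cells.append(("perm", f"perm_{label}", build))
    for pattern, bigger_pair in (("x-x-z", True), ("x-y-x", True),
                                 ("x-y-y", True), ("x-x-z", False),
                                 ("x-y-x", False), ("x-y-y", False)):
        shape = "x=y>z" if bigger_pair else "x=y<z"

        def build(rng, pattern=pattern, bigger_pair=bigger_pair):
            if bigger_pair:
                pair = int(rng.integers(2, 8))
                odd = int(rng.integers(1, pair))
            else:
                pair = int(rng.integers(1, 7))
                odd = int(rng.integers(pair + 1, 8))
            lengths = {"x-x-z": (pair, pair, odd),
                       "x-y-x": (pair, odd, pair),
                       "x-y-y": (odd, pair, pair)}[pattern]
            return dict(nt=3,
                        loops=[_rand_string(rng, _LOOP_BASES, l)
                               for l in lengths],
                        bulge=None, flank5=_neutral_flank(rng, w),
                        flank3=_neutral_flank(rng, w))
        cells.append(("perm", f"perm_{pattern}|{shape}", build))
    # telomeric WT and A-to-T variants
    cells.append(("telo", "telomeric_WT", simple(3, ("TTA",) * 3)))

    def build_variant(rng):
        k = int(rng.integers(1, 4))
        which = rng.choice(3, size=k, replace=False)
        loops = ["TTT" if i in which else "TTA" for i in range(3)]
        return dict(nt=3, loops=loops, bulge=None,
                    flank5=_neutral_flank(rng, w),
                    flank3=_neutral_flank(rng, w))
    cells.append(("telo", "telomeric_AtoT", build_variant))
    # 1-3-1 and 1-6-1 composition grids
    for middle_len, tag in ((3, "131"), (6, "161")):
        for b1, b3 in product(_LOOP_BASES, repeat=2):
            cells.append((
                f"comp{tag}", f"comp{tag}_{b1}-{b3}",
                simple(3, (b1, "T" * middle_len, b3)),
            ))
    # flank classes on a three-layer, 1-nt-loop core
    def flank5_cell(pattern):
        fixed = pattern.replace("N", "")
        n_rand = pattern.count("N")

        def build(rng):
            flank5 = (_rand_string(rng, _NEUTRAL_BASES, w - len(pattern))
                      + _rand_string(rng, _LOOP_BASES, n_rand) + fixed)
            return dict(nt=3, loops=["T", "T", "T"], bulge=None,
                        flank5=flank5, flank3=_neutral_flank(rng, w))
        return build

    def flank3_cell(pattern):
        fixed = pattern.rstrip("N")
        n_rand = pattern.count("N")

        def build(rng):
            flank3 = (fixed + _rand_string(rng, _LOOP_BASES, n_rand)
                      + _rand_string(rng, _NEUTRAL_BASES, w - len(pattern)))
            return dict(nt=3, loops=["T", "T", "T"], bulge=None,
                        flank5=_neutral_flank(rng, w), flank3=flank3)
        return build

    cells.append(("flank5", "flank5_NNNTT", flank5_cell("NNNTT")))
    cells.append(("flank5", "flank5_NNTGA", flank5_cell("NNTGA")))
    cells.append(("flank3", "flank3_GAANN", flank3_cell("GAANN")))
    cells.append(("flank3", "flank3_TTNNN", flank3_cell("TTNNN")))
    return cells


def _motif_core(features) -> str:
    nt = features["nt"]
    loops = features["loops"]
    bulge = features["bulge"]
    parts = []
    for i in range(4):
        tract = "G" * nt
        if bulge is not None and bulge[0] == i:
            _, offset, seq = bulge
            tract = "G" * offset + seq + "G" * (nt - offset)
        parts.append(tract)
        if i < 3:
            parts.append(loops[i])
    return "".join(parts)


_GC_RUN = re.compile(r"(?<=G)G+|(?<=C)C+")


def _background(rng, length: int, gc: float) -> str:
    if length <= 0:
        return ""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=probs)
    seq = "".join("ACGT"[i] for i in idx)
    # break every G-run and C-run down to a single base: a longer run near
    # an embedded motif could complete a spurious (bulged) parse on the
    # plus strand (G) or minus strand (C); replacements come from {A, T}
    # so no new run can form at a junction
    return _GC_RUN.sub(
        lambda m: _rand_string(rng, "AT", len(m.group(0))), seq
    )


@dataclass
class SyntheticLibrary:
    """Generated genome, per-motif truth table and resolved config."""

    config: SyntheticModelConfig
    sequences: dict[str, str]
    truth: pd.DataFrame

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def generate_library(config: SyntheticModelConfig | None = None
                     ) -> SyntheticLibrary:
    """Embed one motif library into background sequence.

    Motifs are placed non-overlapping with at least ``separation``
    background nucleotides between consecutive flanked inserts; roughly
    half are embedded on the minus strand.  The truth table records
    coordinates, features, cell labels and the latent stability S
    (deterministic part and the per-motif noisy draw used for the
    signal tracks).
    """
    cfg = config or SyntheticModelConfig()
    rng = np.random.default_rng([cfg.seed, 0])
    cells = _build_cells(cfg)

    inserts = []
    for family, cell, build in cells:
        for _ in range(cfg.n_per_cell):
            features = build(rng)
            inserts.append((family, cell, features))
    order = rng.permutation(len(inserts))
    inserts = [inserts[i] for i in order]

    pad = cfg.separation
    segments: list[str] = []
    records = []
    cursor = 0

    lead = _background(rng, pad, cfg.gc_fraction)
    segments.append(lead)
    cursor += len(lead)
    for family, cell, features in inserts:
        core = _motif_core(features)
        flank5, flank3 = features["flank5"], features["flank3"]
        block = flank5 + core + flank3
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start = cursor + len(flank5)
        else:
            block = reverse_complement(block)
            start = cursor + len(flank3)
        end = start + len(core)
        segments.append(block)
        cursor += len(block)
        sep = _background(rng, cfg.separation + int(rng.integers(0, 11)),
                          cfg.gc_fraction)
        segments.append(sep)
        cursor += len(sep)

        bulge = features["bulge"]
        loops = features["loops"]
        s_det = latent_stability(cfg, features["nt"], loops,
                                 len(bulge[2]) if bulge else 0,
                                 flank5, flank3)
        noise = float(rng.normal(0.0, cfg.noise_sd))
        records.append(dict(
            chrom=cfg.chrom, start=start, end=end, strand=strand,
            family=family, cell=cell, nt=features["nt"],
            ll1=len(loops[0]), ll2=len(loops[1]), ll3=len(loops[2]),
            loops=",".join(loops),
            bulge_size=len(bulge[2]) if bulge else 0,
            bulge_tract=bulge[0] if bulge else -1,
            bulge_offset=bulge[1] if bulge else -1,
            bulge_seq=bulge[2] if bulge else ".",
            flank5=flank5, flank3=flank3,
            latent_det=s_det, latent=s_det + noise,
        ))

    genome = "".join(segments)
    required = len(genome)
    if cfg.genome_length is not None:
        if cfg.genome_length < required:
            raise PackingError(
                f"genome_length={cfg.genome_length} cannot hold "
                f"{len(inserts)} motifs; at least {required} nt required"
            )
        genome += _background(rng, cfg.genome_length - required,
                              cfg.gc_fraction)
    truth = pd.DataFrame.from_records(records).sort_values(
        ["start", "end"], kind="mergesort").reset_index(drop=True)
    return SyntheticLibrary(config=cfg, sequences={cfg.chrom: genome},
                            truth=truth)


def emit_tracks(library: SyntheticLibrary
                ) -> tuple[SignalTrack, SignalTrack, pd.DataFrame, pd.DataFrame]:
    """Map latent stabilities to per-base mm_pct / phred_quality tracks.

    Motif footprints get their motif's mapped level plus per-base
    jitter; background positions get a constant background level
    (written as merged intervals).  Returns the two in-memory tracks and
    a bedGraph record frame (chrom/start/end/value) for each.
    """
    cfg = library.config
    rng = np.random.default_rng([cfg.seed, 1])
    truth = library.truth
    genome_len = library.genome_length
    chrom = cfg.chrom

    starts = truth["start"].to_numpy()
    ends = truth["end"].to_numpy()
    latent = truth["latent"].to_numpy()
    lengths = ends - starts
    total = int(lengths.sum())

    positions = np.concatenate(
        [np.arange(s, e) for s, e in zip(starts, ends)]
    ) if total else np.empty(0, dtype=np.int64)
    per_base_s = np.repeat(latent, lengths)
    mm = np.clip(cfg.mm_of(per_base_s)
                 + rng.normal(0.0, cfg.jitter_mm, size=total), 0.0, 100.0)
    qual = np.clip(cfg.quality_of(per_base_s)
                   + rng.normal(0.0, cfg.jitter_quality, size=total),
                   0.0, 41.0)

    # background: the complement of motif footprints, merged intervals
    bg_start_list, bg_end_list = [], []
    prev = 0
    for s, e in zip(starts, ends):
        if s > prev:
            bg_start_list.append(int(prev))
            bg_end_list.append(int(s))
        prev = max(prev, int(e))
    if genome_len > prev:
        bg_start_list.append(prev)
        bg_end_list.append(genome_len)
    bg_starts = np.asarray(bg_start_list, dtype=np.int64)
    bg_ends = np.asarray(bg_end_list, dtype=np.int64)

    def records(values, bg_level) -> pd.DataFrame:
        frame = pd.DataFrame({
            "chrom": chrom,
            "start": np.concatenate([positions, bg_starts]),
            "end": np.concatenate([positions + 1, bg_ends]),
            "value": np.concatenate(
                [values, np.full(len(bg_starts), float(bg_level))]
            ),
        })
        return frame.sort_values("start", kind="mergesort",
                                 ignore_index=True)

    def build_track(kind, motif_vals, bg_level) -> SignalTrack:
        bg_pos = (np.concatenate([np.arange(s, e) for s, e
                                  in zip(bg_starts, bg_ends)])
                  if len(bg_starts) else np.empty(0, np.int64))
        all_pos = np.concatenate([positions, bg_pos])
        all_val = np.concatenate(
            [motif_vals, np.full(len(bg_pos), float(bg_level))]
        )
        sorter = np.argsort(all_pos, kind="mergesort")
        return SignalTrack(kind=kind,
                           data={chrom: (all_pos[sorter], all_val[sorter])})

    mm_track = build_track("mm_pct", mm, cfg.background_mm)
    qual_track = build_track("phred_quality", qual, cfg.background_quality)
    return (mm_track, qual_track,
            records(mm, cfg.background_mm),
            records(qual, cfg.background_quality))


def write_library(library: SyntheticLibrary, outdir) -> dict[str, Path]:
    """Write FASTA, truth TSV, both bedGraphs and the JSON manifest."""
    from .io import write_fasta
    from .signals import write_bedgraph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "truth": outdir / "truth.tsv",
        "mm_bedgraph": outdir / "signal_mm_pct.bedgraph",
        "quality_bedgraph": outdir / "signal_phred_quality.bedgraph",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(library.sequences, paths["fasta"])
    library.truth.to_csv(paths["truth"], sep="\t", index=False)
    _, _, mm_records, qual_records = emit_tracks(library)
    write_bedgraph(mm_records, paths["mm_bedgraph"])
    write_bedgraph(qual_records, paths["quality_bedgraph"])
    manifest = dict(
        config=dataclasses.asdict(library.config),
        n_motifs=int(len(library.truth)),
        genome_length=library.genome_length,
        cells=sorted(library.truth["cell"].unique().tolist()),
    )
    paths["manifest"].write_text(json.dumps(manifest, indent=2,
                                            default=str) + "\n")
    return paths


def simulate_tm_library(config: SyntheticModelConfig | None = None,
                        n: int = 1000, seed: int = 42) -> pd.DataFrame:
    """Simulate per-motif melting temperature and free energy vs loop load.

    ``Tm = tm_intercept - tm_loop_penalty * Ltot + N(0, tm_noise_sd)``
    and ``dG = dg_intercept - dg_loop_penalty * Ltot + N(0, dg_noise_sd)``
    with total loop length uniform on ``loop_total_range``.  Returns a
    flat table suitable for regression-based recovery of the penalties.
    """
    cfg = config or SyntheticModelConfig()
    if n < 2:
        raise ConfigError("n must be >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = cfg.loop_total_range
    total = rng.integers(lo, hi + 1, size=n)
    tm = (cfg.tm_intercept - cfg.tm_loop_penalty * total
          + rng.normal(0.0, cfg.tm_noise_sd, size=n))
    dg = (cfg.dg_intercept - cfg.dg_loop_penalty * total
          + rng.normal(0.0, cfg.dg_noise_sd, size=n))
    return pd.DataFrame(
        dict(total_loop_length=total, tm_celsius=tm, dg_kcal_mol=dg)
    )
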
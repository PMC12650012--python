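"""Detection and structural decomposition of potential G-quadruplex
sequences (PQS).

A canonical PQS is four guanine tracts (maximal G-runs of at least
``min_g`` guanines) joined by three G-free loops whose lengths fall in
``[loop_min, loop_max]``.  A bulged PQS additionally carries exactly one
bulge — a run of 1-8 non-guanine bases splitting one tract, with at
least one guanine on either side.  Loops and bulges contain no G on the
motif strand, which makes the decomposition of any matching window
unique; N bases terminate tracts and loops, so no motif spans an
assembly gap.

Within a window a tract may be a trimmed edge of a longer genomic
G-run: per strand, motifs are selected leftmost-greedy and, among
candidates sharing a start, by more tetrad layers, then shorter total
loop length, then shorter span (then, for bulged motifs, smaller bulge
and earlier bulge position).  Surplus guanines of a long terminal run
are thereby left in the flank rather than absorbed into the motif.

Coordinates are 0-based half-open on the plus strand; minus-strand
motifs are reported in plus-strand coordinates with the decomposition
(tracts, loops, flanks) given 5'->3' on the G-rich motif strand.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .errors import ConfigError, InputError

__all__ = [
    "GrammarParams",
    "GTract",
    "BulgeAnnotation",
    "LoopSet",
    "G4Motif",
    "PermutationClass",
    "find_canonical_pqs",
    "find_bulged_pqs",
    "find_all_pqs",
    "scan_sequences",
    "classify_permutation",
    "classify_telomeric_variant",
    "loop_class",
    "match_flank_motif",
    "reverse_complement",
]

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide codes -> set of matching bases.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GrammarParams:
    """Scanner parameters.

    ``min_g`` is the minimum guanine count per tract (bulged tracts count
    guanines only), loops span ``loop_min``..``loop_max`` nucleotides,
    ``flank_width`` bases of context are reported on each side, and
    bulges span ``bulge_min``..``bulge_max`` non-G nucleotides with at
    most one bulge per motif.
    """

    min_g: int = 3
    loop_min: int = 1
    loop_max: int = 7
    flank_width: int = 5
    both_strands: bool = True
    bulge_min: int = 1
    bulge_max: int = 8

    def __post_init__(self) -> None:
        if self.min_g < 2:
            raise ConfigError(f"min_g must be >= 2, got {self.min_g}")
        if self.loop_min < 1:
            raise ConfigError(f"loop_min must be >= 1, got {self.loop_min}")
        if self.loop_min > self.loop_max:
            raise ConfigError(
                f"loop_min ({self.loop_min}) > loop_max ({self.loop_max})"
            )
        if self.bulge_min < 1:
            raise ConfigError(f"bulge_min must be >= 1, got {self.bulge_min}")
        if self.bulge_max < self.bulge_min:
            raise ConfigError(
                f"bulge_max ({self.bulge_max}) < bulge_min ({self.bulge_min})"
            )
        if self.flank_width < 0:
            raise ConfigError("flank_width must be >= 0")


@dataclass(frozen=True)
class BulgeAnnotation:
    """A single non-G insertion splitting a G-tract."""

    tract_index: int
    offset_in_tract: int  # guanines 5' of the bulge within the tract
    size: int
    sequence: str


@dataclass(frozen=True)
class GTract:
    """One column of the quadruplex core; ``start`` is motif-relative."""

    start: int
    g_count: int
    bulge: BulgeAnnotation | None = None

    @property
    def span(self) -> int:
        return self.g_count + (self.bulge.size if self.bulge else 0)


@dataclass(frozen=True)
class LoopSet:
    """The three loops, 5'->3' on the motif strand."""

    loops: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if len(self.loops) != 3:
            raise ValueError("a loop set has exactly 3 loops")

    @property
    def lengths(self) -> tuple[int, int, int]:
        return tuple(length for length, _ in self.loops)  # type: ignore[return-value]

    @property
    def sequences(self) -> tuple[str, str, str]:
        return tuple(seq for _, seq in self.loops)  # type: ignore[return-value]

    @property
    def total_length(self) -> int:
        return sum(self.lengths)


@dataclass(frozen=True)
class G4Motif:
    """A located, stranded PQS with its full structural decomposition."""

    chrom: str
    start: int
    end: int
    strand: str
    n_tetrads: int
    tracts: tuple[GTract, ...]
    loop_set: LoopSet
    flank5: str
    flank3: str
    sequence: str

    @property
    def bulge(self) -> BulgeAnnotation | None:
        for tract in self.tracts:
            if tract.bulge is not None:
                return tract.bulge
        return None

    @property
    def is_bulged(self) -> bool:
        return self.bulge is not None


@dataclass(frozen=True)
class PermutationClass:
    """Ordering pattern of the three loop lengths."""

    shape: str  # all_equal | x!=y!=z | x=y>z | x=y<z
    label: str


# ---------------------------------------------------------------------------
# scanning internals
# ---------------------------------------------------------------------------

_G_RUN = re.compile(r"G+")

# A concrete candidate: (start, end, g_counts, loop_spans, bulge)
#   g_counts:  4-tuple of guanine counts per tract
#   loop_spans: 3-tuple of (start, end) strand-local loop intervals
#   bulge:     None or (tract_index, offset_in_tract, bulge_start, bulge_end)
_Candidate = tuple[int, int, tuple[int, ...], tuple[tuple[int, int], ...], tuple | None]


def _candidate_key(cand: _Candidate):
    start, end, g_counts, loop_spans, bulge = cand
    total_loop = sum(e - s for s, e in loop_spans)
    if bulge is None:
        btie = (0, 0, 0)
    else:
        tract_index, offset, bstart, bend = bulge
        btie = (bend - bstart, tract_index, offset)
    return (start, -min(g_counts), total_loop, end - start) + btie


def _has_n(seq: str, start: int, end: int) -> bool:
    return seq.find("N", start, end) != -1


def _enumerate_canonical(seq: str, runs: Sequence[tuple[int, int]],
                         params: GrammarParams) -> Iterator[_Candidate]:
    mg, lmin, lmax = params.min_g, params.loop_min, params.loop_max
    lens = [e - s for s, e in runs]
    for j in range(len(runs) - 3):
        if (lens[j] < mg or lens[j + 1] < mg
                or lens[j + 2] < mg or lens[j + 3] < mg):
            continue
        r0, r1, r2, r3 = runs[j], runs[j + 1], runs[j + 2], runs[j + 3]
        gaps = (r1[0] - r0[1], r2[0] - r1[1], r3[0] - r2[1])
        if not all(lmin <= g <= lmax for g in gaps):
            continue
        if _has_n(seq, r0[1], r3[0]):
            continue
        loop_spans = ((r0[1], r1[0]), (r1[1], r2[0]), (r2[1], r3[0]))
        inner = (lens[j + 1], lens[j + 2])
        for s in range(r0[0], r0[1] - mg + 1):
            for e in range(r3[0] + mg, r3[1] + 1):
                g_counts = (r0[1] - s, *inner, e - r3[0])
                yield (s, e, g_counts, loop_spans, None)


def _enumerate_bulged(seq: str, runs: Sequence[tuple[int, int]],
                      params: GrammarParams) -> Iterator[_Candidate]:
    mg, lmin, lmax = params.min_g, params.loop_min, params.loop_max
    bmin, bmax = params.bulge_min, params.bulge_max
    lens = [e - s for s, e in runs]
    n_runs = len(runs)
    for j in range(n_runs - 4):
        win = [runs[j + k] for k in range(5)]
        gaps = [win[k + 1][0] - win[k][1] for k in range(4)]
        for i in range(4):  # merge runs (j+i, j+i+1) into the bulged tract
            if not bmin <= gaps[i] <= bmax:
                continue
            loop_gaps = [gaps[k] for k in range(4) if k != i]
            if not all(lmin <= g <= lmax for g in loop_gaps):
                continue
            # intact tracts: every run not in the merged pair; interior ones
            # must carry >= min_g guanines in full.
            intact = [k for k in range(5) if k != i and k != i + 1]
            if any(lens[j + k] < mg for k in intact if 0 < k < 4):
                continue
            if 0 in intact and lens[j] < mg:
                continue
            if 4 in intact and lens[j + 4] < mg:
                continue
            if _has_n(seq, win[0][1], win[4][0]):
                continue
            # edge trim ranges
            if i == 0:   # left half of the bulged tract is a run-j suffix
                left_opts = range(max(1, mg - lens[j + 1]), lens[j] + 1)
            else:
                left_opts = range(mg, lens[j] + 1)
            if i == 3:   # right half of the bulged tract is a run-(j+4) prefix
                right_opts = range(max(1, mg - lens[j + 3]), lens[j + 4] + 1)
            else:
                right_opts = range(mg, lens[j + 4] + 1)
            pair_l, pair_r = win[i], win[i + 1]
            bulge_span = (pair_l[1], pair_r[0])
            for lo in left_opts:
                s = win[0][1] - lo
                for ro in right_opts:
                    e = win[4][0] + ro
                    g_counts = []
                    tract_index = None
                    k = 0
                    idx = 0
                    while k < 5:
                        if k == i:
                            gl = lo if k == 0 else lens[j + k]
                            gr = ro if k + 1 == 4 else lens[j + k + 1]
                            g_counts.append(gl + gr)
                            tract_index = idx
                            offset = gl
                            k += 2
                        else:
                            if k == 0:
                                g_counts.append(lo)
                            elif k == 4:
                                g_counts.append(ro)
                            else:
                                g_counts.append(lens[j + k])
                            k += 1
                        idx += 1
                    if g_counts[tract_index] < mg:
                        continue
                    spans = []
                    for k in range(4):
                        if k == i:
                            continue
                        spans.append((win[k][1], win[k + 1][0]))
                    yield (
                        s, e, tuple(g_counts), tuple(spans),
                        (tract_index, offset, bulge_span[0], bulge_span[1]),
                    )


def _greedy_select(candidates: Iterable[_Candidate]) -> list[_Candidate]:
    """Leftmost-greedy non-overlapping selection with the tie-break key."""
    selected: list[_Candidate] = []
    max_end = -1
    for cand in sorted(candidates, key=_candidate_key):
        if cand[0] >= max_end:
            selected.append(cand)
            max_end = cand[1]
    return selected


def _overlaps_any(cand: _Candidate, starts: list[int], ends: list[int]) -> bool:
    # intervals in (starts, ends) are sorted and non-overlapping
    idx = bisect_right(starts, cand[1] - 1) - 1
    return idx >= 0 and ends[idx] > cand[0]


def _build_motif(seq: str, cand: _Candidate, chrom: str, strand: str,
                 seq_len: int, flank_width: int) -> G4Motif:
    start, end, g_counts, loop_spans, bulge = cand
    tracts = []
    pos = start
    spans = list(loop_spans)
    if bulge is not None:
        b_tract, b_offset, b_start, b_end = bulge
    for idx in range(4):
        if bulge is not None and idx == b_tract:
            ann = BulgeAnnotation(
                tract_index=idx,
                offset_in_tract=b_offset,
                size=b_end - b_start,
                sequence=seq[b_start:b_end],
            )
        else:
            ann = None
        tracts.append(GTract(start=pos - start, g_count=g_counts[idx], bulge=ann))
        pos += g_counts[idx] + (ann.size if ann else 0)
        if idx < 3:
            ls, le = spans[idx]
            pos += le - ls
    loops = tuple(
        (le - ls, seq[ls:le]) for ls, le in loop_spans
    )
    flank5 = seq[max(0, start - flank_width):start]
    flank3 = seq[end:min(seq_len, end + flank_width)]
    if strand == "+":
        g_start, g_end = start, end
    else:
        g_start, g_end = seq_len - end, seq_len - start
    return G4Motif(
        chrom=chrom,
        start=g_start,
        end=g_end,
        strand=strand,
        n_tetrads=min(g_counts),
        tracts=tuple(tracts),
        loop_set=LoopSet(loops=loops),
        flank5=flank5,
        flank3=flank3,
        sequence=seq[start:end],
    )


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise InputError(
            f"sequence contains invalid characters: {sorted(bad)}"
        )
    return seq


def _scan_strand(seq: str, chrom: str, strand: str, params: GrammarParams
                 ) -> tuple[list[G4Motif], list[G4Motif]]:
    """Scan one strand-local sequence; returns (canonical, bulged) motifs."""
    runs = [(m.start(), m.end()) for m in _G_RUN.finditer(seq)]
    seq_len = len(seq)
    canonical_sel = _greedy_select(_enumerate_canonical(seq, runs, params))
    starts = [c[0] for c in canonical_sel]
    ends = [c[1] for c in canonical_sel]
    bulged_cands = [
        c for c in _enumerate_bulged(seq, runs, params)
        if not _overlaps_any(c, starts, ends)
    ]
    bulged_sel = _greedy_select(bulged_cands)
    build = lambda c: _build_motif(seq, c, chrom, strand, seq_len,
                                   params.flank_width)
    return [build(c) for c in canonical_sel], [build(c) for c in bulged_sel]


def _scan(sequence: str, params: GrammarParams, chrom: str
          ) -> tuple[list[G4Motif], list[G4Motif]]:
    seq = _check_sequence(sequence)
    canonical, bulged = _scan_strand(seq, chrom, "+", params)
    if params.both_strands:
        rc = reverse_complement(seq)
        c_minus, b_minus = _scan_strand(rc, chrom, "-", params)
        canonical += c_minus
        bulged += b_minus
    key = lambda m: (m.start, m.end, m.strand)
    return sorted(canonical, key=key), sorted(bulged, key=key)


def find_canonical_pqs(sequence: str, params: GrammarParams | None = None,
                       chrom: str = "seq") -> list[G4Motif]:
    """Locate canonical (bulge-free) PQS motifs in ``sequence``."""
    params = params or GrammarParams()
    return _scan(sequence, params, chrom)[0]


def find_bulged_pqs(sequence: str, params: GrammarParams | None = None,
                    chrom: str = "seq") -> list[G4Motif]:
    """Locate single-bulge PQS motifs.

    Loci matched by the canonical grammar are never reported as bulged:
    bulged candidates overlapping a selected canonical motif on the same
    strand are discarded before selection.
    """
    params = params or GrammarParams()
    return _scan(sequence, params, chrom)[1]


def find_all_pqs(sequence: str, params: GrammarParams | None = None,
                 chrom: str = "seq") -> tuple[list[G4Motif], list[G4Motif]]:
    """Scan once and return ``(canonical, bulged)`` motif lists."""
    params = params or GrammarParams()
    return _scan(sequence, params, chrom)


def scan_sequences(sequences: dict[str, str],
                   params: GrammarParams | None = None,
                   include_bulged: bool = True) -> list[G4Motif]:
    """Scan a dict of named sequences (e.g. a FASTA) for PQS motifs."""
    params = params or GrammarParams()
    motifs: list[G4Motif] = []
    for chrom, seq in sequences.items():
        canonical, bulged = _scan(seq, params, chrom)
        motifs.extend(canonical)
        if include_bulged:
            motifs.extend(bulged)
    motifs.sort(key=lambda m: (m.chrom, m.start, m.end, m.strand))
    return motifs


# ---------------------------------------------------------------------------
# feature classifiers
# ---------------------------------------------------------------------------

def classify_permutation(loop_set: LoopSet | Sequence[int]) -> PermutationClass:
    """Classify the ordering pattern of the three loop lengths.

    Three distinct lengths map to an s/m/l rank label (e.g. ``s-l-m`` for
    short-long-median); a single equal pair maps to a positional x/y/z
    pattern where the equal positions share the letter of the earlier one
    (``x-x-z``, ``x-y-x`` or ``x-y-y``).
    """
    lengths = loop_set.lengths if isinstance(loop_set, LoopSet) else tuple(loop_set)
    if len(lengths) != 3 or any(l < 1 for l in lengths):
        raise InputError(f"need 3 loop lengths >= 1, got {lengths!r}")
    a, b, c = lengths
    if a == b == c:
        return PermutationClass(shape="all_equal", label="x-x-x")
    if a != b and b != c and a != c:
        order = sorted(lengths)
        rank = {order[0]: "s", order[1]: "m", order[2]: "l"}
        return PermutationClass(
            shape="x!=y!=z", label="-".join(rank[l] for l in lengths)
        )
    # exactly one equal pair
    if a == b:
        pattern, pair, odd = "x-x-z", a, c
    elif a == c:
        pattern, pair, odd = "x-y-x", a, b
    else:
        pattern, pair, odd = "x-y-y", b, a
    shape = "x=y>z" if pair > odd else "x=y<z"
    return PermutationClass(shape=shape, label=pattern)


def loop_class(motif: G4Motif | Sequence[int]) -> str:
    """Loop-length class: ``all_1nt``, ``max_2nt`` or ``long``."""
    lengths = motif.loop_set.lengths if isinstance(motif, G4Motif) else tuple(motif)
    longest = max(lengths)
    if longest == 1:
        return "all_1nt"
    if longest == 2:
        return "max_2nt"
    return "long"


def classify_telomeric_variant(motif: G4Motif) -> str:
    """Classify a motif against the human telomeric repeat (GGGTTA)n.

    ``WT``: three TTA loops on a bulge-free core of four exact GGG
    tracts.  ``A_to_T_variant``: same core, loops drawn from {TTA, TTT}
    with at least one TTA->TTT substitution.  Anything else is
    ``not_telomeric``.
    """
    if motif.is_bulged or any(t.g_count != 3 for t in motif.tracts):
        return "not_telomeric"
    loops = motif.loop_set.sequences
    if any(loop not in ("TTA", "TTT") for loop in loops):
        return "not_telomeric"
    if all(loop == "TTA" for loop in loops):
        return "WT"
    return "A_to_T_variant"


def match_flank_motif(motif: G4Motif, side: str, pattern: str) -> bool:
    """Anchored IUPAC match of ``pattern`` against a motif flank.

    A 5' pattern is right-anchored at the motif start (it matches the
    flank bases immediately upstream); a 3' pattern is left-anchored at
    the motif end.  Matching is on the motif strand.  A flank truncated
    below the pattern length (contig edge) never matches.
    """
    if side not in ("5p", "3p"):
        raise ConfigError(f"side must be '5p' or '3p', got {side!r}")
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC_CODES)
    if bad:
        raise ConfigError(f"invalid IUPAC codes in pattern: {sorted(bad)}")
    flank = motif.flank5 if side == "5p" else motif.flank3
    if len(flank) < len(pattern):
        return False
    window = flank[-len(pattern):] if side == "5p" else flank[:len(pattern)]
    return all(base in IUPAC_CODES[code] for base, code in zip(window, pattern))
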
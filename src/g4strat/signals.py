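"""Per-base stability signals and per-motif stability scores.

Two score kinds are supported, both read from 4-column bedGraph:

* ``mm_pct`` — mismatch percentage (0-100).  Elevated values downstream
  of a stable G4 reflect polymerase stalling, so higher means more
  stable as-is.
* ``phred_quality`` — Phred+33 base quality (0-41).  Quality drops at
  stable G4s, so values are transformed with ``ln(41.1 - x)`` to put
  them on the same higher-is-more-stable scale; the transform is
  strictly decreasing and steepest near the 41 ceiling, where the
  discrimination matters most.

A motif's stability score is the mean signal (transformed for quality)
over the motif footprint, optionally extended by a 3' window to capture
the downstream stall signature.  Uncovered bases are skipped; motifs
with zero covered bases are flagged for exclusion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError, InputError
from .grammar import G4Motif

__all__ = [
    "SCORE_KINDS",
    "SignalTrack",
    "ScoredMotif",
    "transform_quality",
    "inverse_transform_quality",
    "read_bedgraph",
    "write_bedgraph",
    "motif_stability_score",
    "score_motifs",
]

logger = logging.getLogger(__name__)

#: value range (inclusive) per score kind
SCORE_KINDS = {"mm_pct": (0.0, 100.0), "phred_quality": (0.0, 41.0)}

#: tolerance absorbing float round-trips at the quality boundaries
_BOUND_TOL = 1e-6


def transform_quality(x):
    """``ln(41.1 - x)`` for Phred qualities ``0 <= x <= 41``.

    Accepts a scalar or array; strictly decreasing in ``x``.  Values
    outside [0, 41] (beyond a 1e-6 tolerance) raise :class:`DomainError`
    naming the offending position.
    """
    arr = np.asarray(x, dtype=float)
    bad = (arr < -_BOUND_TOL) | (arr > 41.0 + _BOUND_TOL)
    if np.any(bad):
        pos = int(np.argmax(bad))
        raise DomainError(
            f"quality value {arr.reshape(-1)[pos] if arr.ndim else float(arr)}"
            f" at position {pos} outside [0, 41]"
        )
    out = np.log(41.1 - np.clip(arr, 0.0, 41.0))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def inverse_transform_quality(t):
    """Inverse of :func:`transform_quality`: ``41.1 - exp(t)``."""
    arr = np.asarray(t, dtype=float)
    out = 41.1 - np.exp(arr)
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


@dataclass
class SignalTrack:
    """Sparse per-base numeric track over a genome.

    ``data`` maps chromosome -> (positions, values); positions are
    sorted, unique, 0-based.
    """

    kind: str
    data: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SCORE_KINDS:
            raise ConfigError(
                f"unknown score kind {self.kind!r}; expected one of "
                f"{sorted(SCORE_KINDS)}"
            )

    @classmethod
    def from_intervals(cls, intervals, kind: str, source: str = "<intervals>"):
        """Build a track from (chrom, start, end, value) records.

        Interval values are expanded per base; where intervals overlap
        the record appearing later wins (a warning is logged).
        """
        track = cls(kind=kind)
        lo, hi = SCORE_KINDS[kind]
        per_chrom: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        for chrom, start, end, value in intervals:
            if end <= start or start < 0:
                raise InputError(
                    f"{source}: invalid interval {chrom}:{start}-{end}"
                )
            if value < lo - _BOUND_TOL or value > hi + _BOUND_TOL:
                raise DomainError(
                    f"{source}: value {value} at {chrom}:{start}-{end} "
                    f"outside [{lo}, {hi}] for kind {kind!r}"
                )
            pos = np.arange(start, end, dtype=np.int64)
            per_chrom.setdefault(chrom, []).append(
                (pos, np.full(len(pos), float(value)))
            )
        for chrom, chunks in per_chrom.items():
            pos = np.concatenate([p for p, _ in chunks])
            val = np.concatenate([v for _, v in chunks])
            # last occurrence wins: unique() on the reversed arrays keeps
            # the latest record for each duplicated position
            upos, idx = np.unique(pos[::-1], return_index=True)
            if len(upos) < len(pos):
                logger.warning(
                    "%s: %d overlapping base(s) on %s; last record wins",
                    source, len(pos) - len(upos), chrom,
                )
            track.data[chrom] = (upos, val[::-1][idx])
        return track

    def values_in(self, chrom: str, start: int, end: int
                  ) -> tuple[np.ndarray, int]:
        """Covered values in [start, end); returns (values, span length)."""
        span = max(0, end - start)
        if chrom not in self.data:
            return np.empty(0), span
        pos, val = self.data[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return val[lo:hi], span

    def n_positions(self) -> int:
        return sum(len(p) for p, _ in self.data.values())


def read_bedgraph(path, kind: str) -> SignalTrack:
    """Read a 4-column bedGraph (0-based half-open) into a track."""
    if kind not in SCORE_KINDS:
        raise ConfigError(f"unknown score kind {kind!r}")
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if (not line or line.startswith("#")
                    or line.startswith(("track", "browser"))):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise InputError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            intervals.append((chrom, start, end, value))
    return SignalTrack.from_intervals(intervals, kind, source=str(path))


def write_bedgraph(source, path) -> None:
    """Write a track, record frame or (chrom, start, end, value) iterable
    as bedGraph text."""
    records: object
    if isinstance(source, SignalTrack):
        records = []
        for chrom in sorted(source.data):
            pos, val = source.data[chrom]
            for p, v in zip(pos, val):
                records.append((chrom, int(p), int(p) + 1, float(v)))
    elif hasattr(source, "itertuples"):  # pandas frame
        records = source.itertuples(index=False)
    else:
        records = source
    with open(path, "w") as handle:
        for chrom, start, end, value in records:
            handle.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


@dataclass(frozen=True)
class ScoredMotif:
    """A motif joined to its aggregated stability score.

    ``score`` is on the higher-is-more-stable scale (mean raw MM%, or
    mean transformed quality); NaN when no base of the aggregation span
    was covered, in which case ``excluded`` is True.
    """

    motif: G4Motif
    score: float
    kind: str
    coverage: float
    n_covered: int

    @property
    def excluded(self) -> bool:
        return self.n_covered == 0


def _aggregation_span(motif: G4Motif, window_3p: int) -> tuple[int, int]:
    # the stall signature sits 3' of the motif on the motif strand:
    # rightward on +, leftward on -
    if motif.strand == "+":
        return motif.start, motif.end + window_3p
    return max(0, motif.start - window_3p), motif.end


def motif_stability_score(motif: G4Motif, track: SignalTrack,
                          window_3p: int = 0) -> ScoredMotif:
    """Aggregate the track over the motif footprint (+ optional 3' window)."""
    if window_3p < 0:
        raise ConfigError("window_3p must be >= 0")
    start, end = _aggregation_span(motif, window_3p)
    values, span = track.values_in(motif.chrom, start, end)
    if len(values) == 0:
        return ScoredMotif(motif=motif, score=math.nan, kind=track.kind,
                           coverage=0.0, n_covered=0)
    if track.kind == "phred_quality":
        values = transform_quality(values)
    return ScoredMotif(
        motif=motif,
        score=float(np.mean(values)),
        kind=track.kind,
        coverage=len(values) / span if span else 0.0,
        n_covered=int(len(values)),
    )


def score_motifs(motifs, track: SignalTrack, window_3p: int = 0
                 ) -> tuple[list[ScoredMotif], int]:
    """Score motifs against a track; returns (kept, n_excluded).

    Motifs without any covered base are excluded (counted and logged).
    """
    scored = [motif_stability_score(m, track, window_3p) for m in motifs]
    kept = [s for s in scored if not s.excluded]
    n_excluded = len(scored) - len(kept)
    if n_excluded:
        logger.warning(
            "%d of %d motifs had no signal coverage and were excluded",
            n_excluded, len(scored),
        )
    return kept, n_excluded
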
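"""Readers and writers for the package's file formats.

Motifs travel as headerless BED6+ with the structural decomposition in
extra tab-separated columns (see :data:`MOTIF_BED_COLUMNS`); the
decomposition is complete, so a motif read back from BED is
reconstructed exactly, including tract offsets and its sequence.
Scored motifs travel as TSV with a header.  FASTA goes through
Biopython.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .grammar import BulgeAnnotation, G4Motif, GTract, LoopSet, classify_permutation
from .signals import ScoredMotif

__all__ = [
    "MOTIF_BED_COLUMNS",
    "read_fasta",
    "write_fasta",
    "write_motif_bed",
    "read_motif_bed",
    "write_scored_tsv",
    "read_scored_tsv",
]

MOTIF_BED_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "nt", "ll1", "ll2", "ll3", "bulge_size", "bulge_tract",
    "flank5", "flank3", "perm_label",
    "loops", "tract_gs", "bulge_offset", "bulge_seq",
]


def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA -> {name: uppercase sequence}."""
    sequences = {rec.id: str(rec.seq).upper()
                 for rec in SeqIO.parse(str(path), "fasta")}
    if not sequences:
        raise InputError(f"{path}: no FASTA records found")
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def motif_to_row(motif: G4Motif, name: str = ".") -> dict:
    bulge = motif.bulge
    return dict(
        chrom=motif.chrom, start=motif.start, end=motif.end, name=name,
        score=motif.n_tetrads, strand=motif.strand,
        nt=motif.n_tetrads,
        ll1=motif.loop_set.lengths[0], ll2=motif.loop_set.lengths[1],
        ll3=motif.loop_set.lengths[2],
        bulge_size=bulge.size if bulge else 0,
        bulge_tract=bulge.tract_index if bulge else -1,
        flank5=motif.flank5 or ".", flank3=motif.flank3 or ".",
        perm_label=classify_permutation(motif.loop_set).label,
        loops=",".join(motif.loop_set.sequences),
        tract_gs=",".join(str(t.g_count) for t in motif.tracts),
        bulge_offset=bulge.offset_in_tract if bulge else -1,
        bulge_seq=bulge.sequence if bulge else ".",
    )


def row_to_motif(row) -> G4Motif:
    """Rebuild a full :class:`G4Motif` from one BED6+ row."""
    g_counts = [int(g) for g in str(row["tract_gs"]).split(",")]
    loops = str(row["loops"]).split(",") if str(row["loops"]) else ["", "", ""]
    if len(g_counts) != 4 or len(loops) != 3:
        raise InputError(f"malformed motif row: {dict(row)!r}")
    bulge_size = int(row["bulge_size"])
    bulge = None
    if bulge_size > 0:
        bulge = BulgeAnnotation(
            tract_index=int(row["bulge_tract"]),
            offset_in_tract=int(row["bulge_offset"]),
            size=bulge_size,
            sequence=str(row["bulge_seq"]),
        )
    tracts = []
    seq_parts = []
    pos = 0
    for i in range(4):
        ann = bulge if bulge is not None and bulge.tract_index == i else None
        tracts.append(GTract(start=pos, g_count=g_counts[i], bulge=ann))
        if ann is not None:
            seq_parts.append("G" * ann.offset_in_tract + ann.sequence
                             + "G" * (g_counts[i] - ann.offset_in_tract))
            pos += g_counts[i] + ann.size
        else:
            seq_parts.append("G" * g_counts[i])
            pos += g_counts[i]
        if i < 3:
            seq_parts.append(loops[i])
            pos += len(loops[i])
    flank5 = "" if str(row["flank5"]) == "." else str(row["flank5"])
    flank3 = "" if str(row["flank3"]) == "." else str(row["flank3"])
    return G4Motif(
        chrom=str(row["chrom"]), start=int(row["start"]), end=int(row["end"]),
        strand=str(row["strand"]), n_tetrads=min(g_counts),
        tracts=tuple(tracts),
        loop_set=LoopSet(loops=tuple((len(l), l) for l in loops)),
        flank5=flank5, flank3=flank3, sequence="".join(seq_parts),
    )


def write_motif_bed(motifs, path) -> None:
    rows = [motif_to_row(m, name=f"pqs_{i + 1}")
            for i, m in enumerate(motifs)]
    frame = pd.DataFrame(rows, columns=MOTIF_BED_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, header=False)


def read_motif_bed(path) -> list[G4Motif]:
    try:
        frame = pd.read_csv(path, sep="\t", header=None,
                            names=MOTIF_BED_COLUMNS, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    return [row_to_motif(row) for _, row in frame.iterrows()]


SCORED_COLUMNS = MOTIF_BED_COLUMNS + ["kind", "stability_score", "coverage",
                                      "n_covered"]


def write_scored_tsv(scored, path) -> None:
    rows = []
    for i, s in enumerate(scored):
        row = motif_to_row(s.motif, name=f"pqs_{i + 1}")
        row.update(kind=s.kind, stability_score=s.score,
                   coverage=s.coverage, n_covered=s.n_covered)
        rows.append(row)
    pd.DataFrame(rows, columns=SCORED_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_scored_tsv(path) -> list[ScoredMotif]:
    frame = pd.read_csv(path, sep="\t", dtype={"loops": str, "flank5": str,
                                               "flank3": str,
                                               "tract_gs": str,
                                               "bulge_seq": str})
    scored = []
    for _, row in frame.iterrows():
        scored.append(ScoredMotif(
            motif=row_to_motif(row),
            score=float(row["stability_score"]),
            kind=str(row["kind"]),
            coverage=float(row["coverage"]),
            n_covered=int(row["n_covered"]),
        ))
    return scored
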
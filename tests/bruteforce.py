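"""Independent brute-force oracles used by the test suite.

These re-derive expected results from first principles — substring
enumeration for the PQS grammar, full permutation enumeration for the
rank-sum null — and never call into the package's scanning or testing
code paths.
"""

from __future__ import annotations

import re
from itertools import combinations

_G_RUN = re.compile(r"G+")


def _runs(seq):
    return [(m.start(), m.end()) for m in _G_RUN.finditer(seq)]


def _key(cand):
    start, end, g_counts, loops, bulge = cand
    total_loop = sum(len(l) for l in loops)
    if bulge is None:
        btie = (0, 0, 0)
    else:
        btie = (len(bulge[2]), bulge[0], bulge[1])
    return (start, -min(g_counts), total_loop, end - start) + btie


def _greedy(cands):
    out, max_end = [], -1
    for c in sorted(cands, key=_key):
        if c[0] >= max_end:
            out.append(c)
            max_end = c[1]
    return out


def _canonical_parse(sub, min_g, loop_min, loop_max):
    """Parse a substring as a canonical PQS, or return None."""
    if "N" in sub:
        return None
    runs = _runs(sub)
    if len(runs) != 4:
        return None
    if runs[0][0] != 0 or runs[-1][1] != len(sub):
        return None
    if any(e - s < min_g for s, e in runs):
        return None
    loops = [sub[runs[k][1]:runs[k + 1][0]] for k in range(3)]
    if any(not loop_min <= len(l) <= loop_max for l in loops):
        return None
    return tuple(e - s for s, e in runs), tuple(loops)


def _bulged_parses(sub, min_g, loop_min, loop_max, bulge_min, bulge_max):
    """All single-bulge parses of a substring (bulges are G-free)."""
    if "N" in sub:
        return []
    runs = _runs(sub)
    if len(runs) != 5 or runs[0][0] != 0 or runs[-1][1] != len(sub):
        return []
    lens = [e - s for s, e in runs]
    gaps = [runs[k + 1][0] - runs[k][1] for k in range(4)]
    parses = []
    for i in range(4):
        if not bulge_min <= gaps[i] <= bulge_max:
            continue
        if any(not loop_min <= gaps[k] <= loop_max
               for k in range(4) if k != i):
            continue
        if any(lens[k] < min_g for k in range(5) if k not in (i, i + 1)):
            continue
        if lens[i] + lens[i + 1] < min_g:
            continue
        g_counts = []
        loops = []
        bulge = None
        idx = 0
        k = 0
        while k < 5:
            if k == i:
                g_counts.append(lens[k] + lens[k + 1])
                bulge = (idx, lens[k], sub[runs[k][1]:runs[k + 1][0]])
                k += 2
            else:
                g_counts.append(lens[k])
                k += 1
            if k <= 4:
                loops.append(sub[runs[k - 1][1]:runs[k][0]])
            idx += 1
        parses.append((tuple(g_counts), tuple(loops), bulge))
    return parses


def oracle_scan(seq, min_g=3, loop_min=1, loop_max=7, bulge_min=1,
                bulge_max=8):
    """Brute-force single-strand scan by testing every substring.

    Returns (canonical, bulged) lists of normalised decompositions:
    ``(start, end, g_counts, loop_seqs, bulge)`` with
    ``bulge = (tract_index, offset, sequence)`` or None.
    """
    seq = seq.upper()
    n = len(seq)
    run_list = _runs(seq)
    max_run = max((e - s for s, e in run_list), default=0)
    cap = 4 * max_run + 3 * loop_max + bulge_max
    canonical, bulged = [], []
    g_pos = [i for i in range(n) if seq[i] == "G"]
    g_set = set(g_pos)
    for i in g_pos:
        for j in range(i + 1, min(n, i + cap) + 1):
            if (j - 1) not in g_set:
                continue
            sub = seq[i:j]
            parse = _canonical_parse(sub, min_g, loop_min, loop_max)
            if parse is not None:
                canonical.append((i, j, parse[0], parse[1], None))
            for g_counts, loops, bulge in _bulged_parses(
                    sub, min_g, loop_min, loop_max, bulge_min, bulge_max):
                bulged.append((i, j, g_counts, loops, bulge))
    canonical_sel = _greedy(canonical)
    blocked = [(c[0], c[1]) for c in canonical_sel]
    bulged = [
        c for c in bulged
        if not any(s < c[1] and e > c[0] for s, e in blocked)
    ]
    return canonical_sel, _greedy(bulged)


def normalise_motif(motif):
    """Package motif -> the oracle's decomposition tuple (strand-local)."""
    bulge = motif.bulge
    return (
        motif.start, motif.end,
        tuple(t.g_count for t in motif.tracts),
        motif.loop_set.sequences,
        (bulge.tract_index, bulge.offset_in_tract, bulge.sequence)
        if bulge else None,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum by exhaustive permutation
# ---------------------------------------------------------------------------

def oracle_wilcoxon(a, b):
    """Exact two-sided rank-sum p by enumerating all group labelings.

    Handles ties through the pair-count definition of U
    (#{a_i > b_j} + 0.5 #{a_i == b_j}); the p-value doubles the smaller
    tail (capped at 1), counting the observed U into both tails.
    """
    a, b = list(a), list(b)
    pooled = a + b
    m = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    observed = u_stat(a, b)
    us = []
    idx = range(len(pooled))
    for chosen in combinations(idx, m):
        chosen_set = set(chosen)
        ga = [pooled[i] for i in chosen]
        gb = [pooled[i] for i in idx if i not in chosen_set]
        us.append(u_stat(ga, gb))
    total = len(us)
    eps = 1e-9
    p_le = sum(u <= observed + eps for u in us) / total
    p_ge = sum(u >= observed - eps for u in us) / total
    return observed, min(1.0, 2.0 * min(p_le, p_ge))
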
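"""Feature-stratified statistics over scored PQS motifs.

Scored motifs are grouped by a structural feature (tetrad layers by
loop class, bulge presence/size, total loop length, loop permutation,
telomeric A-to-T status, 1-nt loop base composition, or flank class),
each group is summarised by the mean and SD of 1000 scores resampled
with replacement, and the feature-specific pairwise contrasts are tested
with the two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

Raw p-values drive the significance symbols (ns / * / ** / *** at
0.05 / 0.01 / 0.001); a Benjamini-Hochberg adjusted column is emitted
alongside for transparency but not used for the symbols.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, InputError
from .grammar import (
    G4Motif,
    classify_permutation,
    classify_telomeric_variant,
    loop_class,
    match_flank_motif,
)

__all__ = [
    "FEATURE_IDS",
    "ReportConfig",
    "GroupSummary",
    "FeatureReport",
    "group_motifs",
    "resampled_mean",
    "wilcoxon_rank_sum",
    "run_feature_report",
    "significance_symbol",
]

#: sample sizes up to which the exact U null is enumerated (no ties)
EXACT_LIMIT = 12

LOOP_CLASSES = ("all_1nt", "max_2nt", "long")
PERMUTATION_LABELS = (
    "s-m-l", "s-l-m", "m-s-l", "m-l-s", "l-s-m", "l-m-s",
    "x-x-z|x=y>z", "x-y-x|x=y>z", "x-y-y|x=y>z",
    "x-x-z|x=y<z", "x-y-x|x=y<z", "x-y-y|x=y<z",
)
COMPOSITION_LABELS = tuple(
    f"{a}-{b}" for a, b in product("ACT", repeat=2)
)


@dataclass(frozen=True)
class ReportConfig:
    """Knobs of the stratified reports."""

    resample_n: int = 1000
    seed: int = 0
    min_layers: int = 3
    max_layers: int = 5
    max_total_loop: int = 21
    flank5_patterns: tuple[str, str] = ("NNNTT", "NNTGA")
    flank3_patterns: tuple[str, str] = ("GAANN", "TTNNN")

    def __post_init__(self) -> None:
        if self.resample_n < 1:
            raise ConfigError("resample_n must be >= 1")


def significance_symbol(p: float) -> str:
    if math.isnan(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def _is_canonical_3layer(m: G4Motif) -> bool:
    return not m.is_bulged and m.n_tetrads == 3


def _group_layers_by_loopclass(scored, config):
    labels = [
        f"NT{nt}|{lc}"
        for lc in LOOP_CLASSES
        for nt in range(config.min_layers, config.max_layers + 1)
    ]
    groups = OrderedDict((lab, []) for lab in labels)
    excluded = 0
    for s in scored:
        m = s.motif
        if m.is_bulged or not (config.min_layers <= m.n_tetrads
                               <= config.max_layers):
            excluded += 1
            continue
        groups[f"NT{m.n_tetrads}|{loop_class(m)}"].append(s.score)
    return groups, excluded


def _group_bulge_presence(scored, config):
    groups = OrderedDict((lab, []) for lab in ("no_bulge", "bulge"))
    excluded = 0
    for s in scored:
        m = s.motif
        if m.n_tetrads != 3 or loop_class(m) != "all_1nt":
            excluded += 1
            continue
        groups["bulge" if m.is_bulged else "no_bulge"].append(s.score)
    return groups, excluded


def _group_bulge_size(scored, config):
    groups = OrderedDict((str(size), []) for size in range(1, 9))
    excluded = 0
    for s in scored:
        m = s.motif
        if (not m.is_bulged or m.n_tetrads != 3
                or loop_class(m) != "all_1nt" or not 1 <= m.bulge.size <= 8):
            excluded += 1
            continue
        groups[str(m.bulge.size)].append(s.score)
    return groups, excluded


def _group_total_loop_length(scored, config):
    # conditioned on three-layer canonical motifs so the loop-length
    # effect is not confounded with tetrad-layer effects
    groups = OrderedDict(
        (str(total), []) for total in range(3, config.max_total_loop + 1)
    )
    excluded = 0
    for s in scored:
        m = s.motif
        total = m.loop_set.total_length
        if not _is_canonical_3layer(m) or not 3 <= total <= config.max_total_loop:
            excluded += 1
            continue
        groups[str(total)].append(s.score)
    return groups, excluded


def _permutation_label(m: G4Motif) -> str | None:
    cls = classify_permutation(m.loop_set)
    if cls.shape == "all_equal":
        return None
    if cls.shape == "x!=y!=z":
        return cls.label
    return f"{cls.label}|{cls.shape}"


def _group_permutation(scored, config):
    groups = OrderedDict((lab, []) for lab in PERMUTATION_LABELS)
    excluded = 0
    for s in scored:
        m = s.motif
        label = _permutation_label(m) if _is_canonical_3layer(m) else None
        if label is None:
            excluded += 1
            continue
        groups[label].append(s.score)
    return groups, excluded


def _group_telomeric(scored, config):
    groups = OrderedDict((lab, []) for lab in ("WT", "A_to_T"))
    excluded = 0
    for s in scored:
        variant = classify_telomeric_variant(s.motif)
        if variant == "WT":
            groups["WT"].append(s.score)
        elif variant == "A_to_T_variant":
            groups["A_to_T"].append(s.score)
        else:
            excluded += 1
    return groups, excluded


def _group_composition(scored, config, middle_len):
    groups = OrderedDict((lab, []) for lab in COMPOSITION_LABELS)
    excluded = 0
    for s in scored:
        m = s.motif
        lengths = m.loop_set.lengths
        first, _, third = m.loop_set.sequences
        if (not _is_canonical_3layer(m)
                or lengths != (1, middle_len, 1)
                or first not in "ACT" or third not in "ACT"):
            excluded += 1
            continue
        groups[f"{first}-{third}"].append(s.score)
    return groups, excluded


def _group_flank(scored, config, side, patterns):
    groups = OrderedDict((pat, []) for pat in patterns)
    excluded = 0
    for s in scored:
        m = s.motif
        if not _is_canonical_3layer(m) or loop_class(m) != "all_1nt":
            excluded += 1
            continue
        for pat in patterns:
            if match_flank_motif(m, side, pat):
                groups[pat].append(s.score)
                break
        else:
            excluded += 1
    return groups, excluded


_GROUPERS = OrderedDict(
    [
        ("layers_by_loopclass", _group_layers_by_loopclass),
        ("bulge_presence", _group_bulge_presence),
        ("bulge_size", _group_bulge_size),
        ("total_loop_length", _group_total_loop_length),
        ("permutation", _group_permutation),
        ("telomeric_AtoT", _group_telomeric),
        ("loop_composition_131",
         lambda s, c: _group_composition(s, c, middle_len=3)),
        ("loop_composition_161",
         lambda s, c: _group_composition(s, c, middle_len=6)),
        ("flank5", lambda s, c: _group_flank(s, c, "5p", c.flank5_patterns)),
        ("flank3", lambda s, c: _group_flank(s, c, "3p", c.flank3_patterns)),
    ]
)

FEATURE_IDS = tuple(_GROUPERS)


def group_motifs(scored_motifs, feature_id: str,
                 config: ReportConfig | None = None
                 ) -> tuple["OrderedDict[str, list[float]]", int]:
    """Group scored motifs by a structural feature.

    Returns ``(label -> scores, n_excluded)``; motifs matching no
    category of the feature are excluded and counted.  Motifs flagged as
    coverage-excluded are dropped beforehand (also counted).
    """
    if feature_id not in _GROUPERS:
        raise ConfigError(
            f"unknown feature id {feature_id!r}; valid ids: "
            f"{', '.join(FEATURE_IDS)}"
        )
    config = config or ReportConfig()
    usable = [s for s in scored_motifs if not s.excluded]
    n_dropped = len(scored_motifs) - len(usable)
    groups, excluded = _GROUPERS[feature_id](usable, config)
    return groups, excluded + n_dropped


# ---------------------------------------------------------------------------
# resampling and rank tests
# ---------------------------------------------------------------------------

def resampled_mean(scores, resample_n: int = 1000, seed: int | None = None,
                   rng: np.random.Generator | None = None
                   ) -> tuple[float, float]:
    """Mean and SD of ``resample_n`` scores drawn with replacement.

    Scores are sorted before drawing so the result depends only on the
    score multiset and the seed, not on input order.  An empty list
    yields ``(nan, nan)``.
    """
    arr = np.sort(np.asarray(list(scores), dtype=float))
    if arr.size == 0:
        return math.nan, math.nan
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.choice(arr, size=resample_n, replace=True)
    sd = float(np.std(draws, ddof=1)) if resample_n > 1 else 0.0
    return float(np.mean(draws)), sd


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns ``(U, p)`` with U counted for ``a`` over ``b`` using
    midranks for ties.  In ``auto`` mode the exact null distribution is
    enumerated when ``len(a) + len(b) <= 12`` and there are no ties;
    otherwise the normal approximation with tie and continuity
    correction is used.  Two identical constant samples give ``p = 1``
    by convention.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("wilcoxon_rank_sum requires two non-empty samples")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ConfigError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "auto":
        mode = ("exact" if a.size + b.size <= EXACT_LIMIT and not has_ties
                else "asymptotic")
    if mode == "exact" and has_ties:
        mode = "asymptotic"
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Comparison:
    other_label: str
    statistic: float
    p_value: float
    symbol: str
    p_adjusted: float = math.nan


@dataclass
class GroupSummary:
    """One stratification cell of a feature report."""

    label: str
    n_motifs: int
    resample_n: int
    mean: float
    sd: float
    comparisons: list[Comparison] = field(default_factory=list)


@dataclass
class FeatureReport:
    """All group summaries for one structural feature and track kind."""

    feature_id: str
    kind: str
    groups: list[GroupSummary]
    n_excluded: int
    resample_n: int
    seed: int

    def group(self, label: str) -> GroupSummary:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)

    def means(self) -> dict[str, float]:
        return {g.label: g.mean for g in self.groups}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            if g.comparisons:
                for c in g.comparisons:
                    rows.append(
                        dict(label=g.label, n=g.n_motifs,
                             resample_n=g.resample_n, mean=g.mean, sd=g.sd,
                             vs=c.other_label, U=c.statistic, p=c.p_value,
                             p_bh=c.p_adjusted, significance=c.symbol)
                    )
            else:
                rows.append(
                    dict(label=g.label, n=g.n_motifs, resample_n=g.resample_n,
                         mean=g.mean, sd=g.sd, vs="", U=math.nan, p=math.nan,
                         p_bh=math.nan, significance="")
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _comparison_pairs(feature_id: str, groups, config: ReportConfig
                      ) -> list[tuple[str, str]]:
    """(group, reference) contrasts: each feature's natural reference."""
    nonempty = [lab for lab, sc in groups.items() if sc]
    pairs: list[tuple[str, str]] = []
    if feature_id == "layers_by_loopclass":
        # each layer count vs the previous one within a loop class
        for lc in LOOP_CLASSES:
            chain = [lab for lab in nonempty if lab.endswith(f"|{lc}")]
            pairs += list(zip(chain[1:], chain[:-1]))
    elif feature_id in ("bulge_presence", "telomeric_AtoT", "flank5", "flank3"):
        if len(nonempty) == 2:
            pairs.append((nonempty[1], nonempty[0]))
    elif feature_id == "bulge_size":
        ref = nonempty[0] if nonempty else None
        pairs += [(lab, ref) for lab in nonempty[1:]]
    elif feature_id == "total_loop_length":
        # each group vs the group immediately to its left
        pairs += list(zip(nonempty[1:], nonempty[:-1]))
    elif feature_id == "permutation":
        # each group vs the highest-mean group within its shape panel
        panels = {
            "x!=y!=z": [l for l in nonempty if "|" not in l],
            "x=y>z": [l for l in nonempty if l.endswith("x=y>z")],
            "x=y<z": [l for l in nonempty if l.endswith("x=y<z")],
        }
        for labs in panels.values():
            if len(labs) < 2:
                continue
            ref = max(labs, key=lambda l: np.mean(groups[l]))
            pairs += [(lab, ref) for lab in labs if lab != ref]
    elif feature_id in ("loop_composition_131", "loop_composition_161"):
        ref = "A-A" if "A-A" in nonempty else None
        if ref:
            pairs += [(lab, ref) for lab in nonempty if lab != ref]
    return pairs


def run_feature_report(scored_motifs, feature_id: str,
                       config: ReportConfig | None = None) -> FeatureReport:
    """Summarise and test one structural feature over scored motifs."""
    config = config or ReportConfig()
    groups, excluded = group_motifs(scored_motifs, feature_id, config)
    kind = next((s.kind for s in scored_motifs), "mm_pct")
    feature_index = FEATURE_IDS.index(feature_id)

    summaries: dict[str, GroupSummary] = {}
    for gi, (label, scores) in enumerate(groups.items()):
        rng = np.random.default_rng([config.seed, feature_index, gi])
        mean, sd = resampled_mean(scores, config.resample_n, rng=rng)
        summaries[label] = GroupSummary(
            label=label, n_motifs=len(scores), resample_n=config.resample_n,
            mean=mean, sd=sd,
        )

    pairs = _comparison_pairs(feature_id, groups, config)
    raw = []
    for lab, ref in pairs:
        u, p = wilcoxon_rank_sum(groups[lab], groups[ref])
        raw.append((lab, ref, u, p))
    if raw:
        p_adj = multipletests([r[3] for r in raw], method="fdr_bh")[1]
    else:
        p_adj = []
    for (lab, ref, u, p), q in zip(raw, p_adj):
        summaries[lab].comparisons.append(
            Comparison(other_label=ref, statistic=u, p_value=p,
                       symbol=significance_symbol(p), p_adjusted=float(q))
        )
    return FeatureReport(
        feature_id=feature_id, kind=kind,
        groups=[summaries[lab] for lab in groups],
        n_excluded=excluded, resample_n=config.resample_n, seed=config.seed,
    )
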
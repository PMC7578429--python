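"""Nonparametric group comparisons for score distributions.

Kruskal-Wallis with Dunn's all-pairs post hoc for multi-group PMHBR/PHBR
comparisons, two-tailed Mann-Whitney for pairwise comparisons, two-tailed
Wilcoxon signed-rank for paired comparisons, and proportion-matched
resampling (with replacement) for building combined control groups whose
per-mutation composition mirrors an observed group.

Rank-sum machinery is delegated to scipy.stats; Dunn's test is computed
here on pooled mid-ranks with the standard tie correction, adjusted by
all-pairs Bonferroni multiplication (capped at 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AllZeroDifferences, DegenerateInput, MissingStratum

#: pooled-size boundary below which Mann-Whitney uses exact enumeration
EXACT_MW_POOLED_MAX = 12
#: nonzero-pair boundary below which Wilcoxon uses the exact distribution
EXACT_WILCOXON_PAIRS_MAX = 15

__all__ = [
    "ScoreGroup",
    "kruskal_wallis",
    "dunn_posthoc",
    "mann_whitney",
    "wilcoxon_paired",
    "balanced_resample",
]


@dataclass
class ScoreGroup:
    """A labelled sample of positive scores, optionally annotated per value
    with the mutation (stratum) each score derives from."""

    label: str
    values: np.ndarray
    strata: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise DegenerateInput(f"group {self.label!r} is empty")
        if self.strata is not None:
            self.strata = np.asarray(self.strata)
            if self.strata.shape != self.values.shape:
                raise ValueError("strata must align with values")

    def __len__(self) -> int:
        return self.values.size


def _check_groups(groups: Sequence[ScoreGroup], min_groups: int) -> None:
    if len(groups) < min_groups:
        raise ValueError(f"need at least {min_groups} groups, got {len(groups)}")
    pooled = np.concatenate([g.values for g in groups])
    if np.all(pooled == pooled[0]):
        raise DegenerateInput("all pooled values identical")


def kruskal_wallis(groups: Sequence[ScoreGroup]) -> tuple[float, float]:
    """Rank-based H with tie correction; p from chi-square with k−1 df.

    Degenerate input (all values identical) yields (H=0, p=1) with a
    warning instead of an error, so sweep drivers keep running.
    """
    try:
        _check_groups(groups, 3)
    except DegenerateInput:
        warnings.warn("Kruskal-Wallis on identical values: H=0, p=1", stacklevel=2)
        return 0.0, 1.0
    h, p = stats.kruskal(*[g.values for g in groups])
    return float(h), float(p)


def dunn_posthoc(groups: Sequence[ScoreGroup]) -> pd.DataFrame:
    """Dunn's z-tests on pooled mid-ranks, all-pairs Bonferroni adjusted.

    Returns one row per unordered pair with columns ``group1``, ``group2``,
    ``z``, ``p_raw``, ``p_adjusted`` (raw p multiplied by the number of
    pairs, capped at 1).
    """
    try:
        _check_groups(groups, 3)
        degenerate = False
    except DegenerateInput:
        warnings.warn("Dunn post hoc on identical values: all p=1", stacklevel=2)
        degenerate = True

    pooled = np.concatenate([g.values for g in groups])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[offsets[i]: offsets[i + 1]].mean() for i in range(len(groups))
    ]
    # tie correction: sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if degenerate or variance_base <= 0:
                z, p_raw = 0.0, 1.0
            else:
                se = np.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "group1": groups[i].label,
                    "group2": groups[j].label,
                    "z": float(z),
                    "p_raw": float(p_raw),
                    "p_adjusted": float(min(1.0, p_raw * n_pairs)),
                }
            )
    return pd.DataFrame(rows)


def mann_whitney(g1: ScoreGroup, g2: ScoreGroup) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U.

    Exact enumeration when the pooled size is at most
    :data:`EXACT_MW_POOLED_MAX` and there are no ties; tie-corrected normal
    approximation (with continuity correction) otherwise.
    """
    _check_groups([g1, g2], 2)
    pooled = np.concatenate([g1.values, g2.values])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MW_POOLED_MAX and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1.values, g2.values, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank on paired samples.

    Zero differences are removed before ranking; with at most
    :data:`EXACT_WILCOXON_PAIRS_MAX` nonzero pairs the exact distribution
    is used, the normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        raise AllZeroDifferences("every within-pair difference is zero")
    method = "exact" if nonzero.size <= EXACT_WILCOXON_PAIRS_MAX else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def balanced_resample(
    group: ScoreGroup,
    target_proportions: Mapping[str, float],
    n_out: int,
    seed: int,
) -> ScoreGroup:
    """Resample ``n_out`` scores with replacement so per-stratum counts match
    ``target_proportions`` via largest-remainder rounding.

    Used to build a combined control distribution whose per-mutation score
    composition mirrors the observed case group. Reproducible under seed.
    """
    if group.strata is None:
        raise ValueError("source group carries no stratum annotation")
    rng = np.random.default_rng(seed)
    available = {str(s) for s in group.strata}
    missing = [s for s in target_proportions if s not in available]
    if missing:
        raise MissingStratum(f"strata absent from source group: {missing}")

    items = sorted(target_proportions.items())
    raw = {s: n_out * p for s, p in items}
    counts = {s: int(np.floor(v)) for s, v in raw.items()}
    shortfall = n_out - sum(counts.values())
    by_remainder = sorted(items, key=lambda kv: (-(raw[kv[0]] - counts[kv[0]]), kv[0]))
    for s, _ in by_remainder[:shortfall]:
        counts[s] += 1

    pieces = []
    strata_out = []
    for s, k in sorted(counts.items()):
        if k == 0:
            continue
        pool = group.values[np.asarray([str(t) == s for t in group.strata])]
        pieces.append(rng.choice(pool, size=k, replace=True))
        strata_out.extend([s] * k)
    return ScoreGroup(
        f"{group.label}_resampled",
        np.concatenate(pieces),
        np.asarray(strata_out),
    )
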
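"""The presentation-score algebra: BR, IBR, PHBR, PMHBR, MinRank and the
mutant-vs-wild-type criteria.

All scores start from eluted-ligand percentile ranks (lower = more likely
presented; <0.5 "strong binder", 0.5-2.0 "weak binder", >2.0 unlikely).

For a mutation m and one HLA allotype, BR(m) is the minimum rank over all
mutant windows of m whose predicted interaction core (Icore) spans the
mutated residue — a window whose Icore misses the mutation presents an
effectively wild-type sequence and is excluded. With no eligible window,
BR takes the sentinel value 100 (the rank-scale maximum: "not presented"),
which keeps harmonic means finite.

Per individual with six class I allotypes (two each for HLA-A, -B, -C):

    IBR(m)  = min_i BR_i(m)                      (best single chance)
    PHBR(m) = 6 / sum_i 1/BR_i(m)                (harmonic mean over the six)

and over a population panel, PMHBR(m) is the median PHBR. MinRank is the
per-peptide analogue of IBR: the minimum rank of one peptide across an
individual's allotypes. The mutant-vs-wild-type criteria compare mutant
and wild-type MinRanks pairwise per window, with thresholds 0.5 / 2.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInput, MissingAllotypeBR
from .haplotype_io import LOCI, Allotype, Haplotype, HaplotypePanel, common_alleles
from .mutation_catalog import MutationSet
from .peptide_factory import PeptidePair
from .predictor_gateway import RankStore

logger = logging.getLogger(__name__)

#: BR when no mutant window has a mutation-spanning Icore.
SENTINEL_BR = 100.0
#: Ranks of exactly 0 (predictor rounding) are clamped here before harmonic means.
RANK_FLOOR = 1e-3

__all__ = [
    "SENTINEL_BR",
    "RANK_FLOOR",
    "BRTable",
    "CriterionConfig",
    "icore_spans_mutation",
    "best_rank",
    "build_br_table",
    "phbr",
    "ibr",
    "pmhbr",
    "pct_presented",
    "minrank",
    "mutant_vs_wt",
    "pct_mutant_vs_wt",
    "individual_scores",
    "population_summary",
    "br_heatmap",
]


def icore_spans_mutation(pair: PeptidePair, icore: str) -> bool:
    """Whether an Icore located within the mutant window covers the mutated
    residue. All placements of the Icore substring are considered; a single
    spanning placement suffices."""
    if not icore:
        return False
    start = pair.mutant.find(icore)
    while start != -1:
        if start <= pair.mutation_offset < start + len(icore):
            return True
        start = pair.mutant.find(icore, start + 1)
    return False


def _clamp(rank: float) -> float:
    if rank < RANK_FLOOR:
        logger.info("rank %g clamped to %g", rank, RANK_FLOOR)
        return RANK_FLOOR
    return rank


def best_rank(pairs: Sequence[PeptidePair], allotype: Allotype, store: RankStore) -> float:
    """BR of a mutation for one allotype: minimum rank over mutant windows
    with a mutation-spanning Icore; :data:`SENTINEL_BR` when none is eligible."""
    eligible = []
    for pair in pairs:
        rec = store.get(pair.mutant, allotype)
        if icore_spans_mutation(pair, rec.icore):
            eligible.append(rec.rank)
    if not eligible:
        return SENTINEL_BR
    return _clamp(min(eligible))


class BRTable:
    """Per-mutation, per-allotype BR values."""

    def __init__(self):
        self._values: dict[tuple[str, str], float] = {}

    def set(self, mutation_id: str, allotype: Allotype, br: float) -> None:
        if br <= 0:
            raise DomainError(f"BR must be positive, got {br}")
        self._values[(mutation_id, str(allotype))] = br

    def get(self, mutation_id: str, allotype: Allotype) -> float:
        try:
            return self._values[(mutation_id, str(allotype))]
        except KeyError:
            raise MissingAllotypeBR(
                f"no BR for mutation {mutation_id!r}, allotype {allotype}"
            ) from None

    def mutation_ids(self) -> list[str]:
        return sorted({m for m, _ in self._values})

    def __len__(self) -> int:
        return len(self._values)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mutation_id": m, "allotype": a, "br": v} for (m, a), v in self._values.items()
        ]
        return pd.DataFrame(rows, columns=["mutation_id", "allotype", "br"])


def build_br_table(
    pairs_by_mutation: Mapping[str, Sequence[PeptidePair]],
    allotypes: Iterable[Allotype],
    store: RankStore,
) -> BRTable:
    table = BRTable()
    for mid, pairs in pairs_by_mutation.items():
        for allo in sorted(set(allotypes)):
            table.set(mid, allo, best_rank(pairs, allo, store))
    return table


def phbr(brs: Sequence[float]) -> float:
    """Harmonic mean of BR values: n / sum(1/BR_i).

    Bounded by min and max of the inputs; equals r when all inputs are r.
    """
    if len(brs) == 0:
        raise EmptyInput("harmonic mean of no values")
    if any(b <= 0 for b in brs):
        raise DomainError(f"BR values must be positive: {brs}")
    values = [_clamp(b) for b in brs]
    return len(values) / sum(1.0 / b for b in values)


def ibr(brs: Sequence[float]) -> float:
    """Minimum BR across an individual's allotypes — the best single
    presentation chance."""
    if len(brs) == 0:
        raise EmptyInput("min of no values")
    return min(brs)


def _individual_brs(
    haplotype: Haplotype, mutation_id: str, br_table: BRTable, loci: Sequence[str] = LOCI
) -> list[float]:
    return [br_table.get(mutation_id, a) for a in haplotype.at_loci(loci)]


def pmhbr(
    mutation_id: str,
    panel: HaplotypePanel,
    br_table: BRTable,
    loci: Sequence[str] = LOCI,
) -> float:
    """Population-wide median of per-individual PHBR values.

    ``loci`` restricts the harmonic mean to a subset of genes (e.g. ("A","B")
    to drop the lower-expressed HLA-C allotypes); even-sized panels use the
    midpoint of the two central values.
    """
    if len(panel) == 0:
        raise EmptyInput("PMHBR over an empty panel")
    values = [phbr(_individual_brs(h, mutation_id, br_table, loci)) for h in panel]
    return float(np.median(values))


def pct_presented(
    mutation_id: str,
    panel: HaplotypePanel,
    br_table: BRTable,
    threshold: float = 0.5,
    loci: Sequence[str] = LOCI,
) -> float:
    """Percent of panel individuals with IBR strictly below ``threshold``."""
    if len(panel) == 0:
        raise EmptyInput("percentage over an empty panel")
    hits = sum(
        1 for h in panel if ibr(_individual_brs(h, mutation_id, br_table, loci)) < threshold
    )
    return 100.0 * hits / len(panel)


def minrank(peptide: str, haplotype: Haplotype, store: RankStore,
            loci: Sequence[str] = LOCI) -> float:
    """Minimum rank of one peptide across the individual's (distinct) allotypes."""
    allotypes = {a for a in haplotype.at_loci(loci)}
    if not allotypes:
        raise EmptyInput("no allotypes at requested loci")
    return min(store.rank(peptide, a) for a in allotypes)


@dataclass(frozen=True)
class CriterionConfig:
    """Configuration of the mutant-vs-wild-type comparison.

    mode "fixed_thresholds": mutant MinRank < t_mut and wild-type
    MinRank >= t_wt (with t_wt >= t_mut); mode "mutant_below_wt": mutant
    MinRank < t_mut and strictly below the wild-type MinRank.
    """

    mode: str = "fixed_thresholds"
    t_mut: float = 0.5
    t_wt: float | None = None

    def __post_init__(self):
        if self.mode not in ("fixed_thresholds", "mutant_below_wt"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.t_mut <= 0:
            raise ValueError("t_mut must be positive")
        if self.mode == "fixed_thresholds":
            t_wt = self.t_wt if self.t_wt is not None else self.t_mut
            if t_wt < self.t_mut:
                raise ValueError("t_wt must be >= t_mut in fixed_thresholds mode")

    @property
    def wt_threshold(self) -> float:
        return self.t_wt if self.t_wt is not None else self.t_mut

    @property
    def tag(self) -> str:
        if self.mode == "fixed_thresholds":
            return f"mut<{self.t_mut}_wt>={self.wt_threshold}"
        return f"mut<{self.t_mut}_below_wt"


def _mutant_minrank(pair: PeptidePair, haplotype: Haplotype, store: RankStore,
                    loci: Sequence[str]) -> float | None:
    """MinRank of the mutant window over allotypes whose record's Icore spans
    the mutation; None when no allotype yields an eligible record."""
    ranks = []
    for allo in {a for a in haplotype.at_loci(loci)}:
        rec = store.get(pair.mutant, allo)
        if icore_spans_mutation(pair, rec.icore):
            ranks.append(rec.rank)
    return min(ranks) if ranks else None


def mutant_vs_wt(
    pairs: Sequence[PeptidePair],
    haplotype: Haplotype,
    store: RankStore,
    cfg: CriterionConfig = CriterionConfig(),
    loci: Sequence[str] = LOCI,
) -> bool:
    """True iff at least one window pair satisfies the configured criterion
    for this individual. Pairs whose mutant record never spans the mutation
    on any of the individual's allotypes are ineligible."""
    for pair in pairs:
        mut_mr = _mutant_minrank(pair, haplotype, store, loci)
        if mut_mr is None:
            continue
        wt_mr = minrank(pair.wildtype, haplotype, store, loci)
        if cfg.mode == "fixed_thresholds":
            if mut_mr < cfg.t_mut and wt_mr >= cfg.wt_threshold:
                return True
        else:
            if mut_mr < cfg.t_mut and mut_mr < wt_mr:
                return True
    return False


def pct_mutant_vs_wt(
    pairs: Sequence[PeptidePair],
    panel: HaplotypePanel,
    store: RankStore,
    cfg: CriterionConfig = CriterionConfig(),
    loci: Sequence[str] = LOCI,
) -> float:
    """Percent of panel individuals for whom the criterion holds."""
    if len(panel) == 0:
        raise EmptyInput("percentage over an empty panel")
    hits = sum(1 for h in panel if mutant_vs_wt(pairs, h, store, cfg, loci))
    return 100.0 * hits / len(panel)


# ---------------------------------------------------------------------------
# Tabular summaries

def individual_scores(
    mutation_ids: Sequence[str],
    panel: HaplotypePanel,
    br_table: BRTable,
    loci: Sequence[str] = LOCI,
) -> pd.DataFrame:
    """Per-(individual, mutation) PHBR and IBR table."""
    rows = []
    for mid in mutation_ids:
        for h in panel:
            brs = _individual_brs(h, mid, br_table, loci)
            rows.append(
                {
                    "individual_id": h.individual_id,
                    "mutation_id": mid,
                    "phbr": phbr(brs),
                    "ibr": ibr(brs),
                }
            )
    return pd.DataFrame(rows, columns=["individual_id", "mutation_id", "phbr", "ibr"])


@dataclass
class PopulationSummary:
    """Per-mutation population-wide summary."""

    mutation_id: str
    pmhbr: float
    pct_presented: dict[float, float] = field(default_factory=dict)
    pct_mut_vs_wt: dict[str, float] = field(default_factory=dict)


def population_summary(
    pairs_by_mutation: Mapping[str, Sequence[PeptidePair]],
    panel: HaplotypePanel,
    br_table: BRTable,
    store: RankStore,
    thresholds: Sequence[float] = (0.5, 2.0),
    criteria: Sequence[CriterionConfig] = (
        CriterionConfig("fixed_thresholds", 0.5),
        CriterionConfig("mutant_below_wt", 0.5),
    ),
    loci: Sequence[str] = LOCI,
) -> pd.DataFrame:
    """One row per mutation: PMHBR, % individuals with IBR below each
    threshold, and % satisfying each mutant-vs-wild-type criterion."""
    rows = []
    for mid, pairs in pairs_by_mutation.items():
        row = {"mutation_id": mid, "pmhbr": pmhbr(mid, panel, br_table, loci)}
        for t in thresholds:
            row[f"pct_ibr_lt_{t}"] = pct_presented(mid, panel, br_table, t, loci)
        for cfg in criteria:
            row[f"pct_{cfg.tag}"] = pct_mutant_vs_wt(pairs, panel, store, cfg, loci)
        rows.append(row)
    return pd.DataFrame(rows)


def br_heatmap(
    mutations: MutationSet,
    panel: HaplotypePanel,
    br_table: BRTable,
    min_freq: float = 0.01,
    display_cap: float = 4.0,
) -> tuple[pd.DataFrame, dict]:
    """Presentation-profile matrix: mutations (rows, grouped by gene) by
    common alleles (columns, per-locus descending frequency).

    Raw BR values are preserved in the matrix; ``display_cap`` (the
    color-scale saturation point for rendering) is recorded as metadata
    only, never applied to the exported values.
    """
    columns = common_alleles(panel, min_freq)
    ordered = sorted(mutations, key=lambda m: (m.gene, m.position, m.mut_residue))
    matrix = pd.DataFrame(
        {
            str(allo): [br_table.get(m.mutation_id, allo) for m in ordered]
            for allo in columns
        },
        index=pd.Index([m.mutation_id for m in ordered], name="mutation_id"),
    )
    metadata = {
        "display_cap": display_cap,
        "min_freq": min_freq,
        "row_genes": {m.mutation_id: m.gene for m in ordered},
        "column_loci": {str(a): a.locus for a in columns},
    }
    return matrix, metadata
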
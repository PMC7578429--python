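"""Mutation-set construction: COSMIC resistance tables and generic missense lists.

The resistance catalog dialect (CosmicResistanceMutations.tsv) lists one row
per reported patient; rows are collapsed to unique missense substitutions
whose ``occurrences`` equals the patient row count. Entries without an exact
amino-acid substitution, non-missense entries, and configured duplicate
accessions are removed. Companion loaders consume generic TSVs for the
passenger / driver / SNP / random comparison sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import FormatError, UnparseableSubstitution

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

__all__ = [
    "MissenseMutation",
    "MutationSet",
    "parse_protein_change",
    "load_resistance_table",
    "load_mutation_table",
    "write_mutation_table",
    "stratify_by_recurrence",
    "split_by_gene",
    "filter_min_occurrences",
]


@dataclass(frozen=True)
class MissenseMutation:
    """A single amino-acid substitution with its recurrence count."""

    mutation_id: str
    gene: str
    transcript_id: str
    position: int  # 1-based protein coordinate
    wt_residue: str
    mut_residue: str
    occurrences: int = 1
    set_label: str = ""

    def __post_init__(self):
        if self.wt_residue == self.mut_residue:
            raise ValueError(f"{self.mutation_id}: synonymous change is not missense")
        if self.wt_residue not in STANDARD_AA or self.mut_residue not in STANDARD_AA:
            raise ValueError(f"{self.mutation_id}: non-standard residue")
        if self.position < 1:
            raise ValueError(f"{self.mutation_id}: position must be >= 1")
        if self.occurrences < 0:
            raise ValueError(f"{self.mutation_id}: negative occurrence count")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        """Identity key; transcript included because two mutations of one gene
        may legitimately map to different transcripts."""
        return (self.gene, self.transcript_id, self.position, self.wt_residue, self.mut_residue)

    @property
    def protein_change(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"

    @property
    def label(self) -> str:
        return f"{self.gene} {self.protein_change}"


@dataclass
class MutationSet:
    """A labelled collection of unique missense mutations."""

    mutations: list[MissenseMutation] = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        keys = [m.key for m in self.mutations]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate mutation keys in set {self.label!r}")

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self) -> Iterator[MissenseMutation]:
        return iter(self.mutations)

    def relabel(self, label: str) -> "MutationSet":
        return MutationSet([replace(m, set_label=label) for m in self.mutations], label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mutation_id": [m.mutation_id for m in self.mutations],
                "gene": [m.gene for m in self.mutations],
                "transcript_id": [m.transcript_id for m in self.mutations],
                "position": [m.position for m in self.mutations],
                "wt_residue": [m.wt_residue for m in self.mutations],
                "mut_residue": [m.mut_residue for m in self.mutations],
                "occurrences": [m.occurrences for m in self.mutations],
                "set_label": [m.set_label for m in self.mutations],
            }
        )


_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})$")


def parse_protein_change(change: str) -> tuple[int, str, str]:
    """Parse "p.T790M" / "T790M" / "p.Thr790Met" to (position, wt, mut).

    Raises :class:`UnparseableSubstitution` for anything that is not a
    simple single-residue missense substitution (indels, frameshifts,
    nonsense, "p.?", synonymous changes).
    """
    if not isinstance(change, str) or not change.strip():
        raise UnparseableSubstitution("empty amino-acid change")
    s = change.strip()
    m = _CHANGE_RE.match(s)
    if not m:
        raise UnparseableSubstitution(f"not a simple substitution: {change!r}")
    wt_raw, pos, mut_raw = m.groups()

    def _residue(r: str) -> str:
        if len(r) == 1 and r.upper() in STANDARD_AA:
            return r.upper()
        if len(r) == 3 and r.capitalize() in _THREE_TO_ONE:
            return _THREE_TO_ONE[r.capitalize()]
        raise UnparseableSubstitution(f"unrecognized residue {r!r} in {change!r}")

    wt, mut = _residue(wt_raw), _residue(mut_raw)
    if wt == mut:
        raise UnparseableSubstitution(f"synonymous change is not missense: {change!r}")
    return int(pos), wt, mut


_COLUMN_ALIASES: Mapping[str, tuple[str, ...]] = {
    "mutation_id": ("mutation_id", "mutation id", "id_mutation", "id mutation",
                    "legacy_mutation_id", "legacy mutation id", "genomic_mutation_id"),
    "gene": ("gene", "gene_name", "gene name", "gene symbol"),
    "transcript_id": ("transcript", "transcript_id", "accession number", "accession_number"),
    "aa_change": ("aa_mutation", "aa mutation", "mutation aa", "mutation_aa",
                  "protein change", "protein_change", "aa_change"),
}


def _resolve_columns(columns: Iterable[str]) -> dict[str, str]:
    lowered = {str(c).strip().lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for target, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                resolved[target] = lowered[alias]
                break
    missing = [t for t in ("gene", "transcript_id", "aa_change") if t not in resolved]
    if missing:
        raise FormatError(f"mandatory columns absent: {missing}; found {list(columns)}")
    return resolved


def load_resistance_table(
    source,
    duplicate_pairs: Iterable[tuple[str, str]] = (),
    label: str = "resistance",
) -> tuple[MutationSet, pd.DataFrame]:
    """Load a COSMIC resistance-mutation dialect TSV into a cleaned MutationSet.

    One input row per reported patient; output mutations are unique
    (gene, transcript, substitution) entries with ``occurrences`` set to the
    collapsed row count. ``duplicate_pairs`` is a list of (drop_id, keep_id)
    accession pairs for manually curated duplicates: rows carrying a drop_id
    are removed before collapsing.

    Returns (mutation_set, drop_log) where drop_log records every removed
    row with its reason.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns)
    drop_ids = {str(d) for d, _ in duplicate_pairs}

    dropped: list[dict] = []
    collapsed: dict[tuple, dict] = {}
    for _, row in df.iterrows():
        mid = str(row[cols["mutation_id"]]) if "mutation_id" in cols else ""
        gene = str(row[cols["gene"]]).strip()
        transcript = str(row[cols["transcript_id"]]).strip()
        change = row[cols["aa_change"]]
        if mid in drop_ids:
            dropped.append({"mutation_id": mid, "gene": gene, "reason": "configured_duplicate"})
            continue
        try:
            pos, wt, mut = parse_protein_change(change if isinstance(change, str) else "")
        except UnparseableSubstitution as exc:
            dropped.append({"mutation_id": mid, "gene": gene, "reason": str(exc)})
            continue
        key = (gene, transcript, pos, wt, mut)
        if key in collapsed:
            collapsed[key]["occurrences"] += 1
        else:
            collapsed[key] = {"mutation_id": mid or f"{gene}_{wt}{pos}{mut}", "occurrences": 1}

    mutations = [
        MissenseMutation(
            mutation_id=v["mutation_id"], gene=g, transcript_id=t, position=p,
            wt_residue=w, mut_residue=m, occurrences=v["occurrences"], set_label=label,
        )
        for (g, t, p, w, m), v in collapsed.items()
    ]
    log = pd.DataFrame(dropped, columns=["mutation_id", "gene", "reason"])
    if len(log):
        logger.info("load_resistance_table: dropped %d rows", len(log))
    return MutationSet(mutations, label), log


def load_mutation_table(source, label: str = "") -> MutationSet:
    """Load the generic mutation TSV dialect.

    Requires columns ``gene``, ``position``, ``wt_residue``, ``mut_residue``
    (or a single ``aa_change`` column); optional ``transcript_id``,
    ``occurrences``, ``mutation_id``, ``set_label``.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    lowered = {str(c).strip().lower(): c for c in df.columns}
    mutations = []
    for i, row in df.iterrows():
        if "aa_change" in lowered and "position" not in lowered:
            pos, wt, mut = parse_protein_change(row[lowered["aa_change"]])
        else:
            try:
                pos = int(row[lowered["position"]])
                wt = str(row[lowered["wt_residue"]]).strip().upper()
                mut = str(row[lowered["mut_residue"]]).strip().upper()
            except KeyError as exc:
                raise FormatError(f"mandatory column absent: {exc}") from exc
        gene = str(row[lowered["gene"]]).strip()
        mutations.append(
            MissenseMutation(
                mutation_id=str(row[lowered["mutation_id"]]) if "mutation_id" in lowered
                else f"{gene}_{wt}{pos}{mut}",
                gene=gene,
                transcript_id=str(row[lowered["transcript_id"]]).strip()
                if "transcript_id" in lowered and pd.notna(row[lowered["transcript_id"]]) else "",
                position=pos, wt_residue=wt, mut_residue=mut,
                occurrences=int(row[lowered["occurrences"]]) if "occurrences" in lowered else 1,
                set_label=str(row[lowered["set_label"]]) if "set_label" in lowered else label,
            )
        )
    return MutationSet(mutations, label)


def write_mutation_table(mset: MutationSet, path) -> None:
    mset.to_frame().to_csv(path, sep="\t", index=False)


def stratify_by_recurrence(mset: MutationSet, threshold: int) -> tuple[MutationSet, MutationSet]:
    """Exact disjoint partition into (highly recurrent, not highly recurrent).

    ``threshold`` is the minimum patient count for the HR stratum (20 for
    COSMIC resistance mutations, 30 for TCGA drivers).
    """
    hr = [m for m in mset if m.occurrences >= threshold]
    not_hr = [m for m in mset if m.occurrences < threshold]
    return (
        MutationSet(hr, f"{mset.label}-HR"),
        MutationSet(not_hr, f"{mset.label}-not-HR"),
    )


def split_by_gene(mset: MutationSet, gene: str) -> tuple[MutationSet, MutationSet]:
    """Exact disjoint partition into (mutations in ``gene``, the rest)."""
    inside = [m for m in mset if m.gene == gene]
    rest = [m for m in mset if m.gene != gene]
    return (
        MutationSet(inside, f"{mset.label}-{gene}"),
        MutationSet(rest, f"{mset.label}-no-{gene}"),
    )


def filter_min_occurrences(mset: MutationSet, min_n: int) -> MutationSet:
    """Subset with occurrences >= min_n, original order preserved."""
    return MutationSet([m for m in mset if m.occurrences >= min_n], mset.label)
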
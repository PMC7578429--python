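"""Mutation-to-protein mapping and mutant/wild-type peptide window generation.

For a missense mutation at protein position ``p`` every window of length 8
to 11 that covers ``p`` yields a mutant peptide (window with the substituted
residue) paired with its wild-type counterpart (the unmodified window). A
mutation away from the protein termini (position in [11, N-10], N >= 21)
yields 4+5+6+7+8+9+10+11 − shortfall = exactly 38 pairs; terminal positions
yield the correspondingly smaller enumerable counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .mutation_catalog import STANDARD_AA, MissenseMutation

logger = logging.getLogger(__name__)

PEPTIDE_LENGTHS = (8, 9, 10, 11)

__all__ = [
    "PEPTIDE_LENGTHS",
    "ProteinRecord",
    "PeptidePair",
    "Discard",
    "Proteome",
    "map_to_protein",
    "generate_pairs",
    "pairs_for_mutations",
    "expected_pair_count",
    "write_peptide_table",
    "write_peptide_fasta",
]


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    transcript_id: str
    gene: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")


@dataclass(frozen=True)
class PeptidePair:
    """A mutant window and its wild-type counterpart.

    ``window_start`` is the 1-based protein coordinate of the window's first
    residue; ``mutation_offset`` the 0-based position of the substituted
    residue within the window.
    """

    mutant: str
    wildtype: str
    window_start: int
    mutation_offset: int

    def __post_init__(self):
        if len(self.mutant) != len(self.wildtype):
            raise ValueError("mutant/wildtype length mismatch")
        if not 8 <= len(self.mutant) <= 11:
            raise ValueError(f"window length {len(self.mutant)} outside 8..11")
        diffs = [i for i, (a, b) in enumerate(zip(self.mutant, self.wildtype)) if a != b]
        if diffs != [self.mutation_offset]:
            raise ValueError("pair must differ exactly at mutation_offset")

    @property
    def length(self) -> int:
        return len(self.mutant)


@dataclass(frozen=True)
class Discard:
    """A mutation that could not be mapped onto any protein sequence."""

    mutation_id: str
    reason: str  # no_transcript | residue_mismatch | position_out_of_range


_HEADER_FIELD_RE = re.compile(r"(\w+):(\S+)")


def _strip_version(accession: str) -> str:
    return accession.split(".")[0]


class Proteome:
    """Protein records indexed by transcript id (version-insensitive) and gene."""

    def __init__(self, records: Iterable[ProteinRecord]):
        self.records = list(records)
        self.by_transcript: dict[str, ProteinRecord] = {}
        self.by_gene: dict[str, list[ProteinRecord]] = {}
        for rec in self.records:
            if rec.transcript_id:
                self.by_transcript.setdefault(_strip_version(rec.transcript_id), rec)
            if rec.gene:
                self.by_gene.setdefault(rec.gene, []).append(rec)

    @classmethod
    def from_fasta(cls, path) -> "Proteome":
        """Read an EnsEMBL-style peptide FASTA.

        Headers of the form ``>ENSP0... pep ... transcript:ENST0...
        gene_symbol:EGFR ...`` are parsed for transcript id and gene symbol;
        plain id-only headers are also accepted (the id doubles as the
        transcript key).
        """
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = dict(_HEADER_FIELD_RE.findall(rec.description))
            transcript = fields.get("transcript", rec.id)
            gene = fields.get("gene_symbol", fields.get("gene", ""))
            records.append(
                ProteinRecord(
                    protein_id=rec.id,
                    transcript_id=transcript,
                    gene=gene,
                    sequence=str(rec.seq),
                )
            )
        return cls(records)

    def __len__(self) -> int:
        return len(self.records)


def _matches(record: ProteinRecord, mutation: MissenseMutation) -> bool:
    pos = mutation.position
    return pos <= len(record.sequence) and record.sequence[pos - 1] == mutation.wt_residue


def map_to_protein(
    mutation: MissenseMutation,
    proteome: Proteome,
    canonical_map: Mapping[str, str] | None = None,
    alt_map: Mapping[str, Sequence[str]] | None = None,
) -> ProteinRecord | Discard:
    """Resolve the protein sequence a mutation lives on.

    A transcript id on the mutation is used directly. Otherwise the gene's
    canonical transcript is tried first, then the non-canonical transcripts,
    then any proteome record for the gene. A candidate is valid only when
    its sequence carries the wild-type residue at the mutated position;
    with no valid candidate the mutation is discarded with a reason.
    """
    candidates: list[ProteinRecord] = []
    if mutation.transcript_id:
        rec = proteome.by_transcript.get(_strip_version(mutation.transcript_id))
        if rec is not None:
            candidates.append(rec)
    else:
        tried: set[str] = set()
        canonical = (canonical_map or {}).get(mutation.gene)
        for tid in ([canonical] if canonical else []) + list((alt_map or {}).get(mutation.gene, [])):
            key = _strip_version(tid)
            if key in tried:
                continue
            tried.add(key)
            rec = proteome.by_transcript.get(key)
            if rec is not None:
                candidates.append(rec)
        if not candidates:
            candidates.extend(proteome.by_gene.get(mutation.gene, []))

    if not candidates:
        return Discard(mutation.mutation_id, "no_transcript")
    reason = "residue_mismatch"
    for rec in candidates:
        if mutation.position > len(rec.sequence):
            reason = "position_out_of_range"
            continue
        if _matches(rec, mutation):
            return rec
    return Discard(mutation.mutation_id, reason)


def expected_pair_count(position: int, protein_length: int,
                        lengths: Sequence[int] = PEPTIDE_LENGTHS) -> int:
    """Closed-form count of windows covering ``position``:
    sum over L of max(0, min(position, N−L+1) − max(1, position−L+1) + 1)."""
    total = 0
    for L in lengths:
        lo = max(1, position - L + 1)
        hi = min(position, protein_length - L + 1)
        total += max(0, hi - lo + 1)
    return total


def generate_pairs(
    sequence: str,
    position: int,
    wt: str,
    mut: str,
    lengths: Sequence[int] = PEPTIDE_LENGTHS,
) -> list[PeptidePair]:
    """All mutant/wild-type window pairs of the requested lengths.

    ``position`` is 1-based and must carry ``wt`` in ``sequence``. Windows
    containing a residue outside the 20-letter alphabet (e.g. '*', 'X', 'U'
    in EnsEMBL peptide files) are skipped with a log notice — the window,
    not the mutation. Output is deterministically ordered by (length, start).
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside 1..{len(sequence)}")
    if sequence[position - 1] != wt:
        raise ValueError(
            f"sequence has {sequence[position - 1]!r} at {position}, expected {wt!r}"
        )
    pairs: list[PeptidePair] = []
    for L in sorted(lengths):
        lo = max(1, position - L + 1)
        hi = min(position, len(sequence) - L + 1)
        for start in range(lo, hi + 1):
            window = sequence[start - 1 : start - 1 + L]
            if any(ch not in STANDARD_AA for ch in window):
                logger.info("skipping window at %d (len %d): non-standard residue", start, L)
                continue
            offset = position - start
            mutant = window[:offset] + mut + window[offset + 1 :]
            pairs.append(PeptidePair(mutant, window, start, offset))
    return pairs


def pairs_for_mutations(
    mutations: Iterable[MissenseMutation],
    proteome: Proteome,
    canonical_map: Mapping[str, str] | None = None,
    alt_map: Mapping[str, Sequence[str]] | None = None,
    lengths: Sequence[int] = PEPTIDE_LENGTHS,
) -> tuple[dict[str, list[PeptidePair]], list[Discard]]:
    """Map each mutation and enumerate its windows; returns (pairs keyed by
    mutation_id, discards)."""
    pairs_by_mutation: dict[str, list[PeptidePair]] = {}
    discards: list[Discard] = []
    for mutation in mutations:
        hit = map_to_protein(mutation, proteome, canonical_map, alt_map)
        if isinstance(hit, Discard):
            discards.append(hit)
            continue
        pairs_by_mutation[mutation.mutation_id] = generate_pairs(
            hit.sequence, mutation.position, mutation.wt_residue, mutation.mut_residue, lengths
        )
    return pairs_by_mutation, discards


def write_peptide_table(pairs_by_mutation: Mapping[str, Sequence[PeptidePair]], path) -> None:
    rows = [
        {
            "mutation_id": mid,
            "length": p.length,
            "window_start": p.window_start,
            "mutation_offset": p.mutation_offset,
            "mutant": p.mutant,
            "wildtype": p.wildtype,
        }
        for mid, plist in pairs_by_mutation.items()
        for p in plist
    ]
    pd.DataFrame(
        rows, columns=["mutation_id", "length", "window_start", "mutation_offset",
                       "mutant", "wildtype"]
    ).to_csv(path, sep="\t", index=False)


def write_peptide_fasta(pairs_by_mutation: Mapping[str, Sequence[PeptidePair]], path) -> None:
    """Plain peptide FASTA (mutant and wild-type windows) for predictor submission."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        for mid, plist in pairs_by_mutation.items():
            for i, p in enumerate(plist):
                for role, pep in (("mut", p.mutant), ("wt", p.wildtype)):
                    if pep in seen:
                        continue
                    seen.add(pep)
                    fh.write(f">{mid}_{i}_{role}\n{pep}\n")
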
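"""Uniform access to per-(peptide, allotype) eluted-ligand percentile ranks.

The prediction model itself (NetMHCpan-4.0) is treated strictly as a black
box: this module parses its tabular output, caches results in a resumable
TSV rank store, and exposes the :class:`PredictorContract` protocol that the
synthetic predictor in :mod:`neoscreen.synthetic_data` also satisfies, so
the whole pipeline runs identically against either source of ranks.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import pandas as pd

from .errors import FormatError, MissingRecord, RangeError, UnsupportedAllotype
from .haplotype_io import Allotype, parse_allotype
from .peptide_factory import PeptidePair

__all__ = [
    "RankRecord",
    "PredictorContract",
    "RankStore",
    "parse_netmhcpan_output",
    "query_with_cache",
    "NetMHCpanAdapter",
]


@dataclass(frozen=True)
class RankRecord:
    """One predicted (peptide, allotype) elution percentile rank with its Icore."""

    peptide: str
    allotype: Allotype
    rank: float
    icore: str

    def __post_init__(self):
        if not 0.0 <= self.rank <= 100.0:
            raise RangeError(f"rank {self.rank} outside [0, 100] for {self.peptide}")
        if self.icore and self.icore not in self.peptide:
            raise ValueError(f"Icore {self.icore!r} not a substring of {self.peptide!r}")


@runtime_checkable
class PredictorContract(Protocol):
    """Anything that can score peptides against a library of allotypes.

    ``query`` must return exactly one record per requested (peptide,
    allotype) pair and be deterministic for fixed inputs.
    """

    library: frozenset[Allotype]

    def query(self, peptides: Sequence[str], allotypes: Sequence[Allotype]) -> list[RankRecord]:
        ...


# ---------------------------------------------------------------------------
# NetMHCpan-4.0 output parsing

_PEPTIDE_ALIASES = ("peptide",)
_ALLELE_ALIASES = ("hla", "mhc", "allele")
_ICORE_ALIASES = ("icore",)
_RANK_ALIASES = ("%rank_el", "el_rank", "%rank", "rank_el", "rank")


def _find_column(tokens: list[str], aliases: tuple[str, ...]) -> int | None:
    lowered = [t.lower() for t in tokens]
    for alias in aliases:
        if alias in lowered:
            return lowered.index(alias)
    return None


def parse_netmhcpan_output(stream) -> list[RankRecord]:
    """Parse NetMHCpan-4.0 output into rank records.

    Both the whitespace-aligned stdout table and a tab-delimited export are
    accepted; columns are identified by header name (peptide, allele, Icore,
    eluted-ligand %rank), never by position. Banner, comment and separator
    lines are skipped; trailing annotations on data rows ("<= SB") are
    ignored because fields are taken at the header's column indices.
    """
    if hasattr(stream, "read"):
        lines = stream.read().splitlines()
    elif isinstance(stream, (str, Path)) and "\n" not in str(stream):
        lines = Path(stream).read_text().splitlines()
    else:
        lines = str(stream).splitlines()

    header_idx: dict[str, int] | None = None
    sep: str | None = None
    records: list[RankRecord] = []
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith("#") or set(stripped) <= {"-", " "}:
            continue
        candidate_sep = "\t" if "\t" in line else None
        tokens = line.split(candidate_sep)
        tokens = [t.strip() for t in tokens if t.strip()]
        if header_idx is None:
            pep = _find_column(tokens, _PEPTIDE_ALIASES)
            allele = _find_column(tokens, _ALLELE_ALIASES)
            icore = _find_column(tokens, _ICORE_ALIASES)
            rank = _find_column(tokens, _RANK_ALIASES)
            if pep is not None and allele is not None and rank is not None:
                header_idx = {"peptide": pep, "allele": allele, "rank": rank}
                if icore is not None:
                    header_idx["icore"] = icore
                sep = candidate_sep
            continue
        tokens = [t.strip() for t in line.split(sep) if t.strip()]
        if len(tokens) <= max(header_idx.values()):
            continue
        try:
            rank_value = float(tokens[header_idx["rank"]])
        except ValueError:
            continue  # e.g. repeated banner between result blocks
        peptide = tokens[header_idx["peptide"]]
        allotype = parse_allotype(tokens[header_idx["allele"]])
        icore = tokens[header_idx["icore"]] if "icore" in header_idx else peptide
        records.append(RankRecord(peptide, allotype, rank_value, icore))
    if header_idx is None:
        raise FormatError("no header with peptide/allele/%rank columns found")
    return records


# ---------------------------------------------------------------------------
# Rank store with caching

class RankStore:
    """In-memory (peptide, allotype) → RankRecord map with TSV persistence.

    The store is the pipeline's single source of ranks during scoring; a
    lookup miss raises :class:`MissingRecord` before any score is emitted.
    """

    def __init__(self, records: Iterable[RankRecord] = (), version_tag: str = ""):
        self._records: dict[tuple[str, str], RankRecord] = {}
        self.version_tag = version_tag
        for rec in records:
            self.add(rec)

    @staticmethod
    def _key(peptide: str, allotype: Allotype) -> tuple[str, str]:
        return (peptide, str(allotype))

    def add(self, record: RankRecord) -> None:
        self._records[self._key(record.peptide, record.allotype)] = record

    def __contains__(self, key: tuple[str, Allotype]) -> bool:
        return self._key(*key) in self._records

    def __len__(self) -> int:
        return len(self._records)

    def get(self, peptide: str, allotype: Allotype) -> RankRecord:
        try:
            return self._records[self._key(peptide, allotype)]
        except KeyError:
            raise MissingRecord(f"no rank record for ({peptide}, {allotype})") from None

    def rank(self, peptide: str, allotype: Allotype) -> float:
        return self.get(peptide, allotype).rank

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "peptide": [r.peptide for r in self._records.values()],
                "allotype": [str(r.allotype) for r in self._records.values()],
                "rank": [r.rank for r in self._records.values()],
                "icore": [r.icore for r in self._records.values()],
            }
        ).sort_values(["peptide", "allotype"])
        with open(path, "w") as fh:
            if self.version_tag:
                fh.write(f"# predictor: {self.version_tag}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RankStore":
        version_tag = ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# predictor:"):
                version_tag = first.split(":", 1)[1].strip()
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"peptide": str, "allotype": str, "icore": str})
        records = [
            RankRecord(row.peptide, parse_allotype(row.allotype), float(row.rank),
                       "" if pd.isna(row.icore) else str(row.icore))
            for row in df.itertuples()
        ]
        return cls(records, version_tag=version_tag)


def query_with_cache(
    predictor: PredictorContract,
    pairs: Iterable[PeptidePair],
    panel_allotypes: Iterable[Allotype],
    store: RankStore | None = None,
) -> RankStore:
    """Fill a rank store with every (mutant, allotype) and (wildtype, allotype)
    combination, querying the predictor only for keys not already cached.

    Raises :class:`UnsupportedAllotype` up front when any requested allotype
    is outside the predictor's library.
    """
    allotypes = sorted(set(panel_allotypes))
    unsupported = [a for a in allotypes if a not in predictor.library]
    if unsupported:
        raise UnsupportedAllotype(unsupported)

    peptides: list[str] = []
    seen: set[str] = set()
    for pair in pairs:
        for pep in (pair.mutant, pair.wildtype):
            if pep not in seen:
                seen.add(pep)
                peptides.append(pep)

    store = store if store is not None else RankStore()
    missing = [
        (pep, allo) for pep in peptides for allo in allotypes if (pep, allo) not in store
    ]
    if missing:
        # group by allotype to keep predictor calls few and deterministic
        by_allotype: dict[Allotype, list[str]] = {}
        for pep, allo in missing:
            by_allotype.setdefault(allo, []).append(pep)
        for allo in sorted(by_allotype):
            for rec in predictor.query(by_allotype[allo], [allo]):
                store.add(rec)
    return store


# ---------------------------------------------------------------------------
# Optional subprocess adapter

class NetMHCpanAdapter:
    """Subprocess adapter for a locally installed, licensed NetMHCpan-4.0.

    Optional: the test suite and the synthetic pipeline never require it.
    The exact command line is recorded as the store version tag for
    provenance.
    """

    def __init__(self, executable: str = "netMHCpan", extra_args: Sequence[str] = ()):
        self.executable = executable
        self.extra_args = list(extra_args)
        path = shutil.which(executable)
        if path is None:
            raise FileNotFoundError(f"{executable} not found on PATH")
        self.library: frozenset[Allotype] = frozenset()  # populated lazily if listed

    def _allele_arg(self, allotype: Allotype) -> str:
        # NetMHCpan spells alleles without the '*' separator
        return f"HLA-{allotype.locus}{allotype.group}:{allotype.protein}{allotype.suffix}"

    def command(self, fasta_path: str, allotypes: Sequence[Allotype]) -> list[str]:
        alleles = ",".join(self._allele_arg(a) for a in allotypes)
        return [self.executable, "-f", fasta_path, "-a", alleles, *self.extra_args]

    def query(self, peptides: Sequence[str], allotypes: Sequence[Allotype]) -> list[RankRecord]:
        with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
            for i, pep in enumerate(peptides):
                fh.write(f">p{i}\n{pep}\n")
            fasta = fh.name
        cmd = self.command(fasta, allotypes)
        out = subprocess.run(cmd, capture_output=True, text=True, check=True)
        self.last_command = " ".join(cmd)
        return parse_netmhcpan_output(out.stdout)
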
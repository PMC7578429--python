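"""HLA class I haplotype table parsing, normalization, and allele frequencies.

A *haplotype panel* is a set of individuals, each annotated with six HLA
class I allotypes (two each for HLA-A, -B and -C). Panels come from
population references (the 1000 Genomes HLA-diversity table dialect) or
from patient cohorts typed upstream; this module normalizes the several
allotype naming dialects in circulation ("A*03:01", "HLA-A03:01",
"HLA-A*03:01") onto one canonical rendering, applies the exclusion rules
for ill-defined typings, and derives per-locus allele frequencies.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import EmptyPanel, FormatError, MalformedAllotype

LOCI = ("A", "B", "C")

__all__ = [
    "LOCI",
    "Allotype",
    "Haplotype",
    "HaplotypePanel",
    "parse_allotype",
    "load_haplotype_table",
    "allele_frequencies",
    "common_alleles",
]


@dataclass(frozen=True, order=True)
class Allotype:
    """A four-digit-resolution HLA class I allotype, e.g. HLA-A*02:01.

    ``group`` and ``protein`` are kept as zero-padded digit strings so that
    rendering is the exact canonical name, not a numeric reinterpretation.
    ``suffix`` carries an optional expression letter (N, L, S, Q, C, A).
    """

    locus: str
    group: str
    protein: str
    suffix: str = ""

    def __post_init__(self):
        if self.locus not in LOCI:
            raise MalformedAllotype(f"locus must be one of {LOCI}, got {self.locus!r}")
        if not (self.group.isdigit() and self.protein.isdigit()):
            raise MalformedAllotype(
                f"group/protein must be digit strings, got {self.group!r}:{self.protein!r}"
            )

    @property
    def name(self) -> str:
        return f"HLA-{self.locus}*{self.group}:{self.protein}{self.suffix}"

    def __str__(self) -> str:
        return self.name


_ALLOTYPE_RE = re.compile(r"^(?:HLA-?)?([ABC])\*?([0-9:]+)([A-Z]?)$")
_EXPRESSION_SUFFIXES = set("NLSQCA")


def parse_allotype(raw: str, locus_hint: str | None = None) -> Allotype:
    """Parse an allotype name in any accepted dialect to its canonical form.

    Accepted: "A*03:01", "HLA-A03:01", "HLA-A*03:01", colon-less four-digit
    forms ("A0301"), higher-than-four-digit names (extra fields truncated),
    and, when ``locus_hint`` is given, bare digit forms ("03:01") as found in
    per-locus table columns.

    Raises
    ------
    MalformedAllotype
        For names without four-digit resolution (e.g. "HLA-B44", "HLA-C15"),
        the placeholder "0000", or anything else unparseable.
    """
    if not raw or not raw.strip():
        raise MalformedAllotype("empty allotype string")
    s = raw.strip()
    if locus_hint and s[:1] not in "ABCH" and s[:1].isdigit() and s != "0000":
        s = f"{locus_hint}*{s}"
    m = _ALLOTYPE_RE.match(s)
    if not m:
        raise MalformedAllotype(f"unparseable allotype: {raw!r}")
    locus, digits, suffix = m.groups()
    if suffix and suffix not in _EXPRESSION_SUFFIXES:
        raise MalformedAllotype(f"unknown expression suffix in {raw!r}")
    if ":" in digits:
        fields = digits.split(":")
        group, protein = fields[0], fields[1]
        if not (group and protein):
            raise MalformedAllotype(f"incomplete fields in {raw!r}")
    elif len(digits) == 4:
        group, protein = digits[:2], digits[2:]
    else:
        # two-digit-only names ("B44") lack four-digit resolution
        raise MalformedAllotype(f"not resolved at four-digit level: {raw!r}")
    if not (2 <= len(group) <= 3 and 2 <= len(protein) <= 3):
        raise MalformedAllotype(f"field width out of range in {raw!r}")
    return Allotype(locus, group, protein, suffix)


@dataclass(frozen=True)
class Haplotype:
    """One individual's six class I allotypes (two per locus; duplicates = homozygous)."""

    individual_id: str
    allotypes: tuple[Allotype, ...]
    population_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.allotypes) != 6:
            raise FormatError(
                f"{self.individual_id}: expected 6 allotypes, got {len(self.allotypes)}"
            )
        for locus in LOCI:
            n = sum(1 for a in self.allotypes if a.locus == locus)
            if n != 2:
                raise FormatError(
                    f"{self.individual_id}: expected 2 HLA-{locus} allotypes, got {n}"
                )

    def at_loci(self, loci: Sequence[str] = LOCI) -> tuple[Allotype, ...]:
        """The 2×|loci| allotypes at the requested loci, in locus order."""
        return tuple(a for locus in loci for a in self.allotypes if a.locus == locus)

    @property
    def distinct_allotypes(self) -> frozenset[Allotype]:
        return frozenset(self.allotypes)


@dataclass
class HaplotypePanel:
    """An ordered collection of haplotypes with unique individual ids."""

    haplotypes: list[Haplotype] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [h.individual_id for h in self.haplotypes]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate individual_id in panel")

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(self.haplotypes)

    @property
    def ids(self) -> list[str]:
        return [h.individual_id for h in self.haplotypes]

    @property
    def all_allotypes(self) -> frozenset[Allotype]:
        return frozenset(a for h in self.haplotypes for a in h.allotypes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.haplotypes:
            a = h.at_loci()
            rows.append(
                {
                    "individual_id": h.individual_id,
                    "A.1": str(a[0]), "A.2": str(a[1]),
                    "B.1": str(a[2]), "B.2": str(a[3]),
                    "C.1": str(a[4]), "C.2": str(a[5]),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "HaplotypePanel":
        """Read the generic 7-column panel dialect (id + six canonical allotypes)."""
        panel, _ = load_haplotype_table(path, provenance=provenance or str(path))
        return panel


_ALLOTYPE_HEADER_RE = re.compile(r"^(hla[._-]?)?[abc][._-]?[12]$", re.IGNORECASE)
_COLUMN_LOCI = ("A", "A", "B", "B", "C", "C")


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, (str,)) or hasattr(source, "read"):
        return pd.read_csv(source, sep=r"\s+", header=None, dtype=str, comment="#")
    if hasattr(source, "__fspath__"):
        return pd.read_csv(source, sep=r"\s+", header=None, dtype=str, comment="#")
    # iterable of lines
    return pd.read_csv(io.StringIO("\n".join(source)), sep=r"\s+", header=None, dtype=str)


def _first_entry(cell: str) -> str:
    """Keep only the first "/"-separated typing alternative."""
    return str(cell).split("/")[0].strip().strip('"')


def load_haplotype_table(
    source,
    predictor_library: Iterable[Allotype] | None = None,
    exclusions: Iterable[str] = (),
    *,
    has_header: bool | None = None,
    provenance: str = "",
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Load a whitespace/tab-delimited haplotype table into a filtered panel.

    The table must carry one individual per row: an id column first, optional
    population-label columns, and six allotype columns last (A, A, B, B, C, C).
    Cells may hold "/"-separated typing alternatives; only the first entry is
    considered. Individuals carrying any allotype that is malformed, on the
    exclusion list, or absent from the predictor library are dropped and
    logged. Duplicate individual ids keep the first row.

    Parameters
    ----------
    source
        Path, text stream, or iterable of lines.
    predictor_library
        If given, the set of allotypes the downstream predictor supports;
        individuals with allotypes outside it are rejected.
    exclusions
        Raw or canonical allotype names to reject outright (e.g. the
        ill-defined typings "HLA-B44", "HLA-C0140", "0000").
    has_header
        Force header presence; by default the first row is sniffed (treated
        as a header when its allotype cells fail parsing and look like
        column names).

    Returns
    -------
    (panel, rejections)
        The retained panel and a rejection-log DataFrame with columns
        ``individual_id``, ``cell``, ``reason``.
    """
    df = _read_table(source)
    if df.shape[1] < 7:
        raise FormatError(f"expected at least 7 columns (id + six allotypes), got {df.shape[1]}")

    allo_cols = list(df.columns[-6:])
    first = df.iloc[0]
    if has_header is None:
        def _looks_like_header(row) -> bool:
            for col, locus in zip(allo_cols, _COLUMN_LOCI):
                cell = _first_entry(row[col])
                try:
                    parse_allotype(cell, locus_hint=locus)
                except MalformedAllotype:
                    if _ALLOTYPE_HEADER_RE.match(cell):
                        return True
            return False
        has_header = _looks_like_header(first)
    if has_header:
        df = df.iloc[1:].reset_index(drop=True)

    library = frozenset(predictor_library) if predictor_library is not None else None
    excl = {e.strip() for e in exclusions}

    haplotypes: list[Haplotype] = []
    seen_ids: set[str] = set()
    rejections: list[dict] = []

    for _, row in df.iterrows():
        ind_id = str(row[df.columns[0]]).strip().strip('"')
        pop_labels = tuple(
            str(row[c]).strip().strip('"') for c in df.columns[1:-6] if pd.notna(row[c])
        )
        if ind_id in seen_ids:
            rejections.append({"individual_id": ind_id, "cell": "", "reason": "duplicate_id"})
            continue
        allotypes: list[Allotype] = []
        bad: tuple[str, str] | None = None
        for col, locus in zip(allo_cols, _COLUMN_LOCI):
            cell = row[col]
            if pd.isna(cell):
                bad = ("", "missing_cell")
                break
            entry = _first_entry(cell)
            if entry in excl:
                bad = (entry, "excluded")
                break
            try:
                allo = parse_allotype(entry, locus_hint=locus)
            except MalformedAllotype:
                bad = (entry, "malformed")
                break
            if str(allo) in excl:
                bad = (entry, "excluded")
                break
            if allo.locus != locus:
                bad = (entry, "locus_mismatch")
                break
            if library is not None and allo not in library:
                bad = (entry, "not_in_predictor_library")
                break
            allotypes.append(allo)
        if bad is not None:
            rejections.append({"individual_id": ind_id, "cell": bad[0], "reason": bad[1]})
            continue
        seen_ids.add(ind_id)
        haplotypes.append(Haplotype(ind_id, tuple(allotypes), pop_labels))

    panel = HaplotypePanel(haplotypes, provenance=provenance)
    log = pd.DataFrame(rejections, columns=["individual_id", "cell", "reason"])
    return panel, log


def allele_frequencies(panel: HaplotypePanel) -> pd.DataFrame:
    """Per-locus allele frequencies: count / (2 × panel size).

    Returns a DataFrame with columns ``locus``, ``allotype`` (canonical
    name), ``count``, ``frequency``; frequencies sum to 1 within each locus.
    """
    if len(panel) == 0:
        raise EmptyPanel("cannot compute frequencies on an empty panel")
    counts: dict[Allotype, int] = {}
    for h in panel:
        for a in h.allotypes:
            counts[a] = counts.get(a, 0) + 1
    denom = 2 * len(panel)
    rows = [
        {"locus": a.locus, "allotype": str(a), "count": n, "frequency": n / denom}
        for a, n in counts.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["locus", "frequency", "allotype"], ascending=[True, False, True]
    )
    return df.reset_index(drop=True)


def common_alleles(panel: HaplotypePanel, min_freq: float = 0.01) -> list[Allotype]:
    """Allotypes with frequency strictly above ``min_freq``.

    Grouped by locus (A, then B, then C), each group sorted by descending
    frequency with ties broken by canonical name — the ordering used for
    presentation-profile heatmap columns.
    """
    if not 0 <= min_freq < 1:
        raise ValueError(f"min_freq must be in [0, 1), got {min_freq}")
    freqs = allele_frequencies(panel)
    out: list[Allotype] = []
    for locus in LOCI:
        sub = freqs[(freqs["locus"] == locus) & (freqs["frequency"] > min_freq)]
        sub = sub.sort_values(["frequency", "allotype"], ascending=[False, True])
        out.extend(parse_allotype(name) for name in sub["allotype"])
    return out
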
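"""Synthetic populations, proteomes, mutations and rank landscapes.

Everything the real pipeline consumes — a 1000G-like haplotype panel, an
EnsEMBL-like proteome with planted missense mutations, and a deterministic
predictor of eluted-ligand percentile ranks — can be generated here with
known ground truth, so end-to-end behaviour (presentation coverage,
mutant-vs-wild-type contrasts, PMHBR orderings) is testable without any
licensed predictor or downloaded reference data.

The panel generator draws two alleles per locus independently from a
frequency spectrum (Hardy-Weinberg sampling; no linkage between loci). The
synthetic predictor assigns each (peptide, allotype) a deterministic
pseudo-random rank via seeded hashing, warped so that the fraction of
random peptides below the strong-binder threshold (rank 0.5) matches a
small configurable mass, mimicking percentile-rank semantics. Planted
signals make chosen (mutation, allotype) combinations strong binders with
known wild-type behaviour; every generator is a pure function of
(parameters, seed).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidSpectrum
from .haplotype_io import LOCI, Allotype, Haplotype, HaplotypePanel
from .mutation_catalog import MissenseMutation, MutationSet
from .peptide_factory import PEPTIDE_LENGTHS, PeptidePair, ProteinRecord, generate_pairs
from .predictor_gateway import RankRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default fraction of random (peptide, allotype) ranks below 0.5
DEFAULT_STRONG_BINDER_MASS = 0.005
#: background ranks for a planted mutation's windows are floored here (> 2.0)
DEFAULT_BACKGROUND_FLOOR = 2.5

__all__ = [
    "AlleleSpectrum",
    "PlantedSignal",
    "SyntheticPredictor",
    "CoverageScenario",
    "simulate_panel",
    "simulate_proteome_and_mutations",
    "synthetic_predictor",
    "planted_coverage_scenario",
]


@dataclass(frozen=True)
class AlleleSpectrum:
    """Per-locus allotype frequency distributions."""

    per_locus: Mapping[str, Mapping[Allotype, float]]

    def __post_init__(self):
        for locus in LOCI:
            if locus not in self.per_locus or not self.per_locus[locus]:
                raise InvalidSpectrum(f"missing spectrum for locus {locus}")
            freqs = self.per_locus[locus]
            if any(f < 0 for f in freqs.values()):
                raise InvalidSpectrum(f"negative frequency at locus {locus}")
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidSpectrum(f"locus {locus} frequencies sum to {total}, not 1")
            if any(a.locus != locus for a in freqs):
                raise InvalidSpectrum(f"allotype at wrong locus under {locus}")

    @property
    def allotypes(self) -> frozenset[Allotype]:
        return frozenset(a for freqs in self.per_locus.values() for a in freqs)

    def frequency(self, allotype: Allotype) -> float:
        return self.per_locus[allotype.locus].get(allotype, 0.0)

    @classmethod
    def uniform(cls, n_per_locus: int = 10) -> "AlleleSpectrum":
        """Equal-frequency spectrum with ``n_per_locus`` allotypes per locus."""
        per_locus = {
            locus: {
                Allotype(locus, f"{i + 1:02d}", "01"): 1.0 / n_per_locus
                for i in range(n_per_locus)
            }
            for locus in LOCI
        }
        return cls(per_locus)

    @classmethod
    def zipf(cls, n_per_locus: Mapping[str, int] | None = None,
             exponent: float = 1.0) -> "AlleleSpectrum":
        """Rank-frequency spectrum f_k ∝ 1/k^exponent.

        Defaults emulate the shape of class I diversity in population
        references: a few common allotypes and a long rare tail, with more
        distinct HLA-B than HLA-A or HLA-C allotypes.
        """
        n_per_locus = n_per_locus or {"A": 25, "B": 35, "C": 20}
        per_locus = {}
        for locus in LOCI:
            n = n_per_locus[locus]
            weights = np.array([1.0 / (k + 1) ** exponent for k in range(n)])
            weights /= weights.sum()
            per_locus[locus] = {
                Allotype(locus, f"{k + 1:02d}", "01"): float(w)
                for k, w in enumerate(weights)
            }
        return cls(per_locus)


def simulate_panel(n: int, spectrum: AlleleSpectrum, seed: int) -> HaplotypePanel:
    """Draw ``n`` diploid individuals under Hardy-Weinberg sampling.

    Two allotypes per locus are drawn independently from the locus spectrum;
    homozygotes arise naturally. Identical (n, spectrum, seed) give an
    identical panel.
    """
    if n < 1:
        raise ValueError("panel size must be >= 1")
    rng = np.random.default_rng(seed)
    draws = {}
    for locus in LOCI:
        alleles = sorted(spectrum.per_locus[locus])
        probs = np.array([spectrum.per_locus[locus][a] for a in alleles])
        idx = rng.choice(len(alleles), size=(n, 2), p=probs)
        draws[locus] = [(alleles[i], alleles[j]) for i, j in idx]
    width = max(4, len(str(n)))
    haplotypes = [
        Haplotype(
            f"SIM{i:0{width}d}",
            tuple(a for locus in LOCI for a in draws[locus][i]),
            ("synthetic",),
        )
        for i in range(n)
    ]
    return HaplotypePanel(haplotypes, provenance=f"simulated(seed={seed}, n={n})")


def simulate_proteome_and_mutations(
    n_genes: int = 20,
    length_range: tuple[int, int] = (60, 400),
    n_mutations: int = 40,
    seed: int = 0,
) -> tuple[list[ProteinRecord], MutationSet]:
    """Random proteome with planted missense mutations.

    Sequences are uniform over the 20-letter alphabet. Mutation positions
    cycle through the boundary strata (first residue, N-terminal edge
    region, interior, C-terminal edge, last residue) so window-count edge
    cases are always represented; interior mutations yield exactly 38
    mutant/wild-type pairs. Wild-type residues always match the sequence,
    so every generated mutation maps without discard.
    """
    lo, hi = length_range
    if lo < 21:
        raise ValueError("minimum protein length must be >= 21 for full window sets")
    rng = np.random.default_rng(seed)
    proteins = []
    for g in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        proteins.append(
            ProteinRecord(
                protein_id=f"SYNP{g:04d}",
                transcript_id=f"SYNT{g:04d}",
                gene=f"GENE{g:02d}",
                sequence=seq,
            )
        )

    strata = ("first", "nterm", "interior", "cterm", "last")
    mutations = []
    for i in range(n_mutations):
        prot = proteins[int(rng.integers(0, n_genes))]
        n = len(prot.sequence)
        stratum = strata[i % len(strata)]
        if stratum == "first":
            pos = 1
        elif stratum == "nterm":
            pos = int(rng.integers(2, 11))
        elif stratum == "interior":
            pos = int(rng.integers(11, n - 9))
        elif stratum == "cterm":
            pos = int(rng.integers(n - 9, n))
        else:
            pos = n
        wt = prot.sequence[pos - 1]
        mut = rng.choice([a for a in AMINO_ACIDS if a != wt])
        mutations.append(
            MissenseMutation(
                mutation_id=f"SYNM{i:04d}",
                gene=prot.gene,
                transcript_id=prot.transcript_id,
                position=pos,
                wt_residue=wt,
                mut_residue=str(mut),
                occurrences=int(rng.integers(1, 60)),
                set_label="synthetic",
            )
        )
    # identical substitutions can collide when two mutations land on the
    # same residue; keep first occurrence
    unique: dict[tuple, MissenseMutation] = {}
    for m in mutations:
        unique.setdefault(m.key, m)
    return proteins, MutationSet(list(unique.values()), "synthetic")


def write_proteome_fasta(proteins: Sequence[ProteinRecord], path) -> None:
    """EnsEMBL-style peptide FASTA for the synthetic proteome."""
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(
                f">{p.protein_id} pep transcript:{p.transcript_id} "
                f"gene_symbol:{p.gene}\n{p.sequence}\n"
            )


@dataclass(frozen=True)
class PlantedSignal:
    """Ground truth for one mutation: which allotypes present it strongly.

    One window of the mutation receives ``target_rank`` (< 0.5) on each
    strong allotype with a mutation-spanning Icore, while its wild-type
    counterpart is floored at ``wt_rank_floor`` (>= 0.5); all other windows
    of the mutation are floored above the presentation threshold so the
    planted combination is the mutation's only presentation route.
    """

    mutation_id: str
    strong_allotypes: frozenset[Allotype]
    target_rank: float = 0.1
    wt_rank_floor: float = 5.0

    def __post_init__(self):
        if not self.target_rank < 0.5 <= self.wt_rank_floor:
            raise ValueError("require target_rank < 0.5 <= wt_rank_floor")


class SyntheticPredictor:
    """Deterministic pseudo-rank predictor satisfying the predictor contract.

    Ranks derive from a seeded blake2b hash of (seed, peptide, allotype),
    mapped log-uniformly onto [rank_lo, rank_hi] through a power warp of the
    uniform variate calibrated so that P(rank < 0.5) equals
    ``strong_binder_mass``. Icore is the full peptide by default. Planted
    signals override ranks for their mutation's windows (see
    :class:`PlantedSignal`); outside strong allotypes, every window of a
    planted mutation is floored at ``background_floor``.
    """

    def __init__(
        self,
        seed: int,
        library: Iterable[Allotype],
        planted: Sequence[PlantedSignal] = (),
        planted_pairs: Mapping[str, Sequence[PeptidePair]] | None = None,
        strong_binder_mass: float = DEFAULT_STRONG_BINDER_MASS,
        rank_range: tuple[float, float] = (0.01, 100.0),
        background_floor: float = DEFAULT_BACKGROUND_FLOOR,
    ):
        self.seed = seed
        self.library = frozenset(library)
        self.rank_lo, self.rank_hi = rank_range
        self.background_floor = background_floor
        self.strong_binder_mass = strong_binder_mass
        c = math.log(0.5 / self.rank_lo) / math.log(self.rank_hi / self.rank_lo)
        self._alpha = math.log(c) / math.log(strong_binder_mass)
        self.call_count = 0

        self._signal_by_peptide: dict[str, tuple[PlantedSignal, str, PeptidePair]] = {}
        planted_pairs = planted_pairs or {}
        for signal in planted:
            pairs = list(planted_pairs.get(signal.mutation_id, ()))
            if not pairs:
                raise ValueError(f"no peptide pairs supplied for {signal.mutation_id}")
            chosen = pairs[0]
            for pair in pairs:
                role_mut = "chosen_mut" if pair is chosen else "other"
                self._signal_by_peptide[pair.mutant] = (signal, role_mut, pair)
                role_wt = "chosen_wt" if pair is chosen else "other"
                self._signal_by_peptide.setdefault(pair.wildtype, (signal, role_wt, pair))

    # -- rank machinery ----------------------------------------------------
    def _uniform(self, peptide: str, allotype: Allotype) -> float:
        digest = hashlib.blake2b(
            f"{self.seed}|{peptide}|{allotype}".encode(), digest_size=8
        ).digest()
        return int.from_bytes(digest, "big") / 2.0**64

    def _background_rank(self, peptide: str, allotype: Allotype) -> float:
        u = self._uniform(peptide, allotype)
        return self.rank_lo * (self.rank_hi / self.rank_lo) ** (u**self._alpha)

    def mass_below(self, threshold: float) -> float:
        """P(background rank < threshold) under the warped distribution."""
        if threshold <= self.rank_lo:
            return 0.0
        c = math.log(threshold / self.rank_lo) / math.log(self.rank_hi / self.rank_lo)
        return min(1.0, c ** (1.0 / self._alpha))

    def _rank_for(self, peptide: str, allotype: Allotype) -> float:
        raw = self._background_rank(peptide, allotype)
        hit = self._signal_by_peptide.get(peptide)
        if hit is None:
            return raw
        signal, role, _pair = hit
        if allotype in signal.strong_allotypes:
            if role == "chosen_mut":
                return signal.target_rank
            if role == "chosen_wt":
                return max(raw, signal.wt_rank_floor)
        return max(raw, self.background_floor)

    def query(self, peptides: Sequence[str], allotypes: Sequence[Allotype]) -> list[RankRecord]:
        self.call_count += 1
        records = []
        for allo in allotypes:
            for pep in peptides:
                records.append(RankRecord(pep, allo, self._rank_for(pep, allo), icore=pep))
        return records


def synthetic_predictor(
    seed: int,
    planted: Sequence[PlantedSignal] = (),
    planted_pairs: Mapping[str, Sequence[PeptidePair]] | None = None,
    library: Iterable[Allotype] | None = None,
    **kwargs,
) -> SyntheticPredictor:
    """Convenience constructor; the library defaults to the allotypes named
    by the planted signals plus a uniform 10-allele spectrum."""
    if library is None:
        lib = set(AlleleSpectrum.uniform(10).allotypes)
        for signal in planted:
            lib.update(signal.strong_allotypes)
        library = lib
    return SyntheticPredictor(seed, library, planted, planted_pairs, **kwargs)


@dataclass
class CoverageScenario:
    """A panel/predictor pair with the analytically expected presentation
    coverage for each planted mutation."""

    panel: HaplotypePanel
    predictor: SyntheticPredictor
    expected_pct: dict[str, float]
    pairs_by_mutation: dict[str, list[PeptidePair]]
    mutations: MutationSet = field(default_factory=lambda: MutationSet([], "planted"))


def hardy_weinberg_carrier_pct(spectrum: AlleleSpectrum,
                               strong: Iterable[Allotype]) -> float:
    """100 × (1 − Π_locus (1 − q_locus)²), q_locus = summed frequency of the
    strong allotypes at that locus — the probability that a diploid
    individual carries at least one strong allotype."""
    strong = set(strong)
    prob_none = 1.0
    for locus in LOCI:
        q = sum(f for a, f in spectrum.per_locus[locus].items() if a in strong)
        prob_none *= (1.0 - q) ** 2
    return 100.0 * (1.0 - prob_none)


def planted_coverage_scenario(
    spectrum: AlleleSpectrum,
    planted: Sequence[PlantedSignal],
    n: int,
    seed: int,
    pairs_by_mutation: Mapping[str, Sequence[PeptidePair]] | None = None,
    **predictor_kwargs,
) -> CoverageScenario:
    """Panel + predictor + analytic expectation for coverage-recovery tests.

    ``expected_pct[mutation_id]`` is the Hardy-Weinberg carrier probability
    of the mutation's strong allotypes under ``spectrum``; because the
    planted mutation's ranks are floored above the presentation threshold
    everywhere else, pipeline ``pct_presented`` at threshold 0.5 estimates
    exactly this quantity. When ``pairs_by_mutation`` is not supplied a
    small synthetic protein is generated per planted mutation.
    """
    missing = [
        str(a) for s in planted for a in s.strong_allotypes
        if a not in spectrum.allotypes
    ]
    if missing:
        raise InvalidSpectrum(f"planted allotypes absent from spectrum: {missing}")

    mutations = MutationSet([], "planted")
    if pairs_by_mutation is None:
        rng = np.random.default_rng(seed + 1)
        pairs_by_mutation = {}
        muts = []
        for i, signal in enumerate(planted):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=41))
            pos = 21
            wt = seq[pos - 1]
            mut = str(rng.choice([a for a in AMINO_ACIDS if a != wt]))
            pairs_by_mutation[signal.mutation_id] = generate_pairs(
                seq, pos, wt, mut, PEPTIDE_LENGTHS
            )
            muts.append(
                MissenseMutation(signal.mutation_id, f"PLANT{i:02d}", f"PLANTT{i:02d}",
                                 pos, wt, mut, occurrences=20, set_label="planted")
            )
        mutations = MutationSet(muts, "planted")

    panel = simulate_panel(n, spectrum, seed)
    predictor = SyntheticPredictor(
        seed, spectrum.allotypes, planted, pairs_by_mutation, **predictor_kwargs
    )
    expected = {
        s.mutation_id: hardy_weinberg_carrier_pct(spectrum, s.strong_allotypes)
        for s in planted
    }
    return CoverageScenario(panel, predictor, expected,
                            {k: list(v) for k, v in pairs_by_mutation.items()}, mutations)
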
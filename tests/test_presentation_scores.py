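"""Score algebra: BR / IBR / PHBR / PMHBR / MinRank / criteria, with an
independent brute-force oracle on randomized micro-instances."""

import itertools
import random

import numpy as np
import pytest

from neoscreen.errors import DomainError, EmptyInput, MissingAllotypeBR
from neoscreen.haplotype_io import Haplotype, HaplotypePanel
from neoscreen.mutation_catalog import MissenseMutation, MutationSet
from neoscreen.peptide_factory import PeptidePair
from neoscreen.predictor_gateway import RankRecord, RankStore
from neoscreen.presentation_scores import (
    SENTINEL_BR,
    BRTable,
    CriterionConfig,
    best_rank,
    br_heatmap,
    build_br_table,
    ibr,
    icore_spans_mutation,
    minrank,
    mutant_vs_wt,
    pct_mutant_vs_wt,
    pct_presented,
    phbr,
    pmhbr,
)

from conftest import allo, make_haplotype, make_store

PAIR1 = PeptidePair("ACDEFGHW", "ACDEFGHI", 1, 7)  # mutation at window index 7
PAIR2 = PeptidePair("CDEFGHWK", "CDEFGHIK", 2, 6)
A1 = "A*01:01"


class TestBestRank:
    def test_wildtype_icore_excluded_from_minimum(self):
        # PAIR2's icore misses the mutated residue -> its better rank must not win
        store = make_store([
            (PAIR1.mutant, A1, 0.3, "CDEFGHW"),   # spans offset 7? icore at idx 1..7 -> yes
            (PAIR2.mutant, A1, 0.1, "CDEFGH"),    # idx 0..5, offset 6 -> wild-type core
        ])
        assert best_rank([PAIR1, PAIR2], allo(A1), store) == 0.3

    def test_all_wildtype_icores_give_sentinel(self):
        store = make_store([
            (PAIR1.mutant, A1, 0.3, "ACDEFGH"),
            (PAIR2.mutant, A1, 0.1, "CDEFGH"),
        ])
        assert best_rank([PAIR1, PAIR2], allo(A1), store) == SENTINEL_BR

    def test_single_eligible_peptide(self):
        store = make_store([(PAIR1.mutant, A1, 1.7)])
        assert best_rank([PAIR1], allo(A1), store) == 1.7

    def test_exclusion_never_lowers_br(self):
        store = make_store([
            (PAIR1.mutant, A1, 0.9),
            (PAIR2.mutant, A1, 0.05, "CDEFGH"),
        ])
        with_exclusion = best_rank([PAIR1, PAIR2], allo(A1), store)
        no_exclusion = min(store.rank(p.mutant, allo(A1)) for p in (PAIR1, PAIR2))
        assert with_exclusion >= no_exclusion

    def test_icore_span_detection_checks_all_placements(self):
        # icore "CDC" occurs twice in "ACDCDC.."; only the second spans offset 4
        pair = PeptidePair("ACDCDCKW", "ACDCACKW", 1, 4)
        assert icore_spans_mutation(pair, "CDC")
        assert not icore_spans_mutation(pair, "AC")


class TestHarmonicMeanScores:
    def test_equal_inputs_give_that_value(self):
        assert phbr([1.0] * 6) == pytest.approx(1.0)
        assert phbr([SENTINEL_BR] * 6) == pytest.approx(SENTINEL_BR)

    def test_hand_computed_value(self):
        assert phbr([0.5, 1, 1, 1, 1, 1]) == pytest.approx(6 / 7)

    def test_bounds_and_monotonicity(self):
        rng = random.Random(0)
        for _ in range(50):
            brs = [rng.uniform(0.01, 100) for _ in range(6)]
            v = phbr(brs)
            assert min(brs) <= v <= max(brs)
            lowered = list(brs)
            lowered[rng.randrange(6)] *= 0.5
            assert phbr(lowered) <= v

    def test_nonpositive_input_rejected(self):
        with pytest.raises(DomainError):
            phbr([1, 1, 1, 1, 1, -2])

    def test_ibr_is_minimum_and_bounded_by_phbr(self):
        brs = [3, 0.2, 50, 4, 4, 4]
        assert ibr(brs) == 0.2
        assert ibr(brs) <= phbr(brs)
        with pytest.raises(EmptyInput):
            ibr([])


def _table(mapping):
    table = BRTable()
    for (mid, name), v in mapping.items():
        table.set(mid, allo(name), v)
    return table


def _uniform_table(mid, haplotypes, values):
    """One BR per individual spread over that individual's allotypes."""
    table = BRTable()
    for h, v in zip(haplotypes, values):
        for a in h.allotypes:
            table.set(mid, a, v)
    return table


class TestPmhbrAndCoverage:
    def test_single_individual_median_is_phbr(self, two_person_panel):
        solo_h = two_person_panel.haplotypes[0]
        table = _uniform_table("m", [solo_h], [2.0])
        solo = HaplotypePanel([solo_h])
        assert pmhbr("m", solo, table) == pytest.approx(2.0)

    def test_even_panel_median_is_midpoint(self):
        haps = [
            make_haplotype(f"I{i}", a1=f"A*{i+20:02d}:01", a2=f"A*{i+20:02d}:01",
                           b1=f"B*{i+20:02d}:01", b2=f"B*{i+20:02d}:01",
                           c1=f"C*{i+20:02d}:01", c2=f"C*{i+20:02d}:01")
            for i in range(4)
        ]
        table = _uniform_table("m", haps, [1.0, 2.0, 3.0, 4.0])
        assert pmhbr("m", HaplotypePanel(haps), table) == pytest.approx(2.5)

    def test_median_matches_independent_sort(self):
        rng = random.Random(3)
        haps = [
            make_haplotype(f"I{i}", a1=f"A*{i+10:02d}:01", a2=f"A*{i+10:02d}:02",
                           b1=f"B*{i+10:02d}:01", b2=f"B*{i+10:02d}:02",
                           c1=f"C*{i+10:02d}:01", c2=f"C*{i+10:02d}:02")
            for i in range(7)
        ]
        table = BRTable()
        phbrs = []
        for h in haps:
            brs = [rng.uniform(0.1, 50) for _ in range(6)]
            for a, v in zip(h.at_loci(), brs):
                table.set("m", a, v)
            phbrs.append(6 / sum(1 / b for b in brs))
        expected = sorted(phbrs)[3]
        assert pmhbr("m", HaplotypePanel(haps), table) == pytest.approx(expected)

    def test_pct_presented_extremes_and_monotonicity(self, two_person_panel):
        table = _uniform_table("m", two_person_panel.haplotypes, [0.1, 0.1])
        assert pct_presented("m", two_person_panel, table, 0.5) == 100.0
        high = _uniform_table("m", two_person_panel.haplotypes, [50.0, 50.0])
        assert pct_presented("m", two_person_panel, high, 0.5) == 0.0
        mixed = _uniform_table("m", two_person_panel.haplotypes, [1.0, 3.0])
        assert pct_presented("m", two_person_panel, mixed, 2.0) >= pct_presented(
            "m", two_person_panel, mixed, 0.5
        )

    def test_strict_inequality_at_threshold(self, two_person_panel):
        table = _uniform_table("m", two_person_panel.haplotypes, [0.5, 0.5])
        assert pct_presented("m", two_person_panel, table, 0.5) == 0.0

    def test_missing_allotype_br_raises(self, two_person_panel):
        with pytest.raises(MissingAllotypeBR):
            pmhbr("m", two_person_panel, BRTable())

    def test_loci_subset_uses_four_values(self, six_allotype_haplotype):
        table = BRTable()
        for a, v in zip(six_allotype_haplotype.at_loci(), [1, 2, 3, 4, 5, 6]):
            table.set("m", a, float(v))
        panel = HaplotypePanel([six_allotype_haplotype])
        ab = pmhbr("m", panel, table, loci=("A", "B"))
        assert ab == pytest.approx(4 / (1 / 1 + 1 / 2 + 1 / 3 + 1 / 4))
        full = pmhbr("m", panel, table)
        for v in (ab, full):
            assert 1.0 <= v <= 6.0


class TestMinRankAndCriteria:
    def test_minrank_over_six_allotypes(self, six_allotype_haplotype):
        ranks = [0.7, 0.2, 5, 5, 5, 5]
        store = make_store([
            ("PEPTIDEX", str(a), r)
            for a, r in zip(six_allotype_haplotype.at_loci(), ranks)
        ])
        assert minrank("PEPTIDEX", six_allotype_haplotype, store) == 0.2

    def test_minrank_homozygous_three_distinct(self):
        hap = make_haplotype("H", a2="A*01:01", b2="B*07:02", c2="C*07:01")
        store = make_store([
            ("PEPTIDEX", "A*01:01", 3.0),
            ("PEPTIDEX", "B*07:02", 1.5),
            ("PEPTIDEX", "C*07:01", 9.0),
        ])
        assert minrank("PEPTIDEX", hap, store) == 1.5

    def _criterion_store(self, hap, mut_rank, wt_rank):
        entries = []
        for a in hap.distinct_allotypes:
            entries.append((PAIR1.mutant, str(a), 50.0))
            entries.append((PAIR1.wildtype, str(a), 50.0))
        store = make_store(entries)
        best = sorted(hap.distinct_allotypes)[0]
        store.add(RankRecord(PAIR1.mutant, best, mut_rank, PAIR1.mutant))
        store.add(RankRecord(PAIR1.wildtype, best, wt_rank, PAIR1.wildtype))
        return store

    def test_fixed_threshold_criterion_true(self, six_allotype_haplotype):
        store = self._criterion_store(six_allotype_haplotype, 0.3, 0.9)
        cfg = CriterionConfig("fixed_thresholds", 0.5, 0.5)
        assert mutant_vs_wt([PAIR1], six_allotype_haplotype, store, cfg)

    def test_mode_contrast_wt_weakly_presented(self, six_allotype_haplotype):
        # mutant 0.3, wild type 0.4: fails fixed 0.5/0.5, passes mutant-below-wt
        store = self._criterion_store(six_allotype_haplotype, 0.3, 0.4)
        assert not mutant_vs_wt(
            [PAIR1], six_allotype_haplotype, store,
            CriterionConfig("fixed_thresholds", 0.5, 0.5),
        )
        assert mutant_vs_wt(
            [PAIR1], six_allotype_haplotype, store,
            CriterionConfig("mutant_below_wt", 0.5),
        )

    def test_no_eligible_pair_is_false(self, six_allotype_haplotype):
        entries = [
            (p, str(a), 0.1, "CDEFGH")  # icore misses the mutation
            for a in six_allotype_haplotype.distinct_allotypes
            for p in (PAIR2.mutant, PAIR2.wildtype)
        ]
        store = make_store(entries)
        assert not mutant_vs_wt([PAIR2], six_allotype_haplotype, store,
                                CriterionConfig("fixed_thresholds", 0.5))

    def test_criterion_config_invariant(self):
        with pytest.raises(ValueError):
            CriterionConfig("fixed_thresholds", t_mut=2.0, t_wt=0.5)


class TestBruteForceOracle:
    """Full-pipeline equivalence against independent enumeration on
    micro-instances (<=5 individuals, <=3 peptides, <=6 allotypes)."""

    @staticmethod
    def _spans(peptide, icore, offset):
        return any(
            i <= offset < i + len(icore)
            for i in range(len(peptide) - len(icore) + 1)
            if peptide[i : i + len(icore)] == icore
        )

    def _random_instance(self, rng):
        allotypes = [allo(f"{l}*{g:02d}:01") for l in "ABC" for g in (1, 2)]
        base = "ACDEFGHIKLMN"
        pairs = []
        n_pep = rng.randint(1, 3)
        for i in range(n_pep):
            start = i + 1
            window = base[start - 1 : start - 1 + 8]
            offset = rng.randrange(8)
            mut_res = "W" if window[offset] != "W" else "Y"
            mutant = window[:offset] + mut_res + window[offset + 1 :]
            pairs.append(PeptidePair(mutant, window, start, offset))
        store = RankStore()
        for pair in pairs:
            for a in allotypes:
                rank_m = round(rng.uniform(0.05, 6.0), 3)
                icore = pair.mutant if rng.random() < 0.6 else pair.mutant[
                    : rng.randint(4, 7)
                ]
                store.add(RankRecord(pair.mutant, a, rank_m, icore))
                store.add(RankRecord(pair.wildtype, a, round(rng.uniform(0.05, 6.0), 3),
                                     pair.wildtype))
        n_ind = rng.randint(1, 5)
        haps = []
        for i in range(n_ind):
            chosen = []
            for locus in "ABC":
                pool = [a for a in allotypes if a.locus == locus]
                chosen.extend(rng.choices(pool, k=2))
            haps.append(Haplotype(f"I{i}", tuple(chosen)))
        return pairs, allotypes, store, HaplotypePanel(haps)

    def test_oracle_reproduces_all_scores_exactly(self):
        rng = random.Random(2024)
        for _ in range(25):
            pairs, allotypes, store, panel = self._random_instance(rng)

            # oracle BR: enumerate every (peptide, allotype) record
            def oracle_br(a):
                eligible = [
                    store.get(p.mutant, a).rank
                    for p in pairs
                    if self._spans(p.mutant, store.get(p.mutant, a).icore,
                                   p.mutation_offset)
                ]
                return min(eligible) if eligible else 100.0

            table = build_br_table({"m": pairs}, allotypes, store)
            for a in allotypes:
                assert table.get("m", a) == oracle_br(a)

            # oracle IBR / PHBR / PMHBR per individual
            phbrs = []
            for h in panel:
                brs = [oracle_br(a) for a in h.at_loci()]
                assert ibr(brs) == min(brs)
                expected_phbr = 6 / sum(1 / b for b in brs)
                got = phbr([table.get("m", a) for a in h.at_loci()])
                assert got == pytest.approx(expected_phbr)
                phbrs.append(expected_phbr)
            assert pmhbr("m", panel, table) == pytest.approx(
                float(np.median(phbrs))
            )

            # oracle criterion: exhaustive over pairs and allotypes
            cfg = CriterionConfig("fixed_thresholds", 2.0, 2.0)
            for h in panel:
                expected = False
                for p in pairs:
                    elig = [
                        store.get(p.mutant, a).rank
                        for a in set(h.at_loci())
                        if self._spans(p.mutant, store.get(p.mutant, a).icore,
                                       p.mutation_offset)
                    ]
                    if not elig:
                        continue
                    wt_mr = min(store.get(p.wildtype, a).rank for a in set(h.at_loci()))
                    if min(elig) < 2.0 and wt_mr >= 2.0:
                        expected = True
                assert mutant_vs_wt(pairs, h, store, cfg) == expected


class TestHeatmap:
    def _setup(self, two_person_panel):
        mutations = MutationSet([
            MissenseMutation("m1", "EGFR", "T1", 790, "T", "M"),
            MissenseMutation("m2", "ABL1", "T2", 315, "T", "I"),
        ])
        table = BRTable()
        for i, m in enumerate(mutations):
            for a in two_person_panel.all_allotypes:
                table.set(m.mutation_id, a, 0.5 + i + (hash(str(a)) % 7))
        return mutations, table

    def test_matrix_shape_and_column_order(self, two_person_panel):
        mutations, table = self._setup(two_person_panel)
        matrix, meta = br_heatmap(mutations, two_person_panel, table, min_freq=0.0)
        from neoscreen.haplotype_io import common_alleles

        expected_cols = [str(a) for a in common_alleles(two_person_panel, 0.0)]
        assert list(matrix.columns) == expected_cols
        assert matrix.shape == (2, len(expected_cols))
        # rows grouped by gene (ABL1 before EGFR alphabetically)
        assert list(matrix.index) == ["m2", "m1"]

    def test_raw_values_preserved_above_display_cap(self, two_person_panel):
        mutations, table = self._setup(two_person_panel)
        a = sorted(two_person_panel.all_allotypes)[0]
        table.set("m1", a, 37.0)
        matrix, meta = br_heatmap(mutations, two_person_panel, table, min_freq=0.0)
        assert matrix.loc["m1", str(a)] == 37.0
        assert meta["display_cap"] == 4.0
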
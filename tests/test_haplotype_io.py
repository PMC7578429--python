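"""Allotype normalization, haplotype-table filtering, allele frequencies."""

import io

import pytest
from hypothesis import given, strategies as st

from neoscreen.errors import EmptyPanel, FormatError, MalformedAllotype
from neoscreen.haplotype_io import (
    Allotype,
    HaplotypePanel,
    allele_frequencies,
    common_alleles,
    load_haplotype_table,
    parse_allotype,
)

from conftest import make_haplotype


class TestParseAllotype:
    @pytest.mark.parametrize(
        "raw, canonical",
        [
            ("A*02:01", "HLA-A*02:01"),
            ("HLA-A02:01", "HLA-A*02:01"),
            ("HLA-A*02:01", "HLA-A*02:01"),
            ("A0201", "HLA-A*02:01"),
            ("HLA-A03:03N", "HLA-A*03:03N"),
            ("HLA-C0140", "HLA-C*01:40"),
            ("B*44:02:01", "HLA-B*44:02"),  # extra fields truncated to 4-digit
        ],
    )
    def test_accepted_dialects_normalize(self, raw, canonical):
        assert str(parse_allotype(raw)) == canonical

    @pytest.mark.parametrize(
        "raw", ["HLA-B44", "HLA-C15", "0000", "HLA-C14XX", "", "DRB1*04:01", "A*:01"]
    )
    def test_rejects_underresolved_and_malformed(self, raw):
        with pytest.raises(MalformedAllotype):
            parse_allotype(raw)

    def test_locus_hint_enables_bare_digit_cells(self):
        assert str(parse_allotype("24:02", locus_hint="B")) == "HLA-B*24:02"

    @given(
        locus=st.sampled_from("ABC"),
        group=st.integers(1, 99),
        protein=st.integers(1, 99),
        dialect=st.sampled_from(["{l}*{g:02d}:{p:02d}", "HLA-{l}{g:02d}:{p:02d}",
                                 "HLA-{l}*{g:02d}:{p:02d}"]),
    )
    def test_parse_render_parse_is_fixed_point(self, locus, group, protein, dialect):
        raw = dialect.format(l=locus, g=group, p=protein)
        parsed = parse_allotype(raw)
        assert parse_allotype(str(parsed)) == parsed


TABLE_HEADER = "id pop A.1 A.2 B.1 B.2 C.1 C.2\n"


def _row(ind, *cells):
    return f"{ind} EUR " + " ".join(cells) + "\n"


class TestLoadHaplotypeTable:
    def test_first_slash_entry_kept(self):
        text = TABLE_HEADER + _row(
            "I1", "A*03:01/A*03:20", "A*02:01", "B*07:02", "B*08:01", "C*07:01", "C*07:02"
        )
        panel, log = load_haplotype_table(io.StringIO(text))
        assert len(panel) == 1 and log.empty
        assert str(panel.haplotypes[0].allotypes[0]) == "HLA-A*03:01"

    def test_malformed_cell_drops_individual_and_logs(self):
        text = TABLE_HEADER + _row(
            "I1", "A*03:01", "A*02:01", "B*07:02", "B*08:01", "HLA-C14XX", "C*07:02"
        )
        panel, log = load_haplotype_table(io.StringIO(text))
        assert len(panel) == 0
        assert list(log.reason) == ["malformed"] and list(log.individual_id) == ["I1"]

    def test_exclusion_list_and_library_filtering(self):
        lib = {parse_allotype(n) for n in
               ("A*03:01", "A*02:01", "B*07:02", "B*08:01", "C*07:01", "C*07:02")}
        text = TABLE_HEADER + "".join([
            _row("OK", "A*03:01", "A*02:01", "B*07:02", "B*08:01", "C*07:01", "C*07:02"),
            _row("EXCL", "A*03:01", "A*02:01", "B*07:02", "B*08:01", "HLA-C15", "C*07:02"),
            _row("NOLIB", "A*03:01", "A*11:01", "B*07:02", "B*08:01", "C*07:01", "C*07:02"),
        ])
        panel, log = load_haplotype_table(
            io.StringIO(text), predictor_library=lib, exclusions=["HLA-C15"]
        )
        assert panel.ids == ["OK"]
        assert dict(zip(log.individual_id, log.reason)) == {
            "EXCL": "excluded", "NOLIB": "not_in_predictor_library"
        }

    def test_all_valid_rows_retained(self):
        rows = [
            _row(f"I{i}", "A*03:01", "A*02:01", "B*07:02", "B*08:01", "C*07:01", "C*07:02")
            for i in range(3)
        ]
        panel, log = load_haplotype_table(io.StringIO(TABLE_HEADER + "".join(rows)))
        assert len(panel) == 3 and log.empty

    def test_retained_plus_rejected_equals_input(self):
        rows = [
            _row("I1", "A*03:01", "A*02:01", "B*07:02", "B*08:01", "C*07:01", "C*07:02"),
            _row("I2", "0000", "A*02:01", "B*07:02", "B*08:01", "C*07:01", "C*07:02"),
            _row("I1", "A*03:01", "A*02:01", "B*07:02", "B*08:01", "C*07:01", "C*07:02"),
        ]
        panel, log = load_haplotype_table(io.StringIO(TABLE_HEADER + "".join(rows)))
        assert len(panel) + len(log) == 3
        assert "duplicate_id" in set(log.reason)

    def test_too_few_columns_raises(self):
        with pytest.raises(FormatError):
            load_haplotype_table(io.StringIO("id A.1 A.2\nI1 A*01:01 A*02:01\n"))

    def test_panel_tsv_roundtrip(self, tmp_path, two_person_panel):
        path = tmp_path / "panel.tsv"
        two_person_panel.write_tsv(path)
        reloaded = HaplotypePanel.from_tsv(path)
        assert reloaded.ids == two_person_panel.ids
        assert [h.allotypes for h in reloaded] == [h.allotypes for h in two_person_panel]


class TestAlleleFrequencies:
    def test_homozygous_panel_gives_frequency_one(self):
        panel = HaplotypePanel([
            make_haplotype("I1", a1="A*01:01", a2="A*01:01"),
            make_haplotype("I2", a1="A*01:01", a2="A*01:01"),
        ])
        freqs = allele_frequencies(panel)
        a = freqs[freqs.locus == "A"]
        assert len(a) == 1 and a.frequency.iloc[0] == 1.0

    def test_heterozygote_gives_half_each(self):
        panel = HaplotypePanel([make_haplotype("I1", a1="A*01:01", a2="A*02:01")])
        a = allele_frequencies(panel).query("locus == 'A'")
        assert sorted(a.frequency) == [0.5, 0.5]

    def test_per_locus_frequencies_sum_to_one(self, two_person_panel):
        freqs = allele_frequencies(two_person_panel)
        for locus in "ABC":
            assert freqs[freqs.locus == locus].frequency.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_panel_raises(self):
        with pytest.raises(EmptyPanel):
            allele_frequencies(HaplotypePanel([]))

    def test_simulated_panel_frequencies_near_spectrum(self):
        # sampling recovery against the generating spectrum at n=2,000
        from neoscreen.synthetic_data import AlleleSpectrum, simulate_panel

        spectrum = AlleleSpectrum.uniform(10)
        panel = simulate_panel(2000, spectrum, seed=7)
        freqs = allele_frequencies(panel)
        for _, row in freqs.iterrows():
            assert row.frequency == pytest.approx(0.1, abs=0.02)


class TestCommonAlleles:
    def test_min_freq_zero_returns_distinct_allotypes(self):
        panel = HaplotypePanel([make_haplotype("I1")])
        names = {str(a) for a in common_alleles(panel, 0.0)}
        assert names == {str(a) for a in panel.all_allotypes}

    def test_threshold_filters_by_brute_force_count(self):
        # 10 individuals: A*01:01 dominant, A*02:01 in one, others unique-ish
        haps = [make_haplotype(f"I{i}", a1="A*01:01", a2="A*01:01") for i in range(9)]
        haps.append(make_haplotype("I9", a1="A*02:01", a2="A*31:01"))
        panel = HaplotypePanel(haps)
        # brute force: counts/20 -> A*01:01 .9, A*02:01 .05, A*31:01 .05
        result = [str(a) for a in common_alleles(panel, 0.06) if a.locus == "A"]
        assert result == ["HLA-A*01:01"]

    def test_ordering_is_locus_grouped_descending_frequency(self, two_person_panel):
        ordering = common_alleles(two_person_panel, 0.0)
        loci = [a.locus for a in ordering]
        assert loci == sorted(loci)  # A then B then C
        freqs = allele_frequencies(two_person_panel).set_index("allotype").frequency
        for locus in "ABC":
            fs = [freqs[str(a)] for a in ordering if a.locus == locus]
            assert fs == sorted(fs, reverse=True)

    def test_near_one_threshold_empty_without_fixed_allele(self, two_person_panel):
        assert common_alleles(two_person_panel, 1 - 1e-9) == []
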
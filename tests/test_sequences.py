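"""Strand-library parsing, domain discovery, annotation and design checks."""

import pytest

import hairpinrep as hr
from hairpinrep.sequences import (
    LibraryError,
    DomainError,
    AnnotationError,
    StrandLibrary,
    longest_complementary_stretch,
    parse_strand_id,
    strand_id,
)
from hairpinrep.thermo import reverse_complement


def brute_force_domains(lib, bit):
    """Independent oracle: exhaustive 15-mer intersection over the bit's strands."""
    sense = [s.sequence for s in lib.select(bit=bit, sense="sense")]
    anti = [s.sequence for s in lib.select(bit=bit, sense="antisense")]
    found = set()
    for i in range(len(sense[0]) - 14):
        cand = sense[0][i : i + 15]
        if all(cand in s for s in sense) and all(
            reverse_complement(cand) in a for a in anti
        ):
            found.add(cand)
    return found


class TestLoadLibrary:
    def test_packaged_fixture_complete(self, library):
        assert len(library) == 16
        for s in library.strands.values():
            assert 82 <= len(s) <= 84
            assert set(s.sequence) <= set("ACGT")

    def test_missing_strand_named_in_error(self, library, tmp_path):
        fa = tmp_path / "partial.fa"
        with fa.open("w") as f:
            for sid, s in library.strands.items():
                if sid != "0D":
                    f.write(f">{sid}\n{s.sequence}\n")
        with pytest.raises(LibraryError, match=r"\('0', 'D', 'sense'\)"):
            hr.load_library(fa)

    def test_non_acgt_character_rejected(self, library, tmp_path):
        fa = tmp_path / "bad.fa"
        seq = library["0A"].sequence[:-1] + "X"
        fa.write_text(f">0A\n{seq}\n")
        with pytest.raises(LibraryError, match="position 83"):
            hr.load_library(fa)

    def test_non_strand_headers_ignored(self, library, tmp_path):
        fa = tmp_path / "with_random.fa"
        with fa.open("w") as f:
            f.write(">R0\n" + "ACGT" * 21 + "\n")
            for sid, s in library.strands.items():
                f.write(f">{sid}\n{s.sequence}\n")
        assert len(hr.load_library(fa)) == 16

    @pytest.mark.parametrize(
        "header,expected",
        [
            ("0A", ("0", "A", "sense", None)),
            ("1D*", ("1", "D", "antisense", None)),
            ("0A-Cy5", ("0", "A", "sense", "Cy5")),
            ("R7", None),
        ],
    )
    def test_header_parsing(self, header, expected):
        assert parse_strand_id(header) == expected


class TestInformationDomains:
    def test_discovered_domains_match_brute_force(self, library):
        for bit in "01":
            assert {library.info_domains[bit]} == brute_force_domains(library, bit)

    def test_expected_domain_sequences(self, library):
        # frozen from the brute-force oracle above on the printed strands
        assert library.info_domains["0"] == "AGTGGGTAATAATGA"
        assert library.info_domains["1"] == "AAAAGAAGAGAAAGA"

    def test_involutive_under_complementation(self, library):
        """Swapping sense/antisense roles returns the reverse complements."""
        swapped = StrandLibrary(
            {
                sid: hr.Strand(
                    id=s.id,
                    sequence=s.sequence,
                    bit=s.bit,
                    position=s.position,
                    sense="antisense" if s.sense == "sense" else "sense",
                )
                for sid, s in library.strands.items()
            }
        )
        domains = hr.find_information_domains(swapped)
        for bit in "01":
            assert domains[bit] == reverse_complement(library.info_domains[bit])

    def test_sense_only_library_fails(self, library):
        sense_only = library.subset(
            [sid for sid in library.strands if "*" not in sid]
        )
        sense_only.info_domains = {}
        with pytest.raises(DomainError, match="antisense"):
            hr.find_information_domains(sense_only)

    def test_revcomp_in_antisense_partner(self, library):
        for bit in "01":
            rc = reverse_complement(library.info_domains[bit])
            for s in library.select(bit=bit, sense="antisense"):
                assert rc in s.sequence


class TestAnnotation:
    def test_spans_partition_every_strand(self, library):
        for s in library.strands.values():
            ann = hr.annotate_strand(s, library)
            assert ann.hairpin5[0] == 0
            assert ann.hairpin3[1] == len(s)
            total = sum(
                b - a for a, b in (ann.hairpin5, ann.info, ann.hairpin3)
            )
            assert total == len(s)

    def test_info_span_located_by_substring(self, library):
        s = library["0A"]
        ann = hr.annotate_strand(s, library)
        assert s.sequence[slice(*ann.info)] == library.info_domains["0"]
        assert 0 < ann.info[0] and ann.info[1] < len(s)

    def test_antisense_span_is_revcomp_match(self, library):
        s = library["0A*"]
        ann = hr.annotate_strand(s, library)
        assert s.sequence[slice(*ann.info)] == reverse_complement(
            library.info_domains["0"]
        )

    def test_duplicated_domain_is_ambiguous(self, library):
        dom = library.info_domains["0"]
        seq = (dom + dom + "G" * 54)[:84]
        fake = hr.Strand(id="0A", sequence=seq, bit="0", position="A", sense="sense")
        with pytest.raises(AnnotationError, match="occurs 2 times"):
            hr.annotate_strand(fake, library)


class TestDesignValidation:
    def test_all_backbone_stretches_long(self, design_report):
        assert len(design_report.pairs) == 16
        assert (design_report.pairs["stretch_nt"] >= 20).all()
        assert design_report.pairs["ok"].all()

    def test_melting_order_info_below_backbone(self, design_report):
        """Info duplexes must melt at the peak while backbones survive."""
        assert design_report.max_info_tm < 67.0
        assert design_report.min_backbone_tm > 74.0
        assert design_report.ordering_ok

    def test_info_tm_near_measured_value(self, design_report):
        assert design_report.info_tm["0"] == pytest.approx(48.0, abs=3.0)

    def test_scrambled_hairpin_flagged(self, library):
        seq = library["0B"].sequence
        ann = hr.annotate_strand(library["0B"], library)
        start, stop = ann.hairpin5
        # swap A<->C inside the 5' hairpin: length/alphabet stay valid
        scrambled = (
            seq[:start]
            + seq[start:stop].translate(str.maketrans("AC", "CA"))
            + seq[stop:]
        )
        strands = dict(library.strands)
        strands["0B"] = hr.Strand(
            id="0B", sequence=scrambled, bit="0", position="B", sense="sense"
        )
        broken = StrandLibrary(strands, dict(library.info_domains))
        rep = hr.validate_design(broken)
        flagged = rep.pairs.loc[~rep.pairs["ok"]]
        assert set(flagged["successor"]) == {"0B"}
        assert rep.pairs.loc[rep.pairs["strand"] == "0B", "ok"].all()

    def test_stretch_finder_on_known_pair(self, library):
        """Sliding-window oracle value for the 0A->0B junction."""
        ann_a = hr.annotate_strand(library["0A"], library)
        ann_b = hr.annotate_strand(library["0B"], library)
        hp3 = library["0A"].sequence[slice(*ann_a.hairpin3)]
        hp5 = library["0B"].sequence[slice(*ann_b.hairpin5)]
        m = longest_complementary_stretch(hp3, hp5)
        assert m.length == 32
        assert m.mismatches == 0


class TestStrandSets:
    def test_full_pattern_returns_all_16(self):
        ss = hr.strands_for_template("0000", "++++")
        assert len(ss.included) == 16

    def test_single_knockout(self):
        ss = hr.strands_for_template("0000", "+++-")
        assert strand_id("0", "D") not in ss.included
        assert len(ss.included) == 15
        assert strand_id("0", "D", True) in ss.included

    def test_double_knockout(self):
        ss = hr.strands_for_template("0000", "++--")
        missing = {"0C", "0D"}
        assert missing.isdisjoint(ss.included)
        assert len(ss.included) == 14

    def test_knockout_follows_template_bits(self):
        ss = hr.strands_for_template("0101", "-+++")
        assert "0A" not in ss.included
        assert "1A" in ss.included

    def test_bad_pattern_rejected(self):
        with pytest.raises(LibraryError):
            hr.strands_for_template("0000", "+++")
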
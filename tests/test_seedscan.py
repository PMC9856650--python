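"""Seed-pattern derivation, site classification and variant filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirutr.seedscan import (
    MatureMiRNA,
    SeedSite,
    UtrRecord,
    VariantRecord,
    count_sites_by_region,
    filter_variants_overlapping_sites,
    full_complement_site,
    multiplicity_class,
    normalize_sequence,
    reverse_complement,
    scan_utr,
    site_patterns,
)
from conftest import CONSTRUCTS, MIR1_SEQ, oracle_scan, random_utr

DNA = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("ugga", "TGGA"),
            ("TTACATACTTCTTTACATTCCA", "TTACATACTTCTTTACATTCCA"),
            (MIR1_SEQ, "TGGAATGTAAAGAAGTATGTAT"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_sequence(raw) == expected

    def test_rejects_non_iupac_naming_position(self):
        with pytest.raises(ValueError, match="position 3"):
            normalize_sequence("AC!T")

    @given(DNA)
    @settings(deadline=None)
    def test_revcomp_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestPatterns:
    def test_mir1_patterns(self, mir1):
        assert site_patterns(mir1) == {
            "8mer": "ACATTCCA",
            "7mer-m8": "ACATTCC",
            "7mer-A1": "CATTCCA",
            "6mer": "CATTCC",
        }

    def test_mir129_patterns(self, mir129):
        assert site_patterns(mir129) == {
            "8mer": "CGCAAAAA",
            "7mer-m8": "CGCAAAA",
            "7mer-A1": "GCAAAAA",
            "6mer": "GCAAAA",
        }

    @given(st.text(alphabet="ACGU", min_size=8, max_size=25))
    @settings(deadline=None)
    def test_suffix_relations(self, seq):
        """8mer = 7mer-m8 + 'A' and 7mer-A1 = 6mer + 'A' for any miRNA."""
        pats = site_patterns(MatureMiRNA("m", seq))
        assert pats["8mer"] == pats["7mer-m8"] + "A"
        assert pats["7mer-A1"] == pats["6mer"] + "A"

    def test_full_complement(self, mir206, mir124):
        assert full_complement_site(mir206) == "CCACACACTTCCTTACATTCCA"
        assert full_complement_site(mir124) == "TTGGCATTCACCGCGTGCCTTA"

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            MatureMiRNA("short", "UGGAAUG")


class TestScan:
    @pytest.mark.parametrize("name", list(CONSTRUCTS))
    def test_reporter_constructs(self, name, mir1, mir206):
        """Each single-site reporter construct classifies to its named type."""
        seq, site_type, start, end = CONSTRUCTS[name]
        mirna = mir206 if name == "miR-206 WT" else mir1
        sites = scan_utr(UtrRecord("c", seq), mirna)
        assert [(s.site_type, s.start, s.end) for s in sites] == [(site_type, start, end)]

    def test_seed_family_members_share_sites(self, mir1, mir206):
        """miR-1 and miR-206 share a seed: the 8mer construct hits both."""
        utr = UtrRecord("c", CONSTRUCTS["miR-206 8mer"][0])
        for m in (mir1, mir206):
            sites = scan_utr(utr, m)
            assert len(sites) == 1 and sites[0].site_type == "8mer"

    def test_empty_utr(self, mir1):
        assert scan_utr(UtrRecord("e", ""), mir1) == []

    def test_ambiguity_codes_never_match(self, mir1):
        seq = CONSTRUCTS["miR-1-3p 8mer"][0].replace("ACATTCCA", "ACNTTCCA")
        assert scan_utr(UtrRecord("n", seq), mir1) == []

    def test_region_assignment(self, mir1):
        seq = CONSTRUCTS["miR-1-3p 8mer"][0]  # site at 15-22
        common = scan_utr(UtrRecord("c", seq, breakpoint=16), mir1)[0]
        extended = scan_utr(UtrRecord("c", seq, breakpoint=10), mir1)[0]
        assert common.region == "common"
        assert extended.region == "extended"

    def test_breakpoint_outside_utr_rejected(self):
        with pytest.raises(ValueError, match="breakpoint"):
            UtrRecord("b", "ACGT", breakpoint=9)

    def test_oracle_equivalence_random(self, mir1, mir129):
        """Anchor-based scanner equals the exhaustive-window oracle."""
        rng = np.random.default_rng(20230106)
        for i in range(150):
            utr = random_utr(rng, int(rng.integers(50, 1500)))
            for mirna in (mir1, mir129):
                assert scan_utr(utr, mirna) == oracle_scan(utr, mirna)

    def test_spans_by_type(self, mir1):
        """Reported spans are 8/7/7/6 nt for the four canonical types."""
        rng = np.random.default_rng(7)
        spans = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}
        seen = set()
        for _ in range(300):
            for s in scan_utr(random_utr(rng, 400), mir1):
                if s.site_type != "full":
                    assert s.span == spans[s.site_type]
                    seen.add(s.site_type)
        assert seen == set(spans)  # every type exercised


class TestRegionCounts:
    def test_multi_site_architecture(self, mir1):
        """Sites at 637/1225/1498 with a breakpoint at 1300: 2 common, 1 extended."""
        sites = [
            SeedSite("m", "7mer-A1", s, s + 6) for s in (637, 1225, 1498)
        ]
        utr = UtrRecord("kif5b-like", "A" * 2000, breakpoint=1300)
        assert count_sites_by_region(utr, sites) == {
            "common": 2, "extended": 1, "total": 3
        }

    def test_empty_and_degenerate(self, mir1):
        utr = UtrRecord("u", "ACGT" * 100, breakpoint=400)
        assert count_sites_by_region(utr, []) == {"common": 0, "extended": 0, "total": 0}
        sites = [SeedSite("m", "6mer", 10, 15), SeedSite("m", "6mer", 390, 395)]
        assert count_sites_by_region(utr, sites)["extended"] == 0

    def test_out_of_range_site_rejected(self):
        utr = UtrRecord("u", "ACGTACGT")
        with pytest.raises(ValueError, match="outside"):
            count_sites_by_region(utr, [SeedSite("m", "6mer", 5, 10)])

    def test_partition_property(self, mir1):
        rng = np.random.default_rng(11)
        for _ in range(50):
            utr = random_utr(rng, 600)
            utr.breakpoint = int(rng.integers(1, 600))
            sites = scan_utr(utr, mir1)
            counts = count_sites_by_region(utr, sites)
            assert counts["common"] + counts["extended"] == counts["total"] == len(sites)
            for s in sites:
                assert s.region == ("extended" if s.start > utr.breakpoint else "common")


@pytest.mark.parametrize(
    "n, expected", [(0, "0"), (1, "1"), (2, "2"), (3, ">2"), (7, ">2")]
)
def test_multiplicity_class(n, expected):
    assert multiplicity_class(n) == expected


class TestVariantFilter:
    def test_rule_application(self):
        site = SeedSite("m", "7mer-A1", 637, 643)
        deletion = VariantRecord("t", 640, "AT", "A")
        snv = VariantRecord("t", 640, "A", "G")
        off_site = VariantRecord("t", 700, "GG", "G")
        kept = filter_variants_overlapping_sites([deletion, snv, off_site], [site])
        assert kept == [deletion]

    def test_against_interval_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            sites = [
                SeedSite("m", "6mer", int(s), int(s) + 5)
                for s in rng.integers(1, 500, size=5)
            ]
            variants = []
            for p in rng.integers(1, 520, size=20):
                ref = "A" * int(rng.integers(1, 4))
                alt = "A" * int(rng.integers(1, 4))
                variants.append(VariantRecord("t", int(p), ref, alt))
            expected = [
                v
                for v in variants
                if len(v.ref) != len(v.alt)
                and any(
                    set(range(v.position, v.position + len(v.ref)))
                    & set(range(s.start, s.end + 1))
                    for s in sites
                )
            ]
            assert filter_variants_overlapping_sites(variants, sites) == expected
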
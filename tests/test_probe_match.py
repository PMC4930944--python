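"""Probe site matching, competitor checks, coverage tables."""

import random

import numpy as np
import pytest

from ebprbin import probe_match as pm
from ebprbin import synthetic_data as sd

BY_NAME = {p.name: p for p in pm.DESIGNED_PROBES}
PROP207 = BY_NAME["Prop207"]
PROP470 = BY_NAME["Prop470"]


def brute_force_matches(probe, target, max_mismatch):
    site = pm.reverse_complement(probe.sequence)
    target = target.upper().replace("U", "T")
    out = []
    for start in range(len(target) - len(site) + 1):
        window = target[start : start + len(site)]
        d = sum(
            0 if p in pm.IUPAC.get(t, set()) else 1 for t, p in zip(window, site)
        )
        if d <= max_mismatch:
            out.append((start + 1, d))
    return out


class TestMatchProbe:
    def test_exact_site_found_once_with_zero_mismatches(self):
        target = "AAAA" + pm.reverse_complement(PROP207.sequence) + "TTTT"
        matches = pm.match_probe(PROP207, target, max_mismatch=0)
        assert len(matches) == 1
        assert matches[0].start == 5 and matches[0].mismatches == 0

    def test_probe_against_own_reverse_complement(self):
        matches = pm.match_probe(PROP207, pm.reverse_complement(PROP207.sequence), 0)
        assert len(matches) == 1 and matches[0].start == 1

    def test_two_substitutions_need_max_mismatch_two(self):
        """A site carrying two substitutions is invisible at stringency 1
        but reported (mismatches=2) at stringency 2 — the Prop470 vs
        R. tenuis situation."""
        site = list(pm.reverse_complement(PROP470.sequence))
        site[4] = "A" if site[4] != "A" else "G"
        site[15] = "A" if site[15] != "A" else "G"
        target = "CCCC" + "".join(site) + "GGGG"
        assert pm.match_probe(PROP470, target, max_mismatch=1) == []
        matches = pm.match_probe(PROP470, target, max_mismatch=2)
        assert len(matches) == 1 and matches[0].mismatches == 2

    def test_matches_brute_force_scan_on_random_targets(self):
        rng = random.Random(6)
        probe = pm.ProbeSpec("q", "ACGGTACCTA")
        for _ in range(100):
            target = "".join(rng.choice("ACGT") for _ in range(80))
            for k in (0, 1, 2, 3):
                got = [(m.start, m.mismatches) for m in pm.match_probe(probe, target, k)]
                assert sorted(got) == sorted(brute_force_matches(probe, target, k))

    def test_rna_targets_and_case_handled(self):
        target = pm.reverse_complement(PROP207.sequence).replace("T", "u").lower()
        assert pm.match_probe(PROP207, target, 0)

    def test_degenerate_target_base_matches_any_expansion(self):
        site = pm.reverse_complement(PROP207.sequence)
        degenerate = "N" + site[1:]
        assert pm.match_probe(PROP207, degenerate, 0)
        # R covers A/G only
        r_site = "R" + site[1:]
        expected = 0 if site[0] in "AG" else 1
        assert pm.match_probe(PROP207, r_site, expected)

    def test_non_nucleotide_characters_are_universal_mismatches(self, caplog):
        site = pm.reverse_complement(PROP207.sequence)
        target = "X" + site[1:]
        with caplog.at_level("WARNING"):
            assert not pm.match_probe(PROP207, target, 0)
            assert pm.match_probe(PROP207, target, 1)[0].mismatches == 1
        assert "non-nucleotide" in caplog.text

    def test_single_deletion_found_with_indel_flag(self):
        site = pm.reverse_complement(PROP207.sequence)
        deleted = site[:10] + site[11:]  # one base missing from the target
        target = "AAAA" + deleted + "TTTT"
        assert pm.match_probe(PROP207, target, 1) == []
        matches = pm.match_probe(PROP207, target, 1, allow_single_indel=True)
        assert matches and matches[0].indel.startswith("del@")
        assert matches[0].mismatches == 1  # the gap counts as one mismatch-equivalent

    def test_single_insertion_found_with_indel_flag(self):
        site = pm.reverse_complement(PROP207.sequence)
        inserted = site[:12] + "A" + site[12:]
        target = "GG" + inserted + "CC"
        matches = pm.match_probe(PROP207, target, 1, allow_single_indel=True)
        assert matches and matches[0].indel.startswith("ins@")

    def test_probe_longer_than_target_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            pm.match_probe(PROP207, "ACGT", 0)


class TestCompetitors:
    def test_all_designed_competitor_pairs_have_distance_one(self):
        expected_positions = {
            ("Prop207", "Prop207c"): 12,
            ("Prop470", "Prop470c1"): 3,
            ("Prop470", "Prop470c2"): 5,
            ("Prop470", "Prop470c3"): 23,
        }
        for probe in pm.DESIGNED_PROBES:
            for comp in probe.competitors:
                dist, positions = pm.competitor_check(probe, BY_NAME[comp])
                assert dist == 1
                assert positions == [expected_positions[(probe.name, comp)]]

    def test_probe_against_itself_is_zero(self):
        assert pm.competitor_check(PROP207, PROP207) == (0, [])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pm.competitor_check(PROP207, PROP470)


class TestProbeSpec:
    def test_declared_spans_match_probe_lengths(self):
        assert len(PROP207) == 24 and pm.validate_span(PROP207)
        assert len(PROP470) == 25 and pm.validate_span(PROP470)

    def test_inconsistent_span_rejected(self):
        with pytest.raises(ValueError, match="24-mer"):
            pm.ProbeSpec("bad", PROP207.sequence, 207, 231)

    def test_degenerate_probe_rejected(self):
        with pytest.raises(ValueError, match="non-degenerate"):
            pm.ProbeSpec("bad", "ACGTN")

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "probes.tsv"
        pm.write_probe_tsv(pm.DESIGNED_PROBES, path)
        back = pm.read_probe_tsv(path)
        assert [p.name for p in back] == [p.name for p in pm.DESIGNED_PROBES]
        assert back[0].sequence == PROP207.sequence
        assert back[0].ecoli_start == 207 and back[0].ecoli_end == 230


class TestEcoliPositions:
    def reference(self):
        rng = np.random.default_rng(31)
        bases = np.array(list("ACGT"))
        ref = list("".join(rng.choice(bases, size=1542)))
        site = pm.reverse_complement(PROP207.sequence)
        ref[206 : 206 + len(site)] = site  # plant at declared position 207
        return "".join(ref)

    def test_unique_site_located_at_declared_span(self):
        ref = self.reference()
        assert pm.map_ecoli_positions(PROP207, ref) == (207, 230)

    def test_missing_site_rejected(self):
        rng = np.random.default_rng(32)
        ref = "".join(rng.choice(np.array(list("ACGT")), size=500))
        with pytest.raises(ValueError, match="no site"):
            pm.map_ecoli_positions(PROP207, ref, max_mismatch=0)

    def test_ambiguous_site_rejected(self):
        site = pm.reverse_complement(PROP207.sequence)
        ref = "AAAA" + site + "CCCC" + site + "GGGG"
        with pytest.raises(ValueError, match="ambiguous"):
            pm.map_ecoli_positions(PROP207, ref)


class TestCoverageTable:
    @pytest.fixture(scope="class")
    def planted_set(self):
        return sd.generate_16s_set(
            [PROP207, PROP470],
            {"Propionivibrio": 10, "Dechloromonas": 6, "Unlisted": 4},
            {
                "Propionivibrio": 0,
                "Dechloromonas": {"Prop207": 2, "Prop470": 2},
                "Unlisted": {"Prop207": 0, "Prop470": 2},
            },
            seed=41,
        )

    def test_table_reflects_the_planted_plan_exactly(self, planted_set):
        table = pm.coverage_table(
            [PROP207, PROP470], planted_set.records, max_mismatch=0,
            taxa=["Propionivibrio", "Dechloromonas"],
        )
        row207 = table[table.probe == "Prop207"].iloc[0]
        assert row207["Propionivibrio"] == 100.0
        assert row207["Dechloromonas"] == 0.0
        assert row207["total_other_hits"] == 4  # the unlisted perfect sites

    def test_percentages_monotone_in_max_mismatch(self, planted_set):
        taxa = ["Propionivibrio", "Dechloromonas"]
        t0 = pm.coverage_table([PROP207, PROP470], planted_set.records, 0, taxa)
        t2 = pm.coverage_table([PROP207, PROP470], planted_set.records, 2, taxa)
        for tax in taxa:
            assert (t2[tax] >= t0[tax]).all()
        assert t2[taxa].to_numpy().min() >= 0.0
        assert t2[taxa].to_numpy().max() <= 100.0

    def test_two_mismatch_plan_invisible_at_stringency_zero(self, planted_set):
        table = pm.coverage_table(
            [PROP207], planted_set.records, 0, ["Dechloromonas"]
        )
        assert table["Dechloromonas"].iloc[0] == 0.0
        table2 = pm.coverage_table(
            [PROP207], planted_set.records, 2, ["Dechloromonas"]
        )
        assert table2["Dechloromonas"].iloc[0] == 100.0

    def test_empty_taxon_reported_as_not_applicable(self, planted_set):
        table = pm.coverage_table([PROP207], planted_set.records, 0, ["Ghost"])
        assert np.isnan(table["Ghost"].iloc[0])

    def test_probe_matching_nothing_gives_zero_row(self):
        seqs = [("s1", "TaxA", "ACGT" * 100)]
        probe = pm.ProbeSpec("nomatch", "GGGGGGGGGGGG")
        table = pm.coverage_table([probe], seqs, 0)
        assert table["TaxA"].iloc[0] == 0.0
        assert table["total_other_hits"].iloc[0] == 0
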
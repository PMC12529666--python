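"""RBNS read processing: demux, trim, count, enrich, fidelity."""

import numpy as np
import pytest
from scipy import stats as sstats

from agodyn import rbns, simulate
from agodyn.rbns import ReadCountTable
from agodyn.seeds import LibraryMember, SiteClass, classify_library


class TestDemultiplex:
    def test_exact_assignment(self):
        out, un = rbns.demultiplex(["AAAAAAAAGGG"], {"AAAAAAAA": "s1"})
        assert out["s1"] == ["GGG"] and un == []

    def test_ambiguous_goes_unassigned(self):
        # read barcode one edit from both barcodes at max_mismatch=1
        out, un = rbns.demultiplex(
            ["AAAAAAACGGG"], {"AAAAAAAA": "s1", "AAAAAACC": "s2"}, max_mismatch=1
        )
        assert un == ["AAAAAAACGGG"]
        assert not out["s1"] and not out["s2"]

    def test_conservation_on_generated_pool(self):
        rng = np.random.default_rng(0)
        bcs = {"AAAAAAAA": "s1", "CCCCCCCC": "s2"}
        reads = [
            rng.choice(list(bcs) + ["GGGGGGGG"]) + "ACGU" for _ in range(100)
        ]
        out, un = rbns.demultiplex(reads, bcs)
        assert sum(map(len, out.values())) + len(un) == 100

    def test_duplicate_barcode_rejected(self):
        with pytest.raises(ValueError):
            rbns.demultiplex([], {"AAAA": "s1", "AAAC": "s2", "AAAAC": "s3"})


class TestTrimAndFilter:
    def test_adapter_removed_at_first_occurrence(self):
        kept, tally = rbns.trim_and_filter(["ACGUACGUXAD"], "XAD", 8)
        assert kept == ["ACGUACGU"] and tally == {"no-adapter": 0, "wrong-length": 0}

    def test_short_read_tallied(self):
        kept, tally = rbns.trim_and_filter(["ACGXAD"], "XAD", 8)
        assert kept == [] and tally["wrong-length"] == 1

    def test_planted_rejects_accounted(self):
        good = ["ACGUACGU" + "XAD"] * 950
        bad = ["ACG" + "XAD"] * 50
        kept, tally = rbns.trim_and_filter(good + bad, "XAD", 8)
        assert len(kept) == 950 and tally["wrong-length"] == 50


class TestCountMembers:
    def test_basic_assignment(self):
        lib = [LibraryMember("ACACUCCA"), LibraryMember("GCACUCCG")]
        reads = ["ACACUCCA"] * 3 + ["UUUUUUUU"]
        table = rbns.count_members(reads, lib)
        assert table.counts == {"ACACUCCA": 3, "GCACUCCG": 0}
        assert table.unmatched == 1 and table.total == 4

    def test_empty_input(self):
        table = rbns.count_members([], [LibraryMember("ACACUCCA")])
        assert table.total == 0

    def test_multinomial_counts_within_envelope(self):
        lib = [LibraryMember("AAAAAAAA"), LibraryMember("CCCCCCCC")]
        rng = np.random.default_rng(1)
        n, p = 2000, 0.7
        reads = ["AAAAAAAA" if rng.random() < p else "CCCCCCCC" for _ in range(n)]
        table = rbns.count_members(reads, lib)
        lo, hi = sstats.binom.interval(0.99, n, p)
        assert lo <= table.counts["AAAAAAAA"] <= hi


class TestFractionsAndEnrichment:
    def test_fractions(self):
        t = ReadCountTable("s", {"X": 90, "Y": 10})
        assert rbns.read_fractions(t) == {"X": 0.9, "Y": 0.1}

    def test_zero_matched_raises(self):
        with pytest.raises(ValueError):
            rbns.read_fractions(ReadCountTable("s", {"X": 0}))

    def test_hand_arithmetic(self):
        df = rbns.fold_enrichment({"X": 0.9, "Y": 0.1}, {"X": 0.5, "Y": 0.5})
        fe = dict(zip(df.sequence, df.fold_enrichment))
        assert fe["X"] == pytest.approx(1.8) and fe["Y"] == pytest.approx(0.2)

    def test_identity(self):
        f = {"X": 0.25, "Y": 0.75}
        df = rbns.fold_enrichment(f, f)
        assert np.allclose(df.fold_enrichment, 1.0)

    def test_zero_input_flagged_not_dropped(self):
        df = rbns.fold_enrichment({"X": 1.0, "Y": 0.0}, {"X": 1.0, "Y": 0.0})
        row = df[df.sequence == "Y"].iloc[0]
        assert row.undefined and np.isnan(row.fold_enrichment)

    def test_scale_invariance(self):
        t1 = ReadCountTable("s", {"X": 30, "Y": 70})
        t2 = ReadCountTable("s", {"X": 300, "Y": 700})
        inp = {"X": 0.5, "Y": 0.5}
        e1 = rbns.fold_enrichment(rbns.read_fractions(t1), inp).fold_enrichment
        e2 = rbns.fold_enrichment(rbns.read_fractions(t2), inp).fold_enrichment
        assert np.allclose(e1, e2)


class TestFidelitySummary:
    def test_arithmetic(self, guide):
        lib = [LibraryMember("ACACUCCA"), LibraryMember("UUUUUUUU")]
        classes = classify_library(lib, guide)
        t = ReadCountTable("s", {"ACACUCCA": 70, "UUUUUUUU": 30})
        s = rbns.fidelity_summary(t, classes)
        assert s["seed_match"] == pytest.approx(0.70)
        assert s["8mer"] == pytest.approx(0.70)

    def test_all_none_reads(self, guide):
        lib = [LibraryMember("UUUUUUUU")]
        t = ReadCountTable("s", {"UUUUUUUU": 10})
        s = rbns.fidelity_summary(t, classify_library(lib, guide))
        assert s["seed_match"] == 0.0

    def test_class_fractions_sum_to_one(self, library, library_classes):
        rng = np.random.default_rng(2)
        counts = {m.variable: int(rng.integers(0, 50)) for m in library}
        s = rbns.fidelity_summary(ReadCountTable("s", counts), library_classes)
        total = sum(s[sc.label] for sc in SiteClass)
        assert total == pytest.approx(1.0)


def _pipeline_fidelity(scenario, depth, seed, library_config, members, classes):
    """Full demux -> trim -> count -> summarize chain on generated reads."""
    reads, barcodes, _ = simulate.gen_rbns(scenario, depth=depth, seed=seed)
    pooled = [r for sample in reads.values() for r in sample]
    by_sample, unassigned = rbns.demultiplex(pooled, barcodes)
    assert sum(map(len, by_sample.values())) + len(unassigned) == len(pooled)
    expected = len(library_config.flank5) + 8 + len(library_config.flank3)
    out = {}
    for sample, rs in by_sample.items():
        kept, _ = rbns.trim_and_filter(rs, library_config.adapter, expected)
        table = rbns.count_members(kept, members)
        assert table.total == len(kept)
        out[sample] = rbns.fidelity_summary(table, classes)["seed_match"]
    return out


class TestSimulationProperties:
    def test_enrichment_monotone_in_class_weight(self, library_config, library, library_classes):
        reads, _, _ = simulate.gen_rbns(simulate.WT_LIKE, depth=30_000, timepoints_s=(3600.0,), seed=11)
        inp = rbns.count_members(
            [r[8:] for r in reads["input"]], library
        )  # strip barcode; flanks/adapter stay in-read
        kept_i, _ = rbns.trim_and_filter(
            [r[8:] for r in reads["input"]], library_config.adapter, 24
        )
        kept_b, _ = rbns.trim_and_filter(
            [r[8:] for r in reads["wt_3600s"]], library_config.adapter, 24
        )
        fi = rbns.read_fractions(rbns.count_members(kept_i, library), pseudocount=1)
        fb = rbns.read_fractions(rbns.count_members(kept_b, library), pseudocount=1)
        df = rbns.fold_enrichment(fb, fi, library_classes)
        means = df.groupby("site_class")["fold_enrichment"].mean()
        assert (
            means["8mer"] > means["7mer-m8"] > means["7mer-A1"] > means["6mer"] > means["none"]
        )

    def test_fidelity_ordering_wt_vs_mutant(self, library_config, library, library_classes):
        wt = _pipeline_fidelity(
            simulate.WT_LIKE, 20_000, 13, library_config, library, library_classes
        )
        mut = _pipeline_fidelity(
            simulate.MUTANT_LIKE, 20_000, 13, library_config, library, library_classes
        )
        assert wt["wt_30s"] > mut["mutant_30s"]
        assert mut["mutant_3600s"] > mut["mutant_30s"]
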
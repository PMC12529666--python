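"""isomiR classification, arm ratios, exclusivity, BH, DE thresholds, delta-Ct."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from agodyn import simulate
from agodyn.isomirs import (
    CanonicalMiRNA,
    arm_ratio,
    assign_and_classify,
    bh_adjust,
    categorize,
    category_summary,
    de_threshold_filter,
    exclusivity,
    mirap_delta_ct,
)

CANON = [
    CanonicalMiRNA("mir-a-5p", "UGAGGUAGUAGGUUGUAUAGUU", precursor="mir-a", arm="5p"),
    CanonicalMiRNA("mir-b-3p", "CUAUACAAUCUACUGUCUUUCC", precursor="mir-b", arm="3p"),
]


class TestAssignAndClassify:
    def test_canonical_identity(self):
        rec = assign_and_classify(CANON[0].sequence, CANON)
        assert rec.category == "canonical"
        assert (rec.offset5, rec.offset3, rec.mismatches) == (0, 0, 0)

    def test_3p_trimmed(self):
        rec = assign_and_classify(CANON[0].sequence[:-1], CANON)
        assert rec.category == "3p-trimmed" and rec.offset3 == -1

    def test_3p_trimmed_with_exchange(self):
        seq = list(CANON[0].sequence[:-1])
        seq[10] = "C" if seq[10] != "C" else "G"
        rec = assign_and_classify("".join(seq), CANON)
        assert rec.category == "3p-trimmed+exchange"
        assert rec.mismatches == 1 and rec.offset3 == -1

    def test_unassignable_read(self):
        assert assign_and_classify("ACGU" * 6, CANON, max_mismatch=2) is None

    def test_deterministic_and_idempotent(self):
        seq = CANON[0].sequence[:-2] + "GG"
        first = assign_and_classify(seq, CANON)
        assert first == assign_and_classify(seq, CANON)

    @pytest.mark.parametrize(
        "off5,off3,mm,expected",
        [
            (0, 0, 0, "canonical"),
            (0, 0, 2, "nucleotide-exchange"),
            (-1, 0, 0, "5p-variant"),
            (2, 0, 0, "5p-variant"),
            (0, -2, 0, "3p-trimmed"),
            (0, 3, 0, "3p-extended"),
            (0, -1, 1, "3p-trimmed+exchange"),
            (0, 2, 1, "3p-extended+exchange"),
            (1, -1, 0, "mixed"),
            (-1, 0, 1, "mixed"),
        ],
    )
    def test_category_grammar(self, off5, off3, mm, expected):
        assert categorize(off5, off3, mm) == expected

    def test_planted_variants_roundtrip(self):
        _, canon, truth = simulate.gen_smallrna(seed=9)
        for name, meta in truth["species_meta"].items():
            if meta["kind"] != "exclusive-isomir":
                continue
            rec = assign_and_classify(meta["sequence"], canon)
            assert rec is not None
            assert rec.category == meta["category"]


class TestExclusivity:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["m_r1", "m_r2", "w_r1", "w_r2"]).rename_axis("species")

    COND = {"m_r1": "L192P", "m_r2": "L192P", "w_r1": "WT", "w_r2": "WT"}

    def test_definition(self):
        counts = pd.DataFrame({"m_r1": [5], "m_r2": [7], "w_r1": [0], "w_r2": [0]}, index=["A"])
        ex = exclusivity(counts, self.COND)
        assert ex["L192P"] == ["A"] and ex["WT"] == []

    def test_all_replicate_rule(self):
        counts = pd.DataFrame({"m_r1": [5], "m_r2": [0], "w_r1": [0], "w_r2": [0]}, index=["B"])
        ex = exclusivity(counts, self.COND)
        assert ex["L192P"] == []

    def test_planted_exclusives_recovered_exactly(self):
        counts, _, truth = simulate.gen_smallrna(n_exclusive=10, seed=3)
        ex = exclusivity(counts, truth["condition_of"])
        assert sorted(ex["mutant"]) == sorted(truth["exclusive_to"]["mutant"])
        assert ex["wt"] == []


class TestCategorySummary:
    def test_fraction_arithmetic(self):
        records = {f"s{i}": ("3p-trimmed" if i < 10 else "canonical") for i in range(20)}
        counts = pd.DataFrame({"r1": np.arange(20, 0, -1)}, index=[f"s{i}" for i in range(20)])
        fracs, truncated = category_summary(records, counts, top_n=20)
        assert fracs["3p-trimmed"] == pytest.approx(0.5)
        assert not truncated

    def test_all_canonical(self):
        records = {"a": "canonical", "b": "canonical"}
        counts = pd.DataFrame({"r1": [5, 3]}, index=["a", "b"])
        fracs, truncated = category_summary(records, counts, top_n=2)
        assert fracs == {"canonical": 1.0}

    def test_truncation_flag(self):
        records = {"a": "canonical"}
        counts = pd.DataFrame({"r1": [5]}, index=["a"])
        _, truncated = category_summary(records, counts, top_n=20)
        assert truncated

    def test_planted_proportions_recovered(self):
        counts, _, truth = simulate.gen_smallrna(n_exclusive=20, seed=5)
        meta = truth["species_meta"]
        excl = truth["exclusive_to"]["mutant"]
        records = {s: meta[s]["category"] for s in excl}
        fracs, _ = category_summary(records, counts.loc[excl], top_n=20)
        expected = pd.Series([meta[s]["category"] for s in excl]).value_counts() / len(excl)
        for cat, frac in fracs.items():
            assert frac == pytest.approx(expected[cat])


class TestArmRatio:
    def _counts(self, c3, c5, samples):
        return pd.DataFrame([c3, c5], index=["p-3p", "p-5p"], columns=samples)

    ARM_OF = {"p-3p": ("p", "3p"), "p-5p": ("p", "5p")}

    def test_equal_arms_zero_ratio(self):
        samples = ["a1", "a2", "b1", "b2"]
        res = arm_ratio(
            self._counts([50, 50, 50, 50], [50, 50, 50, 50], samples),
            self.ARM_OF,
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        assert res.loc["p", "mean_log2_ratio_A"] == pytest.approx(0.0)

    def test_pseudocount_arithmetic(self):
        samples = ["a1", "a2", "b1", "b2"]
        res = arm_ratio(
            self._counts([80, 80, 80, 80], [20, 20, 20, 20], samples),
            self.ARM_OF,
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            pseudocount=1.0,
        )
        assert res.loc["p", "mean_log2_ratio_A"] == pytest.approx(np.log2(81 / 21))

    def test_single_arm_skipped(self):
        counts = pd.DataFrame([[5, 5]], index=["q-3p"], columns=["a1", "b1"])
        res = arm_ratio(counts, {"q-3p": ("q", "3p")}, {"a1": "A", "b1": "B"})
        assert bool(res.loc["q", "skipped"])

    def test_planted_flip_detected(self):
        counts, canon, truth = simulate.gen_smallrna(seed=8, replicates=4)
        arm_of = {c.name: (c.precursor, c.arm) for c in canon}
        canonical_rows = counts.loc[[c.name for c in canon]]
        res = arm_ratio(canonical_rows, arm_of, truth["condition_of"])
        hits = set(res[res.p_value <= 0.05].index)
        assert set(truth["flipped_precursors"]) <= hits


class TestBHAdjust:
    def test_hand_computed_example(self):
        # p*m/i then monotone cummin from the largest rank
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_matches_brute_force_definition(self, pvals):
        adj = bh_adjust(pvals)
        m = len(pvals)
        order = np.argsort(np.asarray(pvals), kind="stable")
        # brute force: adj for rank i = min over j >= i of p_(j) * m / j
        brute = np.empty(m)
        sorted_p = np.asarray(pvals)[order]
        for i in range(m):
            brute[order[i]] = min(
                min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
            )
        assert np.allclose(adj, brute)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_matches_statsmodels(self, pvals):
        assert np.allclose(bh_adjust(pvals), multipletests(pvals, method="fdr_bh")[1])


class TestDEThreshold:
    TOY = pd.DataFrame(
        {
            "feature": ["a", "b", "c", "d", "e", "f"],
            "log2fc": [1.5, -2.0, 0.5, 1.2, -1.1, 3.0],
            "padj": [0.01, 0.001, 0.01, 0.06, 0.04, 0.2],
        }
    )

    def test_smallrna_rule(self):
        sets = de_threshold_filter(self.TOY, alpha=0.05, min_abs_lfc=1.0)
        assert sets["up"] == {"a"} and sets["down"] == {"b", "e"}

    def test_mrna_rule_no_lfc_cut(self):
        sets = de_threshold_filter(self.TOY, alpha=0.05, min_abs_lfc=0.0)
        assert sets["up"] == {"a", "c"} and sets["down"] == {"b", "e"}

    def test_boundary_exclusions(self):
        rec = pd.DataFrame({"feature": ["x"], "log2fc": [1.5], "padj": [0.06]})
        sets = de_threshold_filter(rec, alpha=0.05, min_abs_lfc=1.0)
        assert not sets["up"] and not sets["down"]


class TestDeltaCt:
    def test_scalar(self):
        assert mirap_delta_ct(20.0, 25.0) == pytest.approx(-5.0)
        assert mirap_delta_ct(22.0, 22.0) == 0.0

    def test_vector(self):
        out = mirap_delta_ct([20.0, 30.0], [25.0, 28.0])
        assert np.allclose(out, [-5.0, 2.0])

    def test_missing_ct_rejected(self):
        with pytest.raises(ValueError):
            mirap_delta_ct(np.nan, 25.0)
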
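"""Small-RNA profiling: isomiR classification, arm ratios, exclusivity, DE.

isomiRs are sequence variants of a canonical miRNA: trimmed or extended at
either end, carrying internal substitutions (nucleotide exchange), or
combinations.  A read is assigned to the canonical miRNA and end offsets
that minimize (mismatches, total end displacement) lexicographically; its
category is then a deterministic function of the signed 5'/3' offsets
(+ = extension beyond the canonical end, - = trimming) and the mismatch
count inside the aligned overlap.

Also here: 3p/5p arm-ratio analysis with a two-group Welch test on log2
ratios, condition-exclusivity calls (present in every replicate of one
condition, absent from all others), Benjamini-Hochberg adjustment, the
differential-expression threshold rule, and miRAP delta-Ct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from agodyn.seeds import _normalize_rna

__all__ = [
    "CanonicalMiRNA",
    "IsomiRRecord",
    "CATEGORIES",
    "assign_and_classify",
    "categorize",
    "exclusivity",
    "category_summary",
    "arm_ratio",
    "bh_adjust",
    "de_threshold_filter",
    "mirap_delta_ct",
]

CATEGORIES = (
    "canonical",
    "5p-variant",
    "3p-trimmed",
    "3p-extended",
    "nucleotide-exchange",
    "3p-trimmed+exchange",
    "3p-extended+exchange",
    "mixed",
)


@dataclass(frozen=True)
class CanonicalMiRNA:
    """A reference mature miRNA (one arm of a precursor)."""

    name: str
    sequence: str
    precursor: str = ""
    arm: str = ""  # "5p" or "3p"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize_rna(self.sequence, context=self.name))
        if self.arm and self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be '5p' or '3p', got {self.arm!r}")


@dataclass(frozen=True)
class IsomiRRecord:
    read: str
    canonical: str
    offset5: int  # + = 5' extension, - = 5' trimming
    offset3: int  # + = 3' extension, - = 3' trimming
    mismatches: int
    category: str


def categorize(offset5: int, offset3: int, mismatches: int) -> str:
    """Map (5' offset, 3' offset, mismatch count) to an isomiR category.

    The closed category set follows the offsets/mismatch grammar: pure 5'
    changes, pure 3' trimming/extension (with or without exchange), pure
    exchange, and everything combining 5' with 3'/exchange as ``mixed``.
    """
    if offset5 == 0 and offset3 == 0:
        return "canonical" if mismatches == 0 else "nucleotide-exchange"
    if offset5 == 0:
        base = "3p-trimmed" if offset3 < 0 else "3p-extended"
        return base + ("+exchange" if mismatches else "")
    if offset3 == 0 and mismatches == 0:
        return "5p-variant"
    return "mixed"


def assign_and_classify(
    read: str,
    canonicals: list[CanonicalMiRNA],
    max_shift: int = 3,
    max_mismatch: int = 2,
) -> IsomiRRecord | None:
    """Assign a read to its best canonical miRNA and classify the variant.

    For each canonical and each admissible 5' offset the implied 3' offset
    is fixed by the length difference; the aligned overlap is compared
    base-by-base.  The best assignment minimizes
    (mismatches, |offset5| + |offset3|) lexicographically, with ties broken
    by canonical name order.  Returns None if no alignment satisfies the
    shift and mismatch limits.
    """
    if max_shift < 0 or max_mismatch < 0:
        raise ValueError("limits must be >= 0")
    r = _normalize_rna(read, context="read")
    best: tuple[int, int, str, IsomiRRecord] | None = None
    for canon in sorted(canonicals, key=lambda c: c.name):
        c = canon.sequence
        dlen = len(r) - len(c)
        for off5 in range(-max_shift, max_shift + 1):
            off3 = dlen - off5
            if abs(off3) > max_shift:
                continue
            # read[i] aligns to canonical position i - off5
            start = max(0, off5)
            stop = min(len(r), len(c) + off5)
            if stop - start <= 0:
                continue
            mm = sum(r[i] != c[i - off5] for i in range(start, stop))
            if mm > max_mismatch:
                continue
            key = (mm, abs(off5) + abs(off3), canon.name)
            if best is None or key < (best[0], best[1], best[2]):
                rec = IsomiRRecord(r, canon.name, off5, off3, mm, categorize(off5, off3, mm))
                best = (mm, abs(off5) + abs(off3), canon.name, rec)
    return None if best is None else best[3]


def exclusivity(
    counts: pd.DataFrame,
    condition_of: dict[str, str],
    min_count: int = 1,
) -> dict[str, list[str]]:
    """Condition-exclusive species calls.

    ``counts`` is indexed by species with one column per replicate sample;
    ``condition_of`` maps sample -> condition.  A species is exclusive to
    condition c iff its count is >= ``min_count`` in every replicate of c
    and exactly 0 in every replicate of every other condition.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    missing = set(counts.columns) - set(condition_of)
    if missing:
        raise ValueError(f"samples without a condition label: {sorted(missing)}")
    conditions = sorted(set(condition_of[s] for s in counts.columns))
    cols = {c: [s for s in counts.columns if condition_of[s] == c] for c in conditions}
    out: dict[str, list[str]] = {c: [] for c in conditions}
    for c in conditions:
        own = counts[cols[c]]
        others = counts[[s for cc in conditions if cc != c for s in cols[cc]]]
        mask = (own >= min_count).all(axis=1) & (others == 0).all(axis=1)
        out[c] = sorted(counts.index[mask])
    return out


def category_summary(
    records: dict[str, str],
    counts: pd.DataFrame,
    top_n: int = 20,
) -> tuple[dict[str, float], bool]:
    """Category fractions among the ``top_n`` species by mean count.

    ``records`` maps species -> category; ``counts`` is species x replicate.
    Returns (fractions summing to 1 over represented categories, truncated
    flag set when fewer than ``top_n`` species were available).
    """
    avail = counts.loc[[s for s in counts.index if s in records]]
    truncated = len(avail) < top_n
    top = avail.mean(axis=1).sort_values(ascending=False, kind="stable").head(top_n)
    if len(top) == 0:
        raise ValueError("no classified species to summarize")
    cats = pd.Series([records[s] for s in top.index])
    fracs = (cats.value_counts() / len(cats)).to_dict()
    return fracs, truncated


def arm_ratio(
    counts: pd.DataFrame,
    arm_of: dict[str, tuple[str, str]],
    groups: dict[str, str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-precursor log2(3p/5p) arm ratios and a two-group Welch test.

    ``counts`` is indexed by mature-miRNA name with one column per sample;
    ``arm_of`` maps mature name -> (precursor, arm); ``groups`` maps
    sample -> group (exactly two groups).  For each precursor with both
    arms annotated, the per-sample ratio log2((c3p + pc)/(c5p + pc)) is
    compared between groups with a two-sided Welch t-test; the raw p-value
    is reported (thresholding at p <= 0.05 is the caller's).  Precursors
    with a single annotated arm are skipped and listed with NaN statistics.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    group_names = sorted(set(groups[s] for s in counts.columns))
    if len(group_names) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = group_names
    precursors: dict[str, dict[str, str]] = {}
    for mature, (prec, arm) in arm_of.items():
        precursors.setdefault(prec, {})[arm] = mature
    rows = []
    for prec in sorted(precursors):
        arms = precursors[prec]
        if "3p" not in arms or "5p" not in arms or arms["3p"] not in counts.index or arms["5p"] not in counts.index:
            rows.append({"precursor": prec, "skipped": True, "p_value": np.nan,
                         f"mean_log2_ratio_{g1}": np.nan, f"mean_log2_ratio_{g2}": np.nan})
            continue
        c3 = counts.loc[arms["3p"]].astype(float)
        c5 = counts.loc[arms["5p"]].astype(float)
        ratios = np.log2((c3 + pseudocount) / (c5 + pseudocount))
        r1 = ratios[[s for s in counts.columns if groups[s] == g1]].to_numpy()
        r2 = ratios[[s for s in counts.columns if groups[s] == g2]].to_numpy()
        stat, p = stats.ttest_ind(r1, r2, equal_var=False)
        rows.append(
            {
                "precursor": prec,
                "skipped": False,
                f"mean_log2_ratio_{g1}": float(np.mean(r1)),
                f"mean_log2_ratio_{g2}": float(np.mean(r2)),
                "t_stat": float(stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("precursor")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order-preserving).

    adj_i = min over j >= rank(i) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def de_threshold_filter(
    records: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_lfc: float = 0.0,
) -> dict[str, set[str]]:
    """Significance-threshold rule for differential-expression tables.

    ``records`` needs columns ``feature``, ``log2fc``, ``padj``.  A feature
    is selected iff padj < alpha and |log2fc| > min_abs_lfc; direction by
    the sign of log2fc.  ``min_abs_lfc=1`` is the small-RNA rule, 0 the
    mRNA rule.
    """
    sig = records[(records["padj"] < alpha) & (records["log2fc"].abs() > min_abs_lfc)]
    return {
        "up": set(sig.loc[sig["log2fc"] > 0, "feature"]),
        "down": set(sig.loc[sig["log2fc"] < 0, "feature"]),
    }


def mirap_delta_ct(ct_ip, ct_in):
    """miRAP relative enrichment: delta-Ct = Ct(IP) - Ct(IN), element-wise.

    Lower (more negative) values mean stronger enrichment in the
    immunoprecipitate.
    """
    ip = np.asarray(ct_ip, dtype=float)
    inp = np.asarray(ct_in, dtype=float)
    if not (np.all(np.isfinite(ip)) and np.all(np.isfinite(inp))):
        raise ValueError("Ct values must be finite")
    out = ip - inp
    return float(out) if out.ndim == 0 else out
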
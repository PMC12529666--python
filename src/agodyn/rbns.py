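"""RNA Bind-n-Seq read processing: demultiplex, trim, count, enrich.

The RBNS library is fully enumerable (one 8-nt variable region between
constant flanks), so reads are assigned to members by exact match of the
variable region -- no error-tolerant mapping.  Enrichment of a member is its
read fraction in a bound sample divided by its read fraction in the input
library; fractions are computed over member-matched reads (unmatched reads
are excluded from denominators, which the output metadata records).

A fidelity summary collapses member counts onto seed-site classes: the
fraction of bound reads carrying any canonical seed match is the targeting-
fidelity statistic compared between wild-type-like and mutant-like samples.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from agodyn.seeds import LibraryMember, SiteClass

__all__ = [
    "ReadCountTable",
    "demultiplex",
    "trim_and_filter",
    "count_members",
    "read_fractions",
    "fold_enrichment",
    "fidelity_summary",
]


@dataclass
class ReadCountTable:
    """Per-member read counts for one sample.

    Invariant: sum of member counts + unmatched = total.
    """

    sample: str
    counts: dict[str, int]
    unmatched: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unmatched

    @property
    def matched(self) -> int:
        return sum(self.counts.values())


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[str],
    barcode_map: Mapping[str, str],
    max_mismatch: int = 0,
) -> tuple[dict[str, list[str]], list[str]]:
    """Assign reads to samples by their leading barcode.

    Each read must start with a barcode (all barcodes the same length); the
    barcode is stripped from assigned reads.  A read within ``max_mismatch``
    of two or more barcodes, or of none, goes to the unassigned pool intact.
    Returns ``({sample: reads}, unassigned)``; counts are conserved.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    barcodes = list(barcode_map)
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in map")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have the same length")
    (blen,) = lengths
    samples = set(barcode_map.values())
    out: dict[str, list[str]] = {s: [] for s in samples}
    unassigned: list[str] = []
    for read in reads:
        prefix = read[:blen]
        hits = [b for b in barcodes if _hamming(prefix, b) <= max_mismatch] if len(prefix) == blen else []
        if len(hits) == 1:
            out[barcode_map[hits[0]]].append(read[blen:])
        else:
            unassigned.append(read)
    return out, unassigned


def trim_and_filter(
    reads: Iterable[str],
    adapter: str,
    expected_length: int,
) -> tuple[list[str], dict[str, int]]:
    """Trim the adapter and keep reads of exactly the expected length.

    The adapter is removed at its first literal occurrence; reads without an
    adapter, or whose trimmed length differs from ``expected_length``, are
    rejected and tallied as ``no-adapter`` / ``wrong-length``.
    """
    if expected_length <= 0:
        raise ValueError("expected_length must be positive")
    retained: list[str] = []
    tally = {"no-adapter": 0, "wrong-length": 0}
    for read in reads:
        idx = read.find(adapter) if adapter else -1
        if idx < 0:
            # an adapterless read can still be exact-length (fully trimmed upstream)
            if len(read) == expected_length:
                retained.append(read)
            else:
                tally["no-adapter"] += 1
            continue
        trimmed = read[:idx]
        if len(trimmed) == expected_length:
            retained.append(trimmed)
        else:
            tally["wrong-length"] += 1
    return retained, tally


def count_members(
    reads: Iterable[str],
    library: Sequence[LibraryMember],
    sample: str = "sample",
) -> ReadCountTable:
    """Exact-match assignment of each read's variable region to a member.

    Reads must be length-normalized to the full construct; the variable
    region is excised at its fixed position between the flanks.
    """
    if not library:
        raise ValueError("empty library")
    f5 = len(library[0].flank5)
    vlen = len(library[0].variable)
    members = {m.variable for m in library}
    counts: Counter[str] = Counter()
    unmatched = 0
    expected = f5 + vlen + len(library[0].flank3)
    for read in reads:
        var = read[f5 : f5 + vlen]
        if len(read) == expected and var in members:
            counts[var] += 1
        else:
            unmatched += 1
    full = {m.variable: counts.get(m.variable, 0) for m in library}
    return ReadCountTable(sample, full, unmatched)


def read_fractions(table: ReadCountTable, pseudocount: float = 0.0) -> dict[str, float]:
    """Per-member read fractions over member-matched reads (sum to 1)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    total = table.matched + pseudocount * len(table.counts)
    if total <= 0:
        raise ValueError(f"sample {table.sample!r} has no member-matched reads")
    return {m: (c + pseudocount) / total for m, c in table.counts.items()}


def fold_enrichment(
    sample_fractions: Mapping[str, float],
    input_fractions: Mapping[str, float],
    classes: Mapping[str, SiteClass] | None = None,
) -> pd.DataFrame:
    """Fold enrichment = sample fraction / input fraction, per member.

    Members absent from the input (zero fraction) get NaN enrichment and an
    ``undefined`` flag instead of being dropped.  Returns a DataFrame with
    columns sequence, input_fraction, sample_fraction, fold_enrichment,
    undefined and, when ``classes`` is given, site_class.
    """
    if set(sample_fractions) != set(input_fractions):
        raise ValueError("sample and input must cover the same member universe")
    rows = []
    for m in sorted(sample_fractions):
        fi = input_fractions[m]
        fs = sample_fractions[m]
        undefined = fi <= 0
        rows.append(
            {
                "sequence": m,
                "input_fraction": fi,
                "sample_fraction": fs,
                "fold_enrichment": np.nan if undefined else fs / fi,
                "undefined": undefined,
            }
        )
    df = pd.DataFrame(rows)
    if classes is not None:
        df["site_class"] = [classes[m].label for m in df["sequence"]]
    return df


def fidelity_summary(
    table: ReadCountTable,
    classes: Mapping[str, SiteClass],
) -> dict[str, float]:
    """Read-fraction of each seed-site class, plus the seed-match total.

    Fractions are over member-matched reads and sum to 1 across the five
    classes; ``seed_match`` = 1 - no-seed fraction.
    """
    missing = set(table.counts) - set(classes)
    if missing:
        raise ValueError(f"{len(missing)} counted members lack a site class")
    total = table.matched
    if total == 0:
        raise ValueError(f"sample {table.sample!r} has no member-matched reads")
    by_class = Counter()
    for m, c in table.counts.items():
        by_class[classes[m]] += c
    out = {sc.label: by_class.get(sc, 0) / total for sc in SiteClass}
    out["seed_match"] = 1.0 - out[SiteClass.NONE.label]
    return out
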
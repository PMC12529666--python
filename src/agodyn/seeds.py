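"""Canonical miRNA seed-site taxonomy over a degenerate target library.

The miRNA seed comprises guide nucleotides g2-g8 (1-based from the guide 5'
end).  A target site is written 5'->3' so that its 3'-most base faces g1
(position t1).  Canonical site classes, in decreasing affinity:

* 8mer      -- t2-t8 Watson-Crick complementary to g2-g8 and t1 = A
* 7mer-m8   -- t2-t8 complementary, t1 != A
* 7mer-A1   -- t2-t7 complementary, t1 = A, t8 not complementary
* 6mer      -- t2-t7 complementary, t1 != A, t8 not complementary

G:U wobbles count as mismatches throughout.  The RBNS target library is the
expansion of a purine/pyrimidine degenerate pattern (e.g. ``RYRYYYYR`` ->
256 concrete 8-mers) embedded between constant flanks.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

__all__ = [
    "DEGENERATE",
    "GuideRNA",
    "SiteClass",
    "LibraryMember",
    "expand_degenerate",
    "revcomp",
    "seed_region",
    "classify_site",
    "classify_library",
]

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: IUPAC-style degeneracies accepted in library patterns.
DEGENERATE = {
    "A": "A",
    "C": "C",
    "G": "G",
    "U": "U",
    "R": "AG",
    "Y": "CU",
    "N": "ACGU",
}


def _normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and map T->U; reject anything outside A/C/G/U."""
    out = seq.upper().replace("T", "U")
    for i, ch in enumerate(out):
        if ch not in _COMPLEMENT:
            raise ValueError(f"invalid symbol {ch!r} at position {i + 1} in {context}")
    return out


class SiteClass(enum.IntEnum):
    """Canonical seed-match classes, ordered by priority (higher = stronger)."""

    NONE = 0
    SIX_MER = 1
    SEVEN_MER_A1 = 2
    SEVEN_MER_M8 = 3
    EIGHT_MER = 4

    @property
    def label(self) -> str:
        return _CLASS_LABELS[self]


_CLASS_LABELS = {
    SiteClass.EIGHT_MER: "8mer",
    SiteClass.SEVEN_MER_M8: "7mer-m8",
    SiteClass.SEVEN_MER_A1: "7mer-A1",
    SiteClass.SIX_MER: "6mer",
    SiteClass.NONE: "none",
}


@dataclass(frozen=True)
class GuideRNA:
    """A guide RNA with 1-based position semantics.

    ``sequence`` is stored 5'->3' in the RNA alphabet (T on input is
    normalized to U).  The seed is g2-g8.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        norm = _normalize_rna(self.sequence, context=f"guide {self.name!r}")
        if len(norm) < 8:
            raise ValueError(
                f"guide {self.name!r} has length {len(norm)}; need >= 8 for a g2-g8 seed"
            )
        object.__setattr__(self, "sequence", norm)

    def nt(self, position: int) -> str:
        """Guide nucleotide at a 1-based position from the 5' end."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside guide of length {len(self.sequence)}")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class LibraryMember:
    """One concrete member of the degenerate RBNS target library."""

    variable: str
    flank5: str = ""
    flank3: str = ""
    site_class: SiteClass | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variable", _normalize_rna(self.variable, context="variable region"))
        object.__setattr__(self, "flank5", _normalize_rna(self.flank5, context="5' flank"))
        object.__setattr__(self, "flank3", _normalize_rna(self.flank3, context="3' flank"))

    @property
    def construct(self) -> str:
        """Full-length library sequence: 5' flank + variable + 3' flank."""
        return self.flank5 + self.variable + self.flank3


def expand_degenerate(pattern: str) -> list[str]:
    """Expand a degenerate pattern into all concrete sequences.

    Expansion is the Cartesian product of per-position alternatives, returned
    in lexicographic order; the count equals the product of the per-position
    degeneracies (``RYRYYYYR`` -> 256).
    """
    if not pattern:
        raise ValueError("empty pattern")
    norm = pattern.upper().replace("T", "U")
    choices: list[str] = []
    for i, ch in enumerate(norm):
        try:
            choices.append(DEGENERATE[ch])
        except KeyError:
            raise ValueError(f"invalid symbol {ch!r} at position {i + 1} in pattern") from None
    return ["".join(tup) for tup in itertools.product(*choices)]


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA sequence (A<->U, C<->G)."""
    norm = _normalize_rna(seq)
    return "".join(_COMPLEMENT[ch] for ch in reversed(norm))


def seed_region(guide: GuideRNA) -> str:
    """The g2-g8 seed of a guide, 5'->3' (7 nt)."""
    return guide.sequence[1:8]


def classify_site(window: str, guide: GuideRNA) -> SiteClass:
    """Classify an 8-nt target window against a guide's seed.

    The window is written 5'->3'; its 3'-most base is t1 (opposite g1), so
    ``window[8 - i]`` is t_i.  Classes are assigned with strict priority
    8mer > 7mer-m8 > 7mer-A1 > 6mer > none using Watson-Crick pairing only.
    """
    w = _normalize_rna(window, context="target window")
    if len(w) != 8:
        raise ValueError(f"target window must be exactly 8 nt, got {len(w)}")

    def paired(i: int) -> bool:
        # t_i is w[8 - i]; complementary to g_i.
        return w[8 - i] == _COMPLEMENT[guide.nt(i)]

    t1_is_a = w[7] == "A"
    core27 = all(paired(i) for i in range(2, 8))
    if core27 and paired(8):
        return SiteClass.EIGHT_MER if t1_is_a else SiteClass.SEVEN_MER_M8
    if core27:
        return SiteClass.SEVEN_MER_A1 if t1_is_a else SiteClass.SIX_MER
    return SiteClass.NONE


def classify_library(
    members: list[LibraryMember],
    guide: GuideRNA,
    scan_mode: str = "fixed-register",
) -> dict[str, SiteClass]:
    """Label every library member with its seed-site class.

    In ``fixed-register`` mode only the 8-nt variable region is classified at
    its known position.  In ``full-scan`` mode every 8-nt window of the full
    construct (flanks included) is classified and the highest-priority class
    over windows is reported, which admits sites spanning the variable/flank
    junction.  Returns ``{variable sequence: SiteClass}``.
    """
    if scan_mode not in ("fixed-register", "full-scan"):
        raise ValueError(f"unknown scan_mode {scan_mode!r}")
    out: dict[str, SiteClass] = {}
    for m in members:
        if scan_mode == "fixed-register":
            if len(m.variable) != 8:
                raise ValueError("fixed-register mode requires an 8-nt variable region")
            out[m.variable] = classify_site(m.variable, guide)
        else:
            seq = m.construct
            best = SiteClass.NONE
            for start in range(len(seq) - 7):
                best = max(best, classify_site(seq[start : start + 8], guide))
            out[m.variable] = best
    return out
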
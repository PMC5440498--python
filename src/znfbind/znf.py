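"""Finger-to-nucleotide target mapping, chimera and truncation design.

A tandem C2H2 zinc-finger array reads DNA three nucleotides per finger.
For the 12-finger murine array modeled here (one separate upstream finger,
one degenerate CH2-type finger, then ten sequence-specific C2H2 fingers)
the 31-nt target site is tiled as

    finger k (k = 2..11)  ->  site positions [3k-4, 3k-2]   (1-based, inclusive)

so finger 2 reads nt 2-4 and finger 11 reads nt 29-31.  Finger 1 (the
degenerate CH2 finger) straddles the upstream site boundary (positions -1..1,
only nt 1 inside the site) and makes no sequence-specific contact; finger 0
sits apart from the array and touches no site position.  This closed form is
the unique 3-nt tiling consistent with the full panel of chimera
finger annotations it is validated against in the test suite.

Chimeras keep a chosen interval of the specific site on an otherwise
unspecific donor duplex; truncations shorten the duplex from either end.
Expected binding is classified from how many fingers keep their full
triplet: a finger with all 3 nt counts 1, a finger with 1-2 nt counts 0.5,
and the score thresholds >=8 (comparable), >=5 (reduced), <5 (strongly
reduced) reproduce the observed three-way classification of the chimera
panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "SITE_LENGTH",
    "BindingClass",
    "ZincFinger",
    "ZnFArray",
    "TargetSite",
    "ChimeraDesign",
    "TruncationDesign",
    "DEFAULT_CHIMERA_INTERVALS",
    "DEFAULT_TRUNCATION_NAMES",
    "finger_triplet_map",
    "contacted_fingers",
    "binding_score",
    "classify_binding",
    "generate_chimeras",
    "generate_truncations",
]

#: length of the specifically contacted target site, nucleotides
SITE_LENGTH = 31

#: the chimera panel: retained specific intervals, 1-based inclusive
DEFAULT_CHIMERA_INTERVALS: tuple[tuple[int, int], ...] = (
    (1, 31),
    (6, 31),
    (1, 26),
    (11, 31),
    (16, 31),
    (1, 21),
    (1, 16),
    (21, 31),
    (1, 11),
    (6, 15),
    (6, 20),
    (6, 10),
)

DEFAULT_TRUNCATION_NAMES = ("75 bp", "39 bp", "34 bp", "31 bp", "28 bp-d", "28 bp-u")


class BindingClass(str, Enum):
    COMPARABLE = "comparable"
    REDUCED = "reduced"
    STRONGLY_REDUCED = "strongly_reduced"


@dataclass(frozen=True)
class ZincFinger:
    """One finger: array index, its 3-nt anchor on the site (or None), and
    whether it makes sequence-specific contacts."""

    index: int
    triplet: tuple[int, int] | None
    specific: bool


@dataclass(frozen=True)
class ZnFArray:
    """Ordered finger array.  Index 0 is the separate upstream finger,
    index 1 the degenerate CH2 finger, indices 2-11 the specific tandem
    C2H2 fingers."""

    fingers: tuple[ZincFinger, ...]

    def __post_init__(self) -> None:
        idx = [f.index for f in self.fingers]
        if len(set(idx)) != len(idx) or idx != sorted(idx):
            raise ValueError("finger indices must be unique and ordered")
        for f in self.fingers:
            if f.specific:
                if f.triplet is None or f.triplet[1] - f.triplet[0] != 2:
                    raise ValueError(
                        f"specific finger {f.index} must anchor exactly 3 positions"
                    )

    @classmethod
    def default(cls) -> "ZnFArray":
        """The 12-finger array with the closed-form triplet tiling."""
        fingers = [ZincFinger(0, None, False), ZincFinger(1, (-1, 1), False)]
        fingers += [
            ZincFinger(k, (3 * k - 4, 3 * k - 2), True) for k in range(2, 12)
        ]
        return cls(tuple(fingers))

    @property
    def specific_fingers(self) -> tuple[ZincFinger, ...]:
        return tuple(f for f in self.fingers if f.specific)


def finger_triplet_map(array: ZnFArray | None = None) -> dict[int, tuple[int, int] | None]:
    """Per-finger site interval (1-based inclusive; None for no contact)."""
    array = array or ZnFArray.default()
    return {f.index: f.triplet for f in array.fingers}


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def contacted_fingers(
    retained: tuple[int, int] | None,
    array: ZnFArray | None = None,
    include_nonspecific: bool = False,
) -> tuple[frozenset[int], frozenset[int]]:
    """Fingers whose triplet is fully / partially inside a retained interval.

    ``retained`` is 1-based inclusive within the site (None or an empty
    interval yields two empty sets).  Only sequence-specific fingers are
    counted unless ``include_nonspecific`` -- the degenerate CH2 finger
    overlaps position 1 but contributes no specificity.
    """
    array = array or ZnFArray.default()
    if retained is not None:
        a, b = retained
        if a < 1 or b > SITE_LENGTH:
            raise ValueError(f"retained interval {retained} outside [1, {SITE_LENGTH}]")
        if b < a:
            retained = None
    full, partial = set(), set()
    if retained is not None:
        for f in array.fingers:
            if f.triplet is None or (not f.specific and not include_nonspecific):
                continue
            n = _overlap_len(f.triplet, retained)
            if n == f.triplet[1] - f.triplet[0] + 1:
                full.add(f.index)
            elif n > 0:
                partial.add(f.index)
    return frozenset(full), frozenset(partial)


def binding_score(full: Iterable[int], partial: Iterable[int]) -> float:
    """Contact score: 1 per fully contacted finger, 0.5 per partial one."""
    return len(set(full)) + 0.5 * len(set(partial))


def classify_binding(full: Iterable[int], partial: Iterable[int]) -> BindingClass:
    """Three-way expected-binding class from contacted-finger counts.

    score >= 8 -> comparable to the full site; 5 <= score < 8 -> reduced;
    score < 5 -> strongly reduced (too few fingers to confer specificity).
    """
    score = binding_score(full, partial)
    if score >= 8:
        return BindingClass.COMPARABLE
    if score >= 5:
        return BindingClass.REDUCED
    return BindingClass.STRONGLY_REDUCED


_BASES = set("ACGT")


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if set(seq) - _BASES:
        raise ValueError(f"{what} contains non-ACGT characters")
    return seq


@dataclass(frozen=True)
class TargetSite:
    """The specific binding site plus its flanks, on the stored strand.

    Positions 1..31 index ``sequence``; the full duplex is
    flank5 + sequence + flank3.
    """

    sequence: str
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_dna(self.sequence, "site"))
        object.__setattr__(self, "flank5", _check_dna(self.flank5, "flank5"))
        object.__setattr__(self, "flank3", _check_dna(self.flank3, "flank3"))
        if len(self.sequence) != SITE_LENGTH:
            raise ValueError(f"target site must be {SITE_LENGTH} nt")

    @property
    def full_sequence(self) -> str:
        return self.flank5 + self.sequence + self.flank3

    @property
    def site_offset(self) -> int:
        """0-based index of site position 1 within the full duplex."""
        return len(self.flank5)


@dataclass(frozen=True)
class ChimeraDesign:
    """A duplex keeping ``retained`` site positions on an unspecific donor."""

    name: str
    retained: tuple[int, int]
    sequence: str
    contacted_full: frozenset[int]
    contacted_partial: frozenset[int]
    binding_class: BindingClass

    @property
    def score(self) -> float:
        return binding_score(self.contacted_full, self.contacted_partial)


def generate_chimeras(
    site: TargetSite,
    donor: str,
    intervals: Sequence[tuple[int, int]] | None = None,
    array: ZnFArray | None = None,
) -> list[ChimeraDesign]:
    """Build the chimera panel: donor everywhere except the retained interval.

    ``donor`` must be at least as long as the site context; the retained
    site positions are copied over the donor at the site's own offset, so
    flanks are always donor-derived (the full-site chimera replaces only
    the flanks).
    """
    donor = _check_dna(donor, "donor")
    context = site.full_sequence
    if len(donor) < len(context):
        raise ValueError("donor must be at least as long as the site context")
    intervals = tuple(intervals) if intervals is not None else DEFAULT_CHIMERA_INTERVALS
    off = site.site_offset
    designs = []
    for a, b in intervals:
        if a < 1 or b > SITE_LENGTH or b < a:
            raise ValueError(f"retained interval ({a}, {b}) outside [1, {SITE_LENGTH}]")
        seq = donor[: off + a - 1] + site.sequence[a - 1 : b] + donor[off + b :]
        full, partial = contacted_fingers((a, b), array)
        designs.append(
            ChimeraDesign(
                name=f"Chim. nt {a}-{b}",
                retained=(a, b),
                sequence=seq,
                contacted_full=full,
                contacted_partial=partial,
                binding_class=classify_binding(full, partial),
            )
        )
    return designs


@dataclass(frozen=True)
class TruncationDesign:
    """A shortened duplex and the site interval it retains."""

    name: str
    length: int
    retained: tuple[int, int]
    sequence: str
    contacted_full: frozenset[int]
    contacted_partial: frozenset[int]


def generate_truncations(
    site: TargetSite,
    names: Sequence[str] | None = None,
    array: ZnFArray | None = None,
) -> list[TruncationDesign]:
    """Build the length-truncation panel of the reference duplex.

    Panel conventions (site positions are 1-based):

    - ``75 bp``   full context (requires 75 bp of context)
    - ``39 bp``   site plus 4 nt of flank on each side
    - ``34 bp``   site plus 3 nt of 5' flank (covers the degenerate finger)
    - ``31 bp``   the exact site span
    - ``28 bp-u`` site minus positions 1-3 (loses finger 2)
    - ``28 bp-d`` site minus positions 29-31 (loses finger 11)
    """
    names = tuple(names) if names is not None else DEFAULT_TRUNCATION_NAMES
    context = site.full_sequence
    off = site.site_offset
    specs: dict[str, tuple[tuple[int, int], str]] = {}
    for name in names:
        if name == "75 bp":
            if len(context) < 75:
                raise ValueError("75 bp fragment needs >= 75 bp of context")
            specs[name] = ((1, 31), context)
        elif name == "39 bp":
            if off < 4 or len(site.flank3) < 4:
                raise ValueError("39 bp fragment needs >= 4 nt of flank on each side")
            specs[name] = ((1, 31), context[off - 4 : off + SITE_LENGTH + 4])
        elif name == "34 bp":
            if off < 3:
                raise ValueError("34 bp fragment needs >= 3 nt of 5' flank")
            specs[name] = ((1, 31), context[off - 3 : off + SITE_LENGTH])
        elif name == "31 bp":
            specs[name] = ((1, 31), site.sequence)
        elif name == "28 bp-u":
            specs[name] = ((4, 31), site.sequence[3:])
        elif name == "28 bp-d":
            specs[name] = ((1, 28), site.sequence[:28])
        else:
            raise ValueError(f"unknown truncation name {name!r}")
    out = []
    for name, (retained, seq) in specs.items():
        full, partial = contacted_fingers(retained, array)
        out.append(
            TruncationDesign(
                name=name,
                length=len(seq),
                retained=retained,
                sequence=seq,
                contacted_full=full,
                contacted_partial=partial,
            )
        )
    return out
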
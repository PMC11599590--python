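"""Canonical algebra of Cas9 editing outcomes.

A Cas9 blunt cut between two bases of a target sequence is repaired into a
deletion, an insertion, or a combination of the two.  The same edited
sequence can usually be written in several equivalent ways (a deletion
inside a repeat can slide along it), so all counting starts from a canonical
representation.  This module provides:

* :class:`TargetSite` -- a target sequence with protospacer/PAM coordinates
  and the derived cut locus,
* :class:`OutcomeSpec` -- one mutagenic outcome (deletion interval plus
  inserted sequence) in canonical, left-most form,
* canonicalization, microhomology length, the ten-way outcome
  classification, insertion/flank templating match, deletion directionality,
  frame effect, and the text descriptor grammar used by all TSV files.

Coordinates are 0-based half-open throughout.  The cut is a *gap* index:
gap ``g`` lies between sequence positions ``g - 1`` and ``g``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

__all__ = [
    "TargetSite",
    "OutcomeSpec",
    "OutcomeCategory",
    "FlankMatch",
    "OutOfWindowError",
    "apply_outcome",
    "canonicalize",
    "equivalent_start_range",
    "microhomology_length",
    "deletion_split",
    "directionality",
    "insertion_flank_match",
    "classify",
    "is_in_frame",
    "enumerate_outcomes",
    "parse_descriptor",
    "format_descriptor",
    "CATEGORIES",
]

_VALID_BASES = frozenset("ACGT")

# How far (in gap units) a pure insertion may sit from the cut and still be
# considered an on-target outcome, matching the candidate enumeration window.
INSERTION_WINDOW = 3


class OutOfWindowError(ValueError):
    """Raised for outcomes that cannot be attributed to the cut locus.

    An outcome is out of window when no equivalent representation of its
    deletion touches the two cut-adjacent bases and no equivalent insertion
    gap lies within :data:`INSERTION_WINDOW` of the cut.
    """


@dataclass(frozen=True)
class TargetSite:
    """A synthetic Cas9 target in protospacer-5'->3' orientation.

    The PAM is NGG: ``sequence[pam_start + 1 : pam_start + 3] == "GG"``.
    Cas9 cuts bluntly 3 bp upstream of the PAM, i.e. between the 17th and
    18th protospacer bases; the cut locus is exposed as :attr:`cut`.
    """

    id: str
    sequence: str
    protospacer_start: int
    pam_start: int

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq or set(seq) - _VALID_BASES:
            raise ValueError(f"target {self.id}: sequence must be non-empty A/C/G/T")
        if self.pam_start != self.protospacer_start + 20:
            raise ValueError(f"target {self.id}: PAM must directly follow the 20 nt protospacer")
        if seq[self.pam_start + 1 : self.pam_start + 3] != "GG":
            raise ValueError(f"target {self.id}: PAM at {self.pam_start} is not NGG")
        cut = self.cut
        if cut < 30 or len(seq) - cut < 30:
            raise ValueError(
                f"target {self.id}: need >= 30 bases on each side of the cut "
                f"(have {cut} and {len(seq) - cut})"
            )

    @property
    def cut(self) -> int:
        """Blunt cut gap index, 3 bp upstream of the PAM."""
        return self.pam_start - 3

    @property
    def pam_distal(self) -> str:
        """Base immediately 5' of the cut."""
        return self.sequence[self.cut - 1]

    @property
    def pam_proximal(self) -> str:
        """Base immediately 3' of the cut."""
        return self.sequence[self.cut]


@dataclass(frozen=True, order=True)
class OutcomeSpec:
    """One mutagenic outcome: delete ``[del_start, del_end)``, insert ``ins_seq``.

    Instances produced by :func:`canonicalize` are in canonical form: the
    deletion interval (or insertion gap) is the left-most among all
    representations yielding the same edited sequence with the same deletion
    and insertion sizes.  The wild-type outcome (no deletion, no insertion)
    is not representable.
    """

    del_start: int
    del_end: int
    ins_seq: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.del_start <= self.del_end):
            raise ValueError("need 0 <= del_start <= del_end")
        if set(self.ins_seq) - _VALID_BASES:
            raise ValueError("ins_seq must be over A/C/G/T")
        if self.del_size == 0 and self.ins_size == 0:
            raise ValueError("wild type (empty deletion and insertion) is not an outcome")

    @property
    def del_size(self) -> int:
        return self.del_end - self.del_start

    @property
    def ins_size(self) -> int:
        return len(self.ins_seq)

    @property
    def net_change(self) -> int:
        return self.ins_size - self.del_size

    @property
    def is_pure_deletion(self) -> bool:
        return self.ins_size == 0

    @property
    def is_pure_insertion(self) -> bool:
        return self.del_size == 0

    def __str__(self) -> str:
        return format_descriptor(self)


class OutcomeCategory(str, Enum):
    """The ten-way outcome stratification by type, size and microhomology."""

    DEL_1 = "DEL_1"
    DEL_2 = "DEL_2"
    DEL_MED_MH = "DEL_MED_MH"
    DEL_MED_NOMH = "DEL_MED_NOMH"
    DEL_LONG_MH = "DEL_LONG_MH"
    DEL_LONG_NOMH = "DEL_LONG_NOMH"
    INS_PROX = "INS_PROX"
    INS_DIST = "INS_DIST"
    OTHER_I_MH = "OTHER_I_MH"
    OTHER_I_NOMH = "OTHER_I_NOMH"


#: Category labels in canonical display order.
CATEGORIES: tuple[str, ...] = tuple(c.value for c in OutcomeCategory)


class FlankMatch(Enum):
    """Templating match of a 1-2 bp cut-site insertion to its flanks."""

    DISTAL_ONLY = "DISTAL_ONLY"
    PROXIMAL_ONLY = "PROXIMAL_ONLY"
    BOTH = "BOTH"
    NEITHER = "NEITHER"


# ---------------------------------------------------------------------------
# sequence editing and canonicalization
# ---------------------------------------------------------------------------


def apply_outcome(target: TargetSite | str, o: OutcomeSpec) -> str:
    """Return the edited sequence produced by ``o``."""
    seq = target.sequence if isinstance(target, TargetSite) else target
    if o.del_end > len(seq):
        raise ValueError("outcome exceeds sequence bounds")
    return seq[: o.del_start] + o.ins_seq + seq[o.del_end :]


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def _start_range(seq: str, del_start: int, del_end: int, ins_seq: str) -> tuple[int, int, str]:
    """All equivalent representations of an edit form a contiguous run of starts.

    A representation with start ``s`` reproduces the edited sequence ``E``
    iff ``E[:s] == seq[:s]`` and the suffixes after the replaced block agree,
    which bounds ``s`` between ``len(E) - k - q`` and ``min(p, len(seq) - L)``
    where ``p``/``q`` are the longest common prefix/suffix of ``seq`` and
    ``E``.  Returns ``(s_min, s_max, E)``.
    """
    L = del_end - del_start
    k = len(ins_seq)
    edited = seq[:del_start] + ins_seq + seq[del_end:]
    p = _common_prefix_len(seq, edited)
    q = _common_suffix_len(seq, edited)
    s_min = max(0, len(edited) - k - q)
    s_max = min(p, len(seq) - L)
    # the supplied representation is itself valid, so the range is non-empty
    s_min = min(s_min, del_start)
    s_max = max(s_max, del_start)
    return s_min, s_max, edited


def equivalent_start_range(target: TargetSite | str, o: OutcomeSpec) -> tuple[int, int]:
    """Inclusive range of starts of all representations equivalent to ``o``."""
    seq = target.sequence if isinstance(target, TargetSite) else target
    s_min, s_max, _ = _start_range(seq, o.del_start, o.del_end, o.ins_seq)
    return s_min, s_max


def _in_window(cut: int, L: int, k: int, s_min: int, s_max: int) -> bool:
    del_ok = L > 0 and s_min <= cut and s_max + L >= cut
    ins_ok = k > 0 and s_min <= cut + INSERTION_WINDOW and s_max >= cut - INSERTION_WINDOW
    return del_ok or ins_ok


def canonicalize(
    target: TargetSite | str,
    del_start: int,
    del_end: int,
    ins_seq: str = "",
    *,
    check_window: bool = True,
) -> OutcomeSpec:
    """Return the canonical (left-most) representation of an edit.

    Two representations are equivalent when they produce byte-identical
    edited sequences with the same deletion and insertion sizes; the
    canonical one has the minimal ``del_start``.  Idempotent.

    Raises :class:`OutOfWindowError` when ``check_window`` is set and no
    equivalent representation can be attributed to the cut (deletion not
    touching the cut-adjacent bases and insertion gap farther than
    :data:`INSERTION_WINDOW` from the cut).  A bare sequence string may be
    passed instead of a :class:`TargetSite`; it has no cut, so the window
    check is skipped.
    """
    if isinstance(target, str):
        seq, cut = target, None
    else:
        seq, cut = target.sequence, target.cut
    if not (0 <= del_start <= del_end <= len(seq)):
        raise ValueError("deletion interval out of sequence bounds")
    if set(ins_seq) - _VALID_BASES:
        raise ValueError("ins_seq must be over A/C/G/T")
    L = del_end - del_start
    k = len(ins_seq)
    if L == 0 and k == 0:
        raise ValueError("wild type is not an outcome")
    s_min, s_max, edited = _start_range(seq, del_start, del_end, ins_seq)
    if check_window and cut is not None and not _in_window(cut, L, k, s_min, s_max):
        raise OutOfWindowError(
            f"outcome D[{del_start},{del_end})+I:{ins_seq!r} cannot be attributed "
            f"to the cut at {cut}"
        )
    return OutcomeSpec(s_min, s_min + L, edited[s_min : s_min + k])


# ---------------------------------------------------------------------------
# microhomology, directionality, frame
# ---------------------------------------------------------------------------


def microhomology_length(target: TargetSite | str, o: OutcomeSpec) -> int:
    """Microhomology length of a pure deletion.

    Equals the number of equivalent same-size deletion intervals minus one,
    which is also the length of the maximal exact repeat shared by the two
    deletion junctions.  Zero for a deletion with a unique representation.
    """
    if not o.is_pure_deletion:
        raise ValueError("microhomology is defined for pure deletions only")
    s_min, s_max = equivalent_start_range(target, o)
    return s_max - s_min


def deletion_split(target: TargetSite, o: OutcomeSpec) -> tuple[int, int]:
    """``(left_del, right_del)``: deleted bases 5' (< cut) and 3' (>= cut) of the cut.

    For microhomology deletions the representation is ambiguous; the split is
    taken from the equivalent interval whose midpoint is closest to the cut
    (ties resolved left-most), so representation choice does not inflate
    directionality.
    """
    if not o.is_pure_deletion:
        raise ValueError("deletion_split is defined for pure deletions only")
    cut = target.cut
    L = o.del_size
    s_min, s_max = equivalent_start_range(target, o)
    # minimize |s + L/2 - cut| over s in [s_min, s_max]; the unconstrained
    # optimum is cut - L/2, clamp and round toward the left for ties
    best = min(max(s_min, (2 * cut - L) // 2), s_max)
    # check the neighbour on the right in case of fractional midpoint
    for cand in (best, best + 1):
        if s_min <= cand <= s_max and abs(2 * (cand + cand + L) - 4 * cut) < abs(
            2 * (best + best + L) - 4 * cut
        ):
            best = cand
    left = min(L, max(0, cut - best))
    return left, L - left


def directionality(target: TargetSite, o: OutcomeSpec) -> float:
    """Asymmetry of a deletion around the cut: ``max(left, right) / total``.

    1 for a deletion confined to one side of the cut (including every 1 bp
    deletion), 0.5 for a perfectly symmetric one.
    """
    left, right = deletion_split(target, o)
    return max(left, right) / o.del_size


def abs_directionality(target: TargetSite, o: OutcomeSpec) -> float:
    """Alternative directionality definition, ``|left - right| / total``."""
    left, right = deletion_split(target, o)
    return abs(left - right) / o.del_size


def is_in_frame(o: OutcomeSpec) -> bool:
    """True iff the net length change is a multiple of 3."""
    return o.net_change % 3 == 0


# ---------------------------------------------------------------------------
# insertion templating and the ten-way classification
# ---------------------------------------------------------------------------


def insertion_flank_match(target: TargetSite, o: OutcomeSpec) -> FlankMatch:
    """Match of a 1-2 bp cut-site insertion to the bases flanking the cut.

    The inserted sequence (anchored at the cut among its equivalent gaps) is
    compared with the ``ins_size`` bases immediately 5' of the cut (the
    PAM-distal template) and immediately 3' of it (the PAM-proximal
    template), each read contiguously from the cut.
    """
    if not o.is_pure_insertion or not 1 <= o.ins_size <= 2:
        raise ValueError("flank match is defined for pure 1-2 bp insertions")
    seq, cut, k = target.sequence, target.cut, o.ins_size
    s_min, s_max, edited = _start_range(seq, o.del_start, o.del_end, o.ins_seq)
    if not s_min <= cut <= s_max:
        raise ValueError("insertion gap is not equivalent to the cut locus")
    ins_at_cut = edited[cut : cut + k]
    distal = seq[cut - k : cut]
    proximal = seq[cut : cut + k]
    if ins_at_cut == distal and ins_at_cut == proximal:
        return FlankMatch.BOTH
    if ins_at_cut == distal:
        return FlankMatch.DISTAL_ONLY
    if ins_at_cut == proximal:
        return FlankMatch.PROXIMAL_ONLY
    return FlankMatch.NEITHER


#: Flanking window (bp each side of the edit) searched for matches between an
#: inserted sequence and the target when calling OTHER_I_MH.
_OTHER_MH_FLANK = 10


def _insertion_matches_flank(target: TargetSite, o: OutcomeSpec, mh_min: int) -> bool:
    if o.ins_size < mh_min:
        return False
    seq = target.sequence
    left = seq[max(0, o.del_start - _OTHER_MH_FLANK) : o.del_start]
    right = seq[o.del_end : o.del_end + _OTHER_MH_FLANK]
    ins = o.ins_seq
    for i in range(o.ins_size - mh_min + 1):
        for j in range(i + mh_min, o.ins_size + 1):
            sub = ins[i:j]
            if sub in left or sub in right:
                return True
    return False


def classify(
    target: TargetSite,
    o: OutcomeSpec,
    mh_min: int = 2,
    *,
    both_as_distal: bool = True,
) -> OutcomeCategory:
    """Assign an outcome to exactly one of the ten categories.

    Pure deletions split by size (1 / 2 / 3-9 / 10+) and microhomology
    (``mh_len >= mh_min``).  Pure 1-2 bp insertions at the cut split by
    templating flank; insertions matching both identical flanks count as
    PAM-distal by default (the dominant mechanism), configurable.  Everything
    else -- longer insertions, off-cut insertions, untemplated cut
    insertions, and mixed insertion-deletions -- is OTHER, with or without a
    >= ``mh_min`` bp match between the inserted sequence and the flanking
    target sequence.
    """
    if o.is_pure_deletion:
        size = o.del_size
        if size == 1:
            return OutcomeCategory.DEL_1
        if size == 2:
            return OutcomeCategory.DEL_2
        mh = microhomology_length(target, o) >= mh_min
        if size <= 9:
            return OutcomeCategory.DEL_MED_MH if mh else OutcomeCategory.DEL_MED_NOMH
        return OutcomeCategory.DEL_LONG_MH if mh else OutcomeCategory.DEL_LONG_NOMH
    if o.is_pure_insertion and 1 <= o.ins_size <= 2:
        s_min, s_max = equivalent_start_range(target, o)
        if s_min <= target.cut <= s_max:
            fm = insertion_flank_match(target, o)
            if fm is FlankMatch.DISTAL_ONLY:
                return OutcomeCategory.INS_DIST
            if fm is FlankMatch.PROXIMAL_ONLY:
                return OutcomeCategory.INS_PROX
            if fm is FlankMatch.BOTH:
                return OutcomeCategory.INS_DIST if both_as_distal else OutcomeCategory.INS_PROX
            # NEITHER falls through to OTHER
    if _insertion_matches_flank(target, o, mh_min):
        return OutcomeCategory.OTHER_I_MH
    return OutcomeCategory.OTHER_I_NOMH


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

_ALPHABET = ("A", "C", "G", "T")


def enumerate_outcomes(
    target: TargetSite,
    max_del: int = 30,
    max_ins: int = 2,
    ins_window: int = INSERTION_WINDOW,
) -> list[OutcomeSpec]:
    """All distinct candidate outcomes at a target, canonical and deduplicated.

    Candidates are every insertion of 1..``max_ins`` nt at a gap within
    ``ins_window`` of the cut, and every deletion of 1..``max_del`` nt whose
    interval (in at least one equivalent representation) touches the two
    cut-adjacent bases.  Outcomes equivalent under representation ambiguity
    collapse to one canonical record; no two returned outcomes produce the
    same edited sequence.
    """
    cut = target.cut
    if cut < max_del or len(target.sequence) - cut < max_del:
        raise ValueError("target too short for the requested deletion window")
    seen: dict[OutcomeSpec, None] = {}
    for L in range(1, max_del + 1):
        for s in range(cut - L, cut + 1):
            o = canonicalize(target, s, s + L, check_window=False)
            seen.setdefault(o, None)
    ins_seqs = list(_ALPHABET)
    if max_ins >= 2:
        ins_seqs += [a + b for a in _ALPHABET for b in _ALPHABET]
    if max_ins > 2:
        raise ValueError("insertions longer than 2 nt are not enumerated")
    for g in range(cut - ins_window, cut + ins_window + 1):
        for ins in ins_seqs:
            o = canonicalize(target, g, g, ins, check_window=False)
            seen.setdefault(o, None)
    return sorted(seen)


# ---------------------------------------------------------------------------
# descriptor grammar
# ---------------------------------------------------------------------------

_DEL_RE = re.compile(r"^D:(\d+)-(\d+)$")
_INS_RE = re.compile(r"^I:(\d+):([ACGT]+)$")


def format_descriptor(o: OutcomeSpec) -> str:
    """Canonical text descriptor: ``D:<start>-<end>`` and/or ``I:<gap>:<seq>``."""
    parts = []
    if o.del_size:
        parts.append(f"D:{o.del_start}-{o.del_end}")
    if o.ins_size:
        parts.append(f"I:{o.del_start}:{o.ins_seq}")
    return "+".join(parts)


def parse_descriptor(target: TargetSite, descriptor: str, *, check_window: bool = True) -> OutcomeSpec:
    """Parse a descriptor, normalizing non-canonical input.

    Accepts ``D:<start>-<end>``, ``I:<gap>:<seq>``, or both joined by ``+``
    (the insertion gap of a combined outcome must equal the deletion start).
    """
    del_start = del_end = None
    gap = None
    ins = ""
    for part in descriptor.strip().split("+"):
        if m := _DEL_RE.match(part):
            if del_start is not None:
                raise ValueError(f"duplicate deletion in descriptor {descriptor!r}")
            del_start, del_end = int(m.group(1)), int(m.group(2))
        elif m := _INS_RE.match(part):
            if gap is not None:
                raise ValueError(f"duplicate insertion in descriptor {descriptor!r}")
            gap, ins = int(m.group(1)), m.group(2)
        else:
            raise ValueError(f"malformed outcome descriptor {descriptor!r}")
    if del_start is None and gap is None:
        raise ValueError(f"empty outcome descriptor {descriptor!r}")
    if del_start is None:
        del_start = del_end = gap
    elif gap is not None and gap != del_start:
        raise ValueError(
            f"descriptor {descriptor!r}: insertion gap must equal deletion start"
        )
    return canonicalize(target, del_start, del_end, ins, check_window=check_window)


# ---------------------------------------------------------------------------
# cached per-(target, outcome) annotation used by the pipeline stages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeAnnotation:
    """Derived per-outcome quantities shared by the downstream stages.

    ``mh_len`` here is the MMEJ-usable microhomology, capped at the deletion
    size: inside long repeat runs the junction repeat (and hence the raw
    representation-ambiguity count of :func:`microhomology_length`) can
    exceed the number of deleted bases, but end joining cannot anneal more
    homology than was deleted.
    """

    outcome: OutcomeSpec
    category: OutcomeCategory
    del_size: int
    ins_size: int
    mh_len: int  # -1 for outcomes with an insertion
    directionality: float  # nan for outcomes with an insertion
    in_frame: bool
    is_1bp_insertion: bool
    flank_match: FlankMatch | None


@lru_cache(maxsize=None)
def _annotate_cached(
    sequence: str, protospacer_start: int, pam_start: int, descriptor: str, mh_min: int
) -> OutcomeAnnotation:
    target = TargetSite("_cache", sequence, protospacer_start, pam_start)
    o = parse_descriptor(target, descriptor, check_window=False)
    category = classify(target, o, mh_min)
    if o.is_pure_deletion:
        mh = min(microhomology_length(target, o), o.del_size)
        direc = directionality(target, o)
    else:
        mh, direc = -1, float("nan")
    fm: FlankMatch | None = None
    is_1bp_ins = o.is_pure_insertion and o.ins_size == 1
    if o.is_pure_insertion and 1 <= o.ins_size <= 2:
        s_min, s_max = equivalent_start_range(target, o)
        if s_min <= target.cut <= s_max:
            fm = insertion_flank_match(target, o)
    return OutcomeAnnotation(
        outcome=o,
        category=category,
        del_size=o.del_size,
        ins_size=o.ins_size,
        mh_len=mh,
        directionality=direc,
        in_frame=is_in_frame(o),
        is_1bp_insertion=is_1bp_ins,
        flank_match=fm,
    )


def annotate(target: TargetSite, outcome: OutcomeSpec | str, mh_min: int = 2) -> OutcomeAnnotation:
    """Annotate one outcome (cached per distinct target sequence/outcome)."""
    descriptor = outcome if isinstance(outcome, str) else format_descriptor(outcome)
    return _annotate_cached(
        target.sequence, target.protospacer_start, target.pam_start, descriptor, mh_min
    )
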
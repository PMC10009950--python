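"""Candidate ATN progression sequences.

An ATN group label combines three binary biomarker categories — amyloid (A),
tau (T) and neurodegeneration (N) — each normal (-) or abnormal (+), giving
2^3 = 8 groups from ``A-T-N-`` (no pathology) to ``A+T+N+`` (pathology in all
categories).  A :class:`GroupSequence` is an ordered hypothesis about how a
person transitions across four of those groups; the amyloid-cascade ordering
(amyloid converts first, tau second, neurodegeneration last) is named ``ACH``.

Two candidate sets are used downstream:

* :func:`permutation_sequences` — all 24 orderings of the four AD-continuum
  groups (ACH plus 23 permuted alternatives), used for face-validity checks.
* :func:`conversion_paths` — the 6 three-step conversion paths from all-
  negative to all-positive status (ACH/ATN, ANT, TAN, TNA, NAT, NTA), which
  also visit groups outside the AD continuum.

Labels are plain ASCII (``A-T-N-``) internally; :func:`pretty_label` renders
the typographic minus used in print.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = [
    "ALL_GROUPS",
    "AD_CONTINUUM",
    "GroupSequence",
    "SequenceSet",
    "group_label",
    "group_flags",
    "pretty_label",
    "expand_order",
    "permutation_sequences",
    "conversion_paths",
]


def group_label(a: bool, t: bool, n: bool) -> str:
    """ATN group label string from the three abnormality flags."""
    return f"A{'+' if a else '-'}T{'+' if t else '-'}N{'+' if n else '-'}"


def group_flags(label: str) -> tuple[bool, bool, bool]:
    """Inverse of :func:`group_label`; raises on malformed labels."""
    if label not in ALL_GROUPS:
        raise ValidationError(f"not a valid ATN group label: {label!r}")
    return (label[1] == "+", label[3] == "+", label[5] == "+")


#: The 8 ATN groups in canonical (tabular) order: A slowest bit, N fastest.
ALL_GROUPS: tuple[str, ...] = tuple(
    group_label(a, t, n)
    for a in (False, True)
    for t in (False, True)
    for n in (False, True)
)

#: The four AD-continuum groups in amyloid-cascade order.
AD_CONTINUUM: tuple[str, str, str, str] = (
    "A-T-N-",
    "A+T-N-",
    "A+T+N-",
    "A+T+N+",
)


def pretty_label(label: str) -> str:
    """Render an ASCII group label with the typographic minus (U+2212)."""
    return label.replace("-", "−")


@dataclass(frozen=True)
class GroupSequence:
    """A named, ordered hypothesis over 4 distinct ATN groups."""

    name: str
    states: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.states) != 4:
            raise ValidationError(f"{self.name}: a sequence has exactly 4 states")
        for s in self.states:
            if s not in ALL_GROUPS:
                raise ValidationError(f"{self.name}: invalid state {s!r}")
        if len(set(self.states)) != 4:
            raise ValidationError(f"{self.name}: states must be pairwise distinct")

    def position_of(self, label: str) -> int | None:
        """1-based position of a group in the sequence, or None if absent."""
        try:
            return self.states.index(label) + 1
        except ValueError:
            return None

    def pretty(self) -> str:
        return " ➔ ".join(pretty_label(s) for s in self.states)

    def to_json(self) -> dict:
        return {"name": self.name, "states": list(self.states)}


@dataclass
class SequenceSet:
    """A named collection of candidate sequences with a reference member."""

    sequences: list[GroupSequence]
    reference: str
    #: Alternative names (e.g. the highlighted alternative permutations
    #: "AP1"/"AP2") mapped onto canonical sequence names.
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sequences]
        if len(set(names)) != len(names):
            raise ValidationError("sequence names must be unique")
        if self.reference not in names:
            raise ValidationError(f"reference {self.reference!r} not in set")
        for alias, target in self.aliases.items():
            if target not in names:
                raise ValidationError(f"alias {alias!r} points to unknown {target!r}")

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sequences]

    def get(self, name: str) -> GroupSequence:
        name = self.aliases.get(name, name)
        for s in self.sequences:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_json(self) -> dict:
        return {
            "reference": self.reference,
            "aliases": dict(self.aliases),
            "sequences": [s.to_json() for s in self.sequences],
        }


def expand_order(order: str) -> GroupSequence:
    """Expand a category conversion order (a permutation of "ATN") into the
    4-state sequence from all-negative to all-positive.

    ``"ATN"`` yields the amyloid-cascade (ACH) states; ``"TAN"`` means tau
    converts first, amyloid second, neurodegeneration last.
    """
    order = order.upper()
    if sorted(order) != ["A", "N", "T"]:
        raise ValidationError(f"order must be a permutation of 'ATN', got {order!r}")
    flags = {"A": False, "T": False, "N": False}
    states = [group_label(flags["A"], flags["T"], flags["N"])]
    for cat in order:
        flags[cat] = True
        states.append(group_label(flags["A"], flags["T"], flags["N"]))
    name = "ACH" if order == "ATN" else order
    return GroupSequence(name=name, states=tuple(states))


# The two alternative permutations highlighted in evidence maps: both place
# the no-pathology group after amyloid conversion (transient-increase shape).
_AP1_STATES = ("A+T-N-", "A+T+N-", "A-T-N-", "A+T+N+")
_AP2_STATES = ("A+T-N-", "A-T-N-", "A+T+N-", "A+T+N+")


def permutation_sequences() -> SequenceSet:
    """All 24 orderings of the four AD-continuum groups.

    The reference ACH ordering comes first; the 23 alternatives follow in
    lexicographic order of state indices and are named ``P01`` .. ``P23``.
    Aliases ``AP1``/``AP2`` name the two transient-increase permutations.
    """
    ach = GroupSequence("ACH", AD_CONTINUUM)
    perms = sorted(itertools.permutations(range(4)))
    sequences = [ach]
    aliases: dict[str, str] = {}
    counter = 0
    for perm in perms:
        states = tuple(AD_CONTINUUM[i] for i in perm)
        if states == AD_CONTINUUM:
            continue
        counter += 1
        name = f"P{counter:02d}"
        sequences.append(GroupSequence(name, states))
        if states == _AP1_STATES:
            aliases["AP1"] = name
        elif states == _AP2_STATES:
            aliases["AP2"] = name
    return SequenceSet(sequences=sequences, reference="ACH", aliases=aliases)


def conversion_paths() -> SequenceSet:
    """The 6 three-step conversion paths from A-T-N- to A+T+N+.

    Each path flips one category per step; names give the category conversion
    order (ACH = amyloid, tau, neurodegeneration).
    """
    sequences = [expand_order("".join(p)) for p in itertools.permutations("ATN")]
    # canonical order: ACH first, then alphabetical by name
    sequences.sort(key=lambda s: (s.name != "ACH", s.name))
    return SequenceSet(sequences=sequences, reference="ACH", aliases={"ATN": "ACH"})
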
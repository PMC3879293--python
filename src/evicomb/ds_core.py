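"""Belief-function algebra on a finite frame of discernment.

Implements the evidence-theoretic layer of the combining classifier:
basic belief assignments (BBAs) over subsets of a finite set of class
hypotheses, belief/plausibility bounds, Dempster's rule of combination
(the orthogonal sum), and the pignistic transformation used to turn a
combined BBA into a probability distribution for decision making.

Subsets of the frame are encoded as bitmasks over the frame's fixed
class order: bit ``i`` set means the ``i``-th class is a member.  This
gives exact set identity, O(1) intersection, and a canonical hashable
encoding for focal elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Frame",
    "MassFunction",
    "PignisticDistribution",
    "NotCombinableError",
    "make_bba",
    "belief",
    "plausibility",
    "conflict",
    "combine",
    "combine_all",
    "pignistic",
    "write_bba",
    "read_bba",
]

#: masses smaller than this after combination are dropped and the BBA
#: renormalized, bounding focal-set growth in long combination chains
MASS_FLOOR = 1e-15

#: two BBAs are treated as non-combinable when their conflict mass K
#: exceeds 1 - COMBINABILITY_EPS (near-total conflict would divide by
#: a catastrophically cancelled 1 - K)
COMBINABILITY_EPS = 1e-12


class NotCombinableError(ValueError):
    """Raised when Dempster's rule is applied to totally conflicting BBAs."""

    def __init__(self, k: float, message: str | None = None):
        self.k = k
        super().__init__(message or f"BBAs are not combinable: conflict K = {k!r}")


@dataclass(frozen=True)
class Frame:
    """Frame of discernment: an ordered set of mutually exclusive classes.

    The order is fixed and defines the canonical bitmask encoding of
    subsets (bit ``i`` corresponds to ``classes[i]``).
    """

    classes: tuple

    def __init__(self, classes: Iterable):
        cls = tuple(classes)
        if len(cls) < 2:
            raise ValueError(f"frame needs at least 2 classes, got {len(cls)}")
        if len(set(cls)) != len(cls):
            raise ValueError("frame classes must be unique")
        object.__setattr__(self, "classes", cls)

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def full_mask(self) -> int:
        return (1 << len(self.classes)) - 1

    def index(self, c) -> int:
        try:
            return self.classes.index(c)
        except ValueError:
            raise KeyError(f"class {c!r} not in frame {self.classes!r}") from None

    def to_mask(self, subset) -> int:
        """Encode a class or an iterable of classes as a bitmask."""
        if isinstance(subset, (str, bytes)) or not isinstance(subset, Iterable):
            subset = (subset,)
        mask = 0
        for c in subset:
            mask |= 1 << self.index(c)
        return mask

    def from_mask(self, mask: int) -> tuple:
        """Decode a bitmask into the canonical tuple of member classes."""
        return tuple(c for i, c in enumerate(self.classes) if mask >> i & 1)


@dataclass(frozen=True)
class MassFunction:
    """A normal basic belief assignment: masses on nonempty subsets, summing to 1."""

    frame: Frame
    focal: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self):
        total = 0.0
        for mask, mass in self.focal.items():
            if mask == 0:
                raise ValueError("empty set cannot be a focal element of a normal BBA")
            if mask & ~self.frame.full_mask:
                raise ValueError(f"focal bitmask {mask:#b} outside frame of size {len(self.frame)}")
            if mass < 0:
                raise ValueError(
                    f"negative mass {mass!r} on subset {self.frame.from_mask(mask)!r}"
                )
            total += mass
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses must sum to 1 (got {total!r})")

    def mass(self, subset) -> float:
        return self.focal.get(self.frame.to_mask(subset), 0.0)

    def items(self):
        """Iterate ``(member-tuple, mass)`` pairs in canonical mask order."""
        for mask in sorted(self.focal):
            yield self.frame.from_mask(mask), self.focal[mask]

    def is_bayesian(self) -> bool:
        return all(mask & (mask - 1) == 0 for mask in self.focal)

    @classmethod
    def vacuous(cls, frame: Frame) -> "MassFunction":
        return cls(frame, {frame.full_mask: 1.0})


@dataclass(frozen=True)
class PignisticDistribution:
    """Probability distribution over the frame's classes (BetP)."""

    frame: Frame
    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.frame),):
            raise ValueError("probs length must equal frame size")
        if (p < -1e-9).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("pignistic probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", p)

    def argmax_class(self):
        """Winning class; ties broken toward the lowest frame index."""
        return self.frame.classes[int(np.argmax(self.probs))]


def make_bba(frame: Frame, assignments: Mapping) -> MassFunction:
    """Build a validated BBA from a ``subset -> mass`` mapping.

    Subset keys may be single class identifiers or iterables of them.
    Masses deviating from unit sum by at most 1e-6 are renormalized;
    larger deviations are rejected.
    """
    focal: dict[int, float] = {}
    for subset, mass in assignments.items():
        mask = frame.to_mask(subset)
        if mask == 0:
            raise ValueError("the empty set cannot receive mass in a normal BBA")
        if mass < 0:
            raise ValueError(f"negative mass {mass!r} on subset {subset!r}")
        focal[mask] = focal.get(mask, 0.0) + float(mass)
    total = sum(focal.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(
            f"masses sum to {total!r}, deviating from 1 by more than 1e-6; "
            f"offending assignment: {dict(assignments)!r}"
        )
    focal = {mask: mass / total for mask, mass in focal.items() if mass > 0.0}
    return MassFunction(frame, focal)


def _check_subset(m: MassFunction, A) -> int:
    mask = m.frame.to_mask(A)
    return mask


def belief(m: MassFunction, A) -> float:
    """bel(A): total mass committed to subsets of A (lower probability bound)."""
    mask = _check_subset(m, A)
    return sum(mass for f, mass in m.focal.items() if f & ~mask == 0)


def plausibility(m: MassFunction, A) -> float:
    """pl(A): total mass not contradicting A (upper probability bound)."""
    mask = _check_subset(m, A)
    return sum(mass for f, mass in m.focal.items() if f & mask)


def conflict(m1: MassFunction, m2: MassFunction) -> float:
    """Conflict mass K: total product mass on empty-intersection focal pairs."""
    if m1.frame != m2.frame:
        raise ValueError("conflict requires BBAs on the same frame")
    k = 0.0
    for f1, v1 in m1.focal.items():
        for f2, v2 in m2.focal.items():
            if f1 & f2 == 0:
                k += v1 * v2
    return k


def combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's rule of combination (orthogonal sum) of two BBAs.

    Raises :class:`NotCombinableError` when the conflict K is within
    ``COMBINABILITY_EPS`` of 1 (no pair of focal elements intersects
    with meaningful joint mass).
    """
    if m1.frame != m2.frame:
        raise ValueError("combine requires BBAs on the same frame")
    acc: dict[int, float] = {}
    k = 0.0
    for f1, v1 in m1.focal.items():
        for f2, v2 in m2.focal.items():
            inter = f1 & f2
            w = v1 * v2
            if inter == 0:
                k += w
            else:
                acc[inter] = acc.get(inter, 0.0) + w
    if k >= 1.0 - COMBINABILITY_EPS:
        raise NotCombinableError(k)
    scale = 1.0 / (1.0 - k)
    focal = {f: v * scale for f, v in acc.items() if v * scale > MASS_FLOOR}
    total = sum(focal.values())
    focal = {f: v / total for f, v in focal.items()}
    return MassFunction(m1.frame, focal)


def combine_all(ms: Sequence[MassFunction]) -> MassFunction:
    """Left fold of :func:`combine` over a sequence of BBAs.

    Associativity of the orthogonal sum makes the pairwise fold exact;
    a :class:`NotCombinableError` is re-raised naming the input whose
    inclusion made the running combination totally conflicting.
    """
    ms = list(ms)
    if not ms:
        raise ValueError("combine_all needs at least one BBA")
    out = ms[0]
    for i, m in enumerate(ms[1:], start=1):
        try:
            out = combine(out, m)
        except NotCombinableError as exc:
            raise NotCombinableError(
                exc.k, f"BBA at position {i} is not combinable with the running "
                f"combination (K = {exc.k!r})"
            ) from None
    return out


def pignistic(m: MassFunction) -> PignisticDistribution:
    """Pignistic transformation: split each focal mass uniformly among members."""
    probs = np.zeros(len(m.frame))
    for mask, mass in m.focal.items():
        members = [i for i in range(len(m.frame)) if mask >> i & 1]
        share = mass / len(members)
        for i in members:
            probs[i] += share
    return PignisticDistribution(m.frame, probs)


# ---------------------------------------------------------------------------
# plain-text serialization: header line naming the frame, then one line per
# focal element "class_id[,class_id...] <TAB> mass" (repr for exact round trip)


def write_bba(m: MassFunction, path) -> None:
    lines = ["# frame\t" + ",".join(str(c) for c in m.frame.classes)]
    for members, mass in m.items():
        lines.append(",".join(str(c) for c in members) + "\t" + repr(float(mass)))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_bba(path, class_type=str) -> MassFunction:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    head = lines[0]
    if not head.startswith("# frame\t"):
        raise ValueError("missing frame header line")
    frame = Frame(class_type(c) for c in head.split("\t", 1)[1].split(","))
    focal: dict[int, float] = {}
    for ln in lines[1:]:
        subset_s, mass_s = ln.split("\t")
        mask = frame.to_mask(tuple(class_type(c) for c in subset_s.split(",")))
        focal[mask] = float(mass_s)
    return MassFunction(frame, focal)
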
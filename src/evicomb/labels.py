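"""Soft/crisp label encoding shared across the relabeling and expert layers.

A *soft label* is a nonempty, strictly increasing tuple of original class
identifiers: the sample is believed to belong to one of its members, without
committing to which.  A singleton tuple is a *crisp* label.  Tuples are the
canonical in-memory form; ``"i|j|k"`` is the on-disk form.
"""

from __future__ import annotations

from typing import Iterable, Sequence

__all__ = ["soft_label", "is_crisp", "expand_class_list", "format_label", "parse_label"]


def soft_label(members: Iterable[int] | int) -> tuple[int, ...]:
    """Canonicalize *members* into a validated soft-label tuple."""
    if isinstance(members, (int,)):
        members = (members,)
    out = tuple(sorted(set(int(m) for m in members)))
    if not out:
        raise ValueError("a soft label must have at least one member class")
    return out


def is_crisp(label: tuple[int, ...]) -> bool:
    return len(label) == 1


def expand_class_list(labels: Sequence[tuple[int, ...]]) -> tuple[tuple[int, ...], ...]:
    """Distinct labels in canonical order: crisp first, then soft, each sorted.

    The order fixes the output-node semantics of an expert trained on the
    relabeled data, so it must be reproducible across runs.
    """
    distinct = {soft_label(lab) for lab in labels}
    return tuple(sorted(distinct, key=lambda m: (len(m) > 1, m)))


def format_label(label: tuple[int, ...]) -> str:
    return "|".join(str(m) for m in label)


def parse_label(text: str, valid_classes: Iterable[int] | None = None) -> tuple[int, ...]:
    lab = soft_label(int(tok) for tok in text.split("|"))
    if valid_classes is not None:
        valid = set(valid_classes)
        bad = [m for m in lab if m not in valid]
        if bad:
            raise ValueError(f"label members {bad} outside the known classes {sorted(valid)}")
    return lab
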
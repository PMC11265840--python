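"""HER2 score labels.

Clinical HER2 immunohistochemistry scores form an ordinal scale
0 < 1+ < 2+ < 3+ (ASCO/CAP). The integer values of :class:`ScoreLabel`
encode that order, so ``max()`` over labels is the clinical maximum score.
"""

from __future__ import annotations

import enum

__all__ = ["ScoreLabel", "NONDIAGNOSTIC", "CLASS_NAMES", "parse_score"]

#: Marker used in rating tables for cores a rater deemed non-scorable.
NONDIAGNOSTIC = "ND"

#: Display names in ordinal order; index == integer value of the label.
CLASS_NAMES = ("0", "1+", "2+", "3+")


class ScoreLabel(enum.IntEnum):
    """Ordinal HER2 IHC score category."""

    ZERO = 0
    ONE_PLUS = 1
    TWO_PLUS = 2
    THREE_PLUS = 3

    def __str__(self) -> str:
        return CLASS_NAMES[self.value]


def parse_score(text: str | int) -> ScoreLabel:
    """Parse a score symbol (``0``, ``1+``/``1``, ``2+``/``2``, ``3+``/``3``).

    Raises
    ------
    ValueError
        If the symbol is not a recognized HER2 score.
    """
    if isinstance(text, (int, ScoreLabel)) and not isinstance(text, bool):
        value = int(text)
    else:
        s = str(text).strip().rstrip("+")
        if not s.isdigit():
            raise ValueError(f"unknown HER2 score symbol: {text!r}")
        value = int(s)
    if value not in (0, 1, 2, 3):
        raise ValueError(f"unknown HER2 score symbol: {text!r}")
    return ScoreLabel(value)
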
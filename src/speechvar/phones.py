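"""ARPABET-style phone inventory.

Phone labels are expected in the convention emitted by English forced
aligners: upper-case ARPABET symbols, with vowels carrying a trailing stress
digit (1 = primary, 2 = secondary, 0 = unstressed), e.g. ``AA1``, ``IY0``.
Diadochokinetic annotations typically use the bare stop symbol plus a vowel.
"""

from __future__ import annotations

#: Monophthong and diphthong vowel nuclei.
VOWELS = frozenset(
    """AA AE AH AO AW AY EH ER EY IH IY OW OY UH UW""".split()
)

VOICELESS_STOPS = frozenset({"P", "T", "K"})
VOICED_STOPS = frozenset({"B", "D", "G"})
STOPS = VOICELESS_STOPS | VOICED_STOPS


def base_label(label: str) -> str:
    """Strip a trailing stress digit: ``'AA1' -> 'AA'``, ``'P' -> 'P'``."""
    if label and label[-1].isdigit():
        return label[:-1]
    return label


def stress_digit(label: str) -> int | None:
    """Trailing stress digit of a vowel label, or None when unmarked."""
    if label and label[-1].isdigit():
        return int(label[-1])
    return None


def is_vowel(label: str) -> bool:
    return base_label(label.upper()) in VOWELS


def is_stop(label: str, voicing: str | None = None) -> bool:
    """True when ``label`` is a stop; ``voicing`` narrows to one class."""
    b = base_label(label.upper())
    if voicing == "voiceless":
        return b in VOICELESS_STOPS
    if voicing == "voiced":
        return b in VOICED_STOPS
    return b in STOPS
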
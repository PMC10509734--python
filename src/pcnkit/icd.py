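"""ICD-10 code helpers: normalization, 3-digit stems, chapter assignment.

Diagnosis codes in hospital discharge records arrive as 3-digit category
codes with an optional 4th (or further) character extension, sometimes
dot-separated (``K56.7``).  All analysis in this package happens at the
3-digit level, so the helpers here normalize raw strings, truncate to the
category stem, and assign the standard ICD-10 chapter.
"""

from __future__ import annotations

import re

__all__ = [
    "normalize",
    "stem",
    "is_valid",
    "is_crc",
    "chapter",
    "CRC_STEMS",
]

#: Colorectal cancer category codes (colon, rectosigmoid, rectum, anus).
CRC_STEMS = ("C18", "C19", "C20", "C21")

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,4}$")


def normalize(code: str) -> str:
    """Uppercase, strip whitespace and dots; raise ``ValueError`` if malformed."""
    if code is None:
        raise ValueError("missing diagnosis code")
    cleaned = str(code).strip().upper().replace(".", "")
    if not _CODE_RE.match(cleaned):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return cleaned


def is_valid(code: str) -> bool:
    try:
        normalize(code)
    except ValueError:
        return False
    return True


def stem(code: str) -> str:
    """3-digit category stem of a (possibly extended) ICD-10 code."""
    return normalize(code)[:3]


def is_crc(code: str) -> bool:
    """True if the code falls in the colorectal cancer range C18-C21."""
    try:
        return stem(code) in CRC_STEMS
    except ValueError:
        return False


# (start stem, end stem, chapter numeral) — stems compare lexicographically
# because the format is one letter + two digits.
_CHAPTERS = (
    ("A00", "B99", "I"),
    ("C00", "D48", "II"),
    ("D50", "D89", "III"),
    ("E00", "E90", "IV"),
    ("F00", "F99", "V"),
    ("G00", "G99", "VI"),
    ("H00", "H59", "VII"),
    ("H60", "H95", "VIII"),
    ("I00", "I99", "IX"),
    ("J00", "J99", "X"),
    ("K00", "K93", "XI"),
    ("L00", "L99", "XII"),
    ("M00", "M99", "XIII"),
    ("N00", "N99", "XIV"),
    ("O00", "O99", "XV"),
    ("P00", "P96", "XVI"),
    ("Q00", "Q99", "XVII"),
    ("R00", "R99", "XVIII"),
    ("S00", "T98", "XIX"),
    ("U00", "U99", "XXII"),
    ("V01", "Y98", "XX"),
    ("Z00", "Z99", "XXI"),
)


def chapter(code: str) -> str:
    """ICD-10 chapter (Roman numeral) of a code's 3-digit stem."""
    s = stem(code)
    for lo, hi, numeral in _CHAPTERS:
        if lo <= s <= hi:
            return numeral
    raise ValueError(f"code outside ICD-10 chapter ranges: {code!r}")
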
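"""Normalization of HGVS protein-change strings to one-letter short form.

Variant annotations arrive in mixed conventions: ``p.Arg175His``,
``p.(R175H)``, ``Arg342Ter``, ``R342X``, ``p.Leu330ArgfsTer3``.  Hotspot
matching in the classifier is exact string equality, so every input is first
reduced to a canonical short form such as ``R175H``, ``R342*`` or
``L330Rfs*3``.  Normalization is idempotent: applying it to an already
normalized string is a no-op.
"""

from __future__ import annotations

import re

# Three-letter to one-letter amino-acid codes. Ter/X/* all denote a stop.
_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Sec": "U",
}

_AA3_RE = re.compile("|".join(_AA3_TO_1))


def normalize_protein_change(value: str | None) -> str:
    """Return the canonical one-letter HGVS short form of *value*.

    Strips a leading ``p.`` and surrounding parentheses, converts
    three-letter amino-acid codes to one-letter, and maps the stop-codon
    spellings ``Ter`` and ``X`` to ``*``.  Empty or missing annotations
    (splice variants typically have none) normalize to ``""``.

    >>> normalize_protein_change("p.Arg175His")
    'R175H'
    >>> normalize_protein_change("p.(Leu330ArgfsTer3)")
    'L330Rfs*3'
    >>> normalize_protein_change("R342X")
    'R342*'
    """
    if value is None:
        return ""
    s = value.strip()
    if not s or s in {".", "-", "?"}:
        return ""
    if s.startswith("p."):
        s = s[2:]
    s = s.strip("()")
    s = _AA3_RE.sub(lambda m: _AA3_TO_1[m.group(0)], s)
    # Stop codon spelled X: only when in a stop position (after a digit or
    # at the end of a frameshift tail), never inside e.g. "X93_splice".
    s = re.sub(r"(?<=\d)X(?=\d|$)", "*", s)
    s = re.sub(r"(?<=\d)X$", "*", s)
    return s


_CODON_RE = re.compile(r"^[A-Z*](\d+)")


def codon_number(protein_change: str) -> int | None:
    """Extract the (first) affected codon number from a normalized
    protein change, or None if it cannot be parsed."""
    m = _CODON_RE.match(normalize_protein_change(protein_change))
    return int(m.group(1)) if m else None
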
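"""Algebra of IUPAC nucleotide ambiguity codes.

Every IUPAC character denotes a non-empty subset of the plain bases
{A, C, G, T}.  A degenerate oligonucleotide written with these codes
stands for the Cartesian product of its per-position base sets; the size
of that pool is the *degeneracy* of the string.  This module provides
membership, degeneracy, expansion, complementation and primer-vs-template
base matching, plus a bitmask encoding used by the vectorised in silico
PCR scanner.

Input normalisation is deliberately tolerant: lowercase is accepted and
uppercased, and RNA 'U' is mapped to 'T'.  Gap characters ('-') are hard
errors everywhere here — gaps are an alignment concept and are handled by
the consensus machinery, never inside a primer.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np

__all__ = [
    "IupacError",
    "IUPAC_SETS",
    "normalize",
    "code_set",
    "code_for_set",
    "degeneracy",
    "degenerate_positions",
    "expand",
    "reverse_complement",
    "complement",
    "base_matches",
    "encode_mask",
    "decode_mask",
    "revcomp_mask",
    "POPCOUNT",
]


class IupacError(ValueError):
    """Raised for characters outside the IUPAC nucleotide alphabet."""


#: Base -> bit used in the mask encoding.
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}

#: Defining subsets of the 15 IUPAC nucleotide codes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE = {s: c for c, s in IUPAC_SETS.items()}
_CODE_TO_MASK = {c: sum(_BITS[b] for b in s) for c, s in IUPAC_SETS.items()}
_MASK_TO_CODE = {m: c for c, m in _CODE_TO_MASK.items()}

_PLAIN_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_COMPLEMENT = {
    c: _SET_TO_CODE[frozenset(_PLAIN_COMPLEMENT[b] for b in s)]
    for c, s in IUPAC_SETS.items()
}

#: popcount over the 16 possible 4-bit masks (index 0 = gap/empty).
POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.int64)

# byte translation tables for fast normalisation / validation
_NORM = {ord(c): c for c in IUPAC_SETS}
_NORM.update({ord(c.lower()): c for c in IUPAC_SETS})
_NORM.update({ord("u"): "T", ord("U"): "T"})

_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in _CODE_TO_MASK.items():
    _MASK_LUT[ord(_c)] = _m
    _MASK_LUT[ord(_c.lower())] = _m
_MASK_LUT[ord("U")] = _CODE_TO_MASK["T"]
_MASK_LUT[ord("u")] = _CODE_TO_MASK["T"]


def normalize(s: str, allow_gaps: bool = False) -> str:
    """Uppercase, map U->T and validate an IUPAC string.

    Raises :class:`IupacError` naming the first offending position.
    """
    out = []
    for i, ch in enumerate(s):
        if allow_gaps and ch == "-":
            out.append("-")
            continue
        norm = _NORM.get(ord(ch))
        if norm is None:
            raise IupacError(
                f"invalid IUPAC nucleotide character {ch!r} at position {i}"
            )
        out.append(norm)
    return "".join(out)


def code_set(base: str) -> frozenset[str]:
    """The defining plain-base subset of one IUPAC character."""
    if len(base) != 1:
        raise IupacError(f"expected a single character, got {base!r}")
    b = normalize(base)
    return IUPAC_SETS[b]


def code_for_set(bases: Iterable[str]) -> str:
    """The minimal IUPAC code whose set equals ``bases``."""
    key = frozenset(bases)
    try:
        return _SET_TO_CODE[key]
    except KeyError:
        raise IupacError(f"no IUPAC code for base set {sorted(key)!r}") from None


def _checked(s: str) -> str:
    if not s:
        raise IupacError("empty IUPAC string")
    return normalize(s)


def degeneracy(s: str) -> int:
    """Product of per-position code-set sizes (>= 1)."""
    s = _checked(s)
    d = 1
    for ch in s:
        d *= len(IUPAC_SETS[ch])
    return d


def degenerate_positions(s: str) -> int:
    """Number of positions whose code set has more than one base."""
    s = _checked(s)
    return sum(1 for ch in s if len(IUPAC_SETS[ch]) > 1)


def expand(s: str, limit: int = 1024) -> set[str]:
    """Full Cartesian expansion of a degenerate string into plain strings.

    Refuses (raises IupacError) when the degeneracy exceeds ``limit`` so a
    stray N-run cannot blow up memory.
    """
    s = _checked(s)
    d = degeneracy(s)
    if d > limit:
        raise IupacError(f"degeneracy {d} exceeds expansion limit {limit}")
    pools = [sorted(IUPAC_SETS[ch]) for ch in s]
    return {"".join(p) for p in itertools.product(*pools)}


def complement(s: str) -> str:
    """Per-code complement without reversal."""
    s = _checked(s)
    return "".join(_COMPLEMENT[ch] for ch in s)


def reverse_complement(s: str) -> str:
    """Reverse strand of a degenerate string (involution)."""
    return complement(s)[::-1]


def base_matches(primer_base: str, template_base: str, strict_template: bool = False) -> bool:
    """Does a primer base bind a template base?

    Intersection semantics: true iff the two code sets share a plain base.
    For a plain template base this reduces to membership in the primer's
    code set.  With ``strict_template`` the template must be plain A/C/G/T.
    """
    p = code_set(primer_base)
    t = code_set(template_base)
    if strict_template and len(t) != 1:
        raise IupacError(
            f"ambiguous template base {template_base!r} rejected in strict mode"
        )
    return not p.isdisjoint(t)


def encode_mask(s: str, allow_gaps: bool = False) -> np.ndarray:
    """Encode an IUPAC string as a uint8 bitmask array (A=1,C=2,G=4,T=8).

    Gap characters encode to 0 when ``allow_gaps`` is set, otherwise they
    (and any invalid character) raise :class:`IupacError`.
    """
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    masks = _MASK_LUT[arr]
    bad = masks == 0
    if bad.any():
        idx = int(np.argmax(bad))
        ch = s[idx]
        if ch == "-":
            if allow_gaps:
                ok = arr == ord("-")
                really_bad = bad & ~ok
                if really_bad.any():
                    idx = int(np.argmax(really_bad))
                    raise IupacError(
                        f"invalid IUPAC nucleotide character {s[idx]!r} at position {idx}"
                    )
                return masks
            raise IupacError(f"gap character at position {idx} not permitted here")
        raise IupacError(f"invalid IUPAC nucleotide character {ch!r} at position {idx}")
    return masks


def decode_mask(masks: np.ndarray, gap_char: str = "-") -> str:
    """Inverse of :func:`encode_mask`; mask 0 decodes to ``gap_char``."""
    return "".join(gap_char if m == 0 else _MASK_TO_CODE[int(m)] for m in masks)


def revcomp_mask(masks: np.ndarray) -> np.ndarray:
    """Reverse complement in mask space (swap bits A<->T and C<->G)."""
    m = masks.astype(np.uint8)
    comp = ((m & 1) << 3) | ((m & 8) >> 3) | ((m & 2) << 1) | ((m & 4) >> 1)
    return comp[::-1].astype(np.uint8)
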
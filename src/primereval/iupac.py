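"""IUPAC nucleotide alphabet tables shared across the package.

Two distinct per-character conventions coexist:

* ``DEGENERACY_SETS`` drives degeneracy and expansion.  Inosine (I) is a
  single synthesized base, so it contributes multiplicity 1.
* ``MATCH_SETS`` drives pattern matching.  Inosine behaves as a universal
  base there and matches any of A/C/G/T.
"""

from __future__ import annotations

import numpy as np

#: Primer alphabet (degenerate IUPAC codes plus inosine).
PRIMER_ALPHABET = frozenset("ACGTRYSWKMBDHVNI")

#: Characters accepted on the target side (no inosine in databases).
TARGET_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

GAP_CHARS = frozenset("-.")

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: base sets used for degeneracy / expansion (I kept as the literal base I)
DEGENERACY_SETS = {**{c: frozenset(s) for c, s in _IUPAC_SETS.items()},
                   "I": frozenset("I")}

#: base sets used for matching (I is a universal base)
MATCH_SETS = {**{c: frozenset(s) for c, s in _IUPAC_SETS.items()},
              "I": frozenset("ACGT")}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N", "I": "I",
}


def complement_char(c: str) -> str:
    try:
        return _COMPLEMENT[c]
    except KeyError:
        raise ValueError(f"cannot complement non-IUPAC character {c!r}") from None


def reverse_complement_seq(seq: str) -> str:
    """Reverse complement of an IUPAC-degenerate sequence string."""
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


# 4-bit encodings: A=1, C=2, G=4, T=8.  A zero mask never matches (gaps).
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}


def _mask(chars: frozenset) -> int:
    return sum(_BIT[c] for c in chars if c in _BIT)


#: 256-entry lookup: ASCII code of a target character -> base-set bitmask.
TARGET_MASKS = np.zeros(256, dtype=np.uint8)
for _c, _s in MATCH_SETS.items():
    if _c != "I":
        TARGET_MASKS[ord(_c)] = _mask(_s)
        TARGET_MASKS[ord(_c.lower())] = _mask(_s)

#: pattern-character -> bitmask under matching semantics (I -> 0b1111)
PATTERN_MASKS = {c: _mask(s) for c, s in MATCH_SETS.items()}


def pattern_mask_array(seq: str) -> np.ndarray:
    """Encode a primer sequence as an array of match bitmasks."""
    return np.array([PATTERN_MASKS[c] for c in seq], dtype=np.uint8)


def target_mask_array(seq: str) -> np.ndarray:
    """Encode an ungapped target sequence as an array of base bitmasks."""
    return TARGET_MASKS[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
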
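"""Genotype call codes shared across the package.

RIL genotype matrices are coded with four single-character symbols:

======  =====  ==============================================
symbol  int    meaning
======  =====  ==============================================
``A``   0      homozygous for the common-parent allele (P1)
``B``   1      homozygous for the alternate-parent allele (P2)
``H``   2      heterozygous
``N``   3      missing call
======  =====  ==============================================

Internally matrices are ``int8`` arrays using the integer codes; text files
use the characters.
"""

from __future__ import annotations

import numpy as np

P1: int = 0
P2: int = 1
HET: int = 2
MISSING: int = 3

CHARS: str = "ABHN"

_CHAR_TO_CODE = {c: i for i, c in enumerate(CHARS)}


def encode(chars: "np.ndarray | list[str]") -> np.ndarray:
    """Map an array of call characters to int8 codes.

    Raises ``ValueError`` naming the first offending symbol.
    """
    arr = np.asarray(chars)
    out = np.empty(arr.shape, dtype=np.int8)
    flat_in = arr.ravel()
    flat_out = out.ravel()
    for i, c in enumerate(flat_in):
        try:
            flat_out[i] = _CHAR_TO_CODE[c]
        except KeyError:
            raise ValueError(f"unknown genotype code {c!r}") from None
    return out


def decode(codes: np.ndarray) -> np.ndarray:
    """Map int8 codes back to the character representation."""
    lut = np.array(list(CHARS))
    return lut[np.asarray(codes, dtype=np.int8)]
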
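"""Nucleotide alphabet used throughout: A,C,G,T coded 0-3, everything else missing.

Lowercase bases are uppercased on input.  ``N`` and the gap character ``-``
are both treated as missing data: deletions carry no substitution signal and
are handled by the standard all-ones partial-likelihood convention.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
MISSING = 4
N_STATES = 4

#: byte -> code lookup (everything not ACGTacgt maps to MISSING)
_LUT = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

#: code -> character (missing rendered as N)
DECODE = np.frombuffer(b"ACGTN", dtype="S1")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a sequence string into uint8 codes (0-3 bases, 4 missing)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an ACGTN string."""
    return DECODE[codes].tobytes().decode("ascii")
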
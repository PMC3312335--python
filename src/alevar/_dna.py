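"""Internal DNA string/array helpers shared across modules.

Bases are encoded as uint8 codes A=0, C=1, G=2, T=3, N=4 for numpy
vectorized work; everything user-facing stays as plain ACGT strings.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
CODE_N = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte value -> code lookup (everything unexpected maps to N)
_ENCODE_LUT = np.full(256, CODE_N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)

# code -> complement code (N stays N)
COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string to uint8 codes."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an ACGTN string."""
    return _DECODE_LUT[codes].tobytes().decode("ascii")
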
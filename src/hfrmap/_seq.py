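"""Nucleotide encoding helpers.

Sequences are held internally as uint8 code arrays (A=0, C=1, G=2, T=3,
anything else = 4) so that simulation and k-mer placement are vectorised.
"""
from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
N_CODE = 4

_ENC = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an upper-case string."""
    return _DEC[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def mutate_codes(rng: np.random.Generator, codes: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Substitute each given position with a uniformly chosen different base."""
    out = codes.copy()
    shift = rng.integers(1, 4, size=positions.size, dtype=np.uint8)
    out[positions] = (out[positions] + shift) % 4
    return out
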
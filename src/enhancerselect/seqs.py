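"""Small shared helpers for DNA sequences.

Sequences are plain Python strings over the alphabet ``ACGT`` (plus ``N``
for uncertain bases in raw genomes).  Internally most numerics work on
integer codes A=0, C=1, G=2, T=3.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_ARRAY = np.frombuffer(b"ACGT", dtype=np.uint8)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class SequenceError(ValueError):
    """Raised for sequences outside the expected alphabet."""


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3).

    Raises :class:`SequenceError` on any character outside ``ACGTacgt``
    (including ``N``).
    """
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(arr == 255)[0][:5]})
        raise SequenceError(f"non-ACGT character(s) in sequence: {bad}")
    return arr


def decode(codes: np.ndarray) -> str:
    return BASE_ARRAY[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def has_n(seq: str) -> bool:
    return "N" in seq or "n" in seq


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """An i.i.d. random DNA string with expected GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p))
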
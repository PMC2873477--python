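"""Shared nucleotide-alphabet helpers.

Sequences are uppercase strings over {A, C, G, T, N}.  For numeric work they
are encoded as int8 arrays with A=0, C=1, G=2, T=3 and N=4; the encoding of
the complement of base ``b`` is ``3 - b``, so reverse complementation of an
encoded array is ``(3 - enc)[::-1]`` (N maps to -1 under that rule and is
handled separately).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_INDEX = 4

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
_ENC[ord("N")] = N_INDEX

_DECODE = np.array(list(BASES + "N"))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N self-paired)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase DNA string as int8 (A=0, C=1, G=2, T=3, N=4)."""
    enc = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if enc.size and enc.min() < 0:
        bad = sorted({c for c in seq if c not in "ACGTN"})
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return enc


def decode(enc: np.ndarray) -> str:
    return "".join(_DECODE[np.asarray(enc)])


def background_from_gc(gc: float) -> np.ndarray:
    """Strand-symmetric mononucleotide background for a given GC fraction."""
    if not 0.0 < gc < 1.0:
        raise ValueError(f"GC fraction must be in (0, 1), got {gc}")
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_sequence(length: int, background: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. encoded sequence drawn from a 4-vector of base probabilities."""
    q = np.asarray(background, dtype=float)
    return rng.choice(4, size=length, p=q / q.sum()).astype(np.int8)
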
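"""Small DNA-sequence helpers shared across modules.

Sequences are plain Python strings over the alphabet ``ACGT``; numeric work
uses uint8 index arrays with the fixed base order A=0, C=1, G=2, T=3.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# lookup table: ASCII byte -> base index (255 = invalid)
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 index array (A=0, C=1, G=2, T=3)."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"invalid base {bad!r} in sequence (alphabet is ACGT)")
    return arr


def encode_many(seqs) -> np.ndarray:
    """Encode equal-length DNA strings into an (n, L) uint8 array."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    joined = "".join(seqs)
    return encode(joined).reshape(len(seqs), lengths.pop())


def decode(indices: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    arr = np.asarray(indices)
    return "".join(BASES[i] for i in arr.tolist())


def validate_dna(seq: str, name: str = "sequence") -> str:
    """Upper-case ``seq`` and check the ACGT alphabet; return the clean string."""
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in BASE_INDEX:
            raise ValueError(f"{name}: invalid base {ch!r} at position {pos}")
    return seq


def one_hot(encoded: np.ndarray) -> np.ndarray:
    """One-hot encode an (n, L) index array to (n, L, 4) float64."""
    encoded = np.asarray(encoded)
    out = np.zeros(encoded.shape + (4,), dtype=np.float64)
    np.put_along_axis(out, encoded[..., None].astype(np.intp), 1.0, axis=-1)
    return out
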
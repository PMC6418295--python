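"""Low-level sequence utilities shared across modules.

Sequences are handled either as Python strings (IO boundary) or as numpy
uint8 code arrays (A=0, C=1, G=2, T=3, N=4) for vectorised scanning.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_COMP_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """String -> uint8 code array (anything not ACGT becomes 4 / N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP_CODE[arr][::-1]


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random sequence with expected GC content ``gc`` (independent bases)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mer codes for every window of ``arr``.

    Returns ``(codes, valid)`` where ``valid[i]`` is False when the window
    contains an N. Requires ``k <= 31`` so codes fit in uint64.
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    a = arr.astype(np.uint64)
    m = n - k + 1
    code = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        code = (code << np.uint64(2)) | (a[j:j + m] & np.uint64(3))
    is_n = (arr == 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cs[k:] - cs[:-k]) == 0
    return code, valid


def spawn_rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic child generator for a labelled subtask of ``seed``.

    Labels are hashed with crc32 so the stream is stable across processes
    (unlike builtin ``hash`` on strings).
    """
    import zlib

    key = tuple(zlib.crc32(str(l).encode()) for l in labels)
    ss = np.random.SeedSequence(seed, spawn_key=key)
    return np.random.default_rng(ss)
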
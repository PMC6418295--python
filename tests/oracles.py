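"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: a two-pointer
per-base diff for insertion discovery, brute-force enumeration for Nxx,
and direct counting for interval coverage.
"""

from __future__ import annotations

import numpy as np


def diff_insertions(ref: str, qry: str, qgap_min: int = 1000,
                    resync: int = 50) -> list[tuple[int, int, int]]:
    """Per-base diff of two sequences differing only by insertions in ``qry``.

    Walks both sequences in lock-step; at the first mismatch, scans the
    query forward for the next ``resync``-mer of the reference. Returns
    (ref_pos_0based, qry_pos_0based, length) per insertion > ``qgap_min``.
    """
    a = np.frombuffer(ref.encode(), dtype=np.uint8)
    b = np.frombuffer(qry.encode(), dtype=np.uint8)
    out = []
    r = q = 0
    nr, nq = a.size, b.size
    while r < nr and q < nq:
        n = min(nr - r, nq - q)
        diff = a[r:r + n] != b[q:q + n]
        i = int(np.argmax(diff))
        if not diff[i]:
            r += n
            q += n
            break
        r += i
        q += i
        probe = ref[r:r + resync]
        j = qry.find(probe, q)
        if j < 0:
            raise AssertionError("cannot resync: sequences differ by more than insertions")
        ins = j - q
        if ins > qgap_min:
            out.append((r, q, ins))
        q = j
    if (nq - q) - (nr - r) > qgap_min:
        out.append((r, q, (nq - q) - (nr - r)))
    return out


def brute_nxx(lengths: list[int], x: float) -> int:
    """Nxx by explicit enumeration: the largest member length L such that
    pieces of at least L cover >= x% of the total."""
    total = sum(lengths)
    for L in sorted(set(lengths), reverse=True):
        if sum(l for l in lengths if l >= L) >= total * x / 100.0:
            return L
    return min(lengths)


def coverage_union(intervals: list[tuple[int, int]], lo: int, hi: int) -> int:
    """Covered bases of [lo, hi] (1-based inclusive) by marking an array."""
    mask = np.zeros(hi - lo + 1, dtype=bool)
    for s, e in intervals:
        a, b = max(s, lo), min(e, hi)
        if b >= a:
            mask[a - lo:b - lo + 1] = True
    return int(mask.sum())


def exhaustive_map_alignment(a: list[int], b: list[int], tol: float) -> int:
    """Maximum number of label matches between two small maps, by exhaustive
    search over monotone index pairings with per-interval tolerance."""
    from functools import lru_cache

    na, nb = len(a), len(b)

    @lru_cache(maxsize=None)
    def best(i, j, pi, pj):
        # i, j: next candidate indices; pi, pj: previous matched pair (or -1)
        if i >= na or j >= nb:
            return 0
        res = max(best(i + 1, j, pi, pj), best(i, j + 1, pi, pj))
        ok = True
        if pi >= 0:
            da = a[i] - a[pi]
            db = b[j] - b[pj]
            ok = abs(da - db) <= tol * max(i - pi, j - pj)
        if ok:
            res = max(res, 1 + best(i + 1, j + 1, i, j))
        return res

    return best(0, 0, -1, -1)
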
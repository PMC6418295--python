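"""Assembly evaluation: Nxx statistics, windowed tracks, telomere and
centromere detection, and in silico PCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import encode, revcomp


def nxx(lengths: list[int], x: float = 50) -> int:
    """Smallest length L such that pieces >= L sum to >= x% of the total.

    N50 is ``nxx(lengths, 50)``, N90 ``nxx(lengths, 90)``.
    """
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    ls = sorted(lengths, reverse=True)
    target = sum(ls) * x / 100.0
    acc = 0
    for l in ls:
        acc += l
        if acc >= target:
            return l
    return ls[-1]


def window_track(
    features: list[tuple[int, int]],
    chrom_len: int,
    window: int = 1_000_000,
    step: int = 500_000,
) -> list[tuple[int, int, float, bool]]:
    """Occupancy fraction of unioned features per sliding window.

    Features are 1-based inclusive intervals. Windows start at 1 and slide
    by ``step``; the final partial window is normalised by its actual span
    and flagged. Returns (start, end, fraction, partial) per window.
    """
    if window < step:
        raise ValueError("window must be >= step")
    cov = np.zeros(chrom_len + 2, dtype=np.int32)
    for s, e in features:
        s, e = max(1, s), min(chrom_len, e)
        if e >= s:
            cov[s] += 1
            cov[e + 1] -= 1
    covered = (np.cumsum(cov)[1:chrom_len + 1] > 0)
    cum = np.concatenate([[0], np.cumsum(covered)])
    out = []
    start = 1
    while start <= chrom_len:
        end = min(start + window - 1, chrom_len)
        n_cov = int(cum[end] - cum[start - 1])
        span = end - start + 1
        out.append((start, end, n_cov / span, span < window))
        if end == chrom_len:
            break
        start += step
    return out


def gc_track(seq: str, window: int = 200_000) -> list[tuple[int, int, float]]:
    """GC fraction over non-N bases per non-overlapping window.

    All-N windows get ``nan``. Returns (start, end, gc) per window, 1-based.
    """
    arr = encode(seq)
    is_gc = ((arr == 1) | (arr == 2)).astype(np.int64)
    not_n = (arr < 4).astype(np.int64)
    out = []
    for start in range(0, arr.size, window):
        end = min(start + window, arr.size)
        denom = int(not_n[start:end].sum())
        gc = float(is_gc[start:end].sum()) / denom if denom else float("nan")
        out.append((start + 1, end, gc))
    return out


@dataclass
class TelomereStatus:
    chrom: str
    start_end: bool
    distal_end: bool
    arrays: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, copies)

    @property
    def category(self) -> str:
        n = int(self.start_end) + int(self.distal_end)
        return {0: "none", 1: "single", 2: "both"}[n]


def _tandem_arrays(arr: np.ndarray, motif: np.ndarray, max_mismatch: int,
                   min_copies: int) -> list[tuple[int, int, int]]:
    """Maximal tandem arrays of >= min_copies motif copies (<=1 mismatch each).

    Copies must be exactly motif-length apart. Returns 1-based intervals.
    """
    m = motif.size
    n = arr.size
    if n < m:
        return []
    # mismatch count of a motif copy starting at each position
    mm = np.zeros(n - m + 1, dtype=np.int16)
    for j in range(m):
        mm += arr[j:j + n - m + 1] != motif[j]
    ok = mm <= max_mismatch
    arrays = []
    i = 0
    while i < ok.size:
        if not ok[i]:
            i += 1
            continue
        copies = 1
        j = i                       # start of the last accepted copy
        while j + m <= n - m and ok[j + m]:
            copies += 1
            j += m
        if copies >= min_copies:
            arrays.append((i + 1, j + m, copies))   # 1-based inclusive span
        i = j + m
    return arrays


def detect_telomeres(
    chrom: str,
    seq: str,
    motif: str = "CCCTAAA",
    terminal_window: int = 10_000,
    min_copies: int = 10,
    max_mismatch_per_copy: int = 1,
) -> TelomereStatus:
    """Find telomeric tandem-repeat arrays at chromosome ends.

    Both strands are scanned (the motif on one end appears as its reverse
    complement on the other); an end is telomeric when a tandem array of at
    least ``min_copies`` consecutive motif copies, each with at most one
    mismatch, lies entirely within ``terminal_window`` of that end.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    arr = encode(seq)
    arrays: list[tuple[int, int, int]] = []
    for mot in {motif, revcomp(motif)}:
        arrays.extend(_tandem_arrays(arr, encode(mot), max_mismatch_per_copy,
                                     min_copies))
    arrays.sort()
    n = arr.size
    start_end = any(e <= terminal_window for s, e, c in arrays)
    distal_end = any(s > n - terminal_window for s, e, c in arrays)
    keep = [(s, e, c) for s, e, c in arrays
            if e <= terminal_window or s > n - terminal_window]
    return TelomereStatus(chrom, start_end, distal_end, keep)


def detect_centromeric_repeats(
    seq: str,
    monomer: str,
    min_identity: float = 0.8,
    min_span: int = 1000,
) -> list[tuple[int, int]]:
    """Find arrays of a centromeric repeat monomer by direct identity scan.

    The monomer is compared (both strands) against every genome offset; hits
    at >= ``min_identity`` are merged when within one monomer length, and
    merged spans of at least ``min_span`` bp are reported (1-based).
    """
    if len(monomer) < 20:
        raise ValueError("monomer must be >= 20 bp")
    arr = encode(seq)
    m = len(monomer)
    n = arr.size
    if n < m:
        return []
    hits = []
    for mot in {monomer, revcomp(monomer)}:
        mo = encode(mot)
        match = np.zeros(n - m + 1, dtype=np.int32)
        for j in range(m):
            match += arr[j:j + n - m + 1] == mo[j]
        hits.append(np.flatnonzero(match >= min_identity * m))
    pos = np.unique(np.concatenate(hits))
    if pos.size == 0:
        return []
    out = []
    s = e = int(pos[0])
    for p in pos[1:]:
        if p - e <= m:
            e = int(p)
        else:
            out.append((s + 1, e + m))
            s = e = int(p)
    out.append((s + 1, e + m))
    return [(a, b) for a, b in out if b - a + 1 >= min_span]


# ---------------------------------------------------------------------------
# in silico PCR
# ---------------------------------------------------------------------------


@dataclass
class PrimerPair:
    id: str
    forward: str
    reverse: str

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if len(p) < 15:
                raise ValueError(f"primer {self.id}: length < 15")
            if set(p.upper()) - set("ACGT"):
                raise ValueError(f"primer {self.id}: degenerate bases not supported")


@dataclass
class PCRHit:
    chrom: str
    start: int      # 1-based product interval (5' end of plus-strand primer ...)
    end: int
    product_size: int
    fwd_primer: str  # which primer ('forward'/'reverse') matched the plus strand


def _primer_sites(genome_arrs: dict[str, np.ndarray], primer: str,
                  max_mismatch: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Plus/minus-strand binding 0-based start offsets per chromosome.

    A site must have <= max_mismatch mismatches overall and an exact match
    over the primer's three 3'-terminal bases.
    """
    p = encode(primer)
    prc = encode(revcomp(primer))
    m = p.size
    out = {}
    for chrom, arr in genome_arrs.items():
        n = arr.size
        if n < m:
            out[chrom] = (np.empty(0, np.int64), np.empty(0, np.int64))
            continue
        mm_p = np.zeros(n - m + 1, dtype=np.int32)
        tail_p = np.zeros(n - m + 1, dtype=np.int32)
        mm_m = np.zeros(n - m + 1, dtype=np.int32)
        tail_m = np.zeros(n - m + 1, dtype=np.int32)
        for j in range(m):
            dp = (arr[j:j + n - m + 1] != p[j]).astype(np.int32)
            dm = (arr[j:j + n - m + 1] != prc[j]).astype(np.int32)
            mm_p += dp
            mm_m += dm
            if j >= m - 3:
                tail_p += dp
            if j < 3:    # revcomp primer: its 3' end sits at the window start
                tail_m += dm
        plus = np.flatnonzero((mm_p <= max_mismatch) & (tail_p == 0))
        minus = np.flatnonzero((mm_m <= max_mismatch) & (tail_m == 0))
        out[chrom] = (plus.astype(np.int64), minus.astype(np.int64))
    return out


def in_silico_pcr(
    genome: dict[str, str],
    pairs: list[PrimerPair],
    max_product: int = 1000,
    max_mismatch: int = 2,
) -> tuple[dict[str, PCRHit], dict[str, str]]:
    """Electronic PCR with orientation, size and uniqueness filters.

    For each pair, all binding sites of both primers on both strands are
    found (<= ``max_mismatch`` mismatches, exact 3'-terminal trinucleotide).
    A product is a plus-strand site of one primer and a downstream
    minus-strand site of the other with 3' ends facing and product size
    < ``max_product`` (strict). Pairs with exactly one product are retained;
    pairs with zero or multiple products are reported with the reason.

    Returns ``(retained: id -> PCRHit, rejected: id -> reason)``. The result
    does not depend on primer-pair order or chromosome order.
    """
    arrs = {c: encode(s) for c, s in genome.items()}
    retained: dict[str, PCRHit] = {}
    rejected: dict[str, str] = {}
    for pair in pairs:
        fsites = _primer_sites(arrs, pair.forward, max_mismatch)
        rsites = _primer_sites(arrs, pair.reverse, max_mismatch)
        products: list[PCRHit] = []
        for chrom in sorted(arrs):
            for a_name, a_sites, b_sites, b_len in (
                ("forward", fsites[chrom][0], rsites[chrom][1], len(pair.reverse)),
                ("reverse", rsites[chrom][0], fsites[chrom][1], len(pair.forward)),
            ):
                for s in a_sites:
                    for t in b_sites:
                        end = int(t) + b_len  # product end (exclusive, 0-based)
                        size = end - int(s)
                        if size > 0 and size < max_product and t >= s:
                            products.append(PCRHit(chrom, int(s) + 1, end, size, a_name))
        if len(products) == 1:
            retained[pair.id] = products[0]
        elif not products:
            rejected[pair.id] = "no_hit"
        else:
            rejected[pair.id] = f"multiple_hits({len(products)})"
    return retained, rejected
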
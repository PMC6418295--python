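"""Whole-genome alignment blocks: parsing, a built-in unique-anchor aligner,
and adjacency pairing.

The internal coordinate convention is 1-based inclusive on both genomes
(the `show-coords` convention); PAF input is converted at the boundary.
Minus-strand query intervals are normalised to start <= end with the strand
kept in a separate field.

The anchor aligner stands in for an external whole-genome aligner run with
unique-match, no-extension settings: it finds k-mers that occur exactly once
in each genome (either strand of the query), collapses diagonal runs, chains
co-linear runs per (ref chromosome, query chromosome, strand) and merges
them into blocks. Blocks therefore break exactly at insertions, inversions
and translocation boundaries, which is what the downstream event calling
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .util import encode, kmer_codes, revcomp


@dataclass
class AlignmentBlock:
    ref_chrom: str
    ref_start: int      # 1-based inclusive
    ref_end: int
    qry_chrom: str
    qry_start: int      # 1-based inclusive, start <= end regardless of strand
    qry_end: int
    strand: str         # '+' or '-'
    identity: float = 1.0

    def __post_init__(self):
        if self.ref_start > self.ref_end or self.qry_start > self.qry_end:
            raise ValueError(f"inverted interval in block {self}")
        if not 0 <= self.identity <= 1:
            raise ValueError(f"identity {self.identity} outside [0,1]")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def qry_span(self) -> int:
        return self.qry_end - self.qry_start + 1


@dataclass
class AdjacentPair:
    left: AlignmentBlock
    right: AlignmentBlock
    ref_gap: int    # signed; negative = overlap
    qry_gap: int


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------


def read_alignment_blocks(path, dialect: str) -> list[AlignmentBlock]:
    """Read blocks from `show-coords -rcl -T` output or PAF.

    PAF's 0-based half-open coordinates are shifted to 1-based inclusive;
    coords identity percentages are converted to fractions.
    """
    if dialect not in ("coords", "paf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            try:
                if dialect == "paf":
                    qname, _qlen, qs, qe = f[0], int(f[1]), int(f[2]), int(f[3])
                    strand = f[4]
                    rname, _rlen, rs, re_ = f[5], int(f[6]), int(f[7]), int(f[8])
                    nmatch, alen = int(f[9]), int(f[10])
                    blocks.append(AlignmentBlock(
                        rname, rs + 1, re_, qname, qs + 1, qe, strand,
                        identity=nmatch / alen if alen else 0.0))
                else:
                    # show-coords -T columns: S1 E1 S2 E2 LEN1 LEN2 %IDY ... refname qryname
                    if not f[0].lstrip("-").isdigit():
                        continue  # header lines
                    s1, e1, s2, e2 = int(f[0]), int(f[1]), int(f[2]), int(f[3])
                    idy = float(f[6]) / 100.0
                    rname, qname = f[-2], f[-1]
                    strand = "+" if s2 <= e2 else "-"
                    qs, qe = (s2, e2) if s2 <= e2 else (e2, s2)
                    blocks.append(AlignmentBlock(rname, s1, e1, qname, qs, qe, strand, idy))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed {dialect} line {ln}: {exc}") from exc
    return blocks


def write_blocks_tsv(blocks: list[AlignmentBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_chrom\tref_start\tref_end\tqry_chrom\tqry_start\tqry_end\tstrand\tidentity\n")
        for b in blocks:
            fh.write(f"{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t{b.qry_chrom}\t"
                     f"{b.qry_start}\t{b.qry_end}\t{b.strand}\t{b.identity:.6f}\n")


def read_blocks_tsv(path) -> list[AlignmentBlock]:
    blocks = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("ref_chrom")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            blocks.append(AlignmentBlock(f[0], int(f[1]), int(f[2]), f[3],
                                         int(f[4]), int(f[5]), f[6], float(f[7])))
    return blocks


def write_paf(blocks: list[AlignmentBlock], path,
              ref_lens: dict[str, int] | None = None,
              qry_lens: dict[str, int] | None = None) -> None:
    ref_lens = ref_lens or {}
    qry_lens = qry_lens or {}
    with open(path, "w") as fh:
        for b in blocks:
            alen = max(b.ref_span, b.qry_span)
            nmatch = int(round(b.identity * alen))
            fh.write(f"{b.qry_chrom}\t{qry_lens.get(b.qry_chrom, b.qry_end)}\t"
                     f"{b.qry_start - 1}\t{b.qry_end}\t{b.strand}\t"
                     f"{b.ref_chrom}\t{ref_lens.get(b.ref_chrom, b.ref_end)}\t"
                     f"{b.ref_start - 1}\t{b.ref_end}\t{nmatch}\t{alen}\t60\n")


# ---------------------------------------------------------------------------
# unique-anchor alignment
# ---------------------------------------------------------------------------


def _unique_kmer_table(seqs: dict[str, np.ndarray], k: int):
    """Codes unique across all chromosomes, with (chrom index, offset)."""
    codes, chrom_idx, offsets = [], [], []
    for ci, arr in enumerate(seqs.values()):
        c, valid = kmer_codes(arr, k)
        idx = np.flatnonzero(valid)
        codes.append(c[idx])
        chrom_idx.append(np.full(idx.size, ci, dtype=np.int32))
        offsets.append(idx.astype(np.int64))
    if not codes:
        return (np.empty(0, np.uint64),) * 3
    codes = np.concatenate(codes)
    chrom_idx = np.concatenate(chrom_idx)
    offsets = np.concatenate(offsets)
    order = np.argsort(codes, kind="stable")
    codes, chrom_idx, offsets = codes[order], chrom_idx[order], offsets[order]
    # keep codes occurring exactly once
    uniq = np.ones(codes.size, dtype=bool)
    if codes.size > 1:
        dup = codes[1:] == codes[:-1]
        uniq[1:] &= ~dup
        uniq[:-1] &= ~dup
    return codes[uniq], chrom_idx[uniq], offsets[uniq]


def _max_weight_chain(q0: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Max-weight chain of segments with strictly increasing query order.

    Segments arrive sorted by reference position; a Fenwick max-tree over
    query ranks gives the heaviest co-linear subsequence in O(n log n).
    Returns the chained indices in input order.
    """
    n = q0.size
    rank = np.empty(n, dtype=np.int64)
    rank[np.argsort(q0, kind="stable")] = np.arange(n)
    tree_val = np.zeros(n + 1)
    tree_idx = np.full(n + 1, -1, dtype=np.int64)
    prev = np.full(n, -1, dtype=np.int64)
    dp = np.zeros(n)
    best_i = -1
    for i in range(n):
        # query prefix max over ranks < rank[i]
        j = rank[i]
        bv, bi = 0.0, -1
        while j > 0:
            if tree_val[j] > bv:
                bv, bi = tree_val[j], tree_idx[j]
            j -= j & (-j)
        dp[i] = bv + weights[i]
        prev[i] = bi
        j = rank[i] + 1
        while j <= n:
            if dp[i] > tree_val[j]:
                tree_val[j] = dp[i]
                tree_idx[j] = i
            j += j & (-j)
        if best_i < 0 or dp[i] > dp[best_i]:
            best_i = i
    out = []
    i = best_i
    while i >= 0:
        out.append(i)
        i = prev[i]
    return np.array(out[::-1], dtype=np.int64)


def anchor_align(
    ref_genome: dict[str, str],
    qry_genome: dict[str, str],
    k: int = 21,
    min_anchor: int = 0,
    min_chain: int = 500,
    indel_slop: int = 20,
    max_merge_gap: int = 20_000,
) -> list[AlignmentBlock]:
    """Align two genomes via k-mers unique in both, chained into blocks.

    Anchors on the query minus strand are found by matching reference k-mers
    against the reverse complement of each query chromosome. Diagonal runs
    of anchors are collapsed, outliers removed by longest-increasing-
    subsequence chaining per (ref chrom, qry chrom, strand), and consecutive
    runs merged into one block while the reference and query gaps agree
    within ``indel_slop`` bp (pure substitution gaps). Blocks shorter than
    ``min_chain`` on the reference are discarded.
    """
    if k < 15:
        raise ValueError("k must be >= 15")
    ref_names = list(ref_genome)
    qry_names = list(qry_genome)
    ref_arrs = {c: encode(s) for c, s in ref_genome.items()}
    if not ref_genome or not qry_genome:
        return []

    r_codes, r_chrom, r_off = _unique_kmer_table(ref_arrs, k)

    # query: forward and reverse-complement k-mer tables combined so
    # uniqueness is enforced across both strands
    q_arr_fwd = {c: encode(s) for c, s in qry_genome.items()}
    q_codes_all, q_meta = [], []   # meta: (chrom idx, offset, strand)
    for ci, cname in enumerate(qry_names):
        arr = q_arr_fwd[cname]
        c, valid = kmer_codes(arr, k)
        idx = np.flatnonzero(valid)
        q_codes_all.append(c[idx])
        q_meta.append((np.full(idx.size, ci, np.int32), idx.astype(np.int64),
                       np.zeros(idx.size, np.int8)))
        rc = encode(revcomp(qry_genome[cname]))
        c2, valid2 = kmer_codes(rc, k)
        idx2 = np.flatnonzero(valid2)
        q_codes_all.append(c2[idx2])
        q_meta.append((np.full(idx2.size, ci, np.int32), idx2.astype(np.int64),
                       np.ones(idx2.size, np.int8)))
    q_codes = np.concatenate(q_codes_all)
    q_chrom = np.concatenate([m[0] for m in q_meta])
    q_off = np.concatenate([m[1] for m in q_meta])
    q_strand = np.concatenate([m[2] for m in q_meta])
    order = np.argsort(q_codes, kind="stable")
    q_codes, q_chrom, q_off, q_strand = (q_codes[order], q_chrom[order],
                                         q_off[order], q_strand[order])
    uniq = np.ones(q_codes.size, dtype=bool)
    if q_codes.size > 1:
        dup = q_codes[1:] == q_codes[:-1]
        uniq[1:] &= ~dup
        uniq[:-1] &= ~dup
    q_codes, q_chrom, q_off, q_strand = (q_codes[uniq], q_chrom[uniq],
                                         q_off[uniq], q_strand[uniq])

    # join unique ref codes with unique qry codes
    pos = np.searchsorted(q_codes, r_codes)
    pos_c = np.clip(pos, 0, max(q_codes.size - 1, 0))
    hit = (q_codes.size > 0) & (q_codes[pos_c] == r_codes)
    ri = np.flatnonzero(hit)
    qi = pos_c[ri]

    blocks: list[AlignmentBlock] = []
    qry_lens = {c: len(qry_genome[c]) for c in qry_names}

    # process per (ref chrom, qry chrom, strand)
    keys = (r_chrom[ri].astype(np.int64) * 2 * len(qry_names)
            + q_chrom[qi].astype(np.int64) * 2 + q_strand[qi])
    for key in np.unique(keys):
        sel = keys == key
        rc_i = int(key // (2 * len(qry_names)))
        qc_i = int((key % (2 * len(qry_names))) // 2)
        strand = "-" if key % 2 else "+"
        rpos = r_off[ri[sel]]           # 0-based offsets on ref
        qpos = q_off[qi[sel]]           # 0-based on fwd (or rc) query strand
        order2 = np.argsort(rpos, kind="stable")
        rpos, qpos = rpos[order2], qpos[order2]
        if rpos.size == 0:
            continue
        # collapse diagonal runs (consecutive in both)
        same_run = np.diff(rpos) == 1
        same_run &= np.diff(qpos) == 1
        run_start = np.flatnonzero(np.concatenate([[True], ~same_run]))
        run_end = np.concatenate([run_start[1:], [rpos.size]]) - 1
        seg_r0, seg_r1 = rpos[run_start], rpos[run_end] + k - 1
        seg_q0, seg_q1 = qpos[run_start], qpos[run_end] + k - 1
        # iterative co-linear chaining: extract the heaviest chain with
        # query order increasing along the reference, set it aside, repeat —
        # so displaced runs (translocations) survive as their own chains
        # instead of being discarded as chaining outliers
        seg_len = (seg_r1 - seg_r0 + 1).astype(np.float64)
        merged = []

        def _merge_chain(idx: np.ndarray) -> None:
            m_r0, m_r1 = seg_r0[idx[0]], seg_r1[idx[0]]
            m_q0, m_q1 = seg_q0[idx[0]], seg_q1[idx[0]]
            m_match = seg_r1[idx[0]] - seg_r0[idx[0]] + 1
            for i2 in idx[1:]:
                rgap = seg_r0[i2] - m_r1 - 1
                qgap = seg_q0[i2] - m_q1 - 1
                if (abs(rgap - qgap) <= indel_slop and min(rgap, qgap) > -k
                        and max(rgap, qgap) <= max_merge_gap):
                    # equal-gap anchor deserts are shared repeats (assumed
                    # identical); short gaps are substitution clusters
                    if rgap == qgap and rgap > 2 * k:
                        m_match += rgap
                    m_r1, m_q1 = seg_r1[i2], seg_q1[i2]
                    m_match += seg_r1[i2] - seg_r0[i2] + 1
                else:
                    merged.append((m_r0, m_r1, m_q0, m_q1, m_match))
                    m_r0, m_r1 = seg_r0[i2], seg_r1[i2]
                    m_q0, m_q1 = seg_q0[i2], seg_q1[i2]
                    m_match = seg_r1[i2] - seg_r0[i2] + 1
            merged.append((m_r0, m_r1, m_q0, m_q1, m_match))

        remaining = np.arange(seg_r0.size)
        rounds = 0
        while remaining.size and rounds < 50:
            local = _max_weight_chain(seg_q0[remaining], seg_len[remaining])
            chain = remaining[local]
            _merge_chain(chain)
            mask = np.ones(remaining.size, dtype=bool)
            mask[local] = False
            remaining = remaining[mask]
            rounds += 1
            if seg_len[remaining].sum() < max(min_chain, k):
                break   # leftovers can never reach min_chain even combined

        rname = ref_names[rc_i]
        qname = qry_names[qc_i]
        qlen = qry_lens[qname]
        for r0, r1, q0, q1, match in merged:
            span = r1 - r0 + 1
            if span < max(min_chain, min_anchor):
                continue
            if strand == "+":
                qs, qe = q0 + 1, q1 + 1
            else:
                # offsets were on the reverse-complemented query sequence
                qs, qe = qlen - q1, qlen - q0
            blocks.append(AlignmentBlock(
                rname, int(r0 + 1), int(r1 + 1), qname, int(qs), int(qe),
                strand, identity=min(1.0, match / span)))

    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.qry_chrom, b.qry_start))
    _trim_microhomology_overlaps(blocks, max_trim=2 * k)
    return blocks


def _trim_microhomology_overlaps(blocks: list[AlignmentBlock], max_trim: int) -> None:
    """Resolve small overlaps between consecutive blocks in place.

    Exact-match chaining extends both flanks of an event junction across any
    shared bases (micro-homology), so adjacent blocks can claim the same few
    reference or query bases. Overlaps up to ``max_trim`` bp are assigned to
    the left block by trimming the right one; larger overlaps are left alone
    (they indicate genuine rearrangement, not junction ambiguity).
    """
    for left, right in zip(blocks, blocks[1:]):
        if left.ref_chrom != right.ref_chrom:
            continue
        v = left.ref_end - right.ref_start + 1
        if 0 < v <= max_trim and right.ref_span > v:
            right.ref_start += v
            if left.qry_chrom == right.qry_chrom and left.strand == right.strand:
                if right.strand == "+" and right.qry_span > v:
                    right.qry_start += v
                elif right.strand == "-" and right.qry_span > v:
                    right.qry_end -= v
        if left.qry_chrom != right.qry_chrom or left.strand != right.strand:
            continue
        if left.strand == "+":
            w = left.qry_end - right.qry_start + 1
            if 0 < w <= max_trim and right.qry_span > w and right.ref_span > w:
                right.qry_start += w
                right.ref_start += w
        else:
            w = right.qry_end - left.qry_start + 1
            if 0 < w <= max_trim and right.qry_span > w and right.ref_span > w:
                right.qry_end -= w
                right.ref_start += w


# ---------------------------------------------------------------------------
# adjacency pairing and filtering
# ---------------------------------------------------------------------------


def pair_adjacent(blocks: list[AlignmentBlock]) -> list[AdjacentPair]:
    """Pair consecutive blocks sharing ref chrom, qry chrom and strand.

    ``ref_gap = right.ref_start - left.ref_end - 1``; the query gap is
    measured between the query-proximal ends, i.e. strand-aware: on '-'
    blocks query coordinates run backwards along the reference, so the gap
    is ``left.qry_start - right.qry_end - 1``. Pairs are only formed when
    the query order is consistent with the strand. Blocks nested inside an
    earlier block's reference span (e.g. a dispersed-repeat match) carry no
    adjacency information and are skipped.
    """
    out: list[AdjacentPair] = []
    bs_all = sorted(blocks, key=lambda b: (b.ref_chrom, b.ref_start, b.ref_end))
    bs: list[AlignmentBlock] = []
    max_end: dict[str, int] = {}
    for b in bs_all:
        if b.ref_end <= max_end.get(b.ref_chrom, 0):
            continue   # contained in a previous block
        max_end[b.ref_chrom] = b.ref_end
        bs.append(b)
    for left, right in zip(bs, bs[1:]):
        if left.ref_chrom != right.ref_chrom:
            continue
        if left.qry_chrom != right.qry_chrom or left.strand != right.strand:
            continue
        ref_gap = right.ref_start - left.ref_end - 1
        if left.strand == "+":
            if right.qry_start <= left.qry_start:
                continue  # query order inconsistent with strand
            qry_gap = right.qry_start - left.qry_end - 1
        else:
            if right.qry_end >= left.qry_end:
                continue
            qry_gap = left.qry_start - right.qry_end - 1
        out.append(AdjacentPair(left, right, int(ref_gap), int(qry_gap)))
    return out


def filter_blocks(blocks: list[AlignmentBlock], min_len: int) -> list[AlignmentBlock]:
    """Drop blocks whose reference span is below ``min_len`` (strict)."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [b for b in blocks if b.ref_span >= min_len]
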
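"""Event calling from synteny blocks.

Implements the comparative-genomics rules used to contrast a wild and a
cultivated soybean assembly:

* insertions in the query genome — adjacent alignment blocks with a query
  gap > 1 Kb and a reference gap < 100 bp;
* TE insertions — insertions whose query interval is > 80% covered by
  TE annotation (strict), with the reference-side gap defined as the TE
  insertion site;
* TE-affected genes — genes whose body extended by a 500 bp flank
  intersects a TE insertion site;
* large (> 100 Kb) structural variants — inversions, intra- and
  inter-chromosomal translocations detected as displaced runs of blocks;
* QTL-region overlap — aligned-base fraction of two region sequences after
  discarding blocks shorter than 1 Kb.

All inequality directions follow the literal rules (">", "<") and are
therefore strict.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .synteny import AdjacentPair, AlignmentBlock


@dataclass
class InsertionCall:
    ref_chrom: str
    ref_site_start: int     # reference alignment gap (may be empty: start > end-1)
    ref_site_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    length: int
    te_fraction: float = 0.0
    is_te_insertion: bool = False


@dataclass
class StructuralVariant:
    kind: str               # inversion | intra_translocation | inter_translocation
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    size: int
    breakpoints: tuple[int, int] = (0, 0)   # bounding ref coords between flanks


def call_insertions(pairs: list[AdjacentPair], qgap_min: int = 1000,
                    rgap_max: int = 100) -> list[InsertionCall]:
    """One insertion per adjacent pair with qry_gap > qgap_min and
    0 <= ref_gap < rgap_max (both strict; overlapping blocks are not gaps)."""
    calls = []
    for p in pairs:
        if p.qry_gap > qgap_min and 0 <= p.ref_gap < rgap_max:
            if p.left.strand == "+":
                qs, qe = p.left.qry_end + 1, p.right.qry_start - 1
            else:
                qs, qe = p.right.qry_end + 1, p.left.qry_start - 1
            calls.append(InsertionCall(
                ref_chrom=p.left.ref_chrom,
                ref_site_start=p.left.ref_end + 1,
                ref_site_end=p.right.ref_start - 1,
                qry_chrom=p.left.qry_chrom,
                qry_start=qs, qry_end=qe,
                length=qe - qs + 1))
    return calls


def classify_te_insertions(
    calls: list[InsertionCall],
    te_annotation: dict[str, list[tuple[int, int]]],
    threshold: float = 0.8,
) -> list[InsertionCall]:
    """Annotate each call with the TE-covered fraction of its query interval.

    Overlapping TE intervals are unioned before measuring; a call is a TE
    insertion when the covered fraction strictly exceeds ``threshold``.
    TE intervals on chromosomes absent from the calls are ignored.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, ivs in te_annotation.items():
        t = IntervalTree()
        for s, e in ivs:
            if e >= s:
                t.addi(s, e + 1)     # tree is half-open
        t.merge_overlaps()
        trees[chrom] = t
    for c in calls:
        tree = trees.get(c.qry_chrom)
        covered = 0
        if tree is not None:
            for iv in tree.overlap(c.qry_start, c.qry_end + 1):
                covered += min(iv.end, c.qry_end + 1) - max(iv.begin, c.qry_start)
        c.te_fraction = covered / c.length if c.length else 0.0
        c.is_te_insertion = c.te_fraction > threshold
    return calls


def find_te_affected_genes(
    calls: list[InsertionCall],
    genes: dict[str, list[tuple[int, int, str]]],
    flank: int = 500,
) -> dict[int, list[str]]:
    """Genes whose flank-extended body intersects a TE insertion site.

    Only calls flagged ``is_te_insertion`` contribute. Intervals are closed;
    a site exactly ``flank`` bp from the gene body is affected. Returns a
    mapping of call index -> sorted affected gene ids.
    """
    out: dict[int, list[str]] = {}
    trees: dict[str, IntervalTree] = {}
    for chrom, gs in genes.items():
        t = IntervalTree()
        for s, e, gid in gs:
            t.addi(max(1, s - flank), e + flank + 1, gid)
        trees[chrom] = t
    for i, c in enumerate(calls):
        if not c.is_te_insertion:
            continue
        tree = trees.get(c.ref_chrom)
        if tree is None:
            continue
        # the insertion site can be a zero-width point between two bases
        lo = min(c.ref_site_start, c.ref_site_end)
        hi = max(c.ref_site_start, c.ref_site_end)
        hits = sorted({iv.data for iv in tree.overlap(lo, hi + 1)})
        if hits:
            out[i] = hits
    return out


# ---------------------------------------------------------------------------
# large structural variants
# ---------------------------------------------------------------------------


def _runs(flags: list[bool]) -> list[tuple[int, int]]:
    """Maximal [i, j] index runs where flag is True."""
    runs, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def _lis_len_set(values: list[int]) -> set[int]:
    """Index set of one longest non-decreasing subsequence."""
    import bisect

    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(values)
    for i, v in enumerate(values):
        j = bisect.bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j else -1
    keep = set()
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        keep.add(i)
        i = prev[i]
    return keep


def detect_large_svs(blocks: list[AlignmentBlock],
                     min_size: int = 100_000) -> list[StructuralVariant]:
    """Detect > ``min_size`` inversions and translocations from block runs.

    Input order is irrelevant (blocks are sorted internally by reference
    position). Per reference chromosome:

    * the dominant query chromosome is the one receiving the most aligned
      bases; maximal runs of blocks mapping elsewhere, spanning more than
      ``min_size`` on the reference, are inter-chromosomal translocations;
    * among blocks on the dominant partner, the dominant strand is found the
      same way; opposite-strand runs over ``min_size`` are inversions;
    * among dominant-strand blocks, a longest non-decreasing subsequence of
      query starts defines the collinear backbone; displaced runs over
      ``min_size`` are intra-chromosomal translocations.

    Breakpoints are the reference coordinates bounding the run, i.e. the
    inner edges of the flanking collinear blocks.
    """
    svs: list[StructuralVariant] = []
    by_ref: dict[str, list[AlignmentBlock]] = {}
    for b in sorted(blocks, key=lambda b: (b.ref_chrom, b.ref_start)):
        by_ref.setdefault(b.ref_chrom, []).append(b)

    for rchrom, bs in by_ref.items():
        # dominant query partner
        bases: dict[str, int] = {}
        for b in bs:
            bases[b.qry_chrom] = bases.get(b.qry_chrom, 0) + b.ref_span
        dom_q = max(bases, key=bases.get)

        def emit(kind: str, run: list[AlignmentBlock], context: list[AlignmentBlock]):
            rs, re_ = run[0].ref_start, run[-1].ref_end
            if re_ - rs + 1 <= min_size:
                return
            qs = min(b.qry_start for b in run)
            qe = max(b.qry_end for b in run)
            left = max((b.ref_end for b in context if b.ref_end < rs), default=rs - 1)
            right = min((b.ref_start for b in context if b.ref_start > re_), default=re_ + 1)
            svs.append(StructuralVariant(kind, rchrom, rs, re_, run[0].qry_chrom,
                                         qs, qe, re_ - rs + 1, (left, right)))

        off = [b.qry_chrom != dom_q for b in bs]
        for i, j in _runs(off):
            run = bs[i:j + 1]
            # group the run by its query chromosome (a reciprocal swap puts
            # one foreign partner per reference chromosome)
            emit("inter_translocation", run, [b for b in bs if b.qry_chrom == dom_q])

        same = [b for b in bs if b.qry_chrom == dom_q]
        strand_bases = {"+": 0, "-": 0}
        for b in same:
            strand_bases[b.strand] += b.ref_span
        dom_s = "+" if strand_bases["+"] >= strand_bases["-"] else "-"
        flip = [b.strand != dom_s for b in same]
        for i, j in _runs(flip):
            emit("inversion", same[i:j + 1], [b for b in same if b.strand == dom_s])

        collinear = [b for b in same if b.strand == dom_s]
        if len(collinear) >= 2:
            qstarts = [b.qry_start if dom_s == "+" else -b.qry_start for b in collinear]
            keep = _lis_len_set(qstarts)
            displaced = [i not in keep for i in range(len(collinear))]
            ctx = [collinear[i] for i in keep]
            for i, j in _runs(displaced):
                emit("intra_translocation", collinear[i:j + 1], ctx)
    return svs


def compare_qtl_regions(blocks: list[AlignmentBlock],
                        region_ref_len: int, region_qry_len: int,
                        min_block: int = 1000) -> dict:
    """Overlap summary of two aligned region sequences.

    Blocks shorter than ``min_block`` (on the reference) are discarded; the
    surviving aligned intervals are unioned per side and reported as aligned
    bp and fraction of each region length.
    """
    kept = [b for b in blocks if b.ref_span >= min_block]

    def union_len(ivs):
        t = IntervalTree()
        for s, e in ivs:
            t.addi(s, e + 1)
        t.merge_overlaps()
        return sum(iv.end - iv.begin for iv in t)

    ref_bp = union_len([(b.ref_start, b.ref_end) for b in kept]) if kept else 0
    qry_bp = union_len([(b.qry_start, b.qry_end) for b in kept]) if kept else 0
    return {
        "n_blocks": len(kept),
        "ref_aligned_bp": ref_bp,
        "qry_aligned_bp": qry_bp,
        "ref_fraction": ref_bp / region_ref_len if region_ref_len else 0.0,
        "qry_fraction": qry_bp / region_qry_len if region_qry_len else 0.0,
    }


def write_insertions_tsv(calls: list[InsertionCall], path,
                         affected: dict[int, list[str]] | None = None) -> None:
    affected = affected or {}
    with open(path, "w") as fh:
        fh.write("ref_chrom\tref_site_start\tref_site_end\tqry_chrom\tqry_start\t"
                 "qry_end\tlength\tte_fraction\tis_te_insertion\taffected_genes\n")
        for i, c in enumerate(calls):
            genes = ",".join(affected.get(i, []))
            fh.write(f"{c.ref_chrom}\t{c.ref_site_start}\t{c.ref_site_end}\t"
                     f"{c.qry_chrom}\t{c.qry_start}\t{c.qry_end}\t{c.length}\t"
                     f"{c.te_fraction:.4f}\t{int(c.is_te_insertion)}\t{genes}\n")


def write_svs_tsv(svs: list[StructuralVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tref_chrom\tref_start\tref_end\tqry_chrom\tqry_start\t"
                 "qry_end\tsize\tbp_left\tbp_right\n")
        for s in svs:
            fh.write(f"{s.kind}\t{s.ref_chrom}\t{s.ref_start}\t{s.ref_end}\t"
                     f"{s.qry_chrom}\t{s.qry_start}\t{s.qry_end}\t{s.size}\t"
                     f"{s.breakpoints[0]}\t{s.breakpoints[1]}\n")
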
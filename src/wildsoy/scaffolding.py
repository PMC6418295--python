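"""Evidence-merged superscaffolding and redundant-flank gap closing.

Two independent scaffold orderings of the same contig set — one from Hi-C
contact scaffolding, one from optical-map hybrid scaffolding — are merged
into superscaffolds. Each adjacency between oriented contigs is classified
by its supporting evidence: ``both`` (present in both sources), ``map``
(hybrid/optical only) or ``hic`` (Hi-C only). Source-exclusive adjacencies
are kept only when the other source does not place a different neighbour on
the same contig end; contradictions are never joined and are reported.

Gap closing: when the sequence flanking a gap is redundant head-to-tail
(the left flank's suffix repeats as the right flank's prefix), long-range
evidence (mate-pair inserts, optical molecule spans — abstracted to counts)
decides between trimming one copy and keeping the gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import encode

Element = tuple[str, str]          # (contig_id, orientation '+'/'-')


@dataclass
class ScaffoldChain:
    id: str
    elements: list[Element]


@dataclass
class Linkage:
    left: Element
    right: Element
    evidence: str                   # both | map | hic


@dataclass
class MergeResult:
    superscaffolds: list[ScaffoldChain]
    linkages: list[Linkage]
    conflicts: list[tuple[tuple, tuple]]   # pairs of contradicting adjacencies


def _ends(left: Element, right: Element) -> tuple[tuple, tuple]:
    """The two contig ends joined by adjacency left -> right.

    A '+' contig contributes its tail on the left side of a junction and its
    head on the right; '-' swaps them. The canonical adjacency is the
    unordered end pair, which makes (A+,B+) identical to (B-,A-).
    """
    le = (left[0], "tail" if left[1] == "+" else "head")
    re_ = (right[0], "head" if right[1] == "+" else "tail")
    return le, re_


def _canon(left: Element, right: Element) -> tuple:
    le, re_ = _ends(left, right)
    return (le, re_) if le <= re_ else (re_, le)


def _source_adjacencies(chains: list[ScaffoldChain], source: str) -> dict[tuple, tuple]:
    seen_contigs: set[str] = set()
    adj: dict[tuple, tuple] = {}
    for ch in chains:
        for cid, _o in ch.elements:
            if cid in seen_contigs:
                raise ValueError(f"contig {cid} appears twice in {source} chains")
            seen_contigs.add(cid)
        for left, right in zip(ch.elements, ch.elements[1:]):
            adj[_canon(left, right)] = (left, right)
    return adj


def merge_scaffolds(hic: list[ScaffoldChain],
                    hybrid: list[ScaffoldChain]) -> MergeResult:
    """Merge Hi-C and optical-hybrid scaffold chains into superscaffolds.

    Every input adjacency is either emitted with its evidence class or
    listed in the conflict report; emitted superscaffolds are simple paths.
    """
    hic_adj = _source_adjacencies(hic, "hic")
    map_adj = _source_adjacencies(hybrid, "map")

    evidence: dict[tuple, str] = {}
    for key in hic_adj:
        evidence[key] = "both" if key in map_adj else "hic"
    for key in map_adj:
        evidence.setdefault(key, "map")

    # an end is contested when distinct adjacencies use it
    end_users: dict[tuple, list[tuple]] = {}
    for key in evidence:
        for end in key:
            end_users.setdefault(end, []).append(key)
    conflicts: list[tuple[tuple, tuple]] = []
    dropped: set[tuple] = set()
    for end, users in sorted(end_users.items()):
        if len(users) > 1:
            users = sorted(users)
            for a, b in zip(users, users[1:]):
                conflicts.append((a, b))
            dropped.update(users)

    kept = {k: v for k, v in evidence.items() if k not in dropped}

    # build simple paths over contig ends
    neighbour: dict[tuple, tuple] = {}
    for (e1, e2) in kept:
        neighbour[e1] = e2
        neighbour[e2] = e1
    contigs = sorted({c for ch in hic + hybrid for c, _o in ch.elements})

    visited: set[str] = set()
    superscaffolds: list[ScaffoldChain] = []
    linkages: list[Linkage] = []
    other = {"head": "tail", "tail": "head"}
    for start in contigs:
        if start in visited:
            continue
        # walk left to the path terminus
        cid, end_ = start, "head"
        guard = 0
        while (cid, end_) in neighbour and guard <= len(contigs):
            ncid, nend = neighbour[(cid, end_)]
            if ncid == start and guard:       # circular: break arbitrarily
                break
            cid, end_ = ncid, other[nend]
            guard += 1
        # walk right, emitting elements
        elements: list[Element] = []
        first = cid
        orient = "+" if end_ == "head" else "-"
        while True:
            visited.add(cid)
            elements.append((cid, orient))
            out_end = ("tail" if orient == "+" else "head")
            nxt = neighbour.get((cid, out_end))
            if nxt is None or nxt[0] in visited:
                break
            cid = nxt[0]
            orient = "+" if nxt[1] == "head" else "-"
        superscaffolds.append(ScaffoldChain(f"ss{len(superscaffolds) + 1}", elements))
        for left, right in zip(elements, elements[1:]):
            linkages.append(Linkage(left, right, kept[_canon(left, right)]))
        _ = first
    return MergeResult(superscaffolds, linkages, conflicts)


# ---------------------------------------------------------------------------
# gap closing
# ---------------------------------------------------------------------------


@dataclass
class RedundancyCandidate:
    overlap: int
    identity: float
    left_flank_len: int
    right_flank_len: int


def find_redundant_gap_flanks(
    seq: str,
    max_flank: int = 20_000,
    min_identity: float = 0.98,
    min_len: int = 1000,
) -> RedundancyCandidate | None:
    """Head-to-tail comparison of the two flanks of the first gap in ``seq``.

    The gap is the first run of Ns. The suffix of the left flank is compared
    with the prefix of the right flank at every overlap length up to
    ``max_flank``; the longest overlap of at least ``min_len`` bp with
    identity >= ``min_identity`` is reported, or None.
    """
    i = seq.find("N")
    if i < 0:
        return None
    j = i
    while j < len(seq) and seq[j] == "N":
        j += 1
    left = encode(seq[max(0, i - max_flank):i])
    right = encode(seq[j:j + max_flank])
    lmax = min(left.size, right.size)
    best = None
    for L in range(min_len, lmax + 1):
        matches = int(np.sum(left[-L:] == right[:L]))
        ident = matches / L
        if ident >= min_identity:
            best = RedundancyCandidate(L, ident, left.size, right.size)
    return best


def resolve_gap(
    candidate: RedundancyCandidate,
    one_copy_support: int,
    two_copy_support: int,
    min_support: int = 5,
) -> str:
    """Decide between closing a gap (trim one redundant copy) and keeping it.

    Close only when spanning evidence favours a single copy: strictly more
    one-copy than two-copy support and at least ``min_support`` one-copy
    observations. Ties and thin evidence keep the gap (never destroy
    sequence on ambiguous evidence). Returns 'close_and_trim' or 'keep_gap'.
    """
    if one_copy_support < 0 or two_copy_support < 0:
        raise ValueError("support counts must be non-negative")
    if one_copy_support > two_copy_support and one_copy_support >= min_support:
        return "close_and_trim"
    return "keep_gap"


def close_gap(seq: str, candidate: RedundancyCandidate) -> str:
    """Apply a close_and_trim decision: drop the gap and one overlap copy."""
    i = seq.find("N")
    j = i
    while j < len(seq) and seq[j] == "N":
        j += 1
    return seq[:i - candidate.overlap] + seq[j:]


def write_agp(chains: list[ScaffoldChain], contig_lens: dict[str, int], path,
              gap_len: int = 100) -> None:
    """AGP-like TSV: object, object coords, part number, contig, orientation."""
    with open(path, "w") as fh:
        for ch in chains:
            pos = 1
            part = 1
            for idx, (cid, orient) in enumerate(ch.elements):
                L = contig_lens[cid]
                fh.write(f"{ch.id}\t{pos}\t{pos + L - 1}\t{part}\tW\t{cid}\t1\t{L}\t{orient}\n")
                pos += L
                part += 1
                if idx < len(ch.elements) - 1:
                    fh.write(f"{ch.id}\t{pos}\t{pos + gap_len - 1}\t{part}\tN\t{gap_len}\t"
                             f"scaffold\tyes\tna\n")
                    pos += gap_len
                    part += 1
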
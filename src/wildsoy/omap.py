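"""Optical genome map operations.

An optical map is an ordered list of label positions (bp) on a molecule or
in-silico-digested contig. Operations: digestion of sequence at nicking-
enzyme motifs, sub-resolution label merging, molecule quality filters,
removal of purely repetitive maps, a dynamic-programming label aligner, and
molecule-coverage screening of regions.

Default thresholds follow standard single-molecule QC practice for plant
nanochannel data: molecules shorter than 150 Kb, with backbone signal
intensity above 0.6, or with fewer than 9 labels are discarded; labels
closer than 1 Kb (the optical resolution limit) are merged; contig regions
supported by fewer than 30 molecules are excluded from comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import encode, revcomp

NICKING_MOTIFS = {
    "Nt.BspQI": "GCTCTTC",
    "Nb.BssSI": "CACGAG",
}


@dataclass
class OpticalMap:
    id: str
    length: int
    labels: list[int]           # sorted bp positions, 1-based
    channel: str = "1"

    def __post_init__(self):
        lab = list(self.labels)
        if any(b <= a for a, b in zip(lab, lab[1:])):
            raise ValueError(f"map {self.id}: labels not strictly increasing")
        if lab and (lab[0] < 1 or lab[-1] > self.length):
            raise ValueError(f"map {self.id}: labels outside [1, length]")

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def intervals(self) -> np.ndarray:
        return np.diff(np.asarray(self.labels, dtype=float))


@dataclass
class OpticalMolecule(OpticalMap):
    intensity: float = 0.0
    source: tuple[str, int, int] | None = None   # (map id, start, end) if simulated


@dataclass
class OMAlignment:
    ref_id: str
    qry_id: str
    orientation: str                     # 'forward' | 'reverse'
    pairs: list[tuple[int, int]]         # matched (ref label idx, qry label idx)
    ref_skips: int
    qry_skips: int
    score: float
    qry_span_on_ref: tuple[int, int] = (0, 0)   # ref bp interval covered


def digest(seq: str, motifs: list[str] | str, map_id: str = "map",
           channel: str = "1") -> OpticalMap:
    """In silico digestion: one label at the forward-strand start coordinate
    of every motif occurrence on either strand; duplicates collapsed."""
    if isinstance(motifs, str):
        motifs = [motifs]
    arr = encode(seq)
    n = arr.size
    positions: set[int] = set()
    for motif in motifs:
        for mot in {motif.upper(), revcomp(motif.upper())}:
            mo = encode(mot)
            m = mo.size
            if n < m:
                continue
            match = np.ones(n - m + 1, dtype=bool)
            for j in range(m):
                match &= arr[j:j + n - m + 1] == mo[j]
            positions.update((np.flatnonzero(match) + 1).tolist())
    return OpticalMap(map_id, n, sorted(positions), channel)


def merge_labels(omap: OpticalMap, min_gap: int = 1000) -> OpticalMap:
    """Merge label clusters closer than ``min_gap`` into their midpoints.

    Clustering is greedy left-to-right: a label joins the current cluster
    when its gap to the previous label is < ``min_gap``; each cluster is
    replaced by its rounded midpoint (mean of members). Idempotent: output
    labels are pairwise >= ``min_gap`` apart.
    """
    labels = list(omap.labels)
    if not labels:
        return OpticalMap(omap.id, omap.length, [], omap.channel)
    clusters: list[list[int]] = [[labels[0]]]
    for p in labels[1:]:
        if p - clusters[-1][-1] < min_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    merged = [int(round(sum(c) / len(c))) for c in clusters]
    # midpoints of adjacent clusters can in principle collapse closer than
    # min_gap; re-merge until stable so the result is idempotent
    out = merged
    while True:
        again = [[out[0]]]
        for p in out[1:]:
            if p - again[-1][-1] < min_gap:
                again[-1].append(p)
            else:
                again.append([p])
        nxt = [int(round(sum(c) / len(c))) for c in again]
        if nxt == out:
            break
        out = nxt
    return OpticalMap(omap.id, omap.length, out, omap.channel)


def qc_filter_molecules(
    mols: list[OpticalMolecule],
    min_len: int = 150_000,
    max_intensity: float = 0.6,
    min_labels: int = 9,
) -> tuple[list[OpticalMolecule], list[tuple[OpticalMolecule, list[str]]]]:
    """Partition molecules into retained and removed (with reasons).

    A molecule is removed when ANY rule triggers: length < ``min_len``,
    intensity > ``max_intensity``, or label count < ``min_labels``.
    """
    retained, removed = [], []
    for m in mols:
        reasons = []
        if m.length < min_len:
            reasons.append("length")
        if m.intensity > max_intensity:
            reasons.append("intensity")
        if m.n_labels < min_labels:
            reasons.append("labels")
        if reasons:
            removed.append((m, reasons))
        else:
            retained.append(m)
    return retained, removed


def filter_repetitive_maps(
    maps: list[OpticalMap],
    cv_window: float = 0.10,
    modal_fraction: float = 0.9,
) -> tuple[list[OpticalMap], list[OpticalMap]]:
    """Remove maps consisting only of a repeated label spacing.

    A map with >= 3 labels is removed when at least ``modal_fraction`` of
    its inter-label intervals lie within +-``cv_window`` of the modal
    interval (the interval value maximising that count) — the signature of
    a tandem repeat array. Maps with < 3 labels are never removed.
    """
    retained, removed = [], []
    for m in maps:
        ivs = m.intervals()
        if ivs.size < 2:
            retained.append(m)
            continue
        best = 0
        for v in ivs:
            best = max(best, int(np.sum(np.abs(ivs - v) <= cv_window * v)))
        if best >= modal_fraction * ivs.size:
            removed.append(m)
        else:
            retained.append(m)
    return retained, removed


def align_maps(
    a: OpticalMap,
    b: OpticalMap,
    sizing_tolerance: float = 1500,
    miss_penalty: float = 1.0,
    fp_penalty: float = 1.0,
    max_skip: int = 4,
    match_score: float = 3.0,
) -> OMAlignment:
    """Global label alignment of two maps by dynamic programming.

    A match extends an alignment from label pair (i-d1, j-d2) to (i, j),
    1 <= d1, d2 <= ``max_skip`` + 1, when the two spanned distances agree
    within ``sizing_tolerance`` x max(d1, d2); skipped labels cost
    ``miss_penalty`` (on a) / ``fp_penalty`` (on b). Both orientations of
    ``b`` are scored and the better one returned; ties prefer fewer skips,
    then forward orientation.
    """
    if a.n_labels < 2 or b.n_labels < 2:
        raise ValueError("align_maps needs >= 2 labels on both maps")

    def _dp(bl: list[int]) -> tuple[float, list[tuple[int, int]], int, int]:
        # dp[i, j]: best score of an alignment ending with matched pair (i, j);
        # any pair may start a chain (alignment is local at both ends).
        al = a.labels
        na, nb = len(al), len(bl)
        dp = np.full((na, nb), match_score)
        back = np.full((na, nb, 2), -1, dtype=np.int32)
        for i in range(na):
            for j in range(nb):
                s = dp[i, j]
                for d1 in range(1, min(max_skip + 2, i + 1)):
                    da = al[i] - al[i - d1]
                    for d2 in range(1, min(max_skip + 2, j + 1)):
                        db = bl[j] - bl[j - d2]
                        if abs(da - db) <= sizing_tolerance * max(d1, d2):
                            cand = (dp[i - d1, j - d2] + match_score
                                    - miss_penalty * (d1 - 1) - fp_penalty * (d2 - 1))
                            if cand > s:
                                s = cand
                                back[i, j] = (d1, d2)
                dp[i, j] = s
        i, j = np.unravel_index(int(np.argmax(dp)), dp.shape)
        best = float(dp[i, j])
        pairs = []
        while True:
            pairs.append((int(i), int(j)))
            d1, d2 = back[i, j]
            if d1 < 0:
                break
            i, j = i - d1, j - d2
        pairs.reverse()
        a_skips = sum(pairs[t + 1][0] - pairs[t][0] - 1 for t in range(len(pairs) - 1))
        b_skips = sum(pairs[t + 1][1] - pairs[t][1] - 1 for t in range(len(pairs) - 1))
        return best, pairs, a_skips, b_skips

    fwd = _dp(list(b.labels))
    rev_labels = sorted(b.length - p + 1 for p in b.labels)
    rev = _dp(rev_labels)

    def key(res, pref):
        return (res[0], -(res[2] + res[3]), pref)

    if key(rev, 0) > key(fwd, 1):
        sc, pairs, a_sk, b_sk = rev
        orient = "reverse"
        nb = b.n_labels
        pairs = [(i, nb - 1 - j) for i, j in pairs]
    else:
        sc, pairs, a_sk, b_sk = fwd
        orient = "forward"
    span = ((a.labels[pairs[0][0]], a.labels[pairs[-1][0]]) if pairs else (0, 0))
    return OMAlignment(a.id, b.id, orient, pairs, a_sk, b_sk, sc, span)


def region_coverage(
    alignments: list[OMAlignment],
    ref_id: str,
    region: tuple[int, int],
    min_coverage: int = 30,
) -> tuple[int, bool]:
    """Count molecules whose aligned span covers ``region`` on ``ref_id``.

    Returns (depth, retained); regions supported by fewer than
    ``min_coverage`` molecules are flagged for exclusion.
    """
    s, e = region
    depth = sum(1 for al in alignments
                if al.ref_id == ref_id
                and al.qry_span_on_ref[0] <= s and al.qry_span_on_ref[1] >= e)
    return depth, depth >= min_coverage


# ---------------------------------------------------------------------------
# CMAP / molecule TSV IO
# ---------------------------------------------------------------------------

_CMAP_HEADER = (
    "# CMAP File Version:\t0.1\n"
    "# Label Channels:\t1\n"
    "#h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition\t"
    "StdDev\tCoverage\tOccurrence\n"
    "#f int\tfloat\tint\tint\tint\tfloat\tfloat\tint\tint\n"
)


def write_cmap(maps: list[OpticalMap], path) -> None:
    """Minimal single-channel CMAP v0.1 writer (one terminal site per map)."""
    with open(path, "w") as fh:
        fh.write(_CMAP_HEADER)
        for m in maps:
            import zlib
            mid = "".join(ch for ch in m.id if ch.isdigit()) or str(zlib.crc32(m.id.encode()) % 10 ** 8)
            n = m.n_labels
            for i, pos in enumerate(m.labels, 1):
                fh.write(f"{mid}\t{float(m.length):.1f}\t{n}\t{i}\t1\t{float(pos):.1f}\t1.0\t1\t1\n")
            fh.write(f"{mid}\t{float(m.length):.1f}\t{n}\t{n + 1}\t0\t{float(m.length):.1f}\t1.0\t1\t1\n")


def read_cmap(path) -> list[OpticalMap]:
    maps: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            mid, length, channel, pos = f[0], float(f[1]), f[4], float(f[5])
            rec = maps.setdefault(mid, {"length": int(round(length)), "labels": []})
            if channel != "0":
                rec["labels"].append(int(round(pos)))
    return [OpticalMap(mid, rec["length"], sorted(set(rec["labels"])))
            for mid, rec in maps.items()]


def write_molecules_tsv(mols: list[OpticalMolecule], path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\tlength\tintensity\tlabels\n")
        for m in mols:
            lab = ",".join(str(p) for p in m.labels)
            fh.write(f"{m.id}\t{m.length}\t{m.intensity:.4f}\t{lab}\n")


def read_molecules_tsv(path) -> list[OpticalMolecule]:
    mols = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("molecule_id")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            labels = [int(x) for x in f[3].split(",")] if f[3] else []
            mols.append(OpticalMolecule(f[0], int(f[1]), labels, "1", float(f[2])))
    return mols
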
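"""RIL binmap construction and QTL scanning.

Pipeline: SNP-call filtering, per-line sliding-window genotype calling
(15-SNP windows, 1-SNP step), recombination-breakpoint detection, merging
of 50 Kb grid intervals into recombination bins, genetic distances from
adjacent-bin discordance (Kosambi by default), and a single-QTL interval-
mapping LOD scan on a 0.5 cM grid with an empirical genome-wide threshold
from phenotype permutations (1000 by default, alpha = 0.05).

Genotype codes throughout: 'A'/'B' parental homozygotes, 'H' heterozygous
or ambiguous, '-' missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# SNP table and filters
# ---------------------------------------------------------------------------


@dataclass
class SNPCallTable:
    chrom: list[str]
    pos: list[int]                    # strictly increasing per chromosome
    genotypes: np.ndarray             # (n_lines, n_loci) of 'A'/'B'/'H'/'-'
    quality: np.ndarray | None = None  # (n_loci,) per-locus SNP quality

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]


def filter_snps(
    table: SNPCallTable,
    min_qual: float = 30,
    max_per_10bp: int = 3,
    window_bp: int = 10,
    min_lines: int = 20,
) -> SNPCallTable:
    """Apply the SNP locus filters used before binmap construction.

    * quality must be strictly greater than ``min_qual``;
    * any ``window_bp`` window may hold fewer than ``max_per_10bp`` loci —
      every locus of an offending window is dropped;
    * heterozygous calls are treated as missing and loci that carry no
      parental (A/B) information are dropped;
    * loci genotyped (A/B) in fewer than ``min_lines`` lines are dropped.
    """
    n = table.n_loci
    keep = np.ones(n, dtype=bool)
    if table.quality is not None:
        keep &= np.asarray(table.quality) > min_qual

    chrom = np.asarray(table.chrom)
    pos = np.asarray(table.pos)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        # count loci in every window of window_bp starting at each locus
        j = np.searchsorted(p, p + window_bp, side="left")
        for a in range(p.size):
            if j[a] - a >= max_per_10bp:
                keep[idx[a:j[a]]] = False

    geno = table.genotypes.copy()
    geno[geno == "H"] = "-"
    informative = np.sum((geno == "A") | (geno == "B"), axis=0)
    keep &= informative > 0
    keep &= informative >= min_lines

    sel = np.flatnonzero(keep)
    return SNPCallTable(
        [table.chrom[i] for i in sel],
        [table.pos[i] for i in sel],
        geno[:, sel],
        None if table.quality is None else np.asarray(table.quality)[sel],
    )


# ---------------------------------------------------------------------------
# sliding-window genotypes and breakpoints
# ---------------------------------------------------------------------------


def sliding_window_genotypes(
    calls: np.ndarray,
    window: int = 15,
    majority: int = 11,
    min_informative: int = 5,
) -> np.ndarray:
    """Window genotype sequence for one line along one chromosome.

    Each ``window``-SNP window (step 1) is called 'A' or 'B' when at least
    ``majority`` of its non-missing calls agree, 'H' otherwise, and '-'
    when fewer than ``min_informative`` calls are non-missing. A chromosome
    shorter than one window is called as a single whole-chromosome window.
    """
    calls = np.asarray(calls)
    n = calls.size
    if n == 0:
        return np.empty(0, dtype="<U1")
    w = min(window, n)
    a = (calls == "A").astype(np.int32)
    b = (calls == "B").astype(np.int32)
    ca = np.concatenate([[0], np.cumsum(a)])
    cb = np.concatenate([[0], np.cumsum(b)])
    m = n - w + 1
    na = ca[w:w + m] - ca[:m]
    nb = cb[w:w + m] - cb[:m]
    out = np.full(m, "H", dtype="<U1")
    informative = na + nb
    thresh = majority * w / window  # scale majority for a short final window
    out[(na >= thresh) & (na >= nb)] = "A"
    out[(nb >= thresh) & (nb > na)] = "B"
    out[informative < min_informative] = "-"
    return out


@dataclass
class Breakpoint:
    start: int        # bp uncertainty interval (inclusive)
    end: int
    from_state: str
    to_state: str

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def detect_breakpoints(window_calls: np.ndarray, positions: np.ndarray,
                       window: int = 15) -> list[Breakpoint]:
    """Crossovers between successive opposite homozygous window states.

    A breakpoint is emitted between the last window of one homozygous state
    and the first window of the other; its uncertainty interval runs from
    the last SNP covered only by the outgoing state's window to the first
    SNP of the incoming state's window, spanning any intervening H/missing
    windows. Isolated H or missing runs without a state change emit nothing.
    """
    positions = np.asarray(positions)
    wc = np.asarray(window_calls)
    n_win = wc.size
    w = min(window, positions.size)
    homo = np.flatnonzero((wc == "A") | (wc == "B"))
    out: list[Breakpoint] = []
    for a, b in zip(homo, homo[1:]):
        if wc[a] == wc[b]:
            continue
        # window i covers SNPs [i, i+w-1]
        left_snp = a          # last SNP before the incoming window's span
        right_snp = b + w - 1
        s = int(positions[min(left_snp, positions.size - 1)])
        e = int(positions[min(right_snp, positions.size - 1)])
        out.append(Breakpoint(s, e, str(wc[a]), str(wc[b])))
    _ = n_win
    return out


# ---------------------------------------------------------------------------
# binmap
# ---------------------------------------------------------------------------


@dataclass
class BinMap:
    chrom: list[str]
    start: list[int]                 # 1-based inclusive bin intervals
    end: list[int]
    genotypes: np.ndarray            # (n_lines, n_bins)
    cM: np.ndarray | None = None     # genetic position of each bin (per chrom)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]


def build_binmap(
    breakpoints: list[dict[str, list[Breakpoint]]],
    base_states: list[dict[str, str]],
    chrom_len: dict[str, int],
    interval: int = 50_000,
) -> BinMap:
    """Partition chromosomes into recombination bins on a fixed 50 Kb grid.

    The grid is anchored at position 1. A grid boundary is retained when any
    line has a breakpoint uncertainty interval overlapping it, or is the
    boundary nearest a breakpoint midpoint (so every detected crossover
    keeps at least one boundary even when its uncertainty interval falls
    inside a single cell); all other boundaries are merged away.

    Each line's genotype is piecewise constant along the chromosome,
    starting from its ``base_states`` call and switching at the retained
    boundary nearest each of its breakpoint midpoints; two switches snapped
    to the same boundary cancel. Bins are therefore internally consistent
    by construction. Lines with base state '-' are missing throughout.
    """
    n_lines = len(breakpoints)
    chroms, starts, ends = [], [], []
    cols = []
    flip = {"A": "B", "B": "A"}
    for c, L in chrom_len.items():
        edges = np.arange(interval, L, interval)        # candidate boundaries
        if edges.size == 0:
            edges = np.array([], dtype=int)
        keep = np.zeros(edges.size, dtype=bool)
        # midpoint snaps per line, resolved against the retained set below
        snaps: list[list[int]] = []
        for i in range(n_lines):
            line_snaps = []
            for bp in breakpoints[i].get(c, []):
                if edges.size:
                    keep |= (edges >= bp.start) & (edges <= bp.end)
                    nearest = int(np.argmin(np.abs(edges - bp.midpoint)))
                    keep[nearest] = True
                    line_snaps.append(int(edges[nearest]))
            snaps.append(line_snaps)
        kept_edges = edges[keep].tolist()
        bounds = [0] + kept_edges + [L]
        for bi, (s, e) in enumerate(zip(bounds, bounds[1:])):
            chroms.append(c)
            starts.append(s + 1)
            ends.append(e)
            col = np.full(n_lines, "-", dtype="<U1")
            for i in range(n_lines):
                st = base_states[i].get(c, "-")
                if st not in ("A", "B"):
                    continue
                for sp in snaps[i]:
                    if sp <= s:
                        st = flip[st]
                col[i] = st
            cols.append(col)
    geno = np.stack(cols, axis=1) if cols else np.empty((n_lines, 0), dtype="<U1")
    return BinMap(chroms, starts, ends, geno)


def line_chromosome_calls(
    calls: np.ndarray,
    positions: np.ndarray,
    window: int = 15,
    majority: int = 11,
    min_informative: int = 5,
) -> tuple[np.ndarray, list[Breakpoint], str]:
    """Window calls, breakpoints and base state for one line-chromosome."""
    wc = sliding_window_genotypes(calls, window, majority, min_informative)
    bps = detect_breakpoints(wc, positions, window)
    homo = wc[(wc == "A") | (wc == "B")]
    base = str(homo[0]) if homo.size else "-"
    return wc, bps, base


def binmap_from_population(
    pop,
    window: int = 15,
    majority: int = 11,
    interval: int = 50_000,
    mapping_function: str = "kosambi",
) -> tuple[BinMap, list[dict[str, list[Breakpoint]]]]:
    """Full binmap pipeline for a simulated or parsed RIL population.

    Runs sliding-window genotype calling and breakpoint detection per line
    and chromosome, builds the 50 Kb-grid binmap, and assigns genetic
    positions. Returns (binmap, per-line breakpoints).
    """
    chrom_order = list(dict.fromkeys(pop.snp_chrom))
    snp_chrom = np.asarray(pop.snp_chrom)
    pos_all = np.asarray(pop.snp_pos)
    n_lines = pop.genotypes.shape[0]
    breakpoints: list[dict[str, list[Breakpoint]]] = []
    base_states: list[dict[str, str]] = []
    for i in range(n_lines):
        bd: dict[str, list[Breakpoint]] = {}
        sd_: dict[str, str] = {}
        for c in chrom_order:
            sel = snp_chrom == c
            _, bps, base = line_chromosome_calls(
                pop.genotypes[i, sel], pos_all[sel], window, majority)
            bd[c] = bps
            sd_[c] = base
        breakpoints.append(bd)
        base_states.append(sd_)
    chrom_len = getattr(pop.truth, "chrom_bp", None) or {
        c: int(pos_all[snp_chrom == c].max()) for c in chrom_order}
    bm = build_binmap(breakpoints, base_states, chrom_len, interval)
    bm = genetic_distances(bm, mapping_function)
    return bm, breakpoints


# ---------------------------------------------------------------------------
# genetic distances
# ---------------------------------------------------------------------------


def kosambi(r: float) -> float:
    """Kosambi map distance in cM: 25 ln((1+2r)/(1-2r))."""
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


def haldane(r: float) -> float:
    """Haldane map distance in cM: -50 ln(1-2r)."""
    return -50.0 * np.log(1 - 2 * r)


def kosambi_inv(d_cM: float) -> float:
    """Recombination fraction from a Kosambi distance."""
    e = np.exp(d_cM / 25.0)
    return 0.5 * (e - 1) / (e + 1)


def haldane_inv(d_cM: float) -> float:
    return 0.5 * (1 - np.exp(-d_cM / 50.0))


_MAPFN = {"kosambi": (kosambi, kosambi_inv), "haldane": (haldane, haldane_inv)}


def genetic_distances(binmap: BinMap, mapping_function: str = "kosambi",
                      ril_correction: bool = True,
                      r_cap: float = 0.4999) -> BinMap:
    """Assign cumulative cM positions to bins from adjacent-bin discordance.

    The observed discordance R between adjacent bins is the fraction of
    lines with opposite homozygous genotypes among lines informative in
    both (H/missing excluded). For a selfed RIL population the discordance
    is map-expanded relative to a single meiosis, R = 2r/(1+2r); with
    ``ril_correction`` (the convention of standard genetic-map software for
    selfed RILs) the meiotic fraction r = R/(2-2R) is used, so map lengths
    are on the F1-meiosis scale. Fractions at or above 0.5 are capped at
    ``r_cap`` with a warning. Positions restart at 0 on each chromosome.
    """
    import warnings

    fn, _ = _MAPFN[mapping_function]
    g = binmap.genotypes
    cm = np.zeros(binmap.n_bins)
    for i in range(1, binmap.n_bins):
        if binmap.chrom[i] != binmap.chrom[i - 1]:
            cm[i] = 0.0
            continue
        a, b = g[:, i - 1], g[:, i]
        ok = ((a == "A") | (a == "B")) & ((b == "A") | (b == "B"))
        n = int(ok.sum())
        r = float(np.sum(a[ok] != b[ok]) / n) if n else 0.0
        if ril_correction:
            r = r / (2.0 - 2.0 * r) if r < 1.0 else r_cap
        if r >= 0.5:
            warnings.warn(f"adjacent-bin r={r:.3f} capped at {r_cap}")
            r = r_cap
        cm[i] = cm[i - 1] + fn(r)
    binmap.cM = cm
    return binmap


# ---------------------------------------------------------------------------
# LOD scan, permutation threshold, QTL calls
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    chrom: list[str]
    pos_cM: np.ndarray
    lod: np.ndarray
    threshold: float | None = None
    qtls: list = field(default_factory=list)


def _expected_genotype_grid(binmap: BinMap, step_cM: float,
                            mapping_function: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Expected +-1 genotype score at every grid position for every line.

    Between flanking bins the conditional probability of the 'A' state given
    the flanking genotypes uses the mapping function's inverse to convert cM
    gaps to recombination fractions (standard interval-mapping conditioning,
    with RIL genotypes treated as a two-state Markov chain). Missing/H
    flanks fall back to single-flank conditioning; fully uninformative lines
    score 0.
    """
    if binmap.cM is None:
        raise ValueError("binmap has no genetic positions; run genetic_distances")
    _, inv = _MAPFN[mapping_function]
    chroms_out: list[str] = []
    pos_out: list[float] = []
    cols: list[np.ndarray] = []
    g = binmap.genotypes
    n_lines = binmap.n_lines
    for c in dict.fromkeys(binmap.chrom):
        idx = [i for i, cc in enumerate(binmap.chrom) if cc == c]
        cm = np.asarray([binmap.cM[i] for i in idx])
        gen = g[:, idx]
        grid = np.arange(0.0, cm[-1] + step_cM / 2, step_cM) if cm[-1] > 0 else np.array([0.0])
        score = np.array([[1.0 if x == "A" else -1.0 if x == "B" else 0.0
                           for x in gen[i]] for i in range(n_lines)])
        known = np.abs(score) > 0
        for p in grid:
            jr = int(np.searchsorted(cm, p, side="left"))
            col = np.zeros(n_lines)
            for i in range(n_lines):
                kl = np.flatnonzero(known[i, :])
                if kl.size == 0:
                    continue
                left = kl[kl < jr][-1] if np.any(kl < jr) else None
                right_c = kl[kl >= jr]
                right = right_c[0] if right_c.size else None
                if left is not None and right is not None:
                    rl = inv(p - cm[left])
                    rr = inv(cm[right] - p)
                    gl, gr = score[i, left], score[i, right]
                    if gl == gr:
                        pa = (1 - rl) * (1 - rr) / ((1 - rl) * (1 - rr) + rl * rr)
                        col[i] = gl * (2 * pa - 1)
                    else:
                        pa = (1 - rl) * rr / ((1 - rl) * rr + rl * (1 - rr))
                        col[i] = gl * (2 * pa - 1)
                elif left is not None:
                    r = inv(p - cm[left])
                    col[i] = score[i, left] * (1 - 2 * r)
                elif right is not None:
                    r = inv(cm[right] - p)
                    col[i] = score[i, right] * (1 - 2 * r)
            chroms_out.append(c)
            pos_out.append(float(p))
            cols.append(col)
    X = np.stack(cols, axis=1)     # (n_lines, n_positions)
    return chroms_out, np.asarray(pos_out), X


def _lod_from_corr(r2: np.ndarray, n: int) -> np.ndarray:
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    return (n / 2.0) * np.log10(1.0 / (1.0 - r2))


def lod_scan(
    binmap: BinMap,
    phenotype: np.ndarray,
    step_cM: float = 0.5,
    window_cM: float = 10.0,
    mapping_function: str = "kosambi",
) -> ScanResult:
    """Single-QTL interval-mapping LOD scan on a ``step_cM`` grid.

    At every grid position the phenotype is regressed on the expected
    genotype score given the flanking bins; LOD = (n/2) log10(RSS0/RSS1),
    equal to (n/2) log10(1/(1-R^2)) for the one-predictor model. Lines with
    missing phenotypes are excluded. ``window_cM`` is kept for interface
    compatibility with composite scans (cofactors outside the window); the
    default scan is plain interval mapping and does not use it.
    """
    y = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(y)
    chroms, pos, X = _expected_genotype_grid(binmap, step_cM, mapping_function)
    y = y[ok]
    X = X[ok]
    n = y.size
    yc = y - y.mean()
    denom_y = float(np.sum(yc ** 2))
    Xc = X - X.mean(axis=0)
    denom_x = np.sum(Xc ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (Xc.T @ yc) ** 2 / (denom_x * denom_y)
    r2 = np.nan_to_num(r2)
    lod = _lod_from_corr(r2, n) if denom_y > 0 else np.zeros(pos.size)
    return ScanResult(chroms, pos, lod)


def permutation_threshold(
    binmap: BinMap,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    step_cM: float = 0.5,
    mapping_function: str = "kosambi",
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype vector is permuted ``n_perm`` times against the fixed
    genotype grid; the threshold is the empirical (1 - alpha) quantile of
    the per-permutation maximum LOD.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(y)
    _, _, X = _expected_genotype_grid(binmap, step_cM, mapping_function)
    y = y[ok]
    X = X[ok]
    n = y.size
    Xc = X - X.mean(axis=0)
    denom_x = np.sum(Xc ** 2, axis=0)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
    Pc = perms - perms.mean(axis=0)
    denom_y = np.sum(Pc ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (Xc.T @ Pc) ** 2 / (denom_x[:, None] * denom_y[None, :])
    r2 = np.nan_to_num(r2)
    max_lod = _lod_from_corr(r2, n).max(axis=0)
    return float(np.quantile(max_lod, 1.0 - alpha, method="higher"))


@dataclass
class QTLCall:
    chrom: str
    peak_cM: float
    peak_lod: float
    support_start_cM: float       # 1.5-LOD support interval
    support_end_cM: float


def call_qtl(scan: ScanResult, drop: float = 1.5, merge_cM: float = 10.0) -> list[QTLCall]:
    """Super-threshold regions with peaks and 1.5-LOD support intervals.

    Contiguous runs of positions above the threshold are QTL regions; runs
    on the same chromosome separated by less than ``merge_cM`` are merged
    (a linked QTL's LOD curve can dip briefly below the cutoff). Each
    region reports its peak and the interval where LOD stays within
    ``drop`` of the peak.
    """
    if scan.threshold is None:
        raise ValueError("scan has no permutation threshold")
    qtls: list[QTLCall] = []
    chrom = np.asarray(scan.chrom)
    for c in dict.fromkeys(scan.chrom):
        sel = np.flatnonzero(chrom == c)
        lod = scan.lod[sel]
        pos = scan.pos_cM[sel]
        above = lod > scan.threshold
        runs: list[list[int]] = []
        start = None
        for i in range(above.size + 1):
            if i < above.size and above[i]:
                if start is None:
                    start = i
            elif start is not None:
                runs.append([start, i - 1])
                start = None
        merged: list[list[int]] = []
        for r in runs:
            if merged and pos[r[0]] - pos[merged[-1][1]] < merge_cM:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        for a, b in merged:
            peak = a + int(np.argmax(lod[a:b + 1]))
            cut = lod[peak] - drop
            lo = peak
            while lo > 0 and lod[lo - 1] >= cut:
                lo -= 1
            hi = peak
            while hi < lod.size - 1 and lod[hi + 1] >= cut:
                hi += 1
            qtls.append(QTLCall(c, float(pos[peak]), float(lod[peak]),
                                float(pos[lo]), float(pos[hi])))
    scan.qtls = qtls
    return qtls
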
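"""Synthetic genomes, RIL populations and optical molecules with planted truth.

Every downstream stage of the pipeline (synteny block calling, insertion and
structural-variant detection, optical-map QC and alignment, binmap/QTL
mapping) consumes data produced here, so each generator records the exact
ground truth it planted: event breakpoints with their coordinates in both
genomes, per-line crossover positions, and per-molecule label provenance.

Coordinates are 1-based inclusive throughout, matching the convention used
by the synteny module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import decode, encode, random_seq, revcomp, spawn_rng

# ---------------------------------------------------------------------------
# reference genome + annotations
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSet:
    """A simulated reference genome with TE and gene annotations."""

    genome: dict[str, str]
    te_library: list[str]                       # elements 500 bp .. 10 Kb
    te_intervals: dict[str, list[tuple[int, int]]]   # 1-based inclusive
    gene_intervals: dict[str, list[tuple[int, int, str]]]  # (start, end, gene_id)


def generate_reference(
    n_chrom: int,
    lengths: list[int],
    gc: float = 0.35,
    te_library_size: int = 20,
    n_genes: int = 50,
    n_te_copies: int = 30,
    seed: int = 0,
) -> ReferenceSet:
    """Simulate a reference genome with a TE library, planted TE copies and genes.

    ``lengths`` must all be >= 100 Kb and ``gc`` in (0, 1). TE copies are
    verbatim library elements overwriting background sequence at random
    non-overlapping positions; genes are random non-overlapping intervals
    disjoint from the TE copies.
    """
    if n_chrom != len(lengths):
        raise ValueError(f"n_chrom={n_chrom} but {len(lengths)} lengths given")
    if any(l < 100_000 for l in lengths):
        raise ValueError("chromosome lengths must be >= 100 Kb")
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0,1), got {gc}")

    rng = spawn_rng(seed, "reference")
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    genome = {c: random_seq(rng, L, gc) for c, L in zip(chrom_names, lengths)}

    te_library = [
        random_seq(rng, int(rng.integers(500, 10_001)), gc)
        for _ in range(te_library_size)
    ]

    # plant TE copies and genes on disjoint intervals
    te_intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    gene_intervals: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chrom_names}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def _place(length: int) -> tuple[str, int] | None:
        for _ in range(200):
            c = chrom_names[int(rng.integers(n_chrom))]
            L = lengths[chrom_names.index(c)]
            if L <= length + 2:
                continue
            start = int(rng.integers(1, L - length))  # 1-based
            if all(start > e + 1 or start + length - 1 < s - 1
                   for s, e in occupied[c]):
                occupied[c].append((start, start + length - 1))
                return c, start
        return None

    arrs = {c: encode(genome[c]) for c in chrom_names}
    if te_library_size:
        for _ in range(n_te_copies):
            elem = te_library[int(rng.integers(te_library_size))]
            loc = _place(len(elem))
            if loc is None:
                continue
            c, start = loc
            arrs[c][start - 1:start - 1 + len(elem)] = encode(elem)
            te_intervals[c].append((start, start + len(elem) - 1))
    for i in range(n_genes):
        glen = int(rng.integers(1_000, 6_001))
        loc = _place(glen)
        if loc is None:
            continue
        c, start = loc
        gene_intervals[c].append((start, start + glen - 1, f"gene{i + 1:04d}"))

    genome = {c: decode(a) for c, a in arrs.items()}
    for c in chrom_names:
        te_intervals[c].sort()
        gene_intervals[c].sort()
    return ReferenceSet(genome, te_library, te_intervals, gene_intervals)


def clear_position(reference: ReferenceSet, chrom: str, pos: int,
                   clearance: int = 2000) -> int:
    """Shift ``pos`` to the nearest coordinate >= ``clearance`` bp away from
    every annotated TE copy on ``chrom``.

    Planted events inside or immediately beside a repeat copy have no
    unique flanking anchors, so their breakpoints are undefined at anchor
    resolution; placing events in unique sequence keeps the planted truth
    well-posed for alignment-based recovery.
    """
    ivs = sorted(reference.te_intervals.get(chrom, []))
    L = len(reference.genome[chrom])

    def ok(p: int) -> bool:
        return 1 + clearance <= p <= L - clearance and all(
            p < s - clearance or p > e + clearance for s, e in ivs)

    if ok(pos):
        return pos
    for d in range(1, L):
        if ok(pos + d):
            return pos + d
        if ok(pos - d):
            return pos - d
    raise ValueError(f"no TE-clear position near {chrom}:{pos}")


# ---------------------------------------------------------------------------
# variant genome derivation
# ---------------------------------------------------------------------------

EVENT_KINDS = {
    "te_insertion",
    "novel_insertion",
    "inversion",
    "intra_translocation",
    "inter_translocation",
}


@dataclass
class PlannedEvent:
    """One planted event, positioned in ancestor (= reference) coordinates.

    * insertions: inserted immediately after base ``pos``; ``length`` bp total,
      of which a fraction ``te_fraction`` is a verbatim TE-library fragment.
    * inversion: segment [pos, pos+length-1] reversed in place.
    * intra_translocation: segment [pos, pos+length-1] excised and re-inserted
      after base ``pos2`` of the same chromosome.
    * inter_translocation: reciprocal tail swap — [pos..end] of ``chrom``
      exchanged with [pos2..end] of ``chrom2``.
    """

    kind: str
    chrom: str
    pos: int
    length: int = 0
    chrom2: str | None = None
    pos2: int = 0
    te_element: int = 0
    te_fraction: float = 1.0

    def ancestor_intervals(self, chrom_lens: dict[str, int]) -> list[tuple[str, int, int]]:
        if self.kind in ("te_insertion", "novel_insertion"):
            return [(self.chrom, self.pos, self.pos)]
        if self.kind == "inversion":
            return [(self.chrom, self.pos, self.pos + self.length - 1)]
        if self.kind == "intra_translocation":
            return [(self.chrom, self.pos, self.pos + self.length - 1),
                    (self.chrom, self.pos2, self.pos2)]
        if self.kind == "inter_translocation":
            return [(self.chrom, self.pos, chrom_lens[self.chrom]),
                    (self.chrom2, self.pos2, chrom_lens[self.chrom2])]
        raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class SVPlan:
    events: list[PlannedEvent] = field(default_factory=list)

    def validate(self, chrom_lens: dict[str, int]) -> None:
        """Events must lie within bounds and be pairwise non-overlapping."""
        ivs: list[tuple[str, int, int, PlannedEvent]] = []
        for ev in self.events:
            if ev.kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {ev.kind!r}")
            for c, s, e in ev.ancestor_intervals(chrom_lens):
                if c not in chrom_lens or s < 1 or e > chrom_lens[c]:
                    raise ValueError(f"event {ev.kind}@{c}:{s} outside chromosome bounds")
                ivs.append((c, s, e, ev))
        ivs.sort(key=lambda t: (t[0], t[1]))
        for (c1, s1, e1, a), (c2, s2, e2, b) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 <= e1 and a is not b:
                raise ValueError(
                    f"overlapping planted events: {a.kind}@{c1}:{s1}-{e1} "
                    f"vs {b.kind}@{c2}:{s2}-{e2}"
                )


@dataclass
class _Piece:
    """A run of the query genome: either a reference interval or inserted seq."""

    kind: str                  # "ref" | "ins"
    src_chrom: str = ""
    s: int = 0                 # ancestor coords, 1-based inclusive
    e: int = 0
    strand: str = "+"
    seq: str = ""              # for "ins"
    te_len: int = 0            # leading TE fragment length of an insertion
    event: PlannedEvent | None = None

    def __len__(self) -> int:
        return (self.e - self.s + 1) if self.kind == "ref" else len(self.seq)


@dataclass
class EventTruth:
    event: PlannedEvent
    qry_chrom: str = ""
    qry_start: int = 0
    qry_end: int = 0
    qry_chrom2: str = ""       # second segment for inter_translocation
    qry_start2: int = 0
    qry_end2: int = 0


@dataclass
class VariantTruth:
    """Planted truth in query coordinates plus the full liftover table."""

    events: list[EventTruth]
    # (qry_chrom, qstart, qend, src_chrom, sstart, send, strand) per ref piece
    liftover: list[tuple[str, int, int, str, int, int, str]]
    qry_te_intervals: dict[str, list[tuple[int, int]]]
    n_snps: int = 0

    def lift(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Map an ancestor coordinate into the query genome (None if deleted)."""
        for qc, qs, qe, sc, ss, se, strand in self.liftover:
            if sc == chrom and ss <= pos <= se:
                return (qc, qs + (pos - ss)) if strand == "+" else (qc, qe - (pos - ss))
        return None


def _split_ref_piece(pieces: list[_Piece], idx: int, pos: int) -> int:
    """Split a '+' ref piece so that ``pos`` starts a new piece; return its index."""
    p = pieces[idx]
    assert p.kind == "ref" and p.strand == "+"
    if pos == p.s:
        return idx
    left = _Piece("ref", p.src_chrom, p.s, pos - 1)
    right = _Piece("ref", p.src_chrom, pos, p.e)
    pieces[idx:idx + 1] = [left, right]
    return idx + 1


def _locate(chroms: dict[str, list[_Piece]], src_chrom: str, pos: int) -> tuple[str, int]:
    for cname, pieces in chroms.items():
        for i, p in enumerate(pieces):
            if p.kind == "ref" and p.src_chrom == src_chrom and p.s <= pos <= p.e:
                return cname, i
    raise ValueError(f"ancestor position {src_chrom}:{pos} not found in query layout")


def derive_variant_genome(
    reference: ReferenceSet,
    plan: SVPlan,
    snp_rate: float = 0.0,
    snp_breakpoint_clearance: int = 200,
    seed: int = 0,
) -> tuple[dict[str, str], VariantTruth]:
    """Apply a plan of structural events (plus background SNPs) to a genome.

    Events are applied in a fixed order — translocations, then inversions,
    then insertions, then SNPs — so that every planted breakpoint has a
    well-defined image in query coordinates. Background SNPs are kept at
    least ``snp_breakpoint_clearance`` bp away from every piece boundary so
    anchor alignment stays unambiguous next to events.
    """
    genome = reference.genome
    chrom_lens = {c: len(s) for c, s in genome.items()}
    plan.validate(chrom_lens)
    rng = spawn_rng(seed, "variant")

    chroms: dict[str, list[_Piece]] = {
        c: [_Piece("ref", c, 1, L)] for c, L in chrom_lens.items()
    }

    order = {"inter_translocation": 0, "intra_translocation": 1,
             "inversion": 2, "te_insertion": 3, "novel_insertion": 3}
    for ev in sorted(plan.events, key=lambda e: order[e.kind]):
        if ev.kind == "inter_translocation":
            ca, ia = _locate(chroms, ev.chrom, ev.pos)
            ia = _split_ref_piece(chroms[ca], ia, ev.pos)
            tail_a = chroms[ca][ia:]
            del chroms[ca][ia:]
            cb, ib = _locate(chroms, ev.chrom2, ev.pos2)
            ib = _split_ref_piece(chroms[cb], ib, ev.pos2)
            tail_b = chroms[cb][ib:]
            del chroms[cb][ib:]
            chroms[ca].extend(tail_b)
            chroms[cb].extend(tail_a)
        elif ev.kind == "intra_translocation":
            c, i = _locate(chroms, ev.chrom, ev.pos)
            i = _split_ref_piece(chroms[c], i, ev.pos)
            c2, j = _locate(chroms, ev.chrom, ev.pos + ev.length - 1)
            assert c2 == c
            j = _split_ref_piece(chroms[c], j, ev.pos + ev.length)
            moved = chroms[c][i:j]
            del chroms[c][i:j]
            ct, t = _locate(chroms, ev.chrom, ev.pos2)
            t = _split_ref_piece(chroms[ct], t, ev.pos2 + 1)
            chroms[ct][t:t] = moved
        elif ev.kind == "inversion":
            c, i = _locate(chroms, ev.chrom, ev.pos)
            i = _split_ref_piece(chroms[c], i, ev.pos)
            c2, j = _locate(chroms, ev.chrom, ev.pos + ev.length - 1)
            assert c2 == c and i == j, "inversion spans multiple pieces"
            j = _split_ref_piece(chroms[c], j, ev.pos + ev.length)
            chroms[c][j - 1].strand = "-"
        else:  # insertions
            te_len = int(round(ev.te_fraction * ev.length)) if ev.kind == "te_insertion" else 0
            if te_len:
                elem = reference.te_library[ev.te_element % len(reference.te_library)]
                te_seq = (elem * (te_len // len(elem) + 1))[:te_len]
            else:
                te_seq = ""
            filler = random_seq(rng, ev.length - te_len, 0.5)
            c, i = _locate(chroms, ev.chrom, ev.pos)
            i = _split_ref_piece(chroms[c], i, ev.pos + 1)
            chroms[c].insert(i, _Piece("ins", seq=te_seq + filler, te_len=te_len, event=ev))

    # materialise query sequences + liftover + truth
    qry: dict[str, str] = {}
    liftover: list[tuple[str, int, int, str, int, int, str]] = []
    qry_te: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    truth_by_event: dict[int, EventTruth] = {}

    for cname, pieces in chroms.items():
        parts: list[str] = []
        pos = 0  # query bp emitted so far
        for p in pieces:
            qs, qe = pos + 1, pos + len(p)
            if p.kind == "ref":
                seq = genome[p.src_chrom][p.s - 1:p.e]
                if p.strand == "-":
                    seq = revcomp(seq)
                liftover.append((cname, qs, qe, p.src_chrom, p.s, p.e, p.strand))
                # lift reference TE annotation onto query coordinates
                for ts, te_ in reference.te_intervals.get(p.src_chrom, []):
                    os_, oe = max(ts, p.s), min(te_, p.e)
                    if os_ <= oe:
                        if p.strand == "+":
                            qry_te[cname].append((qs + (os_ - p.s), qs + (oe - p.s)))
                        else:
                            qry_te[cname].append((qe - (oe - p.s), qe - (os_ - p.s)))
            else:
                seq = p.seq
                if p.te_len:
                    qry_te[cname].append((qs, qs + p.te_len - 1))
                et = truth_by_event.setdefault(id(p.event), EventTruth(p.event))
                et.qry_chrom, et.qry_start, et.qry_end = cname, qs, qe
            parts.append(seq)
            pos = qe
        qry[cname] = "".join(parts)
        qry_te[cname].sort()

    # truth records for inversions and translocations from the liftover table
    for ev in plan.events:
        if ev.kind in ("te_insertion", "novel_insertion"):
            continue
        segs = [(qc, qs, qe, sc, ss, se, st) for qc, qs, qe, sc, ss, se, st in liftover]
        et = EventTruth(ev)
        if ev.kind == "inversion":
            for qc, qs, qe, sc, ss, se, st in segs:
                if sc == ev.chrom and ss == ev.pos and st == "-":
                    et.qry_chrom, et.qry_start, et.qry_end = qc, qs, qe
        elif ev.kind == "intra_translocation":
            for qc, qs, qe, sc, ss, se, st in segs:
                if sc == ev.chrom and ss == ev.pos:
                    et.qry_chrom, et.qry_start, et.qry_end = qc, qs, qe
        else:  # inter_translocation: the two relocated tails
            for qc, qs, qe, sc, ss, se, st in segs:
                if sc == ev.chrom and ss == ev.pos:
                    et.qry_chrom, et.qry_start, et.qry_end = qc, qs, qe
                if sc == ev.chrom2 and ss == ev.pos2:
                    et.qry_chrom2, et.qry_start2, et.qry_end2 = qc, qs, qe
        truth_by_event[id(ev)] = et

    truth = VariantTruth(
        events=[truth_by_event[id(ev)] for ev in plan.events],
        liftover=liftover,
        qry_te_intervals=qry_te,
    )

    # background SNPs, away from breakpoints
    if snp_rate > 0:
        n_snps = 0
        for cname in qry:
            arr = encode(qry[cname])
            allowed = np.ones(arr.size, dtype=bool)
            bounds = [0, arr.size]
            for qc, qs, qe, *_ in liftover:
                if qc == cname:
                    bounds.extend([qs - 1, qe])
            for b in bounds:
                lo = max(0, b - snp_breakpoint_clearance)
                hi = min(arr.size, b + snp_breakpoint_clearance)
                allowed[lo:hi] = False
            allowed &= arr < 4
            hit = np.flatnonzero(allowed & (rng.random(arr.size) < snp_rate))
            shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
            arr[hit] = (arr[hit] + shift) % 4
            qry[cname] = decode(arr)
            n_snps += hit.size
        truth.n_snps = n_snps

    return qry, truth


# ---------------------------------------------------------------------------
# RIL population simulation
# ---------------------------------------------------------------------------


@dataclass
class QTLSpec:
    chrom: str
    pos_bp: int
    effect: float = 1.0


@dataclass
class RILTruth:
    # per line, per chromosome: sorted crossover positions (bp)
    crossovers: list[dict[str, list[int]]]
    # per line, per chromosome: parental state ('A'/'B') of each segment,
    # segments delimited by the crossover list
    states: list[dict[str, list[str]]]
    qtls: list[QTLSpec]
    heritability: float
    noise_sd: float
    chrom_bp: dict[str, int]

    def genotype_at(self, line: int, chrom: str, pos: int) -> str:
        xs = self.crossovers[line][chrom]
        seg = int(np.searchsorted(np.asarray(xs), pos, side="left"))
        return self.states[line][chrom][seg]


@dataclass
class RILPopulation:
    snp_chrom: list[str]
    snp_pos: list[int]                 # 1-based, sorted within chromosome
    genotypes: np.ndarray              # (n_lines, n_snps) of 'A'/'B'/'H'/'-'
    phenotypes: np.ndarray             # (n_lines,)
    truth: RILTruth


def simulate_ril_population(
    n_lines: int,
    chrom_genetic_lengths: dict[str, float],     # cM
    n_snps: int,
    qtls: list[QTLSpec] | None = None,
    heritability: float = 0.3,
    missing_rate: float = 0.0,
    genotype_error_rate: float = 0.0,
    residual_het_rate: float = 0.003,
    bp_per_cM: int = 200_000,
    interference_cM: float = 5.0,
    telomere_margin_cM: float = 2.5,
    seed: int = 0,
) -> RILPopulation:
    """Simulate a selfed RIL population with planted crossovers and QTLs.

    Crossovers per line per chromosome are Poisson with mean 2 x (genetic
    length in Morgans) — the classical 2-fold map expansion of a selfed RIL
    relative to a single meiosis — with positions uniform in bp (a uniform
    cM/bp map of ``bp_per_cM``). Lines are homozygous A/B apart from a small
    residual-heterozygosity rate. The phenotype is the sum of additive QTL
    effects (A = +effect, B = -effect) plus Gaussian noise scaled to the
    requested narrow-sense heritability.

    Two qualitative features of plant meiosis are modelled: crossover
    interference (no two crossovers of a line closer than
    ``interference_cM``) and suppression of crossovers immediately at the
    chromosome termini (``telomere_margin_cM`` exclusion at each end).
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if qtls and not 0 < heritability < 1:
        raise ValueError(f"heritability must be in (0,1), got {heritability}")
    for r in (missing_rate, genotype_error_rate, residual_het_rate):
        if not 0 <= r < 1:
            raise ValueError("rates must be in [0,1)")
    qtls = qtls or []
    rng = spawn_rng(seed, "ril")
    chrom_bp = {c: max(int(round(L * bp_per_cM)), 100)
                for c, L in chrom_genetic_lengths.items()}

    # SNP positions: spread across chromosomes proportionally to bp length
    total_bp = sum(chrom_bp.values())
    snp_chrom: list[str] = []
    snp_pos: list[int] = []
    for c, L in chrom_bp.items():
        k = max(2, int(round(n_snps * L / total_bp)))
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=min(k, L), replace=False))
        snp_chrom.extend([c] * pos.size)
        snp_pos.extend(int(p) for p in pos)

    crossovers: list[dict[str, list[int]]] = []
    states: list[dict[str, list[str]]] = []
    for _ in range(n_lines):
        line_x: dict[str, list[int]] = {}
        line_s: dict[str, list[str]] = {}
        for c, cm in chrom_genetic_lengths.items():
            n_x = int(rng.poisson(2.0 * cm / 100.0))
            min_sep = int(interference_cM * bp_per_cM)
            margin = int(telomere_margin_cM * bp_per_cM)
            lo, hi = 1 + margin, max(chrom_bp[c] - margin, 2 + margin)
            xs: list[int] = []
            attempts = 0
            while len(xs) < n_x and attempts < 200 * (n_x + 1):
                p = int(rng.integers(lo, hi))
                if all(abs(p - q) >= min_sep for q in xs):
                    xs.append(p)
                attempts += 1
            xs.sort()
            start = "A" if rng.random() < 0.5 else "B"
            seg = [start]
            for _x in xs:
                seg.append("B" if seg[-1] == "A" else "A")
            line_x[c] = xs
            line_s[c] = seg
        crossovers.append(line_x)
        states.append(line_s)

    # genetic values from true genotypes at QTL positions
    g = np.zeros(n_lines)
    noise_sd = 0.0
    truth = RILTruth(crossovers, states, qtls, heritability, 0.0, chrom_bp)
    if qtls:
        for q in qtls:
            x = np.array([1.0 if truth.genotype_at(i, q.chrom, q.pos_bp) == "A" else -1.0
                          for i in range(n_lines)])
            g += q.effect * x
        var_g = sum(q.effect ** 2 for q in qtls)  # x = +/-1, var 1, unlinked
        noise_sd = float(np.sqrt(var_g * (1 - heritability) / heritability))
    truth.noise_sd = noise_sd
    phenotypes = g + rng.normal(0.0, noise_sd if noise_sd else 1.0, size=n_lines)

    # observed genotype matrix with residual het, errors and missingness
    n_m = len(snp_pos)
    geno = np.empty((n_lines, n_m), dtype="<U1")
    for i in range(n_lines):
        for c in chrom_bp:
            idx = [j for j in range(n_m) if snp_chrom[j] == c]
            if not idx:
                continue
            pos = np.array([snp_pos[j] for j in idx])
            xs = np.asarray(crossovers[i][c])
            seg = np.searchsorted(xs, pos, side="left")
            st = np.array(states[i][c])[seg]
            geno[i, idx] = st
        u = rng.random(n_m)
        het = u < residual_het_rate
        err = (u >= residual_het_rate) & (u < residual_het_rate + genotype_error_rate)
        flip = {"A": "B", "B": "A"}
        row = geno[i]
        row[het] = "H"
        for j in np.flatnonzero(err):
            row[j] = flip.get(row[j], row[j])
        miss = rng.random(n_m) < missing_rate
        row[miss] = "-"

    return RILPopulation(snp_chrom, snp_pos, geno, phenotypes, truth)


# ---------------------------------------------------------------------------
# optical molecule simulation
# ---------------------------------------------------------------------------


def simulate_optical_molecules(
    omap,
    n: int,
    length_dist: tuple[int, int] = (150_000, 400_000),
    label_fn_rate: float = 0.0,
    label_fp_rate_per_100kb: float = 0.0,
    sizing_sd: float = 0.0,
    intensity_dist: tuple[float, float] | float = (0.4, 0.1),
    seed: int = 0,
):
    """Sample molecules from an in-silico map with realistic label noise.

    Each molecule is a uniform-random subinterval of the source map whose
    length is uniform in ``length_dist``. True labels inside the window are
    perturbed by Gaussian sizing error (``sizing_sd`` bp), dropped
    independently at ``label_fn_rate``, and false labels are added as a
    Poisson process at ``label_fp_rate_per_100kb``. ``intensity_dist`` is
    either a constant or a (mean, sd) Gaussian truncated at 0.
    Returns ``(molecules, truth)`` where truth maps molecule id to its
    source interval and kept-label indices.
    """
    from .omap import OpticalMolecule

    if not 0 <= label_fn_rate < 1:
        raise ValueError("label_fn_rate must be in [0,1)")
    if sizing_sd < 0:
        raise ValueError("sizing_sd must be >= 0")
    rng = spawn_rng(seed, "om")
    labels = np.asarray(omap.labels, dtype=float)
    mols: list[OpticalMolecule] = []
    truth: dict[str, dict] = {}
    for m in range(n):
        L = int(rng.integers(length_dist[0], length_dist[1] + 1))
        L = min(L, omap.length)
        start = int(rng.integers(1, omap.length - L + 2))
        end = start + L - 1
        inside = np.flatnonzero((labels >= start) & (labels <= end))
        keep = inside[rng.random(inside.size) >= label_fn_rate]
        pos = labels[keep] - start + 1
        if sizing_sd > 0:
            pos = pos + rng.normal(0, sizing_sd, size=pos.size)
        n_fp = rng.poisson(label_fp_rate_per_100kb * L / 100_000)
        fp = rng.uniform(1, L, size=n_fp)
        allpos = np.clip(np.concatenate([pos, fp]), 1, L)
        allpos = np.unique(np.round(allpos).astype(int))
        if isinstance(intensity_dist, (int, float)):
            inten = float(intensity_dist)
        else:
            inten = max(0.0, float(rng.normal(*intensity_dist)))
        mid = f"mol{m + 1}"
        mols.append(OpticalMolecule(id=mid, length=L, labels=allpos.tolist(),
                                    channel=omap.channel, intensity=inten,
                                    source=(omap.id, start, end)))
        truth[mid] = {"source": (omap.id, start, end),
                      "true_label_idx": inside.tolist(),
                      "kept_label_idx": keep.tolist(),
                      "n_false": int(n_fp)}
    return mols, truth
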
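#!/usr/bin/env python
"""Merge a Hi-C scaffold ordering with an optical-hybrid ordering into
superscaffolds with evidence-classified linkages, then close a redundant-
flank gap backed by spanning evidence.

Writes AGP-like and linkage tables to results/scaffolds/.
"""

from pathlib import Path

import numpy as np

from wildsoy import scaffolding as sc
from wildsoy.util import random_seq

OUT = Path("results/scaffolds")
SEED = 99


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    contigs = [f"ctg{i:02d}" for i in range(1, 21)]
    lens = {c: int(rng.integers(50_000, 400_000)) for c in contigs}

    # ground truth order; each evidence source sees overlapping fragments
    hic = [sc.ScaffoldChain("hic1", [(c, "+") for c in contigs[:12]]),
           sc.ScaffoldChain("hic2", [(c, "+") for c in contigs[12:18]]),
           sc.ScaffoldChain("hic3", [(c, "+") for c in contigs[18:]])]
    # map agrees on most joins but puts ctg20 after ctg16 where Hi-C has ctg17
    hyb = [sc.ScaffoldChain("map1", [(c, "+") for c in contigs[6:16]] + [("ctg20", "+")]),
           sc.ScaffoldChain("map2", [(c, "+") for c in contigs[:6]]),
           sc.ScaffoldChain("map3", [("ctg17", "+"), ("ctg18", "+"), ("ctg19", "+")])]

    res = sc.merge_scaffolds(hic, hyb)
    sc.write_agp(res.superscaffolds, lens, OUT / "superscaffolds.agp")
    with open(OUT / "linkages.tsv", "w") as fh:
        fh.write("left\tleft_orient\tright\tright_orient\tevidence\n")
        for l in res.linkages:
            fh.write(f"{l.left[0]}\t{l.left[1]}\t{l.right[0]}\t{l.right[1]}\t{l.evidence}\n")
    with open(OUT / "conflicts.tsv", "w") as fh:
        fh.write("adjacency_a\tadjacency_b\n")
        for a, b in res.conflicts:
            fh.write(f"{a}\t{b}\n")

    # gap closing demo: redundant head-to-tail flank with strong one-copy support
    s = random_seq(rng, 4000, 0.38)
    gapped = random_seq(rng, 3000, 0.38) + s + "N" * 100 + s + random_seq(rng, 3000, 0.38)
    cand = sc.find_redundant_gap_flanks(gapped, min_len=1000)
    decision = sc.resolve_gap(cand, one_copy_support=18, two_copy_support=2)
    closed = sc.close_gap(gapped, cand) if decision == "close_and_trim" else gapped
    ev = {"both": 0, "hic": 0, "map": 0}
    for l in res.linkages:
        ev[l.evidence] += 1
    print(f"{len(res.superscaffolds)} superscaffolds; linkage evidence {ev}; "
          f"{len(res.conflicts)} conflicts; gap candidate overlap "
          f"{cand.overlap} bp -> {decision}, closed length {len(closed):,} "
          f"(= {len(gapped):,} - 100 - {cand.overlap})")


if __name__ == "__main__":
    main()
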
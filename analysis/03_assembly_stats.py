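#!/usr/bin/env python
"""Assembly QC of the simulated reference: Nxx, feature/GC tracks, telomere
and centromere detection, and an in silico PCR check of unique markers.

Writes tables to results/asmstats/.
"""

from pathlib import Path

import numpy as np

from wildsoy import asmstats, io as wio
from wildsoy.util import random_seq, revcomp

GEN = Path("results/genomes")
OUT = Path("results/asmstats")
SEED = 321


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = wio.read_fasta(GEN / "reference.fa")
    te = wio.read_bed(GEN / "reference_te.bed")
    rng = np.random.default_rng(SEED)

    lengths = [len(s) for s in genome.values()]
    n50, n90 = asmstats.nxx(lengths, 50), asmstats.nxx(lengths, 90)

    with open(OUT / "repeat_track.bedgraph", "w") as fh:
        for chrom, seq in genome.items():
            for s, e, f, _partial in asmstats.window_track(
                    te.get(chrom, []), len(seq)):
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{f:.4f}\n")
    with open(OUT / "gc_track.bedgraph", "w") as fh:
        for chrom, seq in genome.items():
            for s, e, g in asmstats.gc_track(seq):
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{g:.4f}\n")

    # decorate chromosome ends with telomere arrays on a copy, then detect
    telo_genome = {}
    monomer = random_seq(rng, 91, 0.4)
    for i, (chrom, seq) in enumerate(genome.items()):
        seq2 = "CCCTAAA" * 20 + seq if i != 1 else seq
        seq2 = seq2 + "TTTAGGG" * 20 if i != 2 else seq2
        mid = len(seq2) // 2
        seq2 = seq2[:mid] + monomer * 40 + seq2[mid:]
        telo_genome[chrom] = seq2
    with open(OUT / "telomeres_centromeres.tsv", "w") as fh:
        fh.write("chrom\ttelomere_status\tcentromere_intervals\n")
        for chrom, seq in telo_genome.items():
            st = asmstats.detect_telomeres(chrom, seq)
            cents = asmstats.detect_centromeric_repeats(seq, monomer)
            fh.write(f"{chrom}\t{st.category}\t"
                     + ";".join(f"{a}-{b}" for a, b in cents) + "\n")

    # unique-site markers: primer pairs lifted from the reference itself
    pairs = []
    for i in range(8):
        chrom = list(genome)[i % len(genome)]
        pos = 100_000 + i * 137_000
        seq = genome[chrom]
        pairs.append(asmstats.PrimerPair(
            f"ssr{i + 1}", seq[pos:pos + 20], revcomp(seq[pos + 400:pos + 420])))
    retained, rejected = asmstats.in_silico_pcr(genome, pairs)
    with open(OUT / "ispcr.tsv", "w") as fh:
        fh.write("pair\tstatus\tchrom\tproduct_bp\n")
        for p in pairs:
            if p.id in retained:
                h = retained[p.id]
                fh.write(f"{p.id}\tretained\t{h.chrom}\t{h.product_size}\n")
            else:
                fh.write(f"{p.id}\t{rejected[p.id]}\t.\t.\n")

    telo = [asmstats.detect_telomeres(c, s).category for c, s in telo_genome.items()]
    print(f"contig N50 {n50:,} bp, N90 {n90:,} bp; telomere status {telo}; "
          f"{len(retained)}/{len(pairs)} marker pairs retained")


if __name__ == "__main__":
    main()
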
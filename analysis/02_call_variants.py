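#!/usr/bin/env python
"""Align the simulated genome pair and call insertions, TE insertions,
TE-affected genes and large structural variants.

Reads results/genomes/ (run 01_simulate_genomes.py first); writes block,
insertion, SV and TE-affected-gene tables to results/variants/ and prints a
recovery summary against the planted truth.
"""

from pathlib import Path

from wildsoy import io as wio, synteny, variation

GEN = Path("results/genomes")
OUT = Path("results/variants")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = wio.read_fasta(GEN / "reference.fa")
    qry = wio.read_fasta(GEN / "query.fa")
    qry_te = wio.read_bed(GEN / "query_te.bed")
    genes = wio.read_gff3_genes(GEN / "reference_genes.gff3")
    truth = wio.read_truth_json(GEN / "truth.json")

    blocks = synteny.anchor_align(ref, qry, k=21)
    synteny.write_blocks_tsv(blocks, OUT / "blocks.tsv")

    pairs = synteny.pair_adjacent(blocks)
    calls = variation.call_insertions(pairs)
    calls = variation.classify_te_insertions(calls, qry_te)
    affected = variation.find_te_affected_genes(calls, genes)
    variation.write_insertions_tsv(calls, OUT / "insertions.tsv", affected)

    svs = variation.detect_large_svs(blocks, min_size=100_000)
    variation.write_svs_tsv(svs, OUT / "svs.tsv")

    planted = [e for e in truth["events"] if e["kind"].endswith("insertion")]
    recovered = sum(
        1 for e in planted
        if any(c.qry_chrom == e["qry_chrom"] and abs(c.qry_start - e["qry_start"]) <= 21
               for c in calls))
    n_te = sum(1 for c in calls if c.is_te_insertion)
    print(f"{len(blocks)} alignment blocks; {len(calls)} insertion calls "
          f"({recovered}/{len(planted)} planted recovered, {n_te} classified TE); "
          f"{len(svs)} large SVs "
          f"({[s.kind for s in svs]})")


if __name__ == "__main__":
    main()
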
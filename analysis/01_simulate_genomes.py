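#!/usr/bin/env python
"""Simulate the wild/cultivated genome pair with planted structural events.

Writes the reference genome (FASTA + GFF3 genes + BED TEs), the derived
query genome, the query-side TE annotation, and the planted-truth JSON to
results/genomes/.
"""

from pathlib import Path

from wildsoy import io as wio, scenes

OUT = Path("results/genomes")
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref, plan, qry, truth = scenes.sv_benchmark_scene(SEED)

    wio.write_fasta(ref.genome, OUT / "reference.fa")
    wio.write_fasta(qry, OUT / "query.fa")
    wio.write_gff3_genes(ref.gene_intervals, OUT / "reference_genes.gff3")
    wio.write_bed(ref.te_intervals, OUT / "reference_te.bed")
    wio.write_bed(truth.qry_te_intervals, OUT / "query_te.bed")
    wio.write_truth_json({
        "events": [{
            "kind": e.event.kind, "chrom": e.event.chrom, "pos": e.event.pos,
            "length": e.event.length, "te_fraction": e.event.te_fraction,
            "qry_chrom": e.qry_chrom, "qry_start": e.qry_start,
            "qry_end": e.qry_end} for e in truth.events],
        "n_background_snps": truth.n_snps,
    }, OUT / "truth.json")
    print(f"wrote genome pair ({sum(map(len, qry.values())):,} bp query, "
          f"{truth.n_snps:,} background SNPs, {len(plan.events)} planted events) "
          f"to {OUT}/")


if __name__ == "__main__":
    main()
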
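#!/usr/bin/env python
"""Optical-map workflow: digest the reference, simulate noisy molecules,
apply molecule QC and label merging, realign molecules, and screen a target
region for >= 30x molecule support.

Writes CMAP/TSV outputs to results/omap/.
"""

from pathlib import Path

from wildsoy import io as wio, omap, synthdata as sd

GEN = Path("results/genomes")
OUT = Path("results/omap")
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = wio.read_fasta(GEN / "reference.fa")
    chrom = next(iter(genome))
    seq = genome[chrom][:1_500_000]   # one contig-sized region at ~60x molecule coverage
    raw = omap.digest(seq, omap.NICKING_MOTIFS["Nt.BspQI"], map_id="1")
    contig = omap.merge_labels(raw)
    omap.write_cmap([contig], OUT / "reference.cmap")

    mols, _truth = sd.simulate_optical_molecules(
        contig, 400, (120_000, 350_000), label_fn_rate=0.05,
        label_fp_rate_per_100kb=0.5, sizing_sd=300,
        intensity_dist=(0.45, 0.12), seed=SEED)
    omap.write_molecules_tsv(mols, OUT / "molecules_raw.tsv")

    retained, removed = omap.qc_filter_molecules(mols)
    with open(OUT / "molecule_qc.tsv", "w") as fh:
        fh.write("molecule\tstatus\treasons\n")
        for m in retained:
            fh.write(f"{m.id}\tretained\t.\n")
        for m, reasons in removed:
            fh.write(f"{m.id}\tremoved\t{','.join(reasons)}\n")

    merged = [omap.merge_labels(m) for m in retained]
    maps_ok, maps_rep = omap.filter_repetitive_maps(merged)

    alignments = []
    for m in maps_ok:
        if m.n_labels < 2:
            continue
        al = omap.align_maps(contig, m, sizing_tolerance=900)
        alignments.append(al)
    with open(OUT / "alignments.tsv", "w") as fh:
        fh.write("ref\tmolecule\torientation\tmatched\tref_skips\tqry_skips\tref_span\n")
        for al in alignments:
            fh.write(f"{al.ref_id}\t{al.qry_id}\t{al.orientation}\t{len(al.pairs)}\t"
                     f"{al.ref_skips}\t{al.qry_skips}\t"
                     f"{al.qry_span_on_ref[0]}-{al.qry_span_on_ref[1]}\n")

    mid = (1_000_000, 1_050_000)        # interior region, well covered
    edge = (1, 50_000)                  # terminal region, few spanning molecules
    msg = []
    for region in (mid, edge):
        depth, ok = omap.region_coverage(alignments, contig.id, region)
        msg.append(f"region {region[0] // 1000}-{region[1] // 1000} Kb depth "
                   f"{depth} -> {'retained' if ok else 'excluded'}")
    print(f"{contig.n_labels} labels on {chrom}; {len(retained)}/{len(mols)} "
          f"molecules pass QC, {len(maps_rep)} repetitive maps removed; "
          f"{len(alignments)} aligned; " + "; ".join(msg) + " (>=30 rule)")


if __name__ == "__main__":
    main()
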
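# Analysis drivers

Run in order from the repository root; each script prints a one-line
summary and writes its tables under `results/`.

    python analysis/01_simulate_genomes.py   # genome pair + planted truth
    python analysis/02_call_variants.py      # blocks, insertions, TE calls, SVs
    python analysis/03_assembly_stats.py     # Nxx, tracks, telomeres, e-PCR
    python analysis/04_optical_maps.py       # digestion, molecule QC, alignment
    python analysis/05_superscaffold.py      # evidence merging, gap closing
    python analysis/06_binmap_qtl.py         # binmap, LOD scan, permutations

Large regenerable outputs (the two ~10 MB FASTA genomes, the raw genotype
matrix) are not versioned; rerun 01 before 02 on a fresh checkout.
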
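"""Standard simulation scenarios used by the analysis scripts and tests.

The SV benchmark scene is the study's reference condition: a 10 Mb,
three-chromosome genome pair with five TE insertions whose TE fractions
straddle the 0.8 classification threshold, one reportable (150 Kb) and one
sub-threshold (90 Kb) inversion, a reciprocal tail swap between two
chromosomes, and a 0.002/bp SNP background. Insertion positions are shifted
into unique sequence (see ``synthdata.clear_position``) so every planted
breakpoint is well-defined at anchor resolution.
"""

from __future__ import annotations

from . import synthdata as sd

SV_SCENE_TE_FRACTIONS = [1.0, 0.85, 0.5, 0.81, 0.79]


def sv_benchmark_scene(seed: int, snp_rate: float = 0.002):
    """Build the standard genome pair. Returns (reference, plan, query, truth)."""
    ref = sd.generate_reference(3, [4_000_000, 3_000_000, 3_000_000], gc=0.35,
                                te_library_size=20, n_genes=150,
                                n_te_copies=90, seed=seed)
    nominal = [("chr1", 500_000, 1500), ("chr1", 1_500_000, 3000),
               ("chr2", 800_000, 2000), ("chr2", 1_800_000, 8000),
               ("chr3", 600_000, 5000)]
    events = [
        sd.PlannedEvent("te_insertion", c, sd.clear_position(ref, c, p, 2500),
                        length=L, te_element=i, te_fraction=SV_SCENE_TE_FRACTIONS[i])
        for i, (c, p, L) in enumerate(nominal)
    ]

    def clear_segment(chrom: str, pos: int, length: int) -> int:
        # both breakpoints of a segment event must sit in unique sequence
        for d in range(0, 50_000, 500):
            for p in (pos + d, pos - d):
                if (sd.clear_position(ref, chrom, p, 2500) == p
                        and sd.clear_position(ref, chrom, p + length, 2500) == p + length):
                    return p
        return pos

    events += [
        sd.PlannedEvent("inversion", "chr3",
                        clear_segment("chr3", 1_200_000, 150_000), length=150_000),
        sd.PlannedEvent("inversion", "chr3",
                        clear_segment("chr3", 2_200_000, 90_000), length=90_000),
        sd.PlannedEvent("inter_translocation", "chr1",
                        clear_segment("chr1", 3_200_000, 0),
                        chrom2="chr2", pos2=clear_segment("chr2", 2_200_000, 0)),
    ]
    plan = sd.SVPlan(events)
    qry, truth = sd.derive_variant_genome(ref, plan, snp_rate=snp_rate,
                                          seed=seed + 1)
    return ref, plan, qry, truth
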
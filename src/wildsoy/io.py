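"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; annotation intervals are written as GFF3
(genes, 1-based inclusive) and BED (TEs, 0-based half-open); genotype and
phenotype matrices as TSV; planted truth as JSON.
"""

from __future__ import annotations

import json

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    _ = width


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3_genes(genes: dict[str, list[tuple[int, int, str]]], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in genes:
            for s, e, gid in genes[chrom]:
                fh.write(f"{chrom}\twildsoy\tgene\t{s}\t{e}\t.\t+\t.\tID={gid}\n")


def read_gff3_genes(path) -> dict[str, list[tuple[int, int, str]]]:
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            gid = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv).get("ID", f[8])
            out.setdefault(f[0], []).append((int(f[3]), int(f[4]), gid))
    return out


def write_bed(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    """1-based inclusive intervals written as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom in intervals:
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.setdefault(f[0], []).append((int(f[1]) + 1, int(f[2])))
    return out


def write_genotypes_tsv(snp_chrom, snp_pos, genotypes: np.ndarray, path,
                        line_names: list[str] | None = None) -> None:
    n_lines = genotypes.shape[0]
    names = line_names or [f"RIL{i + 1:03d}" for i in range(n_lines)]
    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(names) + "\n")
        for j in range(len(snp_pos)):
            fh.write(f"{snp_chrom[j]}\t{snp_pos[j]}\t"
                     + "\t".join(genotypes[:, j]) + "\n")


def read_genotypes_tsv(path):
    chroms, pos, rows = [], [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = header[2:]
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chroms.append(f[0])
            pos.append(int(f[1]))
            rows.append(f[2:])
    geno = np.array(rows, dtype="<U1").T if rows else np.empty((len(names), 0), "<U1")
    return chroms, pos, geno, names


def write_phenotypes_tsv(phenotypes: np.ndarray, path,
                         line_names: list[str] | None = None,
                         trait: str = "trait") -> None:
    names = line_names or [f"RIL{i + 1:03d}" for i in range(len(phenotypes))]
    with open(path, "w") as fh:
        fh.write(f"line\t{trait}\n")
        for n, v in zip(names, phenotypes):
            fh.write(f"{n}\t{v:.6f}\n")


def read_phenotypes_tsv(path):
    names, vals = [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            names.append(f[0])
            vals.append(float(f[1]))
    return names, np.asarray(vals)


def write_truth_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(f"not serialisable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)


def read_truth_json(path):
    with open(path) as fh:
        return json.load(fh)
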
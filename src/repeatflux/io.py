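"""Readers and writers for the standard formats the pipeline touches:
FASTA assemblies, VCF de novo tables, and TSV rate/distribution tables."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Union

import pandas as pd
import pysam
from Bio import SeqIO

from .rate_estimation import MutationRecord
from .repeat_catalog import LengthDistribution, MotifClass

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Multi-record FASTA (plain or gzip) as a name -> sequence mapping."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as handle:
            return {rec.id: str(rec.seq).upper()
                    for rec in SeqIO.parse(handle, "fasta")}
    with open(path) as handle:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(contigs: Mapping[str, str], path: PathLike,
                width: int = 80) -> None:
    with open(path, "w") as out:
        for name, seq in contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def write_vcf(records: Iterable[MutationRecord],
              contigs: Mapping[str, str], path: PathLike) -> None:
    """Minimal single-sample VCF 4.2 (positions 1-based, indels anchored)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos))
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for name, seq in contigs.items():
            out.write(f"##contig=<ID={name},length={len(seq)}>\n")
        out.write('##INFO=<ID=PHASE,Number=1,Type=String,'
                  'Description="Parental phase">\n')
        out.write('##INFO=<ID=PROBAND,Number=1,Type=String,'
                  'Description="Proband id">\n')
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                  'Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
                  "\tFORMAT\tproband\n")
        for rec in recs:
            info = []
            if rec.phase:
                info.append(f"PHASE={rec.phase}")
            if rec.proband:
                info.append(f"PROBAND={rec.proband}")
            out.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}"
                      f"\t.\tPASS\t{';'.join(info) or '.'}\tGT\t0/1\n")


def read_vcf(path: PathLike) -> List[MutationRecord]:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt in rec.alts or ():
                records.append(MutationRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    proband=str(rec.info.get("PROBAND", "")),
                    phase=rec.info.get("PHASE")))
    return records


def write_distribution_tsv(dist: LengthDistribution, motif: MotifClass,
                           path: PathLike) -> None:
    rows = []
    total = dist.total()
    for L in sorted(dist.counts):
        rows.append({"motif": motif.unit, "length_units": L,
                     "length_nt": L * dist.unit_length,
                     "count": dist.counts[L],
                     "frequency": dist.counts[L] / total if total else 0.0})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_distribution_tsv(path: PathLike) -> LengthDistribution:
    frame = pd.read_csv(path, sep="\t")
    counts = {int(r["length_units"]): float(r["count"])
              for _, r in frame.iterrows()}
    unit = 1
    if len(frame):
        unit = int(frame["length_nt"].iloc[0] // max(frame["length_units"].iloc[0], 1))
    return LengthDistribution(counts, unit_length=max(unit, 1))
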
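"""Readers and writers for the pipeline's file formats.

Variants travel as per-sample VCF v4.2 (depth in INFO/DP, consequence and
transcript linkage in a CSQ-style INFO tag) or as a flat TSV; transcripts as
FASTA + GFF3; coverage as BED-anchored TSV; cohorts and ground truth as
TSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence annotation: class|consequence|transcript|cds_pos">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcfs(variants: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Write one VCF v4.2 per sample; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample, sub in variants.groupby("sample_id"):
        path = outdir / f"{sample}.vcf"
        with open(path, "w") as fh:
            fh.write(VCF_HEADER)
            for r in sub.sort_values(["chrom", "pos"]).itertuples(index=False):
                csq = "|".join(
                    str(x) if pd.notna(x) else ""
                    for x in (r.var_class, r.consequence, r.transcript_id, r.cds_pos)
                )
                fh.write(
                    f"{r.chrom}\t{r.pos}\t{r.mutation_id}\t{r.ref}\t{r.alt}\t.\t.\t"
                    f"DP={r.depth};CSQ={csq}\n"
                )
        paths.append(path)
    return paths


def read_vcf_dir(vcf_dir: str | Path) -> pd.DataFrame:
    """Read every per-sample ``*.vcf`` in a directory back into one table."""
    import pysam

    rows = []
    for path in sorted(Path(vcf_dir).glob("*.vcf")):
        sample = path.stem
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                var_class, consequence, transcript_id, cds_pos = (
                    str(rec.info.get("CSQ", "|||")).split("|")
                )
                rows.append(
                    {
                        "sample_id": sample, "chrom": rec.chrom, "pos": rec.pos,
                        "ref": rec.ref, "alt": rec.alts[0],
                        "depth": int(rec.info["DP"]),
                        "var_class": var_class, "consequence": consequence,
                        "transcript_id": transcript_id or None,
                        "cds_pos": int(cds_pos) if cds_pos else None,
                        "mutation_id": rec.id,
                    }
                )
    return pd.DataFrame(rows)


def write_transcripts(transcripts, genome: Mapping[str, str], outdir: str | Path) -> None:
    """Write CDS FASTA, genome FASTA and a GFF3 exon table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        [SeqRecord(Seq(t.cds_sequence), id=t.transcript_id,
                   description=f"gene={t.gene_id}") for t in transcripts],
        outdir / "cds.fasta", "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()],
        outdir / "genome.fasta", "fasta",
    )
    with open(outdir / "transcripts.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            lo = t.exon_intervals[0][0] + 1
            hi = t.exon_intervals[-1][1]
            fh.write(
                f"{t.chrom}\tmmrsclc\tmRNA\t{lo}\t{hi}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};gene_id={t.gene_id}\n"
            )
            for i, (s, e) in enumerate(t.exon_intervals):
                floxed = t.is_floxed_gene and i == t.floxed_exon_index
                fh.write(
                    f"{t.chrom}\tmmrsclc\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={t.exon_ids[i]};Parent={t.transcript_id};"
                    f"floxed={'true' if floxed else 'false'}\n"
                )


def write_coverage(exon_counts: pd.DataFrame, per_base: pd.DataFrame,
                   outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exon_counts.to_csv(outdir / "exon_counts.tsv", sep="\t", index=False)
    per_base.to_csv(outdir / "per_base_coverage.tsv", sep="\t", index=False)


def write_blacklist(blacklist: Iterable[tuple[str, int, str, str]],
                    path: str | Path) -> None:
    df = pd.DataFrame(sorted(blacklist), columns=["chrom", "pos", "ref", "alt"])
    df.to_csv(path, sep="\t", index=False)


def read_blacklist(path: str | Path) -> set[tuple[str, int, str, str]]:
    df = pd.read_csv(path, sep="\t")
    return set(zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"]))


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
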
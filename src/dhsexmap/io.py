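"""Readers and writers for the pipeline's file formats.

VCF 4.2 (pysam) for SNP calls with per-sample GT and DP; TSV for the
contig x sample depth matrix and the linkage map; BED (0-based,
half-open) for the sex-linked region; GFF3 for gene models; FASTA
(Biopython) for CDS sequences; JSON for the simulation truth and run
reports.  Writers and readers round-trip: reading a written file
reconstructs the in-memory objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .variant_qc import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, SnpRecord

_GT_TO_TUPLE = {GT_HOM_REF: (0, 0), GT_HET: (0, 1), GT_HOM_ALT: (1, 1),
                GT_MISSING: (None, None)}


def write_vcf(records: list[SnpRecord], sample_names: list[str], path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write SNP records as an uncompressed VCF 4.2 with GT and DP."""
    header = pysam.VariantHeader()
    header.add_meta("source", "dhsexmap")
    contigs = sorted({r.contig for r in records})
    lengths = contig_lengths or {}
    for c in contigs:
        header.contigs.add(c, length=lengths.get(c, 2_000_000_000))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in sample_names:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in sorted(records, key=lambda r: (r.contig, r.pos)):
            if rec.genotypes.size != len(sample_names):
                raise InputError(
                    f"{rec.contig}:{rec.pos}: genotype vector does not match sample list")
            row = vf.new_record(contig=rec.contig, start=rec.pos - 1,
                                stop=rec.pos - 1 + len(rec.ref),
                                alleles=(rec.ref, rec.alt), qual=rec.qual)
            for i, s in enumerate(sample_names):
                row.samples[s]["GT"] = _GT_TO_TUPLE[int(rec.genotypes[i])]
                row.samples[s]["DP"] = int(rec.depths[i])
            vf.write(row)


def read_vcf(path: str | Path) -> tuple[list[SnpRecord], list[str]]:
    """Read a VCF with GT/DP into SNP records; QUAL is the site score."""
    records = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for row in vf:
            alts = row.alts or ()
            n_alleles = 1 + len(alts)
            alt = alts[0] if alts else "."
            is_indel = any(len(a) != len(row.ref) for a in alts)
            gts = np.full(len(samples), GT_MISSING, dtype=np.int8)
            dps = np.zeros(len(samples), dtype=np.int32)
            for i, s in enumerate(samples):
                call = row.samples[s]
                gt = call.get("GT")
                if gt is not None and None not in gt:
                    nalt = sum(1 for a in gt if a and a > 0)
                    gts[i] = (GT_HOM_REF, GT_HET, GT_HOM_ALT)[min(nalt, 2)]
                dp = call.get("DP")
                dps[i] = 0 if dp is None else int(dp)
            records.append(SnpRecord(
                contig=row.contig, pos=row.pos, ref=row.ref, alt=str(alt),
                n_alleles=n_alleles, genotypes=gts, depths=dps,
                qual=float(row.qual if row.qual is not None else 0.0),
                is_indel=is_indel))
    return records, samples


def write_depth_tsv(depth: pd.DataFrame, path: str | Path) -> None:
    depth.to_csv(path, sep="\t", index_label="contig", float_format="%.6g")


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="contig")


def write_bed(intervals: list[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (chrom, start, end, name) intervals; BED is 0-based half-open."""
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end", "name"])
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"])
    return [(str(r.chrom), int(r.start), int(r.end), str(r.name))
            for r in df.itertuples()]


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models (gene_id, chrom, start_bp, end_bp, hemizygous) as
    GFF3 gene features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g['gene_id']};hemizygous={str(bool(g['hemizygous'])).lower()}"
            fh.write("\t".join([
                str(g["chrom"]), "dhsexmap", "gene",
                str(int(g["start_bp"]) + 1), str(int(g["end_bp"])),
                ".", "+", ".", attrs]) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene features back into the gene-model table."""
    import gffutils
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append({"gene_id": feat.id, "chrom": feat.seqid,
                     "start_bp": feat.start - 1, "end_bp": feat.end,
                     "hemizygous": feat.attributes.get("hemizygous", ["false"])[0] == "true"})
    return pd.DataFrame(rows)


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_map_tsv(linkage_map, path: str | Path) -> None:
    linkage_map.to_dataframe().to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON (sorted keys, fixed separators, trailing newline)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
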
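"""Readers and writers for the pipeline's plain-text interchange formats.

Variants travel as MAF-like TSV (patient, sample, class, chrom, 1-based
pos, ref, alt, vaf, gene, cosmic_count); references as FASTA; count
matrices as genes x samples TSV with a sample-metadata TSV; gene sets
and target maps as GMT; survival tables as TSV.  Every writer
round-trips losslessly through the corresponding reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionStudy
from .spectrum import VariantRecord

VARIANT_COLUMNS = [
    "patient",
    "sample",
    "class",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vaf",
    "gene",
    "cosmic_count",
]


def write_fasta(reference: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def variants_to_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient": v.patient,
            "sample": v.sample,
            "class": v.lesion_class,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "vaf": v.vaf,
            "gene": v.gene,
            "cosmic_count": v.cosmic_count,
        }
        for v in variants
    ]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def frame_to_variants(frame: pd.DataFrame) -> list[VariantRecord]:
    out = []
    for r in frame.to_dict("records"):
        out.append(
            VariantRecord(
                patient=str(r["patient"]),
                sample=str(r["sample"]),
                lesion_class=str(r["class"]),
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                ref=str(r["ref"]),
                alt=str(r["alt"]),
                vaf=None if pd.isna(r["vaf"]) else float(r["vaf"]),
                gene=None if pd.isna(r["gene"]) else str(r["gene"]),
                cosmic_count=None
                if pd.isna(r["cosmic_count"])
                else int(r["cosmic_count"]),
            )
        )
    return out


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    variants_to_frame(variants).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_variants(path: str | Path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return frame_to_variants(frame)


def write_study(study: ExpressionStudy, counts_path: str | Path,
                metadata_path: str | Path) -> None:
    counts = study.counts.copy()
    counts.index.name = "gene"
    counts.to_csv(counts_path, sep="\t")
    meta = study.metadata.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")


def read_study(counts_path: str | Path, metadata_path: str | Path) -> ExpressionStudy:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    counts.index.name = None
    counts.columns.name = None
    metadata.index.name = "sample"
    return ExpressionStudy(counts=counts, metadata=metadata)


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *sorted(map(str, genes))]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def write_survival(survival: pd.DataFrame, path: str | Path) -> None:
    out = survival.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_survival(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
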